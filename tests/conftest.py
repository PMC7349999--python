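import numpy as np
import pytest

import ldrkit as lk
from ldrkit.synthetic_data import SimConfig, generate


@pytest.fixture(scope="session")
def small_dataset():
    """A small noisy ensemble shared across read-only tests."""
    return generate(SimConfig(n_proteins=8, n_chains_range=(5, 10), seed=3))


@pytest.fixture(scope="session")
def small_stacks(small_dataset):
    ds = small_dataset
    return lk.build_stacks(ds.observations, ds.segments, ds.sequences)


def make_stack(rows: list[str], protein_id: str = "P1", sequence: str | None = None):
    """Build a ProteinTrackStack from per-track state strings over {O,M,N}."""
    L = len(rows[0])
    seq = sequence or "A" * L
    tracks = np.array([list(r) for r in rows], dtype="U1")
    ids = [(f"S{i}", "A") for i in range(len(rows))]
    return lk.ProteinTrackStack(protein_id=protein_id, sequence=seq,
                                tracks=tracks, track_ids=ids)


def make_track(states: str, rule: str = "majority", protein_id: str = "P1"):
    """ConsensusTrack with coverage 1 everywhere except U positions."""
    cov = np.array([0 if s == "U" else 1 for s in states])
    return lk.ConsensusTrack(protein_id=protein_id, rule=rule,
                             states=states, coverage=cov)
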