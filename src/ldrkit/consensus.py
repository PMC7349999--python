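"""Protein-level disorder consensus from multi-chain missing-residue tracks.

Different crystal structures of the same protein routinely disagree about
which residues are missing.  Two consensus rules combine the per-chain
votes into a single per-position call over ``{D, S, U}``:

majority
    a position is disordered (``D``) when it is missing in more than
    ``majority_fraction`` (default strictly more than 50%) of the chains
    covering it;
zero
    a position is disordered only when it is missing in *every* covering
    chain.

Positions covered by no chain are unknown (``U``) under both rules and are
excluded from every downstream decision.  Maximal runs of consecutive
``D`` — broken by ``S`` and by ``U`` — of at least ``ldr_min_len``
residues (default 30) are long disordered regions (LDRs); runs of
``sdr_min_len`` (default 5) up to ``ldr_min_len - 1`` are short disordered
regions (SDRs).  Subtracting the zero consensus from a majority LDR
exposes sub-intervals that are structured in at least one chain —
candidate folding-upon-binding or context-dependent segments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import groupby

import numpy as np

from .ingest import MISSING, NOT_COVERED, ProteinTrackStack

DISORDERED = "D"
STRUCTURED = "S"
UNKNOWN = "U"

CATEGORY_LDR = "LDR-protein"
CATEGORY_SDR = "SDR-protein"
CATEGORY_STRUCTURED = "structured"

__all__ = [
    "ConsensusConfig",
    "ConsensusTrack",
    "Region",
    "ProteinClass",
    "LdrZeroComparison",
    "majority_consensus",
    "zero_consensus",
    "extract_regions",
    "classify_protein",
    "consensus_difference",
    "write_consensus_tsv",
    "write_regions_tsv",
]


@dataclass(frozen=True)
class ConsensusConfig:
    """Thresholds governing consensus calling and region extraction.

    ldr_min_len
        minimum run length (residues) for a long disordered region.
    sdr_min_len
        minimum run length for a short disordered region; shorter runs are
        discarded.
    majority_fraction
        a position is majority-disordered when missing_votes / covering_votes
        is strictly greater than this fraction.
    tail_fraction
        fraction of the protein length counted as an N-/C-terminal tail for
        region localization.
    fully_disordered_fraction
        minimum consensus disorder content for a protein to be called fully
        disordered.
    """

    ldr_min_len: int = 30
    sdr_min_len: int = 5
    majority_fraction: float = 0.5
    tail_fraction: float = 0.2
    fully_disordered_fraction: float = 0.7

    def __post_init__(self) -> None:
        if not 0 < self.sdr_min_len < self.ldr_min_len:
            raise ValueError("require 0 < sdr_min_len < ldr_min_len")
        if not 0 < self.majority_fraction < 1:
            raise ValueError("majority_fraction must be in (0, 1)")
        if not 0 < self.tail_fraction < 0.5:
            raise ValueError("tail_fraction must be in (0, 0.5)")
        if not 0 < self.fully_disordered_fraction <= 1:
            raise ValueError("fully_disordered_fraction must be in (0, 1]")


DEFAULT_CONFIG = ConsensusConfig()


@dataclass
class ConsensusTrack:
    """Per-position consensus states with the number of covering chains."""

    protein_id: str
    rule: str
    states: str
    coverage: np.ndarray

    def __post_init__(self) -> None:
        self.coverage = np.asarray(self.coverage, dtype=int)
        if len(self.states) != self.coverage.shape[0]:
            raise ValueError("states and coverage lengths differ")
        u = np.frombuffer(self.states.encode(), dtype="S1") == UNKNOWN.encode()
        if not np.array_equal(u, self.coverage == 0):
            raise ValueError("state U must coincide exactly with zero coverage")

    @property
    def length(self) -> int:
        return len(self.states)

    @property
    def n_disordered(self) -> int:
        return self.states.count(DISORDERED)

    def disorder_content(self, exclude_unknown: bool = False) -> float:
        denom = self.length - (self.states.count(UNKNOWN) if exclude_unknown else 0)
        if denom == 0:
            raise ValueError(f"{self.protein_id}: no evaluable positions")
        return self.n_disordered / denom


@dataclass(frozen=True)
class Region:
    """A 1-based inclusive disordered interval on the protein sequence.

    ``region_class`` is ``"LDR"`` (length >= ldr_min_len), ``"SDR"``
    (sdr_min_len <= length < ldr_min_len) or ``None`` for sub-threshold
    intervals, which only appear in consensus-difference output.
    """

    protein_id: str
    rule: str
    start: int
    end: int
    region_class: str | None

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"bad region interval {self.start}-{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class ProteinClass:
    protein_id: str
    category: str  # CATEGORY_LDR | CATEGORY_SDR | CATEGORY_STRUCTURED
    fully_disordered: bool


def _counts(stack: ProteinTrackStack) -> tuple[np.ndarray, np.ndarray]:
    covered = stack.tracks != NOT_COVERED
    miss = stack.tracks == MISSING
    return covered.sum(axis=0), miss.sum(axis=0)


def _assemble(states: np.ndarray, coverage: np.ndarray, stack, rule) -> ConsensusTrack:
    return ConsensusTrack(
        protein_id=stack.protein_id,
        rule=rule,
        states="".join(states),
        coverage=coverage,
    )


def majority_consensus(stack: ProteinTrackStack,
                       cfg: ConsensusConfig = DEFAULT_CONFIG) -> ConsensusTrack:
    """Call each position D when missing in more than ``majority_fraction``
    of its covering chains, S otherwise, U when no chain covers it.

    The per-position denominator is the number of chains covering that
    position (uncovered cells do not vote), so an exact 50% split is S.
    """
    c, m = _counts(stack)
    states = np.where(c == 0, UNKNOWN,
                      np.where(m > cfg.majority_fraction * c, DISORDERED, STRUCTURED))
    return _assemble(states, c, stack, "majority")


def zero_consensus(stack: ProteinTrackStack,
                   cfg: ConsensusConfig = DEFAULT_CONFIG) -> ConsensusTrack:
    """Call a position D only when it is missing in every covering chain."""
    c, m = _counts(stack)
    states = np.where(c == 0, UNKNOWN,
                      np.where(m == c, DISORDERED, STRUCTURED))
    return _assemble(states, c, stack, "zero")


def extract_regions(track: ConsensusTrack,
                    cfg: ConsensusConfig = DEFAULT_CONFIG) -> list[Region]:
    """Maximal runs of consecutive D, classified by length.

    Runs are broken by S and by U (disorder is never asserted across
    uncovered sequence).  Runs shorter than ``sdr_min_len`` are discarded.
    Regions are returned sorted by start position.
    """
    regions = []
    pos = 1
    for state, run in groupby(track.states):
        n = sum(1 for _ in run)
        if state == DISORDERED and n >= cfg.sdr_min_len:
            cls = "LDR" if n >= cfg.ldr_min_len else "SDR"
            regions.append(Region(track.protein_id, track.rule, pos, pos + n - 1, cls))
        pos += n
    return regions


def classify_protein(regions: list[Region], track: ConsensusTrack,
                     cfg: ConsensusConfig = DEFAULT_CONFIG) -> ProteinClass:
    """Protein category from its best region class, plus the
    fully-disordered flag (consensus disorder content over the full length
    reaching ``fully_disordered_fraction``)."""
    classes = {r.region_class for r in regions}
    if "LDR" in classes:
        category = CATEGORY_LDR
    elif "SDR" in classes:
        category = CATEGORY_SDR
    else:
        category = CATEGORY_STRUCTURED
    fully = track.n_disordered / track.length >= cfg.fully_disordered_fraction
    return ProteinClass(track.protein_id, category, fully)


@dataclass(frozen=True)
class LdrZeroComparison:
    """One majority LDR compared against the zero consensus.

    ``differences`` holds the maximal sub-intervals of the majority LDR
    whose positions are S under the zero rule — disordered in more than
    half of the chains but structured in at least one.  ``confirmed`` is
    true when the majority LDR contains a full zero-consensus LDR within
    its span.
    """

    majority_region: Region
    differences: tuple[Region, ...]
    confirmed: bool


def consensus_difference(
    majority_regions: list[Region],
    zero_track: ConsensusTrack,
    cfg: ConsensusConfig = DEFAULT_CONFIG,
) -> list[LdrZeroComparison]:
    """Subtract the zero consensus from each majority LDR.

    Only regions with ``region_class == "LDR"`` are compared.  Difference
    intervals are reported whatever their length (class by the usual
    thresholds, ``None`` below ``sdr_min_len``) because even short
    structured-in-one-chain stretches carry the mixture signal.
    """
    zero_ldrs = [r for r in extract_regions(zero_track, cfg) if r.region_class == "LDR"]
    out = []
    for reg in majority_regions:
        if reg.region_class != "LDR":
            continue
        span = zero_track.states[reg.start - 1 : reg.end]
        diffs = []
        pos = reg.start
        for state, run in groupby(span):
            n = sum(1 for _ in run)
            if state == STRUCTURED:
                if n >= cfg.ldr_min_len:
                    cls = "LDR"
                elif n >= cfg.sdr_min_len:
                    cls = "SDR"
                else:
                    cls = None
                diffs.append(Region(reg.protein_id, "difference", pos, pos + n - 1, cls))
            pos += n
        confirmed = any(z.start >= reg.start and z.end <= reg.end for z in zero_ldrs)
        out.append(LdrZeroComparison(reg, tuple(diffs), confirmed))
    return out


# --------------------------------------------------------------------------
# tabular output
# --------------------------------------------------------------------------

def write_consensus_tsv(protein_id: str, sequence: str,
                        majority: ConsensusTrack, zero: ConsensusTrack,
                        path) -> None:
    """Per-position TSV: protein_id, position, residue, majority_state,
    zero_state, coverage."""
    import pandas as pd

    df = pd.DataFrame({
        "protein_id": protein_id,
        "position": np.arange(1, len(sequence) + 1),
        "residue": list(sequence),
        "majority_state": list(majority.states),
        "zero_state": list(zero.states),
        "coverage": majority.coverage,
    })
    df.to_csv(path, sep="\t", index=False)


def write_regions_tsv(regions: list[Region], path) -> None:
    import pandas as pd

    rows = [(r.protein_id, r.rule, r.start, r.end, r.length, r.region_class or "sub")
            for r in regions]
    pd.DataFrame(rows, columns=["protein_id", "rule", "start", "end",
                                "length", "class"]).to_csv(path, sep="\t", index=False)
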