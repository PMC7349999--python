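"""Synthetic multi-chain structure ensembles with known disorder ground truth.

Each simulated protein carries a segment architecture over three states —
disordered, structured and uncrystallized — and is observed by several
independent chains.  Chains never cover uncrystallized segments (those
positions end up unknown at the consensus level, emulating construct
design), may be trimmed at the construct termini, and report each covered
position as missing with a state-conditional probability
(``p_miss_given_disordered`` above one half, ``p_miss_given_structured``
below it, so the majority vote can recover the truth).

The generator emits every input format the pipeline ingests — PDB and
mmCIF structure files, the tabular observation dialect, mapping TSV,
FASTA sequences, per-residue prediction tracks, per-structure quality
records and an OBO + GAF pair with a planted enriched term — so each
stage is testable without downloads.  All sampling is driven by one seed;
per-protein substreams are derived from (seed, protein index) so datasets
are stable when only ``n_proteins`` changes.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.SeqUtils import seq3

from .consensus import DISORDERED, STRUCTURED, UNKNOWN
from .ingest import (
    MISSING,
    OBSERVED,
    ChainObservation,
    MappingSegment,
    write_mapping_tsv,
    write_observations_tsv,
)
from .predictor_eval import PRED_DISORDERED, PRED_ORDERED, PredictionTrack

__all__ = [
    "PredictorSpec",
    "SimConfig",
    "GroundTruth",
    "SyntheticDataset",
    "generate",
    "write_fixture_bundle",
    "to_pdb_text",
    "to_mmcif_text",
    "PLANTED_TERM",
]

# amino-acid frequencies: disorder-promoting composition for disordered
# segments, PDB-like background elsewhere
_AA = "ACDEFGHIKLMNPQRSTVWY"
_BG_FREQ = np.array([8.3, 1.4, 5.9, 6.8, 4.0, 7.3, 2.3, 5.7, 5.8, 9.5,
                     2.2, 4.2, 4.6, 3.8, 5.2, 6.5, 5.4, 6.9, 1.3, 3.4])
_DIS_FREQ = np.array([6.5, 0.5, 7.5, 10.0, 1.5, 8.5, 2.0, 2.5, 8.0, 5.0,
                      1.5, 4.0, 9.5, 6.5, 5.5, 9.5, 5.5, 4.0, 0.5, 1.5])
_BG_FREQ = _BG_FREQ / _BG_FREQ.sum()
_DIS_FREQ = _DIS_FREQ / _DIS_FREQ.sum()

PLANTED_TERM = "GO:9100012"


@dataclass(frozen=True)
class PredictorSpec:
    """A synthetic predictor defined by its per-residue error rates.

    ``miss_rate`` is P(predict ordered | truly disordered) (1 - recall in
    expectation); ``false_rate`` is P(predict disordered | not disordered).
    """

    name: str
    miss_rate: float
    false_rate: float


# defaults mirror the qualitative behaviour of missing-residue-trained
# predictors: high specificity, modest sensitivity
DEFAULT_PREDICTORS = (
    PredictorSpec("precise", miss_rate=0.70, false_rate=0.01),
    PredictorSpec("balanced", miss_rate=0.50, false_rate=0.10),
    PredictorSpec("sensitive", miss_rate=0.35, false_rate=0.20),
)


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic ensemble.

    Defaults: 50 proteins of 150-500 residues observed by 15 chains each,
    disordered positions missing with probability 0.9 and structured ones
    with 0.1, uncrystallized tails sized to leave roughly a third of the
    residues unknown.  ``architectures`` may pin explicit per-protein
    segment lists of ``(state, length)`` with state in ``{D, S, U}``.
    """

    n_proteins: int = 50
    length_range: tuple[int, int] = (150, 500)
    architectures: tuple[tuple[tuple[str, int], ...], ...] | None = None
    n_chains_range: tuple[int, int] = (15, 15)
    p_miss_given_disordered: float = 0.9
    p_miss_given_structured: float = 0.1
    trim_probability: float = 0.3
    trim_max: int = 10
    p_uncrystallized_tail: float = 0.7
    uncrystallized_len_range: tuple[int, int] = (30, 120)
    p_uncrystallized_internal: float = 0.15
    disordered_len_range: tuple[int, int] = (30, 80)
    p_short_disordered: float = 0.25
    short_disordered_len_range: tuple[int, int] = (5, 29)
    structured_len_range: tuple[int, int] = (40, 150)
    p_ldr_protein: float = 1.0
    p_second_ldr: float = 0.12
    predictors: tuple[PredictorSpec, ...] = DEFAULT_PREDICTORS
    quality_resolution_coupling: float = 0.0
    planted_term_target_rate: float = 0.8
    planted_term_background_rate: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_miss_given_disordered", "p_miss_given_structured",
                     "trim_probability", "p_uncrystallized_tail",
                     "p_uncrystallized_internal", "p_short_disordered",
                     "p_ldr_protein", "p_second_ldr", "planted_term_target_rate",
                     "planted_term_background_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.n_proteins < 1:
            raise ValueError("n_proteins must be positive")

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class GroundTruth:
    """True per-position states ('D'/'S'/'U') and the derived region list."""

    protein_id: str
    states: str
    regions: list[tuple[int, int, str]] = field(default_factory=list)
    # regions: (start, end, class) with class LDR | SDR | sub

    def __post_init__(self) -> None:
        if not self.regions:
            self.regions = _true_regions(self.states)

    def true_ldrs(self) -> list[tuple[int, int]]:
        return [(s, e) for s, e, c in self.regions if c == "LDR"]


def _true_regions(states: str, ldr_min: int = 30, sdr_min: int = 5):
    from itertools import groupby

    regions = []
    pos = 1
    for state, run in groupby(states):
        n = sum(1 for _ in run)
        if state == DISORDERED:
            cls = "LDR" if n >= ldr_min else ("SDR" if n >= sdr_min else "sub")
            regions.append((pos, pos + n - 1, cls))
        pos += n
    return regions


@dataclass
class SyntheticDataset:
    config: SimConfig
    ground_truths: dict[str, GroundTruth]
    sequences: dict[str, str]
    observations: list[ChainObservation]
    segments: list[MappingSegment]
    predictions: dict[str, list[PredictionTrack]]
    quality: pd.DataFrame
    annotations: dict[str, set[str]]
    ontology_obo: str

    def ldr_protein_ids(self) -> list[str]:
        return [pid for pid, gt in self.ground_truths.items() if gt.true_ldrs()]


# --------------------------------------------------------------------------
# architecture and sequence sampling
# --------------------------------------------------------------------------

def _ri(rng: np.random.Generator, lohi: tuple[int, int]) -> int:
    """Uniform integer on the inclusive range [lo, hi]."""
    return int(rng.integers(lohi[0], lohi[1] + 1))


def _random_architecture(rng: np.random.Generator, cfg: SimConfig) -> list[tuple[str, int]]:
    budget = _ri(rng, cfg.length_range)
    segs: list[tuple[str, int]] = []
    if rng.random() < cfg.p_uncrystallized_tail:
        n = min(_ri(rng, cfg.uncrystallized_len_range), budget // 3)
        if n:
            segs.append((UNKNOWN, n))
            budget -= n
    c_tail = 0
    if rng.random() < cfg.p_uncrystallized_tail:
        c_tail = min(_ri(rng, cfg.uncrystallized_len_range), budget // 3)
        budget -= c_tail

    state = STRUCTURED if rng.random() < 0.5 else DISORDERED
    long_placed = 0
    if rng.random() < cfg.p_ldr_protein:
        want_long = 2 if rng.random() < cfg.p_second_ldr else 1
        disorder_free = False
    else:
        want_long = 0
        # half of the LDR-free proteins carry no disordered segment at all
        disorder_free = rng.random() < 0.5
    core: list[tuple[str, int]] = []
    while budget > 0:
        if state == DISORDERED:
            if disorder_free:
                state = STRUCTURED
                continue
            if long_placed < want_long:
                n = _ri(rng, cfg.disordered_len_range)
                long_placed += 1
            elif rng.random() < cfg.p_short_disordered:
                n = _ri(rng, cfg.short_disordered_len_range)
            else:
                state = STRUCTURED
                continue
        else:
            n = _ri(rng, cfg.structured_len_range)
        n = min(n, budget)
        core.append((state, n))
        budget -= n
        state = DISORDERED if state == STRUCTURED else STRUCTURED
    # occasionally split the core with an internal uncrystallized gap so
    # multi-segment constructs are exercised
    if len(core) > 2 and rng.random() < cfg.p_uncrystallized_internal:
        cut = int(rng.integers(1, len(core)))
        gap = int(rng.integers(10, 40))
        core = core[:cut] + [(UNKNOWN, gap)] + core[cut:]
    segs.extend(core)
    if c_tail:
        segs.append((UNKNOWN, c_tail))
    return segs


def _states_from_architecture(arch) -> str:
    return "".join(state * n for state, n in arch)


def _sample_sequence(rng: np.random.Generator, states: str) -> str:
    aa = np.array(list(_AA))
    out = np.empty(len(states), dtype="U1")
    arr = np.array(list(states))
    for mask, freq in ((arr == DISORDERED, _DIS_FREQ), (arr != DISORDERED, _BG_FREQ)):
        k = int(mask.sum())
        if k:
            out[mask] = rng.choice(aa, size=k, p=freq)
    return "".join(out)


# --------------------------------------------------------------------------
# chain sampling
# --------------------------------------------------------------------------

def _crystallizable_intervals(states: str) -> list[tuple[int, int]]:
    intervals = []
    start = None
    for i, s in enumerate(states, start=1):
        if s != UNKNOWN and start is None:
            start = i
        elif s == UNKNOWN and start is not None:
            intervals.append((start, i - 1))
            start = None
    if start is not None:
        intervals.append((start, len(states)))
    return intervals


def _sample_chain(rng, cfg, pid, sid, states):
    intervals = [list(iv) for iv in _crystallizable_intervals(states)]
    if not intervals:
        raise ValueError(f"{pid}: architecture has no crystallizable residues")
    # construct trimming at the overall termini
    first, last = intervals[0], intervals[-1]
    if rng.random() < cfg.trim_probability:
        t = min(int(rng.integers(1, cfg.trim_max + 1)), first[1] - first[0] - 4)
        if t > 0:
            first[0] += t
    if rng.random() < cfg.trim_probability:
        t = min(int(rng.integers(1, cfg.trim_max + 1)), last[1] - last[0] - 4)
        if t > 0:
            last[1] -= t
    intervals = [iv for iv in intervals if iv[1] >= iv[0]]

    segs = []
    chain_states = []
    cursor = 1
    for a, b in intervals:
        n = b - a + 1
        segs.append(MappingSegment(sid, "A", cursor, cursor + n - 1, pid, a, b))
        p = np.where(np.array(list(states[a - 1:b])) == DISORDERED,
                     cfg.p_miss_given_disordered, cfg.p_miss_given_structured)
        miss = rng.random(n) < p
        chain_states.append("".join(MISSING if m else OBSERVED for m in miss))
        cursor += n
    year = int(rng.integers(1995, 2019))
    obs = ChainObservation(sid, "A", "".join(chain_states), release_year=year)
    return obs, segs


def _quality_row(rng, cfg, sid, missing_fraction, year):
    res = 1.2 + cfg.quality_resolution_coupling * missing_fraction \
        + rng.normal(1.0, 0.45)
    return {
        "structure_id": sid,
        "resolution": float(np.clip(res, 0.8, 6.0)),
        "r_free": float(np.clip(rng.normal(0.24, 0.035), 0.12, 0.45)),
        "clashscore": float(abs(rng.normal(5.0, 3.0))),
        "rama_outliers": float(abs(rng.normal(0.5, 0.5))),
        "rotamer_outliers": float(abs(rng.normal(2.0, 1.5))),
        "rsrz_outliers": float(abs(rng.normal(2.5, 1.5))),
        "year": year,
    }


# --------------------------------------------------------------------------
# ontology / annotations
# --------------------------------------------------------------------------

def _synthetic_obo() -> str:
    """A small three-namespace is_a ontology (synthetic ids, levels 0-5)."""
    ns_long = {"MF": "molecular_function", "BP": "biological_process",
               "CC": "cellular_component"}
    roots = {"MF": "GO:9100000", "BP": "GO:9200000", "CC": "GO:9300000"}
    lines = ["format-version: 1.2", "ontology: synthetic-go", ""]

    def term(tid, name, ns, parents):
        lines.append("[Term]")
        lines.append(f"id: {tid}")
        lines.append(f"name: {name}")
        lines.append(f"namespace: {ns_long[ns]}")
        for p in parents:
            lines.append(f"is_a: {p} ! parent")
        lines.append("")

    for ns, root in roots.items():
        term(root, f"{ns_long[ns]} root", ns, [])
        base = int(root[3:])
        # three level-1 branches, each with two level-2 children; one branch
        # continues down to level 5 to exercise the level filter
        for b in range(1, 4):
            t1 = f"GO:{base + 10 * b:07d}"
            term(t1, f"{ns} branch {b}", ns, [root])
            for c in range(1, 3):
                t2 = f"GO:{base + 10 * b + c:07d}"
                term(t2, f"{ns} branch {b} child {c}", ns, [t1])
        deep_parent = f"GO:{base + 11:07d}"  # a level-2 term
        for lvl in range(3, 6):
            tid = f"GO:{base + 100 + lvl:07d}"
            term(tid, f"{ns} deep level {lvl}", ns, [deep_parent])
            deep_parent = tid
        # a diamond: term with two paths of different length to the root
        term(f"GO:{base + 99:07d}", f"{ns} diamond", ns,
             [root, f"GO:{base + 10:07d}"])
    return "\n".join(lines)


def _sample_annotations(rng, cfg, ground_truths) -> dict[str, set[str]]:
    """Random leaf annotations per namespace plus a planted term enriched in
    proteins whose ground truth carries an LDR."""
    bases = {"MF": 9100000, "BP": 9200000, "CC": 9300000}
    leaf_pool = []
    for base in bases.values():
        leaf_pool += [f"GO:{base + 10 * b + c:07d}" for b in range(1, 4)
                      for c in range(1, 3)]
    annotations: dict[str, set[str]] = {}
    for pid, gt in ground_truths.items():
        k = int(rng.integers(1, 4))
        terms = set(rng.choice(leaf_pool, size=k, replace=False))
        rate = (cfg.planted_term_target_rate if gt.true_ldrs()
                else cfg.planted_term_background_rate)
        if rng.random() < rate:
            terms.add(PLANTED_TERM)
        annotations[pid] = terms
    return annotations


# --------------------------------------------------------------------------
# top-level generation
# --------------------------------------------------------------------------

def generate(cfg: SimConfig) -> SyntheticDataset:
    """Generate a full synthetic dataset under the given study conditions.

    Deterministic for a fixed config (byte-identical repeated runs); the
    per-protein substream is derived from ``(seed, protein_index)``.
    """
    ground_truths: dict[str, GroundTruth] = {}
    sequences: dict[str, str] = {}
    observations: list[ChainObservation] = []
    segments: list[MappingSegment] = []
    quality_rows = []
    predictions: dict[str, list[PredictionTrack]] = {
        spec.name: [] for spec in cfg.predictors
    }

    for i in range(cfg.n_proteins):
        rng = np.random.default_rng([cfg.seed, i])
        pid = f"SYNP{i:04d}"
        if cfg.architectures is not None:
            arch = list(cfg.architectures[i % len(cfg.architectures)])
        else:
            arch = _random_architecture(rng, cfg)
        states = _states_from_architecture(arch)
        if sum(n for s, n in arch if s != UNKNOWN) == 0:
            raise ValueError(f"{pid}: no crystallizable segment in architecture")
        ground_truths[pid] = GroundTruth(pid, states)
        sequences[pid] = _sample_sequence(rng, states)

        n_chains = int(rng.integers(cfg.n_chains_range[0],
                                    cfg.n_chains_range[1] + 1))
        for j in range(n_chains):
            sid = f"{pid}X{j:02d}"
            obs, segs = _sample_chain(rng, cfg, pid, sid, states)
            observations.append(obs)
            segments.extend(segs)
            frac = obs.n_missing / obs.seqres_length
            quality_rows.append(_quality_row(rng, cfg, sid, frac,
                                             obs.release_year))

        for spec in cfg.predictors:
            arr = np.array(list(states))
            truly_d = arr == DISORDERED
            u = rng.random(len(states))
            pred_d = np.where(truly_d, u >= spec.miss_rate, u < spec.false_rate)
            scores = np.where(pred_d, rng.uniform(0.5, 1.0, len(states)),
                              rng.uniform(0.0, 0.5, len(states)))
            predictions[spec.name].append(
                PredictionTrack(
                    pid, spec.name,
                    states="".join(PRED_DISORDERED if d else PRED_ORDERED
                                   for d in pred_d),
                    scores=scores,
                )
            )

    rng_global = np.random.default_rng([cfg.seed, 999983])
    annotations = _sample_annotations(rng_global, cfg, ground_truths)

    return SyntheticDataset(
        config=cfg,
        ground_truths=ground_truths,
        sequences=sequences,
        observations=observations,
        segments=segments,
        predictions=predictions,
        quality=pd.DataFrame(quality_rows),
        annotations=annotations,
        ontology_obo=_synthetic_obo(),
    )


# --------------------------------------------------------------------------
# structure-file rendering
# --------------------------------------------------------------------------

def _res3(aa: str) -> str:
    try:
        return seq3(aa).upper()
    except KeyError:
        return "UNK"


def to_pdb_text(structure_id: str, chains: list[tuple[str, str, str]],
                release_year: int | None = None) -> str:
    """Render chains as PDB-format text with SEQRES, REMARK 465 and CA
    ATOM records for observed residues.

    ``chains`` is a list of (chain_id, sequence, states) with states over
    ``{O, M}``; author residue numbering equals the SEQRES position.
    """
    lines = []
    yy = (release_year or 2000) % 100
    date = f"01-JAN-{yy:02d}"
    lines.append("HEADER    " + f"{'SYNTHETIC PROTEIN':<40}" + f"{date:>9}"
                 + "   " + structure_id)
    lines.append(f"TITLE     SYNTHETIC DISORDER BENCHMARK ENTRY {structure_id}")

    missing_entries = []
    for chain_id, seq, states in chains:
        for i, s in enumerate(states, start=1):
            if s == MISSING:
                missing_entries.append((chain_id, i, _res3(seq[i - 1])))
    if missing_entries:
        lines.append("REMARK 465")
        lines.append("REMARK 465 MISSING RESIDUES")
        lines.append("REMARK 465 THE FOLLOWING RESIDUES WERE NOT LOCATED IN THE")
        lines.append("REMARK 465 EXPERIMENT. (M=MODEL NUMBER; RES=RESIDUE NAME;")
        lines.append("REMARK 465 C=CHAIN IDENTIFIER; SSSEQ=SEQUENCE NUMBER;")
        lines.append("REMARK 465 I=INSERTION CODE.)")
        lines.append("REMARK 465")
        lines.append("REMARK 465   M RES C SSSEQI")
        for chain_id, pos, res in missing_entries:
            lines.append(f"REMARK 465     {res:>3} {chain_id}{pos:6d}")

    for chain_id, seq, states in chains:
        res3s = [_res3(a) for a in seq]
        for k in range(0, len(res3s), 13):
            ser = k // 13 + 1
            chunk = " ".join(res3s[k:k + 13])
            lines.append(f"SEQRES {ser:3d} {chain_id}{len(seq):5d}  {chunk}")

    serial = 1
    for chain_id, seq, states in chains:
        for i, s in enumerate(states, start=1):
            if s != OBSERVED:
                continue
            x = 3.8 * i
            lines.append(
                f"ATOM  {serial:5d}  CA  {_res3(seq[i - 1]):>3} {chain_id}"
                f"{i:4d}    {x:8.3f}{0.0:8.3f}{0.0:8.3f}{1.0:6.2f}{20.0:6.2f}"
                f"           C"
            )
            serial += 1
        lines.append(f"TER   {serial:5d}")
        serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"


def to_mmcif_text(structure_id: str, chains: list[tuple[str, str, str]],
                  include_unobs: bool = True) -> str:
    """Render chains as mmCIF with ``_entity_poly_seq``, ``_struct_asym``,
    ``_atom_site`` and (optionally) ``_pdbx_unobs_or_zero_occ_residues``.

    With ``include_unobs=False`` the unobserved-residue category is left
    out, exercising the atom-site fallback in the reader.  Label and auth
    numbering coincide.
    """
    from gemmi import cif

    doc = cif.Document()
    block = doc.add_new_block(structure_id)
    block.set_pair("_entry.id", structure_id)

    loop = block.init_loop("_entity_poly_seq.", ["entity_id", "num", "mon_id"])
    for eid, (chain_id, seq, states) in enumerate(chains, start=1):
        for i, aa in enumerate(seq, start=1):
            loop.add_row([str(eid), str(i), _res3(aa)])

    loop = block.init_loop("_struct_asym.", ["id", "entity_id"])
    for eid, (chain_id, seq, states) in enumerate(chains, start=1):
        loop.add_row([chain_id, str(eid)])

    if include_unobs:
        loop = block.init_loop(
            "_pdbx_unobs_or_zero_occ_residues.",
            ["id", "PDB_model_num", "polymer_flag", "occupancy_flag",
             "auth_asym_id", "auth_comp_id", "auth_seq_id",
             "label_asym_id", "label_comp_id", "label_seq_id"],
        )
        n = 1
        for chain_id, seq, states in chains:
            for i, s in enumerate(states, start=1):
                if s == MISSING:
                    loop.add_row([str(n), "1", "Y", "1", chain_id,
                                  _res3(seq[i - 1]), str(i), chain_id,
                                  _res3(seq[i - 1]), str(i)])
                    n += 1

    loop = block.init_loop(
        "_atom_site.",
        ["group_PDB", "id", "type_symbol", "label_atom_id", "label_alt_id",
         "label_comp_id", "label_asym_id", "label_entity_id", "label_seq_id",
         "Cartn_x", "Cartn_y", "Cartn_z", "occupancy", "B_iso_or_equiv",
         "auth_seq_id", "auth_asym_id", "pdbx_PDB_model_num"],
    )
    serial = 1
    for eid, (chain_id, seq, states) in enumerate(chains, start=1):
        for i, s in enumerate(states, start=1):
            if s != OBSERVED:
                continue
            loop.add_row(["ATOM", str(serial), "C", "CA", ".",
                          _res3(seq[i - 1]), chain_id, str(eid), str(i),
                          f"{3.8 * i:.3f}", "0.000", "0.000", "1.00", "20.00",
                          str(i), chain_id, "1"])
            serial += 1
    return doc.as_string()


# --------------------------------------------------------------------------
# fixture bundle
# --------------------------------------------------------------------------

def _chain_view(ds: SyntheticDataset, obs: ChainObservation):
    """(chain_id, seqres_sequence, states) for one observation, derived from
    the mapping segments."""
    segs = sorted((s for s in ds.segments
                   if (s.structure_id, s.chain_id) == (obs.structure_id,
                                                       obs.chain_id)),
                  key=lambda s: s.chain_start)
    seq = "".join(ds.sequences[s.protein_id][s.protein_start - 1:s.protein_end]
                  for s in segs)
    return (obs.chain_id, seq, obs.states)


def write_fixture_bundle(ds: SyntheticDataset, directory) -> dict:
    """Write the dataset in every on-disk format the pipeline ingests.

    Produces per-structure PDB files, the tabular observation dialect,
    mapping TSV, FASTA sequences, prediction TSV, quality CSV, an OBO +
    GAF pair, a ground-truth TSV and a key-value manifest with the seed
    and config hash.  Returns the manifest as a dict.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    (directory / "structures").mkdir(exist_ok=True)

    for obs in ds.observations:
        chain = _chain_view(ds, obs)
        text = to_pdb_text(obs.structure_id, [chain], obs.release_year)
        (directory / "structures" / f"{obs.structure_id}.pdb").write_text(text)

    write_observations_tsv(ds.observations, directory / "observations.tsv")
    write_mapping_tsv(ds.segments, directory / "mapping.tsv")

    with open(directory / "sequences.fasta", "w") as fh:
        for pid in sorted(ds.sequences):
            fh.write(f">{pid}\n")
            seq = ds.sequences[pid]
            for k in range(0, len(seq), 60):
                fh.write(seq[k:k + 60] + "\n")

    from .predictor_eval import write_predictions_tsv
    write_predictions_tsv(ds.predictions, ds.sequences,
                          directory / "predictions.tsv")

    from .quality_corr import write_quality_csv
    write_quality_csv(ds.quality, directory / "quality.csv")

    (directory / "ontology.obo").write_text(ds.ontology_obo)
    gaf_lines = ["!gaf-version: 2.1"]
    for pid in sorted(ds.annotations):
        for term in sorted(ds.annotations[pid]):
            gaf_lines.append("\t".join([
                "SYNDB", pid, pid, "", term, "SYN:0000001", "IEA", "",
                "P", pid, "", "protein", "taxon:0", "20200101", "SYNDB",
                "", "",
            ]))
    (directory / "annotations.gaf").write_text("\n".join(gaf_lines) + "\n")

    with open(directory / "ground_truth.tsv", "w") as fh:
        fh.write("protein_id\tstates\tregions\n")
        for pid in sorted(ds.ground_truths):
            gt = ds.ground_truths[pid]
            regs = ";".join(f"{s}-{e}:{c}" for s, e, c in gt.regions)
            fh.write(f"{pid}\t{gt.states}\t{regs}\n")

    manifest = {
        "seed": ds.config.seed,
        "config_hash": ds.config.config_hash(),
        "n_proteins": ds.config.n_proteins,
        "n_structures": len(ds.observations),
    }
    with open(directory / "manifest.txt", "w") as fh:
        for k, v in manifest.items():
            fh.write(f"{k}={v}\n")
    return manifest
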