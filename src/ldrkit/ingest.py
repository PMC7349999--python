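"""Residue observation status from deposited X-ray structures.

Missing residues — SEQRES positions with no modeled atoms — are the
experimental proxy for intrinsic disorder used throughout this package.
This module reads them from legacy PDB files (SEQRES + REMARK 465) and
from mmCIF (``_entity_poly_seq`` + ``_pdbx_unobs_or_zero_occ_residues``,
with an ``_atom_site`` fallback), and maps per-chain observation tracks
onto protein (UniProt-style) coordinates through SIFTS-like segment
mappings.

Coordinates are 1-based inclusive everywhere: SEQRES positions, chain
construct positions and protein positions, matching PDB and UniProt
conventions.  Per-position states are single characters:

``O``
    observed (modeled) residue,
``M``
    missing residue (present in SEQRES, absent from the model),
``N``
    position of the protein not covered by the chain's crystallized
    construct.
"""

from __future__ import annotations

import logging
import re
from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from gemmi import cif

log = logging.getLogger(__name__)

OBSERVED = "O"
MISSING = "M"
NOT_COVERED = "N"

__all__ = [
    "ChainObservation",
    "MappingSegment",
    "ProteinTrackStack",
    "parse_pdb_missing",
    "parse_mmcif_missing",
    "build_stack",
    "build_stacks",
    "read_observations_tsv",
    "write_observations_tsv",
    "read_mapping_tsv",
    "write_mapping_tsv",
]


@dataclass(frozen=True)
class ChainObservation:
    """Per-chain observation track over SEQRES positions.

    ``states`` is a string over ``{O, M}`` whose i-th character (0-based)
    gives the status of SEQRES position i+1.  One deposited chain is one
    independent vote in the consensus, even when several chains belong to
    the same PDB entry.
    """

    structure_id: str
    chain_id: str
    states: str
    release_year: int | None = None

    def __post_init__(self) -> None:
        if not self.states:
            raise ValueError(f"{self.structure_id}/{self.chain_id}: empty states")
        bad = set(self.states) - {OBSERVED, MISSING}
        if bad:
            raise ValueError(
                f"{self.structure_id}/{self.chain_id}: invalid state chars {bad!r}"
            )

    @property
    def seqres_length(self) -> int:
        return len(self.states)

    @property
    def n_missing(self) -> int:
        return self.states.count(MISSING)

    def missing_positions(self) -> tuple[int, ...]:
        """1-based SEQRES positions flagged missing."""
        return tuple(i + 1 for i, s in enumerate(self.states) if s == MISSING)


@dataclass(frozen=True)
class MappingSegment:
    """Affine mapping of a contiguous chain interval onto protein coordinates.

    The chain interval ``[chain_start, chain_end]`` (SEQRES positions) maps
    residue-by-residue onto ``[protein_start, protein_end]``; both intervals
    are 1-based inclusive and must have equal length.
    """

    structure_id: str
    chain_id: str
    chain_start: int
    chain_end: int
    protein_id: str
    protein_start: int
    protein_end: int

    def __post_init__(self) -> None:
        if self.chain_start < 1 or self.protein_start < 1:
            raise ValueError(f"{self}: coordinates are 1-based, got start < 1")
        if self.chain_end < self.chain_start or self.protein_end < self.protein_start:
            raise ValueError(f"{self}: end precedes start")
        if self.chain_end - self.chain_start != self.protein_end - self.protein_start:
            raise ValueError(f"{self}: chain and protein intervals differ in length")

    @property
    def length(self) -> int:
        return self.chain_end - self.chain_start + 1


@dataclass
class ProteinTrackStack:
    """A protein sequence with aligned per-chain observation tracks.

    ``tracks`` is an ``(n_tracks, L)`` array of single characters over
    ``{O, M, N}``; ``track_ids`` records the contributing
    ``(structure_id, chain_id)`` pairs in row order.
    """

    protein_id: str
    sequence: str
    tracks: np.ndarray
    track_ids: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.tracks = np.asarray(self.tracks, dtype="U1")
        if self.tracks.ndim != 2:
            raise ValueError("tracks must be a 2-D (n_tracks, L) array")
        if self.tracks.shape[0] < 1:
            raise ValueError(f"{self.protein_id}: a stack needs at least one track")
        if self.tracks.shape[1] != len(self.sequence):
            raise ValueError(
                f"{self.protein_id}: track length {self.tracks.shape[1]} != "
                f"sequence length {len(self.sequence)}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def n_tracks(self) -> int:
        return int(self.tracks.shape[0])


# --------------------------------------------------------------------------
# PDB format (SEQRES + REMARK 465)
# --------------------------------------------------------------------------

_R465_SKIP = re.compile(r"(MISSING|FOLLOWING|EXPERIMENT|IDENTIFIER|SSSEQI|MODELS)")


def _parse_header_line(line: str) -> tuple[str | None, int | None]:
    """Extract (id_code, deposition_year) from a HEADER record."""
    sid = line[62:].strip() or None
    year = None
    m = re.search(r"\d{2}-[A-Z]{3}-(\d{2,4})", line)
    if m:
        y = int(m.group(1))
        if y < 100:  # two-digit PDB years pivot at 50
            y += 1900 if y >= 50 else 2000
        year = y
    return sid, year


def parse_pdb_missing(pdb_text: str, structure_id: str | None = None) -> list[ChainObservation]:
    """Read per-chain missing-residue tracks from PDB-format text.

    Every SEQRES position listed in REMARK 465 becomes ``M``, all other
    positions ``O``; chains without REMARK 465 entries are all-``O``.
    REMARK 465 author residue numbers are interpreted as 1-based SEQRES
    positions.  Entries that cannot be resolved to a SEQRES position
    (unknown chain, out-of-range number, unparsable fields) are rejected
    with a logged warning.  When REMARK 465 carries MODEL numbers only the
    first model is read (X-ray convention).

    Raises ``ValueError`` when the text contains no SEQRES records.
    """
    seqres_len: dict[str, int] = {}
    seqres_count: dict[str, int] = defaultdict(int)
    missing: dict[str, set[int]] = defaultdict(set)
    header_id: str | None = None
    year: int | None = None
    first_model: int | None = None

    for line in pdb_text.splitlines():
        rec = line[:6]
        if rec == "HEADER":
            header_id, year = _parse_header_line(line)
        elif rec == "SEQRES":
            chain = line[11]
            declared = int(line[13:17])
            prev = seqres_len.setdefault(chain, declared)
            if prev != declared:
                raise ValueError(f"chain {chain}: inconsistent SEQRES numRes")
            seqres_count[chain] += len(line[19:].split())
        elif rec == "REMARK" and line[7:10] == "465":
            body = line[10:].strip()
            if not body or _R465_SKIP.search(body):
                continue
            tokens = body.split()
            model = None
            if len(tokens) == 4 and tokens[0].lstrip("-").isdigit():
                model = int(tokens[0])
                tokens = tokens[1:]
            if len(tokens) != 3:
                continue
            resname, chain, seqnum = tokens
            if model is not None:
                if first_model is None:
                    first_model = model
                elif model != first_model:
                    continue
            # tolerate insertion codes glued to the number ("100A")
            num_part = seqnum.rstrip("ABCDEFGHIJKLMNOPQRSTUVWXYZ")
            try:
                pos = int(num_part)
            except ValueError:
                log.warning(
                    "REMARK 465 entry %r: unparsable residue number, skipped", body
                )
                continue
            missing[chain].add(pos)

    if not seqres_len:
        raise ValueError("no SEQRES records found: cannot define chain tracks")
    for chain, n in seqres_len.items():
        if seqres_count[chain] != n:
            raise ValueError(
                f"chain {chain}: SEQRES declares {n} residues, lists {seqres_count[chain]}"
            )

    sid = structure_id or header_id or "UNKNOWN"
    observations = []
    for chain, n in seqres_len.items():
        states = [OBSERVED] * n
        for pos in sorted(missing.get(chain, ())):
            if 1 <= pos <= n:
                states[pos - 1] = MISSING
            else:
                log.warning(
                    "%s/%s: REMARK 465 residue %d outside SEQRES 1..%d, skipped",
                    sid, chain, pos, n,
                )
        observations.append(
            ChainObservation(structure_id=sid, chain_id=chain,
                             states="".join(states), release_year=year)
        )
    for chain in missing:
        if chain not in seqres_len:
            log.warning("%s: REMARK 465 references unknown chain %r, skipped", sid, chain)
    return observations


# --------------------------------------------------------------------------
# mmCIF
# --------------------------------------------------------------------------

def _cif_int(value: str, context: str) -> int:
    if value in ("?", ".", ""):
        raise ValueError(f"{context}: missing numeric value")
    return int(value)


def parse_mmcif_missing(cif_text: str, structure_id: str | None = None) -> list[ChainObservation]:
    """Read per-chain missing-residue tracks from mmCIF text.

    Chain lengths and identities come from ``_entity_poly_seq`` joined with
    ``_struct_asym``.  Missing positions come from
    ``_pdbx_unobs_or_zero_occ_residues`` (unobserved rows only); when that
    category is absent the fallback marks as missing every declared position
    without a matching ``_atom_site`` row (first model).

    Raises ``ValueError`` for an empty polymer description or an
    unobserved-residue row whose position cannot be reconciled between
    label and author numbering.
    """
    doc = cif.read_string(cif_text)
    block = doc.sole_block()
    sid = structure_id or block.find_value("_entry.id") or block.name or "UNKNOWN"
    sid = cif.as_string(sid)

    entity_len: dict[str, int] = defaultdict(int)
    for row in block.find("_entity_poly_seq.", ["entity_id", "num"]):
        eid = row.str(0)
        entity_len[eid] = max(entity_len[eid], _cif_int(row.str(1), "_entity_poly_seq.num"))
    if not entity_len:
        raise ValueError(f"{sid}: no _entity_poly_seq rows — empty polymer description")

    chain_entity: dict[str, str] = {}
    for row in block.find("_struct_asym.", ["id", "entity_id"]):
        if row.str(1) in entity_len:
            chain_entity[row.str(0)] = row.str(1)
    if not chain_entity:
        # derive chains from atom_site when struct_asym is absent
        tab = block.find("_atom_site.", ["label_asym_id", "label_entity_id"])
        for row in tab:
            if row.str(1) in entity_len:
                chain_entity.setdefault(row.str(0), row.str(1))
    if not chain_entity:
        raise ValueError(f"{sid}: no polymer chains declared")

    missing: dict[str, set[int]] = {c: set() for c in chain_entity}
    unobs = block.get_mmcif_category("_pdbx_unobs_or_zero_occ_residues.")
    if unobs:
        n_rows = len(next(iter(unobs.values())))

        def cell(col: str, i: int) -> str | None:
            vals = unobs.get(col)
            if vals is None:
                return None
            v = vals[i]
            return None if v in (None, False, "?", ".") else str(v)

        for i in range(n_rows):
            occ = cell("occupancy_flag", i)
            if occ not in (None, "1"):
                continue  # zero-occupancy but modeled: not treated as missing
            chain = cell("label_asym_id", i) or cell("auth_asym_id", i)
            if chain not in missing:
                raise ValueError(f"{sid}: unobserved residue names unknown chain {chain!r}")
            raw = cell("label_seq_id", i) or cell("auth_seq_id", i)
            if raw is None:
                raise ValueError(
                    f"{sid}/{chain}: cannot reconcile label/auth numbering "
                    f"for unobserved residue row"
                )
            pos = _cif_int(raw, "unobs seq_id")
            n = entity_len[chain_entity[chain]]
            if not 1 <= pos <= n:
                raise ValueError(
                    f"{sid}/{chain}: unobserved residue {pos} outside 1..{n}"
                )
            missing[chain].add(pos)
    else:
        modeled: dict[str, set[int]] = {c: set() for c in chain_entity}
        tab = block.find("_atom_site.", ["label_asym_id", "label_seq_id",
                                         "?pdbx_PDB_model_num"])
        first_model: str | None = None
        for row in tab:
            if row.has(2):
                m = row.str(2)
                if first_model is None:
                    first_model = m
                elif m != first_model:
                    continue
            chain = row.str(0)
            if chain not in modeled or row.str(1) in ("?", "."):
                continue
            modeled[chain].add(int(row.str(1)))
        for chain, eid in chain_entity.items():
            n = entity_len[eid]
            missing[chain] = set(range(1, n + 1)) - modeled[chain]

    year = None
    dep = block.find_value("_pdbx_database_status.recvd_initial_deposition_date")
    if dep:
        m = re.match(r"(\d{4})", cif.as_string(dep))
        if m:
            year = int(m.group(1))

    observations = []
    for chain in sorted(chain_entity):
        n = entity_len[chain_entity[chain]]
        states = "".join(
            MISSING if i in missing[chain] else OBSERVED for i in range(1, n + 1)
        )
        observations.append(
            ChainObservation(structure_id=sid, chain_id=chain,
                             states=states, release_year=year)
        )
    return observations


# --------------------------------------------------------------------------
# chain -> protein mapping
# --------------------------------------------------------------------------

def build_stack(
    observations: list[ChainObservation],
    segments: list[MappingSegment],
    protein_id: str,
    sequence: str,
) -> ProteinTrackStack:
    """Project chain observation tracks onto protein coordinates.

    Each (structure, chain) pair in ``observations`` contributes exactly one
    track of length ``len(sequence)``.  Protein positions inside a mapping
    segment inherit O/M from the corresponding chain position via the affine
    offset; positions outside every segment of that chain are ``N``.

    Raises ``ValueError`` when two segments of one chain map onto
    overlapping protein (or chain) intervals, or when a segment exceeds the
    protein or chain bounds.
    """
    L = len(sequence)
    by_chain: dict[tuple[str, str], list[MappingSegment]] = defaultdict(list)
    for seg in segments:
        if seg.protein_id != protein_id:
            raise ValueError(f"segment {seg} does not reference protein {protein_id}")
        if seg.protein_end > L:
            raise ValueError(f"segment {seg} exceeds protein length {L}")
        by_chain[(seg.structure_id, seg.chain_id)].append(seg)

    for key, segs in by_chain.items():
        segs.sort(key=lambda s: s.protein_start)
        for a, b in zip(segs, segs[1:]):
            if b.protein_start <= a.protein_end:
                raise ValueError(
                    f"{key}: segments overlap on protein axis "
                    f"({a.protein_start}-{a.protein_end} vs {b.protein_start}-{b.protein_end})"
                )
        for a, b in zip(sorted(segs, key=lambda s: s.chain_start),
                        sorted(segs, key=lambda s: s.chain_start)[1:]):
            if b.chain_start <= a.chain_end:
                raise ValueError(f"{key}: segments overlap on chain axis")

    tracks = []
    track_ids = []
    for obs in observations:
        key = (obs.structure_id, obs.chain_id)
        row = np.full(L, NOT_COVERED, dtype="U1")
        for seg in by_chain.get(key, []):
            if seg.chain_end > obs.seqres_length:
                raise ValueError(
                    f"{key}: segment chain interval {seg.chain_start}-{seg.chain_end} "
                    f"exceeds SEQRES length {obs.seqres_length}"
                )
            chunk = obs.states[seg.chain_start - 1 : seg.chain_end]
            row[seg.protein_start - 1 : seg.protein_end] = list(chunk)
        tracks.append(row)
        track_ids.append(key)
    return ProteinTrackStack(
        protein_id=protein_id,
        sequence=sequence,
        tracks=np.vstack(tracks),
        track_ids=track_ids,
    )


def build_stacks(
    observations: list[ChainObservation],
    segments: list[MappingSegment],
    sequences: dict[str, str],
) -> dict[str, ProteinTrackStack]:
    """Build one track stack per protein appearing in ``segments``.

    Only observations with at least one mapping segment for a protein are
    included in that protein's stack.
    """
    segs_by_protein: dict[str, list[MappingSegment]] = defaultdict(list)
    for seg in segments:
        segs_by_protein[seg.protein_id].append(seg)
    obs_by_key = {(o.structure_id, o.chain_id): o for o in observations}
    stacks = {}
    for pid, segs in segs_by_protein.items():
        keys = sorted({(s.structure_id, s.chain_id) for s in segs})
        obs = [obs_by_key[k] for k in keys if k in obs_by_key]
        if not obs:
            continue
        stacks[pid] = build_stack(obs, segs, pid, sequences[pid])
    return stacks


# --------------------------------------------------------------------------
# tabular dialects
# --------------------------------------------------------------------------

_OBS_COLS = ["structure_id", "chain_id", "states", "release_year"]
_MAP_COLS = ["structure_id", "chain_id", "chain_start", "chain_end",
             "protein_id", "protein_start", "protein_end"]


def write_observations_tsv(observations: list[ChainObservation], path) -> None:
    rows = [
        (o.structure_id, o.chain_id, o.states,
         "" if o.release_year is None else o.release_year)
        for o in observations
    ]
    pd.DataFrame(rows, columns=_OBS_COLS).to_csv(path, sep="\t", index=False)


def read_observations_tsv(path) -> list[ChainObservation]:
    df = pd.read_csv(path, sep="\t", dtype={"structure_id": str, "chain_id": str,
                                            "states": str})
    out = []
    for row in df.itertuples(index=False):
        year = None if pd.isna(row.release_year) else int(row.release_year)
        out.append(ChainObservation(row.structure_id, row.chain_id, row.states, year))
    return out


def write_mapping_tsv(segments: list[MappingSegment], path) -> None:
    rows = [(s.structure_id, s.chain_id, s.chain_start, s.chain_end,
             s.protein_id, s.protein_start, s.protein_end) for s in segments]
    pd.DataFrame(rows, columns=_MAP_COLS).to_csv(path, sep="\t", index=False)


def read_mapping_tsv(path) -> list[MappingSegment]:
    df = pd.read_csv(path, sep="\t", dtype={"structure_id": str, "chain_id": str,
                                            "protein_id": str})
    return [
        MappingSegment(r.structure_id, r.chain_id, int(r.chain_start),
                       int(r.chain_end), r.protein_id, int(r.protein_start),
                       int(r.protein_end))
        for r in df.itertuples(index=False)
    ]
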