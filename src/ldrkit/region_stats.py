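"""Summary statistics for consensus disorder datasets.

Residue accounting and disorder content, dataset composition tables,
region length histograms, region localization along the sequence, per
amino-acid compositional enrichment, LDR-count distributions and
protein-level overlap of externally supplied region sets.
"""

from __future__ import annotations

import math
from collections import Counter, defaultdict
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .consensus import (
    CATEGORY_LDR,
    CATEGORY_SDR,
    CATEGORY_STRUCTURED,
    DEFAULT_CONFIG,
    DISORDERED,
    STRUCTURED,
    UNKNOWN,
    ConsensusConfig,
    ConsensusTrack,
    ProteinClass,
    Region,
)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

__all__ = [
    "ResidueAccounting",
    "disorder_content",
    "summarize_dataset",
    "length_histogram",
    "length_fraction_in_range",
    "localize_region",
    "aa_enrichment",
    "count_regions_per_protein",
    "compare_region_sets",
    "round_half_up",
]


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal half-up rounding (the convention used for printed percentages)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ResidueAccounting:
    """Counts of missing (disordered), observed (structured) and unknown
    residues over a set of proteins."""

    missing: int
    observed: int
    unknown: int

    def __post_init__(self) -> None:
        if min(self.missing, self.observed, self.unknown) < 0:
            raise ValueError("residue counts must be non-negative")

    @property
    def total(self) -> int:
        return self.missing + self.observed + self.unknown

    def __add__(self, other: "ResidueAccounting") -> "ResidueAccounting":
        return ResidueAccounting(self.missing + other.missing,
                                 self.observed + other.observed,
                                 self.unknown + other.unknown)


def disorder_content(acc: ResidueAccounting, exclude_unknown: bool = False) -> float:
    """Fraction of missing residues, optionally over covered residues only.

    With ``exclude_unknown`` the denominator drops residues never covered
    by a crystallized construct.  Raises ``ValueError`` on an empty
    denominator.
    """
    denom = acc.missing + acc.observed + (0 if exclude_unknown else acc.unknown)
    if denom == 0:
        raise ValueError("disorder content undefined: zero residues in scope")
    return acc.missing / denom


def _accounting_from_track(track: ConsensusTrack) -> ResidueAccounting:
    return ResidueAccounting(track.states.count(DISORDERED),
                             track.states.count(STRUCTURED),
                             track.states.count(UNKNOWN))


_CATEGORIES = (CATEGORY_LDR, CATEGORY_SDR, CATEGORY_STRUCTURED)


def summarize_dataset(
    classes: list[ProteinClass],
    tracks: dict[str, ConsensusTrack],
    regions: list[Region],
) -> pd.DataFrame:
    """Dataset-composition table: one row per protein category plus a total.

    Columns: protein count, median protein length, SDR and LDR counts, and
    missing/observed/unknown residue counts with percentages of the row's
    residue total (1 d.p., half-up).  Consensus D counts as missing, S as
    observed, U as unknown.
    """
    region_counts: dict[str, Counter] = defaultdict(Counter)
    for r in regions:
        if r.region_class in ("LDR", "SDR"):
            region_counts[r.protein_id][r.region_class] += 1

    rows = {}
    groups: dict[str, list[ProteinClass]] = {c: [] for c in _CATEGORIES}
    for pc in classes:
        groups[pc.category].append(pc)

    def build_row(members: list[ProteinClass]):
        acc = ResidueAccounting(0, 0, 0)
        lengths = []
        sdr = ldr = 0
        for pc in members:
            track = tracks[pc.protein_id]
            acc = acc + _accounting_from_track(track)
            lengths.append(track.length)
            sdr += region_counts[pc.protein_id]["SDR"]
            ldr += region_counts[pc.protein_id]["LDR"]
        total = acc.total
        pct = lambda x: round_half_up(100 * x / total, 1) if total else 0.0
        return {
            "proteins": len(members),
            "median_length": float(np.median(lengths)) if lengths else 0.0,
            "sdr": sdr,
            "ldr": ldr,
            "missing": acc.missing,
            "observed": acc.observed,
            "unknown": acc.unknown,
            "missing_pct": pct(acc.missing),
            "observed_pct": pct(acc.observed),
            "unknown_pct": pct(acc.unknown),
        }

    for cat in _CATEGORIES:
        rows[cat] = build_row(groups[cat])
    rows["total"] = build_row(classes)
    return pd.DataFrame.from_dict(rows, orient="index")


def length_histogram(regions: list[Region], bin_width: int = 10,
                     cfg: ConsensusConfig = DEFAULT_CONFIG) -> pd.DataFrame:
    """Histogram of LDR lengths in fixed-width bins.

    The first bin starts at ``ldr_min_len`` ([30, 39], [40, 49], ... by
    default); counts sum to the number of LDR-class regions.  An empty
    region list yields an empty frame.
    """
    lengths = [r.length for r in regions if r.region_class == "LDR"]
    if not lengths:
        return pd.DataFrame(columns=["bin_start", "bin_end", "count"]).astype(int)
    lo = cfg.ldr_min_len
    n_bins = (max(lengths) - lo) // bin_width + 1
    starts = lo + bin_width * np.arange(n_bins)
    counts = np.zeros(n_bins, dtype=int)
    for length in lengths:
        counts[(length - lo) // bin_width] += 1
    return pd.DataFrame({"bin_start": starts,
                         "bin_end": starts + bin_width - 1,
                         "count": counts})


def length_fraction_in_range(regions: list[Region], lo: int, hi: int) -> float:
    """Fraction of LDRs whose length lies in [lo, hi] inclusive."""
    lengths = [r.length for r in regions if r.region_class == "LDR"]
    if not lengths:
        raise ValueError("no LDR-class regions")
    return sum(lo <= x <= hi for x in lengths) / len(lengths)


def localize_region(region: Region, protein_length: int,
                    cfg: ConsensusConfig = DEFAULT_CONFIG) -> str:
    """Label a region as N-terminal, C-terminal, middle or full.

    A tail is the first/last ``ceil(tail_fraction * L)`` residues.  ``full``
    means the region covers every position.  A region touching both tails
    without covering everything is labeled by the tail holding its larger
    overlap; ties go to N-terminal.
    """
    L = protein_length
    if region.end > L:
        raise ValueError(f"region {region.start}-{region.end} exceeds length {L}")
    if region.start == 1 and region.end == L:
        return "full"
    t = math.ceil(cfg.tail_fraction * L)
    c_tail_start = L - t + 1
    touches_n = region.start <= t
    touches_c = region.end >= c_tail_start
    if touches_n and touches_c:
        overlap_n = min(region.end, t) - region.start + 1
        overlap_c = region.end - max(region.start, c_tail_start) + 1
        return "N-terminal" if overlap_n >= overlap_c else "C-terminal"
    if touches_n:
        return "N-terminal"
    if touches_c:
        return "C-terminal"
    return "middle"


def aa_enrichment(region_sequences: list[str],
                  background_sequences: list[str]) -> pd.DataFrame:
    """Per-amino-acid fold change of region composition over a background.

    fold = target_freq / background_freq for each of the 20 standard amino
    acids; residues absent from the background get a missing fold (NaN).
    Frequencies are computed over standard amino acids only.
    """
    def freqs(seqs: list[str]) -> dict[str, float]:
        counts = Counter()
        for s in seqs:
            counts.update(c for c in s.upper() if c in AMINO_ACIDS)
        n = sum(counts.values())
        if n == 0:
            raise ValueError("no standard amino acids in sequence set")
        return {aa: counts[aa] / n for aa in AMINO_ACIDS}

    tf, bf = freqs(region_sequences), freqs(background_sequences)
    rows = []
    for aa in AMINO_ACIDS:
        fold = tf[aa] / bf[aa] if bf[aa] > 0 else float("nan")
        rows.append((aa, tf[aa], bf[aa], fold))
    return pd.DataFrame(rows, columns=["amino_acid", "target_freq",
                                       "background_freq", "fold"])


def count_regions_per_protein(regions: list[Region]) -> pd.DataFrame:
    """Distribution of LDR counts per protein.

    Returns one row per k = number of LDRs, with the number of proteins
    carrying exactly k LDRs and the percentage of LDR-carrying proteins
    (1 d.p., half-up).  Empty when no protein has an LDR.
    """
    per_protein = Counter(r.protein_id for r in regions if r.region_class == "LDR")
    dist = Counter(per_protein.values())
    n = sum(dist.values())
    rows = [(k, dist[k], round_half_up(100 * dist[k] / n, 1))
            for k in sorted(dist)]
    return pd.DataFrame(rows, columns=["n_ldrs", "proteins", "pct"])


def compare_region_sets(set_a, set_b) -> dict:
    """Protein-level overlap between two region (or protein-id) sets.

    Accepts iterables of ``Region`` objects or of protein ids; comparison
    is at the protein level.  Returns intersection / difference id sets and
    their sizes.
    """
    def ids(items) -> set[str]:
        return {x.protein_id if isinstance(x, Region) else str(x) for x in items}

    a, b = ids(set_a), ids(set_b)
    return {
        "intersection": a & b,
        "only_a": a - b,
        "only_b": b - a,
        "n_intersection": len(a & b),
        "n_only_a": len(a - b),
        "n_only_b": len(b - a),
        "n_a": len(a),
        "n_b": len(b),
    }
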