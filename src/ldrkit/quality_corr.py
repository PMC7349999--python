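"""Correlation of structure-quality metrics with missing-residue content.

If long missing-residue regions were mostly crystallographic artifacts,
poor validation metrics (resolution, R-free, clashscore, Ramachandran /
rotamer / RSRZ outliers) should correlate with the fraction of missing
residues.  This module joins a pre-computed per-structure quality table
with disorder fractions (or LDR lengths) and reports Pearson r with
two-sided p-values per metric.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .ingest import MISSING, ChainObservation

QUALITY_METRICS = ("resolution", "r_free", "clashscore", "rama_outliers",
                   "rotamer_outliers", "rsrz_outliers")

QUALITY_COLUMNS = ("structure_id",) + QUALITY_METRICS + ("year",)

__all__ = [
    "QualityRecord",
    "missing_fraction_per_chain",
    "pearson",
    "correlate_quality",
    "read_quality_csv",
    "write_quality_csv",
    "QUALITY_METRICS",
]


@dataclass(frozen=True)
class QualityRecord:
    structure_id: str
    resolution: float
    r_free: float
    clashscore: float
    rama_outliers: float
    rotamer_outliers: float
    rsrz_outliers: float
    year: int | None = None

    def __post_init__(self) -> None:
        if self.resolution <= 0:
            raise ValueError(f"{self.structure_id}: resolution must be positive")
        for name in ("clashscore", "rama_outliers", "rotamer_outliers",
                     "rsrz_outliers"):
            if getattr(self, name) < 0:
                raise ValueError(f"{self.structure_id}: negative {name}")


def missing_fraction_per_chain(obs: ChainObservation) -> float:
    """Fraction of SEQRES positions flagged missing for one chain."""
    return obs.states.count(MISSING) / obs.seqres_length


def pearson(x, y) -> tuple[float, float]:
    """Sample Pearson r with a two-sided p-value (t distribution, n-2 df).

    Raises ``ValueError`` for fewer than 3 pairs or a constant vector
    (correlation undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors differ in length")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def correlate_quality(quality: pd.DataFrame,
                      values: dict[str, float],
                      value_name: str = "disorder_fraction") -> pd.DataFrame:
    """Correlate each quality metric against a per-structure quantity.

    ``values`` maps structure_id to the quantity of interest (fraction of
    missing residues, LDR length, ...).  Records are joined on
    structure_id; structures missing a metric are dropped pairwise.
    Metrics with fewer than 3 complete pairs are flagged insufficient
    (r and p reported as NaN).
    """
    vals = pd.Series(values, name=value_name)
    merged = quality.set_index("structure_id").join(vals, how="inner")
    rows = []
    for metric in QUALITY_METRICS:
        if metric not in merged.columns:
            continue
        sub = merged[[metric, value_name]].dropna()
        if len(sub) < 3:
            rows.append({"metric": metric, "n": len(sub),
                         "r": np.nan, "p": np.nan, "insufficient": True})
            continue
        r, p = pearson(sub[metric].to_numpy(), sub[value_name].to_numpy())
        rows.append({"metric": metric, "n": len(sub), "r": r, "p": p,
                     "insufficient": False})
    return pd.DataFrame(rows, columns=["metric", "n", "r", "p", "insufficient"])


def write_quality_csv(records: list[QualityRecord] | pd.DataFrame, path) -> None:
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        df = pd.DataFrame([r.__dict__ for r in records])
    df.to_csv(path, index=False, columns=list(QUALITY_COLUMNS))


def read_quality_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"structure_id": str})
    missing = set(QUALITY_COLUMNS) - {"year"} - set(df.columns)
    if missing:
        raise ValueError(f"quality CSV lacks columns: {sorted(missing)}")
    return df
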