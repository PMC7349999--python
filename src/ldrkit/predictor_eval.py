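"""Per-residue benchmarking of disorder predictors against a consensus.

The consensus track supplies the reference: ``D`` positions are positives,
``S`` negatives; ``U`` (unknown) positions are excluded from the
assessment entirely.  Counts are pooled over proteins (micro-averaging —
metrics are computed per residue, not per protein) before deriving MCC,
F1, balanced accuracy, precision, specificity and recall.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .consensus import DISORDERED, STRUCTURED, UNKNOWN, ConsensusTrack

PRED_DISORDERED = "D"
PRED_ORDERED = "O"

__all__ = [
    "PredictionTrack",
    "EvalMetrics",
    "confusion",
    "compute_metrics",
    "benchmark",
    "read_predictions_tsv",
    "write_predictions_tsv",
]


@dataclass
class PredictionTrack:
    """Per-position binary disorder prediction, optionally with scores.

    ``states`` is a string over ``{D, O}``.  When only ``scores`` (in
    [0, 1]) are supplied, states are derived by binarizing at 0.5
    (score >= 0.5 -> disordered).
    """

    protein_id: str
    method_name: str
    states: str | None = None
    scores: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.scores is not None:
            self.scores = np.asarray(self.scores, dtype=float)
            if np.any((self.scores < 0) | (self.scores > 1)):
                raise ValueError(f"{self.protein_id}: scores outside [0, 1]")
        if self.states is None:
            if self.scores is None:
                raise ValueError("need states or scores")
            self.states = "".join(
                PRED_DISORDERED if s >= 0.5 else PRED_ORDERED for s in self.scores
            )
        bad = set(self.states) - {PRED_DISORDERED, PRED_ORDERED}
        if bad:
            raise ValueError(f"{self.protein_id}: invalid prediction states {bad!r}")
        if self.scores is not None and len(self.scores) != len(self.states):
            raise ValueError(f"{self.protein_id}: scores/states length mismatch")

    @property
    def length(self) -> int:
        return len(self.states)


@dataclass(frozen=True)
class EvalMetrics:
    """Confusion counts with optional derived per-residue scores.

    Metrics whose denominator is zero are reported as 0.0 and listed in
    ``flagged`` (tables stay rectangular; the flag marks the degeneracy).
    """

    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float | None = None
    bac: float | None = None
    f1: float | None = None
    mcc: float | None = None
    ppv: float | None = None
    tnr: float | None = None
    tpr: float | None = None
    flagged: frozenset = frozenset()

    @property
    def n_evaluated(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def __add__(self, other: "EvalMetrics") -> "EvalMetrics":
        return EvalMetrics(self.tp + other.tp, self.fp + other.fp,
                           self.tn + other.tn, self.fn + other.fn)


def confusion(reference: ConsensusTrack, prediction: PredictionTrack) -> EvalMetrics:
    """Confusion counts of a prediction against a consensus reference.

    Positives are reference ``D``, negatives reference ``S``; reference
    ``U`` positions are skipped.  Raises ``ValueError`` on length mismatch.
    """
    if reference.length != prediction.length:
        raise ValueError(
            f"{reference.protein_id}: reference length {reference.length} != "
            f"prediction length {prediction.length}"
        )
    ref = np.frombuffer(reference.states.encode(), dtype="S1")
    pred = np.frombuffer(prediction.states.encode(), dtype="S1")
    pos = ref == DISORDERED.encode()
    neg = ref == STRUCTURED.encode()
    pd_ = pred == PRED_DISORDERED.encode()
    return EvalMetrics(
        tp=int((pos & pd_).sum()),
        fp=int((neg & pd_).sum()),
        tn=int((neg & ~pd_).sum()),
        fn=int((pos & ~pd_).sum()),
    )


def _safe_div(num: float, den: float, name: str, flags: set) -> float:
    if den == 0:
        flags.add(name)
        return 0.0
    return num / den


def compute_metrics(counts: EvalMetrics) -> EvalMetrics:
    """Derive accuracy, BAC, F1, MCC, PPV, TNR and TPR from counts.

    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN));
    BAC = (TPR + TNR) / 2; F1 = 2*PPV*TPR / (PPV + TPR).  Any metric with a
    zero denominator is defined as 0 and flagged.
    """
    tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn
    flags: set = set()
    n = tp + fp + tn + fn
    accuracy = _safe_div(tp + tn, n, "accuracy", flags)
    tpr = _safe_div(tp, tp + fn, "tpr", flags)
    tnr = _safe_div(tn, tn + fp, "tnr", flags)
    ppv = _safe_div(tp, tp + fp, "ppv", flags)
    bac = (tpr + tnr) / 2
    f1 = _safe_div(2 * ppv * tpr, ppv + tpr, "f1", flags)
    mcc_den = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = _safe_div(tp * tn - fp * fn, mcc_den, "mcc", flags)
    return EvalMetrics(tp=tp, fp=fp, tn=tn, fn=fn, accuracy=accuracy, bac=bac,
                       f1=f1, mcc=mcc, ppv=ppv, tnr=tnr, tpr=tpr,
                       flagged=frozenset(flags))


def benchmark(
    predictions: dict[str, list[PredictionTrack]],
    references: dict[str, ConsensusTrack],
) -> pd.DataFrame:
    """Pooled per-residue evaluation of several methods, ranked by MCC.

    ``predictions`` maps method name to its per-protein tracks;
    ``references`` maps protein id to the consensus track.  Counts are
    pooled over all proteins of a method before deriving metrics.  Returns
    one row per method sorted by MCC descending.
    """
    rows = []
    for method, tracks in predictions.items():
        pooled = EvalMetrics(0, 0, 0, 0)
        for track in tracks:
            if track.protein_id not in references:
                raise KeyError(f"{method}: no reference for {track.protein_id}")
            pooled = pooled + confusion(references[track.protein_id], track)
        m = compute_metrics(pooled)
        rows.append({
            "method": method,
            "mcc": m.mcc, "f1": m.f1, "accuracy": m.accuracy,
            "precision": m.ppv, "specificity": m.tnr, "recall": m.tpr,
            "bac": m.bac,
            "tp": m.tp, "fp": m.fp, "tn": m.tn, "fn": m.fn,
            "flagged": ",".join(sorted(m.flagged)),
        })
    df = pd.DataFrame(rows).sort_values("mcc", ascending=False, kind="stable")
    return df.reset_index(drop=True)


# --------------------------------------------------------------------------
# tabular dialect: protein_id, position, residue, score, state
# --------------------------------------------------------------------------

def write_predictions_tsv(predictions: dict[str, list[PredictionTrack]],
                          sequences: dict[str, str], path) -> None:
    rows = []
    for method, tracks in predictions.items():
        for t in tracks:
            seq = sequences.get(t.protein_id, "X" * t.length)
            for i in range(t.length):
                score = "" if t.scores is None else f"{t.scores[i]:.4f}"
                rows.append((method, t.protein_id, i + 1, seq[i], score,
                             "disordered" if t.states[i] == PRED_DISORDERED
                             else "ordered"))
    pd.DataFrame(rows, columns=["method", "protein_id", "position", "residue",
                                "score", "state"]).to_csv(path, sep="\t", index=False)


def read_predictions_tsv(path) -> dict[str, list[PredictionTrack]]:
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str, "method": str})
    out: dict[str, list[PredictionTrack]] = {}
    for (method, pid), grp in df.groupby(["method", "protein_id"], sort=False):
        grp = grp.sort_values("position")
        states = "".join(PRED_DISORDERED if s == "disordered" else PRED_ORDERED
                         for s in grp["state"])
        scores = None
        if grp["score"].notna().all():
            scores = grp["score"].to_numpy(dtype=float)
        out.setdefault(method, []).append(
            PredictionTrack(pid, method, states=states, scores=scores)
        )
    return out
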