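"""Benchmark labelling, classification metrics and ROC threshold selection.

Alanine-scanning benchmarks come in two flavours: ddG tables (ASEdb-style),
where a residue is a hotspot when mutating it to alanine costs at least
2.0 kcal/mol of binding free energy, a non-hotspot below 0.4 kcal/mol, and
excluded in between; and strength-labelled tables (BID-style), where only
"strong" counts as a hotspot. Predictions are scored with the usual confusion
matrix statistics (ACC, SE, PR, SP, MCC), and per-score thresholds are picked
from ROC curves at the last point where the gain in true-positive rate still
matches the gain in false-positive rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

HOTSPOT = "hotspot"
NON_HOTSPOT = "non-hotspot"
EXCLUDED = "excluded"

DDG_HOTSPOT_MIN = 2.0   # kcal/mol, inclusive
DDG_NONHOTSPOT_MAX = 0.4  # kcal/mol, exclusive

STRENGTH_LABELS = ("strong", "intermediate", "weak", "insignificant")

BENCHMARK_COLUMNS = ["complex_id", "chain", "resnum", "aa"]


class BenchmarkError(ValueError):
    """Malformed benchmark record or table."""


def label_asedb(table: pd.DataFrame) -> pd.DataFrame:
    """Assign hotspot / non-hotspot / excluded truth labels from ddG.

    ddG >= 2.0 kcal/mol -> hotspot; ddG < 0.4 -> non-hotspot; the band
    [0.4, 2.0) is excluded from training. Returns a copy with a `truth`
    column.
    """
    if "ddg" not in table.columns:
        raise BenchmarkError("ddG table must have a 'ddg' column")
    if table["ddg"].isna().any():
        raise BenchmarkError("missing ddG values in ddG-labelled table")
    out = table.copy()
    ddg = out["ddg"].astype(float)
    out["truth"] = np.select(
        [ddg >= DDG_HOTSPOT_MIN, ddg < DDG_NONHOTSPOT_MAX],
        [HOTSPOT, NON_HOTSPOT], default=EXCLUDED)
    return out


def label_bid(table: pd.DataFrame) -> pd.DataFrame:
    """Assign truth labels from BID-style strength labels: strong -> hotspot,
    everything else -> non-hotspot; unknown labels are an error."""
    if "strength" not in table.columns:
        raise BenchmarkError("strength table must have a 'strength' column")
    out = table.copy()
    strengths = out["strength"].astype(str).str.lower()
    unknown = sorted(set(strengths) - set(STRENGTH_LABELS))
    if unknown:
        raise BenchmarkError(f"unknown strength labels: {unknown}")
    out["truth"] = np.where(strengths == "strong", HOTSPOT, NON_HOTSPOT)
    return out


def read_benchmark(source, sep: str = "\t") -> pd.DataFrame:
    """Read a headered benchmark TSV/CSV table."""
    df = pd.read_csv(source, sep=sep)
    missing = [c for c in BENCHMARK_COLUMNS if c not in df.columns]
    if missing:
        raise BenchmarkError(f"benchmark table missing columns: {missing}")
    return df


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion-matrix counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class Metrics:
    acc: float
    se: float
    pr: float
    sp: float
    mcc: float
    flags: Tuple[str, ...] = ()


def confusion(truth: Sequence[bool], predicted: Sequence[bool]) -> ConfusionMatrix:
    t = np.asarray(truth, dtype=bool)
    p = np.asarray(predicted, dtype=bool)
    if t.shape != p.shape:
        raise ValueError("truth and prediction lengths differ")
    return ConfusionMatrix(
        tp=int(np.sum(t & p)), fp=int(np.sum(~t & p)),
        tn=int(np.sum(~t & ~p)), fn=int(np.sum(t & ~p)))


def metrics(cm: ConfusionMatrix) -> Metrics:
    """ACC, SE, PR, SP and MCC; zero-denominator metrics report 0 with a flag."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    flags: List[str] = []

    def safe(num: float, den: float, name: str) -> float:
        if den == 0:
            flags.append(name)
            return 0.0
        return num / den

    acc = (cm.tp + cm.tn) / cm.total
    se = safe(cm.tp, cm.tp + cm.fn, "SE")
    pr = safe(cm.tp, cm.tp + cm.fp, "PR")
    sp = safe(cm.tn, cm.tn + cm.fp, "SP")
    mcc_den = math.sqrt(float(cm.tp + cm.fp) * (cm.tp + cm.fn)
                        * (cm.tn + cm.fp) * (cm.tn + cm.fn))
    mcc = safe(cm.tp * cm.tn - cm.fp * cm.fn, mcc_den, "MCC")
    return Metrics(acc=acc, se=se, pr=pr, sp=sp, mcc=mcc, flags=tuple(flags))


@dataclass(frozen=True)
class RocCurve:
    """ROC points with thresholds descending; one point per distinct score,
    preceded by the (0, 0) origin at threshold +inf."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray

    def auc(self) -> float:
        return float(np.trapezoid(self.tpr, self.fpr))


def roc_curve(scores: Sequence[float], truth: Sequence[bool]) -> RocCurve:
    """Build the ROC curve by sweeping the prediction threshold over every
    distinct score value (prediction rule: score >= threshold)."""
    s = np.asarray(scores, dtype=float)
    t = np.asarray(truth, dtype=bool)
    if s.shape != t.shape:
        raise ValueError("scores and truth lengths differ")
    n_pos = int(t.sum())
    n_neg = int((~t).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC needs at least one positive and one negative")
    order = np.argsort(-s, kind="stable")
    s_sorted = s[order]
    t_sorted = t[order]
    cum_tp = np.cumsum(t_sorted)
    cum_fp = np.cumsum(~t_sorted)
    # last index of each distinct score value in descending order
    distinct_last = np.flatnonzero(np.r_[s_sorted[1:] != s_sorted[:-1], True])
    tpr = np.r_[0.0, cum_tp[distinct_last] / n_pos]
    fpr = np.r_[0.0, cum_fp[distinct_last] / n_neg]
    thresholds = np.r_[np.inf, s_sorted[distinct_last]]
    return RocCurve(fpr=fpr, tpr=tpr, thresholds=thresholds)


@dataclass(frozen=True)
class ElbowResult:
    threshold: float
    index: int
    uninformative: bool


def elbow_threshold(curve: RocCurve) -> ElbowResult:
    """Pick the threshold at the last ROC step whose TPR gain still matches or
    exceeds its FPR gain (walking from high thresholds down).

    A curve that never rises above the diagonal is flagged uninformative.
    """
    n = len(curve.thresholds)
    if n < 3:
        raise ValueError(f"degenerate ROC curve with {n} points")
    d_tpr = np.diff(curve.tpr)
    d_fpr = np.diff(curve.fpr)
    # a step that gains TPR strictly faster than FPR advances the walk; a
    # tied step does not (ties resolve toward the higher threshold), so a
    # pure-diagonal curve falls back to the highest finite threshold
    qualifying = np.flatnonzero(d_tpr > d_fpr)
    if len(qualifying) == 0:
        idx = 1
    else:
        idx = int(qualifying[-1]) + 1
    uninformative = bool(np.max(curve.tpr - curve.fpr) <= 1e-12)
    return ElbowResult(threshold=float(curve.thresholds[idx]), index=idx,
                       uninformative=uninformative)


def rank_auc(scores: Sequence[float], truth: Sequence[bool]) -> float:
    """AUC via the Mann-Whitney rank statistic (independent of the curve)."""
    from scipy.stats import rankdata
    s = np.asarray(scores, dtype=float)
    t = np.asarray(truth, dtype=bool)
    n_pos = int(t.sum())
    n_neg = len(t) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs both classes")
    ranks = rankdata(s)
    u = ranks[t].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def evaluate_predictions(benchmark: pd.DataFrame,
                         predictions: pd.DataFrame) -> Tuple[ConfusionMatrix, Metrics, int]:
    """Join predictions to a labelled benchmark on (complex_id, chain, resnum)
    and compute metrics over non-excluded records.

    The predictions table needs columns complex_id, chain, resnum, hotspot.
    Returns (confusion matrix, metrics, number of unmatched benchmark rows).
    """
    if "truth" not in benchmark.columns:
        raise BenchmarkError("benchmark must be labelled (no 'truth' column)")
    keys = ["complex_id", "chain", "resnum"]
    joined = benchmark.merge(predictions[keys + ["hotspot"]], on=keys, how="left")
    unmatched = int(joined["hotspot"].isna().sum())
    joined = joined.dropna(subset=["hotspot"])
    joined = joined[joined["truth"] != EXCLUDED]
    if joined.empty:
        raise BenchmarkError("no benchmark records matched the predictions")
    cm = confusion(joined["truth"] == HOTSPOT, joined["hotspot"].astype(int) == 1)
    return cm, metrics(cm), unmatched
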