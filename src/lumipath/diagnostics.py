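"""Diagnostic-accuracy evaluation of Lmax-threshold classification.

Implements the statistical stage of the pipeline: binary classification of
cohort records at a luminance threshold, 2x2 contingency tables against the
histopathology reference, the standard test-accuracy metrics (sensitivity,
specificity, PPV, NPV, likelihood ratios, overall accuracy a.k.a.
"credibility"), threshold sweeps, ROC/AUC with Youden-style threshold
selection, Pearson chi-square with Cramer's V, a rank-sum group comparison,
and an AUC-based minimum-sample-size calculation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy import stats

from .phantom import CohortRecord

__all__ = [
    "ContingencyTable",
    "DiagnosticMetrics",
    "ThresholdSweepResult",
    "ROCCurve",
    "AssociationResult",
    "classify",
    "contingency",
    "diagnostic_metrics",
    "sweep_thresholds",
    "roc_curve",
    "select_threshold",
    "chi_square_2x2",
    "rank_group_comparison",
    "sample_size_auc",
]

Direction = Literal["le", "ge"]


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 table: rows = test result, columns = reference method."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
        if self.n < 1:
            raise ValueError("contingency table must contain at least one observation")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def as_array(self) -> np.ndarray:
        return np.array([[self.tp, self.fp], [self.fn, self.tn]], dtype=np.float64)


@dataclass(frozen=True)
class DiagnosticMetrics:
    """Test-accuracy metrics as proportions (ratios for the LRs).

    Ratios with a zero denominator are ``None`` ("undefined"), never a
    number.  ``credibility`` is overall accuracy, (tp+tn)/n.
    """

    sensitivity: float
    specificity: float
    ppv: float | None
    npv: float | None
    lr_plus: float | None
    lr_minus: float | None
    credibility: float

    @property
    def one_minus_sensitivity(self) -> float:
        return 1.0 - self.sensitivity

    @property
    def one_minus_specificity(self) -> float:
        return 1.0 - self.specificity

    def as_percent_row(self, ndigits: int = 2) -> dict:
        """Display row matching the report layout (percentages, 2 dp)."""

        def pct(x):
            return None if x is None else _round_half_up(100.0 * x, ndigits)

        def ratio(x):
            return None if x is None else _round_half_up(x, ndigits)

        return {
            "sensitivity_pct": pct(self.sensitivity),
            "specificity_pct": pct(self.specificity),
            "one_minus_sensitivity_pct": pct(self.one_minus_sensitivity),
            "one_minus_specificity_pct": pct(self.one_minus_specificity),
            "ppv_pct": pct(self.ppv),
            "npv_pct": pct(self.npv),
            "lr_plus": ratio(self.lr_plus),
            "lr_minus": ratio(self.lr_minus),
            "credibility_pct": pct(self.credibility),
        }


def _round_half_up(x: float, ndigits: int) -> float:
    scale = 10**ndigits
    return math.floor(x * scale + 0.5) / scale


@dataclass(frozen=True)
class ThresholdSweepResult:
    thresholds: tuple[float, ...]
    tables: tuple[ContingencyTable, ...]
    metrics: tuple[DiagnosticMetrics, ...]
    direction: Direction

    def _ascending_positive_counts(self) -> list[int]:
        pos = [t.tp + t.fp for t in self.tables]
        order = sorted(range(len(self.thresholds)), key=lambda i: self.thresholds[i])
        return [pos[i] for i in order]

    def monotone(self) -> bool:
        """True when predicted-positive counts move monotonically with the
        threshold in the direction the rule implies (non-decreasing for
        ``le``, non-increasing for ``ge``).  Holds for any sweep produced by
        ``classify``; a violation flags externally supplied counts."""
        seq = self._ascending_positive_counts()
        if self.direction == "le":
            return all(a <= b for a, b in zip(seq, seq[1:]))
        return all(a >= b for a, b in zip(seq, seq[1:]))

    def layout_monotone(self) -> bool:
        """True when positive counts are non-decreasing in ascending threshold
        order — the shape of the published assignment table.  A ``ge`` sweep
        on a discriminating cohort fails this, documenting that such counts
        can only arise under the ``le`` rule."""
        seq = self._ascending_positive_counts()
        return all(a <= b for a, b in zip(seq, seq[1:]))


@dataclass(frozen=True)
class ROCCurve:
    points: tuple[tuple[float, float], ...]  # (1 - specificity, sensitivity)
    auc: float
    thresholds: tuple[float, ...]  # generating threshold of each interior point


@dataclass(frozen=True)
class AssociationResult:
    chi2: float
    df: int
    p_value: float
    cramers_v: float
    corrected: bool = False

    def p_display(self, floor: float = 0.001) -> str:
        return f"< {floor}" if self.p_value < floor else f"{self.p_value:.4g}"


# ---------------------------------------------------------------------------
# Classification and contingency


def classify(
    records: Sequence[CohortRecord], threshold: float, direction: Direction = "le"
) -> list[bool]:
    """Binary test result per record: ``le`` -> positive iff l_max <= t;
    ``ge`` -> positive iff l_max >= t.  Equality is positive either way."""
    if not records:
        raise ValueError("record list is empty")
    if not threshold > 0:
        raise ValueError("threshold must be positive")
    if direction == "le":
        return [rec.l_max <= threshold for rec in records]
    if direction == "ge":
        return [rec.l_max >= threshold for rec in records]
    raise ValueError("direction must be 'le' or 'ge'")


def contingency(
    predictions: Sequence[bool], reference_labels: Sequence[bool]
) -> ContingencyTable:
    """Cross-tabulate predictions against reference labels."""
    if len(predictions) != len(reference_labels):
        raise ValueError("predictions and reference labels differ in length")
    tp = fp = fn = tn = 0
    for pred, ref in zip(predictions, reference_labels):
        if not isinstance(pred, (bool, np.bool_)) or not isinstance(ref, (bool, np.bool_)):
            raise ValueError("labels must be binary (bool)")
        if pred and ref:
            tp += 1
        elif pred and not ref:
            fp += 1
        elif not pred and ref:
            fn += 1
        else:
            tn += 1
    return ContingencyTable(tp, fp, fn, tn)


def reference_labels(records: Sequence[CohortRecord]) -> list[bool]:
    return [rec.is_positive for rec in records]


def diagnostic_metrics(table: ContingencyTable) -> DiagnosticMetrics:
    """Standard 2x2 test-accuracy metrics; zero-denominator ratios are None."""
    if table.tp + table.fn < 1:
        raise ValueError("no reference-positive samples; sensitivity undefined")
    if table.fp + table.tn < 1:
        raise ValueError("no reference-negative samples; specificity undefined")
    sens = table.tp / (table.tp + table.fn)
    spec = table.tn / (table.fp + table.tn)
    ppv = table.tp / (table.tp + table.fp) if table.tp + table.fp > 0 else None
    npv = table.tn / (table.tn + table.fn) if table.tn + table.fn > 0 else None
    lr_plus = sens / (1.0 - spec) if spec < 1.0 else None
    lr_minus = (1.0 - sens) / spec if spec > 0.0 else None
    credibility = (table.tp + table.tn) / table.n
    return DiagnosticMetrics(sens, spec, ppv, npv, lr_plus, lr_minus, credibility)


def sweep_thresholds(
    records: Sequence[CohortRecord],
    thresholds: Sequence[float],
    direction: Direction = "le",
) -> ThresholdSweepResult:
    """Contingency table and metrics at every threshold of the grid."""
    if not thresholds:
        raise ValueError("threshold grid is empty")
    refs = reference_labels(records)
    tables = []
    metrics = []
    for t in thresholds:
        tab = contingency(classify(records, t, direction), refs)
        tables.append(tab)
        metrics.append(diagnostic_metrics(tab))
    return ThresholdSweepResult(tuple(thresholds), tuple(tables), tuple(metrics), direction)


# ---------------------------------------------------------------------------
# ROC


def roc_curve(records: Sequence[CohortRecord], direction: Direction = "le") -> ROCCurve:
    """Empirical ROC over every distinct Lmax value, with trapezoidal AUC.

    Tied Lmax values collapse into a single step, so the curve contains one
    interior point per distinct value plus the (0,0) and (1,1) sentinels.
    """
    refs = reference_labels(records)
    n_pos = sum(refs)
    n_neg = len(refs) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC requires both reference classes")
    values = sorted({rec.l_max for rec in records}, reverse=(direction == "ge"))
    points: list[tuple[float, float]] = [(0.0, 0.0)]
    thresholds: list[float] = []
    for t in values:
        tab = contingency(classify(records, t, direction), refs)
        points.append((tab.fp / n_neg, tab.tp / n_pos))
        thresholds.append(t)
    if points[-1] != (1.0, 1.0):
        points.append((1.0, 1.0))
    xs = np.array([p[0] for p in points])
    ys = np.array([p[1] for p in points])
    auc = float(np.trapezoid(ys, xs))
    return ROCCurve(tuple(points), auc, tuple(thresholds))


def select_threshold(sweep: ThresholdSweepResult) -> tuple[float, dict]:
    """Grid threshold maximizing Youden's J = sensitivity + specificity - 1.

    Ties break toward the largest threshold; the rationale record lists all
    tied thresholds and the achieved J.
    """
    if not sweep.thresholds:
        raise ValueError("empty sweep")
    js = [m.sensitivity + m.specificity - 1.0 for m in sweep.metrics]
    best = max(js)
    tied = [t for t, j in zip(sweep.thresholds, js) if math.isclose(j, best, abs_tol=1e-12)]
    selected = max(tied)
    rationale = {
        "criterion": "max Youden J (sensitivity + specificity - 1), ties to largest threshold",
        "youden_j": best,
        "tied_thresholds": sorted(tied),
        "selected": selected,
    }
    return selected, rationale


# ---------------------------------------------------------------------------
# Association statistics


def chi_square_2x2(table: ContingencyTable, *, correction: bool = False) -> AssociationResult:
    """Pearson chi-square (1 df) and Cramer's V for a 2x2 table.

    Expected counts come from the row/column margins.  No continuity
    correction by default; Yates' correction is available behind the flag.
    V = sqrt(chi2 / (n * min(k-1, r-1))) with min(k-1, r-1) = 1 here.
    """
    obs = table.as_array()
    row_sums = obs.sum(axis=1)
    col_sums = obs.sum(axis=0)
    n = obs.sum()
    if np.any(row_sums == 0) or np.any(col_sums == 0):
        raise ValueError("chi-square undefined: a table margin is zero")
    expected = np.outer(row_sums, col_sums) / n
    diff = np.abs(obs - expected)
    if correction:
        diff = np.maximum(diff - 0.5, 0.0)
    chi2 = float(np.sum(diff**2 / expected))
    p = float(stats.chi2.sf(chi2, df=1))
    v = math.sqrt(chi2 / (n * 1))
    return AssociationResult(chi2=chi2, df=1, p_value=p, cramers_v=v, corrected=correction)


def rank_group_comparison(records: Sequence[CohortRecord]) -> tuple[float, float, float]:
    """Two-sample rank-sum comparison of Lmax between the groups.

    Returns ``(Z, p, r)``: the tie-corrected normal-approximation statistic
    of the Mann-Whitney test, its two-sided p-value, and the effect size
    r = Z / sqrt(n) (biserial correlation of the rank test).
    """
    pos = np.array([r.l_max for r in records if r.is_positive], dtype=np.float64)
    neg = np.array([r.l_max for r in records if not r.is_positive], dtype=np.float64)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both groups must be non-empty")
    n1, n2 = pos.size, neg.size
    n = n1 + n2
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    # tie-corrected variance of U
    _, tie_counts = np.unique(np.concatenate([pos, neg]), return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (n * (n - 1)) if n > 1 else 0.0
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return 0.0, 1.0, 0.0
    z = (u1 - mu) / math.sqrt(var)
    p = 2.0 * float(stats.norm.sf(abs(z)))
    r = z / math.sqrt(n)
    return float(z), min(p, 1.0), float(r)


# ---------------------------------------------------------------------------
# Sample size


def _auc_variance(auc: float, n_pos: int, n_neg: int) -> float:
    """Hanley-McNeil variance of the empirical AUC (exponential model)."""
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc**2 / (1.0 + auc)
    return (
        auc * (1.0 - auc) + (n_pos - 1) * (q1 - auc**2) + (n_neg - 1) * (q2 - auc**2)
    ) / (n_pos * n_neg)


def _split(n_total: int, neg_pos_ratio: float) -> tuple[int, int]:
    """Ratio-respecting split of n_total into (n_pos, n_neg); counts sum to
    n_total exactly, n_neg may be 0 for tiny totals (caller must check)."""
    n_pos = math.ceil(n_total / (1.0 + neg_pos_ratio))
    return n_pos, n_total - n_pos


def sample_size_auc(
    alpha: float, beta: float, neg_pos_ratio: float, auc_alt: float
) -> int:
    """Minimum total n distinguishing ``auc_alt`` from 0.5 (one-sided).

    Uses the Hanley-McNeil AUC variance under the null (AUC = 0.5) and the
    alternative: the smallest n whose ratio-respecting split satisfies
    ``z_alpha * sd0 + z_beta * sd1 <= auc_alt - 0.5``.
    """
    if not (0.0 < alpha < 1.0 and 0.0 < beta < 1.0):
        raise ValueError("alpha and beta must lie in (0, 1)")
    if not neg_pos_ratio > 0:
        raise ValueError("neg_pos_ratio must be positive")
    if not (0.5 < auc_alt < 1.0):
        raise ValueError("auc_alt must lie in (0.5, 1)")
    z_a = float(stats.norm.isf(alpha))
    z_b = float(stats.norm.isf(beta))
    delta = auc_alt - 0.5
    n = 2
    while True:
        n_pos, n_neg = _split(n, neg_pos_ratio)
        if n_pos >= 1 and n_neg >= 1:
            sd0 = math.sqrt(_auc_variance(0.5, n_pos, n_neg))
            sd1 = math.sqrt(_auc_variance(auc_alt, n_pos, n_neg))
            if z_a * sd0 + z_b * sd1 <= delta:
                return n
        n += 1
        if n > 10_000_000:
            raise RuntimeError("sample size search failed to converge")
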