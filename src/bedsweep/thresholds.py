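"""Empirical ROC analysis and the α/β sweep.

Classification direction is fixed throughout: a tumor is predicted positive
(at risk of post-radiotherapy edema) when its score is *at or above* the
threshold — higher BED means higher risk.  Threshold candidates are the
unique observed scores; the curve additionally carries the two degenerate
operating points (sens 0 / spec 1 at +inf and sens 1 / spec 0 at -inf).

The optimal cutpoint is the operating point closest to the upper-left ROC
corner, i.e. minimizing sqrt((1-sens)^2 + (1-spec)^2); Youden's J
(sens + spec - 1) summarizes cutpoint quality and drives the choice of the
best α/β ratio across the sweep.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateLabelsError, EmptyInputError, InvalidParameterError
from .radiobiology import AlphaBetaGrid, bed_matrix, isoeffective_dose_per_fraction

__all__ = [
    "RocCurve",
    "ThresholdMetrics",
    "SweepRow",
    "empirical_roc",
    "auc",
    "auc_pvalue",
    "youden_j",
    "corner_optimal",
    "optimal_cutpoint",
    "CutpointResult",
    "sweep_alpha_beta",
    "sweep_to_frame",
    "select_best_alpha_beta",
]

_TIE_TOL = 1e-12


def _validate_scores_labels(scores, labels):
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    if s.ndim != 1 or y.ndim != 1 or s.shape != y.shape:
        raise InvalidParameterError(
            f"scores and labels must be equal-length 1-D sequences, got shapes {s.shape} and {y.shape}"
        )
    if s.size == 0:
        raise EmptyInputError("empty score vector")
    if not np.all(np.isfinite(s)):
        raise InvalidParameterError("scores must be finite")
    uniq = set(np.unique(y).tolist())
    if not uniq <= {0, 1}:
        raise InvalidParameterError(f"labels must be binary 0/1, got values {sorted(uniq)}")
    y = y.astype(int)
    if y.sum() == 0 or y.sum() == y.size:
        raise DegenerateLabelsError("labels contain a single class; ROC is undefined")
    return s, y


@dataclass(frozen=True)
class RocCurve:
    """Empirical ROC curve: thresholds in decreasing order with the
    sensitivity/specificity attained when classifying ``score >= threshold``
    as positive."""

    thresholds: np.ndarray  # decreasing; +inf first, -inf last
    sensitivity: np.ndarray
    specificity: np.ndarray
    n_positive: int
    n_negative: int

    def operating_points(self, include_degenerate: bool = True):
        """Iterate (threshold, sens, spec) triples."""
        for t, se, sp in zip(self.thresholds, self.sensitivity, self.specificity):
            if not include_degenerate and not np.isfinite(t):
                continue
            yield float(t), float(se), float(sp)


@dataclass(frozen=True)
class ThresholdMetrics:
    """Diagnostic metrics of one operating point."""

    threshold: float
    sensitivity: float
    specificity: float
    youden_j: float
    corner_distance: float


def empirical_roc(scores: Sequence[float], labels: Sequence[int]) -> RocCurve:
    """Build the empirical ROC curve of a continuous predictor.

    One operating point per unique observed score, plus the degenerate
    endpoints (sens 0, spec 1) and (sens 1, spec 0).  Requires at least one
    positive and one negative label.
    """
    s, y = _validate_scores_labels(scores, labels)
    pos = s[y == 1]
    neg = s[y == 0]
    uniq = np.unique(s)[::-1]  # decreasing
    thr = np.concatenate([[np.inf], uniq, [-np.inf]])
    sens = np.empty_like(thr)
    spec = np.empty_like(thr)
    for i, t in enumerate(thr):
        sens[i] = np.mean(pos >= t)
        spec[i] = np.mean(neg < t)
    return RocCurve(
        thresholds=thr,
        sensitivity=sens,
        specificity=spec,
        n_positive=int(pos.size),
        n_negative=int(neg.size),
    )


def auc(curve: RocCurve) -> float:
    """Trapezoidal area under the ROC curve.

    Equals the Mann–Whitney concordance probability (ties counted one half)
    because tied scores produce diagonal jumps that the trapezoid credits at
    half height.
    """
    fpr = 1.0 - curve.specificity
    tpr = curve.sensitivity
    order = np.argsort(fpr, kind="stable")
    return float(np.trapezoid(tpr[order], fpr[order]))


def auc_pvalue(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Two-sided p-value for H0: AUC = 0.5.

    Normal approximation to the Mann–Whitney U statistic with the standard
    tie correction of the null variance; no continuity correction.  A
    constant predictor (null variance zero) returns p = 1.
    """
    s, y = _validate_scores_labels(scores, labels)
    n1 = int(y.sum())
    n0 = int(y.size - n1)
    ranks = stats.rankdata(s)
    u = float(ranks[y == 1].sum()) - n1 * (n1 + 1) / 2.0
    mu = n1 * n0 / 2.0
    n = n1 + n0
    _, counts = np.unique(s, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    var = n1 * n0 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return 1.0
    z = (u - mu) / np.sqrt(var)
    return float(min(1.0, 2.0 * stats.norm.sf(abs(z))))


def youden_j(sensitivity: float, specificity: float) -> float:
    """Youden's J statistic: sensitivity + specificity - 1."""
    for name, v in (("sensitivity", sensitivity), ("specificity", specificity)):
        if not (0.0 <= v <= 1.0):
            raise InvalidParameterError(f"{name} must lie in [0, 1], got {v!r}")
    return sensitivity + specificity - 1.0


def corner_optimal(curve: RocCurve) -> ThresholdMetrics:
    """Operating point closest to the upper-left ROC corner (0, 1).

    Only finite-threshold (observed-score) points are candidates.  Distance
    ties are broken by larger Youden J, then by the smaller threshold (the
    more conservative dose cutoff).
    """
    best = None
    best_key = None
    for t, se, sp in curve.operating_points(include_degenerate=False):
        dist = float(np.hypot(1.0 - se, 1.0 - sp))
        j = se + sp - 1.0
        key = (round(dist / _TIE_TOL) * _TIE_TOL, -round(j / _TIE_TOL) * _TIE_TOL, t)
        if best_key is None or key < best_key:
            best_key = key
            best = ThresholdMetrics(
                threshold=t, sensitivity=se, specificity=sp, youden_j=j, corner_distance=dist
            )
    if best is None:  # cannot happen for a curve built by empirical_roc
        raise EmptyInputError("ROC curve has no finite operating point")
    return best


@dataclass(frozen=True)
class CutpointResult:
    """Optimal cutpoint of a continuous predictor plus curve-level metrics."""

    metrics: ThresholdMetrics
    auc: float
    p_value: float
    n_positive: int
    n_negative: int


def optimal_cutpoint(scores: Sequence[float], labels: Sequence[int]) -> CutpointResult:
    """One-stop ROC evaluation of a continuous predictor (BED, PTV, age...)."""
    curve = empirical_roc(scores, labels)
    return CutpointResult(
        metrics=corner_optimal(curve),
        auc=auc(curve),
        p_value=auc_pvalue(scores, labels),
        n_positive=curve.n_positive,
        n_negative=curve.n_negative,
    )


@dataclass(frozen=True)
class SweepRow:
    """Full result line for one α/β ratio: discrimination of the BED scores
    computed at that ratio, the corner-optimal BED cutoff, and the physical
    dose-per-fraction equivalents of the cutoff for requested schemes."""

    alpha_beta: float
    auc: float
    auc_p_value: float
    optimal_bed: float
    sensitivity: float
    specificity: float
    youden_j: float
    doses: dict[int, float] = field(default_factory=dict)  # n_fractions -> Gy/fx


DEFAULT_FRACTION_SCHEMES = (1, 3, 5, 8, 10, 15, 20)


def sweep_alpha_beta(
    cohort: Iterable,
    grid: AlphaBetaGrid | None = None,
    fraction_schemes: Sequence[int] = DEFAULT_FRACTION_SCHEMES,
) -> list[SweepRow]:
    """Re-compute BED across the α/β grid and evaluate each ratio's ROC.

    ``cohort`` items must expose ``scheme`` (a TreatmentScheme) and
    ``ptbe_event`` (binary outcome).  Returns one :class:`SweepRow` per grid
    value, ascending in α/β.
    """
    cohort = list(cohort)
    if grid is None:
        grid = AlphaBetaGrid()
    labels = np.array([r.ptbe_event for r in cohort], dtype=int)
    if labels.size and (labels.sum() == 0 or labels.sum() == labels.size):
        raise DegenerateLabelsError("cohort outcomes contain a single class")
    mat = bed_matrix(cohort, grid)
    rows: list[SweepRow] = []
    for j, ab in enumerate(grid):
        scores = mat.values[:, j]
        curve = empirical_roc(scores, labels)
        m = corner_optimal(curve)
        rows.append(
            SweepRow(
                alpha_beta=float(ab),
                auc=auc(curve),
                auc_p_value=auc_pvalue(scores, labels),
                optimal_bed=m.threshold,
                sensitivity=m.sensitivity,
                specificity=m.specificity,
                youden_j=m.youden_j,
                doses={
                    int(n): isoeffective_dose_per_fraction(m.threshold, int(n), float(ab))
                    for n in fraction_schemes
                },
            )
        )
    return rows


def sweep_to_frame(rows: Sequence[SweepRow]) -> pd.DataFrame:
    """Tabulate sweep rows with one dose column per fraction scheme."""
    if len(rows) == 0:
        raise EmptyInputError("no sweep rows to tabulate")
    schemes = sorted({n for r in rows for n in r.doses})
    data = {
        "alpha_beta": [r.alpha_beta for r in rows],
        "auc": [r.auc for r in rows],
        "p_value": [r.auc_p_value for r in rows],
        "optimal_bed_gy": [r.optimal_bed for r in rows],
        "sensitivity": [r.sensitivity for r in rows],
        "specificity": [r.specificity for r in rows],
        "youden_j": [r.youden_j for r in rows],
    }
    for n in schemes:
        data[f"dose_{n}fx_gy"] = [r.doses.get(n, np.nan) for r in rows]
    return pd.DataFrame(data)


def _j_maximizers(rows: Sequence[SweepRow]) -> set[float]:
    jmax = max(r.youden_j for r in rows)
    return {r.alpha_beta for r in rows if r.youden_j >= jmax - _TIE_TOL}


def select_best_alpha_beta(
    rows: Sequence[SweepRow], subgroup_rows: Sequence[SweepRow] | None = None
) -> float:
    """α/β ratio with the highest Youden J; ties go to the smallest ratio.

    When ``subgroup_rows`` is supplied (the joint rule), the candidate set is
    first restricted to ratios that maximize J in *both* lists; if the two
    maximizer sets are disjoint the overall maximizers are used.
    """
    rows = list(rows)
    if len(rows) == 0:
        raise EmptyInputError("cannot select alpha/beta from an empty sweep")
    candidates = _j_maximizers(rows)
    if subgroup_rows:
        joint = candidates & _j_maximizers(subgroup_rows)
        if joint:
            candidates = joint
    return min(candidates)
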