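"""Paired diagnostic-accuracy statistics.

ROC/AUC estimation with DeLong confidence intervals and paired AUC tests,
Youden-index cut-off selection, confusion-table metrics (including balanced
accuracy, the quantity clinical validation reports as "predictive accuracy"),
McNemar tests for paired sensitivity/specificity/correct-classification, a
generalized score test for paired positive/negative predictive values, and a
reconstruction of full confusion tables from published Se/Sp percentages and
class counts.

Orientation conventions: for scales where a *higher* score marks the positive
(adverse) class (INCNS, APACHE II), a subject is predicted positive when its
score is >= the threshold; for lower-is-positive scales (GCS, FOUR) when the
score is <= the threshold.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from enum import Enum
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.contingency_tables import mcnemar as _sm_mcnemar


class Orientation(str, Enum):
    HIGHER_IS_POSITIVE = "higher_is_positive"
    LOWER_IS_POSITIVE = "lower_is_positive"


def round_half_up(value: float, ndigits: int = 1) -> float:
    """Decimal round-half-up (binary floats round-half-even: 82.55 -> 82.5)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def percentage(numerator: int, denominator: int, ndigits: int = 1) -> float:
    """A count ratio as a half-up rounded percentage (e.g. 26/271 -> 9.6)."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    q = Decimal(1).scaleb(-ndigits)
    pct = Decimal(numerator) * 100 / Decimal(denominator)
    return float(pct.quantize(q, rounding=ROUND_HALF_UP))


def predictive_accuracy_pct(se_pct: float, sp_pct: float) -> float:
    """Balanced accuracy (Se+Sp)/2 from percentages, half-up to one decimal.

    Computed in decimal arithmetic so that e.g. (76.9 + 88.2)/2 = 82.55 rounds
    up to 82.6 rather than down under binary floating point.
    """
    mean = (Decimal(repr(se_pct)) + Decimal(repr(sp_pct))) / 2
    return float(mean.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# Confusion tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConfusionTable:
    """A 2x2 classification table with the derived accuracy metrics."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.n == 0:
            raise ValueError("confusion table must contain at least one subject")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def se(self) -> float:
        return self.tp / (self.tp + self.fn)

    @property
    def sp(self) -> float:
        return self.tn / (self.tn + self.fp)

    @property
    def ppv(self) -> float:
        return self.tp / (self.tp + self.fp)

    @property
    def npv(self) -> float:
        return self.tn / (self.tn + self.fn)

    @property
    def cc(self) -> float:
        """Fraction of correctly classified subjects."""
        return (self.tp + self.tn) / self.n

    @property
    def balanced_accuracy(self) -> float:
        return (self.se + self.sp) / 2

    @property
    def youden_j(self) -> float:
        return self.se + self.sp - 1

    def as_percentages(self, ndigits: int = 1) -> dict[str, float]:
        """Reporting layer: metrics as half-up rounded percentages."""
        return {k: round_half_up(getattr(self, k) * 100, ndigits)
                for k in ("se", "sp", "ppv", "npv", "cc", "balanced_accuracy")}


def reconstruct_confusion(se_pct: float, sp_pct: float,
                          n_pos: int, n_neg: int) -> ConfusionTable:
    """Rebuild the full confusion table from printed Se/Sp and class counts.

    tp = round(se * n_pos), tn = round(sp * n_neg), rounding half up; the
    remaining cells follow from the class totals.
    """
    if not (0 <= se_pct <= 100 and 0 <= sp_pct <= 100):
        raise ValueError("percentages must lie in [0, 100]")
    if n_pos <= 0 or n_neg <= 0:
        raise ValueError("class counts must be positive")
    tp = int((Decimal(repr(se_pct)) / 100 * n_pos).quantize(Decimal(1), ROUND_HALF_UP))
    tn = int((Decimal(repr(sp_pct)) / 100 * n_neg).quantize(Decimal(1), ROUND_HALF_UP))
    if tp > n_pos or tn > n_neg:
        raise ValueError("rounded cell count exceeds its class total")
    return ConfusionTable(tp=tp, fp=n_neg - tn, tn=tn, fn=n_pos - tp)


# ---------------------------------------------------------------------------
# Empirical AUC and DeLong machinery
# ---------------------------------------------------------------------------

def _prepare(scores, labels, orientation) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be 1-d arrays of equal length")
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be binary")
    if labels.min() == labels.max():
        raise ValueError("both outcome classes must be present")
    if Orientation(orientation) is Orientation.LOWER_IS_POSITIVE:
        scores = -scores
    return scores, labels


def _midrank(x: np.ndarray) -> np.ndarray:
    return sps.rankdata(x, method="average")


def _delong_components(scores: np.ndarray, labels: np.ndarray
                       ) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC and the DeLong structural components (per-positive, per-negative)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    tz = _midrank(np.concatenate([pos, neg]))
    tx = _midrank(pos)
    ty = _midrank(neg)
    v10 = (tz[:m] - tx) / n
    v01 = 1.0 - (tz[m:] - ty) / m
    auc = (tz[:m].sum() - m * (m + 1) / 2) / (m * n)
    return auc, v10, v01


def empirical_auc(scores, labels, orientation=Orientation.HIGHER_IS_POSITIVE) -> float:
    """Mann-Whitney AUC: the probability that a positive subject ranks more
    positive than a negative one, with ties counted half."""
    scores, labels = _prepare(scores, labels, orientation)
    auc, _, _ = _delong_components(scores, labels)
    return float(auc)


def delong_auc_ci(scores, labels, orientation=Orientation.HIGHER_IS_POSITIVE,
                  level: float = 0.95) -> tuple[float, float, float]:
    """AUC with a DeLong-variance confidence interval on the logit scale.

    The logit transform keeps the interval inside [0, 1]; for degenerate data
    (zero DeLong variance, e.g. perfect separation) the interval collapses to
    the point estimate and a warning is issued.
    """
    scores, labels = _prepare(scores, labels, orientation)
    m = int(labels.sum())
    n = int(len(labels) - m)
    if m < 2 or n < 2:
        raise ValueError("need at least two subjects in each class")
    auc, v10, v01 = _delong_components(scores, labels)
    var = v10.var(ddof=1) / m + v01.var(ddof=1) / n
    if var <= 0 or auc in (0.0, 1.0):
        warnings.warn("degenerate DeLong variance: CI collapses to the AUC",
                      stacklevel=2)
        return float(auc), float(auc), float(auc)
    se = math.sqrt(var)
    z = sps.norm.ppf(0.5 + level / 2)
    logit = math.log(auc / (1 - auc))
    se_logit = se / (auc * (1 - auc))
    lo = 1 / (1 + math.exp(-(logit - z * se_logit)))
    hi = 1 / (1 + math.exp(-(logit + z * se_logit)))
    return float(auc), float(np.clip(lo, 0, 1)), float(np.clip(hi, 0, 1))


def bootstrap_auc_ci(scores, labels, orientation=Orientation.HIGHER_IS_POSITIVE,
                     level: float = 0.95, n_boot: int = 2000,
                     rng: Optional[np.random.Generator] = None
                     ) -> tuple[float, float, float]:
    """Percentile bootstrap CI for the AUC (stratified by class)."""
    scores, labels = _prepare(scores, labels, orientation)
    rng = rng or np.random.default_rng()
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    aucs = np.empty(n_boot)
    for b in range(n_boot):
        ps = rng.choice(pos, size=len(pos), replace=True)
        ns = rng.choice(neg, size=len(neg), replace=True)
        s = np.concatenate([ps, ns])
        y = np.concatenate([np.ones(len(ps), int), np.zeros(len(ns), int)])
        aucs[b], _, _ = _delong_components(s, y)
    alpha = 1 - level
    lo, hi = np.quantile(aucs, [alpha / 2, 1 - alpha / 2])
    auc, _, _ = _delong_components(scores, labels)
    return float(auc), float(lo), float(hi)


class Metric(str, Enum):
    AUC = "auc"
    SE = "se"
    SP = "sp"
    CC = "cc"
    PPV = "ppv"
    NPV = "npv"


class TestMethod(str, Enum):
    __test__ = False  # not a pytest class

    DELONG = "delong"
    MCNEMAR_EXACT = "mcnemar_exact"
    MCNEMAR_ASYMPTOTIC = "mcnemar_asymptotic"
    GENERALIZED_SCORE = "generalized_score"
    BOOTSTRAP = "bootstrap"


@dataclass(frozen=True)
class PairedComparison:
    """Result of one paired comparison between two scores."""

    metric: Metric
    method: TestMethod
    statistic: float
    p_value: float
    alpha: float
    note: Optional[str] = None

    def __post_init__(self) -> None:
        if not 0 <= self.p_value <= 1:
            raise ValueError(f"p-value must lie in [0, 1], got {self.p_value}")

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


def delong_paired_test(scores_a, scores_b, labels,
                       orientations=(Orientation.HIGHER_IS_POSITIVE,
                                     Orientation.HIGHER_IS_POSITIVE),
                       alpha: float = 0.0083) -> PairedComparison:
    """Two-sided z-test on AUC_a - AUC_b using the paired DeLong covariance.

    Both scores must be measured on the same subjects; each may carry its own
    severity orientation.
    """
    sa, la = _prepare(scores_a, labels, orientations[0])
    sb, lb = _prepare(scores_b, labels, orientations[1])
    if len(sa) != len(sb):
        raise ValueError("paired scores must have equal length")
    m = int(la.sum())
    n = len(la) - m
    auc_a, v10a, v01a = _delong_components(sa, la)
    auc_b, v10b, v01b = _delong_components(sb, lb)
    diff = auc_a - auc_b
    var = (np.var(v10a - v10b, ddof=1) / m + np.var(v01a - v01b, ddof=1) / n)
    note = None
    if var <= 0:
        if diff == 0:
            return PairedComparison(Metric.AUC, TestMethod.DELONG, 0.0, 1.0,
                                    alpha, note="degenerate: identical placements")
        note = "degenerate variance with nonzero AUC difference"
        z = math.inf if diff > 0 else -math.inf
        p = 0.0
    else:
        z = diff / math.sqrt(var)
        p = 2 * sps.norm.sf(abs(z))
    return PairedComparison(Metric.AUC, TestMethod.DELONG, float(z), float(p),
                            alpha, note=note)


# ---------------------------------------------------------------------------
# Cut-off selection and thresholded confusion tables
# ---------------------------------------------------------------------------

def _predict(scores: np.ndarray, threshold: float, orientation) -> np.ndarray:
    if Orientation(orientation) is Orientation.HIGHER_IS_POSITIVE:
        return scores >= threshold
    return scores <= threshold


def confusion_at_cutoff(scores, labels, threshold: float,
                        orientation=Orientation.HIGHER_IS_POSITIVE) -> ConfusionTable:
    """Confusion table for predicted-positive = score >= (or <=) threshold."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if not math.isfinite(threshold):
        raise ValueError("threshold must be finite")
    pred = _predict(scores, threshold, orientation)
    pos = labels == 1
    return ConfusionTable(
        tp=int((pred & pos).sum()), fp=int((pred & ~pos).sum()),
        tn=int((~pred & ~pos).sum()), fn=int((~pred & pos).sum()))


def youden_cutoff(scores, labels, orientation=Orientation.HIGHER_IS_POSITIVE
                  ) -> tuple[float, ConfusionTable]:
    """Cut-off maximizing Youden's J = Se + Sp - 1 over observed scores.

    Ties in J are broken toward higher sensitivity (a miss is costlier than a
    false alarm in prognostic screening), then toward the more inclusive
    threshold.
    """
    arr, lab = _prepare(scores, labels, Orientation.HIGHER_IS_POSITIVE)  # validation only
    del arr, lab
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    best = None
    higher = Orientation(orientation) is Orientation.HIGHER_IS_POSITIVE
    candidates = np.unique(scores)
    order = candidates if higher else candidates[::-1]
    for thr in order:
        ct = confusion_at_cutoff(scores, labels, float(thr), orientation)
        key = (ct.youden_j, ct.se, -thr if higher else thr)
        if best is None or key > best[0]:
            best = (key, float(thr), ct)
    return best[1], best[2]


def roc_points(scores, labels, orientation=Orientation.HIGHER_IS_POSITIVE
               ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(thresholds, Se, Sp) at every observed score, thresholds ascending."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    thresholds = np.unique(scores)
    se = np.empty_like(thresholds, dtype=float)
    sp = np.empty_like(thresholds, dtype=float)
    for i, thr in enumerate(thresholds):
        ct = confusion_at_cutoff(scores, labels, float(thr), orientation)
        se[i], sp[i] = ct.se, ct.sp
    return thresholds, se, sp


@dataclass
class ROCCurve:
    """Empirical ROC of one scale for one outcome."""

    scale: str
    orientation: Orientation
    thresholds: np.ndarray
    se_at: np.ndarray
    sp_at: np.ndarray
    auc: float
    ci95: tuple[float, float]
    n_pos: int
    n_neg: int

    @classmethod
    def from_scores(cls, scores, labels, scale: str = "",
                    orientation=Orientation.HIGHER_IS_POSITIVE,
                    ci_method: str = "delong", n_boot: int = 2000,
                    rng: Optional[np.random.Generator] = None) -> "ROCCurve":
        thresholds, se, sp = roc_points(scores, labels, orientation)
        if ci_method == "bootstrap":
            auc, lo, hi = bootstrap_auc_ci(scores, labels, orientation,
                                           n_boot=n_boot, rng=rng)
        else:
            auc, lo, hi = delong_auc_ci(scores, labels, orientation)
        labels_arr = np.asarray(labels).astype(int)
        return cls(scale=scale, orientation=Orientation(orientation),
                   thresholds=thresholds, se_at=se, sp_at=sp, auc=auc,
                   ci95=(lo, hi), n_pos=int(labels_arr.sum()),
                   n_neg=int(len(labels_arr) - labels_arr.sum()))


# ---------------------------------------------------------------------------
# Paired tests on thresholded classifications
# ---------------------------------------------------------------------------

def mcnemar_paired(metric: Metric, class_a_correct, class_b_correct,
                   alpha: float = 0.05, exact_threshold: int = 25) -> PairedComparison:
    """McNemar test on paired correctness indicators.

    Exact binomial test on the discordant pairs when their number is below
    ``exact_threshold``, else the chi-square approximation with continuity
    correction.  With no discordant pairs the test is degenerate and p = 1.
    """
    a = np.asarray(class_a_correct).astype(bool)
    b = np.asarray(class_b_correct).astype(bool)
    if a.shape != b.shape:
        raise ValueError("paired correctness arrays must have equal length")
    disc_ab = int((a & ~b).sum())
    disc_ba = int((~a & b).sum())
    n_disc = disc_ab + disc_ba
    if n_disc == 0:
        return PairedComparison(Metric(metric), TestMethod.MCNEMAR_EXACT, 0.0,
                                1.0, alpha, note="degenerate: no discordant pairs")
    table = [[0, disc_ab], [disc_ba, 0]]
    exact = n_disc < exact_threshold
    res = _sm_mcnemar(table, exact=exact, correction=True)
    method = TestMethod.MCNEMAR_EXACT if exact else TestMethod.MCNEMAR_ASYMPTOTIC
    return PairedComparison(Metric(metric), method, float(res.statistic),
                            float(min(res.pvalue, 1.0)), alpha)


def compare_predictive_values(metric: Metric, predictions_a, predictions_b,
                              labels, alpha: float = 0.05,
                              method: TestMethod = TestMethod.GENERALIZED_SCORE,
                              n_boot: int = 2000,
                              rng: Optional[np.random.Generator] = None
                              ) -> PairedComparison:
    """Paired test for equality of PPVs (or NPVs) of two dichotomized scores.

    The default is a generalized score statistic: a GEE-type score test of the
    test-identity effect on the disease outcome among predicted-positive
    records (predicted-negative for NPV), with an empirical subject-clustered
    variance.  A subject predicted positive by both scores contributes two
    correlated records.  ``method="bootstrap"`` replaces the model variance by
    a subject-resampling bootstrap standard error.
    """
    metric = Metric(metric)
    if metric not in (Metric.PPV, Metric.NPV):
        raise ValueError("metric must be ppv or npv")
    pa = np.asarray(predictions_a).astype(int)
    pb = np.asarray(predictions_b).astype(int)
    d = np.asarray(labels).astype(int)
    if not (pa.shape == pb.shape == d.shape):
        raise ValueError("predictions and labels must have equal length")
    if metric is Metric.NPV:
        pa, pb, d = 1 - pa, 1 - pb, 1 - d
    na, nb = int(pa.sum()), int(pb.sum())
    if na == 0 or nb == 0:
        raise ValueError(f"{metric.value} undefined: a score has no "
                         f"predicted {'positives' if metric is Metric.PPV else 'negatives'}")

    pv_a = float(d[pa == 1].mean())
    pv_b = float(d[pb == 1].mean())

    if method == TestMethod.BOOTSTRAP:
        rng = rng or np.random.default_rng()
        n = len(d)
        diffs = []
        for _ in range(n_boot):
            idx = rng.integers(0, n, n)
            ra, rb, rd = pa[idx], pb[idx], d[idx]
            if ra.sum() == 0 or rb.sum() == 0:
                continue
            diffs.append(rd[ra == 1].mean() - rd[rb == 1].mean())
        se = float(np.std(diffs, ddof=1))
        diff = pv_a - pv_b
        if se == 0:
            stat, p = 0.0, 1.0
        else:
            stat = diff / se
            p = 2 * sps.norm.sf(abs(stat))
        return PairedComparison(metric, TestMethod.BOOTSTRAP, float(stat),
                                float(p), alpha)

    # generalized score statistic with subject-clustered empirical variance
    tot = na + nb
    phat = (d[pa == 1].sum() + d[pb == 1].sum()) / tot
    zbar = nb / tot
    u = (pa * (0 - zbar) + pb * (1 - zbar)) * (d - phat)
    numerator = u.sum() ** 2
    denominator = (u ** 2).sum()
    if denominator == 0:
        return PairedComparison(metric, TestMethod.GENERALIZED_SCORE, 0.0, 1.0,
                                alpha, note="degenerate: identical classifications")
    stat = float(numerator / denominator)
    p = float(sps.chi2.sf(stat, df=1))
    return PairedComparison(metric, TestMethod.GENERALIZED_SCORE, stat, p, alpha)


def bonferroni_alpha(n_comparisons: int) -> float:
    """Family-wise 0.05 split over n comparisons, rounded to 4 decimals."""
    if n_comparisons < 1:
        raise ValueError("need at least one comparison")
    alpha = Decimal("0.05") / n_comparisons
    return float(alpha.quantize(Decimal("0.0001"), rounding=ROUND_HALF_UP))
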