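"""Validation analysis of severity scales against a cohort outcome.

:class:`ScoreValidation` is the model object: it binds a cohort table, one
binary outcome and one scoring window.  ``fit()`` produces a
:class:`ValidationResults` carrying, per scale, the empirical ROC with a
DeLong confidence interval, the Youden cut-off with its confusion metrics, the
full pairwise DeLong AUC comparison matrix (at the multiplicity-corrected
alpha), and — for the reference scale against each comparator — McNemar tests
of sensitivity, specificity and correct classification plus generalized score
tests of PPV and NPV at each scale's own cut-off.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .cohort import CohortRow, cohort_to_frame
from .scales import HIGHER_IS_WORSE, Scale
from .stats import (
    ConfusionTable,
    Metric,
    Orientation,
    PairedComparison,
    ROCCurve,
    compare_predictive_values,
    confusion_at_cutoff,
    mcnemar_paired,
    youden_cutoff,
)

OUTCOME_COLUMNS = {
    "unfavorable": "outcome_unfavorable",
    "nicu_death": "outcome_nicu_death",
    "3m_death": "outcome_3m_death",
}


def scale_orientation(scale: Scale) -> Orientation:
    return (Orientation.HIGHER_IS_POSITIVE if HIGHER_IS_WORSE[Scale(scale)]
            else Orientation.LOWER_IS_POSITIVE)


class ScoreValidation:
    """Paired diagnostic-accuracy comparison of severity scales.

    Parameters
    ----------
    data
        Cohort table with ``<scale>_<window>`` score columns and the binary
        outcome columns.
    outcome
        One of ``unfavorable``, ``nicu_death``, ``3m_death``.
    window
        Scoring window in hours (24 or 72).
    scales
        Scales to analyse; the first pairwise family alpha defaults to the
        conventional multiplicity-corrected 0.0083 for ROC comparisons, and
        0.05 for the thresholded metric comparisons.
    reference
        The scale whose thresholded metrics are tested against every other
        scale (the new instrument under validation).
    """

    def __init__(self, data: pd.DataFrame, outcome: str, window: int,
                 scales: Sequence[Scale] = (Scale.INCNS, Scale.APACHE2,
                                            Scale.FOUR, Scale.GCS),
                 reference: Scale = Scale.INCNS,
                 alpha_roc: float = 0.0083, alpha_metrics: float = 0.05):
        if outcome not in OUTCOME_COLUMNS:
            raise ValueError(f"unknown outcome {outcome!r}; "
                             f"expected one of {sorted(OUTCOME_COLUMNS)}")
        if window not in (24, 72):
            raise ValueError("window must be 24 or 72")
        self.data = data.reset_index(drop=True)
        self.outcome = outcome
        self.window = int(window)
        self.scales = tuple(Scale(s) for s in scales)
        self.reference = Scale(reference)
        if self.reference not in self.scales:
            raise ValueError("reference scale must be among the analysed scales")
        self.alpha_roc = alpha_roc
        self.alpha_metrics = alpha_metrics
        self.labels = self.data[OUTCOME_COLUMNS[outcome]].astype(int).to_numpy()
        if self.labels.min() == self.labels.max():
            raise ValueError("both outcome classes must be present in the cohort")
        missing = [self._column(s) for s in self.scales
                   if self._column(s) not in self.data.columns]
        if missing:
            raise ValueError(f"cohort table lacks score columns: {missing}")

    @classmethod
    def from_cohort(cls, rows: Sequence[CohortRow], outcome: str, window: int,
                    **kwargs) -> "ScoreValidation":
        return cls(cohort_to_frame(rows), outcome, window, **kwargs)

    def _column(self, scale: Scale) -> str:
        return f"{Scale(scale).value}_{self.window}"

    def scores(self, scale: Scale) -> np.ndarray:
        return self.data[self._column(scale)].to_numpy(dtype=float)

    def fit(self) -> "ValidationResults":
        rocs: dict[Scale, ROCCurve] = {}
        cutoffs: dict[Scale, float] = {}
        confusions: dict[Scale, ConfusionTable] = {}
        predictions: dict[Scale, np.ndarray] = {}
        for scale in self.scales:
            s = self.scores(scale)
            orient = scale_orientation(scale)
            rocs[scale] = ROCCurve.from_scores(s, self.labels, scale.value, orient)
            thr, ct = youden_cutoff(s, self.labels, orient)
            cutoffs[scale] = thr
            confusions[scale] = ct
            if orient is Orientation.HIGHER_IS_POSITIVE:
                predictions[scale] = (s >= thr).astype(int)
            else:
                predictions[scale] = (s <= thr).astype(int)

        from .stats import delong_paired_test  # local to keep module surface tidy
        pairwise_auc: dict[tuple[Scale, Scale], PairedComparison] = {}
        for a, b in combinations(self.scales, 2):
            pairwise_auc[(a, b)] = delong_paired_test(
                self.scores(a), self.scores(b), self.labels,
                orientations=(scale_orientation(a), scale_orientation(b)),
                alpha=self.alpha_roc)

        metric_tests: dict[tuple[Scale, Scale, Metric], PairedComparison] = {}
        pos = self.labels == 1
        for other in self.scales:
            if other is self.reference:
                continue
            pred_r, pred_o = predictions[self.reference], predictions[other]
            correct_r = pred_r == self.labels
            correct_o = pred_o == self.labels
            pair = (self.reference, other)
            metric_tests[(*pair, Metric.SE)] = mcnemar_paired(
                Metric.SE, correct_r[pos], correct_o[pos], alpha=self.alpha_metrics)
            metric_tests[(*pair, Metric.SP)] = mcnemar_paired(
                Metric.SP, correct_r[~pos], correct_o[~pos], alpha=self.alpha_metrics)
            metric_tests[(*pair, Metric.CC)] = mcnemar_paired(
                Metric.CC, correct_r, correct_o, alpha=self.alpha_metrics)
            for metric in (Metric.PPV, Metric.NPV):
                metric_tests[(*pair, metric)] = compare_predictive_values(
                    metric, pred_r, pred_o, self.labels, alpha=self.alpha_metrics)

        return ValidationResults(
            model=self, rocs=rocs, cutoffs=cutoffs, confusions=confusions,
            predictions=predictions, pairwise_auc=pairwise_auc,
            metric_tests=metric_tests, nobs=len(self.labels))


@dataclass
class ValidationResults:
    """Fitted validation analysis: estimates, uncertainties and tests."""

    model: ScoreValidation
    rocs: dict
    cutoffs: dict
    confusions: dict
    predictions: dict
    pairwise_auc: dict
    metric_tests: dict
    nobs: int

    def summary(self) -> str:
        """Human-readable summary tables (statsmodels SimpleTable layout)."""
        from statsmodels.iolib.table import SimpleTable

        m = self.model
        head = (f"Score validation  outcome={m.outcome}  window={m.window} h  "
                f"n={self.nobs} ({int(m.labels.sum())} positive)")

        rows = []
        for scale in m.scales:
            roc, ct = self.rocs[scale], self.confusions[scale]
            pct = ct.as_percentages()
            rows.append([
                scale.value, f"{roc.auc:.3f}",
                f"({roc.ci95[0]:.3f}-{roc.ci95[1]:.3f})",
                f"{self.cutoffs[scale]:g}", f"{pct['se']:.1f}",
                f"{pct['sp']:.1f}", f"{pct['ppv']:.1f}", f"{pct['npv']:.1f}",
                f"{pct['cc']:.1f}", f"{pct['balanced_accuracy']:.1f}"])
        t1 = SimpleTable(
            rows,
            headers=["scale", "AUC", "95% CI", "cutoff", "Se%", "Sp%",
                     "PPV%", "NPV%", "CC%", "pred.acc%"],
            title=head)

        rows2 = [[a.value, b.value, f"{c.statistic:.3f}", f"{c.p_value:.4f}",
                  "*" if c.significant else ""]
                 for (a, b), c in self.pairwise_auc.items()]
        t2 = SimpleTable(rows2, headers=["scale A", "scale B", "z", "p", ""],
                         title=f"Paired DeLong AUC tests (alpha={m.alpha_roc})")

        rows3 = [[a.value, b.value, metric.value, c.method.value,
                  f"{c.p_value:.4f}", "*" if c.significant else ""]
                 for (a, b, metric), c in self.metric_tests.items()]
        t3 = SimpleTable(rows3, headers=["ref", "vs", "metric", "method", "p", ""],
                         title=f"Thresholded metric tests (alpha={m.alpha_metrics})")
        return "\n".join([t1.as_text(), "", t2.as_text(), "", t3.as_text()])

    def to_dict(self) -> dict:
        """JSON-serializable result payload."""
        m = self.model
        out = {
            "outcome": m.outcome, "window": m.window, "n": self.nobs,
            "n_pos": int(m.labels.sum()),
            "alpha_roc": m.alpha_roc, "alpha_metrics": m.alpha_metrics,
            "scales": {}, "pairwise_auc": [], "metric_tests": [],
        }
        for scale in m.scales:
            roc, ct = self.rocs[scale], self.confusions[scale]
            out["scales"][scale.value] = {
                "auc": roc.auc, "ci95": list(roc.ci95),
                "orientation": roc.orientation.value,
                "cutoff": self.cutoffs[scale],
                "confusion": {"tp": ct.tp, "fp": ct.fp, "tn": ct.tn, "fn": ct.fn},
                "metrics_pct": ct.as_percentages(),
            }
        for (a, b), c in self.pairwise_auc.items():
            out["pairwise_auc"].append({
                "a": a.value, "b": b.value, "statistic": c.statistic,
                "p_value": c.p_value, "alpha": c.alpha, "method": c.method.value})
        for (a, b, metric), c in self.metric_tests.items():
            out["metric_tests"].append({
                "a": a.value, "b": b.value, "metric": metric.value,
                "method": c.method.value, "statistic": c.statistic,
                "p_value": c.p_value, "alpha": c.alpha})
        return out

    def plot_roc(self, ax=None):
        """Plot all fitted ROC curves on one axis (returns the axis)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 5))
        for scale, roc in self.rocs.items():
            fpr = 1 - roc.sp_at
            order = np.argsort(fpr, kind="stable")
            x = np.concatenate([[0.0], fpr[order], [1.0]])
            y = np.concatenate([[0.0], roc.se_at[order], [1.0]])
            ax.plot(x, y, label=f"{scale.value} (AUC {roc.auc:.3f})")
        ax.plot([0, 1], [0, 1], "k--", lw=0.8)
        ax.set_xlabel("1 - specificity")
        ax.set_ylabel("sensitivity")
        ax.set_title(f"{self.model.outcome}, {self.model.window} h")
        ax.legend(loc="lower right", fontsize=8)
        return ax
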