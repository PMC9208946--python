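"""ROI-level group comparison and ROC discrimination of zALFF values.

Given per-subject zALFF maps and an integer ROI label volume, this module
extracts ROI mean values, compares two groups with t / chi-square tests,
and builds empirical ROC curves with trapezoidal AUC and the Youden-index
cut-off.  Inference is at the ROI level; p-values are reported uncorrected
by default, with optional Bonferroni/FDR adjustment helpers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve as _sk_roc_curve

from .alff import ZALFFMap

__all__ = [
    "ROISet",
    "ROCCurve",
    "roi_means",
    "two_sample_t",
    "two_sample_t_from_summary",
    "chi_square_2x2",
    "roc_analysis",
    "adjust_pvalues",
]


@dataclass
class ROISet:
    """An integer label volume plus a code → name table."""

    labels: np.ndarray
    names: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        codes = np.unique(self.labels)
        codes = codes[codes > 0]
        if any(c <= 0 for c in self.names):
            raise ValueError("ROI codes must be positive")
        if len(set(self.names.values())) != len(self.names):
            raise ValueError("ROI names must be unique")
        for c in codes:
            self.names.setdefault(int(c), f"roi-{int(c)}")

    @property
    def codes(self) -> list[int]:
        return sorted(self.names)


@dataclass
class ROCCurve:
    """Empirical ROC: operating points sorted by threshold, trapezoidal AUC,
    and the Youden cut-off with its sensitivity/specificity.

    ``direction`` records the decision rule: ``"cases_high"`` calls
    score >= threshold a case, ``"cases_low"`` calls score <= threshold a
    case.
    """

    points: pd.DataFrame  # columns: threshold, sensitivity, specificity
    auc: float
    youden_cutoff: float
    sens_at_cutoff: float
    spec_at_cutoff: float
    direction: str


def roi_means(zalff: ZALFFMap, rois: ROISet) -> pd.DataFrame:
    """Mean in-mask zALFF per ROI code.

    Returns a tidy frame (roi, name, n_voxels, mean); an ROI with no voxels
    inside the map's mask is flagged with ``n_voxels=0`` and a NaN mean
    rather than a fabricated zero.
    """
    if rois.labels.shape != zalff.values.shape:
        raise ValueError(
            f"ROI grid {rois.labels.shape} does not match zALFF grid "
            f"{zalff.values.shape}"
        )
    rows = []
    for code in rois.codes:
        sel = (rois.labels == code) & zalff.mask
        n = int(sel.sum())
        rows.append(
            {
                "roi": code,
                "name": rois.names[code],
                "n_voxels": n,
                "mean": float(zalff.values[sel].mean()) if n else np.nan,
            }
        )
    return pd.DataFrame(rows)


def two_sample_t(a, b, variant: str = "welch") -> tuple[float, float]:
    """Two-sided two-sample t-test; ``variant`` selects Welch or pooled.

    Degenerate input — zero variance in both groups with equal means —
    returns (0.0, 1.0); zero variance with unequal means is undefined and
    raises.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    if variant not in ("welch", "pooled"):
        raise ValueError("variant must be 'welch' or 'pooled'")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        raise ValueError("zero variance in both groups with unequal means")
    t, p = stats.ttest_ind(a, b, equal_var=(variant == "pooled"))
    return float(t), float(p)


def two_sample_t_from_summary(
    mean1: float,
    sd1: float,
    n1: int,
    mean2: float,
    sd2: float,
    n2: int,
    variant: str = "welch",
) -> tuple[float, float]:
    """t-test from printed group summaries (mean ± SD, n) only."""
    if min(n1, n2) < 2:
        raise ValueError("each group needs n >= 2")
    v1, v2 = sd1**2, sd2**2
    if variant == "welch":
        se2 = v1 / n1 + v2 / n2
        t = (mean1 - mean2) / np.sqrt(se2)
        df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    elif variant == "pooled":
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        t = (mean1 - mean2) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
        df = n1 + n2 - 2
    else:
        raise ValueError("variant must be 'welch' or 'pooled'")
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(p)


def chi_square_2x2(table, correction: bool = False) -> tuple[float, float]:
    """Pearson chi-square on a 2×2 count table (df = 1, two-sided p).

    Yates continuity correction is off by default.
    """
    tab = np.asarray(table)
    if tab.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {tab.shape}")
    if (tab < 0).any() or not np.issubdtype(tab.dtype, np.integer):
        tab_f = np.asarray(table, dtype=float)
        if (tab_f < 0).any() or not np.allclose(tab_f, np.round(tab_f)):
            raise ValueError("counts must be non-negative integers")
        tab = np.round(tab_f).astype(int)
    if (tab.sum(axis=0) == 0).any() or (tab.sum(axis=1) == 0).any():
        raise ValueError("table has a zero margin")
    chi2, p, _, _ = stats.chi2_contingency(tab, correction=correction)
    return float(chi2), float(p)


def roc_analysis(cases, controls, direction: str = "auto") -> ROCCurve:
    """Empirical ROC of case vs control scores.

    The curve is built over every distinct threshold; AUC is trapezoidal
    (equal to the Mann–Whitney pair-ordering proportion for an empirical
    ROC).  The Youden cut-off maximises sensitivity + specificity − 1, ties
    broken toward the lowest threshold.  ``direction="auto"`` orients the
    rule so AUC >= 0.5 and records the choice.
    """
    cases = np.asarray(cases, dtype=float)
    controls = np.asarray(controls, dtype=float)
    if len(cases) == 0 or len(controls) == 0:
        raise ValueError("both groups must be non-empty")
    if direction not in ("auto", "cases_high", "cases_low"):
        raise ValueError("direction must be 'auto', 'cases_high' or 'cases_low'")

    def _build(flip: bool):
        sign = -1.0 if flip else 1.0
        scores = np.concatenate([sign * cases, sign * controls])
        y = np.concatenate([np.ones(len(cases)), np.zeros(len(controls))])
        fpr, tpr, thr = _sk_roc_curve(y, scores, drop_intermediate=False)
        return fpr, tpr, thr, float(_trapezoid_auc(fpr, tpr))

    if direction == "auto":
        fpr, tpr, thr, area = _build(False)
        chosen = "cases_high"
        if area < 0.5:
            fpr, tpr, thr, area = _build(True)
            chosen = "cases_low"
    else:
        chosen = direction
        fpr, tpr, thr, area = _build(direction == "cases_low")

    sign = -1.0 if chosen == "cases_low" else 1.0
    finite = np.isfinite(thr)
    sens = tpr[finite]
    spec = 1.0 - fpr[finite]
    cutpoints = sign * thr[finite]  # back to the original score scale

    youden = sens + spec - 1.0
    best = np.flatnonzero(youden == youden.max())
    # ties -> lowest threshold on the original scale
    pick = best[np.argmin(cutpoints[best])]

    points = (
        pd.DataFrame(
            {"threshold": cutpoints, "sensitivity": sens, "specificity": spec}
        )
        .sort_values("threshold", kind="stable")
        .reset_index(drop=True)
    )
    return ROCCurve(
        points=points,
        auc=area,
        youden_cutoff=float(cutpoints[pick]),
        sens_at_cutoff=float(sens[pick]),
        spec_at_cutoff=float(spec[pick]),
        direction=chosen,
    )


def adjust_pvalues(pvalues, method: str = "none") -> np.ndarray:
    """Optional multiple-testing adjustment: 'none', 'bonferroni' or 'fdr_bh'."""
    p = np.asarray(pvalues, dtype=float)
    if method == "none":
        return p.copy()
    if method == "bonferroni":
        return np.minimum(p * len(p), 1.0)
    if method == "fdr_bh":
        order = np.argsort(p)
        ranked = p[order] * len(p) / (np.arange(len(p)) + 1)
        ranked = np.minimum.accumulate(ranked[::-1])[::-1]
        out = np.empty_like(p)
        out[order] = np.minimum(ranked, 1.0)
        return out
    raise ValueError("method must be 'none', 'bonferroni' or 'fdr_bh'")
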