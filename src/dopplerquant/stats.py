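"""Cohort statistics: normality-gated group tests, ROC cut-offs, paired AUCs.

Group comparisons follow the classic two-branch recipe: when both groups
pass a Shapiro-Wilk normality gate (alpha = 0.05) an unequal-variance
two-sample t-test is used and groups are summarized as mean +/- SD;
otherwise a two-sided Mann-Whitney U test with median (Q1-Q3) summaries.

ROC analysis uses the Mann-Whitney concordance estimator of the AUC (ties
count one half), auto-orients the decision direction so AUC >= 0.5, and
reports the *nadir value*: the observed cut-off maximizing Youden's
J = sensitivity + specificity - 1, ties broken toward higher specificity
and then the smaller threshold.  Under the lower-is-malignant orientation
the decision rule is "value <= nadir => malignant".

Paired AUC comparison between two parameters measured on the same cases
uses DeLong's test for correlated AUCs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import (
    DegenerateSampleError,
    InsufficientGroupError,
    InsufficientPairsError,
    SingleClassError,
)

POSITIVE_LABEL = "malignant"
NEGATIVE_LABEL = "inflammatory"

#: The six flow parameters of the two Doppler methods.
DTPM_PARAMS = ("tfv", "tri", "tpi")
SVFM_PARAMS = ("fv", "ri", "volf")
ALL_PARAMS = DTPM_PARAMS + SVFM_PARAMS


@dataclass
class GroupComparison:
    parameter: str
    test: str  # "t" | "mann-whitney"
    summary_positive: str  # malignant group
    summary_negative: str  # inflammatory group
    p: float


@dataclass
class RocResult:
    parameter: str
    direction: str  # "lower-is-malignant" | "higher-is-malignant"
    auc: float
    nadir: float
    sensitivity: float
    specificity: float
    acc: float
    p: float  # AUC vs 0.5, Mann-Whitney normal approximation
    curve: dict = field(default_factory=dict)  # {"fpr": [...], "tpr": [...]}


def normality_gate(sample, alpha: float = 0.05) -> bool:
    """True iff the Shapiro-Wilk test does not reject normality at ``alpha``."""
    x = np.asarray(sample, dtype=float)
    if x.size < 3:
        raise DegenerateSampleError("degenerate sample: need at least 3 observations")
    if np.ptp(x) == 0:
        raise DegenerateSampleError("degenerate sample: constant values")
    return bool(sps.shapiro(x).pvalue >= alpha)


def _split(values, labels):
    v = np.asarray(values, dtype=float)
    lab = np.asarray(labels)
    pos = v[lab == POSITIVE_LABEL]
    neg = v[lab == NEGATIVE_LABEL]
    pos = pos[np.isfinite(pos)]
    neg = neg[np.isfinite(neg)]
    return pos, neg


def compare_groups(
    values, labels, parameter: str = "", alpha: float = 0.05, method: str = "auto"
) -> GroupComparison:
    """Two-group comparison; the normality gate chooses the test unless
    ``method`` forces "t" or "mann-whitney"."""
    pos, neg = _split(values, labels)
    if min(pos.size, neg.size) < 3:
        raise InsufficientGroupError("insufficient group size: need >= 3 per group")
    if method == "auto":
        try:
            normal = normality_gate(pos, alpha) and normality_gate(neg, alpha)
        except DegenerateSampleError:
            normal = False
    else:
        normal = method == "t"
    if normal:
        res = sps.ttest_ind(pos, neg, equal_var=False)
        summarize = lambda x: f"{x.mean():.3f} ±{x.std(ddof=1):.3f}"
        test = "t"
    else:
        res = sps.mannwhitneyu(pos, neg, alternative="two-sided")
        summarize = lambda x: (
            f"{np.median(x):.3f} ({np.percentile(x, 25):.3f}–{np.percentile(x, 75):.3f})"
        )
        test = "mann-whitney"
    return GroupComparison(
        parameter=parameter,
        test=test,
        summary_positive=summarize(pos),
        summary_negative=summarize(neg),
        p=float(res.pvalue),
    )


def concordance_auc(pos: np.ndarray, neg: np.ndarray) -> float:
    """Mann-Whitney concordance P(pos > neg) + 0.5 P(pos == neg), via midranks."""
    pos = np.asarray(pos, dtype=float)
    neg = np.asarray(neg, dtype=float)
    allv = np.concatenate([pos, neg])
    ranks = sps.rankdata(allv)
    u = ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))


def _confusion_at(pos, neg, nadir, lower_is_positive: bool):
    if lower_is_positive:
        sens = float(np.mean(pos <= nadir))
        spec = float(np.mean(neg > nadir))
    else:
        sens = float(np.mean(pos >= nadir))
        spec = float(np.mean(neg < nadir))
    acc = (sens * pos.size + spec * neg.size) / (pos.size + neg.size)
    return sens, spec, float(acc)


def roc_analysis(values, labels, parameter: str = "") -> RocResult:
    """ROC with concordance AUC, auto-orientation and Youden-optimal nadir."""
    pos, neg = _split(values, labels)
    if pos.size == 0 or neg.size == 0:
        raise SingleClassError("single-class input: both labels required")

    auc_higher = concordance_auc(pos, neg)  # P(malignant value > inflammatory)
    lower = (1.0 - auc_higher) >= auc_higher
    auc = 1.0 - auc_higher if lower else auc_higher
    direction = "lower-is-malignant" if lower else "higher-is-malignant"

    thresholds = np.unique(np.concatenate([pos, neg]))
    best = None  # (J, spec, -thr) maximized; ties -> higher spec, smaller thr
    curve_fpr, curve_tpr = [], []
    for thr in thresholds:
        sens, spec, _ = _confusion_at(pos, neg, thr, lower)
        curve_fpr.append(1.0 - spec)
        curve_tpr.append(sens)
        key = (sens + spec - 1.0, spec, -thr)
        if best is None or key > best[0]:
            best = (key, thr, sens, spec)
    _, nadir, sens, spec = best
    acc = (sens * pos.size + spec * neg.size) / (pos.size + neg.size)

    if np.ptp(np.concatenate([pos, neg])) == 0:
        p = 1.0
    else:
        p = float(sps.mannwhitneyu(pos, neg, alternative="two-sided", method="asymptotic").pvalue)

    order = np.argsort(curve_fpr, kind="stable")
    return RocResult(
        parameter=parameter,
        direction=direction,
        auc=float(auc),
        nadir=float(nadir),
        sensitivity=float(sens),
        specificity=float(spec),
        acc=float(acc),
        p=p,
        curve={
            "fpr": [0.0] + [float(curve_fpr[i]) for i in order] + [1.0],
            "tpr": [0.0] + [float(curve_tpr[i]) for i in order] + [1.0],
        },
    )


def _delong_components(pos: np.ndarray, neg: np.ndarray):
    """Placement values V10 (per positive) and V01 (per negative)."""
    diff = pos[:, None] - neg[None, :]
    psi = np.where(diff > 0, 1.0, np.where(diff == 0, 0.5, 0.0))
    return psi.mean(axis=1), psi.mean(axis=0), float(psi.mean())


def compare_auc(values_a, values_b, labels) -> float:
    """DeLong two-sided p for the paired AUC difference of two parameters.

    Both parameters must be observed on the same cases; cases missing
    either value are dropped pairwise.  Each parameter is auto-oriented
    (as in :func:`roc_analysis`) before comparison, so the test contrasts
    discriminative ability regardless of decision direction.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    lab = np.asarray(labels)
    keep = np.isfinite(a) & np.isfinite(b)
    a, b, lab = a[keep], b[keep], lab[keep]
    is_pos = lab == POSITIVE_LABEL
    is_neg = lab == NEGATIVE_LABEL
    if min(is_pos.sum(), is_neg.sum()) < 2:
        raise InsufficientPairsError("insufficient pairs: need >= 2 cases per class")

    v10 = np.empty((2, int(is_pos.sum())))
    v01 = np.empty((2, int(is_neg.sum())))
    aucs = np.empty(2)
    for k, vals in enumerate((a, b)):
        pos, neg = vals[is_pos], vals[is_neg]
        if concordance_auc(pos, neg) < 0.5:
            pos, neg = -pos, -neg  # orient so higher score = malignant
        v10[k], v01[k], aucs[k] = _delong_components(pos, neg)

    m, n = v10.shape[1], v01.shape[1]
    s10 = np.cov(v10) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(v01) if n > 1 else np.zeros((2, 2))
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    diff = aucs[0] - aucs[1]
    if var <= 1e-15:
        return 1.0 if abs(diff) < 1e-12 else 0.0
    z = diff / np.sqrt(var)
    return float(2.0 * sps.norm.sf(abs(z)))


def build_report(cohort: pd.DataFrame, parameters=ALL_PARAMS):
    """Group-comparison and ROC tables for a per-case cohort table.

    ``cohort`` needs columns ``case_id``, ``label`` and the parameter
    columns (missing values allowed, e.g. for SVFM-excluded cases).
    Returns ``(table1, table2, roc_curves)`` where the tables are
    DataFrames (one row per parameter, NA rows where a parameter has no
    analyzable data) and ``roc_curves`` maps parameter -> curve points.
    """
    t1_rows, t2_rows, curves = [], [], {}
    for p in parameters:
        vals = cohort[p].to_numpy(dtype=float)
        labs = cohort["label"].to_numpy()
        try:
            gc = compare_groups(vals, labs, parameter=p)
            roc = roc_analysis(vals, labs, parameter=p)
        except (InsufficientGroupError, SingleClassError, DegenerateSampleError):
            t1_rows.append({"parameter": p, "malignant": "NA", "inflammatory": "NA", "test": "NA", "p": np.nan})
            t2_rows.append(
                {"parameter": p, "nadir": np.nan, "sensitivity": np.nan, "specificity": np.nan,
                 "acc": np.nan, "auc": np.nan, "p": np.nan, "direction": "NA"}
            )
            continue
        t1_rows.append(
            {"parameter": p, "malignant": gc.summary_positive, "inflammatory": gc.summary_negative,
             "test": gc.test, "p": gc.p}
        )
        t2_rows.append(
            {"parameter": p, "nadir": roc.nadir, "sensitivity": roc.sensitivity,
             "specificity": roc.specificity, "acc": roc.acc, "auc": roc.auc,
             "p": roc.p, "direction": roc.direction}
        )
        curves[p] = roc.curve
    return pd.DataFrame(t1_rows), pd.DataFrame(t2_rows), curves
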