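"""Cohort statistics: normality gate, group tests, ROC, paired AUC comparison."""

from itertools import combinations

import numpy as np
import pytest

import dopplerquant as dq
from dopplerquant.errors import (
    DegenerateSampleError,
    InsufficientPairsError,
    SingleClassError,
)
from dopplerquant.stats import concordance_auc


def labels_of(n_mal, n_inf):
    return np.array(["malignant"] * n_mal + ["inflammatory"] * n_inf)


def brute_force_auc(pos, neg):
    """Pairwise concordance count, the independent AUC oracle."""
    wins = ties = 0
    for x in pos:
        for y in neg:
            wins += x > y
            ties += x == y
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


def exact_mwu_p(x, y):
    """Full-enumeration two-sided Mann-Whitney p for small samples."""
    pooled = list(x) + list(y)
    n = len(x)

    def u_of(idx):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(len(pooled)) if i not in idx]
        return sum(a > b for a in xs for b in ys) + 0.5 * sum(a == b for a in xs for b in ys)

    observed = u_of(range(n))
    mean_u = len(x) * len(y) / 2.0
    dev = abs(observed - mean_u)
    count = total = 0
    for idx in combinations(range(len(pooled)), n):
        total += 1
        if abs(u_of(set(idx)) - mean_u) >= dev - 1e-12:
            count += 1
    return count / total


def test_normality_gate_levels(rng):
    normal_pass = sum(dq.normality_gate(rng.normal(size=40)) for _ in range(400))
    assert 0.91 <= normal_pass / 400 <= 0.99  # ~5% false-rejection level
    exp_pass = sum(dq.normality_gate(rng.exponential(size=40)) for _ in range(200))
    assert exp_pass / 200 <= 0.3  # strong power against Exp(1) at n=40


def test_normality_gate_rejects_constant():
    with pytest.raises(DegenerateSampleError, match="degenerate sample"):
        dq.normality_gate([2.0] * 10)


def test_identical_groups_give_p_one():
    vals = np.array([1.0, 2, 3, 4, 5, 1, 2, 3, 4, 5])
    gc = dq.compare_groups(vals, labels_of(5, 5))
    assert gc.p == pytest.approx(1.0)


def test_mann_whitney_exact_p_matches_enumeration():
    x, y = [1, 2, 3, 4, 5], [10, 11, 12, 13, 14]
    vals = np.array(x + y, dtype=float)
    gc = dq.compare_groups(vals, labels_of(5, 5), method="mann-whitney")
    assert gc.test == "mann-whitney"
    assert gc.p == pytest.approx(exact_mwu_p(x, y), abs=1e-9)
    assert gc.p == pytest.approx(2 / 252, abs=1e-9)


def test_normal_groups_use_t_test_and_separate(rng):
    hits = t_used = 0
    for _ in range(100):
        m = rng.normal(1.422, 0.742, 40)
        i = rng.normal(2.653, 0.733, 29)
        gc = dq.compare_groups(np.concatenate([m, i]), labels_of(40, 29))
        t_used += gc.test == "t"
        hits += gc.p < 0.001
    assert t_used >= 85  # the gate almost always selects the t-test here
    assert hits >= 95


def test_roc_perfect_separation():
    roc = dq.roc_analysis(np.array([1.0, 2, 3, 4]), labels_of(2, 2))
    assert roc.auc == 1.0
    assert roc.sensitivity == 1.0 and roc.specificity == 1.0
    assert roc.direction == "lower-is-malignant"


def test_roc_all_ties_gives_half():
    roc = dq.roc_analysis(np.ones(10), labels_of(5, 5))
    assert roc.auc == 0.5
    assert roc.p == 1.0


def test_roc_auc_matches_brute_force_with_ties(rng):
    for _ in range(40):
        n_m, n_i = rng.integers(3, 15, 2)
        vals = np.round(rng.normal(size=n_m + n_i), 1)  # rounding injects ties
        lab = labels_of(n_m, n_i)
        roc = dq.roc_analysis(vals, lab)
        oracle = brute_force_auc(vals[n_m:], vals[:n_m])  # P(inf > mal)
        assert roc.auc == pytest.approx(max(oracle, 1 - oracle), abs=1e-12)


def test_accuracy_identity_at_nadir(rng):
    for _ in range(25):
        n_m, n_i = rng.integers(4, 20, 2)
        vals = rng.normal(size=n_m + n_i)
        roc = dq.roc_analysis(vals, labels_of(n_m, n_i))
        expected = (roc.sensitivity * n_m + roc.specificity * n_i) / (n_m + n_i)
        assert roc.acc == pytest.approx(expected, abs=1e-12)


def test_auc_invariances(rng):
    vals = rng.normal(size=30)
    lab = labels_of(14, 16)
    a = dq.roc_analysis(vals, lab).auc
    assert dq.roc_analysis(np.exp(vals), lab).auc == pytest.approx(a, abs=1e-12)
    flipped = np.where(lab == "malignant", "inflammatory", "malignant")
    raw = concordance_auc(vals[:14], vals[14:])
    raw_f = concordance_auc(vals[14:], vals[:14])
    assert raw_f == pytest.approx(1 - raw, abs=1e-12)


def test_compare_auc_of_self_is_one(rng):
    vals = rng.normal(size=40)
    lab = labels_of(20, 20)
    assert dq.compare_auc(vals, vals, lab) == 1.0
    assert dq.compare_auc(vals, np.exp(vals), lab) == 1.0  # monotone transform


def test_compare_auc_requires_pairs():
    with pytest.raises(InsufficientPairsError):
        dq.compare_auc([1.0, 2.0], [1.0, 2.0], np.array(["malignant", "inflammatory"]))


def test_roc_single_class_rejected():
    with pytest.raises(SingleClassError):
        dq.roc_analysis(np.ones(5), np.array(["malignant"] * 5))


def bootstrap_auc_test(a, b, lab, rng, n_boot=199):
    """Independent oracle for the paired AUC comparison: stratified bootstrap."""
    is_m = lab == "malignant"
    am, ai = a[is_m], a[~is_m]
    bm, bi = b[is_m], b[~is_m]

    def oriented(pm, pi):
        x = concordance_auc(pm, pi)
        return max(x, 1 - x)

    diff = oriented(am, ai) - oriented(bm, bi)
    diffs = np.empty(n_boot)
    for k in range(n_boot):
        im = rng.integers(0, am.size, am.size)
        ii = rng.integers(0, ai.size, ai.size)
        diffs[k] = oriented(am[im], ai[ii]) - oriented(bm[im], bi[ii])
    sd = diffs.std(ddof=1)
    if sd == 0:
        return 1.0
    from scipy.stats import norm

    return float(2 * norm.sf(abs(diff) / sd))


def test_delong_power_matches_bootstrap_oracle():
    """Two parameters with population AUCs ~0.90 and ~0.73 at n = 40/29:
    the DeLong rejection rate must agree with a stratified-bootstrap test."""
    rng = np.random.default_rng(2024)
    lab = labels_of(40, 29)
    shift_a, shift_b = 1.81, 0.87  # binormal AUC 0.90 / 0.73 at unit variance

    def cohort():
        z = rng.standard_normal(69)
        signal = np.where(lab == "malignant", 0.0, 1.0)
        a = signal * shift_a + (z + rng.standard_normal(69)) / np.sqrt(2)
        b = signal * shift_b + (z + rng.standard_normal(69)) / np.sqrt(2)
        return a, b

    delong_rej = 0
    n_delong = 600
    for _ in range(n_delong):
        a, b = cohort()
        delong_rej += dq.compare_auc(a, b, lab) < 0.05
    boot_rej = 0
    n_boot = 250
    for _ in range(n_boot):
        a, b = cohort()
        boot_rej += bootstrap_auc_test(a, b, lab, rng) < 0.05
    assert abs(delong_rej / n_delong - boot_rej / n_boot) <= 0.05 + 2.5 * np.sqrt(
        0.25 / n_delong + 0.25 / n_boot
    )


def test_build_report_structure(rng):
    import pandas as pd

    n = 8
    df = pd.DataFrame({
        "case_id": [f"c{i}" for i in range(2 * n)],
        "label": ["malignant"] * n + ["inflammatory"] * n,
    })
    from dopplerquant.stats import ALL_PARAMS

    for p in ALL_PARAMS:
        df[p] = rng.normal(size=2 * n)
    df.loc[:, "fv"] = np.nan  # all SVFM-excluded for this parameter
    t1, t2, curves = dq.build_report(df)
    assert len(t1) == 6 and len(t2) == 6
    assert t1.loc[t1.parameter == "fv", "malignant"].item() == "NA"
    assert np.isnan(t2.loc[t2.parameter == "fv", "auc"].item())
    assert "tfv" in curves and "fv" not in curves
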