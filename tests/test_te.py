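"""TE arithmetic against printed worked examples, the NB exact test (oracle
tail summation, null symmetry, type-I calibration), size factors, filtering
semantics and unique-gene collapsing."""
from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ribote.te import (FilterCriteria, collapse_unique_genes, compute_te,
                       expressed_counts, filter_transcripts, nb_test,
                       percentage, prepare_test_counts, size_factors,
                       te_report)

COLS = ["SCT_1", "SCT_2", "SFP_1", "SFP_2"]
UNIT = pd.Series(1.0, index=COLS)


@pytest.mark.parametrize("ct,fp,expected", [
    (377, 498, 1.32),        # seed lectin, late stage
    (1311, 1143, 0.87),      # conglycinin, late stage
    (528.44, 850.64, 1.61),  # Kunitz trypsin inhibitor, late stage
    (87.1, 3.6, 0.04),       # ribosomal protein, early stage
    (0.1, 0.1, 1.00),        # both at floor
    (1411, 74, 0.05),        # chloroplast rbcL, early stage
    (180, 22, 0.12),         # chloroplast photosystem II D2
])
def test_te_report_reproduces_printed_values(ct, fp, expected):
    assert te_report(ct, fp) == expected


def test_compute_te_requires_positive_control():
    with pytest.raises(ValueError):
        compute_te(0.0, 5.0)


def test_prepare_test_counts_zero_conversion(small_analysis):
    counts, _, _ = small_analysis
    stage = counts.libraries[0].stage
    prepared = prepare_test_counts(counts, stage)
    labels = [k.label for k in counts.libraries if k.stage == stage]
    original = counts.counts[labels]
    n_zero = int((original == 0).sum().sum())
    n_changed = int((prepared[original.columns] != original).sum().sum())
    assert n_changed == n_zero
    assert (prepared >= 1).all().all()
    # all-positive rows unchanged
    pos = original[(original > 0).all(axis=1)]
    pd.testing.assert_frame_equal(prepared.loc[pos.index, pos.columns], pos)


def test_size_factors_symmetry_and_scaling():
    a = pd.DataFrame({"SCT_1": [10, 50, 200], "SCT_2": [10, 50, 200]})
    f = size_factors(a)
    assert f.to_numpy() == pytest.approx([1.0, 1.0])
    b = pd.DataFrame({"SCT_1": [10, 50, 200], "SCT_2": [20, 100, 400]})
    f = size_factors(b)
    assert f["SCT_2"] / f["SCT_1"] == pytest.approx(2.0)


def test_size_factors_match_literal_formula():
    rng = np.random.default_rng(8)
    counts = pd.DataFrame(rng.negative_binomial(5, 0.1, size=(50, 4)) + 1,
                          columns=COLS)
    f = size_factors(counts)
    arr = counts.to_numpy(float)
    geo = np.exp(np.log(arr).mean(axis=1))
    for j, c in enumerate(COLS):
        assert f[c] == pytest.approx(np.median(arr[:, j] / geo))


def test_size_factors_need_positive_row():
    counts = pd.DataFrame({"SCT_1": [0, 5], "SFP_1": [3, 0]})
    with pytest.raises(ValueError, match="zero"):
        size_factors(counts)


def _oracle_pvalue(ka, kb, mu, var):
    """Independent conditional-tail oracle using an explicit log-gamma NB pmf
    (common mean/variance in both conditions)."""
    def nb_logpmf(k, mu, var):
        if var <= mu:
            return k * math.log(mu) - mu - math.lgamma(k + 1)
        r = mu * mu / (var - mu)
        p = r / (r + mu)
        return (math.lgamma(k + r) - math.lgamma(r) - math.lgamma(k + 1)
                + r * math.log(p) + k * math.log(1 - p))
    ks = ka + kb
    logs = [nb_logpmf(a, mu, var) + nb_logpmf(ks - a, mu, var)
            for a in range(ks + 1)]
    m = max(logs)
    probs = [math.exp(l - m) for l in logs]
    obs = logs[ka]
    num = sum(p for l, p in zip(logs, probs) if l <= obs + 1e-12)
    return min(1.0, num / sum(probs))


def test_nb_test_matches_tail_summation_oracle():
    rows = [(12, 9, 30, 25), (40, 2, 10, 12), (5, 5, 5, 5), (100, 90, 60, 70)]
    counts = pd.DataFrame(rows, columns=COLS)
    pvals = nb_test(counts, factors=UNIT, use_trend=False)
    arr = counts.to_numpy(float)
    q0 = arr.mean(axis=1)
    w = (arr[:, :2].var(ddof=1, axis=1) + arr[:, 2:].var(ddof=1, axis=1)) / 2
    disp = np.maximum((w - q0) / q0**2, 1e-8)
    for i, (c1, c2, f1, f2) in enumerate(rows):
        mu = q0[i] * 2
        var = mu + disp[i] * q0[i]**2 * 2
        expected = _oracle_pvalue(c1 + c2, f1 + f2, mu, var)
        assert pvals.iloc[i] == pytest.approx(expected, rel=1e-4)


def test_nb_test_null_symmetry_and_power():
    null = pd.DataFrame([[10, 10, 10, 10]], columns=COLS)
    assert nb_test(null, factors=UNIT, use_trend=False).iloc[0] >= 0.99
    strong = pd.DataFrame([[1000, 1000, 10, 10]], columns=COLS)
    assert nb_test(strong, factors=UNIT, use_trend=False).iloc[0] < 1e-6


def test_nb_test_rejects_non_integer():
    with pytest.raises(ValueError, match="integer"):
        nb_test(pd.DataFrame([[1.5, 2.0, 3.0, 4.0]], columns=COLS),
                factors=UNIT)


def test_nb_test_type_one_error_calibration():
    """Seeded null simulation: 2000 transcripts with a common NB mean and
    dispersion 0.1, 2+2 replicates; rejection rate at 0.05 within 0.05 +/- 0.02."""
    rng = np.random.default_rng(42)
    n, disp = 2000, 0.1
    r = 1.0 / disp
    means = 10 ** rng.uniform(0.7, 3.0, size=n)
    counts = pd.DataFrame(
        rng.negative_binomial(r, r / (r + means[:, None]), size=(n, 4)),
        columns=COLS).clip(lower=1)
    p = nb_test(counts)
    assert 0.03 <= (p < 0.05).mean() <= 0.07


def _row(p, te, fp=5.0, ct=5.0, stage="C25", tid="t.1"):
    return {"transcript_id": tid, "stage": stage, "ct_rpkm": ct,
            "fp_rpkm": fp, "te": te, "pvalue": p}


def test_filter_thresholds_exact_semantics():
    high = FilterCriteria.high_te()
    rows = pd.DataFrame([
        _row(0.04, 1.2, fp=1.0, tid="keep.1"),     # FP >= 1 inclusive
        _row(0.05, 2.0, fp=5.0, tid="p_edge.1"),    # p not strictly < 0.05
        _row(0.04, 1.0, fp=5.0, tid="te_edge.1"),   # TE not strictly > 1
        _row(0.04, 1.5, fp=0.99, tid="fp_low.1"),
    ])
    assert filter_transcripts(rows, high, "C25") == {"keep.1"}
    low = FilterCriteria.low_te()
    rows = pd.DataFrame([
        _row(0.01, 0.1, ct=10.0, tid="edge.1"),     # TE <= 0.1 and CT >= 10 inclusive
        _row(0.01, 0.11, ct=50.0, tid="te_high.1"),
        _row(0.01, 0.05, ct=9.9, tid="ct_low.1"),
    ])
    assert filter_transcripts(rows, low, "C25") == {"edge.1"}


@settings(max_examples=40, deadline=None, derandomize=True)
@given(st.floats(0.01, 0.2), st.floats(0.5, 2.0), st.floats(0.5, 5.0))
def test_filter_monotonicity(pval_max, te_bound, fp_min):
    """Relaxing any single threshold never shrinks the retained set."""
    rng = np.random.default_rng(77)
    rows = pd.DataFrame([
        _row(float(p), float(t), fp=float(f), tid=f"t{i}.1")
        for i, (p, t, f) in enumerate(zip(rng.uniform(0, 0.3, 60),
                                          rng.uniform(0.1, 4, 60),
                                          rng.uniform(0, 10, 60)))])
    base = FilterCriteria(pval_max, te_bound, "above", "fp_rpkm", fp_min)
    got = filter_transcripts(rows, base, "C25")
    for relaxed in (
        FilterCriteria(pval_max * 2, te_bound, "above", "fp_rpkm", fp_min),
        FilterCriteria(pval_max, te_bound / 2, "above", "fp_rpkm", fp_min),
        FilterCriteria(pval_max, te_bound, "above", "fp_rpkm", fp_min / 2),
    ):
        assert got <= filter_transcripts(rows, relaxed, "C25")


def test_collapse_unique_genes():
    gs = collapse_unique_genes(
        {"C25": {"Glyma.06G324400.2", "Glyma.06G324400.1"},
         "C100": {"Glyma.06G324400.1", "Glyma.04G257100.2"}})
    assert gs.per_stage_genes["C25"] == {"Glyma.06G324400"}
    assert gs.union_genes == {"Glyma.06G324400", "Glyma.04G257100"}
    empty = collapse_unique_genes({})
    assert empty.union_genes == set()


def test_expressed_counts_and_percentage():
    rows = pd.DataFrame([
        _row(0.5, 1.0, ct=2.0, tid="a.1"),
        _row(0.5, 1.0, ct=1.0, tid="a.2"),      # same gene, at threshold
        _row(0.5, 1.0, ct=0.5, tid="b.1"),
    ])
    out = expressed_counts(rows, threshold=1.0)
    assert out.loc["C25", "transcripts"] == 2
    assert out.loc["C25", "unique_genes"] == 1
    assert expressed_counts(rows, threshold=100.0).loc["C25", "transcripts"] == 0
    assert percentage(136, 14888) == 0.91
    assert percentage(46, 8027) == 0.57
    with pytest.raises(ValueError):
        percentage(1, 0)


def test_te_identity_on_fixture(small_analysis):
    """Every reported row satisfies rounded(fp/ct) == stored rounded te, and
    both-at-floor rows give exactly 1.00."""
    _, _, results = small_analysis
    for _, row in results.iterrows():
        assert te_report(row["ct_rpkm"], row["fp_rpkm"]) == row["te_rounded"]
        if row["ct_rpkm"] == 0.1 and row["fp_rpkm"] == 0.1:
            assert row["te_rounded"] == 1.00
    assert results["pvalue"].between(0, 1, inclusive="right").all()
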