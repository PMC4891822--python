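"""TPM, Audic-Claverie exact test, five-way classification."""

import math

import numpy as np
import pytest
from scipy import stats

from srnakit.diffexpr import (
    DiffExprPair,
    audic_point_mass,
    audic_point_mass_exact,
    audic_pvalue,
    category_tally,
    classify,
    filter_low_abundance,
    profile_table,
    substitute_zero,
    tpm_normalize,
)


def test_tpm_unit_scale_and_zero():
    assert tpm_normalize(2, 1_000_000) == 2.0
    assert tpm_normalize(0, 10_000_000) == 0.0
    with pytest.raises(ValueError):
        tpm_normalize(-1, 100)
    with pytest.raises(ValueError):
        tpm_normalize(1, 0)


def test_tpm_reproduces_printed_library_share():
    tpm = tpm_normalize(1_985_940, 18_179_025)
    assert abs(tpm - 109_243.5) < 0.05
    assert round(tpm / 1e4, 2) == 10.92  # the same number as a percentage


def test_substitute_zero_rule():
    assert substitute_zero(0.0) == 0.01
    assert substitute_zero(5.3) == 5.3
    assert substitute_zero(0.005) == 0.005  # only exact zero is substituted


def test_point_mass_closed_forms():
    # p(0|0) with N1=N2 reduces to 1/2
    assert audic_point_mass(0, 0, 100, 100) == pytest.approx(0.5, abs=1e-12)
    # p(5|5) with N1=N2 = C(10,5)/2^11 = 252/2048
    assert audic_point_mass(5, 5, 10_000, 10_000) == pytest.approx(252 / 2048, abs=1e-12)


def test_point_mass_matches_negative_binomial():
    # p(y|x; N1, N2) is NB(y; x+1, N1/(N1+N2)) - independent cross-check
    rng = np.random.default_rng(0)
    for _ in range(50):
        x, y = int(rng.integers(0, 200)), int(rng.integers(0, 200))
        N1, N2 = int(rng.integers(10**4, 10**7)), int(rng.integers(10**4, 10**7))
        ours = audic_point_mass(y, x, N1, N2)
        ref = stats.nbinom.pmf(y, x + 1, N1 / (N1 + N2))
        assert ours == pytest.approx(ref, rel=1e-10)


def test_tails_match_negative_binomial():
    for x, y, N1, N2 in [(5, 25, 10**6, 10**6), (120, 80, 2 * 10**6, 10**6), (0, 0, 10, 20)]:
        p = N1 / (N1 + N2)
        lower = audic_pvalue(DiffExprPair(x, y, N1, N2), "less")
        upper = audic_pvalue(DiffExprPair(x, y, N1, N2), "greater")
        assert lower == pytest.approx(stats.nbinom.cdf(y, x + 1, p), rel=1e-9)
        assert upper == pytest.approx(stats.nbinom.sf(y - 1, x + 1, p), rel=1e-9)


def test_extreme_tail_is_positive_and_tiny():
    p = audic_pvalue(DiffExprPair(10, 500, 10**6, 10**6), "greater")
    assert 0 < p < 1e-100


def test_point_mass_swap_relation():
    # exactly symmetric at equal totals; off by the factor N1/N2 otherwise
    for x, y, n in [(3, 9, 10**5), (12, 12, 10**6), (0, 7, 500)]:
        assert audic_point_mass(y, x, n, n) == pytest.approx(
            audic_point_mass(x, y, n, n), rel=1e-12
        )
    for x, y, n1, n2 in [(3, 9, 10**5, 3 * 10**5), (0, 4, 50, 70)]:
        a = audic_point_mass(y, x, n1, n2)
        b = audic_point_mass(x, y, n2, n1)
        assert a == pytest.approx(b * n1 / n2, rel=1e-12)


def test_log_space_agrees_with_exact_rational():
    rng = np.random.default_rng(1)
    cases = [(0, 0), (0, 100), (50, 50), (1, 99)] + [
        (int(rng.integers(0, 50)), int(rng.integers(0, 50))) for _ in range(30)
    ]
    for x, y in cases:
        exact = float(audic_point_mass_exact(y, x, 3_333, 7_777))
        ours = audic_point_mass(y, x, 3_333, 7_777)
        assert ours == pytest.approx(exact, rel=1e-12)


def test_pvalue_validates_inputs():
    with pytest.raises(ValueError):
        DiffExprPair(1, 1, 0, 10)
    with pytest.raises(ValueError):
        DiffExprPair(-1, 1, 10, 10)
    with pytest.raises(ValueError):
        DiffExprPair(11, 1, 10, 10)
    with pytest.raises(ValueError):
        audic_pvalue(DiffExprPair(1, 1, 10, 10), "sideways")


def test_classify_slight_down_tier():
    # TPM pair 2508.94 -> 1796.79: |log2FC| ~ 0.48, a slight down-regulation
    prof = classify("mir172a-like", 2_508_940, 1_796_790, 10**9, 10**9)
    assert prof.tpm_c == pytest.approx(2508.94)
    assert prof.tpm_t == pytest.approx(1796.79)
    assert abs(prof.log2fc) == pytest.approx(0.48, abs=0.01)
    assert prof.category == "slightly_down"
    assert prof.exclusive_flag == "shared"


def test_classify_complete_repression():
    # 132.63 TPM falling to the 0.01 substitute: control-only, significant
    prof = classify("mir-x", 132_630, 0, 10**9, 10**9)
    assert prof.tpm_c == pytest.approx(132.63)
    assert prof.tpm_t == 0.01
    assert prof.log2fc == pytest.approx(math.log2(0.01 / 132.63), rel=1e-6)
    assert prof.category == "significantly_down"
    assert prof.exclusive_flag == "control_only"
    assert prof.p_value < 0.05


def test_classify_null_is_unobvious():
    prof = classify("m", 500, 500, 10**6, 10**6)
    assert prof.log2fc == 0.0
    assert prof.category == "unobvious"


def test_strong_fold_change_needs_significance():
    # |log2FC| >= 1 with an insignificant p lands in unobvious, not slight
    prof = classify("m", 2, 0, 10**6, 10**6)
    assert abs(prof.log2fc) >= 1
    assert prof.p_value >= 0.05
    assert prof.category == "unobvious"


def test_filter_low_abundance_boundaries():
    mk = lambda c, t: classify("m", c, t, 10**6, 10**6)
    removed = filter_low_abundance([mk(1, 1)], 2.0)  # 1.0/1.0 TPM: below in both
    one_side = filter_low_abundance([mk(1, 3)], 2.0)  # 3.0 TPM in treatment
    boundary = filter_low_abundance([mk(2, 0)], 2.0)  # exactly 2.0 TPM
    assert removed == []
    assert len(one_side) == 1
    assert len(boundary) == 1


def test_tpm_sums_to_one_million(small_results):
    n1 = small_results.n_clean_c
    total = sum(tpm_normalize(t.count_c, n1) for t in small_results.tags)
    assert total == pytest.approx(1e6, rel=1e-6)


def test_classification_swap_symmetry():
    rng = np.random.default_rng(2)
    flip = {
        "significantly_up": "significantly_down",
        "significantly_down": "significantly_up",
        "slightly_up": "slightly_down",
        "slightly_down": "slightly_up",
        "unobvious": "unobvious",
    }
    for _ in range(30):
        x, y = int(rng.integers(0, 3000)), int(rng.integers(0, 3000))
        a = classify("m", x, y, 10**6, 2 * 10**6)
        b = classify("m", y, x, 2 * 10**6, 10**6)
        assert b.category == flip[a.category]
        assert b.log2fc == pytest.approx(-a.log2fc, rel=1e-9)


def test_profile_table_and_tally():
    counts = {"a": (100, 800), "b": (50, 49), "c": (0, 40), "d": (500, 300)}
    df = profile_table(counts, 10**5, 10**5, bh_column=True)
    assert list(df["mirna"]) == ["a", "b", "c", "d"]
    assert set(df.columns) >= {"tpm_c", "tpm_t", "log2fc", "p_value", "category", "p_bh"}
    assert df.loc[df["mirna"] == "c", "exclusive_flag"].item() == "treatment_only"
    tally = category_tally(df)
    assert tally.loc[tally["category"] == "responsive_total", "n"].item() == int(
        (df["category"] != "unobvious").sum()
    )
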