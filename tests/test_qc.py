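import numpy as np
import pytest
from scipy import stats

from embryoqc.matrix import HET, HOM_A, HOM_B, NO_CALL
from embryoqc.qc import (
    classify_call,
    classify_calls,
    callrate_error_correlation,
    expected_binomial_concordance,
    locus_effect_test,
    quality_threshold_curve,
    replicate_concordance,
    tally,
)
from embryoqc.wga import (
    CAT_ADO,
    CAT_CORRECT,
    CAT_HET_GAIN,
    CAT_HOM_REVERSAL,
    CAT_NO_CALL,
    WgaErrorModel,
    error_mask_is_error,
    inject_wga_errors,
)

from conftest import toy_matrix


@pytest.mark.parametrize(
    "ref, obs, cat",
    [
        (HET, HOM_A, CAT_ADO),
        (HET, HOM_B, CAT_ADO),
        (HOM_A, HET, CAT_HET_GAIN),
        (HOM_A, HOM_B, CAT_HOM_REVERSAL),
        (HOM_B, HOM_A, CAT_HOM_REVERSAL),
        (HET, HET, CAT_CORRECT),
        (HOM_A, NO_CALL, CAT_NO_CALL),
    ],
)
def test_classify_call_taxonomy(ref, obs, cat):
    assert classify_call(ref, obs) == cat


def test_classify_rejects_uncalled_reference():
    with pytest.raises(ValueError):
        classify_calls(np.array([NO_CALL]), np.array([HET]))


def test_tally_identity_case():
    rng = np.random.default_rng(1)
    m = toy_matrix(rng.integers(0, 3, size=(5, 300)))
    t = tally(m, m)
    assert t.error_rate == 0.0
    assert t.call_rate == 1.0
    assert t.correct_prop == 1.0


def test_tally_matches_injection_mask_exactly():
    rng = np.random.default_rng(2)
    truth = toy_matrix(rng.integers(0, 3, size=(20, 2000)))
    deg, mask = inject_wga_errors(truth, WgaErrorModel(0.1, 0.2, 0.05, 0.01), rng)
    t = tally(truth, deg)
    assert t.n_nocall_vs_ref == (mask == CAT_NO_CALL).sum()
    assert t.n_ado == (mask == CAT_ADO).sum()
    assert t.n_hetgain == (mask == CAT_HET_GAIN).sum()
    assert t.n_homrev == (mask == CAT_HOM_REVERSAL).sum()
    # sum identities asserted at construction; spot-check rates
    assert t.error_rate == pytest.approx(error_mask_is_error(mask).sum() / t.n_called)


def test_uniform_random_calls_hit_two_thirds_error():
    rng = np.random.default_rng(3)
    n = 120_000
    ref = toy_matrix(rng.integers(0, 3, size=(1, n)))
    obs = toy_matrix(rng.integers(0, 3, size=(1, n)))
    rate = tally(ref, obs).error_rate
    lo, hi = stats.binom.interval(0.999, n, 2 / 3)
    assert lo / n <= rate <= hi / n


def test_replicate_concordance_degenerate_cases():
    full = toy_matrix(np.ones((2, 50), dtype=np.int8))
    empty = toy_matrix(np.full((2, 50), NO_CALL, dtype=np.int8))
    c = replicate_concordance([full.copy(), full.copy(), full.copy()], full)
    assert c.f_all == c.f_any == 1.0 and c.err_any == 0.0
    c = replicate_concordance([full.copy(), empty.copy(), empty.copy()], full)
    assert c.f_any == 1.0 and c.f_atleast2 == 0.0 and c.f_all == 0.0


def test_replicate_concordance_matches_binomial():
    rng = np.random.default_rng(4)
    ref = toy_matrix(rng.integers(0, 3, size=(1, 100_000)))
    reps = []
    for _ in range(3):
        deg, _ = inject_wga_errors(ref, WgaErrorModel(miss_rate=0.1), rng)
        reps.append(deg)
    c = replicate_concordance(reps, ref)
    n = c.n_ref_loci
    lo, hi = stats.binom.interval(0.999, n, 0.9**3)
    assert lo / n <= c.f_all <= hi / n
    assert c.f_all <= c.f_atleast2 <= c.f_any


@pytest.mark.parametrize(
    "p, expected",
    [
        (1.0, {"all": 1000, "atleast2": 1000, "any": 1000}),
        (0.0, {"all": 0, "atleast2": 0, "any": 0}),
        (0.9, {"all": 729, "atleast2": 972, "any": 999}),
    ],
)
def test_expected_binomial_concordance(p, expected):
    got = expected_binomial_concordance(p, 3, 1000)
    for key, val in expected.items():
        assert got[key] == pytest.approx(val)


def test_locus_effect_test_null_identity():
    res = locus_effect_test([100, 200, 300], [100, 200, 300], 1000)
    assert res.pvalue == 1.0 and res.mean_diff == 0.0


def _simulate_homogeneity_pvalue(rng, dispersion=0.0, n_loci=2000, k=3):
    """One run of the locus-effect test on simulated call counts."""
    ps = [0.5, 0.6, 0.7, 0.8, 0.85, 0.9]
    observed, expected = [], []
    for p in ps:
        if dispersion > 0:
            nu = (1 - dispersion) / dispersion
            locus_p = rng.beta(p * nu, (1 - p) * nu, size=n_loci)
        else:
            locus_p = np.full(n_loci, p)
        calls = rng.binomial(k, locus_p)
        p_hat = calls.sum() / (n_loci * k)
        observed.append((calls == k).sum())
        expected.append(expected_binomial_concordance(p_hat, k, n_loci)["all"])
    return locus_effect_test(observed, expected, n_loci).pvalue


def test_locus_effect_test_type_i_error_calibrated():
    rng = np.random.default_rng(5)
    pvals = np.array([_simulate_homogeneity_pvalue(rng) for _ in range(500)])
    rejection = (pvals < 0.05).mean()
    assert 0.03 <= rejection <= 0.07
    # and P should be roughly uniform under the null
    assert stats.kstest(pvals, "uniform").pvalue > 0.001


def test_locus_effect_test_detects_dispersion():
    rng = np.random.default_rng(6)
    pvals = np.array(
        [_simulate_homogeneity_pvalue(rng, dispersion=0.3) for _ in range(100)]
    )
    assert (pvals < 0.05).mean() > 0.8


@pytest.mark.parametrize(
    "points",
    [
        [(1.0, 0.0), (0.5, 0.5), (0.0, 1.0)],
        [(0.9, 0.1), (0.6, 0.4), (0.3, 0.7), (0.1, 0.9)],
    ],
)
def test_perfectly_colinear_negative_correlation(points):
    r, p = callrate_error_correlation(points)
    assert r == pytest.approx(-1.0)


def test_correlation_requires_variance():
    with pytest.raises(ValueError):
        callrate_error_correlation([(0.5, 0.1), (0.5, 0.2), (0.5, 0.3)])


def test_quality_threshold_curve_separable_case():
    q = np.array([0.0] * 50 + [1.0] * 50)
    err = np.array([True] * 50 + [False] * 50)
    curve = quality_threshold_curve(q, err)
    row = curve.table[np.isclose(curve.table["threshold"], 0.5)].iloc[0]
    assert row["errors_removed"] == 1.0 and row["correct_retained"] == 1.0


def test_quality_threshold_curve_monotone_and_symmetric():
    rng = np.random.default_rng(7)
    q = rng.random(20_000)
    err = rng.random(20_000) < 0.3  # identical score laws
    curve = quality_threshold_curve(q, err)
    removed = curve.table["errors_removed"].to_numpy()
    retained = curve.table["correct_retained"].to_numpy()
    assert (np.diff(removed) >= 0).all()
    assert (np.diff(retained) <= 0).all()
    assert np.allclose(removed, 1 - retained, atol=0.03)


def test_quality_threshold_curve_flags_no_errors():
    curve = quality_threshold_curve(np.array([0.5, 0.9]), np.array([False, False]))
    assert not curve.removal_defined
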