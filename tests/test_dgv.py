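import numpy as np
import pandas as pd
import pytest

from embryoqc.dgv import compare_merit, compute_dgv, compute_index
from embryoqc.io import MarkerEffectSet
from embryoqc.matrix import HET, HOM_A, HOM_B, NO_CALL

from conftest import toy_matrix


def _effects(matrix, values, weights=None, scale=1.0, offset=0.0):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    traits = [f"trait{i + 1}" for i in range(values.shape[1])]
    df = pd.DataFrame(values, index=pd.Index(matrix.loci["locus_id"], name="locus_id"),
                      columns=traits)
    w = pd.Series(1.0 if weights is None else weights, index=traits)
    return MarkerEffectSet(df, w, scale, offset)


def test_zero_effects_zero_dgv():
    m = toy_matrix([[HOM_A, HET], [HOM_B, HOM_B]])
    eff = _effects(m, [[0.0], [0.0]])
    assert (compute_dgv(m, eff).to_numpy() == 0).all()


def test_single_locus_dosage_definition():
    m = toy_matrix([[HOM_A], [HET], [HOM_B]])
    eff = _effects(m, [[1.0]])
    assert list(compute_dgv(m, eff)["trait1"]) == [0.0, 1.0, 2.0]


def test_dgv_rejects_missing_calls():
    m = toy_matrix([[NO_CALL]])
    with pytest.raises(ValueError, match="impute"):
        compute_dgv(m, _effects(m, [[1.0]]))


def test_dgv_matches_brute_force():
    rng = np.random.default_rng(1)
    m = toy_matrix(rng.integers(0, 3, size=(50, 1000)))
    vals = rng.normal(size=(1000, 3))
    eff = _effects(m, vals)
    got = compute_dgv(m, eff).to_numpy()
    # independent elementwise recomputation
    want = np.zeros((50, 3))
    for i in range(50):
        for t in range(3):
            want[i, t] = sum(vals[j, t] * m.calls[i, j] for j in range(1000))
    assert np.allclose(got, want)


def test_dgv_linearity():
    rng = np.random.default_rng(2)
    a = toy_matrix(rng.integers(0, 3, size=(4, 100)))
    b = toy_matrix(rng.integers(0, 3, size=(4, 100)))
    eff = _effects(a, rng.normal(size=(100, 1)))
    mean_calls = (a.calls.astype(float) + b.calls.astype(float)) / 2
    dgv_mean = mean_calls @ eff.effects.to_numpy()
    assert np.allclose(
        dgv_mean[:, 0],
        (compute_dgv(a, eff)["trait1"] + compute_dgv(b, eff)["trait1"]) / 2,
    )


def test_index_is_zscore_for_single_unit_trait():
    rng = np.random.default_rng(3)
    m = toy_matrix(rng.integers(0, 3, size=(20, 50)))
    eff = _effects(m, rng.normal(size=(50, 1)), scale=1.0, offset=0.0)
    dgv = compute_dgv(m, eff)
    idx = compute_index(dgv, eff)
    z = (dgv["trait1"] - dgv["trait1"].mean()) / dgv["trait1"].std(ddof=0)
    assert np.allclose(idx, z)


def test_index_affine_properties():
    rng = np.random.default_rng(4)
    m = toy_matrix(rng.integers(0, 3, size=(20, 50)))
    eff1 = _effects(m, rng.normal(size=(50, 2)), scale=100.0)
    dgv = compute_dgv(m, eff1)
    idx1 = compute_index(dgv, eff1)
    eff2 = MarkerEffectSet(eff1.effects, eff1.index_weights, 200.0, eff1.index_offset)
    idx2 = compute_index(dgv, eff2)
    assert np.ptp(idx2) == pytest.approx(2 * np.ptp(idx1))
    assert list(idx2.rank()) == list(idx1.rank())
    # permuting samples permutes indices identically
    perm = rng.permutation(20)
    idx_perm = compute_index(dgv.iloc[perm], eff1)
    assert np.allclose(idx_perm.to_numpy(), idx1.to_numpy()[perm])


def test_zero_variance_trait_is_skipped():
    m = toy_matrix([[HOM_A, HET], [HOM_A, HOM_B]])
    eff = _effects(m, [[0.0, 1.0], [0.0, 0.5]])
    idx = compute_index(compute_dgv(m, eff), eff)
    assert np.isfinite(idx).all()


def test_compare_merit_identity_and_reversal():
    x = pd.Series([1.0, 5.0, 3.0, 10.0])
    c = compare_merit(x, x.copy())
    assert c.pearson_r == pytest.approx(1.0)
    assert c.mean_abs_divergence == 0.0
    assert c.spearman_rho == pytest.approx(1.0)
    rev = compare_merit(x, -x)
    assert rev.spearman_rho == pytest.approx(-1.0)


def test_compare_merit_requires_variance():
    with pytest.raises(ValueError):
        compare_merit(pd.Series([1.0, 1.0, 1.0]), pd.Series([1.0, 2.0, 3.0]))


def test_clean_channel_gives_perfect_merit_concordance(small_cohort):
    """Zero injected error and missingness: embryo and calf indices agree."""
    from embryoqc.impute import HaplotypeLibrary, impute_matrix
    from embryoqc.cohort import assign_marker_effects
    from embryoqc.wga import WgaErrorModel, inject_wga_errors

    cfg, founders, trios = small_cohort
    clean, _ = inject_wga_errors(trios.embryos, WgaErrorModel(), 5)
    lib = HaplotypeLibrary.from_phased(founders.haplotypes, founders.loci,
                                      founders.sample_ids)
    imputed, _ = impute_matrix(clean, trios.pedigree, founders.matrix(), lib)
    eff = assign_marker_effects(founders.loci, rng=6)
    idx_e = compute_index(compute_dgv(imputed, eff), eff)
    idx_c = compute_index(compute_dgv(trios.embryos, eff), eff)
    c = compare_merit(idx_e, idx_c)
    assert c.pearson_r == pytest.approx(1.0, abs=1e-12)
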