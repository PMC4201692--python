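import numpy as np
import pytest
from scipy import stats

from embryoqc.cohort import (
    CohortConfig,
    QualityModel,
    assign_marker_effects,
    biopsy_dna_yield_pg,
    simulate_founders,
    simulate_quality_scores,
    simulate_trios,
)
from embryoqc.impute import find_mendelian_inconsistencies
from embryoqc.matrix import HET, MALE, NO_CALL, X_CHROM

from conftest import small_config, toy_matrix


def adjacent_genotype_correlation(founders):
    calls = founders.matrix().calls.astype(float)
    chroms = founders.loci["chromosome"].to_numpy()
    rs = []
    for j in range(calls.shape[1] - 1):
        if chroms[j] != chroms[j + 1]:
            continue
        a, b = calls[:, j], calls[:, j + 1]
        if a.std() > 0 and b.std() > 0:
            rs.append(np.corrcoef(a, b)[0, 1])
    return float(np.mean(rs))


def test_linkage_equilibrium_at_rho_zero():
    cfg = small_config(ld_rho=0.0, n_founders=300, n_loci=800, seed=3)
    f = simulate_founders(cfg)
    assert abs(adjacent_genotype_correlation(f)) < 0.02


def test_ld_increases_with_rho():
    base = small_config(n_founders=200, n_loci=800, seed=4)
    r0 = adjacent_genotype_correlation(simulate_founders(small_config(
        n_founders=200, n_loci=800, seed=4, ld_rho=0.0)))
    r9 = adjacent_genotype_correlation(simulate_founders(base))  # ld_rho=0.9
    assert r9 > r0 + 0.3


def test_heterozygosity_at_balanced_maf():
    cfg = small_config(maf_low=0.5, maf_high=0.5, n_founders=400, seed=5)
    f = simulate_founders(cfg)
    auto = f.loci["chromosome"].to_numpy() != X_CHROM
    het = (f.matrix().calls[:, auto] == HET).mean()
    assert het == pytest.approx(0.5, abs=0.01)


def test_founder_freq_spectrum_is_uniform():
    cfg = small_config(n_loci=3000, seed=6)
    f = simulate_founders(cfg)
    u = (f.freqs - cfg.maf_low) / (cfg.maf_high - cfg.maf_low)
    assert stats.kstest(u, "uniform").pvalue > 0.01


def test_male_founders_hemizygous_x():
    cfg = small_config(seed=7)
    f = simulate_founders(cfg)
    x = f.loci["chromosome"].to_numpy() == X_CHROM
    males = f.sexes == MALE
    assert not (f.matrix().calls[np.ix_(males, x)] == HET).any()


def test_trios_have_zero_mendelian_inconsistencies(small_cohort):
    cfg, founders, trios = small_cohort
    parents = founders.matrix()
    x = trios.embryos.x_mask
    for t, eid in enumerate(trios.embryos.sample_ids):
        sire = parents.calls[parents.sample_index(trios.sire_ids[t])]
        dam = parents.calls[parents.sample_index(trios.dam_ids[t])]
        flags = find_mendelian_inconsistencies(
            trios.embryos.calls[t], sire, dam, x, trios.embryo_sexes[t]
        )
        assert not flags.any(), f"embryo {eid} inconsistent at {flags.sum()} loci"


def test_forced_inheritance_at_opposite_homozygotes(small_cohort):
    cfg, founders, trios = small_cohort
    parents = founders.matrix()
    e = trios.embryos.calls
    auto = ~trios.embryos.x_mask
    for t in range(len(trios.sire_ids)):
        s = parents.calls[parents.sample_index(trios.sire_ids[t])]
        d = parents.calls[parents.sample_index(trios.dam_ids[t])]
        forced_het = auto & (s == 0) & (d == 2)
        assert (e[t][forced_het] == HET).all()
        forced_hom = auto & (s == 0) & (d == 0)
        assert (e[t][forced_hom] == 0).all()


def test_male_embryos_have_no_het_x(small_cohort):
    _, _, trios = small_cohort
    x = trios.embryos.x_mask
    for t in range(trios.embryos.n_samples):
        if trios.embryo_sexes[t] == MALE:
            assert not (trios.embryos.calls[t][x] == HET).any()


def test_insufficient_founders_of_a_sex_raises():
    cfg = small_config(n_founders=10, n_trios=8)
    f = simulate_founders(cfg)
    with pytest.raises(ValueError, match="each sex"):
        simulate_trios(f, cfg)


def test_marker_effects_determinism_and_degenerate_scale(small_cohort):
    _, founders, _ = small_cohort
    e1 = assign_marker_effects(founders.loci, rng=42)
    e2 = assign_marker_effects(founders.loci, rng=42)
    assert np.array_equal(e1.effects.to_numpy(), e2.effects.to_numpy())
    e0 = assign_marker_effects(founders.loci, effect_sd=0.0, rng=1)
    assert (e0.effects.to_numpy() == 0).all()


def test_quality_scores_single_population_case():
    rng = np.random.default_rng(8)
    m = toy_matrix(rng.integers(0, 3, size=(20, 500)))
    mask = np.zeros(m.calls.shape, dtype=bool)
    scored = simulate_quality_scores(m, mask, QualityModel(), rng=9)
    # all-correct matrix: scores match the Beta(8, 2) correct-call law
    assert scored.quality.mean() == pytest.approx(0.8, abs=0.01)


def test_quality_scores_identical_laws_are_uninformative():
    rng = np.random.default_rng(10)
    m = toy_matrix(rng.integers(0, 3, size=(40, 500)))
    mask = rng.random(m.calls.shape) < 0.3
    qm = QualityModel(3, 2, 3, 2)
    scored = simulate_quality_scores(m, mask, qm, rng=11)
    q = scored.quality
    # AUC of score as an error classifier ~ 0.5
    err, ok = q[mask], q[~mask]
    auc = stats.mannwhitneyu(err, ok).statistic / (err.size * ok.size)
    assert auc == pytest.approx(0.5, abs=0.02)


def test_no_threshold_separates_default_quality_laws():
    rng = np.random.default_rng(12)
    n = 100_000
    mask = np.zeros(n, dtype=bool)
    mask[: n // 5] = True
    qm = QualityModel()
    q = np.where(
        mask,
        rng.beta(qm.a_error, qm.b_error, n),
        rng.beta(qm.a_correct, qm.b_correct, n),
    )
    for t in np.linspace(0, 1, 101):
        removed = (q[mask] < t).mean()
        retained = (q[~mask] >= t).mean()
        assert not (removed > 0.9 and retained > 0.9)


def test_biopsy_dna_yield():
    assert biopsy_dna_yield_pg(15, 6.0) == 90.0
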