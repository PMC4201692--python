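import numpy as np
import pytest

from embryoqc.impute import (
    HaplotypeLibrary,
    ImputeParams,
    build_library,
    correct_inconsistencies,
    find_mendelian_inconsistencies,
    imputation_report,
    impute_family,
    impute_matrix,
    impute_population,
    impute_trio,
    SideConstraints,
)
from embryoqc.matrix import (
    FEMALE,
    HET,
    HOM_A,
    HOM_B,
    MALE,
    NO_CALL,
    GenotypeMatrix,
    make_locus_table,
)
from embryoqc.wga import WgaErrorModel, error_mask_is_error, inject_wga_errors

from conftest import small_config, toy_matrix


def _arr(*vals):
    return np.array(vals, dtype=np.int8)


# ---------------------------------------------------------------------------
# Mendelian checks
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "sire, dam, embryo, flagged",
    [
        (HOM_A, HOM_A, HET, True),  # HET impossible from AA x AA
        (HOM_A, HOM_B, HOM_A, True),  # must be HET
        (HOM_A, HOM_B, HET, False),
        (HET, HET, HOM_A, False),  # HET x HET allows anything
        (HET, HET, HET, False),
        (HET, HET, HOM_B, False),
        (HOM_A, NO_CALL, HOM_B, True),  # single-parent opposite homozygote
        (HOM_A, NO_CALL, HET, False),
        (NO_CALL, NO_CALL, HOM_B, False),  # no constraint
    ],
)
def test_mendelian_rules_autosomal(sire, dam, embryo, flagged):
    flags = find_mendelian_inconsistencies(_arr(embryo), _arr(sire), _arr(dam))
    assert bool(flags[0]) is flagged


def test_mendelian_rules_male_x():
    x = np.array([True])
    # male het X is impossible outright
    flags = find_mendelian_inconsistencies(_arr(HET), _arr(HOM_A), _arr(HET), x, MALE)
    assert flags[0]
    # male X allele must come from the dam; the sire is irrelevant
    flags = find_mendelian_inconsistencies(_arr(HOM_B), _arr(HOM_B), _arr(HOM_A), x, MALE)
    assert flags[0]
    flags = find_mendelian_inconsistencies(_arr(HOM_B), _arr(HOM_A), _arr(HET), x, MALE)
    assert not flags[0]


def test_correction_blanks_flags_and_rerun_is_empty():
    embryo = _arr(HET, HOM_A, HOM_B)
    sire = _arr(HOM_A, HOM_A, HOM_A)
    dam = _arr(HOM_A, HET, HOM_B)
    flags = find_mendelian_inconsistencies(embryo, sire, dam)
    fixed, n = correct_inconsistencies(embryo, flags)
    assert n == flags.sum() > 0
    assert not find_mendelian_inconsistencies(fixed, sire, dam).any()
    # zero flags: identity
    same, n0 = correct_inconsistencies(embryo, np.zeros(3, bool))
    assert n0 == 0 and np.array_equal(same, embryo)


# ---------------------------------------------------------------------------
# family imputation
# ---------------------------------------------------------------------------

def test_family_fill_forced_heterozygote():
    calls, cons = impute_family(_arr(NO_CALL), _arr(HOM_A), _arr(HOM_B))
    assert calls[0] == HET


def test_family_leaves_het_by_het_missing_but_half_resolves_one_hom_parent():
    calls, cons = impute_family(_arr(NO_CALL, NO_CALL),
                                _arr(HET, HOM_A), _arr(HET, HET))
    assert calls[0] == NO_CALL and calls[1] == NO_CALL
    assert cons.sire_side[0] == -1
    assert cons.sire_side[1] == 0  # one A allele fixed from the sire
    assert cons.dam_side[1] == -1


def test_family_never_contradicts_parents():
    rng = np.random.default_rng(1)
    for _ in range(50):
        sire = rng.integers(-1, 3, 40).astype(np.int8)
        dam = rng.integers(-1, 3, 40).astype(np.int8)
        embryo = np.full(40, NO_CALL, dtype=np.int8)
        filled, _ = impute_family(embryo, sire, dam)
        wrote = filled != NO_CALL
        flags = find_mendelian_inconsistencies(filled, sire, dam)
        assert not (flags & wrote).any()


# ---------------------------------------------------------------------------
# library building / phasing
# ---------------------------------------------------------------------------

def test_library_validation():
    loci = make_locus_table(["a", "b"], ["1", "1"], [1, 2])
    with pytest.raises(ValueError, match="descending"):
        HaplotypeLibrary(np.zeros((4, 2), dtype=np.int8), loci,
                         ["s1", "s1", "s2", "s2"], window_lengths=(10, 10))


def test_phasing_recovers_truth_switch_accuracy(small_cohort):
    """Statistical phasing of founders approaches the information limit.

    With unrelated founder haplotypes the only phase information at a
    double-heterozygous pair is the sign and strength of the pairwise LD,
    so no genotype-only method can exceed the truth concordance fraction
    P(B alleles co-reside | double het).  The chain phaser must sit within
    one point of that ceiling (about 92% at ld_rho = 0.9) and above 90%.
    """
    from embryoqc.cohort import simulate_founders

    cfg = small_config(n_founders=200, n_loci=2000, seed=21)
    founders = simulate_founders(cfg)
    lib = build_library(founders.matrix())
    chroms = founders.loci["chromosome"].to_numpy()
    correct = total = ceiling_hits = 0
    for i, sid in enumerate(founders.sample_ids):
        true_h = founders.haplotypes[i]
        est_h = lib.sample_haplotypes(sid)
        het = true_h[0] != true_h[1]
        for sl_start in np.flatnonzero(np.r_[True, chroms[1:] != chroms[:-1]]):
            sl_end = sl_start
            while sl_end < len(chroms) and chroms[sl_end] == chroms[sl_start]:
                sl_end += 1
            idx = np.flatnonzero(het[sl_start:sl_end]) + sl_start
            if idx.size < 2:
                continue
            # relative orientation of consecutive heterozygous loci
            true_rel = true_h[0, idx[:-1]] == true_h[0, idx[1:]]
            est_rel = est_h[0, idx[:-1]] == est_h[0, idx[1:]]
            correct += (true_rel == est_rel).sum()
            ceiling_hits += true_rel.sum()  # concordant-truth pairs
            total += idx.size - 1
    assert total > 1000
    accuracy = correct / total
    ceiling = ceiling_hits / total
    assert accuracy >= 0.90
    assert accuracy >= ceiling - 0.01


def test_build_library_is_deterministic(small_cohort):
    _, founders, _ = small_cohort
    m = founders.matrix()
    l1 = build_library(m)
    l2 = build_library(m)
    assert np.array_equal(l1.haplotypes, l2.haplotypes)


def test_fully_homozygous_sample_phases_trivially():
    calls = np.tile(_arr(HOM_A, HOM_B, HOM_A, HOM_A), (4, 1))
    lib = build_library(toy_matrix(calls))
    h = lib.sample_haplotypes("s0")
    assert np.array_equal(h[0], h[1])
    assert list(h[0]) == [0, 1, 0, 0]


# ---------------------------------------------------------------------------
# population imputation
# ---------------------------------------------------------------------------

def _unanimous_library(allele, n_loci=6):
    loci = make_locus_table([f"m{i}" for i in range(n_loci)], ["1"] * n_loci,
                            np.arange(1, n_loci + 1))
    haps = np.full((6, n_loci), allele, dtype=np.int8)
    return HaplotypeLibrary(haps, loci, [f"p{i // 2}" for i in range(6)]), loci


def test_population_fill_unanimous_library():
    lib, loci = _unanimous_library(1)
    calls = np.full(6, NO_CALL, dtype=np.int8)
    cons = SideConstraints(np.full(6, -1, np.int8), np.full(6, -1, np.int8))
    out = impute_population(calls, cons, lib, loci)
    assert (out == HOM_B).all()


def test_population_fill_respects_half_resolved_allele():
    lib, loci = _unanimous_library(1)
    calls = np.full(6, NO_CALL, dtype=np.int8)
    sire_side = np.zeros(6, dtype=np.int8)  # allele A fixed from the sire
    cons = SideConstraints(sire_side, np.full(6, -1, np.int8))
    out = impute_population(calls, cons, lib, loci)
    assert (out == HET).all()


def test_empty_library_rejected():
    lib, loci = _unanimous_library(1)
    lib.haplotypes = lib.haplotypes[:0]
    calls = np.full(6, NO_CALL, dtype=np.int8)
    cons = SideConstraints(np.full(6, -1, np.int8), np.full(6, -1, np.int8))
    with pytest.raises(ValueError, match="empty"):
        impute_population(calls, cons, lib, loci)


# ---------------------------------------------------------------------------
# end-to-end on simulated trios
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def degraded_cohort(small_cohort):
    cfg, founders, trios = small_cohort
    het = float((founders.matrix().calls == HET).mean())
    model = WgaErrorModel.calibrated(het)
    degraded, mask = inject_wga_errors(trios.embryos, model, 31)
    lib = HaplotypeLibrary.from_phased(founders.haplotypes, founders.loci,
                                      founders.sample_ids)
    return founders, trios, degraded, mask, lib


def test_end_to_end_correction_and_completion(degraded_cohort):
    founders, trios, degraded, mask, lib = degraded_cohort
    imputed, per_sample = impute_matrix(degraded, trios.pedigree,
                                        founders.matrix(), lib)
    assert not (imputed.calls == NO_CALL).any()
    err = error_mask_is_error(mask)
    restored = (imputed.calls[err] == trios.embryos.calls[err]).mean()
    assert restored > 0.95
    # the output never contradicts the called parents
    parents = founders.matrix()
    x = imputed.x_mask
    for t, eid in enumerate(imputed.sample_ids):
        sire = parents.calls[parents.sample_index(trios.sire_ids[t])]
        dam = parents.calls[parents.sample_index(trios.dam_ids[t])]
        flags = find_mendelian_inconsistencies(imputed.calls[t], sire, dam, x,
                                               trios.embryo_sexes[t])
        assert not flags.any()


def test_parents_beat_population_only(degraded_cohort):
    founders, trios, degraded, mask, lib = degraded_cohort
    err = error_mask_is_error(mask)
    truth = trios.embryos.calls
    with_parents, _ = impute_matrix(degraded, trios.pedigree,
                                    founders.matrix(), lib)
    pop_only, _ = impute_matrix(degraded, trios.pedigree, founders.matrix(),
                                lib, use_parents=False)
    assert not (pop_only.calls == NO_CALL).any()
    eff_fam = (with_parents.calls[err] == truth[err]).mean()
    eff_pop = (pop_only.calls[err] == truth[err]).mean()
    assert eff_fam >= eff_pop


def test_imputation_report_hwe_founders(degraded_cohort):
    founders, trios, degraded, mask, lib = degraded_cohort
    imputed, per_sample = impute_matrix(degraded, trios.pedigree,
                                        founders.matrix(), lib)
    rep = imputation_report(degraded, imputed, trios.pedigree, lib, per_sample)
    assert rep.final_missing_rate == 0.0
    assert rep.pedigree_inbreeding == 0.0  # unrelated founders by design
    assert rep.genomic_inbreeding == pytest.approx(0.0, abs=0.05)
    assert rep.n_mendel_inconsistent == per_sample["n_mendel_inconsistent"].sum()
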