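"""End-to-end in-silico genotyping-fidelity experiment.

One call simulates a trio cohort, produces a triplicate unamplified
reference and its consensus, degrades replicate samples under a panel of
WGA platform profiles, computes the QC statistics (call/error taxonomy,
replicate concordance with the binomial locus-homogeneity test, call-rate
vs error-rate correlation, Games-Howell comparisons, quality-score
threshold sweep), sexes the degraded embryos, runs Mendelian correction
plus family/population imputation, and quantifies genomic-merit
concordance between the imputed embryo genotypes and the clean truth
("calf") genotypes.

Randomness is fanned out from a single seed to per-stage generators via
``numpy.random.SeedSequence.spawn``, so each stage is reproducible in
isolation and the whole run is deterministic under a fixed seed.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import consensus as consensus_mod
from . import qc as qc_mod
from .cohort import (
    CohortConfig,
    QualityModel,
    assign_marker_effects,
    simulate_founders,
    simulate_quality_scores,
    simulate_trios,
)
from .dgv import compare_merit, compute_dgv, compute_index
from .impute import HaplotypeLibrary, ImputeParams, imputation_report, impute_matrix
from .matrix import HET, NO_CALL
from .posthoc import games_howell
from .sexing import sex_table
from .wga import (
    MethodProfile,
    WgaErrorModel,
    default_profiles,
    error_mask_is_error,
    inject_wga_errors,
)

log = logging.getLogger("embryoqc")

DEFAULT_CONFIG: dict = {
    "cohort": {
        "n_loci": 5000,
        "n_autosomes": 29,
        "x_fraction": 0.03,
        "n_founders": 200,
        "n_trios": 50,
        "maf_low": 0.1,
        "maf_high": 0.5,
        "ld_rho": 0.9,
        "recomb_cM_per_Mb": 1.0,
        "spacing_bp": 50_000,
        "seed": 0,
    },
    "qc": {
        "n_qc_samples": 6,  # truth samples degraded under each profile
        "n_replicates": 3,
        "reference_miss_rate": 0.005,
    },
    "profiles": {
        # name: miss_rate, conditional error, ADO share, reversal share
        "embryo_profile": "mda_genomiphi",
    },
    "imputation": {
        "evidence_error": 0.1,
        "fill_threshold": 0.8,
        "haplotype_correction": True,
    },
    "dgv": {
        "n_traits": 3,
        "effect_sd": 0.02,
        "index_scale": 300.0,
        "index_offset": 2000.0,
    },
    "checks": {
        "enabled": True,
        "min_error_correction": 0.95,
        "min_merit_correlation": 0.99,
    },
}


def _merge(base: dict, override: dict | None) -> dict:
    out = {k: dict(v) if isinstance(v, dict) else v for k, v in base.items()}
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k].update(v)
        else:
            out[k] = v
    return out


@dataclass
class ExperimentResult:
    """All tables and statistics produced by :func:`run_experiment`."""

    config: dict
    seed: int
    method_metrics: pd.DataFrame
    concordance: pd.DataFrame
    locus_effect_callrate: qc_mod.LocusEffectResult
    callrate_error_r: tuple[float, float]
    games_howell_error: pd.DataFrame
    games_howell_letters: dict
    quality_curve: pd.DataFrame
    sexing: pd.DataFrame
    sexing_accuracy: float
    imputation: "pd.DataFrame"
    imputation_summary: dict
    error_correction_rate: float
    pre_imputation_errors: int
    post_imputation_errors: int
    merit: dict
    checks: list[tuple[str, bool]]

    @property
    def all_checks_pass(self) -> bool:
        return all(ok for _, ok in self.checks)


def run_experiment(config: dict | None = None, seed: int = 0,
                   out_dir: str | Path | None = None) -> ExperimentResult:
    """Run the full in-silico replication; optionally write TSV reports."""
    cfg = _merge(DEFAULT_CONFIG, config)
    t0 = time.time()
    streams = np.random.SeedSequence(seed).spawn(8)
    rngs = [np.random.default_rng(s) for s in streams]
    (rng_founders, rng_trios, rng_qc, rng_embryo,
     rng_effects, rng_quality, rng_sex, rng_misc) = rngs

    # ----- cohort ---------------------------------------------------------
    ccfg = CohortConfig.from_dict({**cfg["cohort"], "seed": seed})
    founders = simulate_founders(ccfg, rng_founders)
    trios = simulate_trios(founders, ccfg, rng_trios)
    truth = trios.embryos
    het_fraction = float((founders.matrix().calls == HET).mean())
    profiles = default_profiles(het_fraction)
    log.info("cohort simulated: %d founders, %d trios, %d loci (%.1fs)",
             ccfg.n_founders, ccfg.n_trios, ccfg.n_loci, time.time() - t0)

    # ----- reference consensus + per-profile QC ---------------------------
    qc_cfg = cfg["qc"]
    n_qc = int(qc_cfg["n_qc_samples"])
    k = int(qc_cfg["n_replicates"])
    qc_truth = founders.matrix().subset_samples(founders.sample_ids[:n_qc])
    ref_model = WgaErrorModel(miss_rate=float(qc_cfg["reference_miss_rate"]))
    ref_reps = [inject_wga_errors(qc_truth, ref_model, rng_qc)[0] for _ in range(k)]
    reference = consensus_mod.build_consensus(ref_reps, min_agree=2)

    metric_rows, conc_rows = [], []
    observed_all, expected_all = [], []
    points = []
    gh_groups: dict[str, list[float]] = {}
    quality_curve_df = None
    for name, profile in profiles.items():
        reps, masks = [], []
        for _ in range(k):
            deg, mask = inject_wga_errors(qc_truth, profile.model, rng_qc)
            reps.append(deg)
            masks.append(mask)
        tallies = [qc_mod.tally(reference, r) for r in reps]
        err = [t.error_rate for t in tallies]
        cr = [t.call_rate for t in tallies]
        metric_rows.append(
            {
                "method": name,
                "call_rate": np.mean(cr),
                "call_rate_sd": np.std(cr, ddof=1),
                "error_rate": np.mean(err),
                "error_rate_sd": np.std(err, ddof=1),
                "ado_rate": np.mean([t.n_ado / t.n_called for t in tallies]),
                "hetgain_rate": np.mean([t.n_hetgain / t.n_called for t in tallies]),
                "homrev_rate": np.mean([t.n_homrev / t.n_called for t in tallies]),
                "correct_prop": np.mean([t.correct_prop for t in tallies]),
            }
        )
        conc = qc_mod.replicate_concordance(reps, reference)
        conc_rows.append(
            {
                "method": name,
                "coverage_all": conc.f_all,
                "coverage_atleast2": conc.f_atleast2,
                "coverage_any": conc.f_any,
                "error_all": conc.err_all,
                "error_atleast2": conc.err_atleast2,
                "error_any": conc.err_any,
            }
        )
        expected = qc_mod.expected_binomial_concordance(float(np.mean(cr)), k, conc.n_ref_loci)
        observed_all.append(conc.f_all * conc.n_ref_loci)
        expected_all.append(expected["all"])
        points += list(zip(cr, err))
        # per-sample, per-replicate error rates for the heteroscedastic
        # group comparison
        gh_groups[name] = [
            qc_mod.tally(reference, r, s).error_rate
            for r in reps for s in qc_truth.sample_ids
        ]
        if name == cfg["profiles"]["embryo_profile"]:
            scored = simulate_quality_scores(reps[0], error_mask_is_error(masks[0]),
                                             QualityModel(), rng_quality)
            curve = qc_mod.quality_threshold_curve(
                scored.quality[reps[0].calls != NO_CALL],
                error_mask_is_error(masks[0])[reps[0].calls != NO_CALL],
            )
            quality_curve_df = curve.table

    n_ref_loci = qc_mod.tally(reference, ref_reps[0]).n_ref_called
    locus_effect = qc_mod.locus_effect_test(observed_all, expected_all, n_ref_loci)
    r, p = qc_mod.callrate_error_correlation(points)
    gh = games_howell({g: np.asarray(v) for g, v in gh_groups.items()})
    log.info("QC arm done (%.1fs)", time.time() - t0)

    # ----- embryo arm: degrade, sex, impute, merit ------------------------
    profile = profiles[cfg["profiles"]["embryo_profile"]]
    degraded, mask = inject_wga_errors(truth, profile.model, rng_embryo)
    is_err = error_mask_is_error(mask)
    pre_errors = int(is_err.sum())

    sexes = sex_table(degraded)
    sex_truth = dict(zip(truth.sample_ids, trios.embryo_sexes))
    sex_acc = float(np.mean([
        row["sex_call"] == sex_truth[row["sample_id"]]
        for _, row in sexes.iterrows()
    ]))

    library = HaplotypeLibrary.from_phased(
        founders.haplotypes, founders.loci, founders.sample_ids
    )
    params = ImputeParams(
        evidence_error=float(cfg["imputation"]["evidence_error"]),
        fill_threshold=float(cfg["imputation"]["fill_threshold"]),
        haplotype_correction=bool(cfg["imputation"]["haplotype_correction"]),
    )
    imputed, per_sample = impute_matrix(degraded, trios.pedigree,
                                        founders.matrix(), library, params)
    report = imputation_report(degraded, imputed, trios.pedigree, library, per_sample)
    corrected = int((imputed.calls[is_err] == truth.calls[is_err]).sum())
    correction_rate = corrected / pre_errors if pre_errors else np.nan
    post_errors = int((imputed.calls != truth.calls).sum())
    log.info("imputation done: %d/%d errors restored (%.1fs)",
             corrected, pre_errors, time.time() - t0)

    dgv_cfg = cfg["dgv"]
    effects = assign_marker_effects(
        founders.loci, n_traits=int(dgv_cfg["n_traits"]),
        effect_sd=float(dgv_cfg["effect_sd"]),
        index_scale=float(dgv_cfg["index_scale"]),
        index_offset=float(dgv_cfg["index_offset"]), rng=rng_effects,
    )
    idx_embryo = compute_index(compute_dgv(imputed, effects), effects)
    idx_calf = compute_index(compute_dgv(truth, effects), effects)
    merit = compare_merit(idx_embryo, idx_calf)

    checks = []
    if cfg["checks"]["enabled"]:
        checks = [
            ("post_imputation_missing_zero", report.final_missing_rate == 0.0),
            ("error_correction", correction_rate >= float(cfg["checks"]["min_error_correction"])),
            ("merit_correlation", merit.pearson_r >= float(cfg["checks"]["min_merit_correlation"])),
        ]

    result = ExperimentResult(
        config=cfg,
        seed=seed,
        method_metrics=pd.DataFrame(metric_rows),
        concordance=pd.DataFrame(conc_rows),
        locus_effect_callrate=locus_effect,
        callrate_error_r=(r, p),
        games_howell_error=gh.pairwise,
        games_howell_letters=gh.letters,
        quality_curve=quality_curve_df,
        sexing=sexes,
        sexing_accuracy=sex_acc,
        imputation=per_sample,
        imputation_summary={
            "n_mendel_inconsistent": report.n_mendel_inconsistent,
            "n_corrected": report.n_corrected,
            "final_missing_rate": report.final_missing_rate,
            "homozygosity_rate": report.homozygosity_rate,
            "genomic_inbreeding": report.genomic_inbreeding,
            "pedigree_inbreeding": report.pedigree_inbreeding,
        },
        error_correction_rate=float(correction_rate),
        pre_imputation_errors=pre_errors,
        post_imputation_errors=post_errors,
        merit={
            "pearson_r": merit.pearson_r,
            "pearson_p": merit.pearson_p,
            "mean_abs_divergence": merit.mean_abs_divergence,
            "spearman_rho": merit.spearman_rho,
            "top_k_overlap": merit.top_k_overlap,
        },
        checks=checks,
    )
    if out_dir is not None:
        write_reports(result, out_dir)
    log.info("experiment complete (%.1fs)", time.time() - t0)
    return result


def write_reports(result: ExperimentResult, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.method_metrics.to_csv(out / "method_metrics.tsv", sep="\t", index=False)
    result.concordance.to_csv(out / "replicate_concordance.tsv", sep="\t", index=False)
    result.games_howell_error.to_csv(out / "games_howell_error.tsv", sep="\t", index=False)
    if result.quality_curve is not None:
        result.quality_curve.to_csv(out / "quality_threshold_curve.tsv", sep="\t", index=False)
    result.sexing.to_csv(out / "sexing.tsv", sep="\t", index=False)
    result.imputation.to_csv(out / "imputation_per_sample.tsv", sep="\t", index=False)
    le = result.locus_effect_callrate
    summary = pd.DataFrame(
        [
            {"metric": "locus_effect_t", "value": le.statistic},
            {"metric": "locus_effect_p", "value": le.pvalue},
            {"metric": "locus_effect_ci_low", "value": le.ci_low},
            {"metric": "locus_effect_ci_high", "value": le.ci_high},
            {"metric": "callrate_error_pearson_r", "value": result.callrate_error_r[0]},
            {"metric": "callrate_error_pearson_p", "value": result.callrate_error_r[1]},
            {"metric": "sexing_accuracy", "value": result.sexing_accuracy},
            {"metric": "pre_imputation_errors", "value": result.pre_imputation_errors},
            {"metric": "post_imputation_errors", "value": result.post_imputation_errors},
            {"metric": "error_correction_rate", "value": result.error_correction_rate},
            *({"metric": f"imputation_{k}", "value": v}
              for k, v in result.imputation_summary.items()),
            *({"metric": f"merit_{k}", "value": v} for k, v in result.merit.items()),
        ]
    )
    summary.to_csv(out / "summary.tsv", sep="\t", index=False)
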