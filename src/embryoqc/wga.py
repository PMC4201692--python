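"""Whole-genome-amplification error process.

Degrades true genotypes with the error taxonomy observed on amplified
biopsy DNA — missing calls, allele drop-out (AB -> AA/BB), heterozygosity
gain (AA -> AB) and homozygous reversal (AA -> BB) — and recovers the
process parameters from degraded/truth pairs by method of moments.

Missingness and genotype errors are mutually exclusive per cell: the
no-call draw happens first, and error rates are conditional on a call being
made, matching the convention that the error rate is computed relative to
the number of calls a method provides.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .matrix import HET, HOM_A, HOM_B, NO_CALL, GenotypeMatrix

# error-mask categories
CAT_CORRECT = 0
CAT_NO_CALL = 1
CAT_ADO = 2
CAT_HET_GAIN = 3
CAT_HOM_REVERSAL = 4

CATEGORY_NAMES = {
    CAT_CORRECT: "correct",
    CAT_NO_CALL: "no_call",
    CAT_ADO: "allele_dropout",
    CAT_HET_GAIN: "het_gain",
    CAT_HOM_REVERSAL: "hom_reversal",
}


@dataclass(frozen=True)
class WgaErrorModel:
    """Per-call degradation rates of a WGA platform.

    Parameters
    ----------
    miss_rate
        Probability that a cell yields NO_CALL.
    ado_rate
        P(heterozygote called as a homozygote | called); the lost allele is
        chosen uniformly, so AA and BB targets are equally likely.
    hetgain_rate
        P(homozygote called heterozygous | called).
    reversal_rate
        P(homozygote called as the opposite homozygote | called).
    locus_dispersion
        Beta over-dispersion of the per-locus miss rate in [0, 1); 0 means
        every locus shares ``miss_rate`` (the locus-homogeneous binomial
        process).  Variance of the per-locus rate is
        ``miss_rate * (1 - miss_rate) * locus_dispersion``.
    """

    miss_rate: float = 0.0
    ado_rate: float = 0.0
    hetgain_rate: float = 0.0
    reversal_rate: float = 0.0
    locus_dispersion: float = 0.0

    def __post_init__(self):
        for name in ("miss_rate", "ado_rate", "hetgain_rate", "reversal_rate"):
            v = getattr(self, name)
            if not (np.isnan(v) or 0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.hetgain_rate + self.reversal_rate > 1.0 + 1e-12:
            raise ValueError("hetgain_rate + reversal_rate must not exceed 1")
        if not (0.0 <= self.locus_dispersion < 1.0):
            raise ValueError("locus_dispersion must lie in [0, 1)")

    def conditional_error_rate(self, het_fraction: float) -> float:
        """Expected fraction of *calls* that are erroneous, given the truth
        heterozygosity of the genotyped material."""
        return het_fraction * self.ado_rate + (1.0 - het_fraction) * (
            self.hetgain_rate + self.reversal_rate
        )

    @classmethod
    def calibrated(cls, het_fraction: float, total_error: float = 0.124,
                   ado_share: float = 0.85, reversal_share: float = 0.015,
                   miss_rate: float = 0.12,
                   locus_dispersion: float = 0.0) -> "WgaErrorModel":
        """Build a model whose conditional error rate equals ``total_error``.

        ``ado_share`` / ``reversal_share`` apportion the composite error
        among allele drop-out and homozygous reversal (the remainder is
        heterozygosity gain); the per-class rates are then scaled by the
        truth composition so that the realized overall error matches.
        """
        if not (0 < het_fraction < 1):
            raise ValueError("het_fraction must lie in (0, 1)")
        if ado_share + reversal_share > 1:
            raise ValueError("ado_share + reversal_share must not exceed 1")
        ado = total_error * ado_share / het_fraction
        hg = total_error * (1.0 - ado_share - reversal_share) / (1.0 - het_fraction)
        rev = total_error * reversal_share / (1.0 - het_fraction)
        return cls(miss_rate, ado, hg, rev, locus_dispersion)


@dataclass(frozen=True)
class MethodProfile:
    """A named WGA platform profile."""

    name: str
    model: WgaErrorModel


def default_profiles(het_fraction: float) -> dict[str, MethodProfile]:
    """Stylized platform profiles for the low-input (15-cell) setting.

    Rates mimic the qualitative ordering of the tested chemistries: an
    MDA profile calibrated to ~12.4% conditional error dominated by allele
    drop-out, a high-dropout MDA variant, a drop-in-dominated QPLS profile,
    and high-error SPIA/ligation-mediated profiles.  Call and error rates
    are coupled (template loss drives both), so call rate and error rate
    correlate negatively across profiles by construction.
    """
    spec = {
        # name: (miss, total_error, ado_share, reversal_share)
        "reference": (0.005, 0.0005, 0.5, 0.0),
        "mda_genomiphi": (0.12, 0.124, 0.85, 0.015),
        "mda_replig": (0.55, 0.35, 0.90, 0.02),
        "qpls": (0.35, 0.21, 0.30, 0.02),
        "spia": (0.60, 0.45, 0.60, 0.04),
        "lma": (0.75, 0.60, 0.50, 0.09),
        "lma_expresslink": (0.65, 0.50, 0.50, 0.08),
        "lma_ligafast": (0.72, 0.55, 0.50, 0.09),
    }
    return {
        name: MethodProfile(
            name,
            WgaErrorModel.calibrated(het_fraction, err, ado, rev, miss_rate=miss),
        )
        for name, (miss, err, ado, rev) in spec.items()
    }


def inject_wga_errors(truth: GenotypeMatrix, model: WgaErrorModel,
                      rng: np.random.Generator | int | None = None
                      ) -> tuple[GenotypeMatrix, np.ndarray]:
    """Degrade a fully-called truth matrix; return (degraded, category mask).

    The mask assigns exactly one category per cell (correct / no_call /
    allele_dropout / het_gain / hom_reversal).
    """
    if (truth.calls == NO_CALL).any():
        raise ValueError("truth matrix must contain no NO_CALL cells")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    n, L = truth.calls.shape
    calls = truth.calls.copy()
    mask = np.full((n, L), CAT_CORRECT, dtype=np.uint8)

    if model.locus_dispersion > 0 and 0 < model.miss_rate < 1:
        nu = (1.0 - model.locus_dispersion) / model.locus_dispersion
        locus_miss = rng.beta(model.miss_rate * nu, (1.0 - model.miss_rate) * nu, size=L)
    else:
        locus_miss = np.full(L, model.miss_rate)
    missing = rng.random((n, L)) < locus_miss[None, :]
    calls[missing] = NO_CALL
    mask[missing] = CAT_NO_CALL

    u = rng.random((n, L))
    het = (truth.calls == HET) & ~missing
    ado = het & (u < model.ado_rate)
    to_b = rng.random((n, L)) < 0.5  # lost allele chosen uniformly
    calls[ado & to_b] = HOM_B
    calls[ado & ~to_b] = HOM_A
    mask[ado] = CAT_ADO

    hom = (truth.calls != HET) & ~missing
    gain = hom & (u < model.hetgain_rate)
    rev = hom & ~gain & (u < model.hetgain_rate + model.reversal_rate)
    calls[gain] = HET
    calls[rev] = (2 - truth.calls[rev]).astype(np.int8)
    mask[gain] = CAT_HET_GAIN
    mask[rev] = CAT_HOM_REVERSAL

    degraded = GenotypeMatrix(list(truth.sample_ids), truth.loci.copy(), calls)
    return degraded, mask


def error_mask_is_error(mask: np.ndarray) -> np.ndarray:
    """Boolean view of a category mask: True where the call is erroneous."""
    return np.isin(mask, (CAT_ADO, CAT_HET_GAIN, CAT_HOM_REVERSAL))


def estimate_error_model(degraded: GenotypeMatrix, truth: GenotypeMatrix) -> WgaErrorModel:
    """Method-of-moments recovery of the degradation rates.

    Rates with an empty denominator class (e.g. ADO when the truth has no
    heterozygotes) are reported as NaN, not 0.
    """
    if degraded.calls.shape != truth.calls.shape:
        raise ValueError("degraded and truth matrices are not aligned")
    t, d = truth.calls, degraded.calls
    total = t.size
    n_missing = int((d == NO_CALL).sum())
    miss = n_missing / total if total else np.nan

    called = d != NO_CALL
    het_called = (t == HET) & called
    hom_called = (t != HET) & (t != NO_CALL) & called
    n_het = int(het_called.sum())
    n_hom = int(hom_called.sum())
    ado = float((het_called & (d != HET)).sum() / n_het) if n_het else np.nan
    hg = float((hom_called & (d == HET)).sum() / n_hom) if n_hom else np.nan
    rev = float((hom_called & (d == (2 - t))).sum() / n_hom) if n_hom else np.nan
    return WgaErrorModel(miss, ado, hg, rev)


def mask_to_table(mask: np.ndarray, matrix: GenotypeMatrix):
    """Long-format (sample, locus, category) table of non-correct cells."""
    import pandas as pd

    rows = np.nonzero(mask != CAT_CORRECT)
    return pd.DataFrame(
        {
            "sample_id": [matrix.sample_ids[i] for i in rows[0]],
            "locus_id": matrix.loci["locus_id"].to_numpy()[rows[1]],
            "category": [CATEGORY_NAMES[int(c)] for c in mask[rows]],
        }
    )
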