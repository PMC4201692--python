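"""Direct genomic values and the lifetime-profit-style selection index.

DGV(sample, trait) = sum over loci of the per-locus additive effect times
the allele-B dosage; the selection index combines cohort-standardized trait
DGVs with economic weights and maps them to points through an affine scale.
Standardization is within the evaluated cohort (the official population
base is not available here); the affine freedom leaves correlations and
rankings untouched.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import MarkerEffectSet
from .matrix import NO_CALL, GenotypeMatrix


def compute_dgv(matrix: GenotypeMatrix, effects: MarkerEffectSet) -> pd.DataFrame:
    """Per-sample, per-trait direct genomic values.

    The matrix must be fully called (impute first); loci must align with the
    effect table.
    """
    if (matrix.calls == NO_CALL).any():
        raise ValueError("matrix contains NO_CALL cells; impute before computing DGV")
    ids = list(matrix.loci["locus_id"])
    if list(effects.effects.index) != ids:
        try:
            eff = effects.effects.loc[ids]
        except KeyError as exc:
            raise ValueError("effect table does not cover the matrix loci") from exc
    else:
        eff = effects.effects
    dosage = matrix.calls.astype(float)
    values = dosage @ eff.to_numpy()
    return pd.DataFrame(values, index=pd.Index(matrix.sample_ids, name="sample_id"),
                        columns=eff.columns)


def compute_index(dgvs: pd.DataFrame, effects: MarkerEffectSet) -> pd.Series:
    """Selection index in points from per-trait DGVs.

    index = offset + scale * sum_t w_t * z(DGV_t), with z-scoring over the
    evaluated cohort.  A trait with zero cohort variance cannot be
    standardized and is skipped (its weight does not contribute).
    """
    total = pd.Series(np.zeros(len(dgvs)), index=dgvs.index)
    for trait in dgvs.columns:
        w = float(effects.index_weights.get(trait, 0.0))
        col = dgvs[trait].to_numpy(dtype=float)
        sd = col.std(ddof=0)
        if sd == 0:
            continue
        total += w * (col - col.mean()) / sd
    return effects.index_offset + effects.index_scale * total


@dataclass(frozen=True)
class MeritComparison:
    pearson_r: float
    pearson_p: float
    mean_abs_divergence: float
    spearman_rho: float
    top_k_overlap: float
    n: int
    top_k: int


def compare_merit(embryo_index: pd.Series, calf_index: pd.Series,
                  top_k: int = 10) -> MeritComparison:
    """Concordance between two index vectors over the same individuals.

    Reports Pearson r (with two-sided P), the mean absolute divergence in
    index points, Spearman rho, and the overlap fraction of the top-k sets.
    """
    a = np.asarray(embryo_index, dtype=float)
    b = np.asarray(calf_index, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("index vectors must be 1-D and paired")
    if a.size < 3:
        raise ValueError("need at least 3 paired samples")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("correlation undefined: an index vector has zero variance")
    r, p = stats.pearsonr(a, b)
    rho = float(stats.spearmanr(a, b).statistic)
    k = min(top_k, a.size)
    top_a = set(np.argsort(-a, kind="stable")[:k])
    top_b = set(np.argsort(-b, kind="stable")[:k])
    return MeritComparison(
        pearson_r=float(r),
        pearson_p=float(p),
        mean_abs_divergence=float(np.abs(a - b).mean()),
        spearman_rho=rho,
        top_k_overlap=len(top_a & top_b) / k,
        n=a.size,
        top_k=k,
    )
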