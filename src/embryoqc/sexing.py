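"""Sex determination from SNP genotypes.

The 50K cattle panel carries no Y-specific loci, so sex is inferred by
comparing X-chromosome heterozygosity to autosomal heterozygosity: a male
(hemizygous X, arrays report homozygous calls) should show essentially no
heterozygous X genotypes, while a female's X heterozygosity resembles her
autosomal level.  Allele drop-out depresses heterozygosity everywhere, so
the decision uses the X/autosome *ratio* rather than an absolute level;
high drop-out still erodes the contrast and pushes females toward male
calls, which is the expected failure mode.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import FEMALE, HET, MALE, NO_CALL, GenotypeMatrix

UNDETERMINED = "U"


@dataclass(frozen=True)
class HetRates:
    autosomal_het: float
    x_het: float
    n_x_called: int
    n_autosomal_called: int


def het_rates(calls: np.ndarray, x_mask: np.ndarray) -> HetRates:
    """Heterozygosity of one sample's calls, split by autosomes vs X.

    Each rate is HET calls over called loci in its class; zero called X
    loci yields ``x_het = NaN`` (undetermined upstream).
    """
    calls = np.asarray(calls)
    x_mask = np.asarray(x_mask, dtype=bool)
    called = calls != NO_CALL
    n_auto = int((called & ~x_mask).sum())
    n_x = int((called & x_mask).sum())
    if n_auto == 0:
        raise ValueError("no called autosomal loci")
    aut = float((calls[~x_mask & called] == HET).mean())
    x = float((calls[x_mask & called] == HET).mean()) if n_x else np.nan
    return HetRates(aut, x, n_x, n_auto)


def call_sex(rates: HetRates, ratio_threshold: float = 0.2, min_x_loci: int = 50) -> str:
    """MALE / FEMALE / UNDETERMINED from heterozygosity rates.

    MALE requires X heterozygosity below ``ratio_threshold`` times the
    autosomal level with at least ``min_x_loci`` called X loci; FEMALE
    requires X heterozygosity at or above that fraction; anything else
    (no called X loci, zero autosomal heterozygosity, too few X calls) is
    UNDETERMINED.
    """
    if rates.n_x_called == 0 or not np.isfinite(rates.x_het):
        return UNDETERMINED
    if rates.autosomal_het == 0:
        return UNDETERMINED
    if rates.x_het >= ratio_threshold * rates.autosomal_het:
        return FEMALE
    if rates.n_x_called >= min_x_loci:
        return MALE
    return UNDETERMINED


def sex_table(matrix: GenotypeMatrix, ratio_threshold: float = 0.2,
              min_x_loci: int = 50) -> pd.DataFrame:
    """Per-sample heterozygosity rates and sex calls."""
    x_mask = matrix.x_mask
    rows = []
    for i, sid in enumerate(matrix.sample_ids):
        r = het_rates(matrix.calls[i], x_mask)
        rows.append(
            {
                "sample_id": sid,
                "autosomal_het": r.autosomal_het,
                "x_het": r.x_het,
                "n_x_called": r.n_x_called,
                "sex_call": call_sex(r, ratio_threshold, min_x_loci),
            }
        )
    return pd.DataFrame(rows)
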