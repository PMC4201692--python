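"""Genotyping performance metrics.

Call-rate/error-rate tallies against a reference, replicate-concordance
accounting ("all / at least 2 of k / any replicate"), the binomial
locus-homogeneity test, the call-rate vs error-rate correlation, and the
quality-score threshold sweep.

Conventions: loci where the reference is NO_CALL are excluded from every
denominator; the error rate is computed relative to the number of calls the
sample provides, while the call rate and the correct-call proportion are
relative to the reference-called loci.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .matrix import HET, NO_CALL, GenotypeMatrix
from .wga import (
    CAT_ADO,
    CAT_CORRECT,
    CAT_HET_GAIN,
    CAT_HOM_REVERSAL,
    CAT_NO_CALL,
)


# ---------------------------------------------------------------------------
# call classification and tallies
# ---------------------------------------------------------------------------

def classify_calls(ref: np.ndarray, obs: np.ndarray) -> np.ndarray:
    """Vectorized call classification against a called reference.

    Returns the WGA category codes: correct, no_call, allele_dropout
    (ref HET observed homozygous), het_gain (ref homozygous observed HET) or
    hom_reversal (opposite homozygote).  Raises if any reference cell is
    NO_CALL — such loci must be excluded upstream.
    """
    ref = np.asarray(ref)
    obs = np.asarray(obs)
    if (ref == NO_CALL).any():
        raise ValueError("reference contains NO_CALL; exclude those loci first")
    cat = np.full(ref.shape, CAT_CORRECT, dtype=np.uint8)
    cat[obs == NO_CALL] = CAT_NO_CALL
    called = obs != NO_CALL
    wrong = called & (obs != ref)
    cat[wrong & (ref == HET)] = CAT_ADO
    cat[wrong & (ref != HET) & (obs == HET)] = CAT_HET_GAIN
    cat[wrong & (ref != HET) & (obs != HET)] = CAT_HOM_REVERSAL
    return cat


def classify_call(ref: int, obs: int) -> int:
    """Scalar convenience wrapper around :func:`classify_calls`."""
    return int(classify_calls(np.array([ref]), np.array([obs]))[0])


@dataclass(frozen=True)
class ErrorTally:
    """Counts of call outcomes over the reference-called loci of one sample.

    Invariants (asserted at construction):
    ``n_called = n_correct + n_ado + n_hetgain + n_homrev`` and
    ``n_ref_called = n_called + n_nocall_vs_ref``.
    """

    n_ref_called: int
    n_called: int
    n_correct: int
    n_ado: int
    n_hetgain: int
    n_homrev: int
    n_nocall_vs_ref: int

    def __post_init__(self):
        if self.n_called != self.n_correct + self.n_ado + self.n_hetgain + self.n_homrev:
            raise ValueError("tally identity violated: calls != correct + errors")
        if self.n_ref_called != self.n_called + self.n_nocall_vs_ref:
            raise ValueError("tally identity violated: ref-called != called + no-calls")

    @property
    def n_errors(self) -> int:
        return self.n_ado + self.n_hetgain + self.n_homrev

    @property
    def error_rate(self) -> float:
        """Erroneous calls relative to the calls the sample provided."""
        return self.n_errors / self.n_called if self.n_called else np.nan

    @property
    def call_rate(self) -> float:
        return self.n_called / self.n_ref_called if self.n_ref_called else np.nan

    @property
    def correct_prop(self) -> float:
        """Correct calls over reference-called loci (a no-call counts as a
        failure to provide the correct call)."""
        return self.n_correct / self.n_ref_called if self.n_ref_called else np.nan


def tally(ref: GenotypeMatrix, obs: GenotypeMatrix, sample: str | None = None) -> ErrorTally:
    """Tally one sample (or all cells pooled if ``sample`` is None)."""
    if not ref.same_loci(obs):
        raise ValueError("reference and observed matrices are not locus-aligned")
    if sample is None:
        r, o = ref.calls, obs.calls
    else:
        r = ref.calls[ref.sample_index(sample)]
        o = obs.calls[obs.sample_index(sample)]
    keep = r != NO_CALL
    if not keep.any():
        raise ValueError("no overlapping reference-called loci")
    cat = classify_calls(r[keep], o[keep])
    counts = np.bincount(cat.ravel(), minlength=5)
    return ErrorTally(
        n_ref_called=int(keep.sum()),
        n_called=int(counts[CAT_CORRECT] + counts[CAT_ADO] + counts[CAT_HET_GAIN] + counts[CAT_HOM_REVERSAL]),
        n_correct=int(counts[CAT_CORRECT]),
        n_ado=int(counts[CAT_ADO]),
        n_hetgain=int(counts[CAT_HET_GAIN]),
        n_homrev=int(counts[CAT_HOM_REVERSAL]),
        n_nocall_vs_ref=int(counts[CAT_NO_CALL]),
    )


# ---------------------------------------------------------------------------
# replicate concordance
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConcordanceSummary:
    """Fractions of reference loci covered (and erroneous) in all / at least
    2 of k / any replicate."""

    k: int
    n_ref_loci: int
    f_all: float
    f_atleast2: float
    f_any: float
    err_all: float
    err_atleast2: float
    err_any: float

    def __post_init__(self):
        if not (self.f_all <= self.f_atleast2 + 1e-12 and self.f_atleast2 <= self.f_any + 1e-12):
            raise ValueError("coverage fractions must be ordered all <= atleast2 <= any")


def replicate_concordance(replicates: list[GenotypeMatrix], ref: GenotypeMatrix) -> ConcordanceSummary:
    """Per-locus called-replicate (and erroneous-replicate) counts.

    Counts are pooled over samples; fractions are over reference-called
    cells.
    """
    if len(replicates) < 2:
        raise ValueError("need at least 2 replicates")
    k = len(replicates)
    for r in replicates:
        if not r.same_loci(ref) or r.sample_ids != ref.sample_ids:
            raise ValueError("replicates must align with the reference")
    keep = ref.calls != NO_CALL
    n_ref = int(keep.sum())
    called = np.zeros(ref.calls.shape, dtype=np.int32)
    wrong = np.zeros(ref.calls.shape, dtype=np.int32)
    for r in replicates:
        c = r.calls != NO_CALL
        called += c
        wrong += c & (r.calls != ref.calls)
    called, wrong = called[keep], wrong[keep]
    return ConcordanceSummary(
        k=k,
        n_ref_loci=n_ref,
        f_all=float((called == k).mean()),
        f_atleast2=float((called >= 2).mean()),
        f_any=float((called >= 1).mean()),
        err_all=float((wrong == k).mean()),
        err_atleast2=float((wrong >= 2).mean()),
        err_any=float((wrong >= 1).mean()),
    )


def expected_binomial_concordance(p_mean: float, k: int, n_loci: int) -> dict[str, float]:
    """Expected all / at-least-2 / any counts under a locus-homogeneous
    binomial process with per-replicate success probability ``p_mean``."""
    if not 0 <= p_mean <= 1:
        raise ValueError("p_mean must lie in [0, 1]")
    if k < 2:
        raise ValueError("k must be >= 2")
    p_all = p_mean ** k
    p_any = 1.0 - (1.0 - p_mean) ** k
    p_atleast2 = float(stats.binom.sf(1, k, p_mean))
    return {
        "all": n_loci * p_all,
        "atleast2": n_loci * p_atleast2,
        "any": n_loci * p_any,
    }


# ---------------------------------------------------------------------------
# locus-effect (binomial homogeneity) test
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LocusEffectResult:
    statistic: float
    df: int
    pvalue: float
    mean_diff: float
    ci_low: float
    ci_high: float


def locus_effect_test(observed: np.ndarray, expected: np.ndarray,
                      n_loci: np.ndarray | int, confidence: float = 0.95) -> LocusEffectResult:
    """Paired t-test of observed vs binomially expected concordance counts.

    ``observed`` and ``expected`` are method-level counts (one pair per
    method); the test is computed on the paired differences expressed as
    fractions of ``n_loci``.  A mean difference near zero indicates that
    failures are randomly distributed among loci (no locus-specific effect).
    """
    observed = np.asarray(observed, dtype=float)
    expected = np.asarray(expected, dtype=float)
    if observed.shape != expected.shape or observed.ndim != 1:
        raise ValueError("observed and expected must be 1-D and aligned")
    if observed.size < 2:
        raise ValueError("need at least 2 paired method-level values")
    n = np.broadcast_to(np.asarray(n_loci, dtype=float), observed.shape)
    diffs = (observed - expected) / n
    df = observed.size - 1
    mean = float(diffs.mean())
    if diffs.std(ddof=1) == 0:
        # degenerate: all differences identical (e.g. observed == expected)
        stat = 0.0 if mean == 0 else np.inf * np.sign(mean)
        pval = 1.0 if mean == 0 else 0.0
        return LocusEffectResult(stat, df, pval, mean, mean, mean)
    res = stats.ttest_rel(observed / n, expected / n)
    se = float(diffs.std(ddof=1) / np.sqrt(diffs.size))
    tcrit = stats.t.ppf(0.5 + confidence / 2, df)
    return LocusEffectResult(
        statistic=float(res.statistic),
        df=df,
        pvalue=float(res.pvalue),
        mean_diff=mean,
        ci_low=mean - tcrit * se,
        ci_high=mean + tcrit * se,
    )


# ---------------------------------------------------------------------------
# call-rate vs error-rate correlation
# ---------------------------------------------------------------------------

def callrate_error_correlation(points) -> tuple[float, float]:
    """Pearson r (and two-sided P) between call rate and error rate."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise ValueError("need >= 3 (call_rate, error_rate) points")
    x, y = pts[:, 0], pts[:, 1]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined: zero variance in a coordinate")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


# ---------------------------------------------------------------------------
# quality-score threshold sweep
# ---------------------------------------------------------------------------

@dataclass
class QualityThresholdCurve:
    table: pd.DataFrame
    best_threshold: float
    removal_defined: bool


def quality_threshold_curve(quality: np.ndarray, is_error: np.ndarray,
                            thresholds: np.ndarray | None = None) -> QualityThresholdCurve:
    """Sweep quality thresholds; report error removal vs correct retention.

    A call is discarded when its quality falls below the threshold.
    ``errors_removed(t)`` is non-decreasing and ``correct_retained(t)``
    non-increasing in t by construction.  The reported best threshold
    maximizes removal minus correct-call loss.
    """
    quality = np.asarray(quality, dtype=float).ravel()
    is_error = np.asarray(is_error, dtype=bool).ravel()
    keep = np.isfinite(quality)
    quality, is_error = quality[keep], is_error[keep]
    if quality.size == 0:
        raise ValueError("no scored calls")
    if thresholds is None:
        thresholds = np.linspace(0.0, 1.0, 101)
    n_err = int(is_error.sum())
    n_ok = int((~is_error).sum())
    removal = np.array([
        (is_error & (quality < t)).sum() / n_err if n_err else np.nan for t in thresholds
    ])
    retention = np.array([
        (~is_error & (quality >= t)).sum() / n_ok if n_ok else np.nan for t in thresholds
    ])
    table = pd.DataFrame(
        {"threshold": thresholds, "errors_removed": removal, "correct_retained": retention}
    )
    if n_err:
        score = removal - (1.0 - retention)
        best = float(thresholds[int(np.argmax(score))])
    else:
        best = float(thresholds[0])
    return QualityThresholdCurve(table, best, removal_defined=bool(n_err))
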