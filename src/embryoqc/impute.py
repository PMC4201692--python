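"""Mendelian-inconsistency correction and family/population imputation.

The workflow mirrors how embryo-biopsy genotypes are repaired in practice:

1.  Calls impossible under Mendelian transmission given the (clean) parental
    genotypes are detected and blanked.
2.  Family imputation makes the deterministic fills (both parents
    homozygous) and records half-resolved parental-allele constraints.
3.  The embryo's paternal and maternal haplotypes are tracked against the
    parent's two phased haplotypes with a two-state hidden Markov model
    over the informative loci (switch probability from genetic distance,
    vote error rate from the data), which both fills missing calls and —
    via a Bayesian override rule — corrects called genotypes that
    contradict the inherited haplotypes (errors that are
    Mendelian-consistent, e.g. allele drop-out from a HETxHET mating, are
    only catchable this way).
4.  Remaining gaps are closed against a population haplotype library by
    long-to-short window matching with majority fill, with an allele-
    frequency fallback at window length 1, guaranteeing a complete output.

The window-matching design follows the long-to-short overlapping-window
family/population strategy of deterministic livestock imputation software;
it is an independent implementation, not a reimplementation of any
particular program.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import (
    FEMALE,
    HET,
    HOM_A,
    HOM_B,
    MALE,
    NO_CALL,
    UNKNOWN_PARENT,
    X_CHROM,
    GenotypeMatrix,
    Pedigree,
)

# ---------------------------------------------------------------------------
# Mendelian consistency
# ---------------------------------------------------------------------------

def _allele_set(g: int) -> set[int]:
    if g == NO_CALL:
        return {0, 1}
    return {HOM_A: {0}, HET: {0, 1}, HOM_B: {1}}[g]


def _build_mendel_table() -> np.ndarray:
    """Inconsistency lookup indexed by [sire+1, dam+1, embryo+1]."""
    table = np.zeros((4, 4, 4), dtype=bool)
    for s in (NO_CALL, HOM_A, HET, HOM_B):
        for d in (NO_CALL, HOM_A, HET, HOM_B):
            for e in (HOM_A, HET, HOM_B):
                possible = any(
                    a + b == e for a in _allele_set(s) for b in _allele_set(d)
                )
                table[s + 1, d + 1, e + 1] = not possible
    return table


_MENDEL = _build_mendel_table()


def find_mendelian_inconsistencies(
    embryo: np.ndarray,
    sire: np.ndarray | None,
    dam: np.ndarray | None,
    x_mask: np.ndarray | None = None,
    embryo_sex: str = "U",
) -> np.ndarray:
    """Boolean mask of loci where the embryo call is impossible.

    A missing parent (``None`` or NO_CALL at a locus) imposes no constraint
    from that side.  On the X chromosome inheritance is sex-aware: a male
    embryo's single X allele must come from the dam, and a male heterozygous
    X call is impossible outright.
    """
    embryo = np.asarray(embryo)
    L = embryo.shape[0]
    s = np.full(L, NO_CALL, dtype=np.int8) if sire is None else np.asarray(sire)
    d = np.full(L, NO_CALL, dtype=np.int8) if dam is None else np.asarray(dam)
    flags = _MENDEL[s + 1, d + 1, embryo + 1]
    if x_mask is not None and x_mask.any():
        x = np.asarray(x_mask, dtype=bool)
        if embryo_sex == MALE:
            # dam-only transmission; heterozygous X impossible
            dam_only = _MENDEL[0 + NO_CALL + 1, d + 1, embryo + 1]
            flags = np.where(x, dam_only | (embryo == HET), flags)
        # female embryos: the sire's hemizygous X is coded homozygous, so the
        # autosomal table is already correct
    return flags


def correct_inconsistencies(calls: np.ndarray, flags: np.ndarray) -> tuple[np.ndarray, int]:
    """Blank flagged loci; returns (corrected calls, count blanked)."""
    out = np.asarray(calls).copy()
    flags = np.asarray(flags, dtype=bool)
    n = int((flags & (out != NO_CALL)).sum())
    out[flags] = NO_CALL
    return out, n


# ---------------------------------------------------------------------------
# family imputation (deterministic fills + side constraints)
# ---------------------------------------------------------------------------

@dataclass
class SideConstraints:
    """Per-locus parental-allele resolution: -1 unknown, else 0/1 (allele B).

    For a male embryo the X "sire side" mirrors the dam side, matching the
    hemizygote-as-homozygote call coding.
    """

    sire_side: np.ndarray
    dam_side: np.ndarray


def impute_family(
    embryo: np.ndarray,
    sire: np.ndarray | None,
    dam: np.ndarray | None,
    x_mask: np.ndarray | None = None,
    embryo_sex: str = "U",
) -> tuple[np.ndarray, SideConstraints]:
    """Deterministic family fills; never writes a parent-incompatible call.

    Assumes Mendelian inconsistencies were already blanked.  Returns the
    (partially) completed calls plus the half-resolved side constraints.
    """
    e = np.asarray(embryo).copy()
    L = e.shape[0]
    s = np.full(L, NO_CALL, dtype=np.int8) if sire is None else np.asarray(sire)
    d = np.full(L, NO_CALL, dtype=np.int8) if dam is None else np.asarray(dam)
    x = np.zeros(L, dtype=bool) if x_mask is None else np.asarray(x_mask, dtype=bool)
    male_x = x if embryo_sex == MALE else np.zeros(L, dtype=bool)

    ss = np.full(L, -1, dtype=np.int8)
    ds = np.full(L, -1, dtype=np.int8)
    # parental homozygotes fix one side each
    s_hom = (s == HOM_A) | (s == HOM_B)
    d_hom = (d == HOM_A) | (d == HOM_B)
    ss[s_hom] = (s[s_hom] // 2).astype(np.int8)
    ds[d_hom] = (d[d_hom] // 2).astype(np.int8)
    # male X: no paternal contribution
    ss[male_x] = -1
    # embryo homozygote fixes both sides
    e_hom = (e == HOM_A) | (e == HOM_B)
    ss[e_hom & ~male_x] = (e[e_hom & ~male_x] // 2).astype(np.int8)
    ds[e_hom] = (e[e_hom] // 2).astype(np.int8)
    # embryo heterozygote with one side resolved: complement the other
    e_het = e == HET
    fill_d = e_het & (ss >= 0) & (ds < 0) & ~male_x
    ds[fill_d] = 1 - ss[fill_d]
    fill_s = e_het & (ds >= 0) & (ss < 0) & ~male_x
    ss[fill_s] = 1 - ds[fill_s]
    # male X mirrors the maternal allele on the "sire side"
    ss[male_x] = ds[male_x]

    missing = e == NO_CALL
    both = missing & (ss >= 0) & (ds >= 0) & ~male_x
    e[both] = (ss[both] + ds[both]).astype(np.int8)
    mx = missing & male_x & (ds >= 0)
    e[mx] = (2 * ds[mx]).astype(np.int8)
    return e, SideConstraints(ss, ds)


# ---------------------------------------------------------------------------
# haplotype library
# ---------------------------------------------------------------------------

DEFAULT_WINDOWS = (200, 100, 50, 20, 10, 5, 1)


def _chromosome_slices(loci: pd.DataFrame) -> list[slice]:
    chroms = loci["chromosome"].to_numpy()
    out, start = [], 0
    for i in range(1, len(chroms) + 1):
        if i == len(chroms) or chroms[i] != chroms[start]:
            out.append(slice(start, i))
            start = i
    return out


@dataclass
class HaplotypeLibrary:
    """Phased population haplotypes over a fixed locus set.

    ``haplotypes`` has shape (n_haplotypes, n_loci), values 0/1 (allele B);
    ``hap_samples`` names the source individual of each row, so an
    individual's own pair can be looked up for family imputation.
    """

    haplotypes: np.ndarray
    loci: pd.DataFrame
    hap_samples: list[str]
    window_lengths: tuple[int, ...] = DEFAULT_WINDOWS
    min_match: float = 0.97

    def __post_init__(self):
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        if self.haplotypes.ndim != 2 or self.haplotypes.shape[0] < 2:
            raise ValueError("need at least 2 haplotypes")
        if self.haplotypes.shape[1] != len(self.loci):
            raise ValueError("haplotype length does not match locus table")
        if len(self.hap_samples) != self.haplotypes.shape[0]:
            raise ValueError("hap_samples length mismatch")
        w = tuple(self.window_lengths)
        if len(w) < 1 or any(b >= a for a, b in zip(w, w[1:])) or w[-1] < 1:
            raise ValueError("window_lengths must be strictly descending, ending >= 1")
        if not (0 < self.min_match <= 1):
            raise ValueError("min_match must lie in (0, 1]")
        self.window_lengths = w

    @property
    def freqs(self) -> np.ndarray:
        return self.haplotypes.mean(axis=0)

    def sample_haplotypes(self, sample_id: str) -> np.ndarray | None:
        idx = [i for i, s in enumerate(self.hap_samples) if s == sample_id]
        if not idx:
            return None
        return self.haplotypes[idx]

    @classmethod
    def from_phased(cls, haplotypes: np.ndarray, loci: pd.DataFrame,
                    sample_ids: list[str], **kw) -> "HaplotypeLibrary":
        """Build from per-individual phased haplotypes of shape (n, 2, L)."""
        haps = np.asarray(haplotypes, dtype=np.int8)
        flat = haps.reshape(-1, haps.shape[-1])
        names = [s for s in sample_ids for _ in range(2)]
        return cls(flat, loci, names, **kw)


def phase_matrix(matrix: GenotypeMatrix) -> tuple[np.ndarray, list[str]]:
    """Statistically phase a (near-)complete genotype matrix.

    Homozygous loci are trivially phased.  Consecutive heterozygous loci of
    a sample are linked through the sign of the inter-locus composite LD
    (genotype covariance across the matrix): positive LD places the B
    alleles on the same haplotype.  Under the short-range copying LD this
    package simulates, adjacent-locus LD is positive and strong, so the
    chain achieves high switch accuracy; samples with missing calls are
    excluded with a warning.
    """
    dosage = matrix.calls.astype(float)
    dosage[matrix.calls == NO_CALL] = np.nan
    centred = dosage - np.nanmean(dosage, axis=0, keepdims=True)
    centred = np.nan_to_num(centred)
    present = (matrix.calls != NO_CALL).astype(float)

    def cov_pairs(a_idx: np.ndarray, b_idx: np.ndarray) -> np.ndarray:
        out = np.empty(a_idx.size)
        chunk = 20_000
        for lo in range(0, a_idx.size, chunk):
            hi = min(lo + chunk, a_idx.size)
            num = (centred[:, a_idx[lo:hi]] * centred[:, b_idx[lo:hi]]).sum(axis=0)
            cnt = (present[:, a_idx[lo:hi]] * present[:, b_idx[lo:hi]]).sum(axis=0)
            out[lo:hi] = np.where(cnt > 1, num / np.maximum(cnt, 1), 0.0)
        return out

    slices = _chromosome_slices(matrix.loci)
    haps = np.empty((matrix.n_samples, 2, matrix.n_loci), dtype=np.int8)
    kept, kept_ids = [], []
    for i, sid in enumerate(matrix.sample_ids):
        calls = matrix.calls[i]
        if (calls == NO_CALL).any():
            warnings.warn(f"sample {sid!r} has missing calls; excluded from phasing")
            continue
        h1 = (calls // 2).astype(np.int8)  # hom loci: allele; het loci fixed below
        h1[calls == HET] = 0
        h2 = h1.copy()
        # orient het loci chromosome by chromosome
        a_list, b_list, targets = [], [], []
        for sl in slices:
            het = np.flatnonzero(calls[sl] == HET) + sl.start
            if het.size == 0:
                continue
            targets.append(het)
            a_list.append(het[:-1])
            b_list.append(het[1:])
        a_idx = np.concatenate(a_list) if a_list else np.array([], dtype=int)
        b_idx = np.concatenate(b_list) if b_list else np.array([], dtype=int)
        covs = cov_pairs(a_idx, b_idx) if a_idx.size else np.array([])
        pos = 0
        for het in targets:
            orient = 0  # 0: B on h1 at this het locus
            h1[het[0]], h2[het[0]] = 1, 0
            for t in range(1, het.size):
                same = covs[pos] >= 0  # positive LD: B alleles co-reside
                pos += 1
                if not same:
                    orient ^= 1
                h1[het[t]] = 1 - orient
                h2[het[t]] = orient
            # consume the pair list in lockstep with a_idx/b_idx
        haps[len(kept), 0] = h1
        haps[len(kept), 1] = h2
        kept.append(i)
        kept_ids.append(sid)
    return haps[: len(kept)], kept_ids


def build_library(matrix: GenotypeMatrix,
                  window_lengths: tuple[int, ...] = DEFAULT_WINDOWS,
                  min_match: float = 0.97) -> HaplotypeLibrary:
    """Phase a population matrix and wrap it as a haplotype library."""
    haps, ids = phase_matrix(matrix)
    if len(ids) < 1:
        raise ValueError("no phaseable samples")
    return HaplotypeLibrary.from_phased(haps, matrix.loci.copy(), ids,
                                        window_lengths=window_lengths,
                                        min_match=min_match)


# ---------------------------------------------------------------------------
# transmitted-haplotype inference (family step at haplotype level)
# ---------------------------------------------------------------------------

def _infer_transmitted(side: np.ndarray, parent_haps: np.ndarray, sl: slice,
                       cm: np.ndarray, evidence_error: float = 0.1,
                       fill_threshold: float = 0.8
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Track the transmitted parental haplotype along one chromosome.

    The transmitted haplotype is a two-state hidden Markov chain over the
    informative loci (parent heterozygous, embryo side resolved): the
    switch probability between neighbours is their genetic distance in
    Morgans, and each resolved side allele votes for one haplotype with
    error probability ``evidence_error``.  The forward-backward posterior
    is interpolated to every locus; where the two parental haplotypes
    agree the allele is forced with certainty.

    Returns per-locus predicted alleles (-1 where the posterior stays
    below ``fill_threshold``) and P(prediction correct), computed
    leave-one-out at informative loci so that a locus's own — possibly
    erroneous — call cannot vouch for itself.
    """
    h = parent_haps[:, sl]
    s = side[sl]
    cmv = cm[sl]
    n = s.shape[0]
    pred = np.full(n, -1, dtype=np.int8)
    p_right = np.zeros(n)
    differ = h[0] != h[1]
    pred[~differ] = h[0, ~differ]
    p_right[~differ] = 1.0
    evid = np.flatnonzero(differ & (s >= 0))
    if evid.size == 0:
        return pred, p_right

    eps = min(max(evidence_error, 1e-6), 0.49)
    n_e = evid.size
    match0 = s[evid] == h[0, evid]
    emit = np.where(match0[:, None], (1 - eps, eps), (eps, 1 - eps))
    q = np.clip(np.diff(cmv[evid]) / 100.0, 1e-9, 0.49)  # switch probabilities

    f_pre = np.empty((n_e, 2))   # forward before the local emission
    f_post = np.empty((n_e, 2))
    f_pre[0] = 0.5
    for i in range(n_e):
        if i:
            f_pre[i, 0] = f_post[i - 1, 0] * (1 - q[i - 1]) + f_post[i - 1, 1] * q[i - 1]
            f_pre[i, 1] = f_post[i - 1, 1] * (1 - q[i - 1]) + f_post[i - 1, 0] * q[i - 1]
        f_post[i] = f_pre[i] * emit[i]
        f_post[i] /= f_post[i].sum()
    b_excl = np.empty((n_e, 2))  # P(downstream evidence | state), rescaled
    b_excl[-1] = 1.0
    for i in range(n_e - 2, -1, -1):
        nxt = emit[i + 1] * b_excl[i + 1]
        nxt /= nxt.sum()
        b_excl[i, 0] = nxt[0] * (1 - q[i]) + nxt[1] * q[i]
        b_excl[i, 1] = nxt[1] * (1 - q[i]) + nxt[0] * q[i]

    def _norm0(a):
        return a[..., 0] / a.sum(axis=-1)

    post0 = _norm0(f_post * b_excl)   # full posterior P(hap0)
    loo0 = _norm0(f_pre * b_excl)     # leave-one-out posterior

    p0 = np.empty(n)
    p0c = np.empty(n)                 # correction-grade probability
    p0[evid] = post0
    p0c[evid] = loo0
    # terminal extrapolation: decay toward 1/2 with genetic distance
    for end, ev in ((slice(0, evid[0]), 0), (slice(evid[-1] + 1, n), n_e - 1)):
        idx = np.arange(n)[end]
        if idx.size:
            dist = np.clip(np.abs(cmv[idx] - cmv[evid[ev]]) / 100.0, 0, 0.5)
            p0[idx] = post0[ev] * (1 - dist) + (1 - post0[ev]) * dist
            p0c[idx] = p0[idx]
    # interior gaps: pair marginal with a linearly located crossover
    for i in range(1, n_e):
        lo_l, hi_l = evid[i - 1] + 1, evid[i]
        if lo_l >= hi_l:
            continue
        trans = np.array([[1 - q[i - 1], q[i - 1]], [q[i - 1], 1 - q[i - 1]]])
        xi = f_post[i - 1][:, None] * trans * (emit[i] * b_excl[i])[None, :]
        xi /= xi.sum()
        idx = np.arange(lo_l, hi_l)
        span = max(cmv[evid[i]] - cmv[evid[i - 1]], 1e-12)
        w = (cmv[idx] - cmv[evid[i - 1]]) / span
        p0[idx] = xi[0, 0] + xi[0, 1] * (1 - w) + xi[1, 0] * w
        p0c[idx] = p0[idx]

    dif = np.flatnonzero(differ)
    take0 = p0[dif] >= fill_threshold
    take1 = p0[dif] <= 1 - fill_threshold
    pred[dif[take0]] = h[0, dif[take0]]
    pred[dif[take1]] = h[1, dif[take1]]
    decided = dif[take0 | take1]
    p_right[decided] = np.where(p0[decided] >= 0.5, p0c[decided], 1 - p0c[decided])
    return pred, p_right


# ---------------------------------------------------------------------------
# population (library) imputation
# ---------------------------------------------------------------------------

def _match_fill_side(side: np.ndarray, library: HaplotypeLibrary,
                     slices: list[slice]) -> np.ndarray:
    """Fill unknown side alleles by long-to-short window library matching.

    Within each window, candidate haplotypes are those agreeing with the
    side's resolved alleles at a fraction >= ``min_match``; unknowns take
    the candidate-majority allele (population major allele on ties and at
    the length-1 fallback).
    """
    side = side.copy()
    H = library.haplotypes
    freqs = library.freqs
    major = (freqs > 0.5).astype(np.int8)
    for w in library.window_lengths:
        if w == 1:
            unknown = side < 0
            side[unknown] = major[unknown]
            break
        step = max(1, w // 2)
        for sl in slices:
            for start in range(sl.start, sl.stop, step):
                stop = min(start + w, sl.stop)
                seg = slice(start, stop)
                s = side[seg]
                unknown = s < 0
                if not unknown.any():
                    continue
                known = np.flatnonzero(s >= 0)
                if known.size < 3:
                    continue
                agree = (H[:, seg][:, known] == s[known]).mean(axis=1)
                cand = agree >= library.min_match
                if not cand.any():
                    continue
                maj = H[cand][:, seg].mean(axis=0)
                fill = np.where(maj > 0.5, 1, np.where(maj < 0.5, 0, major[seg])).astype(np.int8)
                s[unknown] = fill[unknown]
                side[seg] = s
                if stop == sl.stop:
                    break
    return side


def _resolve_complements(calls: np.ndarray, cons: SideConstraints,
                         male_x: np.ndarray) -> None:
    het = calls == HET
    ss, ds = cons.sire_side, cons.dam_side
    fill_d = het & (ss >= 0) & (ds < 0) & ~male_x
    ds[fill_d] = 1 - ss[fill_d]
    fill_s = het & (ds >= 0) & (ss < 0) & ~male_x
    ss[fill_s] = 1 - ds[fill_s]
    ss[male_x] = np.where(ds[male_x] >= 0, ds[male_x], ss[male_x])


def impute_population(calls: np.ndarray, cons: SideConstraints,
                      library: HaplotypeLibrary, loci: pd.DataFrame,
                      embryo_sex: str = "U") -> np.ndarray:
    """Complete an embryo from a haplotype library given side constraints.

    Guarantees a fully-called output: the length-1 window falls back to the
    library allele frequency.  Fixed parental alleles are never overwritten.
    """
    if library.haplotypes.shape[0] == 0:
        raise ValueError("empty haplotype library")
    x_mask = (loci["chromosome"] == X_CHROM).to_numpy()
    male_x = x_mask if embryo_sex == MALE else np.zeros(len(loci), dtype=bool)
    slices = _chromosome_slices(loci)
    out = np.asarray(calls).copy()
    _resolve_complements(out, cons, male_x)
    cons.sire_side = _match_fill_side(cons.sire_side, library, slices)
    _resolve_complements(out, cons, male_x)
    cons.dam_side = _match_fill_side(cons.dam_side, library, slices)
    _resolve_complements(out, cons, male_x)
    missing = out == NO_CALL
    g = (cons.sire_side + cons.dam_side).astype(np.int8)
    g[male_x] = (2 * cons.dam_side[male_x]).astype(np.int8)
    out[missing] = g[missing]
    return out


# ---------------------------------------------------------------------------
# per-trio orchestration
# ---------------------------------------------------------------------------

@dataclass
class ImputeParams:
    """Tunables of the correction/imputation engine.

    ``evidence_error`` is the assumed error probability of a resolved side
    allele used by the transmitted-haplotype HMM; ``fill_threshold`` is the
    posterior needed before a missing call is filled from the inferred
    haplotype.  ``haplotype_correction`` enables overriding called
    genotypes that contradict the inherited haplotypes (necessary to catch
    Mendelian-consistent errors such as most allele drop-out); a call is
    overridden only when P(prediction correct) beats P(call correct), with
    the call error rate estimated per embryo from its Mendelian-flag count
    times ``mendel_error_multiplier`` (roughly one error in two is
    Mendelian-visible when both parents are genotyped) unless
    ``obs_error_rate`` pins it explicitly.
    """

    evidence_error: float = 0.1
    fill_threshold: float = 0.8
    haplotype_correction: bool = True
    mendel_error_multiplier: float = 2.0
    obs_error_rate: float | None = None


@dataclass
class TrioImputeResult:
    calls: np.ndarray
    n_mendel_inconsistent: int
    n_haplotype_corrected: int
    n_filled: int


def impute_trio(embryo: np.ndarray, sire: np.ndarray | None, dam: np.ndarray | None,
                loci: pd.DataFrame, library: HaplotypeLibrary,
                embryo_sex: str = "U",
                sire_haps: np.ndarray | None = None,
                dam_haps: np.ndarray | None = None,
                params: ImputeParams = ImputeParams()) -> TrioImputeResult:
    """Correct and complete one embryo against its parents and a library."""
    x_mask = (loci["chromosome"] == X_CHROM).to_numpy()
    male_x = x_mask if embryo_sex == MALE else np.zeros(len(loci), dtype=bool)
    slices = _chromosome_slices(loci)
    n_missing_in = int((np.asarray(embryo) == NO_CALL).sum())

    flags = find_mendelian_inconsistencies(embryo, sire, dam, x_mask, embryo_sex)
    calls, n_mendel = correct_inconsistencies(embryo, flags)
    n_called_in = int((np.asarray(embryo) != NO_CALL).sum())
    calls, cons = impute_family(calls, sire, dam, x_mask, embryo_sex)

    n_corrected = 0
    if sire_haps is not None or dam_haps is not None:
        cm = (loci["genetic_pos_cM"].to_numpy()
              if "genetic_pos_cM" in loci.columns
              else loci["position_bp"].to_numpy() / 1e6)
        pred_s = np.full(len(loci), -1, dtype=np.int8)
        pred_d = np.full(len(loci), -1, dtype=np.int8)
        prob_s = np.zeros(len(loci))
        prob_d = np.zeros(len(loci))
        for sl in slices:
            if sire_haps is not None:
                pred_s[sl], prob_s[sl] = _infer_transmitted(
                    cons.sire_side, sire_haps, sl, cm,
                    params.evidence_error, params.fill_threshold)
            if dam_haps is not None:
                pred_d[sl], prob_d[sl] = _infer_transmitted(
                    cons.dam_side, dam_haps, sl, cm,
                    params.evidence_error, params.fill_threshold)
        g_pred = np.full(len(loci), -1, dtype=np.int8)
        both = (pred_s >= 0) & (pred_d >= 0) & ~male_x
        g_pred[both] = (pred_s[both] + pred_d[both]).astype(np.int8)
        mx = male_x & (pred_d >= 0)
        g_pred[mx] = (2 * pred_d[mx]).astype(np.int8)
        g_prob = np.where(male_x, prob_d, prob_s * prob_d)

        if params.haplotype_correction:
            # Bayes rule: override an observed call only when the posterior
            # odds of the haplotype prediction beat the prior odds that the
            # call itself is correct
            if params.obs_error_rate is not None:
                eps_obs = params.obs_error_rate
            else:
                eps_obs = min(
                    0.5,
                    params.mendel_error_multiplier * n_mendel / max(n_called_in, 1),
                )
            wrong = (
                (calls != NO_CALL)
                & (g_pred >= 0)
                & (g_pred != calls)
                & (eps_obs * g_prob > (1.0 - eps_obs) * (1.0 - g_prob))
            )
            n_corrected = int(wrong.sum())
            calls = calls.copy()
            calls[wrong] = g_pred[wrong]
        fill = (calls == NO_CALL) & (g_pred >= 0)
        calls[fill] = g_pred[fill]
        # refresh side constraints from the haplotype predictions
        upd_s = (pred_s >= 0) & ~male_x
        cons.sire_side[upd_s] = pred_s[upd_s]
        upd_d = pred_d >= 0
        cons.dam_side[upd_d] = pred_d[upd_d]

    calls = impute_population(calls, cons, library, loci, embryo_sex)
    n_filled = n_missing_in + n_mendel
    return TrioImputeResult(calls, n_mendel, n_corrected, n_filled)


# ---------------------------------------------------------------------------
# cohort-level driver and report
# ---------------------------------------------------------------------------

def impute_matrix(degraded: GenotypeMatrix, pedigree: Pedigree,
                  parents: GenotypeMatrix | None, library: HaplotypeLibrary,
                  params: ImputeParams = ImputeParams(),
                  use_parents: bool = True) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Correct and impute every sample of ``degraded``.

    Parents are looked up in ``parents`` via the pedigree; their phased
    haplotypes come from the library when present.  Set
    ``use_parents=False`` for population-only imputation.
    """
    out = degraded.calls.copy()
    rows = []
    for i, sid in enumerate(degraded.sample_ids):
        sire_id, dam_id = (UNKNOWN_PARENT, UNKNOWN_PARENT)
        sex = "U"
        if sid in pedigree:
            rec = pedigree.get(sid)
            sire_id, dam_id, sex = rec.sire_id, rec.dam_id, rec.sex

        def parent_calls(pid):
            if not use_parents or pid == UNKNOWN_PARENT or parents is None:
                return None
            if pid in parents.sample_ids:
                return parents.calls[parents.sample_index(pid)]
            return None

        sire_c = parent_calls(sire_id)
        dam_c = parent_calls(dam_id)
        sire_h = library.sample_haplotypes(sire_id) if (use_parents and sire_c is not None) else None
        dam_h = library.sample_haplotypes(dam_id) if (use_parents and dam_c is not None) else None
        res = impute_trio(degraded.calls[i], sire_c, dam_c, degraded.loci,
                          library, sex, sire_h, dam_h, params)
        out[i] = res.calls
        rows.append(
            {
                "sample_id": sid,
                "n_mendel_inconsistent": res.n_mendel_inconsistent,
                "n_haplotype_corrected": res.n_haplotype_corrected,
                "n_filled": res.n_filled,
            }
        )
    imputed = GenotypeMatrix(list(degraded.sample_ids), degraded.loci.copy(), out)
    return imputed, pd.DataFrame(rows)


@dataclass
class ImputationReport:
    """Cohort-level quality summary of a correction + imputation run."""

    n_mendel_inconsistent: int
    n_corrected: int
    final_missing_rate: float
    homozygosity_rate: float
    genomic_inbreeding: float
    pedigree_inbreeding: float
    per_sample: pd.DataFrame


def imputation_report(before: GenotypeMatrix, after: GenotypeMatrix,
                      pedigree: Pedigree, library: HaplotypeLibrary,
                      per_sample_counts: pd.DataFrame | None = None) -> ImputationReport:
    """Summarize an imputation run.

    Genomic inbreeding is the excess-homozygosity F = 1 - observed/expected
    heterozygosity, with the expectation taken from the library allele
    frequencies over autosomal loci; pedigree inbreeding is Wright's path
    coefficient, 0 for the non-inbred trio designs this package simulates.
    """
    auto = (after.loci["chromosome"] != X_CHROM).to_numpy()
    calls = after.calls[:, auto]
    called = calls != NO_CALL
    obs_het = float((calls == HET).sum() / max(called.sum(), 1))
    p = library.freqs[auto]
    exp_het = float((2 * p * (1 - p)).mean())
    genomic_f = 1.0 - obs_het / exp_het if exp_het > 0 else np.nan
    ped_f = float(np.mean([pedigree.inbreeding(s) for s in after.sample_ids
                           if s in pedigree])) if len(pedigree) else 0.0
    if per_sample_counts is None:
        per_sample_counts = pd.DataFrame({"sample_id": after.sample_ids})
    n_mendel = int(per_sample_counts.get("n_mendel_inconsistent", pd.Series(dtype=int)).sum())
    n_corr = int(per_sample_counts.get("n_haplotype_corrected", pd.Series(dtype=int)).sum())
    return ImputationReport(
        n_mendel_inconsistent=n_mendel,
        n_corrected=n_corr,
        final_missing_rate=float((after.calls == NO_CALL).mean()),
        homozygosity_rate=float(1.0 - obs_het),
        genomic_inbreeding=genomic_f,
        pedigree_inbreeding=ped_f,
        per_sample=per_sample_counts,
    )
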