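"""Synthetic cohort generation.

This module produces the statistical structure the downstream analysis
assumes: a ~50k-style biallelic SNP panel over 29 cattle autosomes plus X,
founder haplotypes with tunable short-range linkage disequilibrium,
sire-dam-embryo trios with recombination, simulated marker effects for
genomic values, and per-call quality scores.

LD model
--------
Haplotypes follow a first-order Markov "copying" chain along each
chromosome: a latent uniform variate is carried from one locus to the next
with probability ``ld_rho`` and redrawn otherwise, and the allele at locus l
is B iff the latent variate falls below that locus's allele-B frequency.
This preserves the per-locus frequencies exactly, yields positive allelic
association between nearby loci that decays geometrically with distance,
and reduces to linkage equilibrium at ``ld_rho = 0``.  It deliberately does
not model demography, recombination hot spots or long-range structure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import MarkerEffectSet
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
    PedigreeRecord,
    make_locus_table,
)

PG_PER_DIPLOID_CELL = 6.0  # genomic DNA content of one diploid mammalian cell


def biopsy_dna_yield_pg(n_cells: int = 15, pg_per_cell: float = PG_PER_DIPLOID_CELL) -> float:
    """Expected genomic DNA mass (pg) recoverable from an embryo biopsy."""
    return float(n_cells) * float(pg_per_cell)


@dataclass
class CohortConfig:
    """Parameters of a simulated genotyping cohort.

    Defaults give the desk-scale study design: 5,000 loci (~1/10 of a 50K
    panel) over 29 autosomes plus X, 200 founders, 50 trios, strong
    short-range LD (``ld_rho = 0.9``) and a 1 cM/Mb uniform genetic map with
    50 kb marker spacing.
    """

    n_loci: int = 5000
    n_autosomes: int = 29
    x_fraction: float = 0.03
    n_founders: int = 200
    n_trios: int = 50
    maf_low: float = 0.1
    maf_high: float = 0.5
    ld_rho: float = 0.9
    recomb_cM_per_Mb: float = 1.0
    spacing_bp: int = 50_000
    seed: int = 0

    def __post_init__(self):
        if self.n_loci <= 0 or self.n_autosomes <= 0 or self.n_autosomes > 29:
            raise ValueError("n_loci must be positive and n_autosomes in 1..29")
        if not (0 < self.x_fraction < 1):
            raise ValueError("x_fraction must lie in (0, 1)")
        if self.n_founders <= 0 or self.n_trios <= 0:
            raise ValueError("n_founders and n_trios must be positive")
        if not (0 < self.maf_low <= self.maf_high <= 0.5):
            raise ValueError("require 0 < maf_low <= maf_high <= 0.5")
        if not (0 <= self.ld_rho < 1):
            raise ValueError("ld_rho must lie in [0, 1)")
        if self.recomb_cM_per_Mb <= 0 or self.spacing_bp <= 0:
            raise ValueError("recomb_cM_per_Mb and spacing_bp must be positive")

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        known = {f for f in cls.__dataclass_fields__}
        bad = set(d) - known
        if bad:
            raise ValueError(f"unknown cohort config keys: {sorted(bad)}")
        return cls(**d)


def build_locus_map(config: CohortConfig) -> pd.DataFrame:
    """Lay loci out over the autosomes and X at uniform bp spacing."""
    n_x = max(1, round(config.x_fraction * config.n_loci))
    n_auto = config.n_loci - n_x
    per_chrom = [n_auto // config.n_autosomes] * config.n_autosomes
    for i in range(n_auto % config.n_autosomes):
        per_chrom[i] += 1
    chroms, positions = [], []
    for c in range(config.n_autosomes):
        chroms += [str(c + 1)] * per_chrom[c]
        positions += [(j + 1) * config.spacing_bp for j in range(per_chrom[c])]
    chroms += [X_CHROM] * n_x
    positions += [(j + 1) * config.spacing_bp for j in range(n_x)]
    ids = [f"SNP{i + 1:05d}" for i in range(config.n_loci)]
    cm = np.asarray(positions) / 1e6 * config.recomb_cM_per_Mb
    return make_locus_table(ids, chroms, positions, "A", "B", genetic_pos_cM=cm)


def _chromosome_slices(loci: pd.DataFrame) -> list[tuple[str, slice]]:
    out = []
    chroms = loci["chromosome"].to_numpy()
    start = 0
    for i in range(1, len(chroms) + 1):
        if i == len(chroms) or chroms[i] != chroms[start]:
            out.append((chroms[start], slice(start, i)))
            start = i
    return out


def _simulate_haplotypes(n_haps: int, freqs: np.ndarray, loci: pd.DataFrame,
                         ld_rho: float, rng: np.random.Generator) -> np.ndarray:
    """Draw haplotypes from the latent-uniform copying chain."""
    n_loci = len(freqs)
    haps = np.empty((n_haps, n_loci), dtype=np.int8)
    for _chrom, sl in _chromosome_slices(loci):
        idx = range(sl.start, sl.stop)
        u = rng.random(n_haps)
        for j in idx:
            if j != sl.start and ld_rho > 0:
                redraw = rng.random(n_haps) >= ld_rho
                u = np.where(redraw, rng.random(n_haps), u)
            else:
                u = rng.random(n_haps) if j != sl.start else u
            haps[:, j] = u < freqs[j]
    return haps


@dataclass
class FounderSet:
    """Phased founder haplotypes plus derived genotypes.

    ``haplotypes`` has shape (n_founders, 2, n_loci).  Male founders are
    hemizygous on X: both haplotype rows carry the single X allele, so the
    derived genotype is the homozygote of that allele.
    """

    sample_ids: list[str]
    loci: pd.DataFrame
    haplotypes: np.ndarray
    sexes: np.ndarray
    freqs: np.ndarray

    @property
    def n_founders(self) -> int:
        return len(self.sample_ids)

    def matrix(self) -> GenotypeMatrix:
        calls = self.haplotypes.sum(axis=1).astype(np.int8)
        return GenotypeMatrix(self.sample_ids, self.loci.copy(), calls)

    def pedigree(self) -> Pedigree:
        return Pedigree(
            [PedigreeRecord(s, UNKNOWN_PARENT, UNKNOWN_PARENT, x)
             for s, x in zip(self.sample_ids, self.sexes)]
        )


def simulate_founders(config: CohortConfig, rng: np.random.Generator | None = None) -> FounderSet:
    """Simulate phased founders under the copying-chain LD model."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    loci = build_locus_map(config)
    freqs = rng.uniform(config.maf_low, config.maf_high, size=config.n_loci)
    haps = _simulate_haplotypes(2 * config.n_founders, freqs, loci, config.ld_rho, rng)
    haps = haps.reshape(config.n_founders, 2, config.n_loci)
    # equal sex split so trio formation always has both sexes available
    sexes = np.array([MALE, FEMALE] * ((config.n_founders + 1) // 2))[: config.n_founders]
    x_mask = (loci["chromosome"] == X_CHROM).to_numpy()
    males = sexes == MALE
    # hemizygous X: second haplotype mirrors the first
    haps[np.ix_(males, [1], np.flatnonzero(x_mask))] = haps[
        np.ix_(males, [0], np.flatnonzero(x_mask))
    ]
    ids = [f"F{i + 1:04d}" for i in range(config.n_founders)]
    return FounderSet(ids, loci, haps, sexes, freqs)


def _make_gamete(parent_haps: np.ndarray, loci: pd.DataFrame,
                 rng: np.random.Generator) -> np.ndarray:
    """One recombinant gamete; crossovers per chromosome ~ Poisson(Morgans).

    Crossover interference is modelled crudely by discarding any crossover
    falling within a quarter of the chromosome's genetic length of the
    previous one — real meioses essentially never place two exchanges within
    a few hundred kb, and without this the simulator produces tiny
    double-crossover "islands" no genotype method could resolve.
    """
    n_loci = parent_haps.shape[1]
    gamete = np.empty(n_loci, dtype=np.int8)
    cm = loci["genetic_pos_cM"].to_numpy()
    for _chrom, sl in _chromosome_slices(loci):
        seg_cm = cm[sl]
        length_m = (seg_cm[-1] - seg_cm[0]) / 100.0
        n_co = rng.poisson(length_m)
        current = int(rng.integers(2))
        if n_co == 0:
            gamete[sl] = parent_haps[current, sl]
            continue
        co_pos = np.sort(rng.uniform(seg_cm[0], seg_cm[-1], size=n_co))
        if n_co > 1:  # interference: enforce separation between exchanges
            min_sep = 0.25 * (seg_cm[-1] - seg_cm[0])
            kept = [co_pos[0]]
            for p in co_pos[1:]:
                if p - kept[-1] >= min_sep:
                    kept.append(p)
            co_pos = np.asarray(kept)
        phase = (current + np.searchsorted(co_pos, seg_cm, side="right")) % 2
        idx = np.arange(sl.start, sl.stop)
        gamete[sl] = parent_haps[phase, idx]
    return gamete


@dataclass
class TrioCohort:
    """Simulated sire-dam-embryo trios with truth haplotypes retained."""

    founders: FounderSet
    embryos: GenotypeMatrix
    embryo_haplotypes: np.ndarray  # (n_trios, 2, n_loci); row 0 = sire-side
    embryo_sexes: np.ndarray
    pedigree: Pedigree
    sire_ids: list[str]
    dam_ids: list[str]

    @property
    def loci(self) -> pd.DataFrame:
        return self.founders.loci

    def parent_matrix(self) -> GenotypeMatrix:
        return self.founders.matrix().subset_samples(
            list(dict.fromkeys(self.sire_ids + self.dam_ids))
        )


def simulate_trios(founders: FounderSet, config: CohortConfig,
                   rng: np.random.Generator | None = None) -> TrioCohort:
    """Mate founders into trios and produce recombinant embryos.

    Each embryo receives one recombinant gamete from each parent; sex is
    Bernoulli(1/2); male embryos are hemizygous on X (dam gamete only,
    genotyped as the homozygote of the single allele).  By construction the
    trios contain zero Mendelian inconsistencies.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    males = [s for s, x in zip(founders.sample_ids, founders.sexes) if x == MALE]
    females = [s for s, x in zip(founders.sample_ids, founders.sexes) if x == FEMALE]
    if len(males) < config.n_trios or len(females) < config.n_trios:
        raise ValueError(
            f"need at least {config.n_trios} founders of each sex, have "
            f"{len(males)} males / {len(females)} females"
        )
    sires = males[: config.n_trios]
    dams = females[: config.n_trios]
    loci = founders.loci
    x_idx = np.flatnonzero((loci["chromosome"] == X_CHROM).to_numpy())
    idx_of = {s: i for i, s in enumerate(founders.sample_ids)}

    n = config.n_trios
    haps = np.empty((n, 2, config.n_loci), dtype=np.int8)
    sexes = np.where(rng.random(n) < 0.5, MALE, FEMALE)
    records = list(founders.pedigree())
    embryo_ids = []
    for t in range(n):
        sire_h = founders.haplotypes[idx_of[sires[t]]]
        dam_h = founders.haplotypes[idx_of[dams[t]]]
        paternal = _make_gamete(sire_h, loci, rng)
        maternal = _make_gamete(dam_h, loci, rng)
        if sexes[t] == FEMALE:
            # daughters inherit the sire's single X without recombination
            paternal[x_idx] = sire_h[0, x_idx]
        else:
            # sons: X comes from the dam only; code hemizygote as homozygote
            paternal[x_idx] = maternal[x_idx]
        haps[t, 0] = paternal
        haps[t, 1] = maternal
        eid = f"E{t + 1:04d}"
        embryo_ids.append(eid)
        records.append(PedigreeRecord(eid, sires[t], dams[t], sexes[t]))

    calls = haps.sum(axis=1).astype(np.int8)
    embryos = GenotypeMatrix(embryo_ids, loci.copy(), calls)
    return TrioCohort(founders, embryos, haps, sexes, Pedigree(records), sires, dams)


def assign_marker_effects(loci: pd.DataFrame, n_traits: int = 3,
                          effect_sd: float = 0.02,
                          weights: np.ndarray | None = None,
                          index_scale: float = 100.0,
                          index_offset: float = 0.0,
                          rng: np.random.Generator | int | None = None) -> MarkerEffectSet:
    """Draw per-locus additive effects Normal(0, effect_sd^2) per trait.

    The effects stand in for externally estimated marker solutions; X-linked
    loci are included with dosage as coded (males 0/2).
    """
    if n_traits < 1:
        raise ValueError("n_traits must be >= 1")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    traits = [f"trait{i + 1}" for i in range(n_traits)]
    eff = rng.normal(0.0, effect_sd, size=(len(loci), n_traits))
    df = pd.DataFrame(eff, index=pd.Index(loci["locus_id"], name="locus_id"), columns=traits)
    w = np.ones(n_traits) if weights is None else np.asarray(weights, dtype=float)
    return MarkerEffectSet(df, pd.Series(w, index=traits), index_scale, index_offset)


@dataclass(frozen=True)
class QualityModel:
    """Beta parameters of per-call quality scores for correct/erroneous calls.

    Defaults Beta(8, 2) for correct and Beta(3, 2) for erroneous calls give
    overlapping supports spanning (0, 1), so no score threshold cleanly
    separates errors from correct calls.
    """

    a_correct: float = 8.0
    b_correct: float = 2.0
    a_error: float = 3.0
    b_error: float = 2.0


def simulate_quality_scores(matrix: GenotypeMatrix, error_mask: np.ndarray,
                            model: QualityModel = QualityModel(),
                            rng: np.random.Generator | int | None = None) -> GenotypeMatrix:
    """Attach per-call quality scores drawn by error status.

    ``error_mask`` is boolean, aligned with ``matrix.calls``; True marks an
    erroneous call.  NO_CALL cells get NaN.  Returns a new matrix.
    """
    error_mask = np.asarray(error_mask, dtype=bool)
    if error_mask.shape != matrix.calls.shape:
        raise ValueError("error_mask shape does not match matrix")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    q = rng.beta(model.a_correct, model.b_correct, size=matrix.calls.shape)
    q_err = rng.beta(model.a_error, model.b_error, size=matrix.calls.shape)
    q[error_mask] = q_err[error_mask]
    q[matrix.calls == NO_CALL] = np.nan
    out = matrix.copy()
    out.quality = q
    return out
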