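# Methods

`embryoqc` is an in-silico replication framework for a question from
commercial cattle embryo genotyping: when an embryo biopsy (~15
trophoblast cells, ~90 pg of genomic DNA) must be whole-genome amplified
before SNP-array genotyping, how badly do amplification artifacts degrade
the genotypes, and can Mendelian correction plus genotype imputation
recover breeding-value estimates that match those from the animal's clean
post-natal DNA?  Because no real embryo/calf genotypes are available, the
package pairs every analysis with a synthetic-data generator that encodes
the study design explicitly, so each claim is tested against known truth.

## Synthetic cohort

**Panel.** `n_loci` biallelic SNPs (default 5,000, about a tenth of a 50K
bovine chip) laid out over 29 autosomes plus X at 50 kb spacing, with a
uniform genetic map of 1 cM/Mb.  The X fraction defaults to 3% of loci.
Allele-B frequencies are drawn once per locus from Uniform(`maf_low`,
`maf_high`) (default 0.1–0.5).

**Haplotypes and LD.** Haplotypes follow a first-order latent-uniform
copying chain: a uniform variate is carried to the next locus with
probability `ld_rho` (default 0.9) and redrawn otherwise; the allele is B
iff the variate falls below the locus frequency.  This preserves marginal
frequencies exactly, produces positive short-range allelic association
decaying geometrically with distance, and gives linkage equilibrium at
`ld_rho = 0`.  It deliberately does **not** model demography, haplotype
sharing between founders, recombination hotspots or long-range LD.  One
consequence, verified in the test suite: with unrelated founder
haplotypes, genotype-only statistical phasing is information-limited to
the double-heterozygote phase-concordance probability (~92% switch
accuracy at `ld_rho = 0.9`), which the package's LD-sign chain phaser
attains to within a point.

**Trios.** Founders (default 200, alternating sex) are mated into
`n_trios` sire–dam pairs (default 50), one embryo each.  Each gamete
receives Poisson(genetic length in Morgans) crossovers with positions
uniform on the genetic map, thinned so that two crossovers are never
closer than a quarter of the chromosome's genetic length — a crude stand-in
for crossover interference.  Without it the simulator occasionally
produced double-crossover "islands" of a few loci, artifacts real meioses
essentially never generate at sub-Mb scales and that no genotype-based
imputation could resolve.  Embryo sex is Bernoulli(1/2); male embryos are
hemizygous on X, and the array convention of reporting hemizygotes as
homozygotes is applied throughout.  Simulated trios contain zero Mendelian
inconsistencies by construction (asserted by the checker).

**Marker effects.** Per-locus additive effects are Normal(0,
`effect_sd`^2) per trait (default 3 traits, sd 0.02); they stand in for
externally estimated marker solutions, which the analysis treats as an
exogenous input.  X-linked effects are included with dosage as coded
(males 0/2) — the simplest consistent choice.  The selection index
combines cohort-standardized trait values with unit weights and maps them
to points via an affine scale (default 300 points per weighted SD around
an offset of 2000); the scale is arbitrary and affects neither
correlations nor rankings.

**Quality scores.** Correct calls draw Beta(8, 2), erroneous calls
Beta(3, 2).  The two supports overlap over all of (0, 1), reproducing the
qualitative finding that no quality threshold cleanly separates errors
from correct calls; the parameters are assumptions, chosen only to satisfy
that property.

## WGA degradation model

Each cell of a truth matrix is independently degraded: NO_CALL with
probability `miss_rate` (per-locus Beta-distributed when
`locus_dispersion > 0`, variance `m(1-m)·d`); otherwise, a heterozygote
suffers allele drop-out with probability `ado_rate` (lost allele chosen
uniformly), and a homozygote becomes heterozygous with `hetgain_rate` or
the opposite homozygote with `reversal_rate`.  Missingness and genotype
error are mutually exclusive per cell, matching the accounting convention
that error rates are relative to the calls a method provides.

`WgaErrorModel.calibrated` solves the per-class rates so that the
conditional error over calls equals a target composite (default 12.4%)
given the cohort's truth heterozygosity, apportioned by an ADO share
(default 85%) and a small homozygous-reversal share (1.5%).  The split
among categories is an assumption: the source measurements report the
composite rate and the qualitative ADO dominance of the MDA chemistry,
not the decomposition.  Stylized profiles for the other chemistries
(QPLS drop-in-dominated, high-error SPIA/LMA) couple higher missingness
with higher error, so the negative call-rate/error-rate correlation across
profiles is present by construction; the pipeline's correlation statistic
measures it, it does not discover an independent fact.

Method-of-moments estimation inverts the process exactly (counts over the
appropriate truth-conditional denominators); empty denominators yield NaN,
never 0.

## Consensus, QC statistics

The consensus reference takes the per-cell modal non-missing call across
replicates when the mode is unique with multiplicity >= `min_agree`
(default 2), else NO_CALL; `min_agree = 1` reproduces any-replicate
accounting.  Error taxonomy, call rate (over reference-called loci),
error rate (over provided calls) and correct-call proportion follow the
tally identities asserted at construction.  Replicate concordance counts
loci called (or erroneous) in all / at least 2 / any of k replicates and
is compared with the locus-homogeneous binomial expectation by a paired
t-test across methods on fractions of loci; the test's type-I error is
calibrated (3–7% at alpha 0.05 over 500 null simulations) and its power
against Beta-overdispersed missingness (dispersion 0.3) exceeds 80% in the
suite.  Games–Howell post-hoc comparisons use Welch SEs,
Welch–Satterthwaite df and the studentized-range distribution (SciPy's
implementation, accurate to well below 1e-4 in P); the compact-letter
display is insert-and-absorb over the significance graph with groups
processed by mean descending, so letterings are deterministic.

## Sexing

Sex is called from the ratio of X to autosomal heterozygosity: male if
`x_het < 0.2 · autosomal_het` with at least 50 called X loci, female if
the ratio criterion fails, undetermined otherwise.  The threshold is a
ratio rather than an absolute level so it is invariant to the panel's MAF
spectrum; 0.2 is a package default (no numeric cutoff exists in the
source) and is exposed in the configuration.  Allele drop-out erodes the
contrast, so female-to-male misclassification rises with the ADO rate —
the suite checks the direction, and the pipeline reports sexing accuracy
against truth.

## Mendelian correction and imputation

1. **Mendelian screen.** A lookup table flags embryo calls impossible
   given called parents (single-parent rule: opposite homozygotes); on X
   the rules are sex-aware (male heterozygous X impossible; the male X
   allele must be transmissible by the dam).  Flags are blanked.
2. **Family fills.** Deterministic fills (both parents homozygous) and
   half-resolved constraints (one side's allele pinned by a homozygous
   parent, complements at embryo heterozygotes) are recorded per parental
   side.
3. **Transmitted-haplotype HMM.** For each side the transmitted parental
   haplotype is a two-state hidden Markov chain over informative loci
   (parent heterozygous, side resolved): switch probability equals the
   genetic distance in Morgans, each resolved allele votes with error
   probability `evidence_error` (default 0.1), and the forward–backward
   posterior is interpolated to every locus (linear crossover location
   inside gaps, distance decay beyond the terminal evidence).  Missing
   calls are filled when the posterior reaches `fill_threshold` (0.8).
   Called genotypes are **overridden** — this catches the
   Mendelian-consistent majority of allele drop-out — only when the
   Bayesian odds favour the prediction:
   `eps · P(pred) > (1 − eps) · (1 − P(pred))`, where `P(pred)` is the
   leave-one-out posterior (a call cannot vouch for itself) and `eps` is
   the embryo's call error rate, estimated as twice its Mendelian-flag
   fraction (with both parents genotyped roughly half of the composite
   error is Mendelian-visible under these allele frequencies).  On clean
   data `eps = 0`, so the engine provably never touches a correct cohort.
4. **Population library.** Remaining unknowns are matched against a
   phased haplotype library by long-to-short overlapping windows
   (200/100/50/20/10/5/1 loci, 50% overlap): candidate haplotypes agree
   with the resolved alleles at >= `min_match` (0.97) and unknowns take the
   candidate majority, honouring pinned parental alleles; the length-1
   window falls back to the library allele frequency, guaranteeing a
   complete, Mendelian-consistent output (asserted).

The pipeline builds its library from the founders' phased haplotypes, as
reference populations are phased upstream in practice; `build_library`
also offers genotype-only statistical phasing (LD-sign chaining), whose
~92% switch-accuracy information limit under this LD model is discussed
above and does not bear on the trio results.

The imputation report gives the Mendelian and haplotype-correction
counts, the final missing rate (0 on success), the homozygosity rate,
genomic inbreeding as excess homozygosity F = 1 − observed/expected
heterozygosity over autosomes with expectations from library frequencies,
and Wright's pedigree inbreeding from path counting (0 for the non-inbred
simulated trios).

## Genomic values

DGV(sample, trait) = Σ effects · dosage over a fully imputed matrix; the
index is described above.  Embryo/calf concordance reports Pearson r with
P, mean absolute divergence in index points, Spearman rho and top-k
overlap.

## Problem sizes, determinism and what the tests do and do not show

The experiment runs at a desk scale of 50 trios × 5,000 loci (seconds on
one core); the full 226-embryo × 50K design is reachable through the
configuration.  At the desk scale with the ADO-dominant profile (12%
missingness, 12.4% conditional error) and both parents genotyped, the
engine restores 97.6–98.1% of injected errors across seeds and the
embryo/truth index correlation is 0.993–0.997.  All randomness fans out
from one seed via `numpy.random.SeedSequence.spawn` to per-stage
generators, so stages are reproducible in isolation and full runs are
byte-deterministic on one platform.

Passing these tests shows the algorithms behave correctly under the
generator's assumptions — independent per-cell errors, clean and complete
parental genotypes, a perfectly phased library, short-range Markov LD, no
genotype-intensity artifacts, no pedigree errors.  Real WGA data violate
several of these (correlated template loss along chromosomes,
cluster-file miscalling, occasional parentage errors), so the measured
correction rates are an upper bound on field performance, not a forecast.

## Known limitations

- No coalescent demography or founder haplotype sharing; population-only
  imputation is correspondingly weak (it falls back to frequency fills)
  and is exercised mainly as a lower bound against family imputation.
- The error-category split of the composite 12.4% rate is an assumption.
- Crossover interference is a hard minimum-distance rule, not a gamma
  model.
- The pseudo-autosomal region is not modelled; X enters the index with
  male dosage 0/2.
- The index scale is synthetic; only affine-invariant statistics
  (correlations, rankings) are comparable across settings.
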