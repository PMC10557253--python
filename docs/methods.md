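# Methods

This note documents the models, estimators, numerical choices and known
limitations of `lactotrail`. The package reconstructs, on synthetic data, the
population-genetic workflow used to study the arrival of dairy pastoralism on
the Tibetan Plateau: admixture between West-Eurasian (European-breed-like)
dogs and Tibetan dogs, introgression scans around the dog lactase gene, and
the genotype–phenotype picture of the candidate human lactase-persistence
(LP) allele −13838G>A.

## Haplotype representation and polarization

All stages operate on a phased binary haplotype matrix (two rows per diploid
individual, one column per biallelic SNP, 1-based physical coordinates as in
VCF). Derived-allele polarization uses either a per-site ancestral-allele
annotation (the VCF `AA` tag) or a named outgroup whose fixed allele defines
the ancestral state — the same logic as polarizing dog SNPs against the
Andean fox. Sites whose ancestral allele matches neither REF nor ALT, or
whose outgroup is polymorphic or missing, are removed and counted. Missing
alleles (`.`) are tolerated per haplotype and excluded from every frequency
denominator; sites with more than 20% missing haplotypes are dropped at read
time (the threshold is a free parameter; published call sets rarely document
this step). Window arithmetic everywhere uses half-open `[start, end)`
intervals on 1-based coordinates.

## Coalescent engine

`simulate.coalescent` is a discrete-event Hudson coalescent: independent,
non-recombining loci; infinite-sites mutations Poisson-placed on branches
with rate μ·L per generation. Demographies are population trees with
piecewise-constant diploid sizes, momi-style label merges for splits, and
instantaneous pulses applied backward in time as lineage reassignment
(destination → source with probability p), matching the pulse semantics of
SFS-based inference tools. All times are published in years BP and converted
to generations in exactly one function (`DemographicModel.to_generations`);
the dog defaults are μ = 4.5×10⁻⁹ per bp per generation and a 3-year
generation time.

The default three-population dog model encodes the study conditions: EUR and
Asian dogs split 2×10⁴ years BP (prior range 10⁴–3.3×10⁴), Tibetan dogs and
southern East Asian indigenous dogs (SEAID) split 4.5×10³ BP, pulses from
EUR into Tibetan dogs (3.6×10³ BP) and into SEAID (3.7×10³ BP) at proportion
0.3, and Ne = 2×10⁴ for every branch. The Ne value is not stated per branch
in the source material; 2×10⁴ is a typical village-dog effective size and
lies comfortably inside the fitting bounds [10³, 5×10⁵].

Validation: mean pairwise coalescence time 2N and total branch length
4N(1 + 1/2 + 1/3) within 1%; the neutral SFS passes a χ² test against the
1/i law at 10⁵ loci; a pulse with p = 1 is distributionally identical to a
split; and the joint SFS of the full two-pulse model agrees with msprime
(an independent implementation used only as a cross-check oracle) to total
variation distance < 0.01 at 10⁵ genealogies.

## Forward Wright–Fisher engine

The selection statistics need linked variation along a recombining
chromosome, which the per-locus coalescent cannot produce, so positive and
null cases come from a forward diploid Wright–Fisher simulation:
multiplicative fitness {1, 1+hs, 1+s} at a single focal site, uniform
recombination, infinite-sites mutation on a finite grid of candidate
positions (a grid site can be reused only after its derived allele is lost
again — a desk-scale approximation to infinite sites). Populations are small
(N = 250–500 diploids) with mutation and recombination rates rescaled upward
so that the population-scaled parameters are in a realistic range
(ρ/bp = 4Nr ≈ 10⁻³, θ/bp ≈ 2.5×10⁻⁴ in the calibration runs). The neutral
burn-in (default 4N generations, 2N–3N in the scaled experiments) is
computed once per seed and shared across conditioned retries, so rejection
conditions (segregating, frequency window) re-run only the selection phase.
Two-population mode copies the population at a stated generation and applies
selection in one daughter only, for ΔDAF contrasts. Fixation probability of
a neutral allele matches f₀, and heterozygosity decays at 1 − 1/(2N) per
generation within 5%.

## Joint SFS and demographic inference

The joint SFS tallies derived-copy configurations (i, j, k) over sites
polymorphic within the three populations; the all-ancestral and all-derived
cells are excluded, and per-site coordinates are retained for the block
bootstrap.

The likelihood is a multinomial composite likelihood conditional on
segregation: cell probabilities are expected branch lengths subtending each
configuration divided by total polymorphic branch length, estimated by Monte
Carlo over independent genealogies (the exact-expectation algorithm of
momi2 is deliberately out of scope; the MC estimator is validated by the
1/i law, the nesting identities and the msprime cross-check). Monte-Carlo
cells below 10⁻⁹ are floored to keep the log-likelihood finite.

Fitting uses bounded derivative-free optimization in a transformed unit
cube: log scale for sizes and the outer split time, the inner split
parameterized as a fraction of the outer one (ordering holds by
construction, clipped to its own prior range [2×10³, 1.5×10⁴] BP), pulse
times as fractions of the relevant split, proportions linear in (0.01,
0.99). Three numerical choices matter and were set after measuring
alternatives:

* **Powell, two stages.** Nelder–Mead stalled far from the optimum on the
  8–11-dimensional surface; Powell line search with a coarse stage (a
  quarter of the genealogy budget) warm-starting a full-precision refinement
  reaches within ~50–100 log units of the optimum in a few hundred
  evaluations (500-evaluation cap per run).
* **Common random numbers per run.** Each run holds one MC kernel seed
  across all of its evaluations, so the surface it searches is
  deterministic; different runs draw different surface realizations and are
  genuinely independent. (Sharing one seed across all runs makes every run
  of a model fail together on an unlucky realization — a failure mode
  observed and removed during development.)
* **High-precision re-evaluation.** The optimizer rides favorable MC
  fluctuations (~±60 log units at S ≈ 4×10⁴ sites and 4×10³ genealogies), so
  each run's final log-likelihood is recomputed once at 5×10⁴ genealogies
  with a seed shared across runs and models. This restores the nesting
  ordering ℓ(M2) ≥ ℓ(M1) ≥ ℓ(M0) and makes run distributions comparable for
  model selection. A warm-started run is never allowed to regress below its
  seed point in this metric.

Model selection follows the study protocol: many independent runs per model,
Welch's two-tailed t-test on the run log-likelihood vectors, the highest-mean
model selected unless a simpler (fewer-pulse) model is not significantly
worse (p > 0.05), in which case the simpler model wins. When nested models
are compared, one run of the richer model is warm-started from the nested
null's optimum (standard nested multi-start), which anchors the comparison
without biasing it — a richer model should never fit worse than its special
case. Confidence intervals
come from a contiguous-block bootstrap: sites in coordinate order are split
into K = 100 near-equal blocks (blocks partition *sites*, not base pairs —
the source protocol does not say which; sites were chosen so every block
carries equal information), K blocks are redrawn with replacement B times,
and each resample is refit (reduced starts, warm-started from the full-data
point estimate; the refit seed is a pure function of the resample so
duplicated data give zero-width intervals). The 2.5% and 97.5% percentiles
per parameter form the 95% CI.

Model templates default to constant size per population label plus separate
ancestral-branch sizes (N_ANC for the Asian ancestor, N_ROOT above the
Eurasian split). Per-terminal-branch size *changes* are expressible through
the size-epoch machinery but are not free parameters by default: at
desk-scale data sizes the MC composite likelihood cannot resolve six extra
parameters, and the recovery experiments target the admixture parameters.
For the same reason the scaled-down recovery experiment fixes N_ANC, N_ROOT
and the outer split at their generating values in *both* compared models;
with all sizes free, the no-gene-flow model absorbs most of the pulse signal
into ancestral-size changes and the comparison measures optimizer budget
rather than model evidence.

Scaled-down experiment sizes (the package's own choices, stated here so the
numbers in the test suite are interpretable): data = 3×10³ loci × 10 kb
(S ≈ 4×10⁴ sites) with 4 haplotypes per population; model selection 10
starts per model at 8×10³ genealogies; per-replicate point fits 6×10³
genealogies with a 300-evaluation cap; bootstrap B = 20, K = 100, single
warm-started refit per resample at 2.5×10³ genealogies; coverage assessed
over 20 data replicates.

## Introgression statistics

Frequency-based ABBA–BABA throughout: ABBA = (1−p₁)p₂p₃(1−p_O), BABA =
p₁(1−p₂)p₃(1−p_O), D = Σ(ABBA−BABA)/Σ(ABBA+BABA), for the ordered quartet
(P1 = SEAID, P2 = Tibetan dogs, P3 = European breeds, O = fox) so that
positive D means excess sharing between Tibetan dogs and European breeds. A
pattern-counting oracle (enumerating one-haplotype-per-population quartets)
is kept in the test suite. The genome-wide Z uses a weighted delete-one
block jackknife (5 Mb blocks by default — the source states Z but not the
procedure; weights are block informative-site counts, Busing's variance
formula). Sliding windows are coordinate-anchored (fixed 100 kb / 20 kb grid
from position 1); a window needs ≥ 100 usable SNPs (the published filter).
f_dM uses Malinsky's dynamic-donor denominator; a window whose denominator
is zero reports f_dM as missing, never 0. Outlier calling keeps windows at
or above the empirical (1−q) quantile, ties included.

## Selection statistics

EHH for a core allele is the probability that two random carriers are
identical over the interval from the core: Σ C(n_h,2)/C(n_c,2) over distinct
extended haplotypes. The curve is computed outward by successive group
refinement until EHH < 0.05 (the REHH default the study relied on is not
stated; 0.05 is fixed and documented here), and iHH is the trapezoidal
integral over physical distance including the first point below the cutoff.
Cores still above the cutoff at a chromosome end are flagged invalid rather
than silently truncated. The unstandardized score ln(iHH_A/iHH_D) is
z-normalized within derived-allele-frequency bins (50 bins, bins under 20
SNPs merged into their nearest neighbor; a global mode is available since
the source does not say whether its normalization was frequency-binned).
Sign convention per Voight: strongly negative = unusually long derived
haplotypes. ΔDAF is the plain per-site difference in derived allele
frequency, target minus reference, no smoothing.

Null calibration uses neutral forward-simulated chromosomes; after binned
standardization the |iHS| > 2 fraction matches the two-sided normal tail
(0.046) within ±0.01. The positive control conditions hard sweeps
(s = 0.4, f₀ = 1/2N) on reaching frequency ~0.7 — iHS is most powerful
mid-sweep — and checks that the focal standardized score is below −2 in the
majority of replicates; the ΔDAF control checks that the maximum lands
within 50 kb of the selected site in ≥ 90% of replicates.

## Local ancestry

A re-implementation in the spirit of PCAdmix, not a port: fixed 20-SNP
windows; per-window PCA of the pooled reference panels; per-panel Gaussian
class models with pooled covariance on the leading k = 4 score dimensions
(k = 4 measurably improved window accuracy, 0.95 vs 0.92, and genome-
fraction calibration over k = 2 in a pilot at panel Fst ≈ 0.2); a two-state
HMM along windows whose switch probability per boundary is
1 − exp(−g·r·gap) for an assumed admixture age g (default 100 generations,
no genetic map — constant r). Windows whose class means are separated by
less than 0.1 pooled SD *or* within the χ² sampling noise of the mean
difference are flagged low-information and contribute flat emissions, so
coordinates stay contiguous. Outputs are forward–backward posteriors and a
Viterbi path per target haplotype; the genome-wide donor fraction q̂ is the
posterior mean over windows, and the allele-conditioned donor fraction
(the "what fraction of LP-allele haplotypes are European" quantity) is
reported both as the Viterbi fraction at the SNP's window and as the mean
posterior there.

## Phenotype classification

LP iff the maximum rise of breath hydrogen over the fasting baseline across
the six post-dose readings (30-minute marks over 3 h) is *strictly* less
than 20 ppm — the boundary value 20 classifies as LNP. Allele frequencies
from genotype counts use (2·hom + het)/(2·genotyped); percentages round
half-up to one decimal to match the published renderings (7.3%, ~7.9%,
~3.2%). The carrier-by-phenotype table carries no association test: a
32-person cohort with 2 carriers cannot support one. Whether the published
"30-min intervals over a 3-h period" includes a t = 0 reading is ambiguous;
this package assumes a baseline plus six post-dose readings.

## What the synthetic data do and do not show

The generators reproduce the *structure* of the study data — three dog
populations plus an outgroup with the stated splits and pulses, a
low-frequency derived focal allele, phased haplotypes, a small breath-test
cohort — under idealized conditions: no genotyping or phasing error, no
missing data unless injected, uniform recombination, free recombination
between loci (coalescent) or a single chromosome (forward engine), and
rescaled population sizes in the forward runs. Passing tests therefore
demonstrate correctness of the estimators and calibration of the inference
machinery under the model's own assumptions; they do not demonstrate
robustness to reference bias, phasing switch errors, recombination-rate
variation, or ancient-DNA damage, none of which are modelled. The study's
real-data headline numbers (D = −0.023 with Z = −17.42, 30.96% mean European
ancestry, lct-window D = 0.483 / f_dM = 0.559, iHS = 1.70 for −13838G>A,
split 4523 BP with pulses 3595/3687 BP, 70.5% donor fraction) require the
accession datasets and are recorded as context only.

## Known limitations

* The coalescent engine supports ≤ 64 sampled haplotypes (leaf-set bitmask).
* No intra-locus recombination in the coalescent; loci are exchangeable
  draws, so LD-aware statistics must use the forward engine.
* The MC composite likelihood is consistent but noisy; fits inherit a
  ~50–100 log-unit optimizer shortfall at the default evaluation caps, which
  the bootstrap absorbs into (honestly wider) intervals.
* The forward engine's grid-site recycling slightly violates infinite sites
  at high mutation supply.
* Exactly two donor panels in the ancestry stage; no phasing-error model.
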