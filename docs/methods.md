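# Methods

This note records the models implemented in `palaeokit`, their
assumptions, the defaults and why, and what the synthetic-data generators
do and do not emulate.

## Collagen quality control

Collagen yield is `100 · collagen_mass / sampled_mass`, reported half-up
at one decimal. The atomic C/N ratio uses IUPAC atomic weights
(12.011, 14.007); the difference from 12/14 is below reporting precision
but the standard values are used throughout. Acceptance windows are the
conventional preservation criteria for collagen destined for dating:
yield ≥ 1%, C% in [30, 45], N% in [11, 16], atomic C/N in [2.9, 3.6].
A C/N of 3.5–3.6 passes with a *warning*, reflecting the interpretation
of the upper band as possible low-level carbon contamination rather than
outright failure. Published tables print %C and %N at one decimal while
their C/N column derives from unrounded measurements, so C/N recomputed
from printed values can differ by up to ~0.1 from the printed ratio;
`CollagenSample.cn_reported` lets QC use the lab's own ratio when
available, and validation treats the recomputed value as a ±0.1 property
rather than an equality. Two-point normalization maps measured δ values
of two certified standards onto their certified values by the unique
affine map, which exactly inverts any affine instrument drift.

## Radiocarbon

Conventional ages use the Libby mean life: `t = −8033 ln F14C`, with
`σ_t = 8033 σ_F / F`. Blank correction is the mass-balance inversion
`F_c = (F_m − F_b)/(1 − F_b)` with first-order error propagation, a 30%
relative error assigned to the blank, and an extra relative uncertainty
added in quadrature (0.16% for graphitized targets, 0.4% for gas-source
measurements — the user can override). A measurement more than 3σ below
the blank is flagged `below_background`.

Replicates from one extract are combined by inverse-variance weighting;
agreement is tested with `T = Σ (x_i − μ̂)² / σ_i²` against the upper-α
quantile of χ²(n−1). α defaults to 0.05, the conventional criterion for
this test; simulation shows the type-I error is calibrated (the
acceptance script measures it at n = 1,000 pairs).

Calibration evaluates `p(θ) ∝ exp(−(x − μ(θ))² / 2(σ² + σ_curve(θ)²))`
on a 1-calendar-year grid with linear interpolation of the curve mean and
error, then normalizes. The grid is finer than real curve spacing and
matches reporting precision. Highest-density ranges are built by adding
grid points in descending probability until the requested mass (default
95.4%) is reached, merging contiguous runs, and rounding endpoints
*outward* to 10 years — the convention behind published range tables.
Agreement with other calibration software is therefore expected only
within that rounding.

### One-phase outlier model

Dates belong to a single phase with unknown boundaries (start older than
end). Priors: boundaries flat with start > end; each date's calendar age
uniform in [end, start] (contributing the 1/span^n concentration that
makes the span identifiable); each date an outlier with its prior
probability (default 5%; a prior of 1 forces the date to be modelled as
an outlier). An active outlier displaces the measured age in ¹⁴C space by
`s = t · 10^u`, `t ~ Student-t(ν=5)`, `u ~ Uniform(0, 4)` years — the
heavy-tailed "t-type" shift.

Sampling is Metropolis-within-Gibbs. The boundaries have exact
inverse-CDF Gibbs updates (the conditional for start given the ages is a
Pareto-type density `(start − end)^−n`). Calendar ages use vectorized
random-walk Metropolis with a 10% mixture of large (20×) steps so a date
can jump between "inside the phase" and "outlier-displaced"
configurations. The outlier indicator and shift are never sampled:
the shifted-likelihood term `m(r) = ∫ N(r; s, v) p(s) ds` is precomputed
once per date on a residual grid (direct quadrature of the shift prior
against the Gaussian) and the per-date likelihood is the two-component
mixture. This marginalization removes the severe mode-switching problem
of indicator sampling — with an explicit indicator the chain absorbs a
displaced date by widening the phase and rarely recovers. Posterior
outlier probabilities are Rao-Blackwellized:
`O_i = E[ q·m / ((1−q)·N + q·m) ]` over the kept draws. One numerical
approximation: the outlier kernel uses each date's measurement variance
plus the *median* curve variance (the curve error varies slowly compared
to the kernel's scale); the Gaussian component keeps the exact
θ-dependent variance. Defaults are 50,000 iterations with 10,000
burn-in; the property tests and acceptance script use 3,000/800 at 6
dates per phase, where 95% boundary HPDs cover simulated truth in
95–98/100 replicates. Modeled spans from real multi-date phases depend
on boundary-prior details and interpolation, so cross-software span
values are treated as qualitative.

## Ancient-DNA reads

Filtering keeps reads with ≥ 35 aligned query bases and mapping quality
≥ 25. Duplicates share (reference, start, end, strand); the survivor is
the per-column majority base, ties broken by summed base quality, and the
duplication rate is n_in/n_out. Damage is counted in read orientation:
minus-strand reads are reverse-complemented together with their
reference window, so single-stranded-library deamination appears as C→T
at both ends. Positions are counted along the read; reference bases come
from the aligned pairs, insertions are skipped and soft-clipped bases are
excluded (they are not aligned; whether terminal-base rules should count
soft-clips is ambiguous in common usage — this choice is explicit and
flagged here). Base quality is not used in damage counting by default
(`min_baseq=0` exposed). The deaminated-only filter keeps reads with at
least one C→T mismatch within the first and/or last three aligned
positions; it is idempotent and strongly enriches endogenous molecules,
since an undamaged contaminant can only enter through a sequencing error
landing on a terminal reference-C.

## mtDNA consensus

Pileups count A/C/G/T and spanning deletions per site; insertions do not
correspond to a reference site and are ignored for site calls. A site is
called to its majority base iff coverage ≥ 5 and majority fraction ≥ 0.8
(both inclusive); exact ties and deletion majorities give N. "Support"
counts deletion-spanning reads in the denominator. The reference is
treated as linear; origin-spanning reads on the circular mtDNA are
rejected with an error (the synthetic generator never emits them).
Haplotype comparison counts differences only at sites called in both
genomes and separates shared from private variants; shared variants with
a negative control are surfaced as a laboratory-contamination warning
rather than an automatic failure, since some variants are common across
human populations.

## Sex typing

A target is "covered" if at least one retained fragment overlaps it —
per-target presence, not per-base depth, which is the robust choice at
very low coverage and reproduces published ratios from published counts.
Because capture panels have very different numbers of autosomal, X and Y
targets, raw hit fractions are adjusted by panel composition. Thresholds
apply to the Y-ratio only (< 0.05 female, > 0.2 male, strict
inequalities; boundary values are indeterminate); the X-ratio is
advisory. At moderate per-copy depth, simulation gives 100%
classification accuracy with zero mismapping noise; misclassification
enters only through the indeterminate zone as depth → 0.

## TMRCA for two mtDNA genomes

For k observed differences over L jointly compared bases, the
coalescence-time posterior is Gamma(shape k+1, rate 1+Θ) in coalescent
model units, Θ = 2NμL. Converting model units to years requires a
convention the density itself does not fix, and published year values are
not always explicit about it, so `time_scale` is mandatory with two
built-ins that are reparametrizations of the same posterior:
`per-generation-rate` (Θ′ = 2NμLg, unit N generations, years = t·N·g) and
`per-year-rate` (rates written per year; Gamma(k+1, 1/(Ng) + 2μL)
directly in years). With k = 0, μ = 2.67e−8 /bp/yr, g = 29 y, L = 15,569,
N = 1,000 both give a one-branch mean of ≈ 1,155 years. A frequently
quoted alternative, the pure mutation clock 1/(2μL), gives ≈ 1,203 years;
intermediate values reported elsewhere (e.g. ~1,206 y) are not
reproducible from these parameters under either standard convention, and
this package reproduces the density and parameters exactly rather than
matching any particular year figure. The total branch length is exactly
twice the one-branch mean. k should come from `compare_haplotypes` over
jointly called sites, with L defaulting to that site count (overridable;
note 15,569 vs the 16,569 bp mtDNA reference length — the choice is the
user's). The analytic mean matches trapezoid quadrature of the density to
≲1e−9 relative, and a Monte-Carlo oracle (exponential coalescence +
Poisson mutations, conditioned on k) reproduces the posterior mean.

## f-statistics

Pseudo-haploid calls sample one read base uniformly at a SNP after
discarding bases within 3 bp of either fragment end (deamination
avoidance). Outgroup-f3(X, Y; O) is the mean over usable SNPs of
(p_O − p_X)(p_O − p_Y); D(W, X; Y, Z) is the ratio of summed
(p_W − p_X)(p_Y − p_Z) to summed heterozygosity products. A SNP is usable
only if every involved population has ≥ 1 non-missing call. No
small-sample bias correction is applied to single-individual populations,
matching standard outgroup-f3 usage on pseudo-haploid data. Standard
errors use a weighted delete-one-block jackknife (Busing-type pseudovalue
variance) over physical 5 Mb blocks — the standard stand-in for ~0.05 M
genetic-map blocks when no map is given; zero-weight blocks are dropped.

## Synthetic data

All generators are pure functions of (parameters, seed) via
`numpy.random.default_rng`.

- **Reads**: fragment lengths log-normal (median 50 bp, log-sd 0.25 — a
  stand-in; real fragment-length laws vary by preservation), positions
  uniform, strands random. Deamination is geometric-inward C→T
  (rate 0.25/0.20 at the first 5′/3′ base, decay 0.6 per position),
  single-stranded-library style at both ends, with a `ds` switch for
  double-stranded chemistry (G→A at 3′). The default contaminant
  fraction is 0.55, the regime of heavily handled archaeological
  material; contaminants are undamaged but otherwise identical reads
  from the same reference — real contamination differs by haplotype,
  which this generator deliberately does not model, so consensus
  recovery results demonstrate damage-filter enrichment, not
  haplotype-aware deconvolution.
- **SNP coverage**: each target independently covered with probability
  1 − exp(−λ·copies/2); zero-copy chromosomes get an ε mismapping floor.
  Real capture data adds target-to-target efficiency variation that this
  Poisson-style model omits.
- **¹⁴C replicates**: the true F¹⁴C is blended with a laboratory blank by
  mass balance (exactly inverted by `blank_correct`) and replicates are
  drawn normally in F space with the quoted age errors converted
  consistently.
- **Calibration curve**: μ(θ) = θ + A·sin(2πθ/P) on a 1-yr grid with
  constant error — strictly monotone when 2πA/P < 1, so it exercises the
  calibration machinery without real-curve plateaus and reversals.
  Conclusions about multimodal calibrated densities on the real curve
  are not covered by these tests.
- **Genotypes**: ancestral frequencies Uniform(0.05, 0.95),
  Balding–Nichols Beta drift per branch (fixed alleles stay fixed),
  optional one-pulse admixture between leaves, Bernoulli pseudo-haploid
  calls, SNPs laid out in contiguous chunks across 22 chromosomes at
  100 kb spacing so physical block jackknifing is meaningful. No
  linkage, selection or mutation-rate heterogeneity.

Problem sizes in the test-suite and acceptance script (20,000 reads on a
2 kb reference, 5,000–20,000 SNPs, 100 phase replicates at 6 dates and
3,000 iterations) were chosen as the smallest sizes at which the
statistical tolerances (3σ binomial / Monte-Carlo bounds) are
informative.

## Known limitations

- BAM/CRAM, SAM header validation, and CIGAR ops N/H/P are unsupported;
  short ancient fragments do not need them.
- The phase model implements the t-type (¹⁴C-space) outlier variant
  only; calendar-space variants exist elsewhere and would slot into the
  same marginalized-kernel design.
- Contamination *estimation* (deamination-pattern mixture models) is out
  of scope; the package removes contamination by deamination filtering
  instead of quantifying it.
- Haplogroup nomenclature, tree building, and PCA projection are out of
  scope.
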