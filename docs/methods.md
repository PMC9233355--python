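# Methods

## The estimator

`poolrr` estimates genetic maps and windowed recombination rates (RR) from
the genome-wide allele frequencies of a single pooled sample of a
biparental segregating population. In such a population every polymorphic
locus starts at an expected allele frequency of 0.5; genetic drift (and any
inadvertent selection) displaces it, and the displacement decorrelates
between loci at a rate governed by the recombination fraction separating
them. The per-pair statistic

    K = |ΔAF| / log10(Δdist_bp)

scales the allele-frequency difference of physically adjacent loci by the
decadic log of their physical distance, crediting a given ΔAF with more
recombination when the loci are close. K is accumulated along each
chromosome into the raw pool genetic map (PGM). Division by log10 distance
is the estimator's definition, not a derived quantity; its absolute scale
is meaningless until calibrated.

### Calibration (PGM → nPGM)

The expected magnitude of |ΔAF| depends on the design: with n pooled
individuals the drift scale is ∝ 1/√(2n), and with S assayed markers the
per-interval recombination fraction shrinks as ∝ 1/S. The observed
correction for a sample is `adj_start = ML_ref / ML_PGM` (reference over
raw genome map length). Two regression models of adj_start on
(ΣSNPs, ΣGenotypes) are fitted across a simulation grid:

* linear, no intercept: `a·ΣSNPs + b·ΣGenotypes` (k = 3 for AIC);
* non-linear: `α·e^(β·log2 ΣSNPs)·e^(γ·log2 ΣGenotypes) + θ/√ΣSNPs`
  (k = 5), fitted by trust-region least squares from starts
  α = median(adj_start), β = −0.5, γ = 0.35, θ = 0, parameter/function
  tolerance 1e-10, at most 10,000 function evaluations. The surface can be
  multi-modal; the starts sit in the regime the model form was designed
  for. Fits that fail to converge, or predict a non-positive adjustment on
  their own grid, raise instead of returning silently.

Log-likelihoods are Gaussian with the MLE residual variance; the
non-linear model wins on AIC on every grid we have simulated. Its
prediction multiplies every K (K′ = K·adj_start), which rescales all map
positions linearly — windowed-RR correlations are therefore exactly
invariant to calibration, and only absolute lengths depend on it.

The shipped default model (α = 7958.92, β = −0.5401, γ = 0.3491,
θ = 691.0495) is valid for F2 SNP-array pools; it was fitted against a
barley consensus map and does not transfer across population types. RIL
samples are refused unless the user either supplies a RIL-calibrated model
or opts into a documented heuristic that scales the prediction by the
Haldane–Waddington two-fold map expansion of fully selfed lines.

### Windowed recombination rates

Each adjacent-marker interval contributes RR = Δmap(cM)/(Δbp/10⁶),
anchored at its physical midpoint (a left-marker anchor is available).
Windows of 50 MB slide by half a window by default, from position 0 of
each chromosome; a trailing partial window is kept and flagged; windows
with fewer than 2 contributing intervals report a missing value. The
window statistic is the median for individual-genotype (Haldane) maps and
the **mean** for pool maps: pool-map interval rates are zero-inflated —
an interval in which drift produced no allele-frequency change contributes
K = 0 — so in sparse-recombination regimes (2·n·r per interval < 1) the
within-window median collapses to zero while the mean remains proportional
to the underlying rate.

## Baseline: the two-point Haldane map (HGM)

From individually genotyped simulated populations, adjacent-interval
recombination fractions are estimated by maximum likelihood over the nine
two-locus F2 dosage classes with an EM algorithm (the double-heterozygote
class splits between the 0- and 2-recombinant phases in the E-step), with
a symmetric dosage-misclassification probability (default 1e-4) mixed into
the emissions. Estimates are clamped at r = 0.4999 to keep Haldane
distances `d = −50·ln(1−2r)` finite, and intervals with fewer than 10
jointly called individuals are chained as zero length with a warning. The
marker order is fixed by physical position; multipoint re-estimation of
order is deliberately out of scope. The EM estimator is verified in the
tests against an exhaustive likelihood grid search written independently.

## The simulators

### Meiosis and populations

Gametes follow a no-interference model: crossover counts per chromosome
are Poisson in the genetic length (Morgans) and crossover positions are
uniform on the cM scale, which reproduces Haldane's mapping function
exactly. `simulate_gamete` draws explicit crossover positions; the
population simulators use the equivalent interval representation (origin
switches between adjacent markers are independent Bernoullis with
probability (1−e^(−2d))/2), which is distributionally identical at the
marker loci and vectorizes across thousands of individuals. F2 individuals
are sums of two independent F1 gametes; RILs self repeatedly from the F1
(one selfing generation = F2), and "infinite" selfing runs 24 generations
(expected residual heterozygosity < 2⁻²³ per locus) before resolving any
remaining heterozygote by a fair coin per locus and individual. The
simulator never generates missing data; missingness handling is exercised
through fixtures.

One top-level seed drives everything; replicate streams derive
deterministically from (seed, replicate index), so a configuration is
reproducible bit for bit.

### Synthetic maps

`make_synthetic_map` places markers at equal physical spacing and supports
two Marey-map profiles. `uniform` has constant cM/bp. `barley_like`
emulates the pericentromeric recombination suppression of large cereal
genomes with a piecewise-uniform crossover density: the middle third of
each chromosome carries ~2% of the genetic length (weight 0.04 against 1.0
in the distal thirds). Real consensus maps concentrate their centiMorgans
in the distal thirds in just this way; the plateau structure also keeps
the active marker intervals in the drift regime the calibration model
represents well. Default validation genome: 3 chromosomes × 400 Mb ×
150 cM.

### Pooled sequencing

Sequencing a pool is modelled at read-count level: per-locus depth is
fixed or Poisson around a mean (default Poisson, 50), and the alt-read
count is Binomial(depth, AF·(1−e) + (1−AF)·e) with per-read allele error
e (default 0.001). Read simulation, alignment, and variant calling are
intentionally not modelled. Consequences, documented rather than asserted:
the large absolute overestimation of pool-seq RR reported for full
read-level pipelines does not arise here, and the correlation between
pool-seq and noiseless windowed RR at 10–100 reads is weak (the
allele-frequency noise, sd ≈ √(0.25/depth) ≥ 0.05, exceeds the true ΔAF
signal roughly ten-fold, and the |ΔAF| signal leak is quadratically
suppressed). The robust depth effect under this model is the monotone
decrease of the RMSE between pool-seq and noiseless windowed RR as depth
rises 10 → 50 → 100, which the tests assert alongside the (weak) ordering
of the correlations.

## Validation conditions and what they show

* **Allele-frequency drift law**: 200 loci spread over 10 chromosomes
  (so loci are nearly independent and the Monte-Carlo error of the grand
  mean is small) × 20 replicates; pooled |AF−0.5| moments match the
  Binomial(2n, ½) half-normal law at n = 50 and n = 10,000.
* **HGM unbiasedness**: 1,200 markers, n = 500, 10 replicates; mean
  per-marker estimated/true position ratio ≈ 0.98–1.00.
* **Calibration fixed point**: grid of 3 depths {500, 1500, 3000} × 3
  sizes {50, 200, 1000} × 5 replicates on a 6,000-marker barley-like map;
  the middle depth fraction (25%) mirrors the median depth fraction of the
  designs the estimator targets. After refitting, the mean per-marker
  nPGM/true ratio lands at ≈ 0.95–0.97. Two known mechanisms keep it
  slightly below 1: the model form cannot represent the
  population-size-independent drift regime (2·n·r < 1) that dominates
  high-depth/small-population cells, and in large-population cells |ΔAF|
  grows like √r, compressing the map shape relative to the truth even when
  lengths calibrate.
* **Windowed RR recovery**: 12,000 markers, n = 2,000; Pearson ≈ 0.99
  between nPGM and true 50 MB window tracks.

Problem sizes throughout are the package's own validation choices; the
simulators scale to larger designs unchanged. Passing these checks shows
the estimator's statistical machinery is correct under its own model
(complete biallelic data, no interference, no selection, known physical
positions). It does not certify performance on real pools, where marker
ascertainment, density–RR coupling, variant-calling artifacts and
segregation distortion enter.

## Known limitations

* ΔAF uses a single consistently polarized allele (simulation: parent-2;
  VCF: ALT). Folding to minor-allele frequency would corrupt ΔAF across
  the 0.5 boundary and is deliberately not offered.
* Minimum inter-marker distance defaults to 2 bp (a guard for the log10);
  a larger `--min-dist` (e.g. 10 kb) can stabilize dense sequencing data
  at the price of resolution.
* adj_start is one genome-wide scalar per sample, never per-chromosome.
* The GRE estimator is a sum-to-zero fixed-effects least-squares
  decomposition (RR_pop = μ + effect(p1) + effect(p2)), not a G-BLUP; its
  output says so.
* Crossover interference, sex-specific maps, selection during simulation,
  and read-level sequencing artifacts are out of scope.
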