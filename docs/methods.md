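# Methods

## Signal summaries

**mLRR-Y.** LRR is the log2-scaled normalized total intensity of a SNP
probe, a proxy for DNA copy number. Per sample we take the median LRR over
the male-specific region of chromosome Y (MSY, hg19
chrY:6,611,498–24,510,581; the wider analysis span between the
pseudoautosomal regions is chrY:2,694,521–59,034,049) and subtract the
trimmed mean of autosomal LRR. The subtraction is done in log2 space,
i.e. it normalizes the Y intensity by the sample's autosomal baseline and
cancels array-wide additive biases (mLRR-Y is invariant to adding a
constant to every probe's LRR; this is a tested property). The trim
(default 5% per tail, floor(n·trim) values dropped per tail after
sorting) protects the baseline from genuine copy-number-altered regions;
tumor mode raises it to 25%. The MSY summary is the median; a trimmed
mean over MSY is available as an option. mLRR-Y requires ≥ 10 MSY probes
with LRR (configurable) and is reported missing otherwise.

**B-deviation.** BAF is the normalized allelic intensity ratio, ~0.5 at a
heterozygous SNP. The X–Y homologous regions (PAR1, PAR2, XTR) are
disomic in males, so a Y loss present in a fraction *f* of cells shifts a
heterozygote's BAF from 1/2 to 1/(2−*f*) or its mirror — a deviation of
*b(f) = f/(2(2−f))* (for a gain, *f/(2(2+f))*). B-deviation is the
trimmed mean (5%) of |BAF − 0.5| over heterozygous probes there, and the
inverse map *f = 4b/(1+2b)* (loss; *4b/(1−2b)* gain, both clipped to
[0, 1]) estimates cellularity. BAF is read from the X side of the
homologous regions (plus "XY" pseudo-chromosome probes, matched by X
position): hemizygous Y probes carry no usable BAF. PAR1/PAR2 bounds are
the standard hg19 assembly definitions; the X-side XTR interval is
approximate and all regions can be overridden from a TSV.

Heterozygous probes are selected by the strict BAF window
0.2 < BAF < 0.8 by default (boundary values count as homozygous). That
window fails at cellularity above ~0.75, where the split bands themselves
leave it; when genotype calls are present in the input,
`summarize_sample` therefore selects heterozygotes by genotype (AB)
instead ("auto" mode), which stays informative across the whole
cellularity range. B-deviation requires ≥ 10 heterozygous probes.

## Quality control

Samples with highly variable autosomal LRR produce unreliable mLRR-Y.
Two rules, chosen per platform: a fixed bound sd(autosomal LRR) ≤ 0.28
(Illumina-style data; failure requires strict exceedance), and a
cohort-relative envelope sd ≤ mean + k·sd of the per-sample sds (default
k = 2; Affymetrix-style data). The relative rule's phrasing "within k
times the standard deviation" is ambiguous; it is implemented as the
one-sided mean + k·sd envelope (only high variability is pathological),
documented as this package's interpretation and configurable.

## Calling

Thresholds are median(mLRR-Y) ± 1.2·IQR(mLRR-Y) over the QC-passed
cohort, with quartiles by linear interpolation between order statistics
(the convention matters on small cohorts and is fixed and tested against
an explicit order-statistics oracle). LOY strictly below the lower bound,
GOY strictly above the upper; ties are conservatively normal. For a
normal distribution the one-sided mass beyond 1.2·IQR is
Φ(−1.2·1.349) ≈ 5.3%, the rule's false-discovery bound; lighter-tailed
cohorts give less. Cohorts need ≥ 10 finite mLRR-Y values; a zero IQR
warns and calls nothing.

B-deviation cross-checks calls (threshold 0.05, i.e. heterozygote bands
outside 0.45–0.55): a called sample with B-deviation below threshold is
flagged `lrr_only` (technical LRR shift), a normal sample above it
`bdev_only` (contamination signature). Flags never reclassify
automatically — visual inspection is the intended follow-up — but
`drop_lrr_only` (CLI `--drop-discordant`) optionally demotes unsupported
calls, which on simulated cohorts removes essentially all IQR-rule false
discoveries while keeping true events (see the README example).

Competing methods, for comparison studies: the **reflection method**
(`forsberg`) assumes the no-event distribution symmetric, reflects the
values at or above the median and calls LOY below the one-sided 99%
bound, by default center − z(0.995)·sd(reflected sample) (the 0.5th
percentile of the reflected sample is available as an option since the
original construction is not uniquely specified); it has no gain
category. The **quantitative** treatment uses mLRR-Y directly as a
covariate. The **cellularity proxy** maps mLRR-Y to
f = 1 − 2^((mLRR-Y + 0.45)/r) with a user-tunable response factor r
(default 1): array LRR is compressed relative to the ideal log2
copy-number response and the compression is platform-dependent, so no
fixed value is asserted.

## Synthetic data

`simulate_sample` draws per-probe signal: autosomal and PAR LRR
~ N(0, σ_auto), MSY LRR ~ N(−0.45 + Δ(f), σ_y) with the compressed-log
response Δ(f) = 0.45·log2(1 − f/2) for losses (mirrored for gains), so a
complete loss sits a further −0.45 below the one-copy level — matching
the empirical fact that one copy reads −0.45, not −1. Heterozygous PAR
probes (genotype AB, deterministic even split between bands) sit at
0.5 ± b(f) plus N(0, σ_baf) noise, clipped to [0, 1]; homozygous probes
at 0/1. Defaults σ_auto = 0.12, σ_y = 0.18, σ_baf = 0.03, 2000 autosomal
/ 120 MSY / 300 PAR probes, 50% heterozygous: these give cohort mLRR-Y
dispersion comparable to blood-derived array data, put the detection
floor near 5% cellularity, and pass the fixed QC rule; they are exposed
in `SignalModel`, chosen once and not per-analysis. With all noise at
zero the pipeline recovers mLRR-Y = −0.45 + Δ(f) and B-deviation = b(f)
exactly (tested), and at default noise the median cellularity recovery
error is within ±0.05 across f ∈ [0.1, 0.9]. Tests scale probe counts
down (600/80/200) for speed; statistics are probe-count-robust above the
minimum-probe floors.

What the simulator does *not* emulate: GC/wave LRR artifacts, batch
effects, genotype-calling errors, partial-Y events, chromosome-X
mosaicism, and platform-specific BAF compression near 0/1. Passing tests
therefore demonstrate correctness of the statistical machinery under the
stated signal model, not performance on any particular array product.

`simulate_mlrr_mixture` draws cohort mLRR-Y directly from a labelled
mixture (normal, LOY, GOY components) — the cheap surrogate used by the
power study, where per-probe detail is irrelevant. The no-event component
can be Gaussian or uniform ("platykurtic core"), the latter emulating
cohorts whose dispersion is lighter-tailed than Gaussian, as array
cohorts typically are.

## Association and power

Continuous outcomes use Gaussian GLM (OLS), binary outcomes binomial GLM
(logistic/IRLS), both with Wald two-sided p-values and optional covariate
adjustment; for a binary predictor the logistic estimate equals the 2×2
log odds ratio (tested to 1e-8). Separation is flagged, not silently
reported. α defaults to 0.05.

The power study repeats: draw a labelled mLRR-Y mixture, derive the
outcome from the *true* labels, re-call status with each method (IQR,
reflection, quantitative), test the called predictor, and record
rejections — isolating the power cost of calling misclassification.
Replicates are seeded by spawned child generators of one master seed, so
grids are reproducible and cells independent. Monte-Carlo standard error
√(p(1−p)/reps) is reported per cell. Under the null (zero effect) the
full chain's rejection rate is bounded by α within Monte-Carlo noise
(tested at 400 replicates).

The bundled ordering scenario (tests) uses a uniform no-event core
(half-width 0.08), a wide LOY component (mean −0.75, sd 0.18, reflecting
cellularity heterogeneity — the asymmetric heavy negative tail) and 1%
low-level GOY contamination at +0.10. Under these conditions the IQR rule
calls nearly perfectly, the reflection method misclassifies borderline
events, and the quantitative treatment is diluted by within-class
variance, yielding the power ordering IQR ≥ reflection ≥ quantitative.
The ordering is asserted with a 2·MC-se tolerance; it is a directional,
not a numeric, reproduction, because the mixture parameters of the
original cohort-calibrated simulations are not available.

Problem sizes used by the test and acceptance runs — 300–400 Monte-Carlo
replicates, cohorts of 200–1000, a 100,000-draw cohort for the
false-discovery tail — are the package's chosen desk-scale defaults;
all are arguments.

## Longitudinal follow-up

`summarize_longitudinal` counts blood-cellularity trajectories
(increased / decreased / unchanged between baseline and a follow-up
visit) and saliva detectability from a per-individual percentage table.
The packaged 18-man blood/saliva table (ND = not detectable, parsed as
missing) yields 16 increased, 2 decreased, 7 detectable in saliva;
percentages are reported against all 18 records.

## Known limitations

- Calling is cohort-level: a single sample cannot be called in isolation,
  and cohorts mixing platforms or tissues should be summarized and called
  separately.
- The mLRR-Y → cellularity proxy depends on an unknown platform response
  factor; B-deviation-based cellularity is preferred whenever PAR/XTR
  heterozygotes are available.
- B-deviation is undefined for samples with too few informative
  X–Y-homologous probes (sparse arrays), in which case calls carry
  `bdev_supported = unknown` and cannot be confirmed.
- The IQR rule's ~5% FDR bound is intrinsic on continuous unimodal
  cohorts; B-deviation confirmation, not the threshold, is the false-
  positive control.
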