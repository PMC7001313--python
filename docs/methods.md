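# Methods

## Mixture model and assumptions

Every case is modeled as a two-component mixture: one tumor clone at
fraction *p* (purity) and normal diploid cells. The clone's genotype at the
locus is an allelic configuration (*N* total copies, haplotype split
*a*:*b* with *a* ≥ *b*, all mutant copies on one haplotype). Assumptions
this encodes:

- **One clone.** No subclonal copy-number states; every tumor cell carries
  the same configuration. Mild intratumoral heterogeneity is absorbed into
  the segment means.
- **Single mutational event before the copy-number change.** The somatic
  mutation arose once on one haplotype, so every copy of that haplotype is
  mutant (*M* = *a* or *b*) — never a mixture within a haplotype.
- **Normal cells contribute two wild-type copies, one per haplotype.**
  This fixes both the VAF denominator and the SNP-BAF numerator.
- **Germline heterozygous SNPs on the locus segment share the
  configuration's haplotype copy numbers.** The SNPs used for BAF lie on
  the same segment as the mutation, so their major-haplotype frequency is
  (p·a + (1−p)) / (p·N + 2(1−p)).
- **The mutation is somatic.** Cases whose blood sample shows ~50% VAF
  (germline origin) should be excluded upstream.

All internal arithmetic is on the fraction scale; percentages appear only
at report boundaries, rounded half-up to one decimal (`to_percent`).

## Candidate enumeration and two-stage selection

Candidate total copy numbers from a segment mean *m*: the nearest integer
*i*, plus *i*+1 when *m* > 2 or *i*−1 when *m* < 2 (admixed diploid cells
bias the apparent copy number of an altered segment toward two); *m* = 2
exactly yields {2, 3}; exact halves round away from two; candidates below
one are dropped, and a mean far below one still proposes {1}.

For each candidate total, every split and phasing with at least one mutant
copy is enumerated (balanced splits keep one phasing — the two are
indistinguishable). Stage 1 shortlists the two *distinct* expected-BAF
values closest to the observed band; phasings of one split share a BAF
value, count once at this stage, and both advance to stage 2. Stage 2
selects the shortlisted configuration with the smallest |expected VAF −
observed VAF|. Ties at either stage break toward the smaller total copy
number, then the larger mutant copy number (parsimony first, deterministic
output). Distances are absolute differences; nothing in the data argued
for a likelihood-weighted alternative, and absolute distance is what the
published worked cases are consistent with.

Back-calculation inverts the VAF relation for the selected model. The
inverse is exact (the round trip holds to ~1e−12) but not always feasible:
when the observed VAF exceeds what the model can produce at purity 1 the
inversion is refused rather than clipped. If no shortlisted configuration
is feasible the selection raises; if only the selected one is infeasible
its back-calculated purity is reported absent. Validation compares the
back-calculated purity with the IHC tumor content at an absolute tolerance
of 0.05 — chosen to cover the counting error of IHC purity at typical
field sizes, and consistent with the largest discrepancy the published
cases show (0.039).

## ddPCR quantification

Droplets are gated by fixed amplitude thresholds (FAM 2400, HEX 1700;
strictly-greater comparison, droplets on a threshold are negative). The
VAF is the raw dot ratio FAM-only / (FAM-only + HEX-only); double-positive
droplets contain both templates and are excluded. An occupancy-corrected
estimator (−ln of the per-channel negative fraction) is provided but off
by default — the raw ratio is the published estimator. The raw ratio
carries a small occupancy-dependent bias (about ±0.01 at 0.25 templates
per droplet) that matters only where the purity inverse is steep (see
Limitations). Dilution-series linearity is ordinary least squares of
measured on expected VAF.

## WGS signals

**Copy number.** Per-bin copy number is depth divided by the genome-wide
mean (autosomes only), times two. Zero-depth bins are kept and flagged. No
GC or mappability correction is applied — the generator does not simulate
those biases, and real data should be pre-corrected upstream if needed.

**Segmentation.** Recursive binary splitting on the two-sample pooled
t-statistic; a split is accepted when its permutation p-value is below
alpha. Defaults: alpha 0.01, minimum segment 3 bins, 1000 permutations
(with early stopping once significance is no longer reachable). These
defaults are configurable; segment boundaries need only qualitative
accuracy because the model consumes the locus segment's mean, which is
robust to ±1-bin boundary error.

**BAF track.** SNPs with population allele frequency strictly above 0.05
are binned into 10-kb regions; per-region medians of the mismatch ratio
alt/(ref+alt) are smoothed by a centered 3-region moving average
(truncated at track ends) and mirrored about 0.5 into upper/lower bands —
the displayed track. Because each SNP's ratio reflects an arbitrary phase,
regions that mix phases pull the unfolded medians toward 0.5; at realistic
heterozygous-SNP densities (several SNPs per region) this collapses the
mirrored band almost entirely. The track therefore also carries a `band`
column: the same median/moving-average chain applied to per-SNP ratios
folded about 0.5 — a phase-free estimator of the major-haplotype
frequency. Folding introduces a noise floor for balanced regions
(E|r − 0.5| ≈ 0.06 at ~33× SNP depth, so a balanced region reads ~0.55,
not 0.50); this overshoot is small against the ≥0.1 BAF separation of
competing configurations at moderate purity, and the VAF stage arbitrates
the rest.

**Locus observation.** The segment covering the locus supplies the mean
copy number; the band level is the 0.9 quantile of `band` over the
segment, not the median — an imbalance confined to part of a long
copy-neutral segment (copy-neutral LOH produces no depth step for the
segmenter to cut at) would otherwise be averaged away by the balanced
remainder.

**Variant filter.** Adoption requires variant reads strictly above 10 and
VAF at least 0.05; synonymous/"unknown" effects, variants at ≥1%
population frequency in any annotation column, and dbSNP members are then
excluded. Missing annotation values count as zero.

## IHC quantities

Count fractions (tumor content = K27M⁺/DAPI⁺, Ki-67 index =
Ki-67⁺/K27M⁺, H3K27me3 fraction = H3K27me3⁺/H4⁺) are computed per field
and averaged across the four fields; the relative K27M intensity
(per-tumor-cell K27M/H4 ratio) uses the median within and across fields,
matching how the per-case intensity is tabulated. Both aggregations are
configurable. Inputs are per-cell scalars; image processing is upstream.

## Cohort statistics

Cases split at VAF > 50% (strict). Markers are compared by the two-sided
Wilcoxon rank-sum test (exact null distribution for small untied samples,
via `scipy.stats.mannwhitneyu`); survival by Kaplan–Meier curves and the
standard 1-df chi-square log-rank test (via `lifelines`, which matches
R `survival::survdiff` statistics to 9 decimals on shared data). The
WGS-confirmed MASI flag is carried as metadata; group membership for
comparisons uses the VAF rule, matching the published 4-vs-11 split.

## Synthetic data

The generator emulates the statistical structure of every input at the
study's scale:

| quantity | model | default |
|---|---|---|
| binned depth | gamma-Poisson around genome-mean × mixed CN / 2 | 33× coverage, dispersion 0.1 |
| het SNP counts | binomial at the mixed major-haplotype frequency, random phase per SNP | ~1 SNP / 1.5 kb, pop AF U(0.05, 0.5) |
| droplets | Poisson template loading per channel | 20,000 droplets, 0.25 templates/droplet |
| IHC fields | binomial counts at purity and marker levels | 4 fields × 1000 cells |
| intensities | log-normal per-cell ratios | σ = 0.15 |
| survival | exponential, group hazard ratio | median 18 months, HR 3.5, censoring at 60 months |

Each genome is one 50-Mb chromosome in 10-kb bins with a single 10-Mb
altered segment containing the locus (test grids use a 20-Mb genome with
500 segmentation permutations to keep runs desk-scale). Identical truth
records (including the seed) reproduce byte-identical bundles.

Deliberately **not** emulated: GC/mappability coverage waves, FFPE
artifacts, sequencing error, droplet rain, multi-segment genomes,
subclonality. Passing recovery tests therefore demonstrate the inference
logic under the model's own noise assumptions, not robustness to every
real-data artifact.

## Known limitations

- **Purity back-calculation is ill-conditioned for minor-phase
  configurations.** The inverse amplifies VAF error by |dp/dv| =
  2/(1 − 2v)² for a single mutant copy among several wild-type copies —
  up to ~8 near v ≈ 0.24. There the raw dot-ratio's occupancy bias
  (~0.01) alone exceeds a 0.05 purity tolerance, and even a bias-free
  estimator would need VAF precision beyond what one 10⁴-droplet well
  provides. Configuration *selection* is much less affected (the VAF
  distances between candidate models are large compared to this error);
  the published case types — majority-phase, moderate copy number — sit in
  the well-conditioned regime.
- **High-purity model ambiguity.** At purity ≳0.95 the expected VAF and
  BAF of *N* and *N*+1 full-LOH models differ by less than typical
  measurement error; selections between them approach coin flips. This is
  an identifiability limit of the observables, not of the search.
- **Log-rank small-sample behavior.** The chi-square log-rank is mildly
  anti-conservative at tiny unbalanced designs (null rejection ~0.07 at
  n = 4 vs 11, confirmed against R `survival::survdiff`); p-values near
  0.05 from cohorts this small deserve caution.
- **Folded-band noise floor.** Balanced segments read ~0.55 rather than
  0.50 (see above); band estimates below ~0.57 should not be
  over-interpreted as imbalance.
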