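# Methods

This note documents the models behind each `svscape` component, the
parameters that matter, the design choices made where the method left
room, what the synthetic cohort does and does not emulate, and the known
limitations. Nothing here states an empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## Data model and conventions

All internal coordinates are 1-based; BEDPE and BED inputs (0-based,
half-open) are converted on read. An SV record is a pair of breakends
with strands; the strand pair encodes join orientation — (+,−)
deletion-type, (−,+) TD-type, (+,+) head-to-head inverted, (−,−)
tail-to-tail inverted. When a record's declared type and its strands
disagree, strands win for join-orientation statistics and the declared
type wins for type counting; this keeps orientation-based tests
(chromothripsis joins, fold-back candidacy) independent of caller label
conventions. Unknown type labels map to `OTHER` with a warning, never an
error, so third-party tables parse.

Somatic SNVs pass a read-support filter before any analysis: tumor
alt reads ≥ 4 with tumor coverage ≥ 14, normal alt reads ≤ 2 with normal
coverage ≥ 10 (all boundaries inclusive).

Junction microhomology is the longest sequence identity between the two
junction flanks, computed in both directions from the junction on the
derivative strand and reported as the maximum; homology-vs-insertion
ambiguity is resolved homology-first. A property test checks the
implementation against an independently written character-by-character
oracle on random junctions of every orientation.

## TDP scoring and subgrouping

`Exp_i = TD · L_i / Σ L_i` uses total chromosome length from the supplied
genome model, optionally restricted to a callable footprint; the method
description never fixes this convention, so it is exposed through the
genome model rather than hidden. The score is invariant to chromosome
order and to the genome model's length unit.

Subgrouping fits a Gaussian mixture to log10 TD spans (EM, 10 restarts,
BIC-selected component count up to 3, ties toward fewer components;
`reg_covar` 1e-4). Peaks are component means whose mixture density
reaches ≥ 25% of the maximum peak density. Samples with fewer than 20
TDs are never subgrouped. One deliberate choice: when several peaks fall
in the *same* group range (an EM over-split of one mode), the sample is
classified by the set of ranges hit — all peaks in 1.64–51 kb is group 1,
not "other" — because the over-split carries no evidence of a second
biological mode.

A subtlety worth recording: "adding a TD to the most under-represented
chromosome never decreases the score" is not exactly true at the
boundary. A perfectly proportional catalog (score 0) moves slightly
negative after any addition because the expectations are non-integer. The
provable statement, which the property test asserts, is that the score
never decreases when the target chromosome remains under-represented by
at least one count after the addition, and in general never drops by more
than `2/(TD+1)`.

Breakpoint-region enrichment (e.g. gene bodies vs intergenic) is an exact
binomial test of the in-region breakend count against the region
footprint fraction, conditioning on the total breakend count; the odds
ratio is reported against footprint odds.

## Hotspot detection

The PCF is solved exactly: dynamic programming over cut positions
minimizes `Σ_segments SSE + γ·(#segments)` subject to a minimum segment
length, so results are deterministic and order-invariant. A brute-force
enumeration over all segmentations serves as the oracle in tests for
n ≤ 30. Defaults γ = 25, kmin = 10 on log10 inter-breakpoint distances;
both are exposed. These defaults are validated by a null-calibration
property — uniform breakpoints yield hotspot calls in < 5% of seeds —
rather than by matching any published hotspot count: matching published
loci would require the original cohort and reference genome, which is out
of scope.

Candidate segments become hotspots when physical breakpoint density
(breakpoints per Mb of the segment's [first, last] positions) exceeds
2× the whole-genome background for that category and ≥ 6 distinct
samples contribute; adjacent qualifying segments closer than 1 kb merge.
Both breakends of a record contribute to the breakpoint list, but a
sample counts once per hotspot.

## Fold-back inversions and BFB

Candidates are inversion-orientation intra-chromosomal records without a
reciprocal cluster. The copy-number step is a Welch comparison of
per-window log2R in 100-kb flanks on either side of the junction (window
size exposed); p-values are BH-adjusted across all candidates in the
cohort and a call requires q < 0.001 plus breakend separation < 30 kb.
A BFB locus additionally requires an integer-CN ≥ 5 segment within 1 Mb
and telomeric loss: ≥ 90% (length-weighted) of the segments from the
fold-back to the chromosome end on the distal side — rightward for
head-to-head folds, leftward for tail-to-tail — strictly below
round(sample ploidy). Missing integer CN falls back to log2R thresholds
and is logged.

## Chromothripsis

The spacing test is a goodness-of-fit of adjacent breakpoint spacings to
the exponential distribution with the empirical mean. Because the mean is
estimated from the same data, a plain one-sample test would be
miscalibrated; the null distribution of the KS statistic is therefore
obtained by parametric bootstrap (500 resamples). Two further choices:

* The two arm-boundary gaps are included as spacings when the test is run
  on an arm. Under a homogeneous Poisson null they are themselves
  exponential (memorylessness), so the null is unchanged, and they make
  clustering detectable even when every breakpoint on the arm belongs to
  one cluster — otherwise a pure cluster looks internally exponential.
* The bootstrap p is `#{boot ≥ obs}/B` rather than `(#+1)/(B+1)`, so a
  maximally clustered arm reaches p = 0 and survives BH adjustment across
  arms; under the null the p-value is uniform on a (B+1)-point grid, a
  ~1/B distortion the calibration test bounds.

The join test compares the four orientation counts with
Multinomial(n, ¼,¼,¼,¼): chi-square for n ≥ 40, exact enumeration below.
It is evaluated on the records of the *refined rearranged region*, not
the whole arm: the randomness-of-joins prediction applies to the
shattered region itself, and arm-level counts would be contaminated by
the genome-wide deletion-heavy background. The region is refined by
taking the minimum-mean PCF segment (γ = 10) of the arm's log10
inter-breakpoint distances and trimming to the shortest window holding
80% of its breakpoints.

A call requires, per arm: BH-adjusted spacing q ≤ 0.05 across the
sample's tested arms, join p > 0.05, more than 10 region rearrangements,
and region copy number oscillating between 2–3 integer states covering
≥ 90% of the region (states counted as the minimum number needed to
reach 90% length coverage, so a flat diploid arm — one state — fails).
Arms without usable copy number are reported as undetermined. The
original procedure ended in manual curation; this chain is fully
algorithmic, and planted hotspot or BFB arms can genuinely satisfy the
statistical screen (clustered breakpoints, mixed joins, 2–3 CN states) —
the measured per-arm false-positive rate on simulation bounds that
leakage.

## Kataegis

Candidate clusters are maximal runs of ≥ 6 consecutive SNVs with
inter-mutation distance ≤ 1 kb; kept when the nearest SV breakend is
≤ 10 kb away and the cluster's C>T + C>G fraction exceeds the sample's
genome-wide fraction (one-sided binomial, α = 0.05). The same-parental-
chromosome criterion requires phasing that the inputs do not carry; the
generator emits a phase truth field (all planted showers single-parental)
but the detector applies the criterion only when such truth is provided,
and it is disabled otherwise.

## Hypermutation

The classifier follows the printed distance formulas, with two
conventions fixed here: `d_c` is the median over all pairwise distances
(the formula as printed duplicates `d_j`; "the center of all tumors"
fixes the intent), and `d_j` is the median distance to the *other*
tumors, while `ρ_j` keeps the printed sum including `i = j`. "Low
density" and "long distance" have no printed thresholds; the defaults are
cohort quantiles (ρ in the bottom 10%, d in the top 10%), both exposed.
Quantile thresholds admit at most ~10% of a cohort by construction, so
the rule is an outlier detector: it is accurate when hypermutated tumors
are a minority class well separated in rate space, and degrades when they
approach or exceed the quantile mass — visible in the unit test where a
single extreme outlier is flagged along with a few cluster-edge samples.
Labels are invariant to sample order and to affine rescaling applied
equally to both axes.

## Spectra, NMF and region comparison

Spectra use the canonical 96-channel pyrimidine-reference order;
purine-reference records are reverse-complemented. Signature extraction
is multi-restart (30) multiplicative-update NMF with the KL objective —
the standard likelihood for count spectra — on counts offset by 1e-9 to
keep the updates defined on empty channels. Rank selection walks the
candidate range and accepts a larger rank whenever its best-restart
reconstruction error improves on the best accepted rank by ≥ 5% *and*
its components are stable across restarts (cosine silhouette ≥ 0.8);
an unstable intermediate rank does not block a stable larger one.
Extracted signatures are L1-normalized with exposures rescaled, named by
cosine match (threshold 0.8) against a bundled reference table of
*synthetic* profiles built from the published channel structure of
well-known processes (CpG-deamination aging, APOBEC TpC, a T>G-heavy
"17*-like", a flat C>A "18*-like", a flat T>C), else labelled novel.

Exposures are refit per sample and per region class (coding/noncoding
sub-spectra) by nonnegative least squares against the fixed genome-wide
signature set; refitting, rather than joint per-region extraction, keeps
the signature identities fixed across regions. Per-signature rates are
exposure per Mb of region footprint; the cohort contrast is a two-sided
paired t-test on per-sample coding vs noncoding rates. "Presence" of a
signature in a sample uses a strict > 25% contribution threshold (the
method text says "more than 25%"; a caption variant says "≥" — the strict
reading is implemented and the boundary case is excluded by it).
Feature–exposure association tests a binary feature per sample with a
Welch t-test on proportions and a Fisher exact test on the presence
dichotomy, BH-adjusted across features, skipping features mutated in
≤ 4% of samples.

## The synthetic cohort: study conditions

The generator's defaults are the study conditions, chosen once:

* Genome: 4 chromosomes of 8/7/5/4 Mb (24 Mb), i.i.d. uniform bases,
  centromeres at midpoints; coding regions are 120 evenly spaced 12.5-kb
  blocks (1.5 Mb, ~6%). This scale keeps the full pipeline within a few
  minutes on one CPU; the methods are length-normalized throughout, so
  the scale enters only through density contrasts (see limitations).
* Per-sample SV counts log-uniform in 19–696 (the observed cohort range);
  TDP samples draw from 200–696 so that the ≥ 50 TD criterion is
  reachable at realistic proportions. SV-type mixture follows the
  published cohort percentages (36% DEL, 27% TD, 16% ITX, 12% INV, 5%
  complex deletion, 4% fold-back, 0.4% insertion), with non-TDP samples
  down-weighted and TDP samples up-weighted in TDs (35%, matching the
  reported TDP mean of 42% with range 20–74%).
* TD spans are log-normal mixtures — only the modal positions (~11 kb,
  ~231 kb) are reported, so component SDs default to 0.25 log10 units —
  background samples trimodal with a minor >1 Mb mode; TDP groups 1, 2
  and mix draw their own mixtures. TDs are placed length-proportionally
  for every sample: genome-wide dispersion is the TDP hallmark, and
  TDP-ness is encoded in count, proportion and span modes.
* TDP prevalence 24/168 with subgroup proportions 2:16:6 (groups 1, 2,
  mix); hypermutated fraction 0.08 at 60 mutations/Mb vs 8/Mb regular
  (log10 SD 0.1) — a minority outlier class, consistent with the
  density-outlier definition of hypermutation the classifier implements;
  three hotspot loci (short-TD, modest-TD, deletion; hit probability 0.5,
  2–4 extra events per hit with breakend 1 inside the locus);
  chromothripsis in 20% of samples (40 rearrangements in a 0.3-Mb region,
  states 2/3 — sized so the local density contrast over the scaled-down
  background stays ≥ 10×, in keeping with the defining one-off-catastrophe
  density of the phenomenon); BFB in 24% (fold-back at 5-kb separation,
  CN-8 amplicon, telomeric CN 1); kataegis in 30% (2 foci per sample,
  8–15 C>T/C>G mutations at exponential mean-300-bp spacing, started
  within 2 kb of a breakpoint).
* Three generating mutational processes (CpG-focused C>T "aging-like",
  flat C>A, flat T>C) with Dirichlet per-sample exposures (concentration
  6 — strong inter-sample heterogeneity, as in real cohorts where
  per-sample contributions span 0 to >50%; without that heterogeneity the
  spectrum matrix is near rank-1 and no method could separate the
  processes). The C>A process has a structural zero in coding regions —
  the noncoding-exclusive signature the region comparison must find.
  SNV placement is rejection-free sampling from precomputed
  trinucleotide-context position pools, so spectra are exactly
  recoverable by the spectrum builder. Copy number is emitted as 10-kb
  windows with Gaussian log2R noise (SD 0.08) plus exact integer CN,
  emulating window-based depth segmentation.

Everything is deterministic under the config seed (byte-identical FASTA,
catalogs and truth), and every planted feature is reachable from the
emitted catalogs (property-tested).

What the generator does **not** emulate: mappability and coverage
variation, germline contamination, caller-specific breakend uncertainty,
replication-timing and chromatin covariates of mutation density,
subclonality, purity/ploidy estimation error, and the two-orders-of-
magnitude larger human genome. Passing label-recovery tests therefore
demonstrates that the detectors implement their definitions correctly
and are well calibrated under their own nulls — not that they would
achieve the same operating characteristics on real tumor genomes.

## Validation problem sizes

The validation suite uses: 500 random PCF fixtures of up to 30 values
against exhaustive search; 1000 random catalogs for the TDP formula
oracle and uniform-placement null; 2000 replicates per null calibration
(spacing test with 500-resample bootstraps at 50 spacings; join test at
n = 200, where the chi-square branch is well calibrated); and the default
50-sample cohort for label recovery. On the fixed default cohort the
planted kataegis showers draw unbounded exponential gaps, so a minority
straddle the 1-kb detection threshold and split into sub-threshold runs —
this bounds attainable recovery near 0.9 under these conditions and is a
property of the planting, not the detector.

## Known limitations

* Chromothripsis region refinement is density-based; at low contrast
  between cluster and background (SV-dense genomes on small scales) the
  region boundary is fuzzy and join/CN statistics can be contaminated.
* The hypermutation rule's quantile thresholds tie to cohort composition;
  cohorts whose hypermutated fraction exceeds the quantile mass will be
  under-called by construction.
* The NMF rank rule (5% error improvement, 0.8 stability) can accept a
  genuine extra process present in the data (e.g. the kataegis APOBEC
  component) beyond the configured background processes; recovery is
  scored against the planted processes, not the selected rank.
* Exposure refitting assumes the genome-wide signature set spans the
  region sub-spectra; a region-exclusive process not captured genome-wide
  would bias its own refit downward.
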