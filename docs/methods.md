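# Methods

## Assay model

Each methylation chip carries two channels of the same DNA sample: one half
digested with a methylation-sensitive endonuclease (Cy3, "treated"), the
other untouched (Cy5, "untreated"). A probe covering an unmethylated site is
cut, its treated-channel signal drops, and the per-probe statistic

    M = log2(untreated) − log2(treated),
    A = (log2(untreated) + log2(treated)) / 2

is positive in expectation; a methylated (protected) probe and a control spot
have E[M] = 0. All inference happens on M; A only anchors the within-array
normalization. Intensities below 1 are floored to 1 before taking logs, which
cannot affect bright probes and avoids infinities on near-zero scanner reads.

## Methylation inference

**Chip QC.** A failed digestion makes treated ≈ untreated everywhere, so the
array's M distribution collapses. An array is excluded when its raw-M IQR
falls below `min_iqr_ratio` (default 0.5) × the median IQR across arrays.
The cutoff is a package default — the original analysis states only that two
chips with "small interquartile difference" were dropped — and every
exclusion is reported, never silent.

**Within-array normalization.** A loess curve M~A is fitted per array on
control spots only (statsmodels lowess, locally linear, span 0.3 by default)
and its prediction, interpolated at each probe's A and clamped to the
boundary fitted values outside the control A-range, is subtracted from that
probe's M. At least 50 control spots are required; a global-loess fallback is
available behind an explicit flag.

**Between-array normalization.** Quantile normalization of the M matrix:
each column is mapped onto the mean distribution of column order statistics;
ties receive the mean of the reference values they span, making the transform
well defined and idempotent. Normalizing the individual channels instead is
available as `quantile_on: channels`; M is the modeled quantity, so M is the
default.

**Linear model and moderation.** Control probes are excluded, then each probe
gets a two-group means model with pooled residual variance (df = n − 2) and
three contrasts: mean M in normal, mean M in asthma (null: the probe is
methylated, M = 0), and their difference. Residual variances are shrunk with
the standard empirical-Bayes scheme: an inverse-chi-square prior (d₀, s₀²) is
moment-matched on the log-variance scale via digamma/trigamma transforms,
giving the posterior variance s̃² = (d₀s₀² + d·s²)/(d₀ + d); the moderated t
uses s̃ and d₀ + d degrees of freedom (a normal reference when d₀ is
infinite; when the observed spread of log s² does not exceed its chi-square
sampling component, d₀ = ∞ and s₀² is the arithmetic mean of the variances).
Zero-variance probes are retained and shrunk rather than dropped; if *every*
variance is zero the prior degenerates to (∞, machine floor) with a warning.
This implementation is cross-checked against Bioconductor limma to ~1e-6 in
the test suite; p-values are two-sided, with the positive-log2FC gate in the
call step providing the direction.

**Calls and DMR filter.** A probe is unmethylated in a group when adj-p ≤
0.05 (Benjamini–Hochberg, per contrast) and that group's log2FC ≥ 0.5.
Single-group calls then pass a two-stage filter: the methylated group's
log2FC must stay below 0.5 and the between-group |Δlog2FC| must exceed 0.3.
"log2FC of a group" is that group's contrast estimate throughout, so the call
and the filter use the same quantity.

## Expression inference

Probe-level log2 matrices are screened for outlier samples by PCA: samples
are projected on the first two principal components and flagged when their
distance to the group centroid exceeds median + k·MAD (k = 3) of the pooled
within-group distances. (A rule of the form distance > k·MAD without the
median offset flags typical replicates, because for 2-D Gaussian scatter the
median distance is already ≈3 raw MADs; the robust-z form keeps the intended
"far from its own group" meaning.) Flags are advisory; exclusion of the top
flagged sample per design is opt-in, mirroring a one-array-per-set exclusion.

After quantile normalization, probesets are summarized by Tukey median
polish (row sweep first, ≤10 iterations, tolerance 0.01 on the sum of
absolute residuals); the summary per sample is overall + column effect. DE
uses the same moderated-t machinery with a single asthma-minus-normal
contrast; a transcript passes at adj-p ≤ 0.05 and |log2fc| ≥ log2(1.25). The
two designs (4v4, 5v5) are analyzed separately and merged; the default
`intersection` mode requires passing in both with agreeing direction (merged
log2fc = mean, merged p = max), `union` accepts either and demotes direction
conflicts. No background correction is applied (none is part of the
quantile + median-polish recipe); the config records this as a flag.

## Annotation and integration

Coordinates are 0-based half-open internally; GTF input (1-based inclusive)
is converted on read, BED is taken as-is. The promoter window spans 1,000
bases upstream to 500 downstream of the TSS: [t−1000, t+500) on the plus
strand and the mirror [t−499, t+1001) on the minus strand, clipped at 0. A
probe is assigned to a transcript when it overlaps the body or the promoter
window by ≥1 base and may map to several transcripts; island overlap is
computed the same way, and a `cpg_in_promoter` flag marks probes whose
island also overlaps the promoter window.

Per transcript on both platforms, DMR probes and the DE record are joined.
The concordance paradigm is lower methylation ↔ higher expression:
hypomethylated-in-asthma accords with up-regulation, hypermethylated with
down. Among accordant DMRs one is "influential" by the context priority
promoter∧CpG > promoter > CpG > neither; ties fall to the larger
between-group |Δlog2FC|, then the smaller genomic start (the tie-break below
the priority classes is this package's own rule and is recorded in output).
Dual-direction transcripts (both DMR directions present) are classified by
their influential DMR when one exists, else discordant. Context proportions
are reported against two denominators — transcripts with an influential DMR
and all DE∩DM transcripts — because either reading of the published figure is
defensible. Report percentages render with one decimal below 10% and to the
nearest whole percent above, matching how the source cohort's numbers are
printed.

## Synthetic cohorts

The generator emulates the study conditions: 9 arrays per group, ~10%
control probes, untreated channel log2-intensities N(10, 1), treated =
untreated × 2^−(M_planted + ε) with ε ~ N(0, 0.35) by default, cut effect 1.0
log2 units for probes planted unmethylated in a group, 1,000 group-specific
probes per direction plus 5,000 unmethylated in both groups (≈28% of
experimental probes, matching the scale of the real cohort's "unmethylated
in both" fraction), and coupled 4v4/5v5 expression designs with 300 planted
DE transcripts at |log2fc| = 1.0, noise SD 0.25, and a 0.8 concordance rate.
Planted DE transcripts are drawn from transcripts carrying planted DMR
probes, and the concordant count is exact (round(rate × n)), not binomial.

Transcript body-plus-promoter hulls are placed without mutual overlap by
rejection sampling, so a planted probe's transcript assignment is
unambiguous and truth-table counts (including the planted dual-direction
transcript count) are exact. Probes are 50 bp; half of the group-specific
planted probes are forced into promoter windows and half of the islands are
forced to overlap promoters so the integration context classes are
populated. The generator does not calibrate its context mixture to the
source cohort's published context percentages — those depend on the real
genome's CpG geography, which the uniform synthetic genome does not imitate.

QC-failure arrays (an explicit config list) lose both the cut signal and its
variability — enzyme failure removes cutting altogether, leaving only
attenuated dye noise (scale 0.25) — which is what makes their IQR collapse
diagnostic, as on real failed chips.

Each generator draws from an independent substream derived from the single
master seed by fixed offsets, so runs are reproducible and the three
generators are independently stable under config changes.

What passing synthetic tests does **not** show: robustness to spatial/dye
artifacts, print-tip effects, probe cross-hybridization, correlated probe
noise within regions, or a realistic CpG island distribution — none of which
the generator models.

## Problem sizes and numerical choices

The default study conditions (20,000 probes × 18 arrays, 2,000 transcripts ×
8 probes per probeset) run the full pipeline in ~10 s; the test suite uses a
3,000-probe cohort for end-to-end checks and the 20,000-probe conditions for
the five-seed recovery property. Loess uses statsmodels' locally linear
smoother; BH adjustment delegates to statsmodels. Median polish stops on a
<0.01 change in the sum of absolute residuals. The trigamma inverse in the
prior fit uses Newton iteration from x₀ = 0.5 + 1/y with the standard
asymptotic guards. Degenerate inputs (all-zero variances, empty probesets,
empty DMR sets, empty platform intersections) degrade to warnings or empty
outputs rather than errors wherever the pipeline can meaningfully continue.

## Known limitations

* The IQR exclusion ratio and loess span are package defaults, not values
  from the original analysis; both are configurable.
* Exact reproduction of the original cohort's probe counts requires the raw
  deposited data on disk (see README) and depends on unstated normalization
  details; the corresponding test asserts agreement within 5%.
* The merge rule for the two expression designs is not documented in the
  original analysis; both intersection and union modes are implemented and
  the choice is logged.
* Concordance for dual-direction transcripts follows the influential DMR;
  the alternative (always discordant) is a one-line change and the per-record
  decision is visible in the output table.
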