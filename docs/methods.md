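# Methods

## The measurement model

A multiplexed reporter-ion experiment quantifies each feature (protein
group or phospho-site) as a vector of nonnegative intensities over
channels; a zero means "not detected", never "zero abundance". Two tables
enter the analysis: total-extract channels (`N`) quantifying protein
abundance, and phospho-enriched channels (`PE`) quantifying site
abundance, with only singly-phosphorylated (`___1`) site intensities
used. The sample design maps every channel to (strain, replicate,
timepoint, enrichment); the biological replicate doubles as the batch,
since each replicate timecourse is labelled and acquired as one plex.

## Normalization

1. **Channel-median scaling.** Every channel is multiplied by
   `grand_median / channel_median`, where both medians are taken over
   nonmissing (nonzero) values and the grand median pools all channels.
   The pooled reading of "median of all reporter columns" is the simplest
   literal one; a median-of-channel-medians variant would differ only by
   a single global factor and is not exposed. The operation is exactly
   idempotent. `N` and `PE` tables are scaled separately, since the two
   enrichment types have unrelated intensity scales.
2. **Phospho-to-protein ratio.** Site abundance is divided by the parent
   protein's `N` intensity in the channel with the same (strain,
   replicate, timepoint) and multiplied by 1000. A zero site stays zero
   (missing); a zero protein denominator makes that timepoint
   non-normalizable and later excludes the site (see Filtering).
3. **Batch correction.** Per feature, on log2 intensities with zeros
   masked out, replicate-mean differences are removed: every batch mean
   is moved to the feature's grand mean, which equals least-squares
   removal of batch indicators (sum-to-zero coding) for the balanced
   complete case. Within-batch contrasts are untouched; the result is
   antilogged and zeros restored. Features observed in a single batch
   pass through unchanged and are logged.

All downstream analysis uses the normalized linear-scale values; log2 is
internal to the batch step.

## Filtering

Rules apply in a fixed order (which also defines the audit's "first
failing rule"): search-engine contaminant/reverse flags; localization
probability strictly greater than 0.75; detection — proteins need one
nonzero timepoint in every replicate of every required strain,
phospho-sites need two *adjacent* nonzero timepoints (adjacency in the
ordered list, so 0 -> 45 min counts) in every replicate of every
required strain; and, for sites, a nonzero parent protein in every `N`
channel of the required strains (the strictest reading of "normalizable
at all timepoints": a zero in either replicate excludes the site).
Replicate-only designs (metaphase arrest, analogue-sensitive inhibition)
use a detected-in-at-least-`min_reps`-replicates-of-every-strain rule
instead; the inhibition analyses are the `min_reps`=1-of-2 and 2-of-2
parameterizations of the same operation.

## Differential calling

For a comparison with reference channels \(r_1..r_m\) and test channels
\(t_1..t_m\) (ordered by replicate):

* median fold change: median over replicates of \(t_i / r_i\); any zero
  is first replaced by the smallest nonzero value of the whole filtered
  dataset ("dataset minimum") and the median recomputed, flagged as
  imputed. With two replicates the median is their mean — replicate
  pairing, not all-pairs ratios, is the contract; a pooled
  median-of-test over median-of-reference mode is selectable.
* significance: Welch's two-sample t on the literal intensity values
  (zeros included), two-sided, Satterthwaite degrees of freedom.
  Zero-variance conventions make the degenerate cases deterministic:
  p = 1 when both groups are constant with equal means, p = 0 with
  unequal means (and a log entry).
* category: `increased` / `decreased` when the fold-change rule
  (|log FC| beyond 1.5-fold, or the zero-rescue rule below) and p < 0.05
  hold together; otherwise `no_change`. A comparison where one side is
  entirely undetected and the other entirely detected may satisfy the
  fold-change rule by construction (zero rescue) and is then decided by
  the t-test alone.
* no multiple-testing correction enters the calls; a Benjamini-Hochberg
  column per comparison family is emitted for information only. The
  display clamp of fold changes to [0.2, 2.2] is cosmetic and never
  affects calls.

A feature is *dynamic* when at least one of its nine vs-t0 comparisons is
called, and *strain-different* when at least one matched-timepoint
strain contrast is called. Metaphase-to-anaphase transitions anchor at
75 min (metaphase I) and 120 min (metaphase II — the timepoint before
the 135-min anaphase-II peak) and compare the anchor against each later
timepoint with the same rule.

With n = 2 per group these t-tests have at most 2 degrees of freedom
(critical |t| = 4.30), a deliberate fidelity choice: the procedure is
reproduced exactly as practised, and its statistical behaviour is then
*measured* on synthetic data (see Validation) rather than patched.

## Profile transforms and clustering

Replicates are averaged arithmetically with zeros included, so a value
missing in one replicate is halved rather than dropped. Profiles are
scaled to their own mean over all timepoints (zeros included; mean
exactly 1 afterwards); for combined two-strain views the mean is taken
over all 20 values so inter-strain level differences survive. A
reference-timepoint scaling (profile / value at 75 or 120 min) serves the
metaphase-anchored views. Features with zero mean or zero reference are
excluded and logged.

Clustering is agglomerative Ward on Euclidean distances with un-squared
merge heights (the `ward.D2` convention; scipy's `ward`). When no k is
given, k maximizes the second difference
wss(k-1) - 2·wss(k) + wss(k+1) of the within-group sum-of-squares curve
over interior candidates, smallest k on ties — a deterministic stand-in
for judging the elbow by eye, and therefore always overridable to a
chosen k. For three well-separated, mutually equidistant groups the rule
provably selects k = 3; with markedly unequal between-group gaps maximum
curvature can legitimately sit at a smaller k. Cluster ids are
renumbered by first appearance (R `cutree`-style); summaries report
median and quartile profiles per cluster.

## Motif statistics

The motif grammar (bracketed residue sets, literal residues, wildcard
`x`, exactly one starred phospho-acceptor with residues from {S,T,Y})
compiles to offset -> residue-set constraints anchored at the acceptor.
Matching is total: a constrained offset falling on terminal padding
(`_`) fails. Enrichment per cluster uses the 2x2 Fisher exact test in
the "cluster vs total" construction (the group is part of its own
background) to mirror the published barplots; the rows of that table
overlap, so a statistically conventional "cluster vs rest" mode is
offered alongside. Stars follow the usual *<0.05, **<0.01, ***<0.001
mapping. Percent-difference logos compare foreground and background
residue frequencies per (offset, residue) with a per-cell Fisher test at
alpha 0.05, excluding the acceptor column (conditioned on {S,T}) and
excluding padding from denominators. Sub-motif discovery restricts both
sets to windows matching a base consensus, tests each residue at one
unconstrained offset, and returns the positively enriched residues with
p < 0.05, ranked by p. Besides the scipy-backed per-table test the
package provides `fisher_family_pvalues`, an exact two-sided p for every
table of a margin family at once (tie tolerance 1 + 1e-7, matching R and
scipy), which makes exhaustive verification over all small tables
feasible.

Over-representation analysis is the upper-tail hypergeometric
P(X >= k) with BH correction across terms; significance is reported at
raw p < 0.05 with q available, and the universe defaults to the features
passing the filters. BH is used in place of simulation-defined,
tool-internal correction schemes.

## The synthetic-data generator

The generator emulates the study conditions end to end: 1000 proteins,
2000 sites (assigned uniformly to proteins, so per-protein site counts
are approximately Poisson with mean 2), 10 timepoints (0, 45..165 min in
15-min steps), two replicates, two strains. Protein sequences are drawn
i.i.d. uniform over the 20 amino acids; motif residues for planted sites
are written into the sequences (sites at least 8 residues apart), so
windows, positions and the emitted FASTA agree exactly. Three kinase
classes of 10% of sites each carry activity waves multiplying their
site's phospho signal: a biphasic Cdk-type wave peaking 3x at 75 and
120 min in both strains; a Polo-type meiosis-I wave (`[DEN]x[ST]*F`)
peaking 3x at 75 min in the wild type and flat in the mutant — the only
planted strain difference; and a late casein-kinase-type wave reaching
3x by 150 min in both strains. Intensities are
baseline x protein profile x activity x channel factor x 2^(batch
offset) x mean-one log-normal noise (cv 0.2 per value, independently in
the `N` and `PE` tables); the protein table is 1.3 dex brighter,
standing in for the aggregation of many peptides. Dropout is a logistic
function of log10 intensity (midpoint 4.35, slope 2.5), calibrated once
so that about 10% of site reporter values are zero at the defaults —
proteins, being brighter, drop out at well under 1%. Localization
probabilities are bimodal with 85% of sites above the 0.75 cutoff; 2%
reverse and 2% contaminant rows are appended. Everything is a pure
function of the seed, and two runs with the same seed write
byte-identical tables.

What the generator does *not* emulate: peptide-level quantification and
ratio compression, co-isolation interference, correlated (structured)
missingness, shared peptides between protein groups, and real motif
co-occurrence statistics (background windows are i.i.d. uniform, so
background motif-match rates follow combinatorics and are reported in
the truth summary). Passing recovery tests therefore demonstrates the
pipeline's correctness and the procedure's statistical behaviour under
clean assumptions, not performance on real spectra.

## Validation and measured behaviour

Truth evaluation computes sensitivity TP/(TP+FN) and FDR FP/(TP+FP)
over the analysed feature set (calls must be a subset of the truth ids;
planted sites removed by the localization or detection filters are
outside the evaluated universe), the adjusted Rand index between cluster
labels and planted classes, and Pearson correlations between planted
activity waves and the median profile of the capturing cluster.

At the default conditions the benchmark shows a sharp split. Structure
recovery is excellent: clustering the planted classes at the true k
gives ARI ~ 0.98 and activity-profile correlations ~ 0.99, and sub-motif
discovery returns F at +1 with p below 1e-15 in every seed tested. The
per-site strain-difference calls, in contrast, inherit the weakness of
two-replicate Welch testing: measured sensitivity is ~ 0.51 and measured
FDR ~ 0.73 (seeds 1-3). The FDR is structural, not a bug: with ten
matched-timepoint comparisons at alpha 0.05 and no multiplicity
correction, the null family-wise call rate is ~ 12%, so at 10% true
prevalence false calls outnumber true ones. The package reports these
numbers as measured; tightening them would require changing the
published procedure (fewer comparisons, correction, or more replicates),
which is out of scope.

## Numerical conventions

* Medians/means over even counts are the usual midpoint conventions of
  numpy/pandas; the idempotence of channel scaling holds exactly because
  scaled channels share their median.
* Ward merge ties break toward the smallest cluster-index pair; test
  oracles use continuous random data where ties have measure zero.
* Welch p for degenerate groups: see Differential calling. Fisher
  two-sided ties use the 1 + 1e-7 relative tolerance.
* Fold-change imputation uses the dataset minimum of the *filtered*
  matrix under analysis (proteins and sites have their own minima).
* All randomness flows through one `numpy` Generator seeded from the
  config; reduction orders are fixed, so reruns are bit-identical.

## Run configuration

`pipeline.run` executes a declarative YAML config (design kind, input
paths, thresholds, cluster k, optional motif table and term map, seed)
and writes TSV outputs plus `manifest.json` with per-stage feature
counts, the package version, seed and a config hash; any stage error
aborts with the stage recorded in a partial manifest. The `phoswave`
CLI wraps this (`simulate`, `run`, `enrich-motifs`, `logo`,
`scan-sstp`, `cluster`, `enrich`, `report`); exit code 2 marks
validation errors, 1 runtime failures.
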