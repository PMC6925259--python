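# Methods

This note documents the models, parameters, and numerical choices behind
each analysis stage, what the synthetic-data generator does and does not
emulate, and the known limitations.

## Methylation retention

A probe's beta value (methylated / total signal, in [0, 1]) is binned into
three states with cutoffs at 1/3 and 2/3. The bins are half-open —
[0, 1/3), [1/3, 2/3), [2/3, 1] — so classification is a total function on
the unit interval; the boundary convention affects a measure-zero set and
no finite-precision array in practice. The retention rate of a pair is the
fraction of shared (pairwise non-missing) probes with identical state; it
is symmetric, probe-order invariant, and equals 1/3 in expectation for
independent uniform betas (3 × (1/3)² matching bins), which the tests use
as an analytic calibration point.

Cohort clustering uses average linkage on 1 − Pearson correlation over the
k most variable probes (default k = 20,000, variance ties broken by probe
id). Distance metric and linkage are this package's choices — standard for
methylation arrays — not uniquely determined by the workflow it follows;
both are recorded in the run log. Pair adjacency counts models whose two
samples are immediate neighbours in the dendrogram leaf order, a statistic
invariant to reflections of the dendrogram.

## Copy number from array total signal

Covariate adjustment subtracts the mean signal of each (GC-quantile-bin ×
probe-type) cell — a depth-limited regression tree with axis-aligned splits
on the two technical covariates. Ten GC bins are used by default; when GC
takes fewer distinct values than bins, stratification is by exact value.
Constant covariates degrade gracefully to mean-centering with a warning.

Segmentation is circular binary segmentation: within each segment the arc
[i, j) maximising the pooled-variance two-sample |t| against its complement
is found (all arcs with at least `min_width` = 2 probes on each side), and
the split is accepted when its permutation p-value — the fraction of
within-segment permutations whose max |t| reaches the observed one, with
the +1 correction — falls below `alpha` (default 0.01, `n_perm` default
1,000, at least 100 enforced; a fixed seed makes runs deterministic).
Accepted arcs add up to two breakpoints and recursion continues in each
piece. Zero within-variance with distinct means is treated as |t| = ∞ so a
noiseless step is always found; an all-constant segment never splits.
Near-alpha decisions are intrinsically stochastic: two independent
permutation streams can disagree when the true permutation p sits at the
alpha knife-edge (only relevant for segments of a handful of probes), which
is why the oracle-equivalence tests use instances whose segments are at
least 6 probes.

Recentering subtracts the probe-weighted median of segment means (the
lower weighted median: smallest mean whose cumulative probe weight reaches
half), making the operation idempotent and anchoring a predominantly
diploid genome at zero. States are called per segment by strict
inequalities — mean < −0.2 loss, > +0.2 gain, ties neutral. Paired
profiles are compared probe-wise; the shared fraction is probe-weighted and
the differential map (state_b − state_a clipped to ±1) is antisymmetric
under argument swap.

## Clonal dynamics

Variants carry MAFs in both samples. Detection requires MAF ≥ `detect_maf`
(default 0.02) and ≥ 3 supporting reads — a typical deep-capture noise
floor; both are configurable. Detected-on-one-side variants are private to
that side; both-sides variants are classified by the MAF ratio with a
strict 2× boundary (the boundary ratio itself is shared); below-detection
on both sides is uninformative and excluded with a warning. Classes
partition informative variants and swap consistently (enriched↔depleted,
private↔private) under sample exchange.

Clone reconstruction runs deterministic k-medoids (PAM with greedy BUILD
then best-improvement SWAP) in (MAF_primary, MAF_xeno) space for
k = 2..k_max (default 6), keeping the best mean silhouette; a single clone
is returned when points are essentially coincident (max deviation from the
coordinate median below 0.03) or no split reaches silhouette 0.5. Those two
constants are the package's own criterion for k — the source workflow does
not specify one. Clone frequencies are twice the per-coordinate member
medians, capped at 1 (heterozygous-diploid convention: a clone at cellular
frequency f yields MAFs near f/2). At depth 500 and ≥ 30 variants per
clone, planted frequencies are recovered within 0.05 in well over 90% of
seeds (acceptance checks 50 seeds).

## Preclinical response

Volumes derive from mean diameters via (π/6)·d³. The event is the first
crossing of min(event_rtv × V(0), size_cap) — defaults RTV 4 and 2.5 cm³,
both configurable since the event convention is a testing-program standard
rather than uniquely defined — linearly interpolated between bracketing
measurement days, censored at the 84-day evaluation period (or the last
measurement if the series ends early). Kaplan–Meier medians use lifelines;
a curve that never falls to ≤ 0.5 within the evaluation period reports
`>EP`, and EFS T/C then reports the lower bound EP / control-median as
`> x`. Final RTVs above 10 print as `>10`, matching the reporting dialect
of preclinical response tables.

The exact log-rank test permutes group labels over pooled (time, event)
outcomes: complete enumeration of label assignments when the pooled arm
size is ≤ 16, otherwise ≥ 10,000 seeded permutations; p is the fraction of
assignments whose |observed − expected| statistic reaches the observed one.
The test is exchangeable-exact (identical arms give p = 1; fully separated
4 vs 4 arms give 2/70) and conservative at enumeration scale, so type-I
error stays at or below nominal (verified over 1,000 null simulations).
Volume T/C compares arm means at the last day on which every control mouse
remains on study (the day is not dictated by the source workflow; it is
reported alongside the ratio), with a two-sided exact rank-sum p (defined
as 1 for fully tied degenerate data).

Response calls follow the standard objective-response definitions with
precedence MCR > CR > PR > PD: final volume < 0.10 cm³ → MCR; any
post-baseline volume < 0.10 cm³ → CR; regression to ≤ 50% of baseline with
measurable tumor → PR; otherwise progressive disease, split by the
growth-delay value — equated to EFS T/C, the package's reading of the two
interchangeable terms — at 1.5 (≤ 1.5 PD1, > 1.5 PD2). The group call is
the median per-mouse call under PD1 < PD2 < PR < CR < MCR, taking the lower
class on even splits.

## Transcriptome similarity

Expression enters as FPKM ≥ 0, transformed once to log2(FPKM + 0.01);
genes with max transformed value < 1 are dropped. Negative input is
rejected, which doubles as a double-transform guard (log output contains
negatives). Spearman correlation over all filtered genes builds the sample
matrix; the lowest-quartile threshold for pair flagging is recomputed from
the cohort's pair correlations (never hard-coded — a published realized
threshold is that cohort's 25th percentile, not a constant). PCA is
gene-centered but unscaled (log2 FPKM is already on a comparable scale
across genes). Gene-set scores are mean across-sample z-scores of member
genes (zero-variance genes contribute 0; the score has zero cohort mean by
construction). Paired differential testing is a per-gene paired two-tailed
t with Benjamini–Hochberg step-up q-values; zero-variance difference genes
get p = 1 and a degenerate flag.

## Cohort annotations

The bundled table (`data/cohort_annotations_synthetic.csv`) describes a
45-model Wilms tumor PDX cohort. Models and categories that are pinned by
named evidence are fixed; remaining per-model placements, stages, and
blastema percentages are synthetic, constructed so the cohort-level
marginals (38/45 histologic concordance; 11p15 categories 17/2/18/3/5;
13/45 1q gain; 1/45 combined 1p+16q LOH) hold exactly — the statistics
module always recomputes counts and percentages from whatever table it is
given. Histologic discordance is encoded as enumerated reason codes
(anaplasia not detected in the graft; monomorphic drift of a triphasic
tumor).

The 11p15 cascade orders its evidence: copy ratio below 0.8 → hemizygous
loss; above 1.2 → paternal gain; copy-neutral with all informative
microsatellites homozygous → uniparental disomy; heterozygosity retained
with IC1 methylation index > 0.75 → loss of imprinting; otherwise normal.
Thresholds are configuration with those defaults, since the underlying
assay definitions are qualitative; copy-neutral evidence with no
informative marker returns an explicit `indeterminate`. STR matching
treats a locus as concordant when allele sets are equal or the xenograft's
set is a strict subset of the primary's (allele loss in the graft,
tolerated but counted and reported); the subset rule is deliberately
directional. Blastema enrichment is a paired t with a 95% t-interval on
the xenograft-minus-primary percent differences; passage trajectories
compare each passage against the primary values.

## Synthetic cohort generator

All generators draw from one integer seed (fixed seed → bit-identical
cohort) and plant the parameter the downstream stage recovers:

- **Beta pairs**: a shared probe baseline plus a per-model deviation
  (sd 0.2, so each tumor has a strong global methylation identity and
  pairs cluster adjacently, as on real arrays); per probe the xenograft
  either stays in the primary's bin (truncated normal, sd 0.05) with
  probability equal to the planted retention — default 0.8678, the
  realistic cohort median — or jumps uniformly into one of the other two
  bins.
- **Variant tables**: clones with stated (primary, xenograft) frequencies
  emit binomial MAFs at depth 500 around frequency/2; the default clone
  table spans maintained, expanding, lost, and graft-private clones. A
  separate burden generator draws per-side non-silent counts from Poisson
  distributions centred on realistic burdens (medians 7 primary / 5
  xenograft).
- **Growth studies**: day-0 volume uniform on the 0.2–0.5 cm³ enrollment
  window, V(t) = V0·exp((ln2/doubling − kill)·t) with multiplicative
  lognormal measurement noise (sd 0.05), weekly measurements to day 84,
  truncation at the first reading ≥ 2.5 cm³, and a 0.01 cm³ detection
  floor below which readings record as 0 (making complete regression and
  zero final RTVs representable). Default arms: control (doubling 7 d),
  a strong drug (kill 0.25/d, net regression → MCR) and a weak drug
  (kill 0.03/d, growth delay only → PD).
- **Expression pairs**: xenograft = primary + noise + a planted shift
  (default +1 log2 unit) on a designated 100-gene blastemal set;
  optionally the first n models receive heavy independent xenograft noise,
  making them the planted low-similarity pairs for quartile-flagging
  tests.
- **Signal tracks**: a smooth sinusoidal GC wave plus probe-type offsets
  plus planted copy-number shifts plus Gaussian noise (sd 0.1), so the
  adjustment must remove the first two components while segmentation
  recovers the third.

What the generator does **not** emulate: probe-level spatial
autocorrelation and array batch effects, purity/ploidy and murine-cell
contamination, subclonal copy number, correlated multi-gene expression
programs beyond the planted set, and dropout or censoring patterns other
than the volume cap. Passing recovery tests therefore demonstrate
correctness of the statistics under the stated generative assumptions, not
robustness to every artefact of real arrays and sequencing.

## Problem sizes

Defaults used by the test-suite and the acceptance script: cohorts of
1–39 models, 20,000 probes for retention, 100–200 probes per segmentation
instance (with 100-seed false-split calibration), 50-seed clone recovery
at depth 500, 1,000-simulation log-rank calibration, and a 37-pair
expression cohort with 9 planted low-fidelity pairs. These sizes keep every
stage at desk scale while leaving the Monte-Carlo tolerances (±0.01 on the
uniform-beta 1/3 check, ±0.02 on planted retention, ≤ alpha false-split and
type-I rates, < 0.05 clone-frequency error) comfortably resolvable.

## Known limitations

- Copy-number calls are relative (no absolute ploidy, purity correction,
  or allele-specific states); the ±0.2 rule assumes a mostly diploid
  genome after recentering.
- Clone tracking has no phylogenetic ordering or CCF correction; clusters
  are read directly in MAF space.
- The exact log-rank enumeration grows combinatorially; pooled sizes
  above 16 switch to seeded permutations.
- The bundled annotation table is synthetic at per-model resolution;
  only its cohort-level marginals are meaningful.
- The 11p15 classifier consumes pre-summarised evidence (copy ratio,
  methylation indices, marker zygosity), not raw MS-MLPA exports.
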