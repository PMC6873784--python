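# Methods

## Differential expression

Each feature class is screened with the classic two-gate microarray
filter: linear-scale fold change `max(mean_case, mean_control) /
min(mean_case, mean_control)` (reported as a ratio ≥ 1 plus an up/down
label, so down-regulated features print large positive fold changes) and a
two-sided **pooled-variance Student's t-test** (df = n₁+n₂−2). Defaults:
fold change > 2.0 for miRNA, > 1.5 for lncRNA/mRNA, *P* < 0.05; Welch is
available behind `equal_var=False`. Degenerate conventions are explicit:
zero pooled variance gives *P* = 1 when means are equal and *P* = 0
otherwise; a zero mean against a positive mean gives fold change = ∞ with
the correct direction; both-zero is an error. Raw p-values are the gate —
no multiple-testing correction is applied to the screen, matching common
small-array practice — but a Benjamini–Hochberg q-value column is emitted
for information. Log2 matrices are converted to linear intensities before
means and tests.

## Triplet construction

Pearson correlation is computed across **all samples pooled** (cases +
controls) on the **log2 scale** by default (`use_log2=False` switches to
linear); the pooled single-coefficient reading is deliberate, since the
screen asks whether two transcripts track each other overall, and a
group-restricted mode is unnecessary at these sample sizes. The p-value
uses the t transform *t* = *r*·√((n−2)/(1−*r*²)), df = n−2; |*r*| = 1
maps to *P* = 0. Constant features are dropped with a logged warning
rather than producing undefined coefficients.

Pair gate: *r* > 0.99 and *P* < 0.05 over all DE-lncRNA × DE-mRNA
combinations. Triplet gate: a miRNA must (a) appear in the interaction
table targeting **both** members and (b) satisfy *r* < `neg_threshold`
with *P* < 0.05 against both. `neg_threshold` defaults to 0 — any
significantly negative correlation qualifies — because "negatively
co-expressed" carries no magnitude; it is an exposed flag. The miRNA
anticorrelation reuses the single 0.05 p-cutoff. Each retained pair also
receives a **shared-miRNA hypergeometric score** — the upper-tail
probability that two binder sets of the observed sizes share at least the
observed number of miRNAs out of the miRNA universe. This is this
package's explicit stand-in for an otherwise undefined "ceRNA score" and
is labeled as such (`cerna_score_hypergeom_p`) in outputs.

## Seed matching

The built-in predictor is canonical seed matching only: a site is an
occurrence on the target transcript (5'→3') of the reverse complement of
miRNA positions 2–7, classified by the TargetScan taxonomy (6mer;
7mer-m8 when position 8 also pairs; 7mer-A1 when an A faces position 1;
8mer for both). Coordinates are 0-based half-open; overlapping sites are
all reported; only the transcript strand is scanned; the default minimum
reported class is 7mer. Thermodynamic duplex folding (RNAhybrid-style
MFE) and conservation scoring are out of scope — outputs of such external
tools are consumed as interaction tables and merged by set union on
(miRNA, target) keeping the best score.

## Network topology

The network is undirected; regulatory direction lives in edge relation
labels (`lnc_mir`, `mir_mrna`, optional `lnc_mrna` co-expression edges),
not arc direction. The panel per node:

* **degree** — incident edge count;
* **betweenness** — Brandes, unnormalized, each unordered pair counted
  once (matches the magnitude style of published hub tables);
* **closeness** — harmonic centrality divided by (n−1). The harmonic
  variant is chosen because ceRNA networks are disconnected-prone and
  classic closeness is undefined across components; absolute closeness
  values from specific GUI tools are tool-specific and not comparable;
* **pagerank** — damping 0.85, uniform teleport, converged to L1 <
  1e-12.

Top-*k* ranking (default k = 20) sorts each dimension descending with
lexicographic tie-breaks and reports the intersection across all four
lists. Per-lncRNA pair counts are n_first = miRNA neighbors,
n_secondary = distinct miRNA–mRNA edges incident to those miRNAs
(neighbor miRNAs cannot share an edge, so the union is a plain sum of
per-miRNA mRNA degrees), total = their sum. Subnetwork extraction keeps
the lncRNA, its miRNA neighbors, their mRNA neighbors, and only
lnc_mir/mir_mrna edges among them.

## Random walk with restart

Deterministic power iteration **p** ← (1−r)·W**p** + r·**p**₀ with W the
column-normalized (unweighted by default) adjacency and **p**₀ uniform
over seeds; dangling-node mass is redistributed to **p**₀, keeping the
iterate a probability vector on disconnected graphs. Defaults r = 0.7
(common in network-medicine diffusion; no value is canonical for ceRNA
networks), tolerance 1e-10 (L1), max 1000 iterations; non-convergence
raises an error carrying the last residual. Seeds are caller-supplied;
the pipeline defaults to all lncRNA nodes.

## Modules and enrichment

Bidirectional hierarchical clustering runs agglomerative linkage
independently on rows and columns. Defaults are **1 − Pearson distance
with average linkage** — correlation distance matches the goal of
grouping transcripts by co-expression shape rather than absolute
intensity — with Euclidean/complete available by flag; the cut is k = 2
modules by default (user-supplied), or a height h. Ties in merge order
follow SciPy's deterministic convention; labels are renumbered by first
appearance so module indices are contiguous from 1. Constant rows/columns
are dropped with a warning under correlation distance; a matrix left
smaller than 2×2 is an error (the pipeline reports the stage as skipped).

Enrichment is a generic hypergeometric over-representation test: each
annotation set is intersected with the caller's universe,
*P*(overlap ≥ observed) is computed exactly, and BH correction is applied
across the sets tested. GO/KEGG content is out of scope; sets arrive as
GMT files.

## Synthetic data

The generator emulates a small two-group, three-class microarray study:
log2-normal intensities around `baseline_mean` (default 8.0 log2 units —
a placeholder, not an estimate of any platform), iid noise
`background_noise_sd` (default 0.25), and 3 + 3 samples by default. Each
planted triplet draws one latent N(0, `latent_sd`²) value per sample
(default latent sd 0.5) plus a group shift of ±`effect_size`/2 (default
effect 2.0 log2 units, i.e. fold change 4 — within the range reported by
small cardiomyopathy arrays); lncRNA and mRNA get baseline + latent +
shift, the miRNA gets baseline − latent − shift, so all three pairwise
correlation constraints hold by construction and all planted triplets
share one shift direction (miRNA down in cases). Latent sd 0.5 keeps
cross-triplet correlations near 0.8 — comfortably below the 0.99 pair
gate — while within-triplet correlations stay above 0.99 whenever noise
sd ≲ 0.1. Matrices are emitted on the linear scale with `is_log2=False`
recorded, since fold-change thresholds are linear-scale ratios. The
interaction table contains the planted true pairs plus 3:1 random decoy
pairs with no expression support, so the anticorrelation filter is
actually exercised. Identical specs (including seed) reproduce identical
datasets bit for bit.

**What a green benchmark establishes.** The recovery suite (10 planted
triplets, noise sd 0.05, 12 samples/group, 50 seeds: recall ≥ 0.95,
false-discovery proportion ≤ 0.05) shows the pipeline recovers exactly
the planted correlation structure under its own generative assumptions.
It does not model probe-level artifacts, batch effects, intensity-
dependent variance, correlated backgrounds, or sequence evolution — so it
validates the inference chain, not microarray preprocessing. At the
generator's noisier 3 + 3 default (noise sd 0.25) planted pairs fall
below the 0.99 correlation gate: that regime illustrates the screen's
conservatism rather than a defect. The null-calibration suite runs in the
same 12-per-group world as the recovery benchmark; with only 6 pooled
samples a |r| > 0.99 gate admits ≈ 7.5 × 10⁻⁵ of independent pairs, which
is no longer negligible against thousands of candidate pairs.

## Numerical and interface choices

* Pearson r is computed from the centered dot-product formula and clipped
  to [−1, 1]; identical vectors give exactly r = 1.
* t-test and hypergeometric tails come from scipy.stats; BH from
  statsmodels; graph algorithms from networkx; linkage from
  scipy.cluster — the triplet logic, seed scanner, RWR iteration and
  generator are implemented here.
* All tables are tab-delimited with a mandatory header and "." decimals;
  loading is strict (duplicate ids, non-numeric cells and unlabeled
  samples raise errors naming the line). Sequences are stored as DNA
  (U→T) with the original alphabet flagged. SIF uses the fixed relation
  vocabulary `lnc_mir`/`mir_mrna`/`lnc_mrna`; GraphML round-trips are
  lossless, SIF needs a class registry for isolated nodes.
* The pipeline writes into `run_<sha256(config)[:12]>/` with no
  timestamps, so reruns are byte-comparable; one seed governs all
  randomness.

## Known limitations

No partial-correlation or sensitivity-correlation ceRNA scores; no
multiplex RWR with inter-layer jumps; no probe summarization or
normalization; enrichment ignores ontology structure; fold-change
direction is case-vs-control by definition (the label, not the ratio's
orientation, carries the biology).
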