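# Methods

This note documents the statistical machinery in `effimine`: the models
and their assumptions, the defaults and why they were chosen, what the
synthetic-data generators do and do not emulate, and the numerical
conventions that matter for reproducing results.

## Improvement coding and association rules

Each patient record carries a treatment-exposure flag and a (pre, post)
pair per laboratory marker.  Coding is directional: for a
"high-is-bad" marker (all eight defaults — FBG, PLT, ESR, Hs-CRP, IgA,
IgG, IgM, RF — improve downward), the item `<marker>_improved` is
emitted iff post < pre·(1 − tolerance).  The default tolerance is 0, a
strict decrease; ties never count as improvement.  A patient missing a
marker's pair contributes no item for that marker but still counts in
the record total N, because N is the denominator of the support
formula, not a per-marker count.

Rule metrics are the classical ones: support σ(X∪Y)/N, confidence
σ(X∪Y)/σ(X), lift confidence/support(Y).  They are stored as fractions
in [0, 1] and multiplied by 100 only at rendering time, which keeps the
identities support ≤ confidence ≤ 1 and lift·support(Y) = confidence
exact to machine precision.  When the consequent never occurs
(support(Y) = 0) the lift is reported as 0 rather than undefined; such
rules also have zero support and are filtered by any positive support
threshold.

Strength labels: *strong* iff confidence > 0.60 and lift > 1;
*moderate* iff lift > 1 but not strong; *weak* otherwise.  The strong
criterion is the conventional screening rule for clinical rule tables;
the moderate/weak split is this package's own convention and is
deliberately simple — lift above 1 means the antecedent raises the
consequent's probability at all.

The miner is a from-scratch level-wise Apriori with downward-closure
pruning.  At the scale this package targets (~10³ records, ~10 items)
exhaustive candidate generation is far from any performance limit; the
implementation is verified against literal power-set enumeration in the
test suite.  The default search space is single-item antecedents
(the exposure item) against single-item consequents — the only rule
shape clinical tables report — with `full_search=True` enabling all
subset splits.  Defaults min_support = 0.01 and min_confidence = 0 are
permissive on purpose: weak rules are informative in a screening
context and are labelled rather than hidden.

## Random-walk fluctuation model

Outcomes per record, coded +1 (item present) / −1 (absent) and taken in
record order (standing in for admission order, which file order is
assumed to reflect), define the walk y(l) = Σ increments, y(0) = 0.
The fluctuation function is

    F²(l) = mean(Δy_l²) − mean(Δy_l)²,  Δy_l = y(l₀+l) − y(l₀),

with the mean taken over **all overlapping start points**
l₀ ∈ {0, …, n−l} — maximal averaging, since no windowing scheme is
canonical for this statistic.  Subtracting the squared mean removes the
deterministic drift l·(2p−1) of a biased walk, so F² measures
fluctuation about the trend, not the trend itself.

**Exponent convention.**  The scaling exponent α is defined on
F(l) = √F²(l) ∼ l^α, so that exchangeable (memoryless) outcomes give
α = ½ (since Var(Δy_l) = l·Var(step) grows linearly).  Some authors
write the power law on F²(l) directly, which doubles the exponent; this
package uses the F(l) convention throughout precisely so the null value
is ½.

α̂ is the least-squares slope of ½·log F²(l) against log l.  The default
lag grid is log-spaced from 4 to n/4 with at most 12 lags: lags below 4
are dominated by step discreteness, lags above n/4 by estimator noise
(fewer effectively independent windows).  Lags with F² = 0 are dropped
with a warning; fewer than three surviving lags is an error.

**Permutation test.**  The regression standard error of α̂ is
anti-conservative because F² values at overlapping lags are strongly
dependent, so the null α = ½ is tested by permutation: the increments
are shuffled (destroying serial structure, preserving the marginal),
α̂ is refit per shuffle, and the two-sided p-value uses the add-one
Monte-Carlo convention p = (1 + #{α̂* at least as extreme})/(B + 1).
The add-one rule — the observed statistic is a member of its own
reference set — makes the test exact at the nominal level under
exchangeability; the naive interpolated-quantile rule was measured at
type-I ≈ 0.08 for a nominal 0.05, the add-one rule at 0.05.
Walks with all increments equal are rejected up front: F² is
identically zero under every shuffle and the statistic is undefined.

**A caveat on super-diffusive fixtures.**  The doubly-integrated test
fixture (increments themselves a ±1 random walk) has *ensemble*
displacement variance ∝ l³, suggesting α = 1.5.  A single-walk
overlapping estimator cannot see that law: the displacement from start
l₀ is dominated by the local-trend term l·W(l₀), so the variance over
start points scales as l²·Var(W) and the fitted exponent is ≈ 1.
Recovering 1.5 from one realization requires local detrending (DFA),
which is out of scope here — the plain fluctuation function is the
model.  α̂ ≈ 1 is still far above the memoryless ½, and the permutation
test rejects for such walks with probability ≈ 1.  Users comparing
exponents across conventions should keep this distinction between
ensemble and time-averaged scaling in mind.

## Differential expression

Per-gene screening uses an unequal-variance (Welch) two-sample t-test
on log2-scale values with log2FC = mean(case) − mean(control).  A
moderated-variance (empirical-Bayes) test would gain power at very
small n, but this stage feeds a hard threshold screen rather than a
ranked FDR analysis, and a plain per-gene test keeps the stage
transparent and dependency-free; the substitution is a deliberate
design choice.  Significance defaults to the microarray convention
p < 0.05 **and** |log2FC| > 2, both strict.  No multiple-testing
correction is applied by default, matching the raw-p screening
convention; a Benjamini–Hochberg mode exists for users who want it.

Degenerate genes (zero variance in both groups) get p = 1 when the
means agree and p = 0 with a `degenerate` flag when they differ —
a flagged p = 0 says "look at this gene's data", not "infinitely
significant".  Duplicate gene symbols collapse to the row with maximal
mean expression (the common probe-collapse rule).  Linear-scale input
is auto-detected by a range heuristic (max > 50) and log2(x+1)
transformed, overridable.

Target-set intersection normalizes symbols (trim, upper-case),
deduplicates the union of the compound-target lists, then intersects
with the differential genes; per-list overlap counts are reported for
Venn-style display.

## Network statistics

Centralities on the interaction graph: degree; **harmonic closeness**
(Σ 1/d(v,u)), chosen over classic closeness because interaction
subnetworks are routinely disconnected and harmonic closeness is
well-defined there (unreachable pairs contribute 0); betweenness left
**unnormalized**, because only ranks feed the selection and ranks are
normalization-invariant.  Hub genes are the intersection of the top-k
lists (k = 10 by default) under the three centralities; all rankings
break ties by (score descending, symbol ascending) so results are
deterministic.

Core genes are ranked by maximal-clique centrality,
MCC(v) = Σ over maximal cliques S ∋ v of (|S|−1)!, computed by full
maximal-clique enumeration; an isolated node's singleton clique scores
0! = 1.  Enumeration aborts beyond a configurable budget (10⁶ cliques)
rather than silently running unbounded on pathological graphs.

ROC AUC uses the rank statistic (Mann–Whitney U divided by n₁n₂, ties
counted half), with orientation **fixed** as case-high = positive.  No
auto-flip: a gene whose expression is lower in cases reports AUC < 0.5
visibly instead of being silently inverted, which matters when the
screen's output is read as a direction-of-effect summary.  The
candidate threshold defaults to AUC > 0.7.

## Over-representation analysis

Enrichment of a query list in an annotation set is the one-sided
hypergeometric upper tail P(X ≥ k) with universe size N, set size K,
query size n, overlap k, computed from the exact survival function.
The default universe is the measured-gene background (e.g. all genes in
the expression matrix), not the genome — the conservative convention
when the assay universe is known.  Query genes and set members outside
the universe are dropped with logged counts; zero-overlap terms are
hidden by default.  Significance is flagged on raw p < 0.05 by default
(mirroring the screening convention of enrichment portals), with a
Benjamini–Hochberg q < α mode available.  The plain tail is used rather
than the EASE-style (k−1) deflation; the EASE variant would be a
one-line extension.

## Synthetic-data generators

The generators define the reference conditions under which the pipeline
is validated.

* **Cohort.**  Pre-treatment marker values are log-normal with
  μ = ln(median) and σ = ln(q3/q1)/(2·z₀.₇₅) solved from published
  median (Q1, Q3) summaries — markers are positive and right-skewed,
  and log-normality reproduces the median exactly and the quartile
  *ratio* exactly.  The packaged eight-marker table carries the
  reference ranges and pre-treatment summaries of an active
  rheumatoid-arthritis inpatient cohort (e.g. Hs-CRP median 36 mg/L
  against a < 1 reference).  Treatment effect: with the configured
  conditional probability (given treated/untreated), the post value is
  pre × U(0.60, 0.97) — a multiplicative shrink toward the reference
  range — otherwise pre × U(1.00, 1.15); the low-is-bad direction uses
  reciprocals.  Mean-one log-normal measurement noise with configurable
  CV is multiplied on top.  IgM defaults to high-is-bad with no planted
  effect: its directionality of benefit is genuinely ambiguous
  (pre/post change is typically non-significant), and the default is
  overridable.  The generator draws one pre/post pair per patient; it
  does not model multi-admission trajectories, co-medication, or
  missingness, so passing tests say nothing about those features of
  real cohorts.
* **Improvement sequences.**  Four regimes for the walk model: `iid`
  (±1, P(+1) = p), `drifted` (iid with p ≠ ½), `integrated` (increments
  are themselves a ±1 random-walk — the super-diffusive fixture
  discussed above), `constant` (all +1, the F² ≡ 0 edge case).
* **Expression.**  Background genes share means across groups
  (log2-scale base 8.0); the first n_spiked genes are shifted by
  ±spike_log2fc in the case group (alternating sign), Gaussian noise
  σ per measurement.  Defaults (2,000 genes, 50 spikes at |log2FC| = 3,
  σ = 1, 10 per group) emulate a small two-group microarray comparison
  with a minority of strongly perturbed genes.  Real microarray data
  have correlated genes, batch effects and heavier tails; recovery
  rates measured here are upper bounds on real-data performance.
* **Networks.**  `scale_free_like` (preferential attachment, heavy-tail
  degrees as in protein-interaction graphs) or `erdos_like` (uniform
  edge probability); always simple and undirected.  A planted hub is
  wired to every node and competing saturated nodes are trimmed by one
  edge, so the hub's degree is the strict unique maximum.
* **Gene sets.**  Uniformly sampled member lists with a verbatim
  planted set for enrichment ground truth.

All generators are bit-identical under a fixed seed.  One master seed
feeds named substreams (CRC-32 of the stream name mixed into the seed
sequence), so adding or removing one generator call never perturbs the
draws of another — the property that makes pipeline stage toggles
reproducibility-safe.

## Pipeline

`run_all` executes simulate → mine → walk → differential expression →
target intersection → network → ROC → enrichment, writing every
intermediate (CSV/TSV/JSON) into the output directory plus a
`report.json` whose content is identical under identical seed + config
(elapsed-time fields aside).  Configs are YAML with fail-fast
validation: unknown keys are rejected with a nearest-key suggestion and
all violations are reported together.  Disabling the expression stage
while keeping the network stage requires an explicit gene list or edge
file — the validator enforces the dependency rather than letting the
stage fail midway.

## Problem sizes and numerical conventions

The validation suite runs the walk analyses at n = 5,000 (exponent
recovery, 100 seeds) and n = 1,000 (permutation calibration: 200 null
replicates for size, 100 persistent replicates for power, 99 shuffles
each); oracle comparisons use 50 random transaction tables (≤12
records, ≤6 items), 100 random graphs each for centralities (≤8 nodes)
and cliques (≤10 nodes), and 20 spiked expression matrices — sizes at
which the brute-force oracles are exact and fast while the statistical
bands are tight.  Ratios are compared at 1e-12, closeness at 1e-10.
F² values are clamped at 0 against negative round-off.  All
tie-breaking in rankings is deterministic (score descending, label
ascending); all randomness flows from explicit seeds.

## Known limitations

* Record order stands in for admission time; if the input cohort is not
  chronologically ordered the walk model's serial statement is about
  file order.
* The within-walk fluctuation function cannot distinguish ensemble
  scaling laws from time-averaged ones for non-stationary increment
  processes (see the caveat above).
* The Welch-test stage will differ from moderated-test results at very
  small sample sizes; counts of threshold-passing genes are not
  comparable across the two methods.
* Enrichment results are only as good as the supplied GMT catalogs; no
  ontology structure (term nesting) is modelled.
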