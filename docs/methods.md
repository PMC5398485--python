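# Methods

## Model

For one domain family and one cancer type, let the count at model position
*j* be the number of deduplicated somatic variant events (one per gene ×
patient × protein position × alternate residue) projected onto that
position across all member genes.  With *n_j* positions carrying *j*
events, the counts are modeled as

    f(j) = p0 * f0(j) + p1 * f1(j)

* `f0` — Zero-Inflated Poisson null: `f0(0) = pi + (1-pi) e^{-lam0}`,
  `f0(j) = (1-pi) e^{-lam0} lam0^j / j!` for `j >= 1`.  The zero-inflation
  absorbs positions that are effectively unmutable in the cohort (small
  cohorts, unreachable codons), the Poisson part the passenger background.
* `f1` — Poisson with rate `lam1 >= lam0` (identifiability constraint), a
  deliberately generic elevated-rate alternative.
* `p0` — prior weight of the null; the local false discovery rate at count
  `t` is `fdr(t) = p0 * f0(t) / f(t)`, the posterior probability that a
  position with `t` events is non-significant.

Each family is fit separately.  All member positions are aligned to the
same set of proteins, so region-level covariates of the background mutation
rate (replication timing, expression, chromatin state) are shared across
positions and cancel; only mutational context can differ between aligned
positions and is not modeled.  Synonymous variants are not used for null
estimation — they are excluded from counting entirely (default variant
class: missense only; nonsense can be included by config).

## Estimation

The estimator is a two-component EM on the histogram `n_j`:

* E-step: responsibility of the non-null component per count level, plus a
  nested structural-zero responsibility inside the null for `j = 0`.
* M-step: closed-form updates of `pi`, `lam0`, `p1`, `lam1`, with `lam1`
  clipped up to `lam0` when the constraint would be violated.
* Initialization (deterministic): `lam0` = mean of counts at or below the
  median nonzero count; `pi` from the excess of observed zeros over that
  Poisson's expectation, clamped to [0.05, 0.95] — `pi = 0` is an absorbing
  fixed point of the EM, so the start must be interior; `p0 = 0.95`;
  `lam1` = max(2·lam0, mean of the top-decile counts).
* Convergence: relative log-likelihood change below 1e-8 (max 500
  iterations).  The log-likelihood is asserted non-decreasing at every
  iteration.

Two guards collapse the fit to a pure ZIP null (`p0 = 1`, refit by a
ZIP-only EM): (1) fitted `p1 < 1/N` — less than one expected non-null
position; (2) the mixture fails to beat the pure null on BIC.  The second
is a model-selection guard: on homogeneous null data the two components are
not identifiable and would otherwise split the null between them, deflating
`p0` and mis-calibrating `fdr`.  With genuine signal the likelihood gap is
orders of magnitude beyond the BIC penalty, so the guard never fires there.

`fdr(t)` uses the *fitted* mixture as denominator (not the raw histogram)
for stability on short domains, and is monotonized over `t >= 1` by a
cumulative minimum so calls are nested in the count.  If both densities
underflow at some `t`, `fdr` falls back to 1 when the null's log-density
dominates and 0 otherwise; it is never NaN.  A tail-area FDR
(`p0 * P0(J >= t) / P(J >= t)`, the q-value analogue) is emitted alongside;
local fdr is the decision statistic.

Positions are significant when `count >= 1` and `fdr(count) < cutoff`
(defaults 0.05 primary, 0.01 secondary); zero-count positions are never
significant.  Families shorter than `min_positions` (default 10) or with no
nonzero count are skipped and reported.

## Coordinate projection

Alignments are consumed as a tabular dialect (one row per hit: protein_id,
domain_acc, model_length, evalue, protein_start, model_start, and a
state_string over {M, I, D}; M consumes one protein residue and one model
position, I one residue, D one model position).  Stockholm input is
converted through the `#=GC RF` annotation.  Hits with E-value above 0.001
are ignored.  Projection rules:

* residue on a match column → that model position;
* residue on an insert column → the last match state before the gap
  (flagged `via_gap`); an insert run before the first match state does not
  project (the rule is undefined there) and is tallied;
* residue outside the hit's span → no projection.

One representative protein per gene: any Swiss-Prot entry beats any RefSeq
entry, the longest wins within a source (protein accession breaks exact
ties deterministically).  A variant covered by overlapping hits of the
*same* family counts once, through the hit with the smallest E-value
(leftmost envelope start on ties); hits of *different* families each
receive the event, since families are analyzed independently.

## Conservation and enrichment

Column conservation is the Shannon entropy `H_j = -Σ p(a_i,j) ln p(a_i,j)`
of the gap-excluded amino-acid frequencies in the family alignment column
(`0 ln 0 = 0`; X/U residues excluded).  The conserved rule is stated on a
conservation-oriented score, so we set `C_j = -H_j` and flag positions with
`C_j >= mean(C) + sd(C)` (ties inclusive; equivalently
`H_j <= mean(H) - sd(H)`).  Columns with fewer than two residues are
undefined and excluded from the mean/sd.  When sd = 0 every position would
pass trivially, so none is flagged and a warning is raised.  No sequence
weighting or window averaging is applied to the entropy.

Overlap between hotspot and conserved/annotated position sets is tested by
the two-sided Fisher exact test (scipy's hypergeometric enumeration;
zero-margin tables give p = 1 by convention), with the Haldane–Anscombe
+0.5 odds ratio reported when a cell is zero, Bonferroni correction
(`min(1, m·p)`) across features or terms, and a Pearson (point-biserial)
correlation as a complementary effect-size measure.  Overlap tests pool the
positions of all analyzed domains into a single universe per feature, one
p-value per feature.  Per-residue protein annotations are projected to
model positions through the same alignment machinery as variants; a model
position is annotated when any member protein carries the feature at a
residue aligning there.

## Synthetic data generator

`make_family` emits a seeded protein family: a random consensus of length
L, per-gene substitutions at rate 0.3, deletions (rate 0.02) dropping match
columns, and inserts (rate 0.02, geometric run lengths) between them, plus
an N-terminal flank (the envelope offset).  `plant_variants` draws each
position's count from ZIP(π=0.3, λ₀=0.5) — or Poisson(λ₁=8) at designated
signal positions — and scatters the events over member genes and synthetic
patients (default 200 per cohort), inverting the alignment map so the MAF
protein coordinates project back exactly; (gene, patient, position, alt)
tuples are kept unique so MAF deduplication preserves every event.  For
exact-truth-recovery fixtures the signal draw can be conditioned on a
minimum count (`min_signal_count`, typically 8): an unconditioned
Poisson(8) occasionally lands at 3–4 events, indistinguishable from
background by construction, which is a property of the draw rather than of
the caller.

What the generator does *not* emulate: trinucleotide mutation context,
phylogenetically realistic sequence divergence, gene length and expression
heterogeneity, patient-level mutation-burden variation, or hypermutators.
Passing tests therefore demonstrate statistical calibration and coordinate
bookkeeping under the model's own assumptions, not robustness to every
real-cohort artifact.

## Pipeline, bootstrap, reproducibility

The pipeline (CLI `oncodomains run`, or `run_pipeline` in Python) performs
map → fit → call → conserve → enrich and writes TSVs (hotspots, per-cancer
summary, fit diagnostics, conservation, enrichment) plus a JSON run report
that conserves the variant accounting (rows read = retained + each skip
category).  Every output starts with one `#` header line carrying version,
seed and config hash; reruns with the same config are byte-identical.
Cancer types are analyzed separately by default; `pooled: true` merges all
patients into one POOLED cohort before counting.

The stability analysis subsamples a fraction (default 0.75 and 0.50) of
patients — or, alternatively, of variant events — **without replacement**
(a fraction-of-the-cohort design is incompatible with classical
with-replacement bootstrap), repeats count/fit/call per replicate (default
100), and tabulates oncodomain and hotspot counts; on planted fixtures the
mean counts are monotone in the retained fraction.

All randomness flows through numpy Generators seeded from the configured
seed; nothing reads the wall clock into outputs.

## Problem sizes used in the checks

The calibration script draws 50 replicates × 200 families × 300 positions
(3,000,000 position counts) for the false-discovery proportion; parameter
recovery uses 100 replicates of 2,000 positions; the end-to-end fixture
uses 5 families of length 200 with 3 planted hotspots each (λ₁ = 8,
minimum planted count 8, 4 genes, 300 patients).  These sizes give
Monte-Carlo standard errors well below the tolerances being checked while
keeping a full run in minutes on one CPU.

## Known limitations

* The EM stand-in fixes one concrete estimator for the published fdr(t)
  contract; other estimators of the same mixture would give slightly
  different null parameters on sparse families.
* The alternative is a single Poisson; heterogeneous signal strengths
  within one family are absorbed imperfectly (calls remain valid because
  only the null side enters fdr's numerator).
* Nonsense/frameshift variants are excluded by default; including them
  (config) treats their protein position like a substitution's.
* No isoform-aware analysis: exactly one representative protein per gene.
* Genome-to-protein coordinate annotation is out of scope; input variants
  must already carry protein positions.
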