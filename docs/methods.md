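# Methods

## Sampling model and posterior

Tag counting is modelled as an urn process: each sequenced tag is a draw
whose chance of hitting a given gene equals that gene's mRNA abundance π,
so the count is `N ~ Binomial(T, π)` for a library of `T` total tags.
With a uniform Beta(1, 1) prior the posterior is conjugate:

    π | N, T ~ Beta(N + 1, T − N + 1)

with mean `(N+1)/(T+2)` (the rule of succession) and the prior recovered
at `N = T = 0`.  A gene absent from a library is treated as `N = 0` out of
that library's `T` — absence of a tag is an observation, not missing data
— giving the Beta(1, T+1) posterior.  The prior is fixed; no
hyperparameter is exposed.

## Replicate groups and pools

Two treatments of replicate libraries are supported, with different
semantics:

- **Group** (`A,B` in a question): the abundance distribution is the
  equal-weight mixture `(1/m) Σᵢ Beta(π; Nᵢ+1, Tᵢ−Nᵢ+1)`.  The mixture
  preserves between-library heterogeneity — it answers "a library drawn at
  random from this condition".  Weights are uniform by assumption; the
  package does not weight components by library size.
- **Pool** (`A+B`): counts and totals are summed before the posterior is
  formed, i.e. the libraries are treated as one longer sequencing run.
  Pooling shrinks the posterior variance (roughly halving it for two
  equal libraries) but discards between-library variation.

Mixture sampling uses the component-indicator method (uniform categorical
draw, then a beta draw from the chosen component), which is exact; with
m = 1 it degenerates to plain beta sampling.

## Question semantics and probability estimation

Questions follow the grammar
`clause (AND|OR clause)*` with `clause := operand (<|> operand)+`;
AND binds tighter than OR and parentheses group.  A chained comparison
`A < B < C` desugars to `A < B AND B < C`.  Only strict inequalities are
offered: the posteriors are continuous, so ties have measure zero and an
equality relation would be vacuous.

Each Monte-Carlo iteration draws one abundance per *distinct* operand and
evaluates every atomic comparison on those shared draws.  Shared draws are
a deliberate design choice: it is the only semantics under which a chained
comparison and its explicit conjunction are the same random variable, and
it makes the complement identity `p̂(A>B) + p̂(A<B) = 1` exact.  Draws are
generated in sorted operand-key order from a single seeded generator, so
two questions over the same operands and seed consume identical draws.

The default `n_sims` is 10,000, giving a worst-case Monte-Carlo standard
error of `sqrt(0.25/n) = 0.005`; the per-gene standard error
`sqrt(p̂(1−p̂)/n)` is reported alongside each estimate.  In the batch path
every gene receives an independent child seed derived from the run seed
and the gene's row index, so results do not depend on chunking.

Cutoffs are accepted as fractions or percents; any value in (1, 100] is
interpreted as a percent.  Ranking sorts by probability descending with
ties broken by gene id for reproducible output.

## Enrichment

Enrichment keeps the whole probability-weighted gene list rather than
thresholding it.  For a term with membership weights `w_g ∈ [0, 1]`
(crisp annotations have `w_g = 1`) the fuzzy contingency table over the
universe is

    n11 = Σ p_g w_g       n10 = Σ p_g (1−w_g)
    n01 = Σ (1−p_g) w_g   n00 = Σ (1−p_g)(1−w_g)

which reduces to the classical 2×2 table for crisp `p` and `w`.  The
association statistic is Yule's `Q = (n11·n00 − n10·n01)/(n11·n00 + n10·n01)`
in [−1, 1], defined as 0 when both products vanish; the statistic is a
pluggable callable should another association measure be preferred.

The null permutes the gene → p_g assignment over the universe, preserving
the annotation structure, and the p-value uses the add-one correction
`p = (1 + #{Q_null ≥ Q_obs})/(n_perm + 1)` so it is never zero and is
bounded below by `1/(n_perm+1)`.  `enrich_all` shares one set of
permutations across all terms (one permuted-probability matrix, evaluated
against every term's weight vector); `permutation_pvalue` for a single
term draws its own permutations from its seed, so the two paths agree in
distribution but not draw for draw.  Default `n_perm` is 1,000.
A Benjamini–Hochberg adjusted column is emitted, but threshold filtering
uses the raw permutation p-value by default.  The universe is the set of
genes present in the expression data after tag mapping — not the set of
annotated genes — so terms annotating no expressed gene are skipped with
a warning.

The functional screen is simpler: per term, the count of universe genes
with `p̂ ≥ cutoff`, every term listed (including zero counts), sorted by
count with ties broken by term id.

## Simulator

The generator emulates a counting-based expression experiment and is the
test bed for the whole pipeline:

| parameter | default | meaning |
|---|---|---|
| `n_genes` | 200 | genes per dataset |
| `n_conditions` | 3 | ordered biological conditions |
| `libraries_per_condition` | 1 | replicates per condition (mixture path when > 1) |
| `total_tags` | 100,000 | tags sequenced per library |
| `fraction_true_positives` | 0.1 | genes given a planted monotone profile |
| `effect_size` | 4.0 | multiplicative abundance step per condition |
| `baseline_range` | (1e-6, 1e-3) | log-uniform baseline abundance π |

Positives get abundance `π·s^k` in condition k; negatives keep π
everywhere.  Counts are binomial per gene and library — marginally
equivalent to multinomial tag sampling at the small abundances used, and
matching the per-gene binomial framing the posterior assumes.  If planting
pushes a library's total abundance above 1, abundances in that library are
renormalized with a warning.

What the simulator does *not* emulate: overdispersion beyond binomial
(library-preparation noise), correlated genes, tag-to-gene ambiguity, and
sequencing error.  Passing the detection benchmarks therefore shows the
estimator is correct under its own sampling model, not that real libraries
satisfy that model.

The comparator (`naive_pairwise`) is a transparent stand-in for classical
paired analysis: a one-sided pooled two-proportion z-test per adjacent
condition pair, combined as `min(1 − p)` over the pairs, so a gene scores
highly only if every step is individually significant.  It is a baseline
of our own construction, not a reimplementation of any published tool.
ROC curves use the standard threshold sweep with tied scores grouped; AUC
is the trapezoid area (equal to the Mann–Whitney concordance with ties
counted 1/2) and its uncertainty is a delete-one-gene jackknife.

## Numerical and interface choices

- Reported probabilities are the exact ratio `S_t/S_n`; nothing is
  smoothed or clipped.
- The reference study in `scripts/acceptance.py` uses `n_sims = 2,000`
  per gene for the 200-gene simulation and `n_sims = 10,000` for the
  single-pair checks; these sizes hold the Monte-Carlo error well below
  the effects being measured while keeping the runs quick.
- Count tables are plain TSV (header of library ids, first column gene
  ids, optional reserved `TOTAL` row carrying explicit library totals for
  data whose sequenced-tag total exceeds the retained-tag sum, `#`
  comments, transparent `.gz`).  Reading, writing and re-reading a table
  is the identity.
- The CLI writes results only to files, logs to stderr, and stamps every
  output with version, seed and a configuration hash; identical seeds give
  byte-identical outputs.

## Known limitations

- Equal mixture weights assume replicates are exchangeable; very unequal
  library sizes may warrant size-proportional weights, which are not
  implemented.
- Magnitude questions ("A at least 2-fold above B") and equality
  relations are unsupported.
- The enrichment null permutes probabilities over genes, which treats
  genes as exchangeable; gene-length or expression-level biases in
  annotations are not modelled.
- p-values are bounded below by `1/(n_perm+1)`; ranking among very
  significant terms falls back on the association value.
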