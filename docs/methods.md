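# Methods

## Model and guarantees

The ontology is a single-rooted DAG G = ⟨V, E⟩ with edges oriented parent →
child. A flat predictor assigns each gene a score vector ŷ ∈ [0, 1]^|V|; the
engines return ȳ with the true-path property: for every edge (j, i),
ȳⱼ ≥ ȳᵢ.

**Levels.** ψ(i) is the length of the *longest* directed path from the root,
computed in one topological sweep. Max-distance levels are a correctness
requirement, not an optimisation: with shortest-path levels two terms joined
by an edge can share a level, so the top-down pass may read a parent before
that parent has itself been lowered, leaving a violation.
`htd_correct`/`tpr_correct` therefore reject any level map that is not
strictly increasing along edges; `htd_correct(validate_levels=False)` exists
solely so the failure can be demonstrated (see
`test_max_distance_levels_are_load_bearing`, which constructs the minimal
shortcut DAG root→a, root→x, x→b, a→d, b→d exhibiting it — note a plain
diamond with one shortcut edge cannot, because there the shortcut parent is
never lowered after its child is processed).

**HTD-DAG.** ȳᵢ = ŷᵢ for the root, otherwise min(ŷᵢ, min_{j∈par(i)} ȳⱼ),
visiting terms by increasing ψ. By induction this equals
min over {i} ∪ anc(i) of ŷ, which is the closed form the tests check
exactly. Consequences exploited as test oracles: idempotence, identity on
consistent input, and ancestor dominance (every ancestor's corrected score
≥ the term's).

**TPR-DAG.** Two strictly separated passes. Bottom-up, by decreasing ψ:
ȳᵢ = (ŷᵢ + Σ_{j∈φᵢ} ȳⱼ)/(1 + |φᵢ|), where φᵢ are the positive children —
only positive child evidence propagates, because under the true path rule a
gene may genuinely be annotated to a parent but not to a particular child.
Top-down: exactly HTD on the intermediate scores, restoring consistency.
Under max-distance levels every child of a term sits at a strictly greater
level, so the bottom-up sweep always reads finished values; within a level
order is irrelevant.

Positive-children strategies (all strict comparisons; a child exactly at its
threshold is negative — ties-as-negative is the literal reading of the
selection rules, applied uniformly):

- **T**: ȳⱼ > t̄ with a constant t̄ (default 0.5, the natural choice when
  scores behave like probabilities);
- **AT**: ȳⱼ > t*ⱼ, where t*ⱼ maximises the per-term F-score of the rule
  (score > t) on training annotations over the grid {0.05, …, 0.95}
  (smallest grid point on ties). Thresholds are fitted on *flat* training
  scores: they must exist before the bottom-up pass runs, and fitting on
  partially corrected scores would make the fit depend on evaluation order.
  A cross-validated fit would also be legitimate; the direct fit is
  deterministic and cheap, and the choice is exposed through
  `fit_adaptive_thresholds`;
- **TF**: ȳⱼ > ŷᵢ — children that would raise the parent. TF never lowers a
  score, so TPR-TF dominates HTD entrywise and hence in per-term sensitivity
  at every threshold;
- **W**: ȳᵢ = w·ŷᵢ + (1−w)/|φᵢ|·Σ ȳⱼ over any of the three selections
  (default TF). With φᵢ = ∅ the rule is undefined (division by zero); we
  return ŷᵢ, the limit of the unweighted form, avoiding systematic shrinkage
  of leaves. w = 1 reduces bit-exactly to HTD;
- **D**: positives are drawn from all descendants, Δᵢ = {j ∈ desc(i) | ȳⱼ >
  tⱼ}, with equal contribution — this counters the exponential decay of a
  deep descendant's influence through repeated averaging. The per-descendant
  threshold tⱼ is not pinned down by the formulation; we default to the
  constant t̄, the simplest faithful reading, and the strategy is selectable.

**Weight tuning.** `tune_weight` assigns training genes to seeded folds
(permutation by `numpy.random.default_rng(seed)`, round-robin fold labels),
corrects each held-out fold with TPR-W at every grid weight, and returns the
weight maximising mean fold Fmax (smallest on ties). With the default TF
child selection nothing is fitted per fold, so folds act purely as
evaluation splits; the procedure is deterministic given the seed.

## Preprocessing

OBO parsing uses `obonet`; only `is_a` relationships become edges (the
phenotype hierarchies this targets are is_a-based), obsolete terms are
dropped, `alt_id` lines populate an alternate-id map used to remap stale
annotation ids, and an `is_a` target with no stanza is fatal. Multi-root
documents get a synthetic `VIRTUAL:ROOT` above the source roots; its flat
score is defined as 1.0 and it is stripped from CLI outputs, so per-term
results are unchanged.

Annotation tables are binary gene × term DataFrames, closed under ancestors
(`propagate_annotations`, idempotent; unknown terms are skipped with a
counted warning — when alt-id remapping merges two raw terms onto one
primary id their annotations are unioned).

`prune_terms` removes terms with fewer than `min_count` annotated genes and
re-attaches each survivor to its *nearest surviving ancestors* (computed by
propagating ancestor frontiers along a topological order). This preserves
both ancestor relations among survivors and reachability from the root,
which is never pruned. On a closed table counts are non-increasing along
edges, so ancestors of survivors always survive; the rewiring matters for
tables assembled from external sources.

`check_consistency` flags child − parent > 1e−9; the tolerance absorbs the
sub-epsilon noise that repeated averaging can introduce.

## Flat scoring utilities

Max normalisation divides each term column by its own maximum; quantile
normalisation maps every column onto the mean sorted profile (ties receive
the mean of their would-be reference values), with a flag to normalise
across genes instead — which axis "make scores comparable across terms"
implies is genuinely ambiguous, so both are exposed and columns-as-terms is
the default. Jaccard networks weight gene pairs by |∩|/|∪| of binary feature
profiles. `ua_integrate` min–max normalises each network onto [0, 1] (the
simplest map onto the common range; the integration rule itself is just the
unweighted mean) and averages entrywise over the unioned gene universe.

`kernel_average_score` is a deliberately plain network smoother — the mean
over a term's annotated genes of (D^{−1/2} W D^{−1/2})^steps, max-normalised
— included so the pipeline has an end-to-end flat learner. It is a generic
construction, not a re-implementation of any published ranking method, and
no result here depends on matching one.

## Evaluation

Gene-centric: at threshold τ a gene's prediction set is every term with
score ≥ τ (root excluded); precision is averaged over genes with nonempty
prediction sets among the N annotated genes (the empty set's precision is
0/0; a flag counts it as 0 instead), recall over all N. Fmax is the maximum
harmonic mean over the grid {0.00, 0.01, …, 1.00}, reporting the smallest
attaining τ*. Because τ* is chosen a posteriori, Fmax is an optimistic
summary. Note that at τ = 0 *every* term is predicted under the ≥
convention, so even a perfect predictor attains F = 1 only from the first
positive grid point.

Term-centric: AUROC via the Mann–Whitney statistic (ties count one half) and
AUPRC as the area under the precision–recall step curve, both delegated to
scikit-learn; single-class terms are reported as NaN and excluded from the
unweighted means with a warning.

Candidate nomination: keep terms with AUROC above a cut-off (default 0.95),
optionally leaves only; per term, sort genes by descending score (ties broken
lexicographically by gene id so the top-k set is well defined), take the top
k (default 5), and report the unannotated genes scoring ≥ the best annotated
gene in that set — all k when none is annotated. Ranking uses corrected
scores by default; pass flat scores to the same function to rank on them.

## Synthetic generator

`SyntheticSpec` defaults describe the benchmark condition used throughout:
300 terms over 6 levels, 400 genes, edge density 0.01, Poisson(4) seed
annotations per gene, Gaussian score noise σ = 0.3. The DAG is layered: the
root alone at level 0, remaining terms spread evenly, each term wired to one
parent in the level directly above (making its longest-path level exact)
plus extra shallower parents at the edge density — chosen low so the graph
stays as sparse as real phenotype ontologies, a term or two of extra parents
per node. Seed terms are sampled ∝ level + 1 so deep terms are annotated
often enough to exercise the bottom-up pass; uniform sampling concentrates
annotations near the root and trivialises correction. Noise is added in
score space and clipped to [0, 1] — the simplest model that keeps the
score-matrix contract; logit-space noise would avoid the boundary atoms at 0
and 1 but complicate the noise-free limit.

What the generator does *not* emulate: realistic fan-out and
annotation-frequency distributions, correlated noise between related terms,
and base-learner-specific score shapes. Passing tests therefore establish
the algorithmic contracts (consistency, dominance, degeneracies, metric
correctness) and that correction *can* help under label-correlated noise —
not effect sizes on real ontologies.

`holdout_experiment` splits genes (default 70/30, seeded), fits anything
fit-able (AT thresholds, the TPR-W weight when `tune_w=True`) on training
genes only, corrects the held-out genes' flat scores and returns paired
evaluation reports. The paired Fmax difference is reported without asserting
a sign: when flat scores are already near-perfect or hopeless, correction
cannot improve them, only make them consistent.

## Numerical and degenerate-input choices

- Flat scores outside [0, 1] are fatal; silent rescaling would change
  semantics. `normalize_max` is available when rescaling is intended.
- All floating-point output is printed with 10 significant digits, making
  write→read→write byte-stable.
- Every randomised step (generators, fold assignment, splits) is a pure
  function of an explicit integer seed; CLI runs record seed, parameters and
  input digests in a JSON manifest next to each output.
- Empty positive sets, all-zero score columns, single-class terms,
  single-column quantile normalisation and fewer genes than `top_k` all have
  defined, warned behaviour rather than exceptions, except where the result
  would be meaningless (no annotated genes; empty positive gene set).

## Problem sizes

The test suite sweeps 100 random instances up to 500 terms × 200 genes for
the consistency guarantee, 50 instances for the closed-form and dominance
checks, and 5 seeds of the 300-term hold-out; `scripts/acceptance.py` runs
the same sweeps plus the hold-out at 20 seeds. These sizes give stable means
(the paired Fmax difference has a standard deviation well under 0.01 across
seeds) while the whole suite stays in the tens of seconds.

## Known limitations

- Only `is_a` edges are honoured when parsing OBO; `part_of` and other
  relationship semantics are out of scope.
- AT thresholds are fitted on flat training scores; fitting on corrected
  training scores (a legitimate alternative) is possible by passing
  `training_scores` explicitly.
- The evaluation suite implements the gene-centric protocol with the ≥ τ
  prediction-set convention throughout; no embedded-threshold (unbiased)
  variant of Fmax is provided.
- Alternative child aggregations (e.g. maximum instead of average) are not
  implemented.
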