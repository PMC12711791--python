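# Methods

This note documents the model implemented by `gd2flux`, its assumptions,
the tunable parameters, the numerical choices, and what the synthetic
study used in the tests does and does not establish.

## Model

### Metabolic graph

The glycosphingolipid biosynthesis network is a directed, metabolite-
centric multigraph: nodes are metabolites, edges are enzymatic reactions
annotated with a gene–protein–reaction (GPR) rule. Parallel edges between
one metabolite pair are allowed when their reaction IDs differ.
Degradation reactions (GM1→GM2, GM2→GM3) are excluded at construction:
they run against biosynthesis and must not enter the branch-competition
normalization below. Reversible reactions from KGML input are expanded
into two directed edges (`_f`/`_r`), because transition probabilities are
defined on directed edges only. Every edge ordering used anywhere
(matrix columns, outgoing-edge sets) is lexicographic by reaction ID, so
all order-dependent computation is reproducible.

The bundled pathway definition is the ganglio-series neighborhood of GD2
(the GM3 and GD3 branch points plus the linear stem from ceramide), built
programmatically with real KEGG reaction IDs and HGNC enzyme symbols. A
genome-scale snapshot of the four sphingolipid KEGG pathways is *not*
shipped; users supply their own KGML files or declarative JSON for larger
graphs.

### Reaction Activity Scores

For one sample with per-gene expression g ↦ x_g (normalized counts,
log10-transformed), a reaction's activity is its GPR rule evaluated
arithmetically: `AND` → minimum over operands (a complex is limited by
its scarcest subunit), `OR` → sum (isoenzymes contribute additively),
recursively over the parse tree. `AND` binds tighter than `OR`;
parentheses override. Genes absent from the data contribute 0 by default
(sum-neutral for `OR`, dominating for `AND` — an unobserved subunit
silences its complex); a strict mode errors instead. Reactions with no
GPR get constant activity 0 rather than NA, keeping matrices dense and
the transition probabilities well defined.

GPRs are evaluated on log-scale values. `OR`-as-sum is not scale-
invariant under the log transform, so the transform's placement matters:
here normalization and log10 always precede RAS, and the same order must
be used for training and prediction.

### Transition-probability adjustment

Per sample, each edge e = (x → y) gets

    P_e = r_e / Σ_{e′ ∈ ε_x} r_{e′},

where ε_x is the set of outgoing edges of x. The adjusted weight is
r_e^TP = r_e · P_e: a promiscuous enzyme's activity is partitioned across
the branches competing for its substrate. If a node's outgoing RAS sums
to zero, all its P_e are set to 0 — the adjusted weight is 0 either way,
and this avoids 0/0.

On linear stretches P_e = 1 structurally, so the plain adjustment cannot
differentiate positions along a series. The recursive variant rewrites
each *structural* unit probability (sole outgoing edge with positive
activity) with the nearest upstream non-unit transition probability,
walking the chain of unique predecessors toward the branching node:

    P̃_e = P_{e_j} for the smallest j with P_{e_j} ≠ 1,   r_e^TPrec = r_e · P̃_e.

Boundary rules (all deliberate, as the recursion is defined only for
linear series stretches):

* a multi-edge node that merely concentrates all RAS on one edge keeps
  its P_e — only structural unit probabilities trigger the walk;
* a source-rooted pure chain (no branching anywhere upstream) keeps
  P̃_e = 1;
* if the walk reaches a node with several incoming edges, the edge keeps
  P_e and a warning is logged;
* a cycle during the walk is an error.

The rule is applied graph-wide wherever a unique upstream chain exists,
not only inside the four ganglioside series. Both adjustments are
per-sample, with no cross-sample smoothing, and are invariant to scaling
a sample's whole RAS row (probabilities are ratios).

### Features, SVM, GD2 score

Two features per sample: Σ GD2r⁺ = summed activity of the GD2-promoting
reactions (R05946: GD3→GD2, R05940: GM3→GD3) and Σ GD2r⁻ = summed
activity of the mitigating reactions (R05939: GM3→GM2, R05948: GD3→GT3,
R05947: GD2→GD1b, R05941: GM2→GM1). An SVM is trained on labels 1
(neuroblastoma-like) vs 0 (normal-tissue-like). The GD2 score is the
decision value; for the linear kernel it equals w·scaled(x) + b, the
signed distance from the hyperplane (up to ‖w‖), and is interpretable:
w₁ > 0, w₂ < 0 means the score rises with promoting and falls with
mitigating activity.

Defaults: linear kernel, C = 1, z-score feature scaling fitted on
training data and frozen (the constants are stored in the model file and
reused verbatim at prediction). Linear is the default for
interpretability and robustness in this two-dimensional feature space;
rbf/polynomial/sigmoid/laplacian kernels are available. No class
weighting by default (an option exists): the intended training contrast
is deliberately fitted unweighted. Predicted class is 1 iff the score is
strictly positive; a score of exactly 0 classifies as 0, a deterministic
tie-break on a measure-zero event.

Models persist to JSON (scaling constants, support vectors, dual
coefficients, and for the linear kernel the explicit w and b). Decision
values are always computed from these stored arrays — not via the
training-time solver object — so a saved and reloaded model reproduces
scores bit-identically.

### Frozen normalization

Median-of-ratios with a frozen reference. From training counts x_ij the
fit stores per-gene geometric means g_i over the "usable" genes (strictly
positive in every training sample) and the per-training-sample ratio
medians m_j = median_i x_ij / g_i. A new sample x\* gets

    m* = median_i x*_i / g_i   (over shared usable genes),
    s* = m* / mean_j(m_j),

and normalized values x\*/s\*. Dividing by the mean of the training
medians makes the average training size factor 1, so training and
prediction land on one scale; a `sum` denominator is available as a
config switch (the two differ by the constant n). Genes present in the
reference but missing from the new data are dropped from the median (the
median is robust to moderate missingness); below 50 % overlap a warning
is emitted. Log transform is log10(x + 1) by default — the pseudocount
preserves zeros and is configurable.

## Parameters that matter

| parameter | default | units / range | why |
|---|---|---|---|
| pseudocount | 1 | counts | zeros map to zeros under log10 |
| denominator | mean | mean/sum of m_j | average training size factor = 1 |
| missing gene policy | zero | zero/strict | conservative: silences complexes |
| kernel, C | linear, 1 | — | interpretable two-feature model |
| scaling | scaled | raw/scaled/ranged | z-score, frozen from training |
| permutation N | 10,000 | draws | empirical p resolution 1/N |
| p-value convention | strict | strict / (c+1)/(N+1) | count(permuted > observed)/N |
| CNA min cell size | 5 | samples | testable status levels only |
| CNA gates | adj p < 0.05 and η² > 0.06 | — | moderate-or-stronger associations |

## Evaluation machinery

Metrics come from the confusion matrix with positive class 1; balanced
accuracy is computed as (recall + specificity)/2 so the identity is
exact. ROC curves use the threshold sweep over unique scores; the PR
area uses step interpolation (average precision), which avoids the
optimistic bias of trapezoids on imbalanced data. The permutation test
draws 2 promoting + 4 mitigating reaction labels uniformly without
replacement per iteration from all graph reactions (overlap with the
curated set allowed by chance — a uniform null), retrains the configured
SVM, and reports p = #(permuted metric > observed)/N per metric;
degenerate iterations record 0 and still count.

Group statistics: Wilcoxon rank-sum (exact enumeration when both n ≤ 10
without ties, otherwise the tie-corrected normal approximation without
continuity correction, so the two-group Dunn and Kruskal–Wallis
identities hold exactly); Cliff's δ = (#{a>b} − #{a<b})/(n_A n_B);
Kruskal–Wallis with η² = (H − k + 1)/(n − k) floored at 0 (slightly
negative values at tiny H are not interpretable); Dunn's z with the
pooled tie-corrected rank variance; Benjamini–Hochberg step-up for
multiplicity. In the CNA screen, BH is applied within each subgroup
across its tested genes — subgroups are analyzed separately, so the
family is the subgroup's gene list.

## Synthetic study

The generator stands in for a real tumor/normal training cohort. Study
conditions (fixed defaults): 50 + 50 samples, a 4-fold expression shift
of the class-defining enzymes, lognormal noise sd 0.3, libraries uniform
in 200k–400k over ~100 genes (9 pathway genes + 80 background genes used
by the normalizer). Counts follow a lognormal-Poisson hierarchy: gene
baselines are lognormal, each sample multiplies them by lognormal noise
and the class effect, and counts are Poisson at the sample's library
size. Class 1 shifts the promoting-side enzymes (ST8SIA1, B4GALNT1),
class 0 the mitigating-only enzymes (B3GALT4, ST8SIA3); B4GALNT1 sits on
both sides of the reaction split and moves in class 1 only, reproducing
the enzyme-promiscuity ambiguity the TP adjustment targets.

What passing tests show: the pipeline's contracts hold (oracle
equivalence of the GPR evaluator, per-node conservation of transition
probabilities, exact recursive propagation, frozen-normalizer
self-consistency, linear-SVM affine scoring, permutation-p calibration
under the null) and the method recovers a planted promoting/mitigating
signal essentially perfectly. What they do not show: performance on real
tumors — the generator has no batch effects, no correlated co-expression
programs, no negative-binomial overdispersion, and a far cleaner class
structure than tissue data; observed balanced accuracies near 1.0 on the
fixture say nothing about accuracy on real cohorts.

Problem sizes used by the test suite and the acceptance script (chosen
to keep the full run desk-scale): 1,000 random GPR trees; 500 random
DAGs; 200 branching-chain graphs; permutation calibration with 200
repetitions at N = 200 (30 + 30 null samples) and one informative run at
N = 1,000; CNA null calibration with 1,000 replicate 6-gene screens.

## Known limitations

* The recursive-TP rule is undefined for non-linear upstream structure;
  the fallback (keep P_e, warn) is a design choice, not derived.
* OR-as-sum on log-scale values ties RAS to the normalization pipeline;
  do not feed linear-scale expression.
* The two-feature SVM inherits the biases of its training contrast; a
  model trained on a neural-crest tumor vs normal contrast may overstate
  scores in other lineages.
* The CNA screen is association, not dosage mechanism: co-amplified
  neighbors can carry the signal.
* Single-sample prediction works (frozen normalization needs no cohort),
  but the score's scale is only as comparable as the gene overlap with
  the frozen reference.
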