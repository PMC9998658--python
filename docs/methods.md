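# Methods

This note records the models, the tunable parameters, the numerical
choices, and what the synthetic-data generator does and does not
emulate.

## The filtering model

The input is a MaxQuant-style protein-groups matrix of LFQ intensities
over runs, each run belonging to one condition — a (genetic context,
culture context, concentration) triple — or to the bead-only control.
The full design crosses four genetic contexts with eleven culture
contexts (unstimulated plus five stimuli at 20 and 200 ng/ml), each with
three biological and two technical replicates: 44 conditions, 264 sample
runs.

Filtering runs five steps in a fixed order:

1. **Flag removal.** Proteins flagged "only identified by site",
   "potential contaminant" or "reverse" are dropped.
2. **Zero removal.** An LFQ intensity of 0 is a non-observation, not a
   measurement; zeros become missing values.  Until this step the loader
   deliberately keeps 0 for both absent and zero cells, so the
   missing/zero distinction has a single, auditable origin.
3. **Outlier runs.** A run is removed if it observes fewer than
   `min_proteins` proteins (default: half the cohort median count) or if
   its median log2 intensity falls more than `mad_k = 3` robust SDs below
   the cohort median of run medians.  The robust SD is 1.4826 x MAD with
   a floor of 0.1 log2 units — without the floor, a cohort of
   near-identical runs has a vanishing MAD and trivial fluctuations get
   flagged.  The analogous step in practice is often done by eye from
   per-run histograms; making it a rule keeps the pipeline deterministic.
4. **Presence.** Within each group (the ≤ 6 runs of one condition, or
   the control group), a protein is kept only if observed in ≥ 60% of
   the group's *remaining* runs — the denominator excludes runs removed
   in step 3, since a removed run carries no evidence.  A protein is
   dropped globally only if it survives in no group.
5. **Control enrichment.** Each condition is tested against the bead
   control on log2 intensities.  Missingness is classified per
   (protein, group): missing in *all* runs of a group while observed
   elsewhere is MNAR (below-detection); any other missing cell is MAR.
   MAR cells are imputed by k-nearest-neighbour regression among
   proteins (k = 10, Euclidean distance over shared observed runs,
   distance-weighted mean; column-median fallback with a warning when
   fewer than k neighbour proteins exist).  MNAR cells are imputed at
   the dataset's minimum observed log2 intensity — a below-detection
   floor.  Imputing at a literal 0 is also supported
   (`strategy_mnar` / the imputation scale is configurable) but the
   floor is the default: on the log2 scale a literal 0 is an extreme
   outlier that would dominate every variance estimate, while the floor
   preserves the "below detection" semantics.  The test is a moderated
   two-group t (below) with BH adjustment across proteins within the
   condition; the called set is `p_adj < 0.01 and log2 FC > 1`.

Technical replicates are then merged per biological replicate with the
median over observed values (all-missing stays missing).

## Moderated t

Per protein, the pooled two-group variance `s²` with `d = nA + nB − 2`
degrees of freedom is shrunk toward a prior:

    s²_post = (d0·s0² + d·s²) / (d0 + d)
    t = logFC / (s_post · sqrt(1/nA + 1/nB)),   df = d + d0

The prior (d0, s0²) is fitted by method of moments on the log sample
variances: with `e = log s² − ψ(d/2) + log(d/2)`, the model implies
`Var(e) = ψ′(d/2) + ψ′(d0/2)` and `E(e) = log s0² − ψ(d0/2) + log(d0/2)`
(ψ, ψ′ di-/trigamma).  d0 comes from a Newton inversion of the trigamma
function; it is capped at 1e6 when the observed log-variance spread is
at or below the pure-sampling expectation (homoscedastic data), where
the statistic degrades gracefully to a z-like test.  At d0 = 0 the
statistic is exactly the classical pooled t — the suite asserts this
limit, and asserts empirical type-I error within [0.04, 0.06] at
α = 0.05 on a 2,000-protein heteroscedastic null.

Multiple testing: BH is the standard step-up with cumulative-min
monotonisation; Hommel is the standard closed algorithm.  Both are
verified against exhaustive references (definitional BH; closed testing
with Simes local tests) on vectors of length ≤ 8.

## Factorial ANOVA and Tukey HSD

The per-term scan fits a three-way factorial ANOVA (genetic context,
culture context, concentration; all interaction orders) with **Type-II
sums of squares**, chosen because post-filter designs are unbalanced.
The implementation compares nested least-squares fits: SS of term T is
the residual-SS drop when T joins the model of all terms not containing
T; degrees of freedom are design-matrix rank increments, so aliased
terms (e.g. the culture x concentration interaction, since
"unstimulated" only occurs at concentration "none") get df = 0 and are
dropped with a note rather than producing spurious F statistics.  A
residual SS that is numerically zero flags the result degenerate.  The
"culture context" of the study design is modelled as two factors —
stimulus identity and concentration — which is what makes the ANOVA
three-way.

Per-term ANOVA p-values are corrected *collectively* (all terms x all
effects in one family) with Hommel; terms with an adjusted effect
p < 0.05 get Tukey–Kramer pairwise tables for their significant main
effects (studentized-range p-values at the ANOVA's residual df,
unbalanced-safe SEs), and all Tukey p-values are BH-corrected as one
family.  Terms backed by fewer than 3 annotated identified proteins are
excluded from the scan for stability and reported.

Term profiles are log2(x+1)-transformed before the ANOVA; the collapse
itself sums raw-scale intensities of all annotated identified proteins
per term per sample after propagating annotations to ancestors
(true-path rule).

## GSEA

Weighted KS running sum over the score-ranked gene list (weight
`|score|^p`, p = 1 by default); ES is the signed maximum deviation.  The
null permutes gene labels — random same-size sets — because the
per-condition design has too few samples for phenotype permutation.
`p_perm = (1 + #{|ES*| ≥ |ES|}) / (n_perm + 1)`; NES divides ES by the
mean |ES*| of the same sign; BH across terms gives the FDR.  A gene set
equal to the whole universe returns the degenerate ES = 0; sizes outside
[3, N−3] are rejected.

## Semantic similarity and binary cut

Wang's measure: S-values of a term's ancestor set are propagated
multiplicatively along parent edges (weights 0.8 for `is_a`, 0.6 for
`part_of`, max over paths); similarity of two terms is the sum of both
S-values over common ancestors divided by the sum of all S-values.  The
implementation is checked against a brute-force all-paths oracle on
small DAGs.

Binary cut clusters the similarity matrix recursively: a term subset
stays one cluster when its coherence — the mean of its similarity
submatrix, diagonal included — reaches the cut threshold (default
0.85); otherwise it is split in two by average-linkage hierarchical
clustering (cut by merge order, so tied heights still split) and both
halves are recursed on.  Published descriptions of binary cut differ in
the exact score; this recursive-coherence variant is one concrete,
deterministic choice.  Under it the cluster count is monotone
non-decreasing in the threshold (a higher threshold demands more
coherence, forcing deeper splits), which the suite asserts.

## Biased targeted random walks

The network is built from a weighted edge list by removing edges with
confidence < 0.7 (the threshold itself survives), keeping nodes within
shortest-path distance 4 of the effector layer, and attaching the bait
source to the effectors by directed edges only; all other edges are
undirected and the source is never re-entered.  The step rule favours
nodes in the condition's called-interactor set by a factor of 20
(normalised over the neighbourhood); a walk's budget is
`shortest_path(source, target) + 2` steps, and it succeeds on reaching
the target.  Walks may revisit nodes — the bias rule is memoryless and
nothing in the procedure forbids revisits; an optional non-revisiting
sampler exists but is off by default.  "Iterations exceeded" is read as:
the walk fails after `walklen` steps without absorption.

Paths below frequency 1e-6 (the scale-free form of 100 per 1e8 walks)
are dropped and the top 10 per target kept, ties broken toward shorter,
then lexicographically earlier paths for determinism.  Retained paths
decompose into frequency-weighted edges (condition networks) and
per-effector traversal weights; traversal is frequency-weighted by
default because frequencies are scale-free in the number of walks, with
a raw path-count mode available.

`enumerate_paths_exact` expands the identical process symbolically
(depth-limited, absorbing at the target, guarded at 1e6 partial states)
and is the sampler's oracle: at 10^6 walks on ≤ 8-node graphs every path
frequency sits within three binomial SEs of its exact probability and
the total-variation distance is below 0.01.

## Synthetic data

`simulate_lfq` emulates: log2-normal background intensities
(`baseline_mu = 25`, `baseline_sigma = 2`, typical of MaxLFQ output)
shared with the bead controls; per-(condition, biological replicate)
effects (`sigma_bio = 0.5`) shared across technical replicates, plus
per-run noise (`sigma_tech = 0.25`); per-condition true interactors
(5% of proteins) spiked by `enrichment_logfc = 3.0` log2 units in that
condition's sample runs only — a typical specific-versus-bead enrichment
and comfortably above the logFC > 1 call cutoff; intensity-dependent
MNAR dropout (logistic in −log2 intensity, width 1 log2 unit, midpoint
calibrated by bisection so the realised rate matches `mnar_rate = 0.15`)
and uniform MAR dropout (`mar_rate = 0.05`), disjoint, written as 0 as a
MaxQuant export would show them.  Bead controls share the background but
never receive spikes.

It does **not** emulate peptide-level identification,
match-between-runs, retention-time structure, correlated contaminant
blocks, or intensity-dependent variance — so passing recovery tests
demonstrate that the pipeline's logic is correct under its own
statistical assumptions, not that those assumptions hold for any
particular instrument.

`simulate_network` uses preferential attachment with edge confidences
Uniform(0.5, 1) so the 0.7 filter removes a real fraction;
`simulate_go` grows a rooted DAG (each term under 1–2 existing parents,
20% `part_of` edges) with 1–5 leaf annotations per gene.  All generators
are fully determined by their seed.

## Problem sizes and defaults

The default simulation is the full 44-condition design at 300 proteins.
Repeated-run analyses (filter calibration and recovery, per-term ANOVA
recovery) use a reduced 2 genetic x 3 culture grid with 200 proteins
and 25 terms over 10 seeds — large enough for stable rates, small
enough to keep the whole suite fast on one CPU.  Walk ensembles default
to 1e5 walks per target in the pipeline (1e6 in the oracle-equivalence
checks), with the path-frequency threshold held at its scale-free value
1e-6.

## Known limitations

- The outlier-run rule replaces a visual-inspection step with explicit
  thresholds; on real cohorts `min_proteins` and `mad_k` may need
  adjustment.
- The MNAR/MAR classification (group-wise all-missing ⇒ MNAR) is the
  common heuristic for mixed imputation, not a likelihood-based label.
- The functional-analysis imputation pairing is configurable; the
  default for that stage follows the low-rank ("bpca"-style) route for
  MNAR and MinProb for MAR as specified for the collapse analysis, even
  though the reverse pairing is more common in the imputation
  literature.  The low-rank imputer is an EM-style iterated rank-2 SVD
  (tolerance 1e-6, ≤ 500 iterations), deterministic from its row-mean
  initialisation.
- Walk results are comparable across conditions for a fixed target set
  and network; shorter paths are intrinsically favoured, so comparisons
  across targets with different shortest-path lengths are biased.
- Paper-scale inputs (a full STRING dump, deep MS cohorts) are out of
  desk scope; nothing here reproduces production-scale network sizes.
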