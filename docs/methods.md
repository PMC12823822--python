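# Methods

## Model and assumptions

`kg2ml` treats disease-gene discovery in a knowledge graph as a
positive–unlabeled (PU) classification problem. Genes reached from a
disease anchor by the 2-hop metapath `Disease – Compound – Gene` are
labeled positive; genes reached from those positives via
`Gene – EFO – Gene` but lacking a compound path are unlabeled — a mixture
of hidden positives and true negatives in unknown proportion α. All
inference rests on one assumption:

**SCAR (Selected Completely At Random).** The labeled positives are an
i.i.d. sample of the positive class: whether a positive gene is labeled is
independent of its feature vector. The compound-mediated labeling rule is
what makes this plausible — a gene acquires the label through
pharmacological curation, not through the EFO profile used as features.
Under SCAR the density of classifier scores on the unlabeled set
decomposes as

    f_u(s) = α · f_p(s) + (1 − α) · f_n(s),

so α is identified as the largest value with `α · f_p ≤ f_u` everywhere
(the negatives' density can only add mass). Everything downstream — the
excess-mass estimator, the calibration constraint, the imputation rule —
realizes this identity.

Metapath semantics are deliberately minimal: relationship types are
ignored (any edge counts), traversal is undirected, results are
set-valued, a gene reachable both as a positive and via an EFO path is
positive only, and multi-CUI disease queries union their anchors'
results. Direct Disease–Gene edges do *not* make a gene positive; only
the compound path does, because a direct-association label would be
correlated with the gene's feature profile and break SCAR.

## Feature encoding

Features are the EFO terms mediating the second metapath: binary
adjacency indicators, one column per term, in CSR storage. No weighting,
degree normalization, or embedding is applied — binary path indicators
keep every feature interpretable as "shares ontology term *t* with a
known disease gene". All-zero rows are retained: dropping genes without
EFO links would silently shrink the unlabeled set and bias α. Columns
never observed in any gene are pruned by default (`min_count=1`);
compounds exported by the labeling stage are excluded from the feature
vocabulary altogether.

## The class-prior estimator

Per iteration *i* (seed = `base_seed + i`, data fixed):

1. **Out-of-fold scores.** Stratified 5-fold cross-fitting with an
   XGBoost classifier (`max_depth=4`, `eval_metric=logloss`, single
   thread, all else at library defaults). Depth is the one
   hyperparameter that materially moves the prior estimate; every gene is
   scored by the fold model that never saw it.
2. **Densities.** Histogram densities of positive and unlabeled scores on
   a shared grid over [0, 1]; `auto` bin count = `max(20, ceil(sqrt(N)))`
   capped at 200, with N the pooled sample size.
3. **Excess-mass curve.** On the α grid {0, 0.001, …, 1}:
   `err(α) = Σ_bins max(α·f_p − f_u, 0)·Δx`. Each term is convex and
   non-decreasing in α, hence so is `err`; it is ≈ 0 while α is
   admissible and climbs once `α·f_p` overshoots `f_u`.
4. **Knee.** The estimate is the grid point maximizing the second
   difference of `err` taken over a `knee_window` of 0.075 α-units
   (75 grid steps). Adjacent-step differences see only histogram noise,
   because the per-bin density-ratio crossings that bend `err` are
   scattered; aggregating curvature over a wider window localizes the
   knee while staying narrow relative to the grid. The window width was
   fixed by a calibration sweep against generators with known α (bias
   insensitive across windows 0.05–0.15; 0.075 chosen as the midpoint of
   the stable range). `err` is padded with zeros on the left so the slope
   jump at α = 0 is a knee candidate: with disjoint score supports `err`
   is exactly linear from the origin and that boundary holds all the
   curvature. If even α = 1 incurs no excess mass the unlabeled set is
   indistinguishable from pure positives and the estimate is 1.
5. **Calibration.** A single scalar logit shift *c* applied to the raw
   unlabeled scores, with *c* solved by root bisection so that
   `Σ calibrated = α_i · |U|` (relative tolerance ≪ 1e-6). This is the
   minimal monotone map satisfying the SCAR expected-count constraint;
   rank order is preserved by construction. Scores are clipped to
   `[1e-12, 1 − 1e-12]` before the logit. α = 0 maps everything to 0 and
   α = 1 to 1 exactly.

Across iterations (default 40) the only re-drawn randomness is the CV
fold assignment and classifier seed. The α point estimate is the mean;
the 95% CI is the empirical 2.5/97.5 percentile band of the per-iteration
values. Calibrated probabilities are calibrated per iteration and then
averaged per gene (not averaged-then-calibrated): each iteration's
probabilities then individually satisfy that iteration's α constraint,
and the average inherits the mean constraint.

**Imputation rule.** Probable positives are the top `⌈mean_α · |U|⌉`
unlabeled genes by mean calibrated probability, ties broken
lexicographically by CUI. This is a design choice — any monotone cut at
the α-implied count is consistent with the calibration — made explicit in
the `rule` string of every `ImputedSet`.

## Two-model evaluation

Model 1 trains positives vs. all unlabeled; Model 2 first flips the
imputed genes to class 1. Both use the identical repeated stratified
5-fold protocol, classifier, and seeds, so Model 2 with an empty imputed
set is bitwise Model 1 (a regression guard in the tests). Recall is
computed **only over the original labeled positives** at threshold 0.5 —
the single set whose class is known. The auxiliary metrics (accuracy,
precision, F1, AUROC) are computed against each model's *working* labels
(unlabeled = negative), a convention stated in the output metadata; they
are descriptive, not ground-truth scores, since the working negatives are
partly positive by construction. CIs are empirical percentiles over the
repeats, matching the α CI convention.

## Synthetic benchmark

The generator plants ground truth the real graph cannot provide. Genes
carry one of two EFO-link profiles — positive: Bernoulli(`p_signal=0.35`)
on 40 signal terms plus Bernoulli(`p_background=0.05`) on 260 background
terms; negative: background everywhere — with every entry flipped at
`flip_noise=0.05`. Positive-profile genes split into labeled positives (a
uniform random subset, so SCAR holds by construction) and hidden
positives; only labeled positives are wired `Disease–Compound–Gene` (1–3
compounds each). Hidden counts are set so the hidden fraction among
nominal unlabeled genes equals `true_alpha`. Default sizes — 6,000 genes,
1,200 labeled positives, 300 features — mirror the per-disease scale of
condensed biomedical KGs (a couple of thousand labeled genes, several
thousand unlabeled, a few hundred path features) at a cost that keeps
repeated-CV experiments to seconds.

What the generator does **not** emulate: realistic ontology topology
(EFO terms are exchangeable; real term usage is heavy-tailed and
hierarchical), relationship-type vocabularies and provenance
distributions, feature correlation structure beyond the two-profile
mixture, and any violation of SCAR (e.g., study-bias labeling). Passing
the recovery tests therefore shows the estimator is correct *under its
own assumptions* at realistic scale — not that α estimates on a real
graph carry the same accuracy, where SCAR holds only approximately and
the mixture is not two clean profiles.

## Numerical choices and degenerate inputs

- α grid step 0.001; knee window 0.075; histogram `auto` bins as above.
- Zero-mass densities raise; empty score vectors raise; an empty feature
  set raises (nothing to learn from); zero extracted positives is an
  explicit error since the pipeline cannot proceed.
- The knee clamp means estimates above `1 − knee_window` are only
  reachable through the exact-dominance branch (estimate 1); planted
  fractions that extreme are outside the generator's validated range
  (`true_alpha < 1` by contract).
- Parallel edges collapse to one adjacency entry (multiplicity retained
  in the edge list only); self-loops are dropped; traversal ignores edge
  direction while records preserve it.
- All orderings are deterministic: positives-then-unlabeled rows, each
  block CUI-sorted; CUI-sorted feature columns; lexicographic tie-breaks
  in ranking and imputation. XGBoost runs single-threaded with a fixed
  seed, so full pipeline re-runs are byte-identical.
- Problem sizes in the test and acceptance runs: prior recovery at 5,000
  genes × 10 iterations per grid point, the end-to-end comparison at
  6,000 genes × 20 repeats — sizes at which the mean estimate is stable
  while the full suite stays fast; the reported 95% CIs use 40 iterations
  only where CI width itself is the quantity of interest.

## Known limitations

- The α knee is a point estimate on a noisy convex curve; at small
  unlabeled counts (≲ 1,000) per-iteration estimates scatter widely and
  only the CI is informative (the worked example in the README shows
  this regime deliberately).
- Calibration by a global logit shift adjusts level, not shape; if the
  classifier is badly mis-ranked no monotone recalibration can fix it.
- The imputation count `⌈α·|U|⌉` inherits α's error: an overestimated α
  imputes false positives, which the two-model comparison will partially
  mask because recall is measured on labeled positives only.
- Multi-CUI disease anchors are unioned, not merged into one concept;
  genes linked to different CUIs of the same disease are all positives,
  but their compound sets are tracked jointly.
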