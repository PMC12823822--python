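# kg2ml

Knowledge-graph metapath labeling and positive–unlabeled (PU) learning for
disease-gene discovery.

## The problem

Biomedical knowledge graphs record *known* gene–disease associations, so
the absence of an edge between a gene and a disease does not mean the gene
is unrelated — only that no study has linked them yet. Treating all
unlinked genes as negatives therefore trains classifiers on corrupted
labels. `kg2ml` instead treats the problem as PU learning: genes with a
known path to the disease are positives, everything else is *unlabeled*,
and the task is to estimate which unlabeled genes are hidden positives.

The pipeline, for one disease anchored at one or more UMLS CUIs:

1. **Condense** the heterogeneous property graph to the node types that
   matter (Disease, Compound, Gene, EFO).
2. **Label** genes by two fixed 2-hop metapaths:
   positives via `Disease – Compound – Gene`, unlabeled via
   `PositiveGene – EFO – Gene`. Routing the positive label through
   compound nodes keeps labeling independent of a gene's feature profile
   — the SCAR (Selected Completely At Random) assumption the estimator
   needs. The mediating Experimental Factor Ontology (EFO) terms become
   the feature vocabulary; the compounds are recorded and barred from it.
3. **Featurize**: a sparse binary matrix `X ∈ {0,1}^{n×m}` with
   `X[i,j] = 1` iff gene *i* is adjacent to EFO term *j*, stored in CSR /
   MatrixMarket form.
4. **Estimate α**, the fraction of hidden positives among the `|U|`
   unlabeled genes. Under SCAR the score density of the unlabeled set
   decomposes as `f_u = α·f_p + (1−α)·f_n`, so α is the largest value with
   `α·f_p ≤ f_u` everywhere. The estimator scores every gene out-of-fold
   with a gradient-boosted classifier (XGBoost, `max_depth=4`, log-loss),
   forms histogram densities of the positive and unlabeled scores, and
   takes the knee of the excess-mass curve
   `err(α) = Σ_bins max(α·f_p − f_u, 0)·Δx`.
   Repeating over re-seeded 5-fold CV assignments yields a mean α and an
   empirical 95% CI.
5. **Calibrate** the unlabeled scores by a single logit shift so that the
   expected number of positives among unlabeled equals `α·|U|`, average
   the per-gene probabilities over iterations, and **impute** the top
   `⌈α·|U|⌉` genes as probable positives.
6. **Evaluate** the gain: a baseline classifier (positives vs. all
   unlabeled) against one where imputed genes are flipped to class 1,
   both under repeated stratified 5-fold CV, with recall measured only on
   the original labeled positives — the one set whose class is known.

A synthetic-graph generator (`kg2ml.simulate`) plants hidden positives at
a known α so every stage is quantitatively testable without access to any
proprietary knowledge graph.

## Worked example

Simulate a small knowledge graph with 30% hidden positives planted among
the unlabeled genes, then run every stage:

```
$ kg2ml simulate --preset small --seed 7 --out-dir sim
INFO kg2ml: wrote 721 nodes, 6213 edges to sim

$ kg2ml label --graph-nodes sim/nodes.tsv --graph-edges sim/edges.tsv \
    --disease-cui D0001 --out sim/labels.tsv
INFO kg2ml: 120 positive, 479 unlabeled genes; 80 EFO features

$ kg2ml featurize --graph-nodes sim/nodes.tsv --graph-edges sim/edges.tsv \
    --labels sim/labels.tsv --features sim/features.tsv --out-dir sim/matrix
INFO kg2ml: matrix 599x80, 5935 stored entries

$ kg2ml pulscar --matrix sim/matrix --iterations 10 --seed 1 \
    --out sim/alpha.json --scores sim/scores.tsv
INFO kg2ml: alpha = 0.3540 (0.1538, 0.5623); 170 genes imputed

$ kg2ml evaluate --matrix sim/matrix --imputed sim/scores.tsv \
    --repeats 10 --seed 1 --out sim/comparison.json --plot sim/comparison.png
INFO kg2ml: recall on labeled positives: 0.3250 -> 0.9700

$ kg2ml rank --scores sim/scores.tsv -k 5
rank    gene_cui        mean_prob
1       G000414 0.993275
2       G000126 0.989728
3       G000051 0.988715
4       G000228 0.986859
5       G000018 0.982695
```

Reading the output: the planted hidden-positive fraction is 0.30 and the
estimate is 0.354 with a wide CI — at only 479 unlabeled genes the
per-iteration knee is noisy, which the CI reports honestly; at the default
scale (6,000 genes) the estimate lands within a few hundredths of the
planted value. Flipping the 170 imputed genes to class 1 raises recall on
the 120 known positives from 0.325 to 0.970: the baseline model, forced
to call hidden positives negative, suppresses scores of everything with a
positive-like profile, while the augmented model recovers them. The
ranked genes are the strongest candidates for hidden association.

The same stages run as one command with a manifest of every artifact:

```
kg2ml run --out-dir run1 --seed 9
```

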