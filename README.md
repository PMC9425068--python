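# gcnlmf

Network-based disease-gene prioritization for systems biologists: given a
gene–gene interaction network (e.g. a STRING export) and a short list of
genes known to be associated with a disease, `gcnlmf` scores every gene in
the network for its probability of association and ranks the unlabeled
genes as candidates.

## Method

The model fuses two components:

1. **Graph-convolutional feature propagation.** With adjacency A, self-loops
   are added (Ā = A + I) and symmetrically degree-normalized,
   Â = D^(−1/2) Ā D^(−1/2). Node features are propagated through layers
   H^(i+1) = σ(Â H^(i) W^(i)) with fixed, seeded orthonormal projections
   W^(i) (the encoder is deterministic feature smoothing, not a trained
   network). Genes in the same interaction neighborhood end up with similar
   embedding rows.

2. **Logistic matrix factorization.** The association probability of gene i
   with the disease u is p_i = σ(x_u·y_i + β_u + β_i). Known positives
   (r_i = 1) are up-weighted by a confidence factor a·r_i in a weighted
   Bernoulli likelihood; Gaussian priors on the latent factors give an L2
   penalty (λ/2)(‖x_u‖² + Σ‖y_i‖²). The log-posterior

   Σ_i [ a·r_i·z_i − (1 + a·r_i)·log(1 + e^{z_i}) ] − (λ/2)‖x_u‖² − (λ/2)Σ_i‖y_i‖²

   is maximized by alternating AdaGrad gradient ascent over the disease side
   (x_u, β_u) and the gene side (Y, β).

The fusion: gene latent factors Y are initialized from the propagated
embeddings and fine-tuned only for labeled genes; an unlabeled gene is
scored by the trained disease factor against its network embedding, which is
what lets label information generalize over the interaction topology.

Evaluation follows the standard protocol: sample negatives uniformly from
the non-positive genes (default 200), stratified 10-fold cross-validation,
ROC AUC (Mann–Whitney midrank form) and AUPR (average precision with
pessimistic tie handling).

## Worked example

Simulate a benchmark network with a planted disease module, cross-validate,
then train and rank candidates:

```
$ gcnlmf simulate --out-dir sim            # 500 genes, 40-gene module
$ gcnlmf evaluate sim/network.tsv sim/positives.txt --out-dir eval --seed 7
mean AUC 0.7213 (sd 0.0857), mean AUPR 0.3767 (sd 0.1110)
$ gcnlmf train sim/network.tsv sim/positives.txt --out-dir run --seed 7
$ head -4 run/rankings.csv
rank,gene,probability
1,G0438,0.6896001050336497
2,G0450,0.6662645866237294
3,G0339,0.6194647390766636
```

The evaluate line reports 10-fold cross-validated metrics over the 40
positive and 200 sampled negative genes: AUC 0.72 means a random
disease-module gene outranks a random negative 72% of the time, and AUPR
0.38 is well above the 1/6 positive prevalence. (Cross-validated AUC on
this scenario varies by roughly ±0.1 with the seeded random projection the
encoder draws — the pinned benchmark configuration reproduced by
`scripts/acceptance.py` sits near 0.93; see the run-to-run variance note in
`docs/methods.md`.) The rankings file lists every unlabeled gene with its
fitted association probability, highest first.

The same commands run on real data: an edge list (`gene_a TAB gene_b [TAB
weight]`, `--score-dialect string1000` for STRING combined scores) and a
positive gene list, one symbol per line.

Library users get the same pipeline as scikit-learn-style estimators:

```python
from gcnlmf import GCNLMF, load_edge_list, load_gene_list, LabeledGeneSet

network = load_edge_list("network.tsv", score_dialect="string1000")
labels = LabeledGeneSet(positives=load_gene_list("positives.txt"))
model = GCNLMF(n_factors=32, lam=0.5).fit(network, labels)  # needs negatives; see docs
candidates = model.rank_genes(exclude=labels.labeled)
```

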