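# joingcla

Graph-convolutional fusion of multi-modal brain connectomes and multi-omics
data for disease classification, with an interpretable attention layer and a
synthetic-cohort simulator.

## Who this is for

Studies of neurodegenerative disease (the motivating case is Parkinson's
disease vs. healthy controls) often collect both imaging-derived connectomes
— a symmetric region×region connectivity matrix per scan, structural from
DTI tractography, functional from fMRI time-series correlation — and several
omics panels per subject (SNP genotypes, DNA methylation, RNAseq,
small non-coding RNA).  Both sides are high-dimensional, the cohorts are
small, the classes are severely imbalanced (often >90% patients), and a
subject can contribute several scans.  This package implements a population-
graph approach to fusing all of it in one classifier, plus the evaluation
protocol (subject-grouped splits, oversampling restricted to training data,
MCC-centric reporting) that such cohorts require.

## The model

All P scans are classified jointly (transductively).  Cross-sample
information enters through two kinds of weighted similarity graph over
scans:

* **PSG (population scan graph)** — per imaging modality m, pairwise Pearson
  similarities of the vectorized connectivity features (strict upper
  triangle, J_m = R(R−1)/2 features for an R-region atlas) are min-max
  normalized to [0,1], incremented by 1, and fused by elementwise product
  across modalities, so A ∈ [1, 2^M]^(P×P).
* **POG (population omics graph)** — per omics type n, subject-level Pearson
  correlations are self-looped, rescaled with the unsigned WGCNA soft
  threshold |r|^β (default β = 6, optional scale-free selection), and
  expanded from subjects to scans by block duplication, so B ∈ [0,1]^(P×P)
  with unit diagonal.

The network is three cascaded parts.  A **connectome encoder** reduces the
concatenated connectivity features X^c with a rectified linear layer,
H¹ = ReLU(X^c W¹ + b¹), and smooths it over the PSG with one spectral graph
convolution H² = ReLU(D̂^(−1/2)(A+I)D̂^(−1/2) H¹ W²).  One **omics network**
per data type propagates H² over its POG, H³ = D̂^(−1/2)(B+I)D̂^(−1/2) H² W³,
and produces class logits H⁴ = ReLU(ReLU(H³)W⁴ + b⁴).  An **attention
layer** fuses the N omics networks: per sample the query is the mean logit
vector, keys and values are scalar projections of each network's H³ and H⁴,
and a softmax over the omics axis yields an L⁴×N attention matrix whose
class rows are probability distributions over omics types — the
interpretability output.  H⁵ = scores·values feeds a softmax output layer.
Training minimizes a class-weighted cross-entropy (weights w_c = 1 − P_c/P)
with Adam, dropout after each graph convolution, on the training scans only.

With one omics type the attention layer is bypassed; with none, the encoder
output feeds a linear head directly.  A conventional scaled dot-product
self-attention fusion is included as an ablation baseline.

## Worked example

A desk-scale synthetic cohort: 120 subjects (~180 scans, majority fraction
≈ 0.72), two imaging modalities on a 20-region atlas carrying no class
signal, three omics types (50/200/500 features) of which only `snp` is
informative (a 2-sd mean shift on 10% of its features):

```python
import joingcla as j

cohort = j.simulate_cohort(j.desk_scale_config(1))
rows = j.run_protocol(cohort.bundle(), j.deployment_config(n_seeds=3),
                      [("dti-fmri + all omics", None, ("mirna", "met", "snp"))])
row = rows[0]
print(row["accuracy"], row["mcc"])
print(row["mean_attention"])
```

prints

```
accuracy 96.84 ± 3.29   MCC 0.92 ± 0.08
mean attention (rows: predicted class, cols: mirna, met, snp):
[[0.323 0.246 0.431]
 [0.432 0.112 0.456]]
```

Each protocol run splits the cohort 2:1 into non-test and test at the
subject level (stratified by class), oversamples minority training scans to
parity (duplicates join the population graphs as extra nodes but never the
validation or test sets), trains for the preset epoch count, and evaluates
once on the held-out scans.  Accuracy is in percent; MCC is the Matthews
correlation coefficient, which a majority-class predictor cannot inflate
(it scores exactly 0).  The attention matrix says which omics network the
model weighted when predicting each class — here the informative `snp`
panel receives the largest weight in both class rows, and a model trained
on a cohort with no class signal anywhere stays at MCC ≈ 0.

The same pipeline is scriptable from the shell:

```
joingcla simulate --out data --seed 1 --informative snp
joingcla build-graphs --data data --out graphs
joingcla protocol --data data --out run --seeds 3
joingcla select --data data --out selection     # backward elimination
```

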