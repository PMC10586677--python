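# omicstack

Discovery and classification of molecular subgroups from integrated
multi-omics cancer data.

Tumors from different organs can share molecular alterations, so grouping
patients by molecular profile — rather than tissue of origin — can reveal
subgroups with distinct outcomes and treatment implications. `omicstack`
implements that workflow end to end for four measurement layers: mRNA
expression (F1, FPKM-like), miRNA expression (F2, RPKM-like), DNA-methylation
beta values (F3) and protein expression (F4, RPPA-like):

1. **Preprocessing** — per-datatype filters (drop F1/F2 features with zeros
   in >20% of samples; drop F3/F4 features missing in >10%; drop F3 probes
   on chrX/chrY; keep the top-2000 features by SD for F1/F3), KNN imputation
   (K = 5) for F3/F4, then column-stacking over the samples common to all
   layers.
2. **Integration** — a symmetric autoencoder (tanh hidden layers, linear
   output) trained with Adam on mean-squared reconstruction error, with
   early stopping once the validation loss has not improved for 10 epochs;
   among candidate architectures the fit with the smallest
   |train − validation| loss gap is kept. The bottleneck activations F_AE
   are the clustering space. A 99%-variance PCA baseline (F_PCA) is included.
3. **Consensus clustering** — K-means repeated on random 80% subsamples
   (1000 reps by default) for K = 2..20. Stability is scored by the
   proportion of ambiguously clustered pairs computed from the consensus
   CDF,

       P(K) = C(K, u2) − C(K, u1),        u1 = 0.1, u2 = 0.9,

   and calibrated against B Monte-Carlo reference datasets drawn from a
   single Gaussian with the empirical feature covariance (no clusters) via
   the relative cluster stability index

       RCSI(K) = log10( (1/B) Σ_b P_rf(K, b) ) − log10( P_rl(K) ).

   The K maximising RCSI is selected.
4. **Characterization** — k-group log-rank tests of overall and disease-free
   survival across the discovered subgroups (with Kaplan-Meier curves), and
   differential-feature selection per datatype: one-way ANOVA + one-vs-rest
   Welch t-tests, Benjamini-Hochberg correction, selection at q ≤ 0.01 and
   |log2 fold change| ≥ 5.
5. **Classification** — per feature set, three base classifiers (radial-kernel
   SVM, random forest, feed-forward neural network) tuned by repeated
   stratified cross-validation; their class probabilities are fused linearly,

       P_F = α·P_SVM + β·P_RF + γ·P_FFNN,   α + β + γ = 1,

   with the weights scanned on a 0.01 grid (5151 triples), and nonlinearly by
   logistic-regression / FFNN stackers on the concatenated probabilities —
   with or without a 60/40 holdout between the two levels. New samples with a
   single datatype can then be assigned a multi-omics subgroup.

A synthetic-data generator (`omicstack.synthetic`) emulates the assumed data
structure — shared latent clusters observed through layer-specific nonlinear
maps, zero inflation, missingness, beta values in [0,1], chromosome
annotations, cluster-dependent exponential survival with censoring — so the
whole pipeline is exercised and tested without any external download.

## Worked example

```python
import omicstack as om

cfg = om.GeneratorConfig(n_samples=300, k_true=4,
                         n_features={"F1": 100, "F2": 50, "F3": 100, "F4": 30})
study = om.generate_dataset(cfg, seed=11)
layers, stacked = om.preprocess_study(study.layers)

model = om.SubgroupDiscovery(
    stacked, reducer="ae",
    architectures=[om.AEArchitecture(encoder_widths=(32, 8), max_epochs=120)],
    k_range=range(3, 6), reps=30, B=5, ref_reps=10, n_init=2,
)
res = model.fit(seed=11)
print(res.summary())
```

```
Subgroup discovery results
==========================
samples: 300    latent dim: 8 (F_AE)
reducer: ae    consensus reps: 30 at 80% subsample, B=5
autoencoder: widths (32, 8), train loss 0.3938, val loss 0.4459, epochs 120
selected K: 4    RCSI: 4.256    silhouette: 0.485

 K    pac  mean_ref_pac   rcsi  silhouette
 3 0.2028        0.4641 0.3595      0.3960
 4 0.0000        0.4016 4.2555      0.4848
 5 0.1183        0.3895 0.5177      0.4264
```

K = 4 is selected because its consensus matrix has no ambiguous pairs
(PAC = 0) while structureless reference data clustered the same way is
ambiguous 40% of the time — an RCSI of 4.26, far above the neighbouring K.
The discovered subgroups differ in outcome:

```python
chi2, p, curves = res.logrank(study.survival)
# log-rank OS: chi2 = 65.70, p = 3.55e-14
```

Training the two-level classifier on the same samples:

```python
frame = om.normalize(stacked).to_frame()
clf = om.SubgroupClassifier(frame, study.true_labels, plan=om.SplitPlan(seed=3),
                            cv_folds=3, cv_repeats=1)
print(clf.fit(3).summary())
```

```
Subgroup classifier results
===========================
features: 253    protocol: w/o holdout
splits: 243 train / 27 val / 30 test (L0 243, L1 243)
fusion weights: alpha=0.00 beta=0.00 gamma=1.00 (selection accuracy 1.0000)
test accuracy:
  SVM          1.0000
  RF           1.0000
  FFNN         1.0000
  linear       1.0000
  LR           1.0000
  FFNN_stack   1.0000
```

On well-separated synthetic data every model is perfect; the interesting
guarantees (fusion never worse than the best base model on the selection
set, holdout partitions disjoint, probability rows convex) are enforced by
the test suite.

## Command-line pipeline

Each stage is a subcommand reading one YAML config and writing artifacts +
a manifest to a run directory:

```bash
omicstack simulate   --config config.yaml
omicstack preprocess --config config.yaml
omicstack integrate  --config config.yaml
omicstack cluster    --config config.yaml
omicstack characterize --config config.yaml
omicstack train      --config config.yaml
omicstack predict    --config config.yaml
```

Unknown config keys are rejected. Defaults encode the standard protocol
(filters 0.20/0.10, top-2000 SD, KNN K=5, 1000 reps at 80%, u1/u2 =
0.1/0.9, K = 2..20, q ≤ 0.01 and |log2FC| ≥ 5, 90/10 splits, 60/40 holdout,
0.01 weight grid).

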