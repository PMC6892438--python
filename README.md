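# movae

Multi-omics integration with a stacked variational autoencoder: learn a small
set of non-negative latent factors that jointly explain gene expression,
somatic mutation and copy-number profiles of a tumor cohort, then use those
factors to cluster samples into molecular subtypes, rank factors by clinical
relevance, and judge whether cancer cell lines are faithful models of the
tumors they are meant to represent.

## Who this is for

Computational biologists working with matched multi-omics cohorts (e.g.
expression as FPKM/RPKM, binary nonsynonymous mutation calls, gene-level
copy-number segment means) who want a single low-dimensional representation
that scales to thousands of input features, integrates a protein–protein
interaction (PPI) network to de-noise sparse mutation data, and comes with a
complete evaluation battery (supervised subtype prediction, clustering
agreement, survival separation, concordance).

## The model

Each sample's stacked feature vector **x** = [x₁; x₂; …; x_m] (one block per
modality, each feature scaled to [0, 1]) is explained by latent factors
**z** with prior N(0, I). An encoder with one hidden layer
(linear → batch-norm → ReLU) parameterizes a diagonal Gaussian posterior
q(z|x) = N(μ(x), diag σ²(x)); the reparametrization z = μ + σ·ε with
ε ~ N(0, I) makes the model trainable by backpropagation. The latent code is
rectified — the decoder consumes ReLU(z), and inference reports
ReLU(μ(x)) — so factors are non-negative, encouraging disentangled,
parts-based representations. The decoder mirrors the encoder and ends in
sigmoids; training minimizes the negative evidence lower bound

```
l = BCE(x, x̂) + β · KL( N(μ, σ²) ‖ N(0, I) )
```

with a KL warm-up β = min(1, κ·epoch) (κ = 0.01 by default, so β reaches 1 at
epoch 100). Defaults follow the published configuration: 1,100 hidden units,
100 latent factors, 600 epochs of Adam with minibatches of 100.

Before training, binary mutation matrices can be smoothed over a PPI by
random walks with restarts, F_{t+1} = αAF_t + (1−α)F₀ with column-stochastic
A and restart rate 1−α (α = 0.7 by default); the solver uses the closed-form
fixed point (1−α)(I−αA)⁻¹F₀ for networks up to 5,000 genes.

Downstream: Spearman associations link factors to input features; per-factor
Cox proportional-hazards models (Efron ties, controlling for age, sex and
stage, BH-corrected) select clinically relevant factors; k-means with many
restarts plus adjusted mutual information, nested-CV one-vs-rest linear SVMs
with macro-averaged ROC, cross-validated ridge-Cox concordance and
multivariate log-rank tests make up the benchmark suite; cell-line fitness is
the proportion of a line's K = 5 latent-space nearest neighbors that are
themselves cell lines (a line whose neighbors are all cell lines is flagged
as a poor tumor model).

## Worked example

```python
import movae
from movae.bench import kmeans_cluster, ami
from movae.interpret import clinically_relevant_factors
from movae.survival import cv_cindex, logrank_multivariate
from movae.vae import LatentSpace

# synthetic cohort: 4 molecular subtypes shared across three modalities
stack, truth = movae.generate_multiomics(
    n_samples=200, n_expr=300, n_mut=60, n_cnv=40, seed=7
)
table = movae.generate_survival(truth, beta_star=[1.0], censor_fraction=0.3, seed=8)

scaled, scaling = movae.scale_stack(stack)
model = movae.MultiOmicsVAE(n_hidden=64, n_latent=16, epochs=150, batch_size=50, seed=0)
model.fit(scaled.values.T)
Z = LatentSpace(model.transform(scaled.values.T), stack.sample_ids)

clusters = kmeans_cluster(Z, 4, n_init=100, seed=0)
print("AMI vs planted clusters:", round(ami(clusters.labels, truth.cluster_labels), 3))
chi2, df, p = logrank_multivariate(table, clusters.labels)
print(f"log-rank chi2={chi2:.1f} (df={df}), p={p:.2e}")
selected, summary = clinically_relevant_factors(Z, table)
res = cv_cindex(Z.subset_factors(selected), table, seed=0)
print(f"cross-validated c-index: {res['best_mean_cindex']:.3f} at penalty {res['best_penalty']}")
```

prints

```
AMI vs planted clusters: 0.879
log-rank chi2=100.3 (df=3), p=1.35e-21
clinically relevant factors: ['LF2', 'LF8', 'LF9', 'LF10', 'LF12', 'LF13', 'LF16']
cross-validated c-index: 0.724 at penalty 1000.0
```

The AMI of 0.879 says the k-means partition of the latent space recovers the
four planted subtypes almost perfectly (1.0 = identical partitions, 0 =
chance); the log-rank p shows those clusters separate survival; the c-index
of 0.724 means the ridge-Cox risk score built on the selected factors orders
72% of comparable patient pairs correctly out of sample (0.5 = chance).

There is also a CLI: `movae simulate`, `movae smooth`, `movae train`,
`movae transform`, `movae interpret`, `movae cluster`, `movae benchmark`,
`movae celllines`, and `movae pipeline --config cfg.yaml` which runs the whole
chain from one YAML config with per-stage seeds and a reproducibility
manifest.

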