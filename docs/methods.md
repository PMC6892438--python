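# Methods

## The latent factor model

The stacked feature vector x ∈ [0,1]^p concatenates the scaled expression,
mutation and copy-number blocks of one sample. The generative model is a
variational autoencoder with one deterministic hidden layer on each side:

- encoder: x → dense(N_hidden) → batch-norm → ReLU → (μ, log σ²), each of
  width N_latent;
- latent code: z = μ + σ·ε, ε ~ N(0, I), rectified to z⁺ = max(z, 0) before
  decoding;
- decoder: z⁺ → dense(N_hidden) → batch-norm → ReLU → dense(p) → sigmoid.

The loss is the negative ELBO, reconstruction (binary cross-entropy with the
[0,1]-scaled features as soft targets, summed over features) plus β times the
closed-form Gaussian KL (summed over latent dimensions), both averaged over
the minibatch. β follows the warm-up schedule β = min(1, κ·epoch), applied
per epoch. At inference the representation is ReLU(μ(x)) with batch-norm in
evaluation mode — deterministic, so repeated transforms of the same sample
are identical.

Rectifying the latent code *inside* the model (rather than only clipping μ at
readout) is a deliberate design choice: the decoder can then only use the
positive part of z, so the encoder is forced to store structure in
non-negative coordinates, and the reported ReLU(μ) is exactly the code the
decoder was trained on. In development this mattered: with a signed latent
code, k-means on ReLU(μ) lost roughly a third of the recoverable cluster
information on the standard synthetic fixture; with the rectified code it
recovers the planted partition at the ceiling set by the data itself.

The network is implemented directly on numpy (manual backpropagation, Adam
with the standard moment parameters, batch-norm with momentum 0.9 running
statistics). Gradients are verified against central finite differences in the
test suite. Training is a pure function of (data, config, seed): weight
initialization (Glorot uniform), minibatch shuffling and the reparametrization
draws all come from one seeded generator, so reruns are bit-identical.

### Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `n_hidden` | 1,100 | width of the deterministic hidden layers |
| `n_latent` | 100 | number of latent factors LF1..LFk |
| `epochs` | 600 | full passes over the training set |
| `batch_size` | 100 | minibatch size (shrunk with a warning if n < 100) |
| `kappa` | 0.01 | per-epoch KL warm-up increment; β hits 1 at epoch ⌈1/κ⌉ |
| `learning_rate` | 1e-3 | Adam step size |

The 1,100/100/600/100/0.01 defaults are the published operating point for a
cohort of ~573 samples and 1,300–6,000 features. The published account is
internally inconsistent about whether 80 or 100 latent factors were used for
the final comparisons; 100 is the default here and the value is configurable.
Whether batch-norm precedes or follows the activation is not specified
anywhere; this implementation uses linear → batch-norm → ReLU. The warm-up
increment granularity (per epoch vs per batch) is likewise unspecified;
per-epoch is used, so with κ = 0.01 the KL term is at full weight from epoch
100 of 600.

## Input scaling

Features are stored features × samples. Each feature is z-scored with the
population standard deviation (denominator n) and then mapped affinely to
[0, 1], making every feature a valid soft target for the sigmoid/cross-entropy
output. Zero-variance features map to 0.5 and are kept, so row indices stay
aligned with network and gene-set annotations. The fitted `ScalingModel` is
frozen: new samples are mapped with the training statistics. Two cohorts
measured on different platforms (tumors vs cell lines) are harmonised by
scaling each cohort per feature, concatenating, and rescaling the combined
matrix — an additive per-cohort offset cancels exactly in step one.

Feature selection ranks genes by the raw median absolute deviation
(median |x − median x|, unscaled); ties at the cut break lexicographically by
gene id so selection is deterministic.

## Network smoothing

Binary mutation profiles are diffused over a PPI by random walks with
restarts, F_{t+1} = αAF_t + (1−α)F₀, with A the column-stochastic
degree-normalized adjacency and 1−α the restart rate. The fixed point of this
iteration is (1−α)(I−αA)⁻¹F₀, and that is what the closed-form solver
returns. (A common statement of the closed form omits the (1−α) factor; the
two differ only by a global positive scale, which preserves rankings but not
column mass, and the iteration is taken as the operational definition here.)
The closed form is used up to 5,000 network genes, the iterative solver
(tol 1e-6, max 10,000 iterations) beyond. α defaults to 0.7, a rule of thumb
for smoothing mutation data; when a score grid is available, `select_alpha`
picks the smallest α whose score is within one standard deviation (across CV
folds) of the best.

Genes absent from the network pass through unchanged; network genes absent
from the data participate in the diffusion with signal zero. Isolated network
nodes keep all-zero operator columns and are reported.

## Interpretation and survival

- Factor–feature association: Spearman's ρ for every (factor, feature) pair;
  two-sided p from the t approximation, or exact permutation enumeration for
  n ≤ 8. Both the raw p < 0.001 convention and BH-adjusted p < 0.01 calls are
  emitted; constant columns are excluded and flagged rather than reported as
  ρ = 0.
- Clinical relevance: one Cox model per factor (factor + age + sex + ordinal
  stage; factors standardized by default so coefficients are per-SD log hazard
  ratios), Efron tie handling, BH correction of the factor p-values across
  factors, selection at adjusted p < 0.05. Stage is encoded 1–4 ordinal and
  sex as a binary indicator, since no encoding is prescribed by the source
  material.
- Harrell's C is computed from its pairwise definition (shorter observed time
  with an event defines a comparable pair; risk ties count ½) and is
  cross-checked against lifelines in the tests. Cox fitting, Kaplan–Meier
  estimation and the k-sample log-rank test go through lifelines.
- `cv_cindex` evaluates a ridge Cox model on pre-selected factors with
  event-stratified 5-fold CV over the penalty grid {1, 10, 100, 1000, 10000};
  only the factors enter the penalized model.

## Benchmarks

The compound model-selection score is the plain average of (i) the area under
the macro-averaged one-vs-rest ROC of a nested-CV linear SVM (outer 10-fold:
latent model and SVM trained on 90%, inner 10-fold choosing C from
{0.01, 0.1, 1, 10, 100}; class ROCs interpolated onto a fixed 101-point FPR
grid and averaged), (ii) the adjusted mutual information of k-means (1,000
random restarts by default, best WCSS kept) against reference labels,
(iii) −log₁₀ p of the multivariate log-rank test across the k-means clusters,
and (iv) the cross-validated c-index. Inside the (N_hidden, N_latent) grid
search each cell's latent space is fixed after training and the four
components are computed on it directly (the SVM part by 5-fold CV on the
factors) — retraining the latent model inside every SVM fold for every grid
cell would multiply cost without changing the ranking question the grid is
answering. Differential expression uses Welch t-tests (cluster vs rest, BH
within cluster, adjusted p < 0.05).

## Cell-line fitness

All samples (tumors + cell lines) are embedded in the same latent space; for
each cell line the K = 5 Euclidean nearest neighbors (self excluded, distance
ties broken by sample id) are inspected and the line is rejected as a tumor
model when the cell-line proportion among them exceeds 0.95 — at K = 5
exactly the "all five neighbors are cell lines" rule. The contamination
experiment spikes repeated random draws of foreign cell lines into the cohort
and reports the rejection recall per draw; the K-sweep repeats this for
K = 1..20. Contaminants count as potential neighbors of the target lines,
mirroring the pooled-histogram design. Retained lines are assigned to tumor
clusters by running k-means on the pooled embedding.

## Synthetic data

The generator plants k\* ground-truth factors: cluster c has centroid
separation·e_{c mod k\*} and sample factors are N(centroid, I) rectified at 0
(matching the model's non-negative latent space, which keeps recovery
well-posed). Loadings are sparse — each factor drives a disjoint block of
genes with weights U(0.5, 1.5). Expression is a baseline plus loadings times
factors plus N(0, noise_sd²), clipped at zero; copy number is the same
construction quantized to 0.1 to mimic segment-mean granularity; mutations
are Bernoulli with logistic probabilities whose intercept is tuned by
bisection to a target mean rate (default 0.05 per gene per sample, a
realistic rate for MAD-selected mutation genes). Survival times are
exponential with hazard baseline·exp(β\*ᵀz\*) (baseline 10⁻³/day, so median
survival is a couple of years at baseline risk) with independent uniform
censoring calibrated by bisection to the requested fraction; age, sex and
stage are drawn independently of risk. PPIs are stochastic block models;
pseudo-cell-lines copy random tumors' factors plus a shared offset vector of
chosen norm and are re-decoded through the tumor loadings. Every generator is
a pure function of (parameters, seed).

What the generator does *not* emulate: mutational signatures, genomic
coordinates and segment structure of copy number, library-size and batch
artefacts in expression, correlated censoring, or label noise in subtype
annotations. Passing the recovery tests therefore shows the machinery is
correct and well-calibrated under the planted-factor model, not that any
particular biological cohort will separate as cleanly.

## Study conditions and problem sizes

The standard recovery fixture is n = 400 samples, 4 clusters, 1,000
expression + 200 mutation + 100 CNV features (the 1,300-feature layout),
separation 3, noise SD 0.5, trained 200 epochs with a (128-hidden, 32-latent)
model — the network sized to the fixture's feature count the same way the
published 1,100/100 configuration is sized to its cohort. Under these
conditions k-means on the *planted* factors themselves reaches AMI ≈ 0.83
against the planted labels, so the observed AMI ≈ 0.82 of the full pipeline
is at the intrinsic ceiling of the data. Simulation batteries use n = 300–500
samples and 20–50 repetitions; the nested-CV SVM check runs on a 200-sample,
4-class separable cohort with the scaled features as the latent map (the
machinery under test is the cross-validation and ROC averaging, not the
encoder).

## Numerical choices and degenerate inputs

Sigmoid outputs are clamped to [1e-7, 1−1e-7] inside the cross-entropy;
log σ² is clipped to ±15; a non-finite training loss aborts with advice to
lower the learning rate. Batch-norm uses ε = 1e-5. k-means restarts use
random (not k-means++) initialization to match the many-random-restarts
protocol. Empty gene lists, empty selections, all-censored groups and
zero-variance genes return empty results or flagged rows with warnings rather
than raising, except where the quantity is undefined (no events, no
comparable pairs, single group), which raises with a named reason.

## Known limitations

- The VAE runs on a single CPU thread via numpy; it is sized for cohorts of
  hundreds of samples and thousands of features, not single-cell scale.
- Modality-specific likelihoods (e.g. a Bernoulli head for mutations) are not
  implemented; all features share the sigmoid/cross-entropy head.
- Proportionality diagnostics, time-varying covariates and competing risks
  are out of scope for the survival layer.
- The hypergeometric over-representation test assumes a user-supplied,
  correctly scoped gene universe; no annotation databases ship with the
  package.
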