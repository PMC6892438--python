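"""Shared fixtures: the expensive end-to-end artifacts are built once per session."""

import numpy as np
import pytest

import movae
from movae.bench import kmeans_cluster, svm_label_cv
from movae.vae import LatentSpace


@pytest.fixture(scope="session")
def recovery():
    """End-to-end cluster-recovery fixture: 4 planted clusters, n=400,
    1,000 expression + 200 mutation + 100 CNV features; VAE (128 hidden,
    32 latent) trained 200 epochs; k-means K=4 with 100 restarts."""
    stack, truth = movae.generate_multiomics(seed=11)
    scaled, scaling = movae.scale_stack(stack)
    model = movae.MultiOmicsVAE(
        n_hidden=128, n_latent=32, epochs=200, batch_size=100, seed=0
    )
    model.fit(scaled.values.T)
    Z = LatentSpace(model.transform(scaled.values.T), stack.sample_ids)
    clusters = kmeans_cluster(Z, 4, n_init=100, seed=0)
    return {
        "stack": stack,
        "truth": truth,
        "scaled": scaled,
        "scaling": scaling,
        "model": model,
        "Z": Z,
        "clusters": clusters,
    }


@pytest.fixture(scope="session")
def cox_recovery_sims():
    """50 proportional-hazards simulations (n=300, true beta=1, exponential
    baseline, ~30% censoring), each fit with an unpenalized Cox model."""
    rows = []
    for rep in range(50):
        stack, truth = movae.generate_multiomics(
            n_samples=300, n_expr=10, n_mut=5, n_cnv=5, seed=1000 + rep
        )
        table = movae.generate_survival(
            truth, [1.0], censor_fraction=0.3, seed=2000 + rep
        )
        fit = movae.cox_fit(
            {"z": truth.Z[:, 0]}, table, ridge_penalty=0.0
        )
        rows.append({"beta": fit.coef[0], "se": fit.se[0]})
    return rows


@pytest.fixture(scope="session")
def separable_svm():
    """Nested-CV SVM on four linearly separable synthetic classes, plus a
    label-shuffled control."""
    stack, truth = movae.generate_multiomics(
        n_samples=200, n_expr=40, n_mut=20, n_cnv=10, separation=8.0, noise_sd=0.3, seed=3
    )
    scaled, _ = movae.scale_stack(stack)
    res = svm_label_cv(scaled, truth.cluster_labels, seed=0)
    rng = np.random.default_rng(0)
    shuffled = rng.permutation(truth.cluster_labels)
    res_null = svm_label_cv(scaled, shuffled, seed=0)
    return {"separable": res, "shuffled": res_null, "truth": truth}


@pytest.fixture(scope="session")
def contamination_fixture():
    """Latent-space geometry for the cell-line contamination experiment:
    clustered tumors, tumor-like target lines, and a far-offset contaminant
    pool forming a tight culture cluster."""
    rng = np.random.default_rng(42)
    k = 8
    centers = np.eye(4, k) * 5
    tumor_labels = rng.integers(0, 4, 300)
    tumors = np.maximum(centers[tumor_labels] + rng.normal(0, 0.7, (300, k)), 0)
    targets = np.maximum(
        centers[rng.integers(0, 4, 30)] + rng.normal(0, 0.7, (30, k)), 0
    )
    offset = np.zeros(k)
    offset[4:] = 12.0  # far from every tumor cluster
    pool = np.maximum(offset + rng.normal(0, 0.7, (100, k)), 0)
    return {
        "tumors": LatentSpace(tumors, [f"T{i}" for i in range(300)]),
        "targets": LatentSpace(targets, [f"L{i}" for i in range(30)]),
        "pool": LatentSpace(pool, [f"X{i}" for i in range(100)]),
        "tumor_labels": tumor_labels,
    }
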