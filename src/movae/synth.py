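"""Synthetic multi-omics data with planted ground truth.

Emulates the statistical structure of a tumor multi-omics cohort: continuous
expression driven by a few latent programs, sparse binary mutations, gene-level
copy-number segment means quantized to 0.1, cluster structure shared across
modalities, proportional-hazards survival tied to the latent programs, a
modular PPI, and "cell line" samples shifted by a shared culture offset.

Every generator is a pure function of (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import OmicsMatrix, OmicsStack, stack_modalities
from .netsmooth import PPIGraph
from .survival import SurvivalTable


@dataclass
class SyntheticTruth:
    """Everything needed to regenerate or score a synthetic cohort."""

    Z: np.ndarray  # true latent factors, samples x k_star (non-negative)
    W_expr: np.ndarray
    W_mut: np.ndarray
    W_cnv: np.ndarray
    mut_intercept: float
    cluster_labels: np.ndarray
    sample_ids: list[str]
    seed: int
    params: dict = field(default_factory=dict)
    cellline_offset: np.ndarray | None = None


def _block_loadings(rng, n_features, k_star, factor_of_feature=None):
    """Sparse loadings: each factor drives a disjoint block of features."""
    W = np.zeros((n_features, k_star))
    if factor_of_feature is None:
        factor_of_feature = np.arange(n_features) * k_star // n_features
    for i, f in enumerate(factor_of_feature):
        W[i, int(f) % k_star] = rng.uniform(0.5, 1.5)
    return W


def _tune_intercept(scores: np.ndarray, target_rate: float) -> float:
    """Bisection on b so that mean(logistic(scores + b)) hits the target rate."""
    lo, hi = -30.0, 10.0
    for _ in range(100):
        mid = 0.5 * (lo + hi)
        rate = np.mean(1.0 / (1.0 + np.exp(-(scores + mid))))
        if rate < target_rate:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _decode_omics(rng, Z, truth_like, n_expr, n_mut, n_cnv, noise_sd, sample_ids):
    """Map latent factors to the three modalities with fresh noise draws."""
    W_e, W_m, W_c, b = (
        truth_like["W_expr"],
        truth_like["W_mut"],
        truth_like["W_cnv"],
        truth_like["mut_intercept"],
    )
    n = Z.shape[0]
    expr = np.clip(1.0 + W_e @ Z.T + rng.normal(0, noise_sd, (n_expr, n)), 0, None)
    p_mut = 1.0 / (1.0 + np.exp(-(W_m @ Z.T + b)))
    mut = (rng.uniform(size=(n_mut, n)) < p_mut).astype(float)
    cnv = np.round((W_c @ Z.T + rng.normal(0, noise_sd, (n_cnv, n))) * 10) / 10
    mats = [
        OmicsMatrix(expr, [f"EXP{i+1}" for i in range(n_expr)], sample_ids, "expression"),
        OmicsMatrix(mut, [f"MUT{i+1}" for i in range(n_mut)], sample_ids, "mutation"),
        OmicsMatrix(cnv, [f"CNV{i+1}" for i in range(n_cnv)], sample_ids, "cnv"),
    ]
    return stack_modalities(mats)


def generate_multiomics(
    n_samples: int = 400,
    n_clusters: int = 4,
    k_star: int = 4,
    n_expr: int = 1000,
    n_mut: int = 200,
    n_cnv: int = 100,
    separation: float = 3.0,
    noise_sd: float = 0.5,
    mutation_base_rate: float = 0.05,
    seed: int = 0,
    mutation_modules: np.ndarray | None = None,
):
    """Generate a clustered multi-omics cohort; returns (OmicsStack, SyntheticTruth).

    Cluster c has latent centroid ``separation * e_{c mod k_star}``; sample
    factors are N(centroid, I) rectified at 0, so the planted latent space is
    non-negative like the model's. Feature counts default to the
    1,000/200/100 (expression/mutation/CNV) layout of a MAD-selected cohort.

    ``mutation_modules`` (optional, one module id per mutation gene) couples
    mutation genes to factors module-wise, so mutations concentrate inside
    network modules when the same membership builds the PPI.
    """
    if min(n_samples, n_clusters, k_star, n_expr, n_mut, n_cnv) <= 0:
        raise ValueError("all counts must be positive")
    if separation < 0:
        raise ValueError("separation must be non-negative")
    rng = np.random.default_rng(seed)
    labels = rng.integers(0, n_clusters, size=n_samples)
    centroids = np.zeros((n_clusters, k_star))
    for c in range(n_clusters):
        centroids[c, c % k_star] = separation
    Z = np.maximum(centroids[labels] + rng.normal(0, 1.0, (n_samples, k_star)), 0.0)

    W_expr = _block_loadings(rng, n_expr, k_star)
    mut_factors = None if mutation_modules is None else np.asarray(mutation_modules)
    W_mut = _block_loadings(rng, n_mut, k_star, factor_of_feature=mut_factors)
    W_cnv = _block_loadings(rng, n_cnv, k_star)
    b = _tune_intercept((W_mut @ Z.T).ravel(), mutation_base_rate)

    sample_ids = [f"S{i+1:04d}" for i in range(n_samples)]
    truth = SyntheticTruth(
        Z=Z,
        W_expr=W_expr,
        W_mut=W_mut,
        W_cnv=W_cnv,
        mut_intercept=b,
        cluster_labels=labels,
        sample_ids=sample_ids,
        seed=seed,
        params=dict(
            n_samples=n_samples,
            n_clusters=n_clusters,
            k_star=k_star,
            n_expr=n_expr,
            n_mut=n_mut,
            n_cnv=n_cnv,
            separation=separation,
            noise_sd=noise_sd,
            mutation_base_rate=mutation_base_rate,
        ),
    )
    stack = _decode_omics(
        rng,
        Z,
        {"W_expr": W_expr, "W_mut": W_mut, "W_cnv": W_cnv, "mut_intercept": b},
        n_expr,
        n_mut,
        n_cnv,
        noise_sd,
        sample_ids,
    )
    return stack, truth


def generate_survival(
    truth: SyntheticTruth,
    beta_star,
    baseline_rate: float = 1e-3,
    censor_fraction: float = 0.3,
    seed: int = 0,
) -> SurvivalTable:
    """Exponential proportional-hazards outcomes from the planted factors.

    Event times are exponential with hazard ``baseline_rate * exp(Z* beta*)``
    (times in days); censoring is an independent Uniform(0, c_max) with c_max
    calibrated by bisection so the realized censored fraction matches the
    request. Age, sex and stage are drawn independently of risk.
    """
    if not 0 <= censor_fraction < 1:
        raise ValueError("censor_fraction must lie in [0, 1)")
    beta_star = np.asarray(beta_star, dtype=float)
    k = truth.Z.shape[1]
    if beta_star.size > k:
        raise ValueError(f"beta_star has {beta_star.size} entries but only {k} factors")
    beta_full = np.zeros(k)
    beta_full[: beta_star.size] = beta_star
    rng = np.random.default_rng(seed)
    hazard = baseline_rate * np.exp(truth.Z @ beta_full)
    T = rng.exponential(1.0 / hazard)

    if censor_fraction > 0:
        # P(censored_i) = P(U < T_i) = min(T_i / c_max, 1); decreasing in c_max
        lo, hi = T.min() * 1e-3, T.max() * 1e3
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            frac = np.mean(np.minimum(T / mid, 1.0))
            if frac > censor_fraction:
                lo = mid
            else:
                hi = mid
        c_max = 0.5 * (lo + hi)
        U = rng.uniform(0, c_max, size=T.shape)
        time = np.minimum(T, U)
        event = (T <= U).astype(int)
    else:
        time, event = T, np.ones(len(T), dtype=int)

    covariates = pd.DataFrame(
        {
            "age": rng.normal(65, 10, len(T)),
            "sex": rng.integers(0, 2, len(T)),
            "stage": rng.integers(1, 5, len(T)),
        }
    )
    return SurvivalTable(list(truth.sample_ids), np.maximum(time, 1e-6), event, covariates)


def generate_ppi(
    n_genes: int,
    n_modules: int,
    p_in: float,
    p_out: float,
    seed: int = 0,
    gene_ids: list[str] | None = None,
):
    """Stochastic-block-model PPI; returns (PPIGraph, module label per gene)."""
    if not (0 <= p_out <= p_in <= 1):
        raise ValueError("need 0 <= p_out <= p_in <= 1")
    rng = np.random.default_rng(seed)
    modules = np.arange(n_genes) * n_modules // n_genes
    prob = np.where(modules[:, None] == modules[None, :], p_in, p_out)
    upper = np.triu(rng.uniform(size=(n_genes, n_genes)) < prob, k=1)
    adj = (upper | upper.T).astype(float)
    if gene_ids is None:
        gene_ids = [f"MUT{i+1}" for i in range(n_genes)]
    return PPIGraph(gene_ids=list(gene_ids), adjacency=adj), modules


def generate_celllines(
    truth: SyntheticTruth,
    n_celllines: int,
    culture_offset: float = 0.0,
    seed: int = 0,
):
    """Pseudo-cell-lines: random tumors' factors plus a shared culture shift.

    The offset vector has the requested Euclidean norm and a seeded random
    direction; samples are re-decoded through the tumor loadings, so offset 0
    produces lines indistinguishable from tumors (up to noise).

    Returns (OmicsStack of cell-line samples, cell-line LatentSpace truth
    matrix, source tumor indices).
    """
    if n_celllines < 0:
        raise ValueError("n_celllines must be non-negative")
    rng = np.random.default_rng(seed)
    p = truth.params
    source = rng.integers(0, len(truth.sample_ids), size=n_celllines)
    direction = rng.standard_normal(truth.Z.shape[1])
    direction /= np.linalg.norm(direction)
    offset = culture_offset * direction
    Z_cl = np.maximum(truth.Z[source] + offset, 0.0)
    ids = [f"CL{i+1:03d}" for i in range(n_celllines)]
    stack = _decode_omics(
        rng,
        Z_cl,
        {
            "W_expr": truth.W_expr,
            "W_mut": truth.W_mut,
            "W_cnv": truth.W_cnv,
            "mut_intercept": truth.mut_intercept,
        },
        p["n_expr"],
        p["n_mut"],
        p["n_cnv"],
        p["noise_sd"],
        ids,
    )
    truth.cellline_offset = offset
    return stack, Z_cl, source
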