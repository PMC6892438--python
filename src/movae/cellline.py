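"""Cell-line fitness as tumor models, judged in the latent space.

A cell line that sits inside a "cell line cluster" — all of its latent-space
nearest neighbors are other cell lines — resembles cultures more than tumors
and is flagged as a poor model; a cell line with at least one tumor neighbor
is retained and can be assigned to a tumor cluster.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .bench import kmeans_cluster
from .vae import LatentSpace

DEFAULT_K = 5
DEFAULT_THRESHOLD = 0.95


def pool_latent(*spaces: LatentSpace) -> LatentSpace:
    values = np.vstack([s.values for s in spaces])
    ids = [sid for s in spaces for sid in s.sample_ids]
    if len(set(ids)) != len(ids):
        raise ValueError("pooled latent spaces must have disjoint sample ids")
    return LatentSpace(values, ids)


def neighbor_profile(Z_all: LatentSpace, is_cellline, K: int = DEFAULT_K) -> pd.DataFrame:
    """Proportion of each cell line's K nearest neighbors that are cell lines.

    Euclidean distance over all other samples (tumors and cell lines, self
    excluded); distance ties break deterministically by sample id.
    """
    is_cellline = np.asarray(is_cellline, dtype=bool)
    n = len(Z_all.sample_ids)
    if is_cellline.shape != (n,):
        raise ValueError("is_cellline must have one flag per sample")
    if K >= n:
        raise ValueError(f"K={K} must be smaller than the sample count {n}")
    if not (~is_cellline).any():
        raise ValueError("at least one tumor is required")
    D = cdist(Z_all.values, Z_all.values)
    ids = np.asarray(Z_all.sample_ids)
    rows = []
    for i in np.flatnonzero(is_cellline):
        others = np.delete(np.arange(n), i)
        order = sorted(others, key=lambda j: (D[i, j], ids[j]))
        nn = order[:K]
        prop = float(np.mean(is_cellline[nn]))
        rows.append(
            {
                "sample": ids[i],
                "K": K,
                "proportion": prop,
                "neighbors": ";".join(ids[nn]),
            }
        )
    return pd.DataFrame(rows)


def reject_celllines(report: pd.DataFrame, threshold: float = DEFAULT_THRESHOLD):
    """Partition cell lines: rejected iff neighbor proportion > threshold.

    At K=5 the default threshold 0.95 rejects exactly the lines whose five
    nearest neighbors are all cell lines.
    """
    report = report.copy()
    report["rejected"] = report["proportion"] > threshold
    rejected = report.loc[report["rejected"], "sample"].tolist()
    retained = report.loc[~report["rejected"], "sample"].tolist()
    return rejected, retained, report


def contamination_experiment(
    Z_tumors: LatentSpace,
    Z_target_cl: LatentSpace,
    Z_contaminant_pool: LatentSpace,
    n_contaminants: int = 60,
    n_draws: int = 100,
    K: int = DEFAULT_K,
    threshold: float = DEFAULT_THRESHOLD,
    seed: int = 0,
) -> pd.DataFrame:
    """Artificial contamination: spike random foreign cell lines and measure recall.

    Each draw samples ``n_contaminants`` lines from the pool without
    replacement, pools them with the tumors and the target cell lines (all
    cell lines can neighbor each other), and records the fraction of
    contaminants rejected (recall) and the fraction of target lines rejected.
    """
    if n_draws <= 0:
        raise ValueError("n_draws must be positive")
    pool_n = len(Z_contaminant_pool.sample_ids)
    if pool_n < n_contaminants:
        raise ValueError(f"pool has {pool_n} lines; {n_contaminants} requested per draw")
    rng = np.random.default_rng(seed)
    target_ids = set(Z_target_cl.sample_ids)
    rows = []
    for draw in range(n_draws):
        pick = rng.choice(pool_n, size=n_contaminants, replace=False)
        contaminants = LatentSpace(
            Z_contaminant_pool.values[pick],
            [Z_contaminant_pool.sample_ids[i] for i in pick],
        )
        pooled = pool_latent(Z_tumors, Z_target_cl, contaminants)
        flags = np.array(
            [sid in target_ids or sid in set(contaminants.sample_ids) for sid in pooled.sample_ids]
        )
        report = neighbor_profile(pooled, flags, K=K)
        rejected, _, report = reject_celllines(report, threshold)
        rejected = set(rejected)
        cont_ids = set(contaminants.sample_ids)
        rows.append(
            {
                "draw": draw,
                "recall": len(rejected & cont_ids) / n_contaminants,
                "n_rejected": len(rejected),
                "target_rejected_fraction": (
                    len(rejected & target_ids) / max(len(target_ids), 1)
                ),
            }
        )
    return pd.DataFrame(rows)


def sweep_k(
    Z_all: LatentSpace,
    is_cellline,
    is_contaminant,
    K_range=range(1, 21),
    threshold: float = DEFAULT_THRESHOLD,
) -> pd.DataFrame:
    """Contaminant-rejection recall as a function of the neighbor count K."""
    is_cellline = np.asarray(is_cellline, dtype=bool)
    is_contaminant = np.asarray(is_contaminant, dtype=bool)
    ids = np.asarray(Z_all.sample_ids)
    cont_ids = set(ids[is_contaminant])
    rows = []
    for K in K_range:
        report = neighbor_profile(Z_all, is_cellline, K=K)
        rejected, _, _ = reject_celllines(report, threshold)
        recall = len(set(rejected) & cont_ids) / max(len(cont_ids), 1)
        rows.append({"K": K, "recall": recall})
    return pd.DataFrame(rows)


def assign_celllines(
    Z_tumors: LatentSpace,
    Z_retained_cl: LatentSpace,
    K_clusters: int,
    seed: int = 0,
    n_init: int = 100,
):
    """Cluster tumors together with retained cell lines; report line assignments.

    Returns (assignment DataFrame: sample -> cluster, per-cluster cell-line
    membership dict, full cluster labels over the pooled samples).
    """
    if not Z_retained_cl.sample_ids:
        warnings.warn("no retained cell lines; empty assignment")
        return pd.DataFrame(columns=["sample", "cluster"]), {}, None
    pooled = pool_latent(Z_tumors, Z_retained_cl)
    result = kmeans_cluster(pooled, K_clusters, n_init=n_init, seed=seed)
    n_t = len(Z_tumors.sample_ids)
    assignment = pd.DataFrame(
        {"sample": Z_retained_cl.sample_ids, "cluster": result.labels[n_t:]}
    )
    membership = {
        int(c): assignment.loc[assignment["cluster"] == c, "sample"].tolist()
        for c in np.unique(result.labels)
    }
    return assignment, membership, result
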