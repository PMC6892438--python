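"""Evaluation battery for latent factor models.

Covers supervised subtype prediction (nested-CV one-vs-rest linear SVM with
macro-averaged ROC), unsupervised prediction (k-means with many restarts,
scored by adjusted mutual information), per-cluster differential expression,
survival separation, and the compound benchmark score used for model
selection over the (N_hidden, N_latent) grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_mutual_info_score, roc_auc_score, roc_curve
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.svm import LinearSVC
from statsmodels.stats.multitest import multipletests

from .io import OmicsMatrix, OmicsStack
from .survival import SurvivalTable, cv_cindex, logrank_multivariate
from .vae import LatentSpace, MultiOmicsVAE

DEFAULT_C_GRID = (0.01, 0.1, 1.0, 10.0, 100.0)
_FPR_GRID = np.linspace(0.0, 1.0, 101)


@dataclass
class ClusterResult:
    labels: np.ndarray
    K: int
    wcss: float
    n_init: int
    seed: int


@dataclass
class BenchmarkScore:
    """Average of auROC, AMI, -log10(log-rank p) and c-index."""

    auroc: float
    ami: float
    neg_log10_logrank_p: float
    cindex: float
    compound: float

    def as_dict(self) -> dict:
        return asdict(self)


def kmeans_cluster(Z, K: int, n_init: int = 1000, seed: int = 0) -> ClusterResult:
    """k-means with many random restarts, keeping the lowest-WCSS solution."""
    values = Z.values if isinstance(Z, LatentSpace) else np.asarray(Z, dtype=float)
    if values.size == 0:
        raise ValueError("empty latent space")
    if K < 1:
        raise ValueError("K must be at least 1")
    if K > values.shape[0]:
        raise ValueError("K cannot exceed the sample count")
    km = KMeans(n_clusters=K, n_init=n_init, init="random", random_state=seed)
    labels = km.fit_predict(values)
    return ClusterResult(labels=labels, K=K, wcss=float(km.inertia_), n_init=n_init, seed=seed)


def ami(labels_a, labels_b) -> float:
    """Adjusted mutual information (chance-corrected partition agreement)."""
    labels_a, labels_b = np.asarray(labels_a), np.asarray(labels_b)
    if labels_a.shape != labels_b.shape:
        raise ValueError("labelings must have equal length")
    return float(adjusted_mutual_info_score(labels_a, labels_b))


def roc_auc(scores, binary_labels) -> float:
    scores = np.asarray(scores, dtype=float)
    binary_labels = np.asarray(binary_labels)
    if len(np.unique(binary_labels)) != 2:
        raise ValueError("labels must contain exactly two classes")
    return float(roc_auc_score(binary_labels, scores))


def _mean_roc(per_class: dict) -> tuple[np.ndarray, np.ndarray]:
    """Macro-average: each class's ROC on a fixed 101-point FPR grid."""
    tprs = []
    for fpr, tpr, _ in per_class.values():
        tprs.append(np.interp(_FPR_GRID, fpr, tpr))
    mean_tpr = np.mean(tprs, axis=0)
    mean_tpr[0] = 0.0
    mean_tpr[-1] = 1.0
    return _FPR_GRID, mean_tpr


def identity_latent_trainer(train_stack: OmicsStack):
    """Trivial latent trainer: the scaled stacked features themselves."""
    return lambda stack: stack.values.T


def vae_latent_trainer(**vae_params):
    """Latent trainer factory fitting a fresh VAE on each training split."""

    def train(train_stack: OmicsStack):
        model = MultiOmicsVAE(**vae_params)
        model.fit(train_stack.values.T)
        return lambda stack: model.transform(stack.values.T)

    return train


def svm_label_cv(
    stack: OmicsStack,
    labels,
    latent_trainer=identity_latent_trainer,
    outer_folds: int = 10,
    inner_folds: int = 10,
    C_grid=DEFAULT_C_GRID,
    seed: int = 0,
) -> dict:
    """Nested-CV subtype prediction from latent factors.

    Outer loop: the latent model AND the one-vs-rest linear SVM see only the
    90% training split (unlabeled samples join latent training but never the
    SVM); the held-out 10% is embedded with the fold's latent model and
    scored. Inner loop: the SVM regularizer C is chosen by ``inner_folds``-CV
    on the training split. Per-class ROC curves are pooled over outer folds
    and macro-averaged on a fixed FPR grid.
    """
    labels = pd.Series(list(labels))
    labeled_mask = labels.notna().to_numpy()
    y = labels[labeled_mask].astype(str).to_numpy()
    labeled_idx = np.flatnonzero(labeled_mask)
    unlabeled_idx = np.flatnonzero(~labeled_mask)
    classes = np.unique(y)
    min_count = min(np.sum(y == c) for c in classes)
    if min_count < outer_folds:
        warnings.warn(
            f"smallest class has {min_count} members; reducing outer folds "
            f"from {outer_folds} to {min_count}"
        )
        outer_folds = int(min_count)
    if outer_folds < 2:
        raise ValueError("a class is absent or near-absent; cannot cross-validate")

    scores = np.full((len(y), len(classes)), np.nan)
    predictions = np.empty(len(y), dtype=object)
    outer = StratifiedKFold(n_splits=outer_folds, shuffle=True, random_state=seed)
    for train_lab, test_lab in outer.split(np.zeros(len(y)), y):
        if len(np.unique(y[train_lab])) < len(classes):
            raise ValueError("a class is absent from a training fold")
        latent_train_idx = np.concatenate([labeled_idx[train_lab], unlabeled_idx])
        embed = latent_trainer(stack.subset_samples(np.sort(latent_train_idx)))
        Z_train = embed(stack.subset_samples(labeled_idx[train_lab]))
        Z_test = embed(stack.subset_samples(labeled_idx[test_lab]))
        inner = min(inner_folds, min(np.bincount(pd.factorize(y[train_lab])[0])))
        svm = GridSearchCV(
            LinearSVC(),
            {"C": list(C_grid)},
            cv=StratifiedKFold(n_splits=inner, shuffle=True, random_state=seed),
        )
        svm.fit(Z_train, y[train_lab])
        dec = svm.decision_function(Z_test)
        if dec.ndim == 1:  # binary: expand to two-column convention
            dec = np.column_stack([-dec, dec])
        scores[test_lab] = dec
        predictions[test_lab] = svm.predict(Z_test)

    per_class = {}
    for k, c in enumerate(classes):
        fpr, tpr, _ = roc_curve(y == c, scores[:, k])
        per_class[c] = (fpr, tpr, roc_auc(scores[:, k], y == c))
    grid, mean_tpr = _mean_roc(per_class)
    return {
        "classes": list(classes),
        "per_class_roc": per_class,
        "mean_roc": (grid, mean_tpr),
        "auroc": float(np.trapezoid(mean_tpr, grid)),
        "predictions": predictions,
        "scores": scores,
        "outer_folds": outer_folds,
    }


def differential_expression(expr: OmicsMatrix, cluster_labels) -> pd.DataFrame:
    """Per-cluster one-vs-rest Welch t-tests with BH correction per cluster.

    ``de`` marks genes with adjusted p < 0.05; zero-variance-in-both-groups
    genes are skipped and flagged.
    """
    labels = np.asarray(cluster_labels)
    if len(labels) != expr.n_samples:
        raise ValueError("labels must match the sample count")
    frames = []
    for c in np.unique(labels):
        mask = labels == c
        if mask.sum() < 2 or (~mask).sum() < 2:
            raise ValueError(f"cluster {c!r} needs at least 2 samples on each side")
        a, b = expr.values[:, mask], expr.values[:, ~mask]
        degenerate = (a.std(axis=1) == 0) & (b.std(axis=1) == 0)
        with np.errstate(divide="ignore", invalid="ignore"):
            t, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
        df = pd.DataFrame(
            {
                "gene": expr.feature_ids,
                "cluster": c,
                "t": t,
                "p": p,
                "direction": np.sign(a.mean(axis=1) - b.mean(axis=1)).astype(int),
                "skipped": degenerate,
            }
        )
        tested = ~df["skipped"] & df["p"].notna()
        padj = np.full(len(df), np.nan)
        if tested.any():
            padj[tested.to_numpy()] = multipletests(df.loc[tested, "p"], method="fdr_bh")[1]
        df["p_adj"] = padj
        df["de"] = df["p_adj"] < 0.05
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def compound_benchmark(auroc: float, ami_score: float, logrank_p: float, cindex: float) -> BenchmarkScore:
    """Average the four evaluation scores into one model-selection number."""
    if logrank_p <= 0:
        warnings.warn("log-rank p of 0 clamped to the smallest positive float")
        logrank_p = np.finfo(float).tiny
    if logrank_p > 1:
        raise ValueError("logrank_p must lie in (0, 1]")
    neg = float(-np.log10(logrank_p))
    return BenchmarkScore(
        auroc=auroc,
        ami=ami_score,
        neg_log10_logrank_p=neg,
        cindex=cindex,
        compound=(auroc + ami_score + neg + cindex) / 4.0,
    )


def evaluate_latent(
    Z: LatentSpace,
    labels,
    survival: SurvivalTable,
    K: int = 6,
    seed: int = 0,
    n_init: int = 100,
    penalties=(1.0, 10.0, 100.0, 1000.0, 10000.0),
) -> BenchmarkScore:
    """All four benchmark components for a fixed latent space.

    auROC: 5-fold CV one-vs-rest linear SVM on the factors; AMI and log-rank:
    k-means at the given K; c-index: cross-validated ridge Cox on the factors.
    """
    labels = pd.Series(list(labels))
    mask = labels.notna().to_numpy()
    y = labels[mask].astype(str).to_numpy()
    folds = min(5, min(np.bincount(pd.factorize(y)[0])))
    svm = GridSearchCV(
        LinearSVC(),
        {"C": list(DEFAULT_C_GRID)},
        cv=StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed),
    )
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    aucs = []
    Zl = Z.values[mask]
    for tr, te in skf.split(Zl, y):
        svm.fit(Zl[tr], y[tr])
        dec = svm.decision_function(Zl[te])
        if dec.ndim == 1:
            dec = np.column_stack([-dec, dec])
        fold_aucs = []
        for k, c in enumerate(np.unique(y)):
            truth = y[te] == c
            if truth.any() and not truth.all():
                fold_aucs.append(roc_auc(dec[:, k], truth))
        aucs.append(np.mean(fold_aucs))
    clusters = kmeans_cluster(Z, K, n_init=n_init, seed=seed)
    ami_score = ami(clusters.labels[mask], y)
    _, _, p = logrank_multivariate(survival, clusters.labels)
    cv = cv_cindex(Z, survival, penalties=penalties, seed=seed)
    return compound_benchmark(float(np.mean(aucs)), ami_score, p, cv["best_mean_cindex"])


def grid_search(
    stack_scaled: OmicsStack,
    survival: SurvivalTable,
    labels,
    hidden_grid,
    latent_grid,
    seed: int = 0,
    K: int = 6,
    epochs: int = 100,
    batch_size: int = 100,
    n_init: int = 100,
) -> dict:
    """Compound-benchmark surface over the (N_hidden, N_latent) grid.

    Trains one model per grid cell (same seed), scores it with
    :func:`evaluate_latent`, and returns the surface plus the argmax cell.
    Failed cells are recorded with NaN scores.
    """
    if not len(hidden_grid) or not len(latent_grid):
        raise ValueError("grids must be non-empty")
    rows = []
    for nh in hidden_grid:
        for nl in latent_grid:
            try:
                model = MultiOmicsVAE(
                    n_hidden=int(nh),
                    n_latent=int(nl),
                    epochs=epochs,
                    batch_size=batch_size,
                    seed=seed,
                )
                model.fit(stack_scaled.values.T)
                Z = LatentSpace(model.transform(stack_scaled.values.T), stack_scaled.sample_ids)
                score = evaluate_latent(Z, labels, survival, K=K, seed=seed, n_init=n_init)
                rows.append({"n_hidden": nh, "n_latent": nl, **score.as_dict()})
            except Exception as exc:  # noqa: BLE001 - cell failure is recorded, not fatal
                warnings.warn(f"grid cell ({nh}, {nl}) failed: {exc}")
                rows.append(
                    {
                        "n_hidden": nh,
                        "n_latent": nl,
                        "auroc": np.nan,
                        "ami": np.nan,
                        "neg_log10_logrank_p": np.nan,
                        "cindex": np.nan,
                        "compound": np.nan,
                    }
                )
    surface = pd.DataFrame(rows)
    if surface["compound"].notna().any():
        best = surface.loc[surface["compound"].idxmax()]
        selected = (int(best["n_hidden"]), int(best["n_latent"]))
    else:
        selected = None
    return {"surface": surface, "selected": selected}
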