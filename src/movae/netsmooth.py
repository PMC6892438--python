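"""Network smoothing of gene-level signals by random walks with restarts.

Binary mutation profiles are noisy: two tumors hitting different members of the
same complex look unrelated gene-by-gene. Diffusing each sample's profile over
a protein-protein interaction (PPI) network with restart rate ``1 - alpha``
shares signal between interacting genes,

    F_{t+1} = alpha * A @ F_t + (1 - alpha) * F_0,

with ``A`` the degree-normalized (column-stochastic) adjacency of the PPI. The
iteration contracts for ``alpha < 1``; its fixed point is

    F_inf = (1 - alpha) * (I - alpha * A)^{-1} @ F_0,

which is what ``smooth_closed`` computes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .io import OmicsMatrix

#: Rule-of-thumb restart parameter for smoothing mutation profiles.
DEFAULT_ALPHA = 0.7


@dataclass
class SmoothingConfig:
    alpha: float = DEFAULT_ALPHA
    tol: float = 1e-6
    max_iter: int = 10_000

    def __post_init__(self) -> None:
        if not 0 <= self.alpha < 1:
            raise ValueError("alpha must lie in [0, 1) for the walk to converge")
        if self.tol <= 0 or self.max_iter <= 0:
            raise ValueError("tol and max_iter must be positive")


@dataclass
class PPIGraph:
    """Undirected gene interaction network with its column-stochastic operator."""

    gene_ids: list[str]
    adjacency: np.ndarray
    normalized_operator: np.ndarray = None  # computed on construction

    def __post_init__(self) -> None:
        self.adjacency = np.asarray(self.adjacency, dtype=float)
        n = len(self.gene_ids)
        if self.adjacency.shape != (n, n):
            raise ValueError("adjacency shape does not match gene count")
        if self.normalized_operator is None:
            np.fill_diagonal(self.adjacency, 0.0)
            self.normalized_operator = degree_normalize(self.adjacency)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)


def degree_normalize(adjacency: np.ndarray, atol: float = 1e-8) -> np.ndarray:
    """Column-normalize a symmetric non-negative adjacency to be column-stochastic.

    Isolated nodes keep all-zero columns (reported via a warning): a walk never
    moves to or from them and the restart term alone governs their value.
    """
    A = np.asarray(adjacency, dtype=float)
    if (A < 0).any():
        raise ValueError("adjacency must be non-negative")
    if not np.allclose(A, A.T, atol=atol):
        raise ValueError("adjacency must be symmetric")
    degree = A.sum(axis=0)
    isolated = degree == 0
    if isolated.any():
        warnings.warn(f"{int(isolated.sum())} isolated node(s); their columns stay zero")
    safe = np.where(isolated, 1.0, degree)
    return A / safe


def smooth_iterative(F0: np.ndarray, A: np.ndarray, config: SmoothingConfig | None = None):
    """Run the restart diffusion to convergence; returns (F, n_iter, residual)."""
    config = config or SmoothingConfig()
    F0 = np.asarray(F0, dtype=float)
    F = F0.copy()
    residual = np.inf
    for it in range(1, config.max_iter + 1):
        F_next = config.alpha * (A @ F) + (1 - config.alpha) * F0
        residual = np.abs(F_next - F).max()
        F = F_next
        if residual < config.tol:
            return F, it, residual
    warnings.warn(
        f"smoothing did not converge in {config.max_iter} iterations "
        f"(final residual {residual:.3g})"
    )
    return F, config.max_iter, residual


def smooth_closed(F0: np.ndarray, A: np.ndarray, alpha: float = DEFAULT_ALPHA) -> np.ndarray:
    """Exact fixed point (1-alpha)(I - alpha A)^{-1} F0 of the restart diffusion."""
    if not 0 <= alpha < 1:
        raise ValueError("alpha must lie in [0, 1)")
    F0 = np.asarray(F0, dtype=float)
    n = A.shape[0]
    return (1 - alpha) * np.linalg.solve(np.eye(n) - alpha * A, F0)


def select_alpha(alphas, scores, sds) -> float:
    """Pick the lowest restart parameter within 1 SD of the best score.

    ``scores`` are oriented so larger is better; ``sds`` is the per-alpha SD of
    the score across cross-validation folds.
    """
    alphas = np.asarray(alphas, dtype=float)
    scores = np.asarray(scores, dtype=float)
    sds = np.asarray(sds, dtype=float)
    if alphas.size == 0:
        raise ValueError("empty alpha grid")
    if not (alphas.size == scores.size == sds.size):
        raise ValueError("alphas, scores and sds must have equal length")
    best = int(np.argmax(scores))
    cutoff = scores[best] - sds[best]
    eligible = alphas[scores >= cutoff]
    return float(eligible.min())


def read_edge_list(path, delimiter: str = "\t") -> PPIGraph:
    """Build a PPIGraph from a TSV edge list (gene_a, gene_b[, weight])."""
    df = pd.read_csv(path, sep=delimiter)
    cols = list(df.columns)
    if len(cols) < 2:
        raise ValueError("edge list needs at least two columns (gene_a, gene_b)")
    ga, gb = df[cols[0]].astype(str), df[cols[1]].astype(str)
    w = df[cols[2]].astype(float) if len(cols) > 2 else pd.Series(1.0, index=df.index)
    genes = sorted(set(ga) | set(gb))
    idx = {g: i for i, g in enumerate(genes)}
    adj = np.zeros((len(genes), len(genes)))
    for a, b, weight in zip(ga, gb, w):
        if a == b:
            continue
        adj[idx[a], idx[b]] = weight
        adj[idx[b], idx[a]] = weight
    return PPIGraph(gene_ids=genes, adjacency=adj)


class NetworkSmoother(BaseEstimator, TransformerMixin):
    """Sklearn-style transformer applying RWR smoothing over a PPI.

    Genes of the input matrix present in the network are smoothed; genes absent
    from the network pass through unchanged; network genes absent from the input
    enter the diffusion with signal 0 (they can relay but contribute nothing).

    Parameters
    ----------
    graph : PPIGraph
    alpha : restart parameter in [0, 1); ``1 - alpha`` is the restart rate.
    closed_form_max_genes : use the dense closed form up to this many network
        genes, the iterative solver beyond.
    """

    def __init__(
        self,
        graph: PPIGraph,
        alpha: float = DEFAULT_ALPHA,
        tol: float = 1e-6,
        max_iter: int = 10_000,
        closed_form_max_genes: int = 5_000,
    ):
        self.graph = graph
        self.alpha = alpha
        self.tol = tol
        self.max_iter = max_iter
        self.closed_form_max_genes = closed_form_max_genes

    def fit(self, X: OmicsMatrix, y=None):
        overlap = set(X.feature_ids) & set(self.graph.gene_ids)
        if not overlap:
            raise ValueError(
                "no genes shared between matrix and network; check that both use "
                "the same identifier namespace (e.g. HGNC symbols)"
            )
        self.smoothed_gene_ids_ = sorted(overlap)
        self.unsmoothed_gene_ids_ = [f for f in X.feature_ids if f not in overlap]
        return self

    def transform(self, X: OmicsMatrix) -> OmicsMatrix:
        if not hasattr(self, "smoothed_gene_ids_"):
            self.fit(X)
        A = self.graph.normalized_operator
        n_net = self.graph.n_genes
        gene_pos = {g: i for i, g in enumerate(self.graph.gene_ids)}
        F0 = np.zeros((n_net, X.n_samples))
        rows_in_net = [i for i, f in enumerate(X.feature_ids) if f in gene_pos]
        for i in rows_in_net:
            F0[gene_pos[X.feature_ids[i]]] = X.values[i]
        if n_net <= self.closed_form_max_genes:
            F = smooth_closed(F0, A, self.alpha)
        else:
            F, _, _ = smooth_iterative(
                F0, A, SmoothingConfig(self.alpha, self.tol, self.max_iter)
            )
        out = X.values.copy()
        for i in rows_in_net:
            out[i] = F[gene_pos[X.feature_ids[i]]]
        return replace(X, values=out)


def align_to_network(X: OmicsMatrix, graph: PPIGraph, alpha: float = DEFAULT_ALPHA):
    """Smooth X over the network; returns (smoothed matrix, report).

    The report maps ``"smoothed"`` / ``"passed_through"`` to gene-id lists.
    """
    smoother = NetworkSmoother(graph, alpha=alpha).fit(X)
    report = {
        "smoothed": smoother.smoothed_gene_ids_,
        "passed_through": smoother.unsmoothed_gene_ids_,
    }
    return smoother.transform(X), report
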