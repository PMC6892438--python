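"""Biological interpretation of latent factors.

The encoder is nonlinear, so factor-feature relationships are read off with
Spearman rank correlations rather than loadings; clinical relevance of a
factor is judged by a per-factor Cox model controlling for age, sex and tumor
stage; gene lists are tested for pathway over-representation with an
upper-tail hypergeometric test against GMT gene-set collections.
"""

from __future__ import annotations

import math
import warnings
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import OmicsStack
from .survival import SurvivalTable, cox_fit
from .vae import LatentSpace


def _spearman_p_exact(rho_obs: float, n: int) -> float:
    """Two-sided exact permutation p for Spearman's rho (tie-free ranks, n <= 8)."""
    base = np.arange(n, dtype=float)
    base_std = (base - base.mean()) / base.std()
    count = 0
    total = 0
    for perm in permutations(range(n)):
        r = np.asarray(perm, dtype=float)
        rho = float(base_std @ ((r - r.mean()) / r.std())) / n
        count += abs(rho) >= abs(rho_obs) - 1e-12
        total += 1
    return count / total


def spearman_matrix(A: np.ndarray, B: np.ndarray):
    """All-pairs Spearman rho and two-sided p between columns of A and B.

    Columns are rank-transformed (average ranks on ties) and correlated; p
    comes from the t approximation with n-2 df, or exact permutation
    enumeration when n <= 8. Constant columns give rho = nan.
    """
    n = A.shape[0]
    if B.shape[0] != n:
        raise ValueError("A and B must have the same number of rows (samples)")
    if n < 3:
        raise ValueError("need at least 3 samples for rank correlation")

    def rank_std(M):
        R = np.apply_along_axis(stats.rankdata, 0, M)
        sd = R.std(axis=0)
        const = sd == 0
        Rs = (R - R.mean(axis=0)) / np.where(const, 1.0, sd)
        Rs[:, const] = np.nan
        return Rs

    Ra, Rb = rank_std(A), rank_std(B)
    rho = np.clip(Ra.T @ Rb / n, -1.0, 1.0)
    if n <= 8:
        p = np.empty_like(rho)
        for i in range(rho.shape[0]):
            for j in range(rho.shape[1]):
                p[i, j] = (
                    np.nan if np.isnan(rho[i, j]) else _spearman_p_exact(rho[i, j], n)
                )
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            t = rho * np.sqrt((n - 2) / np.maximum(1.0 - rho**2, 1e-300))
        p = 2 * stats.t.sf(np.abs(t), df=n - 2)
        p[np.isnan(rho)] = np.nan
    return rho, p


def associate_factors(
    Z: LatentSpace, X: OmicsStack, p_cut: float = 0.001
) -> pd.DataFrame:
    """Spearman association of every latent factor with every input feature.

    Returns one row per (factor, feature) pair with rho, the raw two-sided p,
    the BH-adjusted p across all pairs, and significance calls at both
    conventions (``significant``: p < p_cut; ``significant_adj``:
    p_adj < 0.01). Constant factors or features are excluded and listed in
    the DataFrame's ``attrs["excluded"]``.
    """
    if Z.sample_ids != X.sample_ids:
        raise ValueError("latent space and stack must share sample ids")
    rho, p = spearman_matrix(Z.values, X.values.T)
    factors = np.repeat(Z.factor_ids, X.n_features)
    features = np.tile(X.feature_ids, Z.n_factors)
    modality = np.tile(X.modality_of_row, Z.n_factors)
    df = pd.DataFrame(
        {
            "factor": factors,
            "feature": features,
            "modality": modality,
            "rho": rho.ravel(),
            "p": p.ravel(),
        }
    )
    excluded = df[df["rho"].isna()]
    if len(excluded):
        warnings.warn(
            f"excluded {len(excluded)} constant factor/feature pairs from testing"
        )
    df = df.dropna(subset=["rho"]).reset_index(drop=True)
    df["p_adj"] = multipletests(df["p"], method="fdr_bh")[1] if len(df) else []
    df["significant"] = df["p"] < p_cut
    df["significant_adj"] = df["p_adj"] < 0.01
    df.attrs["excluded"] = sorted(
        set(zip(excluded["factor"], excluded["feature"]))
    )
    return df


def clinically_relevant_factors(
    Z: LatentSpace,
    survival: SurvivalTable,
    p_threshold: float = 0.05,
    standardize: bool = True,
    covariate_names: tuple = ("age", "sex", "stage"),
):
    """Select factors whose Cox coefficient survives BH correction.

    One proportional-hazards model per factor (factor + clinical covariates);
    the factor coefficients' p-values are BH-adjusted across factors and
    factors with p_adj < ``p_threshold`` are returned. Factors are
    standardized by default so coefficients are per-SD hazard ratios.

    Returns (selected factor ids, summary DataFrame).
    """
    if survival.event.sum() == 0:
        raise ValueError("no events in the survival data")
    cov = survival.covariates[list(covariate_names)] if covariate_names else None
    rows = []
    for j, fid in enumerate(Z.factor_ids):
        z = Z.values[:, j].astype(float)
        if z.std() == 0:
            rows.append(
                {"factor": fid, "coef": np.nan, "p": np.nan, "flag": "constant"}
            )
            continue
        if standardize:
            z = (z - z.mean()) / z.std()
        X = pd.DataFrame({fid: z})
        if cov is not None:
            X = pd.concat([X, cov.reset_index(drop=True)], axis=1)
        fit = cox_fit(X, survival)
        i = fit.covariate_names.index(fid)
        rows.append(
            {
                "factor": fid,
                "coef": fit.coef[i],
                "se": fit.se[i],
                "ci_lower": fit.ci_lower[i],
                "ci_upper": fit.ci_upper[i],
                "p": fit.p[i],
                "flag": "",
            }
        )
    summary = pd.DataFrame(rows)
    tested = summary["p"].notna()
    padj = np.full(len(summary), np.nan)
    if tested.any():
        padj[tested.to_numpy()] = multipletests(summary.loc[tested, "p"], method="fdr_bh")[1]
    summary["p_adj"] = padj
    summary["selected"] = summary["p_adj"] < p_threshold
    selected = summary.loc[summary["selected"].fillna(False), "factor"].tolist()
    return selected, summary


def read_gmt(path) -> dict:
    """Parse a GMT file (name, description, member genes...) into {name: set}."""
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            sets[parts[0]] = {g for g in parts[2:] if g}
    return sets


def hypergeometric_ora(gene_list, gene_sets: dict, universe) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation test per gene set.

    ``p = P(X >= overlap)`` for X hypergeometric with population ``universe``,
    successes ``set & universe``, draws ``len(gene_list)``. BH adjustment
    across sets. Sets disjoint from the universe are skipped with a warning.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    gene_list = set(gene_list)
    if not gene_list:
        warnings.warn("empty gene list; returning empty enrichment table")
        return pd.DataFrame(
            columns=["gene_set", "overlap", "set_size", "list_size", "universe_size", "p", "p_adj"]
        )
    stray = gene_list - universe
    if stray:
        raise ValueError(f"gene list contains genes outside the universe: {sorted(stray)[:5]}")
    M, N = len(universe), len(gene_list)
    rows = []
    for name, members in gene_sets.items():
        eff = set(members) & universe
        if not eff:
            warnings.warn(f"gene set {name!r} shares no genes with the universe; skipped")
            continue
        k = len(gene_list & eff)
        p = float(stats.hypergeom.sf(k - 1, M, len(eff), N))
        rows.append(
            {
                "gene_set": name,
                "overlap": k,
                "set_size": len(eff),
                "list_size": N,
                "universe_size": M,
                "p": min(p, 1.0),
            }
        )
    df = pd.DataFrame(rows)
    if len(df):
        df["p_adj"] = multipletests(df["p"], method="fdr_bh")[1]
    return df
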