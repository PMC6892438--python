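"""Survival analysis: Cox PH fits, Harrell's C, Kaplan-Meier and log-rank tests.

Model fitting goes through lifelines (Efron handling of tied event times,
optional ridge penalty); Harrell's concordance index is computed directly from
its pairwise definition so the tie conventions are explicit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from sklearn.model_selection import StratifiedKFold

DEFAULT_PENALTIES = (1.0, 10.0, 100.0, 1000.0, 10000.0)


@dataclass
class SurvivalTable:
    """Right-censored survival outcomes with clinical covariates.

    ``time`` is follow-up in days (> 0), ``event`` 1 for death and 0 for
    censoring; covariates default to age (years), sex (binary) and tumor
    stage (ordinal 1-4).
    """

    sample_ids: list[str]
    time: np.ndarray
    event: np.ndarray
    covariates: pd.DataFrame = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        n = len(self.sample_ids)
        if self.time.shape != (n,) or self.event.shape != (n,):
            raise ValueError("time/event length does not match sample ids")
        if (self.time <= 0).any():
            raise ValueError("survival times must be positive")
        if not np.isin(self.event, (0, 1)).all():
            raise ValueError("event indicator must be 0/1")
        if self.covariates is None:
            self.covariates = pd.DataFrame(index=self.sample_ids)
        else:
            self.covariates = self.covariates.copy()
            self.covariates.index = self.sample_ids
            if self.covariates.isna().any().any():
                raise ValueError("covariates contain missing values")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        df = self.covariates.copy()
        df.insert(0, "time", self.time)
        df.insert(1, "event", self.event)
        return df

    def subset(self, idx) -> "SurvivalTable":
        idx = np.asarray(idx)
        return SurvivalTable(
            [self.sample_ids[i] for i in idx],
            self.time[idx],
            self.event[idx],
            self.covariates.iloc[idx],
        )


def read_survival(path, delimiter: str = "\t") -> SurvivalTable:
    df = pd.read_csv(path, sep=delimiter, index_col=0)
    cov = df.drop(columns=["time", "event"])
    return SurvivalTable(
        [str(i) for i in df.index], df["time"].to_numpy(), df["event"].to_numpy(), cov
    )


def write_survival(table: SurvivalTable, path, delimiter: str = "\t") -> None:
    table.to_frame().to_csv(path, sep=delimiter, index_label="sample")


@dataclass
class CoxFit:
    """Summary of a fitted proportional-hazards model (Efron ties)."""

    covariate_names: list[str]
    coef: np.ndarray
    se: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    p: np.ndarray
    log_likelihood: float
    ties: str = "efron"
    penalizer: float = 0.0
    flags: list[str] = field(default_factory=list)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coef": self.coef,
                "se": self.se,
                "ci_lower": self.ci_lower,
                "ci_upper": self.ci_upper,
                "p": self.p,
            },
            index=self.covariate_names,
        )


def cox_fit(covariates, survival: SurvivalTable, ridge_penalty: float = 0.0) -> CoxFit:
    """Fit ln h(t)/h0(t) = sum_i beta_i x_i by penalized partial likelihood.

    Efron's method handles tied event times; Wald confidence intervals and
    p-values are reported. ``ridge_penalty`` adds an L2 penalty on all
    coefficients in the model (0 = unpenalized).
    """
    if ridge_penalty < 0:
        raise ValueError("ridge_penalty must be non-negative")
    if survival.event.sum() == 0:
        raise ValueError("no events in the data; Cox model is unidentifiable")
    X = pd.DataFrame(covariates)
    if X.shape[0] != survival.n_samples:
        raise ValueError("covariate rows must match survival samples")
    X.columns = [str(c) for c in X.columns]
    const = [c for c in X.columns if X[c].nunique() <= 1]
    if const:
        raise ValueError(f"constant covariate(s): {const}")
    df = X.reset_index(drop=True)
    df["time"] = survival.time
    df["event"] = survival.event
    fitter = CoxPHFitter(penalizer=ridge_penalty, l1_ratio=0.0)
    flags = []
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        fitter.fit(df, duration_col="time", event_col="event")
    for w in caught:
        msg = str(w.message)
        if "convergence" in msg.lower() or "separation" in msg.lower():
            flags.append(msg)
            warnings.warn(msg)
    s = fitter.summary
    return CoxFit(
        covariate_names=list(s.index),
        coef=s["coef"].to_numpy(),
        se=s["se(coef)"].to_numpy(),
        ci_lower=s["coef lower 95%"].to_numpy(),
        ci_upper=s["coef upper 95%"].to_numpy(),
        p=s["p"].to_numpy(),
        log_likelihood=float(fitter.log_likelihood_),
        penalizer=ridge_penalty,
        flags=flags,
    )


def concordance_index(risk, survival: SurvivalTable) -> float:
    """Harrell's C: P(higher risk -> shorter survival) over comparable pairs.

    A pair (i, j) is comparable when the shorter observed time carries an
    event; risk ties contribute 0.5.
    """
    risk = np.asarray(risk, dtype=float)
    t, e = survival.time, survival.event
    n = len(risk)
    if risk.shape != (n,):
        raise ValueError("risk length must match survival samples")
    # comparable: t_i < t_j and event_i == 1
    ti = t[:, None]
    comparable = (ti < t[None, :]) & (e[:, None] == 1)
    n_pairs = comparable.sum()
    if n_pairs == 0:
        raise ValueError("no comparable pairs")
    ri = risk[:, None]
    concordant = (ri > risk[None, :]) & comparable
    tied = (ri == risk[None, :]) & comparable
    return float((concordant.sum() + 0.5 * tied.sum()) / n_pairs)


def km_estimate(survival: SurvivalTable, groups) -> dict:
    """Product-limit survival curve per group as a (time, survival) step table."""
    groups = np.asarray(groups)
    if groups.shape != (survival.n_samples,):
        raise ValueError("groups must assign one label per sample")
    out = {}
    for g in np.unique(groups):
        mask = groups == g
        if mask.sum() == 0:
            raise ValueError(f"empty group {g!r}")
        kmf = KaplanMeierFitter()
        kmf.fit(survival.time[mask], survival.event[mask])
        sf = kmf.survival_function_
        out[g] = pd.DataFrame(
            {"time": sf.index.to_numpy(), "survival": sf.iloc[:, 0].to_numpy()}
        )
    return out


def logrank_multivariate(survival: SurvivalTable, groups):
    """k-sample log-rank test; returns (chi-square statistic, df, p)."""
    groups = np.asarray(groups)
    uniq = np.unique(groups)
    if len(uniq) < 2:
        raise ValueError("log-rank test needs at least two groups")
    res = multivariate_logrank_test(survival.time, groups, survival.event)
    return float(res.test_statistic), len(uniq) - 1, float(res.p_value)


def _stratified_folds(event: np.ndarray, folds: int, seed: int):
    """Event-stratified fold assignment; re-draws if a training side has no event."""
    for attempt in range(20):
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed + attempt)
        splits = list(skf.split(np.zeros(len(event)), event))
        if all(event[tr].sum() > 0 for tr, _ in splits):
            if attempt:
                warnings.warn(f"re-drew folds {attempt} time(s) to get events per fold")
            return splits
    raise ValueError("could not build folds with events in every training split")


def cv_cindex(
    Z_relevant,
    survival: SurvivalTable,
    penalties=DEFAULT_PENALTIES,
    folds: int = 5,
    seed: int = 0,
) -> dict:
    """Out-of-fold Harrell's C of a ridge Cox model on pre-selected factors.

    For each penalty in the grid, fits on 4/5 of the samples (event-stratified
    folds) and scores the held-out fifth; returns the grid's best mean C with
    its per-fold values.
    """
    Z = Z_relevant.to_frame() if hasattr(Z_relevant, "to_frame") else pd.DataFrame(Z_relevant)
    Z = Z.reset_index(drop=True)
    splits = _stratified_folds(survival.event, folds, seed)
    results = {}
    for pen in penalties:
        fold_c = []
        for train_idx, test_idx in splits:
            fit = cox_fit(Z.iloc[train_idx], survival.subset(train_idx), ridge_penalty=pen)
            risk = Z.iloc[test_idx].to_numpy() @ fit.coef
            fold_c.append(concordance_index(risk, survival.subset(test_idx)))
        results[pen] = fold_c
    means = {pen: float(np.mean(c)) for pen, c in results.items()}
    best = max(means, key=means.get)
    return {
        "best_penalty": best,
        "best_mean_cindex": means[best],
        "mean_cindex": means,
        "fold_cindex": results,
    }
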