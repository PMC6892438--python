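"""Independent oracles used by the test suite.

Everything here is deliberately naive (brute force, enumeration, permutation,
Monte-Carlo) and shares no code with the implementation it checks.
"""

from itertools import combinations

import numpy as np


def smooth_brute_force(F0, A, alpha, n_steps=1000):
    """Literal n-step unrolling of F_{t+1} = alpha A F_t + (1-alpha) F0."""
    F = np.asarray(F0, dtype=float).copy()
    for _ in range(n_steps):
        F = alpha * (A @ F) + (1 - alpha) * F0
    return F


def kl_monte_carlo(mu, sigma, n_draws, rng):
    """MC estimate of KL(N(mu, sigma^2) || N(0,1)) for scalar mu, sigma."""
    z = rng.normal(mu, sigma, size=n_draws)
    log_q = -0.5 * np.log(2 * np.pi) - np.log(sigma) - 0.5 * ((z - mu) / sigma) ** 2
    log_p = -0.5 * np.log(2 * np.pi) - 0.5 * z**2
    return float(np.mean(log_q - log_p))


def efron_partial_loglik_1cov(beta, x, time, event):
    """Efron partial log-likelihood for one covariate (handles tied events)."""
    x = np.asarray(x, float)
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    eta = beta * x
    ll = 0.0
    for t in np.unique(time[event == 1]):
        D = np.flatnonzero((time == t) & (event == 1))
        R = np.flatnonzero(time >= t)
        sum_r = np.exp(eta[R]).sum()
        sum_d = np.exp(eta[D]).sum()
        ll += eta[D].sum()
        for ell in range(len(D)):
            ll -= np.log(sum_r - (ell / len(D)) * sum_d)
    return ll


def cox_beta_grid(x, time, event, lo=-5.0, hi=5.0):
    """Brute-force maximizer of the Efron partial likelihood over a beta grid.

    Coarse 1e-2 sweep of [lo, hi] followed by a 1e-4 sweep around the coarse
    optimum; equivalent to a flat 1e-4 grid for a unimodal likelihood.
    """
    coarse = np.arange(lo, hi + 1e-2, 1e-2)
    lls = [efron_partial_loglik_1cov(b, x, time, event) for b in coarse]
    b0 = coarse[int(np.argmax(lls))]
    fine = np.arange(b0 - 2e-2, b0 + 2e-2, 1e-4)
    lls = [efron_partial_loglik_1cov(b, x, time, event) for b in fine]
    return float(fine[int(np.argmax(lls))])


def logrank_statistic(time, event, groups):
    """k-sample log-rank chi-square statistic, computed from first principles."""
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    groups = np.asarray(groups)
    uniq = np.unique(groups)
    k = len(uniq)
    O = np.zeros(k)
    E = np.zeros(k)
    V = np.zeros((k, k))
    for t in np.unique(time[event == 1]):
        at_risk = time >= t
        n = at_risk.sum()
        d = ((time == t) & (event == 1)).sum()
        n_g = np.array([(at_risk & (groups == g)).sum() for g in uniq])
        d_g = np.array([((time == t) & (event == 1) & (groups == g)).sum() for g in uniq])
        O += d_g
        E += d * n_g / n
        if n > 1:
            for i in range(k):
                for j in range(k):
                    same = 1.0 if i == j else 0.0
                    V[i, j] += (
                        d * (n - d) / (n - 1) * (n_g[i] / n) * (same - n_g[j] / n)
                    )
    diff = (O - E)[:-1]
    Vsub = V[:-1, :-1]
    return float(diff @ np.linalg.solve(Vsub, diff))


def logrank_permutation_p(time, event, groups, n_perm, rng):
    """Permutation p-value of the log-rank statistic (group labels shuffled)."""
    obs = logrank_statistic(time, event, groups)
    groups = np.asarray(groups)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(groups)
        if logrank_statistic(time, event, perm) >= obs - 1e-12:
            count += 1
    return (count + 1) / (n_perm + 1)


def hypergeom_tail_enumeration(universe, gene_set, gene_list_size, min_overlap):
    """P(overlap >= min_overlap) by enumerating every possible draw.

    Counts size-``gene_list_size`` subsets of ``universe`` whose intersection
    with ``gene_set`` has at least ``min_overlap`` members. Exact, exponential.
    """
    universe = sorted(universe)
    gene_set = set(gene_set)
    hits = 0
    total = 0
    for draw in combinations(universe, gene_list_size):
        total += 1
        if len(gene_set & set(draw)) >= min_overlap:
            hits += 1
    return hits / total


def concordance_brute(risk, time, event):
    """Pairwise Harrell's C by explicit double loop."""
    n = len(risk)
    num = den = 0.0
    for i in range(n):
        for j in range(n):
            if time[i] < time[j] and event[i] == 1:
                den += 1
                if risk[i] > risk[j]:
                    num += 1
                elif risk[i] == risk[j]:
                    num += 0.5
    return num / den
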