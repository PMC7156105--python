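"""Independent oracles used by the test suite.

Everything here is deliberately written along different code paths from the
package: top-down recursive kinship with memoisation (the package uses a
bottom-up tabular sweep), allele-level gene-dropping Monte Carlo for group
coefficients (the package uses the deterministic halving recursion), plain
Monte-Carlo integration for the logit-normal mean (the package uses
Gauss-Hermite quadrature), and a self-contained scalar Gibbs sampler for a
one-way Gaussian mixed model (the package uses a blocked matrix sampler).
"""

from __future__ import annotations

import numpy as np

from ggam.pedigree import IMMIGRANT_GROUP, Pedigree


def recursive_kinship(ped: Pedigree):
    """Top-down memoised kinship phi(i, j); returns a lookup function."""
    dam_of = dict(zip(ped.df["id"], ped.df["dam"]))
    sire_of = dict(zip(ped.df["id"], ped.df["sire"]))
    depth = {i: k for k, i in enumerate(ped.ids)}  # topological rank
    memo: dict[tuple[str, str], float] = {}

    def phi(a: str, b: str) -> float:
        if depth[a] < depth[b]:
            a, b = b, a
        key = (a, b)
        if key in memo:
            return memo[key]
        if a == b:
            d, s = dam_of[a], sire_of[a]
            f = phi(d, s) if (d is not None and s is not None) else 0.0
            val = 0.5 * (1.0 + f)
        else:
            d, s = dam_of[a], sire_of[a]
            val = 0.0
            if d is not None:
                val += 0.5 * phi(d, b)
            if s is not None:
                val += 0.5 * phi(s, b)
        memo[key] = val
        return val

    return phi


def dense_A(ped: Pedigree) -> np.ndarray:
    """Brute-force dense additive relationship matrix A = 2 * kinship."""
    phi = recursive_kinship(ped)
    ids = ped.ids
    n = len(ids)
    A = np.empty((n, n))
    for i in range(n):
        for j in range(i + 1):
            A[i, j] = A[j, i] = 2.0 * phi(ids[i], ids[j])
    return A


def gene_drop_q(ped: Pedigree, groups, n_rep: int, seed: int):
    """Monte-Carlo expectation of q by dropping individual allele copies.

    Each phantom parent contributes two allele copies labelled 1 (immigrant
    group) or 0 (founder group); each offspring allele copy is a uniform
    pick of one of the relevant parent's two copies.  Returns (mean, se)
    arrays over individuals in pedigree order.
    """
    rng = np.random.default_rng(seed)
    dam, sire = ped.parent_indices()
    ids = ped.ids
    n = ped.n
    alleles = np.zeros((n, 2, n_rep), dtype=np.int8)
    for k in range(n):
        for slot, p in ((0, dam[k]), (1, sire[k])):
            if p < 0:
                label = groups[(ids[k], "dam" if slot == 0 else "sire")] == IMMIGRANT_GROUP
                alleles[k, slot] = 1 if label else 0
            else:
                pick = rng.integers(0, 2, n_rep)
                alleles[k, slot] = alleles[p, pick, np.arange(n_rep)]
    frac = alleles.mean(axis=1)  # per replicate: fraction of the 2 copies
    return frac.mean(axis=1), frac.std(axis=1, ddof=1) / np.sqrt(n_rep)


def mc_logit_normal_mean(eta: float, sigma2: float, n: int, seed: int) -> float:
    """Plain Monte-Carlo estimate of E[logit^-1(eta + e)], e ~ N(0, sigma2)."""
    rng = np.random.default_rng(seed)
    e = rng.normal(0.0, np.sqrt(sigma2), n)
    return float(np.mean(1.0 / (1.0 + np.exp(-(eta + e)))))


def reference_oneway_gibbs(y, group, n_iter, seed, fixed_var=1e8, nu=1.0, V=1.0):
    """Scalar-update Gibbs for y_ij = mu + u_j + e_ij with IG variance priors.

    Matches the package's model and priors for a Gaussian response with a
    single random intercept, but implemented with naive scalar conditionals.
    Returns draws dict with mu, var_u, var_e.
    """
    rng = np.random.default_rng(seed)
    y = np.asarray(y, dtype=float)
    group = np.asarray(group)
    J = group.max() + 1
    n = len(y)
    a0, b0 = nu / 2.0, nu * V / 2.0
    mu, var_u, var_e = 0.0, 1.0, 1.0
    u = np.zeros(J)
    out = {"mu": [], "var_u": [], "var_e": []}
    counts = np.bincount(group, minlength=J)
    for _ in range(n_iter):
        prec = n / var_e + 1.0 / fixed_var
        mean = np.sum(y - u[group]) / var_e / prec
        mu = mean + rng.standard_normal() / np.sqrt(prec)
        resid = y - mu
        for j in range(J):
            pj = counts[j] / var_e + 1.0 / var_u
            mj = resid[group == j].sum() / var_e / pj
            u[j] = mj + rng.standard_normal() / np.sqrt(pj)
        var_u = (b0 + 0.5 * np.sum(u**2)) / rng.gamma(a0 + 0.5 * J)
        err = y - mu - u[group]
        var_e = (b0 + 0.5 * np.sum(err**2)) / rng.gamma(a0 + 0.5 * n)
        out["mu"].append(mu)
        out["var_u"].append(var_u)
        out["var_e"].append(var_e)
    return {k: np.array(v) for k, v in out.items()}


def batch_means_se(x: np.ndarray, n_batches: int = 40) -> float:
    """Monte-Carlo standard error of a chain mean by batch means."""
    x = np.asarray(x, dtype=float)
    m = len(x) // n_batches
    means = x[: m * n_batches].reshape(n_batches, m).mean(axis=1)
    return float(means.std(ddof=1) / np.sqrt(n_batches))
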