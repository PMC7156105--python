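"""Bayesian genetic-groups animal model for a brood-level binomial trait.

The observation for brood *b* is the number of extra-pair offspring
``y_b ~ Binomial(n_b, logit^-1(eta_b))`` with latent liability

    eta_b = x_b' beta + a_f[fem(b)] + a_m[mal(b)] + pe_f[fem(b)]
            + pe_m[mal(b)] + pair[p(b)] + year[t(b)] + e_b,

where ``x_b = (1, q_fem, q_mal, year - baseline, male_age)`` carries the
intercept, the immigrant genetic-group regressions (slopes g_f, g_m), and
the year and male-age regressions.  Every pedigree individual carries a
pair of breeding values (a_f, a_m) — one for the female-expressed liability
(extra-pair reproduction), one for the male-expressed liability (paternity
loss) — with joint prior N(0, G kron A) linking the sexes through the
cross-sex covariance in G and through pedigree relatedness in A.  The
brood-level residual e_b gives latent-scale overdispersion.

Fitting is by Gibbs sampling with Polya-Gamma augmentation of the binomial
logit layer: given omega_b ~ PG(n_b, eta_b) the model is linear-Gaussian,
so fixed effects, all random effects, G (inverse-Wishart), and the scalar
variances (inverse-gamma) have conjugate updates.  A Gaussian-response mode
(identity link) exists for validating the sampler against closed forms.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.linalg import cho_factor, cho_solve, solve_triangular
from scipy.stats import gaussian_kde, invwishart

from .pedigree import GroupCoefficients, Pedigree, RelatednessInverse, compute_A_inverse

__all__ = [
    "BroodRecord",
    "read_broods",
    "write_broods",
    "PriorSpec",
    "ChainConfig",
    "Design",
    "build_design",
    "fit_mcmc",
    "PosteriorSamples",
    "summarize",
    "hpd_interval",
    "posterior_mode",
    "predict_genetic_values",
    "adaptive_thin",
    "FitDiagnosticsWarning",
]

VARIANCE_PARAMS = (
    "var_af",
    "var_am",
    "cov_afam",
    "var_pe_f",
    "var_pe_m",
    "var_pair",
    "var_year",
    "var_residual",
)


class FitDiagnosticsWarning(UserWarning):
    """Chain failed a mixing / retention diagnostic."""


@dataclasses.dataclass(frozen=True)
class BroodRecord:
    """One brood-level observation of the emergent trait."""

    brood_id: str
    year: int
    female_id: str
    male_id: str
    male_age: int
    n_offspring: int
    n_epo: int

    def __post_init__(self) -> None:
        if self.n_offspring < 1:
            raise ValueError(f"brood {self.brood_id}: n_offspring must be >= 1")
        if not 0 <= self.n_epo <= self.n_offspring:
            raise ValueError(f"brood {self.brood_id}: n_epo outside [0, n_offspring]")
        if self.male_age < 1:
            raise ValueError(f"brood {self.brood_id}: male_age must be >= 1")


def read_broods(path) -> pd.DataFrame:
    """Read a brood phenotype CSV and validate every record."""
    df = pd.read_csv(
        path,
        dtype={"brood_id": str, "female_id": str, "male_id": str},
    )
    required = ["brood_id", "year", "female_id", "male_id", "male_age", "n_offspring", "n_epo"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"brood file missing columns: {missing}")
    for row in df.itertuples(index=False):
        BroodRecord(
            str(row.brood_id), int(row.year), str(row.female_id), str(row.male_id),
            int(row.male_age), int(row.n_offspring), int(row.n_epo),
        )
    return df[required]


def write_broods(broods: pd.DataFrame, path) -> None:
    broods.to_csv(path, index=False)


@dataclasses.dataclass
class PriorSpec:
    """Relatively uninformative defaults; all values configurable.

    Fixed effects: N(0, fixed_var).  Scalar variances: inverse-gamma with
    shape nu/2 and scale nu*V/2 (defaults nu=1, V=1).  G: inverse-Wishart
    with ``g_df`` degrees of belief and scale matrix ``g_scale``.
    """

    fixed_var: float = 1e8
    var_nu: float = 1.0
    var_V: float = 1.0
    g_df: float = 2.0
    g_scale: np.ndarray = dataclasses.field(default_factory=lambda: np.eye(2))

    def validate(self) -> None:
        if self.fixed_var <= 0 or self.var_nu <= 0 or self.var_V <= 0:
            raise ValueError("prior scale parameters must be positive")
        if self.g_df <= 1:
            raise ValueError("G prior degrees of belief must exceed dim - 1 = 1")
        if not np.allclose(self.g_scale, self.g_scale.T) or np.linalg.eigvalsh(self.g_scale).min() <= 0:
            raise ValueError("G prior scale matrix must be symmetric positive definite")


@dataclasses.dataclass
class ChainConfig:
    n_iter: int = 13000
    burn_in: int = 3000
    thin: int = 5
    seed: int = 1

    def validate(self) -> None:
        if self.burn_in >= self.n_iter:
            raise ValueError("burn_in must be smaller than n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")


@dataclasses.dataclass
class Design:
    """Design matrices linking broods to fixed and random effects.

    ``fem_pos``/``male_pos`` index the pedigree order (animal effects);
    ``pef_idx``/``pem_idx``/``pair_idx``/``year_idx`` index the levels of
    the corresponding scalar random effects.  Any random term may be absent
    (``None``) — used by the Gaussian validation reductions.
    """

    X: np.ndarray
    fixed_names: list[str]
    y: np.ndarray
    n_trials: np.ndarray | None = None
    ainv: sp.csr_matrix | None = None
    animal_ids: list[str] | None = None
    fem_pos: np.ndarray | None = None
    male_pos: np.ndarray | None = None
    pef_idx: np.ndarray | None = None
    n_pef: int = 0
    pem_idx: np.ndarray | None = None
    n_pem: int = 0
    pair_idx: np.ndarray | None = None
    n_pair: int = 0
    year_idx: np.ndarray | None = None
    n_year: int = 0
    pef_ids: list[str] | None = None
    pem_ids: list[str] | None = None
    baseline_year: int | None = None

    @property
    def n_obs(self) -> int:
        return len(self.y)

    @property
    def n_animal(self) -> int:
        return 0 if self.ainv is None else self.ainv.shape[0]


def build_design(
    ped: Pedigree,
    q: GroupCoefficients,
    broods: pd.DataFrame,
    baseline_year: int | None = None,
    rel: RelatednessInverse | None = None,
) -> Design:
    """Construct the model design from pedigree, q coefficients and broods."""
    ids = set(ped.ids)
    for col in ("female_id", "male_id"):
        unknown = sorted(set(broods[col].astype(str)) - ids)
        if unknown:
            raise ValueError(f"broods reference individuals absent from pedigree: {unknown[:5]}")
    if baseline_year is None:
        baseline_year = int(broods["year"].min())
    fem = broods["female_id"].astype(str).to_numpy()
    mal = broods["male_id"].astype(str).to_numpy()
    q_f = np.array([q[i] for i in fem])
    q_m = np.array([q[i] for i in mal])
    X = np.column_stack(
        [
            np.ones(len(broods)),
            q_f,
            q_m,
            broods["year"].to_numpy(dtype=float) - baseline_year,
            broods["male_age"].to_numpy(dtype=float),
        ]
    )
    pos = {i: k for k, i in enumerate(ped.ids)}
    fem_pos = np.array([pos[i] for i in fem])
    male_pos = np.array([pos[i] for i in mal])
    fem_levels = sorted(set(fem))
    mal_levels = sorted(set(mal))
    both = set(fem_levels) & set(mal_levels)
    if both:
        raise ValueError(f"individuals phenotyped in both sexes: {sorted(both)[:5]}")
    fl = {i: k for k, i in enumerate(fem_levels)}
    ml = {i: k for k, i in enumerate(mal_levels)}
    pair_levels = sorted({(f, m) for f, m in zip(fem, mal)})
    pl = {p: k for k, p in enumerate(pair_levels)}
    year_levels = sorted(broods["year"].unique())
    yl = {y: k for k, y in enumerate(year_levels)}
    rel = rel if rel is not None else compute_A_inverse(ped)
    return Design(
        X=X,
        fixed_names=["intercept", "g_f", "g_m", "beta_year", "beta_age"],
        y=broods["n_epo"].to_numpy(dtype=float),
        n_trials=broods["n_offspring"].to_numpy(dtype=np.int64),
        ainv=rel.entries,
        animal_ids=list(ped.ids),
        fem_pos=fem_pos,
        male_pos=male_pos,
        pef_idx=np.array([fl[i] for i in fem]),
        n_pef=len(fem_levels),
        pem_idx=np.array([ml[i] for i in mal]),
        n_pem=len(mal_levels),
        pair_idx=np.array([pl[(f, m)] for f, m in zip(fem, mal)]),
        n_pair=len(pair_levels),
        year_idx=np.array([yl[y] for y in broods["year"]]),
        n_year=len(year_levels),
        pef_ids=fem_levels,
        pem_ids=mal_levels,
        baseline_year=baseline_year,
    )


@dataclasses.dataclass
class PosteriorSamples:
    """Retained MCMC draws plus chain metadata.

    ``params`` has one row per retained draw; ``animal`` optionally holds
    the matching draws of all breeding values (n_draws x 2N, a_f block then
    a_m block, ordered as ``animal_ids``).
    """

    params: pd.DataFrame
    animal: np.ndarray | None
    animal_ids: list[str] | None
    meta: dict

    @property
    def n_draws(self) -> int:
        return len(self.params)

    def lag1_autocorr(self) -> pd.Series:
        out = {}
        for col in self.params.columns:
            x = self.params[col].to_numpy()
            x = x - x.mean()
            denom = (x * x).sum()
            out[col] = float((x[1:] * x[:-1]).sum() / denom) if denom > 0 else 0.0
        return pd.Series(out)


def _sample_ig(rng: np.random.Generator, shape: float, scale: float) -> float:
    """Inverse-gamma draw: X = scale / Gamma(shape)."""
    return scale / rng.gamma(shape)


def _build_W(design: Design) -> tuple[sp.csr_matrix, dict]:
    """Sparse observation matrix over the jointly sampled location block.

    Column layout: fixed | a_f (N) | a_m (N) | pe_f | pe_m.
    """
    B = design.n_obs
    k = design.X.shape[1]
    N = design.n_animal
    layout = {"fixed": (0, k)}
    ncol = k
    rows, cols, vals = [], [], []
    rows.extend(np.repeat(np.arange(B), k))
    cols.extend(np.tile(np.arange(k), B))
    vals.extend(design.X.ravel())
    if N:
        layout["a_f"] = (ncol, ncol + N)
        layout["a_m"] = (ncol + N, ncol + 2 * N)
        rows.extend(np.arange(B))
        cols.extend(ncol + design.fem_pos)
        vals.extend(np.ones(B))
        rows.extend(np.arange(B))
        cols.extend(ncol + N + design.male_pos)
        vals.extend(np.ones(B))
        ncol += 2 * N
    if design.pef_idx is not None and design.n_pef:
        layout["pe_f"] = (ncol, ncol + design.n_pef)
        rows.extend(np.arange(B))
        cols.extend(ncol + design.pef_idx)
        vals.extend(np.ones(B))
        ncol += design.n_pef
    if design.pem_idx is not None and design.n_pem:
        layout["pe_m"] = (ncol, ncol + design.n_pem)
        rows.extend(np.arange(B))
        cols.extend(ncol + design.pem_idx)
        vals.extend(np.ones(B))
        ncol += design.n_pem
    W = sp.coo_matrix((vals, (rows, cols)), shape=(B, ncol)).tocsr()
    return W, layout


def _slice_sample_alpha(rng, A, C, d, E, x0=1.0, max_steps=50):
    """Slice-sample alpha > 0 from log p = -A a^2/2 + C a - d ln a - E / a^2.

    This is the conditional of a multiplicative scale-group move on a
    random-effect block and its variance (generalized Gibbs with the Haar
    measure correction); unimodal in alpha.
    """

    def logp(a):
        return -0.5 * A * a * a + C * a - d * np.log(a) - E / (a * a)

    y = logp(x0) + np.log(rng.random() + 1e-300)
    w = 0.5
    lo, hi = x0 - w, x0 + w
    lo = max(lo, 1e-8)
    steps = max_steps
    while logp(lo) > y and lo > 1e-8 and steps > 0:
        lo = max(lo - w, 1e-8)
        steps -= 1
    steps = max_steps
    while logp(hi) > y and steps > 0:
        hi += w
        steps -= 1
    for _ in range(100):
        a = rng.uniform(lo, hi)
        if logp(a) >= y:
            return a
        if a < x0:
            lo = a
        else:
            hi = a
    return x0  # pragma: no cover - pathological shrinkage


def _diag_random_update(
    rng, idx, n_levels, omega, partial_resid, variance
) -> np.ndarray:
    """Conjugate draw of a scalar random effect with diagonal precision."""
    prec = np.bincount(idx, weights=omega, minlength=n_levels) + 1.0 / variance
    mean = np.bincount(idx, weights=omega * partial_resid, minlength=n_levels) / prec
    return mean + rng.standard_normal(n_levels) / np.sqrt(prec)


def fit_mcmc(
    design: Design,
    priors: PriorSpec | None = None,
    chain: ChainConfig | None = None,
    family: str = "binomial",
    known_residual: float | None = None,
    store_animal: bool = True,
    progress_every: int | None = None,
    min_retained: int = 2000,
    max_lag1: float = 0.05,
) -> PosteriorSamples:
    """Gibbs sampler for the genetic-groups animal model.

    ``family="binomial"`` uses Polya-Gamma augmentation with a brood-level
    latent residual; ``family="gaussian"`` treats ``design.y`` as a direct
    Gaussian response (identity link) whose observation variance is the
    residual variance — fixed when ``known_residual`` is given, sampled
    otherwise.  Emits :class:`FitDiagnosticsWarning` (never silent
    acceptance) if fewer than ``min_retained`` draws are kept or any
    retained parameter's lag-1 autocorrelation is >= ``max_lag1``.
    """
    from .pg import sample_pg

    priors = priors or PriorSpec()
    chain = chain or ChainConfig()
    priors.validate()
    chain.validate()
    if family not in ("binomial", "gaussian"):
        raise ValueError(f"unknown family {family!r}")
    rng = np.random.default_rng(chain.seed)
    B = design.n_obs
    N = design.n_animal
    W, layout = _build_W(design)
    WT = W.T.tocsr()
    p = W.shape[1]
    k_fixed = design.X.shape[1]
    ainv_dense = design.ainv.toarray() if N else None

    has_pair = design.pair_idx is not None and design.n_pair > 0
    has_year = design.year_idx is not None and design.n_year > 0
    has_pef = "pe_f" in layout
    has_pem = "pe_m" in layout
    binomial = family == "binomial"

    # state
    theta = np.zeros(p)
    pair_eff = np.zeros(design.n_pair) if has_pair else None
    year_eff = np.zeros(design.n_year) if has_year else None
    e = np.zeros(B) if binomial else None
    G = np.eye(2)
    var_pe_f = var_pe_m = var_pair = var_year = 1.0
    var_res = known_residual if known_residual is not None else 1.0

    a0 = priors.var_nu / 2.0
    b0 = priors.var_nu * priors.var_V / 2.0

    if binomial:
        kappa = design.y - design.n_trials / 2.0

    param_names = list(design.fixed_names)
    if N:
        param_names += ["var_af", "var_am", "cov_afam"]
    if has_pef:
        param_names.append("var_pe_f")
    if has_pem:
        param_names.append("var_pe_m")
    if has_pair:
        param_names.append("var_pair")
    if has_year:
        param_names.append("var_year")
    param_names.append("var_residual")

    keep = [
        it for it in range(chain.n_iter)
        if it >= chain.burn_in and (it - chain.burn_in) % chain.thin == 0
    ]
    draws = np.empty((len(keep), len(param_names)))
    animal_draws = np.empty((len(keep), 2 * N)) if (store_animal and N) else None
    keep_ptr = 0

    loglik = np.nan
    for it in range(chain.n_iter):
        # linear predictor pieces outside the joint block
        offset = np.zeros(B)
        if has_pair:
            offset += pair_eff[design.pair_idx]
        if has_year:
            offset += year_eff[design.year_idx]
        if binomial:
            offset += e

        eta = W @ theta + offset
        if not np.all(np.isfinite(eta)):
            raise RuntimeError(
                f"divergent chain at iteration {it}: non-finite linear predictor "
                "(check the design for non-finite covariates)"
            )
        if binomial:
            omega = sample_pg(design.n_trials, eta, int(rng.integers(2**31 - 1)))
            z = kappa / omega
        else:
            omega = np.full(B, 1.0 / var_res)
            z = design.y

        # ---- joint location block: fixed + animal + permanent effects
        r = z - offset
        Womega = W.multiply(omega[:, None])
        Q = (WT @ Womega).toarray()
        bvec = WT @ (omega * r)
        # prior precisions
        Q[np.arange(k_fixed), np.arange(k_fixed)] += 1.0 / priors.fixed_var
        if N:
            Ginv = np.linalg.inv(G)
            s0, _ = layout["a_f"]
            Q[s0 : s0 + N, s0 : s0 + N] += Ginv[0, 0] * ainv_dense
            Q[s0 + N : s0 + 2 * N, s0 + N : s0 + 2 * N] += Ginv[1, 1] * ainv_dense
            Q[s0 : s0 + N, s0 + N : s0 + 2 * N] += Ginv[0, 1] * ainv_dense
            Q[s0 + N : s0 + 2 * N, s0 : s0 + N] += Ginv[1, 0] * ainv_dense
        if has_pef:
            s, t = layout["pe_f"]
            Q[np.arange(s, t), np.arange(s, t)] += 1.0 / var_pe_f
        if has_pem:
            s, t = layout["pe_m"]
            Q[np.arange(s, t), np.arange(s, t)] += 1.0 / var_pe_m
        try:
            cf = cho_factor(Q, lower=True, check_finite=False)
        except np.linalg.LinAlgError as exc:  # pragma: no cover
            raise RuntimeError(f"divergent chain at iteration {it}: non-PD precision") from exc
        mu = cho_solve(cf, bvec, check_finite=False)
        theta = mu + solve_triangular(
            cf[0].T, rng.standard_normal(p), lower=False, check_finite=False
        )
        if not np.all(np.isfinite(theta)):
            raise RuntimeError(f"divergent chain at iteration {it}: non-finite state")

        fitted = W @ theta

        # ---- scalar random-effect blocks
        if has_pair:
            partial = z - fitted - (year_eff[design.year_idx] if has_year else 0.0) - (e if binomial else 0.0)
            pair_eff = _diag_random_update(rng, design.pair_idx, design.n_pair, omega, partial, var_pair)
        if has_year:
            partial = z - fitted - (pair_eff[design.pair_idx] if has_pair else 0.0) - (e if binomial else 0.0)
            year_eff = _diag_random_update(rng, design.year_idx, design.n_year, omega, partial, var_year)
        if binomial:
            partial = z - fitted
            if has_pair:
                partial = partial - pair_eff[design.pair_idx]
            if has_year:
                partial = partial - year_eff[design.year_idx]
            prec = omega + 1.0 / var_res
            e = (omega * partial) / prec + rng.standard_normal(B) / np.sqrt(prec)

        # ---- (co)variance components
        if N:
            s0, _ = layout["a_f"]
            U = np.column_stack([theta[s0 : s0 + N], theta[s0 + N : s0 + 2 * N]])
            S = U.T @ (design.ainv @ U)
            G = invwishart.rvs(df=priors.g_df + N, scale=priors.g_scale + S, random_state=rng)
            G = 0.5 * (G + G.T)
        if has_pef:
            s, t = layout["pe_f"]
            var_pe_f = _sample_ig(rng, a0 + 0.5 * (t - s), b0 + 0.5 * np.sum(theta[s:t] ** 2))
        if has_pem:
            s, t = layout["pe_m"]
            var_pe_m = _sample_ig(rng, a0 + 0.5 * (t - s), b0 + 0.5 * np.sum(theta[s:t] ** 2))
        if has_pair:
            var_pair = _sample_ig(rng, a0 + 0.5 * design.n_pair, b0 + 0.5 * np.sum(pair_eff**2))
        if has_year:
            var_year = _sample_ig(rng, a0 + 0.5 * design.n_year, b0 + 0.5 * np.sum(year_eff**2))
        if binomial:
            var_res = _sample_ig(rng, a0 + 0.5 * B, b0 + 0.5 * np.sum(e**2))
        elif known_residual is None:
            resid = design.y - fitted
            if has_pair:
                resid = resid - pair_eff[design.pair_idx]
            if has_year:
                resid = resid - year_eff[design.year_idx]
            var_res = _sample_ig(rng, a0 + 0.5 * B, b0 + 0.5 * np.sum(resid**2))

        # ---- scale-group ("sandwich") moves: jointly rescale each random
        # block and its variance; breaks the slow random walk between an
        # effect vector's magnitude and its variance component.
        if not binomial:
            omega = np.full(B, 1.0 / var_res)  # precision may have been re-sampled
        contrib = {}
        if N:
            s0, _ = layout["a_f"]
            contrib["G"] = theta[s0 + design.fem_pos] + theta[s0 + N + design.male_pos]
        if has_pef:
            s, t = layout["pe_f"]
            contrib["pe_f"] = theta[s:t][design.pef_idx]
        if has_pem:
            s, t = layout["pe_m"]
            contrib["pe_m"] = theta[s:t][design.pem_idx]
        if has_pair:
            contrib["pair"] = pair_eff[design.pair_idx]
        if has_year:
            contrib["year"] = year_eff[design.year_idx]
        if binomial:
            contrib["e"] = e
        eta_nofix = sum(contrib.values(), np.zeros(B)) + design.X @ theta[:k_fixed]
        for name, cb in contrib.items():
            A_lik = float(np.sum(omega * cb * cb))
            if A_lik == 0.0:
                continue
            r_b = z - (eta_nofix - cb)
            C_lik = float(np.sum(omega * cb * r_b))
            if name == "G":
                d_pow = 2.0 * priors.g_df + 1.0
                E_pow = 0.5 * float(np.trace(priors.g_scale @ np.linalg.inv(G)))
            else:
                var_cur = dict(
                    pe_f=var_pe_f, pe_m=var_pe_m, pair=var_pair, year=var_year, e=var_res
                )[name]
                d_pow = priors.var_nu + 1.0
                E_pow = b0 / var_cur
            alpha = _slice_sample_alpha(rng, A_lik, C_lik, d_pow, E_pow)
            if name == "G":
                s0, _ = layout["a_f"]
                theta[s0 : s0 + 2 * N] *= alpha
                G = G * alpha * alpha
            elif name == "pe_f":
                s, t = layout["pe_f"]
                theta[s:t] *= alpha
                var_pe_f *= alpha * alpha
            elif name == "pe_m":
                s, t = layout["pe_m"]
                theta[s:t] *= alpha
                var_pe_m *= alpha * alpha
            elif name == "pair":
                pair_eff = pair_eff * alpha
                var_pair *= alpha * alpha
            elif name == "year":
                year_eff = year_eff * alpha
                var_year *= alpha * alpha
            elif name == "e":
                e = e * alpha
                var_res *= alpha * alpha
            eta_nofix = eta_nofix - cb + alpha * cb
            contrib[name] = alpha * cb

        if progress_every and (it + 1) % progress_every == 0:
            eta_now = fitted + offset
            if binomial:
                pr = 1.0 / (1.0 + np.exp(-eta_now))
                pr = np.clip(pr, 1e-12, 1 - 1e-12)
                loglik = float(
                    np.sum(design.y * np.log(pr) + (design.n_trials - design.y) * np.log1p(-pr))
                )
            print(f"[fit_mcmc] iter {it + 1}/{chain.n_iter} loglik={loglik:.1f}")

        if keep_ptr < len(keep) and it == keep[keep_ptr]:
            row = list(theta[:k_fixed])
            if N:
                row += [G[0, 0], G[1, 1], G[0, 1]]
            if has_pef:
                row.append(var_pe_f)
            if has_pem:
                row.append(var_pe_m)
            if has_pair:
                row.append(var_pair)
            if has_year:
                row.append(var_year)
            row.append(var_res)
            draws[keep_ptr] = row
            if animal_draws is not None:
                s0, _ = layout["a_f"]
                animal_draws[keep_ptr] = theta[s0 : s0 + 2 * N]
            keep_ptr += 1

    params = pd.DataFrame(draws, columns=param_names)
    samples = PosteriorSamples(
        params=params,
        animal=animal_draws,
        animal_ids=list(design.animal_ids) if (animal_draws is not None) else None,
        meta=dict(
            seed=chain.seed,
            n_iter=chain.n_iter,
            burn_in=chain.burn_in,
            thin=chain.thin,
            family=family,
            n_obs=B,
            n_animal=N,
        ),
    )
    if samples.n_draws < min_retained:
        warnings.warn(
            f"only {samples.n_draws} retained draws (< {min_retained}); "
            "lengthen the chain for reporting-grade summaries",
            FitDiagnosticsWarning,
        )
    ac = samples.lag1_autocorr()
    bad = ac[ac.abs() >= max_lag1]
    if len(bad):
        warnings.warn(
            "lag-1 autocorrelation >= "
            f"{max_lag1} for: {', '.join(f'{k}={v:.2f}' for k, v in bad.items())}; "
            "increase thinning (see adaptive_thin)",
            FitDiagnosticsWarning,
        )
    return samples


def adaptive_thin(
    samples: PosteriorSamples, max_lag1: float = 0.05, min_retained: int = 200
) -> PosteriorSamples:
    """Post-thin retained draws until every parameter has lag-1 autocorrelation
    below ``max_lag1``, warning if that cannot be met with ``min_retained``
    draws left."""
    current = samples
    factor = 1
    while current.lag1_autocorr().abs().max() >= max_lag1:
        factor += 1
        if samples.n_draws // factor < min_retained:
            warnings.warn(
                f"cannot reach lag-1 autocorrelation < {max_lag1} with >= "
                f"{min_retained} retained draws; keeping thin factor {factor - 1}",
                FitDiagnosticsWarning,
            )
            break
        current = PosteriorSamples(
            params=samples.params.iloc[::factor].reset_index(drop=True),
            animal=None if samples.animal is None else samples.animal[::factor],
            animal_ids=samples.animal_ids,
            meta={**samples.meta, "post_thin": factor},
        )
    return current


# ----------------------------------------------------------------------
# posterior summaries
# ----------------------------------------------------------------------

def hpd_interval(draws: np.ndarray, prob: float = 0.95) -> tuple[float, float]:
    """Shortest interval containing ``prob`` posterior mass (empirical)."""
    x = np.sort(np.asarray(draws, dtype=float))
    n = len(x)
    m = max(1, int(np.ceil(prob * n)))
    if m >= n:
        return float(x[0]), float(x[-1])
    widths = x[m:] - x[: n - m]
    j = int(np.argmin(widths))
    return float(x[j]), float(x[j + m])


def posterior_mode(draws: np.ndarray, grid_size: int = 512) -> float:
    """Kernel-density argmax (Gaussian kernel, Silverman bandwidth)."""
    x = np.asarray(draws, dtype=float)
    if np.ptp(x) == 0:
        return float(x[0])
    kde = gaussian_kde(x)
    grid = np.linspace(x.min(), x.max(), grid_size)
    return float(grid[np.argmax(kde(grid))])


def summarize(draws: pd.DataFrame, prob: float = 0.95) -> pd.DataFrame:
    """Mean, KDE mode, HPD interval, and %negative per parameter."""
    rows = {}
    for col in draws.columns:
        x = draws[col].to_numpy()
        lo, hi = hpd_interval(x, prob)
        rows[col] = dict(
            mean=float(x.mean()),
            mode=posterior_mode(x),
            hpd_low=lo,
            hpd_high=hi,
            pct_negative=float(100.0 * np.mean(x < 0)),
        )
    return pd.DataFrame(rows).T[["mean", "mode", "hpd_low", "hpd_high", "pct_negative"]]


def predict_genetic_values(
    samples: PosteriorSamples, q: GroupCoefficients, ids: Iterable[str] | None = None
) -> pd.DataFrame:
    """Posterior-mean breeding values a and total additive genetic values u.

    u is computed draw-wise as a + g q per sex, then averaged, so the
    reported posterior means propagate the joint uncertainty in g and a.
    """
    if samples.animal is None:
        raise ValueError("fit was run without store_animal; per-individual draws unavailable")
    all_ids = samples.animal_ids
    ids = list(all_ids) if ids is None else [str(i) for i in ids]
    pos = {i: k for k, i in enumerate(all_ids)}
    missing = [i for i in ids if i not in pos]
    if missing:
        raise ValueError(f"ids absent from fit: {missing[:5]}")
    no_q = [i for i in ids if i not in q.q.index]
    if no_q:
        raise ValueError(f"ids lacking a group coefficient: {no_q[:5]}")
    N = len(all_ids)
    idx = np.array([pos[i] for i in ids])
    a_f = samples.animal[:, idx]
    a_m = samples.animal[:, N + idx]
    qv = np.array([q[i] for i in ids])
    g_f = samples.params["g_f"].to_numpy()[:, None]
    g_m = samples.params["g_m"].to_numpy()[:, None]
    u_f = a_f + g_f * qv[None, :]
    u_m = a_m + g_m * qv[None, :]
    return pd.DataFrame(
        {
            "q": qv,
            "a_f_mean": a_f.mean(axis=0),
            "a_m_mean": a_m.mean(axis=0),
            "u_f_mean": u_f.mean(axis=0),
            "u_m_mean": u_m.mean(axis=0),
        },
        index=pd.Index(ids, name="id"),
    )
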