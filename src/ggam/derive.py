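"""Derived quantities for total additive genetic values, draw-wise.

With immigrant group effects (g_f, g_m) and group-coefficient variance
Var(q) treated as a plug-in constant, each posterior draw of the base
(co)variances maps to:

    Var(u_f)       = Var(a_f) + g_f^2 Var(q)
    Var(u_m)       = Var(a_m) + g_m^2 Var(q)
    cov(u_f, u_m)  = cov(a_f, a_m) + g_f g_m Var(q)
    Var(a_T)       = Var(a_f) + 2 cov(a_f, a_m) + Var(a_m)
    Var(u_T)       = Var(u_f) + 2 cov(u_f, u_m) + Var(u_m)

so that Var(u_T) - Var(a_T) = (g_f + g_m)^2 Var(q) >= 0 identically.
All quantities are computed per draw and only then summarised; a posterior
mean of a ratio (e.g. the cross-sex correlation) is therefore the mean of
draw-wise ratios, not the ratio of posterior means.

Latent heritabilities divide the focal additive variance by the sum of all
estimated variance components (optionally adding the logit link variance
pi^2/3).  Back-transformation to the observed probability scale integrates
the inverse-logit over the latent residual by Gauss-Hermite quadrature.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy.special import expit

from .model import PosteriorSamples

__all__ = [
    "DerivedPosterior",
    "derive_u_covariances",
    "derive_totals",
    "derive_correlations_and_h2",
    "derive_all",
    "logit_normal_mean",
    "back_transform",
]

LINK_VARIANCE = np.pi**2 / 3.0


@dataclasses.dataclass
class DerivedPosterior:
    """Draw-wise derived quantities plus the plug-in Var(q) constant."""

    draws: pd.DataFrame
    var_q: float
    skipped_ratio_draws: int = 0


def derive_u_covariances(samples: PosteriorSamples, var_q: float) -> DerivedPosterior:
    """Total-genetic-value (co)variances per draw."""
    if var_q < 0:
        raise ValueError("var_q must be nonnegative")
    p = samples.params
    out = pd.DataFrame(
        {
            "var_uf": p["var_af"] + p["g_f"] ** 2 * var_q,
            "var_um": p["var_am"] + p["g_m"] ** 2 * var_q,
            "cov_ufum": p["cov_afam"] + p["g_f"] * p["g_m"] * var_q,
        }
    )
    return DerivedPosterior(draws=out, var_q=var_q)


def derive_totals(derived: DerivedPosterior, samples: PosteriorSamples) -> DerivedPosterior:
    """Total variances for the joint emergent trait, and their difference."""
    p = samples.params
    d = derived.draws.copy()
    d["var_aT"] = p["var_af"] + 2.0 * p["cov_afam"] + p["var_am"]
    d["var_uT"] = d["var_uf"] + 2.0 * d["cov_ufum"] + d["var_um"]
    d["delta_varT"] = d["var_uT"] - d["var_aT"]
    return dataclasses.replace(derived, draws=d)


def derive_correlations_and_h2(
    samples: PosteriorSamples,
    derived: DerivedPosterior,
    include_link_variance: bool = False,
) -> DerivedPosterior:
    """Draw-wise cross-sex correlations and latent heritabilities.

    Draws with a zero variance (ratio undefined) are dropped from the ratio
    columns and counted in ``skipped_ratio_draws``.
    """
    p = samples.params
    d = derived.draws.copy()
    denom_a = np.sqrt(p["var_af"] * p["var_am"])
    denom_u = np.sqrt(d["var_uf"] * d["var_um"])
    ok = (denom_a > 0) & (denom_u > 0)
    skipped = int((~ok).sum())
    d["cor_afam"] = np.where(ok, p["cov_afam"] / denom_a.where(ok), np.nan)
    d["cor_ufum"] = np.where(ok, d["cov_ufum"] / denom_u.where(ok), np.nan)
    vc_cols = [
        c
        for c in ("var_af", "var_am", "var_pe_f", "var_pe_m", "var_pair", "var_year", "var_residual")
        if c in p.columns
    ]
    total_var = p[vc_cols].sum(axis=1)
    if include_link_variance:
        total_var = total_var + LINK_VARIANCE
    d["h2_f"] = p["var_af"] / total_var
    d["h2_m"] = p["var_am"] / total_var
    return dataclasses.replace(derived, draws=d, skipped_ratio_draws=skipped)


def derive_all(
    samples: PosteriorSamples, var_q: float, include_link_variance: bool = False
) -> DerivedPosterior:
    """All derived quantities in one pass."""
    d = derive_u_covariances(samples, var_q)
    d = derive_totals(d, samples)
    return derive_correlations_and_h2(samples, d, include_link_variance)


def logit_normal_mean(eta, sigma2, n_nodes: int = 30):
    """E[logit^-1(eta + e)], e ~ N(0, sigma2), by Gauss-Hermite quadrature.

    Vectorised over ``eta`` and ``sigma2`` (broadcast together).
    """
    if n_nodes < 20:
        raise ValueError("use at least 20 quadrature nodes")
    eta = np.asarray(eta, dtype=float)
    sigma2 = np.asarray(sigma2, dtype=float)
    if (sigma2 < 0).any():
        raise ValueError("sigma2 must be nonnegative")
    nodes, weights = np.polynomial.hermite.hermgauss(n_nodes)
    shift = np.sqrt(2.0 * sigma2)[..., None] * nodes
    vals = expit(eta[..., None] + shift)
    return (vals * weights).sum(axis=-1) / np.sqrt(np.pi)


def back_transform(
    samples: PosteriorSamples,
    scenarios: dict | list[dict],
    baseline_year: int,
    n_nodes: int = 30,
) -> pd.DataFrame:
    """Posterior of the expected phenotypic rate under covariate scenarios.

    Each scenario supplies ``q_value``, ``year`` and ``male_age``; per draw
    the latent mean is

        eta = intercept + beta_year (year - baseline) + beta_age male_age
              + (g_f + g_m) q_value

    and the expected observed-scale rate integrates the inverse logit over
    the latent residual (only) at that draw's residual variance.  Returns
    one column of rate draws per scenario, named ``rate_q{q_value}``.
    """
    if isinstance(scenarios, dict):
        scenarios = [scenarios]
    p = samples.params
    out = {}
    for sc in scenarios:
        for key in ("q_value", "year", "male_age"):
            if key not in sc or not np.isfinite(sc[key]):
                raise ValueError(f"scenario missing finite field {key!r}: {sc}")
        eta = (
            p["intercept"].to_numpy()
            + p["beta_year"].to_numpy() * (sc["year"] - baseline_year)
            + p["beta_age"].to_numpy() * sc["male_age"]
            + (p["g_f"].to_numpy() + p["g_m"].to_numpy()) * sc["q_value"]
        )
        rate = logit_normal_mean(eta, p["var_residual"].to_numpy(), n_nodes)
        out[f"rate_q{sc['q_value']:g}"] = rate
    return pd.DataFrame(out)
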