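"""Bayesian whole-genome regression: BayesA, BayesB and the Bayesian lasso.

Single-site Gibbs samplers for y = 1 mu + Z a + e with marker-specific
shrinkage priors:

* BayesA — a_j ~ N(0, s2_j), s2_j ~ scaled-inverse-chi2(nu, S) (every
  marker has its own variance);
* BayesB — point mass at zero with probability pi, else as BayesA
  (variable selection);
* Bayesian lasso — a_j ~ N(0, sigma_e^2 tau2_j), tau2_j ~ Exp(lambda^2/2)
  (conditional double-exponential shrinkage), with a Gamma hyperprior on
  lambda^2.

Hyperparameter scales follow the usual proportion-of-variance heuristic: the
prior marker-variance scale S is set so the implied genetic variance equals
r2_prior of var(y) (r2_prior = 0.5 by default).  Chains are reproducible
given the seed; estimates are post-burn-in means.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = ["ChainConfig", "WgrPosterior", "fit_bayes"]


@dataclass
class ChainConfig:
    """Gibbs-chain settings and prior hyperparameters."""

    n_iter: int = 20000
    burn_in: int = 5000
    thin: int = 1
    seed: int = 0
    df_marker: float = 4.2      # scaled-inv-chi2 df for marker variances
    df_e: float = 5.0           # scaled-inv-chi2 df for the residual variance
    r2_prior: float = 0.5       # prior proportion of variance that is genetic
    pi: float = 0.95            # BayesB prior mass at zero
    lasso_shape: float = 1.1    # Gamma hyperprior on lambda^2
    lasso_rate: float = 1e-4
    fix_marker_var: float = None   # degenerate prior: common fixed s2_j
    fix_sigma_e: float = None      # fix the residual variance
    keep_traces: bool = False

    def __post_init__(self):
        if self.burn_in >= self.n_iter:
            raise ValueError("burn_in must be smaller than n_iter")
        if not 0.0 <= self.pi <= 1.0:
            raise ValueError("pi must be in [0, 1]")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")


@dataclass
class WgrPosterior:
    """Posterior summaries of a whole-genome regression chain."""

    effects: np.ndarray             # posterior-mean marker effects
    effect_vars: np.ndarray         # posterior-mean per-marker variances
    mu: float
    sigma_e2: float
    gebv: np.ndarray                # Z @ effects
    inclusion_prob: np.ndarray = None   # BayesB only
    traces: dict = field(default_factory=dict, repr=False)


def _sample_scaled_inv_chi2(rng, df, scale):
    return df * scale / rng.chisquare(df)


def _sample_inv_gaussian(rng, mu, lam):
    # Michael-Schucany-Haas transformation
    nu = rng.normal()
    z = nu * nu
    x = mu + (mu * mu * z) / (2 * lam) - (mu / (2 * lam)) * np.sqrt(
        4 * mu * lam * z + mu * mu * z * z)
    if rng.random() <= mu / (mu + x):
        return x
    return mu * mu / x


def fit_bayes(y, Z, method: str = "A", config: ChainConfig = None) -> WgrPosterior:
    """Run the Gibbs sampler for one of BayesA / BayesB / Bayesian lasso.

    Parameters
    ----------
    y : response vector.
    Z : n x m marker matrix; columns are centred internally.  Zero-variance
        columns are skipped (effect fixed at 0) with a warning.
    method : "A", "B" or "lasso".
    """
    cfg = config or ChainConfig()
    method = {"a": "A", "b": "B", "bayesa": "A", "bayesb": "B",
              "lasso": "lasso", "bl": "lasso"}.get(str(method).lower())
    if method is None:
        raise ValueError("method must be one of 'A', 'B', 'lasso'")
    y = np.asarray(y, dtype=float)
    Z = np.asarray(Z, dtype=float)
    n, m = Z.shape
    if len(y) != n:
        raise ValueError("length(y) must match rows of Z")
    Zc = Z - Z.mean(axis=0)
    col_ss = np.einsum("ij,ij->j", Zc, Zc)
    active = col_ss > 1e-12
    if not active.all():
        warnings.warn(f"{int((~active).sum())} zero-variance marker columns skipped")

    rng = np.random.default_rng(cfg.seed)
    var_y = max(y.var(), 1e-12)
    sum_var_z = col_ss[active].sum() / n
    # prior scale so that E[a^2] * sum var(z_j) = r2_prior * var(y)
    mean_a2 = cfg.r2_prior * var_y / max(sum_var_z, 1e-12)
    if method == "B" and cfg.pi < 1.0:
        mean_a2 = mean_a2 / (1.0 - cfg.pi)
    nu = cfg.df_marker
    S_marker = mean_a2 * (nu - 2.0) / nu if nu > 2 else mean_a2
    S_e = var_y * (1 - cfg.r2_prior) * (cfg.df_e + 2.0) / cfg.df_e

    mu = float(y.mean())
    a = np.zeros(m)
    s2 = np.full(m, mean_a2)
    if cfg.fix_marker_var is not None:
        s2[:] = cfg.fix_marker_var
    incl = np.ones(m, dtype=bool)
    if method == "B":
        incl = rng.random(m) > cfg.pi
    tau2 = np.full(m, mean_a2 / var_y)
    lam2 = 2.0 / max(tau2.mean(), 1e-12)
    sigma_e2 = var_y * (1 - cfg.r2_prior) if cfg.fix_sigma_e is None else cfg.fix_sigma_e
    r = y - mu - Zc @ a

    keep = 0
    a_sum = np.zeros(m)
    s2_sum = np.zeros(m)
    incl_sum = np.zeros(m)
    mu_sum = 0.0
    se_sum = 0.0
    traces = {"sigma_e2": []} if cfg.keep_traces else None

    order = np.flatnonzero(active)
    for it in range(cfg.n_iter):
        # intercept
        r += mu
        mu = rng.normal(r.mean(), np.sqrt(sigma_e2 / n))
        r -= mu

        if method in ("A", "B"):
            for j in order:
                zj = Zc[:, j]
                c = col_ss[j]
                old = a[j]
                b = zj @ r + c * old            # z_j' r_(-j)
                if method == "B":
                    v1 = sigma_e2 + c * s2[j]
                    log_odds = (np.log1p(-cfg.pi) - np.log(cfg.pi)
                                + 0.5 * (np.log(sigma_e2) - np.log(v1))
                                + 0.5 * b * b * s2[j] / (sigma_e2 * v1))
                    p_in = 1.0 / (1.0 + np.exp(-np.clip(log_odds, -700, 700)))
                    incl[j] = rng.random() < p_in
                    if not incl[j]:
                        if old != 0.0:
                            r += zj * old
                        a[j] = 0.0
                        continue
                prec = c / sigma_e2 + 1.0 / s2[j]
                mean = (b / sigma_e2) / prec
                new = rng.normal(mean, 1.0 / np.sqrt(prec))
                a[j] = new
                r += zj * (old - new)
            if cfg.fix_marker_var is None:
                if method == "A":
                    s2[order] = (nu * S_marker + a[order] ** 2) / \
                        rng.chisquare(nu + 1.0, size=order.size)
                else:
                    in_j = order[incl[order]]
                    out_j = order[~incl[order]]
                    if in_j.size:
                        s2[in_j] = (nu * S_marker + a[in_j] ** 2) / \
                            rng.chisquare(nu + 1.0, size=in_j.size)
                    if out_j.size:
                        s2[out_j] = nu * S_marker / rng.chisquare(nu, size=out_j.size)
            sse = r @ r
            if cfg.fix_sigma_e is None:
                sigma_e2 = (sse + cfg.df_e * S_e) / rng.chisquare(n + cfg.df_e)
        else:   # Bayesian lasso (Park & Casella)
            for j in order:
                zj = Zc[:, j]
                c = col_ss[j]
                old = a[j]
                b = zj @ r + c * old
                prec = c / sigma_e2 + 1.0 / (tau2[j] * sigma_e2)
                mean = (b / sigma_e2) / prec
                new = rng.normal(mean, 1.0 / np.sqrt(prec))
                a[j] = new
                r += zj * (old - new)
            aj2 = np.maximum(a[order] ** 2, 1e-30)
            for idx, j in enumerate(order):
                inv_tau2 = _sample_inv_gaussian(
                    rng, np.sqrt(lam2 * sigma_e2 / aj2[idx]), lam2)
                tau2[j] = 1.0 / max(inv_tau2, 1e-12)
            lam2 = rng.gamma(cfg.lasso_shape + order.size,
                             1.0 / (cfg.lasso_rate + tau2[order].sum() / 2.0))
            if cfg.fix_sigma_e is None:
                sse = r @ r + np.sum(a[order] ** 2 / tau2[order])
                sigma_e2 = (sse + cfg.df_e * S_e) / \
                    rng.chisquare(n + order.size + cfg.df_e)

        if it >= cfg.burn_in and (it - cfg.burn_in) % cfg.thin == 0:
            keep += 1
            a_sum += a
            s2_sum += s2 if method != "lasso" else tau2 * sigma_e2
            incl_sum += incl
            mu_sum += mu
            se_sum += sigma_e2
            if traces is not None:
                traces["sigma_e2"].append(sigma_e2)

    effects = a_sum / keep
    return WgrPosterior(
        effects=effects,
        effect_vars=s2_sum / keep,
        mu=mu_sum / keep,
        sigma_e2=se_sum / keep,
        gebv=Zc @ effects,
        inclusion_prob=(incl_sum / keep) if method == "B" else None,
        traces=traces or {},
    )
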