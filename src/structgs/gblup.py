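"""GBLUP: spectral REML, genomic heritability, GEBV prediction, cross-validation.

The model is y = 1 mu + u + e with u ~ N(0, K sigma_u^2) and
e ~ N(0, I sigma_e^2).  REML is a one-dimensional profile over the variance
ratio delta = sigma_e^2 / sigma_u^2 on the eigenbasis of K (the EMMA-style
spectral trick), so each candidate delta costs O(n) after one
eigendecomposition.  Prediction into unobserved individuals uses the
conditional-expectation form
u_test = K[test, train] (K[train, train] + delta I)^-1 (y_train - mu),
which equals the joint mixed-model-equation solution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .containers import KernelMatrix

__all__ = ["GblupFit", "CvResult", "fit_gblup", "predict_gebv", "cross_validate"]

_LOG_DELTA_LO, _LOG_DELTA_HI = -10.0, 10.0


@dataclass
class GblupFit:
    """REML estimates and BLUPs for a single-kernel GBLUP fit."""

    mu: float
    var_u: float
    var_e: float
    gebv: np.ndarray
    loglik: float
    h2: float                       # genomic heritability var_u / (var_u + var_e)
    delta: float                    # var_e / var_u
    y: np.ndarray = field(repr=False, default=None)


def _as_kernel_values(K) -> np.ndarray:
    return K.values if isinstance(K, KernelMatrix) else np.asarray(K, dtype=float)


def _spectral_reml(y, Kv):
    """Profile restricted log-likelihood over log delta on the eigenbasis of K."""
    n = len(y)
    w, U = np.linalg.eigh(Kv)
    if w.min() < -1e-8 * max(1.0, abs(w).max()):
        raise ValueError(f"kernel not PSD: min eigenvalue {w.min():.3g}")
    w = np.maximum(w, 0.0)
    yt = U.T @ y
    xt = U.T @ np.ones(n)

    def neg_restricted(log_delta):
        delta = np.exp(log_delta)
        d = w + delta
        xdx = float(np.sum(xt * xt / d))
        beta = float(np.sum(xt * yt / d)) / xdx
        r = yt - xt * beta
        rss = float(np.sum(r * r / d))
        su2 = rss / (n - 1)
        ll = -0.5 * ((n - 1) * np.log(2 * np.pi) + (n - 1) * np.log(su2)
                     + float(np.sum(np.log(d))) + np.log(xdx) + (n - 1))
        return -ll

    res = optimize.minimize_scalar(neg_restricted,
                                   bounds=(_LOG_DELTA_LO, _LOG_DELTA_HI),
                                   method="bounded",
                                   options={"xatol": 1e-8})
    # guard against local optima of the profile by scanning a coarse grid
    grid = np.linspace(_LOG_DELTA_LO, _LOG_DELTA_HI, 21)
    best = min(grid, key=neg_restricted)
    if neg_restricted(best) < res.fun:
        res = optimize.minimize_scalar(
            neg_restricted,
            bounds=(max(best - 1.0, _LOG_DELTA_LO),
                    min(best + 1.0, _LOG_DELTA_HI)),
            method="bounded", options={"xatol": 1e-8})
    delta = float(np.exp(res.x))
    d = w + delta
    xdx = float(np.sum(xt * xt / d))
    beta = float(np.sum(xt * yt / d)) / xdx
    r = yt - xt * beta
    su2 = float(np.sum(r * r / d)) / (n - 1)
    ll = -float(res.fun) if res.fun >= neg_restricted(res.x) else -neg_restricted(res.x)
    return delta, beta, su2, -neg_restricted(np.log(delta)), (w, U, yt, xt)


def fit_gblup(y, K) -> GblupFit:
    """Fit GBLUP by spectral REML.

    Parameters
    ----------
    y : response vector (e.g. half-sib family BLUP values).
    K : KernelMatrix or ndarray, PSD, same order as y.

    Returns a :class:`GblupFit`; the genomic heritability is the variance
    explained by the kernel, var_u / (var_u + var_e).
    """
    y = np.asarray(y, dtype=float)
    Kv = _as_kernel_values(K)
    if len(y) != Kv.shape[0]:
        raise ValueError("length(y) must equal dim(K)")
    if np.var(y) < 1e-14:
        warnings.warn("constant response; returning boundary fit with var_u = 0")
        return GblupFit(mu=float(y.mean()), var_u=0.0, var_e=0.0,
                        gebv=np.zeros(len(y)), loglik=np.nan, h2=0.0,
                        delta=np.inf, y=y)
    delta, mu, su2, ll, (w, U, yt, xt) = _spectral_reml(y, Kv)
    se2 = su2 * delta
    # BLUP of u: K (K + delta I)^-1 (y - mu), on the eigenbasis
    resid_t = yt - xt * mu
    gebv = U @ (w / (w + delta) * resid_t)
    return GblupFit(mu=mu, var_u=su2, var_e=se2, gebv=gebv, loglik=ll,
                    h2=su2 / (su2 + se2), delta=delta, y=y)


def predict_gebv(K_full, fit: GblupFit, train_idx, test_idx) -> np.ndarray:
    """Predict GEBVs for held-out individuals from a fitted model.

    u_test = K[test, train] (K[train, train] + delta I)^-1 (y_train - mu).
    """
    Kv = _as_kernel_values(K_full)
    train_idx = np.asarray(train_idx)
    test_idx = np.asarray(test_idx)
    if fit.y is None or len(fit.y) != len(train_idx):
        raise ValueError("fit does not carry a response matching train_idx")
    Ktt = Kv[np.ix_(train_idx, train_idx)]
    Kxt = Kv[np.ix_(test_idx, train_idx)]
    A = Ktt + fit.delta * np.eye(len(train_idx))
    try:
        alpha = np.linalg.solve(A, fit.y - fit.mu)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular prediction system") from exc
    return Kxt @ alpha


@dataclass
class CvResult:
    """Replicated k-fold cross-validation output."""

    fold_assignments: np.ndarray    # reps x n fold index
    gebv: np.ndarray                # reps x n out-of-fold predictions
    accuracy: np.ndarray            # per-replicate Pearson r
    mean_accuracy: float
    mean_gebv: np.ndarray           # per-individual mean over replicates
    accuracy_of_mean_gebv: float


def make_folds(n: int, k: int, rng: np.random.Generator) -> np.ndarray:
    """Random partition into k folds with sizes differing by at most one."""
    sizes = np.full(k, n // k)
    sizes[:n % k] += 1
    fold = np.repeat(np.arange(k), sizes)
    return fold[rng.permutation(n)]


def cross_validate(y, K, k: int = 5, reps: int = 20, seed: int = 0) -> CvResult:
    """Replicated fivefold cross-validation of GBLUP accuracy.

    Per replicate the sample is randomly split into k non-overlapping folds;
    each fold is predicted from a model refit on the remaining folds, and
    accuracy is the Pearson correlation between the response and the
    out-of-fold GEBVs over all individuals.  The per-individual GEBVs
    averaged over replicates, and their correlation with the response, are
    also reported.
    """
    y = np.asarray(y, dtype=float)
    Kv = _as_kernel_values(K)
    n = len(y)
    if n < 2 * k:
        raise ValueError("need n >= 2k for k-fold cross-validation")
    rng = np.random.default_rng(seed)
    folds = np.empty((reps, n), dtype=int)
    preds = np.empty((reps, n))
    acc = np.empty(reps)
    for rep in range(reps):
        fold = make_folds(n, k, rng)
        folds[rep] = fold
        pred = np.empty(n)
        for f in range(k):
            test = np.flatnonzero(fold == f)
            train = np.flatnonzero(fold != f)
            fit = fit_gblup(y[train], Kv[np.ix_(train, train)])
            pred[test] = predict_gebv(Kv, fit, train, test)
        preds[rep] = pred
        if np.std(pred) < 1e-14:
            warnings.warn(f"replicate {rep}: zero-variance predictions; "
                          "accuracy undefined")
            acc[rep] = np.nan
        else:
            acc[rep] = float(np.corrcoef(y, pred)[0, 1])
    mean_gebv = preds.mean(axis=0)
    if np.std(mean_gebv) < 1e-14:
        acc_mean = np.nan
    else:
        acc_mean = float(np.corrcoef(y, mean_gebv)[0, 1])
    mean_acc = float(np.nanmean(acc)) if np.any(np.isfinite(acc)) else np.nan
    return CvResult(fold_assignments=folds, gebv=preds, accuracy=acc,
                    mean_accuracy=mean_acc, mean_gebv=mean_gebv,
                    accuracy_of_mean_gebv=acc_mean)
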