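"""Data-driven movement-profile construction.

A single-factor maximum-likelihood factor analysis (fitted on the feature
correlation matrix) selects the kinematic features that cohere on one
latent dimension: features are removed one at a time, smallest |loading|
first, until every retained loading reaches the threshold (default 0.70).
Fit indices (chi-square, RMSEA with 90% CI, CFI against the independence
baseline, SRMR) are reported at every step together with pass/fail against
the configured criteria. The retained feature set is then scored with the
first principal component of the standardized (reverse-coded) features,
oriented so that lower scores mean better movement performance.

The one-factor ML fit concentrates the likelihood over the uniquenesses
(the largest eigenvalue of psi^-1/2 R psi^-1/2 gives the conditional
loading solution); for three indicators the saturated solution is solved
in closed form from the correlation tetrads so the chi-square is exactly
zero there.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "EFAModel",
    "ProfileScores",
    "FitCriteria",
    "reverse_code",
    "fit_single_factor",
    "fit_indices",
    "prune_features",
    "profile_scores",
    "DEFAULT_REVERSE_CODED",
]

# Higher raw values of these features reflect *better* performance, so they
# are negated after z-scoring ("reverse coded") to put all features on a
# higher-is-worse scale.
DEFAULT_REVERSE_CODED = ("accel_mean", "jerk_mean", "accel_slope")


@dataclass(frozen=True)
class FitCriteria:
    chi_square_alpha: float = 0.05
    rmsea_max: float = 0.06
    cfi_min: float = 0.95
    srmr_max: float = 0.08

    def passed(self, model: "EFAModel") -> bool:
        if model.df == 0:
            return True  # saturated model reproduces the correlations exactly
        return (
            model.p_value > self.chi_square_alpha
            and model.rmsea < self.rmsea_max
            and model.cfi > self.cfi_min
            and model.srmr < self.srmr_max
        )


@dataclass
class EFAModel:
    retained_features: list
    loadings: np.ndarray
    uniquenesses: np.ndarray
    chi_square: float
    df: int
    p_value: float
    rmsea: float
    rmsea_ci90: tuple
    cfi: float
    srmr: float
    n_obs: int
    heywood: bool = False
    converged: bool = True
    criteria_met: bool | None = None
    removal_trail: list = field(default_factory=list)

    def loading_of(self, feature: str) -> float:
        return float(self.loadings[self.retained_features.index(feature)])


@dataclass
class ProfileScores:
    scores: pd.Series  # indexed like the input feature matrix
    component_loadings: np.ndarray
    retained_features: list
    variance_explained_pct: float


def reverse_code(
    features: pd.DataFrame, features_to_flip: tuple = DEFAULT_REVERSE_CODED
) -> pd.DataFrame:
    """Z-score every column, then negate the named ones (higher = worse)."""
    unknown = [f for f in features_to_flip if f not in features.columns]
    if unknown:
        raise KeyError(f"unknown feature(s) to flip: {unknown}")
    out = {}
    for col in features.columns:
        x = features[col].to_numpy(dtype=float)
        sd = np.std(x, ddof=1)
        if sd == 0 or not np.isfinite(sd):
            raise ValueError(f"feature '{col}' has zero variance; cannot z-score")
        z = (x - np.mean(x)) / sd
        out[col] = -z if col in features_to_flip else z
    return pd.DataFrame(out, index=features.index)


def _three_var_closed_form(R: np.ndarray) -> tuple[np.ndarray, np.ndarray] | None:
    """Exact one-factor solution for 3 indicators (correlation tetrads)."""
    r12, r13, r23 = R[0, 1], R[0, 2], R[1, 2]
    if min(abs(r12), abs(r13), abs(r23)) < 1e-12:
        return None
    lam2 = np.array([r12 * r13 / r23, r12 * r23 / r13, r13 * r23 / r12])
    if np.any(lam2 < 0):
        return None
    lam = np.sqrt(lam2)
    # sign pattern: fix sign of lam1 positive, infer others from correlations
    s2 = np.sign(r12)
    s3 = np.sign(r13)
    lam = lam * np.array([1.0, s2, s3])
    if abs(lam[1] * lam[2] - r23) > abs(-lam[1] * lam[2] - r23):
        return None  # inconsistent sign pattern
    if np.any(lam2 >= 1.0):
        return None  # Heywood case: ML optimum is on the boundary
    return lam, 1.0 - lam**2


def fit_single_factor(features: pd.DataFrame) -> EFAModel:
    """One-factor maximum-likelihood factor analysis on the correlations."""
    p = features.shape[1]
    n_obs = features.shape[0]
    if n_obs <= p:
        raise ValueError("need more observations than features")
    R = np.corrcoef(features.to_numpy(dtype=float), rowvar=False)
    sign, logdet_r = np.linalg.slogdet(R)
    if sign <= 0:
        raise ValueError("feature correlation matrix is not positive definite")

    lam, psi, fmin, converged = _ml_one_factor(R)
    heywood = bool(np.any(np.abs(lam) > 1.0))

    df = (p * (p + 1)) // 2 - 2 * p
    chi_square = max((n_obs - 1) * fmin, 0.0)
    if df <= 0:
        df = max(df, 0)
        chi_square = 0.0 if df == 0 and fmin < 1e-6 else chi_square
    # independence baseline: Sigma = I, so F_baseline = -log|R|
    baseline_chi = (n_obs - 1) * max(-logdet_r, 0.0)
    baseline_df = p * (p - 1) // 2
    residual = R - (np.outer(lam, lam) + np.diag(psi))
    rmsea, ci, cfi, srmr = fit_indices(
        chi_square, df, n_obs, baseline_chi, baseline_df, residual
    )
    p_value = float(stats.chi2.sf(chi_square, df)) if df > 0 else 1.0
    return EFAModel(
        retained_features=list(features.columns),
        loadings=lam,
        uniquenesses=psi,
        chi_square=chi_square,
        df=df,
        p_value=p_value,
        rmsea=rmsea,
        rmsea_ci90=ci,
        cfi=cfi,
        srmr=srmr,
        n_obs=n_obs,
        heywood=heywood,
        converged=converged,
    )


def _ml_one_factor(R: np.ndarray) -> tuple[np.ndarray, np.ndarray, float, bool]:
    """Maximize the one-factor likelihood; returns (lambda, psi, F_min, ok).

    The discrepancy F = log|Sigma| + tr(R Sigma^-1) - log|R| - p is
    concentrated over psi: for fixed psi the optimal loading lies along the
    leading eigenvector of psi^-1/2 R psi^-1/2.
    """
    p = R.shape[0]
    if p == 3:
        closed = _three_var_closed_form(R)
        if closed is not None:
            lam, psi = closed
            return lam, psi, _fml(R, lam, psi), True

    # concentrated discrepancy: with the loading profiled out, F equals the
    # sum of (theta_j - log theta_j - 1) over the p-1 smallest eigenvalues
    # of psi^-1/2 R psi^-1/2
    def objective(log_psi: np.ndarray) -> float:
        psi = np.exp(log_psi)
        star = R / np.sqrt(np.outer(psi, psi))
        eigval = np.linalg.eigvalsh(star)
        rest = eigval[:-1]
        rest = np.clip(rest, 1e-10, None)
        return float(np.sum(rest - np.log(rest) - 1.0))

    x0 = np.log(np.clip(1.0 - _smc(R), 0.05, 0.95))
    res = optimize.minimize(
        objective,
        x0,
        method="L-BFGS-B",
        bounds=[(np.log(5e-3), np.log(1.0))] * p,
        options={"maxiter": 500, "ftol": 1e-14, "gtol": 1e-10},
    )
    psi = np.exp(res.x)
    star = R / np.sqrt(np.outer(psi, psi))
    eigval, eigvec = np.linalg.eigh(star)
    theta1 = eigval[-1]
    w = eigvec[:, -1]
    lam = np.sqrt(psi) * w * np.sqrt(max(theta1 - 1.0, 0.0))
    if np.sum(lam) < 0:
        lam = -lam
    return lam, psi, _fml(R, lam, psi), bool(res.success)


def _smc(R: np.ndarray) -> np.ndarray:
    """Squared multiple correlations (communality start values)."""
    inv = np.linalg.inv(R)
    return 1.0 - 1.0 / np.diag(inv)


def _fml(R: np.ndarray, lam: np.ndarray, psi: np.ndarray) -> float:
    p = R.shape[0]
    sigma = np.outer(lam, lam) + np.diag(psi)
    sign_s, logdet_s = np.linalg.slogdet(sigma)
    sign_r, logdet_r = np.linalg.slogdet(R)
    if sign_s <= 0:
        return np.inf
    return float(logdet_s + np.trace(np.linalg.solve(sigma, R)) - logdet_r - p)


def fit_indices(
    chi_square: float,
    df: int,
    n_obs: int,
    baseline_chi_square: float,
    baseline_df: int,
    residual_corr: np.ndarray,
) -> tuple[float, tuple, float, float]:
    """(rmsea, rmsea 90% CI, cfi, srmr) from the chi-square decomposition.

    RMSEA CI bounds invert the noncentral chi-square distribution; SRMR
    averages squared off-diagonal residual correlations (diagonal residuals
    vanish under correlation-matrix analysis).
    """
    if df < 0:
        raise ValueError("model has negative degrees of freedom")
    n1 = max(n_obs - 1, 1)
    if df == 0:
        rmsea, ci = 0.0, (0.0, 0.0)
    else:
        rmsea = float(np.sqrt(max(chi_square - df, 0.0) / (df * n1)))
        ci = (
            _rmsea_bound(chi_square, df, n1, 0.95),
            _rmsea_bound(chi_square, df, n1, 0.05),
        )
    num = max(chi_square - df, 0.0)
    denom = max(baseline_chi_square - baseline_df, num, 0.0)
    cfi = 1.0 if denom == 0 else 1.0 - num / denom
    p = residual_corr.shape[0]
    off = residual_corr[np.triu_indices(p, k=1)]
    srmr = float(np.sqrt(np.mean(off**2))) if off.size else 0.0
    return rmsea, ci, float(cfi), srmr


def _rmsea_bound(chi_square: float, df: int, n1: int, prob: float) -> float:
    """Noncentrality lambda with ncx2.cdf(chi2; df, lambda) = prob."""
    if stats.ncx2.cdf(chi_square, df, 0.0) < prob:
        return 0.0
    hi = max(chi_square, 1.0)
    while stats.ncx2.cdf(chi_square, df, hi) > prob:
        hi *= 2
        if hi > 1e8:
            break
    lam = optimize.brentq(
        lambda nc: stats.ncx2.cdf(chi_square, df, nc) - prob, 0.0, hi
    )
    return float(np.sqrt(lam / (df * n1)))


def prune_features(
    features: pd.DataFrame,
    loading_threshold: float = 0.70,
    criteria: FitCriteria | None = None,
    min_features: int = 3,
    fit_gated: bool = False,
) -> EFAModel:
    """Iteratively drop the weakest-loading feature until all loadings hold.

    Removal is one at a time, smallest |loading| first (ties broken by
    feature name). By default the loop stops once every retained loading
    reaches ``loading_threshold`` (fit indices are still reported and
    checked); with ``fit_gated=True`` pruning also continues while the fit
    criteria fail, down to ``min_features``.
    """
    if features.shape[1] < min_features:
        raise ValueError(f"need at least {min_features} features to start")
    criteria = criteria or FitCriteria()
    current = features.copy()
    trail: list = []
    while True:
        model = fit_single_factor(current)
        model.criteria_met = criteria.passed(model)
        model.removal_trail = list(trail)
        weak = np.abs(model.loadings) < loading_threshold
        done = not weak.any() and (model.criteria_met or not fit_gated)
        if done or current.shape[1] <= min_features:
            return model
        order = sorted(
            range(len(model.retained_features)),
            key=lambda i: (np.abs(model.loadings[i]), model.retained_features[i]),
        )
        drop_idx = order[0]
        dropped = model.retained_features[drop_idx]
        trail.append((dropped, float(model.loadings[drop_idx])))
        current = current.drop(columns=[dropped])


def profile_scores(
    features: pd.DataFrame,
    anchor: str | None = None,
) -> ProfileScores:
    """First-principal-component scores of the retained features.

    ``features`` must already be standardized and reverse-coded (see
    :func:`reverse_code`). The component sign is fixed so the loading of
    ``anchor`` (default: first column, conventionally reverse-coded
    acceleration magnitude) is positive, making lower scores = better
    performance.
    """
    if features.shape[1] < 2:
        raise ValueError("profile scoring requires at least 2 features")
    X = features.to_numpy(dtype=float)
    X = X - X.mean(axis=0)
    cov = np.cov(X, rowvar=False, ddof=1)
    eigval, eigvec = np.linalg.eigh(cov)
    if eigval[-1] <= 1e-12:
        raise ValueError("degenerate feature covariance")
    pc = eigvec[:, -1]
    anchor = anchor or features.columns[0]
    anchor_idx = list(features.columns).index(anchor)
    if pc[anchor_idx] < 0:
        pc = -pc
    scores = X @ pc
    var_pct = 100.0 * eigval[-1] / np.sum(eigval)
    return ProfileScores(
        scores=pd.Series(scores, index=features.index, name="movement_profile"),
        component_loadings=pc,
        retained_features=list(features.columns),
        variance_explained_pct=float(var_pct),
    )
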