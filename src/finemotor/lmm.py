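"""Restricted-maximum-likelihood linear mixed models with random intercepts.

Supports a random intercept per subject plus an optional nested intercept
(e.g. trial-within-subject), i.e. the ``1|subject/trial`` structure. The
marginal covariance of each subject block is

    V_i = sigma2_e I + sigma2_s 11' + sigma2_t Z_i Z_i'

with Z_i the nested-level indicator matrix, so every REML evaluation
reduces (matrix determinant lemma / Woodbury) to one small symmetric solve
per block using precomputed sufficient statistics. This keeps the
simulation-based calibration tests cheap.

Inference uses Satterthwaite denominator degrees of freedom: the variance
of variance-parameter estimates comes from the numerical Hessian of the
REML criterion, and the df of a contrast c is 2 f^2 / (g' A g) with
f = c' Vbeta c and g its gradient in the variance parameters. Multi-df
F tests aggregate per-eigencontrast dfs the same way lmerTest does.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

__all__ = ["LMMFit", "fit_lmm"]

_FLOOR = 1e-10


@dataclass
class _BlockStats:
    """Per-subject sufficient statistics for the Woodbury REML evaluation."""

    n: int
    G: np.ndarray  # U'U, U = [1, Z]
    A: np.ndarray  # U'X
    b: np.ndarray  # U'y
    xtx: np.ndarray
    xty: np.ndarray
    yty: float


@dataclass
class LMMFit:
    """A fitted random-intercept mixed model."""

    beta: np.ndarray
    cov_beta: np.ndarray
    names: list
    sigma2: dict  # {"subject": ..., "nested": ..., "residual": ...}
    reml_neg2ll: float
    n_obs: int
    converged: bool
    simplified: bool  # True if a boundary variance component was dropped
    _engine: "_Engine" = field(repr=False, default=None)

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov_beta))

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X) @ self.beta

    def contrast_t(self, c: np.ndarray) -> tuple[float, float, float, float]:
        """(estimate, SE, t, Satterthwaite df) for a single contrast."""
        c = np.asarray(c, dtype=float)
        est = float(c @ self.beta)
        var = float(c @ self.cov_beta @ c)
        df = self._engine.satterthwaite_df(c)
        return est, np.sqrt(var), est / np.sqrt(var), df

    def wald_f(self, L: np.ndarray) -> tuple[float, int, float, float]:
        """Multi-df Wald F test of L @ beta = 0.

        Returns (F, numerator df, Satterthwaite denominator df, p-value).
        """
        from scipy import stats

        L = np.atleast_2d(np.asarray(L, dtype=float))
        q = L.shape[0]
        vlv = L @ self.cov_beta @ L.T
        lb = L @ self.beta
        fstat = float(lb @ np.linalg.solve(vlv, lb)) / q
        # eigencontrasts of the contrast covariance, per lmerTest
        eigval, eigvec = np.linalg.eigh(vlv)
        keep = eigval > max(eigval.max(), 0) * 1e-10
        dfs = []
        for j in np.flatnonzero(keep):
            row = eigvec[:, j] @ L
            dfs.append(self._engine.satterthwaite_df(row))
        dfs = np.asarray(dfs)
        usable = dfs[dfs > 2]
        if usable.size:
            e_sum = float(np.sum(usable / (usable - 2)))
            ddf = 2 * e_sum / (e_sum - q) if e_sum > q else float(self.n_obs)
        else:
            ddf = float(self.n_obs)
        p = float(stats.f.sf(fstat, q, ddf))
        return fstat, q, ddf, p

    def variance_explained(self, X: np.ndarray) -> tuple[float, float]:
        """(marginal, conditional) R^2 in the Nakagawa decomposition."""
        var_fixed = float(np.var(self.predict(X)))
        var_random = self.sigma2.get("subject", 0.0) + self.sigma2.get("nested", 0.0)
        total = var_fixed + var_random + self.sigma2["residual"]
        return var_fixed / total, (var_fixed + var_random) / total


class _Engine:
    """REML computation over subject blocks with optional nested intercepts."""

    def __init__(
        self,
        y: np.ndarray,
        X: np.ndarray,
        subject: np.ndarray,
        nested: np.ndarray | None,
        components: tuple,
    ) -> None:
        self.n, self.p = X.shape
        self.components = components  # subset of ("subject", "nested")
        self.blocks: list[_BlockStats] = []
        for g in np.unique(subject):
            sel = subject == g
            Xg, yg = X[sel], y[sel]
            cols = [np.ones(int(sel.sum()))] if "subject" in components else []
            k_sub = len(cols)
            if nested is not None and "nested" in components:
                levels = np.unique(nested[sel])
                for lv in levels:
                    cols.append((nested[sel] == lv).astype(float))
            U = np.column_stack(cols) if cols else np.zeros((int(sel.sum()), 0))
            self.blocks.append(
                _BlockStats(
                    n=int(sel.sum()),
                    G=U.T @ U,
                    A=U.T @ Xg,
                    b=U.T @ yg,
                    xtx=Xg.T @ Xg,
                    xty=Xg.T @ yg,
                    yty=float(yg @ yg),
                )
            )
            self._k_sub = k_sub
        self.var_y = float(np.var(y)) or 1.0

    def _d_diag(self, theta: dict, k_total: int) -> np.ndarray:
        d = []
        if "subject" in self.components:
            d.append(theta["subject"])
        n_nested = k_total - len(d)
        d.extend([theta.get("nested", 0.0)] * n_nested)
        return np.asarray(d)

    def neg2ll_and_gls(self, theta: dict):
        """REML -2 log-likelihood plus GLS beta and its covariance."""
        s2e = theta["residual"]
        xtvx = np.zeros((self.p, self.p))
        xtvy = np.zeros(self.p)
        ytvy = 0.0
        logdet_v = 0.0
        for blk in self.blocks:
            k = blk.G.shape[0]
            if k:
                d = np.maximum(self._d_diag(theta, k), _FLOOR)
                M = blk.G + np.diag(s2e / d)
                cho = np.linalg.cholesky(M)
                logdet_v += blk.n * np.log(s2e) + np.sum(np.log(d)) + 2 * np.sum(
                    np.log(np.diag(cho))
                ) - k * np.log(s2e)
                WA = np.linalg.solve(M, blk.A) if blk.A.size else blk.A
                Wb = np.linalg.solve(M, blk.b)
                xtvx += (blk.xtx - blk.A.T @ WA) / s2e
                xtvy += (blk.xty - blk.A.T @ Wb) / s2e
                ytvy += (blk.yty - blk.b @ Wb) / s2e
            else:
                logdet_v += blk.n * np.log(s2e)
                xtvx += blk.xtx / s2e
                xtvy += blk.xty / s2e
                ytvy += blk.yty / s2e
        cho_x = np.linalg.cholesky(xtvx)
        beta = np.linalg.solve(xtvx, xtvy)
        rss = ytvy - beta @ xtvy
        logdet_x = 2 * np.sum(np.log(np.diag(cho_x)))
        neg2 = logdet_v + logdet_x + rss + (self.n - self.p) * np.log(2 * np.pi)
        cov_beta = np.linalg.inv(xtvx)
        return neg2, beta, cov_beta

    # -- optimization -----------------------------------------------------

    def fit(self) -> tuple[dict, float, bool]:
        names = list(self.components) + ["residual"]
        vy = self.var_y

        def unpack(z):
            return {name: float(np.exp(v)) * vy for name, v in zip(names, z)}

        def objective(z):
            try:
                return self.neg2ll_and_gls(unpack(z))[0]
            except np.linalg.LinAlgError:
                return 1e12

        x0 = np.log(np.full(len(names), 1.0 / (len(names) + 1)))
        res = optimize.minimize(
            objective,
            x0,
            method="L-BFGS-B",
            bounds=[(np.log(1e-8), np.log(1e4))] * len(names),
        )
        return unpack(res.x), float(res.fun), bool(res.success)

    # -- Satterthwaite machinery ------------------------------------------

    def prepare_inference(self, theta: dict) -> None:
        """Cache the variance-parameter covariance at the REML optimum."""
        self.theta = theta
        names = [k for k in ("subject", "nested", "residual") if k in theta]
        self._theta_names = names
        th = np.array([theta[k] for k in names])
        h = np.maximum(1e-3 * th, 1e-10 * self.var_y)

        def f(vec):
            return self.neg2ll_and_gls(dict(zip(names, vec)))[0]

        m = len(names)
        H = np.zeros((m, m))
        f0 = f(th)
        for i in range(m):
            for j in range(i, m):
                ei = np.zeros(m)
                ej = np.zeros(m)
                ei[i] = h[i]
                ej[j] = h[j]
                if i == j:
                    H[i, i] = (f(th + ei) - 2 * f0 + f(th - ei)) / h[i] ** 2
                else:
                    H[i, j] = H[j, i] = (
                        f(th + ei + ej) - f(th + ei - ej) - f(th - ei + ej) + f(th - ei - ej)
                    ) / (4 * h[i] * h[j])
        try:
            self._theta_cov = 2.0 * np.linalg.inv(H)
        except np.linalg.LinAlgError:
            self._theta_cov = 2.0 * np.linalg.pinv(H)
        # cache Vbeta at perturbed theta for gradient reuse
        self._grad_cache = {}
        self._h = h
        self._th = th

    def _cov_beta_at(self, vec: np.ndarray) -> np.ndarray:
        key = tuple(np.round(vec, 14))
        if key not in self._grad_cache:
            theta = dict(zip(self._theta_names, np.maximum(vec, _FLOOR)))
            self._grad_cache[key] = self.neg2ll_and_gls(theta)[2]
        return self._grad_cache[key]

    def satterthwaite_df(self, c: np.ndarray) -> float:
        c = np.asarray(c, dtype=float)
        f0 = float(c @ self._cov_beta_at(self._th) @ c)
        m = len(self._th)
        g = np.zeros(m)
        for i in range(m):
            ei = np.zeros(m)
            ei[i] = self._h[i]
            g[i] = (
                float(c @ self._cov_beta_at(self._th + ei) @ c)
                - float(c @ self._cov_beta_at(self._th - ei) @ c)
            ) / (2 * self._h[i])
        denom = float(g @ self._theta_cov @ g)
        if denom <= 0:
            return float(self.n - self.p)
        return max(2 * f0**2 / denom, 1.0)


def fit_lmm(
    y: np.ndarray,
    X: np.ndarray,
    subject: np.ndarray,
    nested: np.ndarray | None = None,
    names: list | None = None,
    include_subject: bool = True,
    include_nested: bool = True,
) -> LMMFit:
    """Fit a REML mixed model with random intercepts.

    Parameters
    ----------
    y, X
        Response vector and fixed-effect design matrix.
    subject
        Subject labels (outer random intercept and blocking factor).
    nested
        Optional labels of the nested factor (e.g. trial number); a random
        intercept is added for each subject x nested level.
    include_subject, include_nested
        Force components out of the model (used by degenerate-case tests:
        with both False the fit is generalized least squares = OLS).
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    subject = np.asarray(subject)
    if X.shape[0] != y.size:
        raise ValueError("X and y lengths differ")
    if np.unique(subject).size < 1:
        raise ValueError("at least one subject required")
    components = tuple(
        name
        for name, ok in (
            ("subject", include_subject and np.unique(subject).size >= 2),
            ("nested", include_nested and nested is not None),
        )
        if ok
    )
    engine = _Engine(y, X, subject, nested, components)
    theta, neg2, converged = engine.fit()

    # boundary components: drop and refit with a simpler structure
    simplified = False
    floor = 1e-7 * engine.var_y
    drop = [k for k in components if theta[k] < floor]
    if drop:
        simplified = True
        components = tuple(k for k in components if k not in drop)
        engine = _Engine(y, X, subject, nested, components)
        theta, neg2, converged = engine.fit()
        for k in drop:
            theta[k] = 0.0

    engine.prepare_inference({k: v for k, v in theta.items() if v > 0 or k == "residual"})
    _, beta, cov_beta = engine.neg2ll_and_gls(
        {k: max(v, _FLOOR) for k, v in theta.items()}
    )
    return LMMFit(
        beta=beta,
        cov_beta=cov_beta,
        names=names or [f"x{i}" for i in range(X.shape[1])],
        sigma2=theta,
        reml_neg2ll=neg2,
        n_obs=y.size,
        converged=converged,
        simplified=simplified,
        _engine=engine,
    )
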