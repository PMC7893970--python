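"""Two-level random-intercept linear mixed model, fit by (RE)ML.

The model is

    y_ij = x_ij' beta + u_j + e_ij,   u_j ~ N(0, sigma_u^2),  e_ij ~ N(0, sigma_e^2)

for woman i in cluster j.  Estimation profiles the Gaussian likelihood over
the variance ratio lambda = sigma_u^2 / sigma_e^2: for a candidate lambda the
GLS solution for beta and the residual scale are available in closed form
(the per-cluster covariance I + lambda * 11' inverts analytically via the
Sherman–Morrison identity), leaving a one-dimensional concave search over
log(lambda).  A coarse grid locates the basin and a bounded scalar
minimization refines it; a solution at the lower bound is reported as the
boundary sigma_u^2 = 0 (ICC 0), in which case the fit coincides with ordinary
least squares.

ML is the default so that AIC/BIC comparisons across specifications with
different fixed effects are valid; REML is available (and is the right choice
for variance components when the fixed part is fixed), but REML likelihoods
of models with different fixed effects are not comparable.

The intraclass correlation coefficient ICC = sigma_u^2/(sigma_u^2+sigma_e^2)
is the share of outcome variance attributable to between-cluster differences.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .errors import RankError, ValidationError

__all__ = ["RandomInterceptLM", "RandomInterceptLMResults", "icc"]

_LAM_LO = 1e-8
_LAM_HI = 1e4


def icc(fit: "RandomInterceptLMResults") -> float:
    """Intraclass correlation sigma_u^2 / (sigma_u^2 + sigma_e^2)."""
    return fit.icc


@dataclass
class _Profile:
    """Profiled quantities at one candidate variance ratio."""

    lam: float
    beta: np.ndarray
    sigma_e2: float
    loglik: float
    xtvix: np.ndarray  # X' V_lam^{-1} X


class RandomInterceptLM:
    """Random-intercept linear model for clustered (two-level) data.

    Parameters
    ----------
    endog : array-like, shape (n,)
        Response vector.
    exog : array-like, shape (n, p)
        Fixed-effects design matrix (include the intercept column yourself,
        or use :meth:`from_dataframe`).
    groups : array-like, shape (n,)
        Cluster labels; any hashable values.
    exog_names : sequence of str, optional
        Column names for reporting; defaults to x0..x{p-1}.
    """

    def __init__(self, endog, exog, groups, exog_names: Optional[Sequence[str]] = None):
        y = np.asarray(endog, dtype=float).ravel()
        X = np.asarray(exog, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        groups = np.asarray(groups)
        if y.shape[0] != X.shape[0] or y.shape[0] != groups.shape[0]:
            raise ValidationError("endog, exog and groups must have equal length")
        if not np.all(np.isfinite(y)) or not np.all(np.isfinite(X)):
            raise ValidationError("endog/exog contain non-finite values")
        n, p = X.shape
        if n <= p + 2:
            raise ValidationError(
                f"need n_obs > n_fixed_effects + 2 (got n={n}, p={p})"
            )
        if np.linalg.matrix_rank(X) < p:
            raise RankError("design matrix is rank deficient")

        codes, uniques = pd.factorize(groups)
        if len(uniques) < 2:
            raise ValidationError("need at least 2 clusters")
        self.endog = y
        self.exog = X
        self.group_codes = codes
        self.group_labels = list(uniques)
        self.exog_names = (
            list(exog_names) if exog_names is not None else [f"x{i}" for i in range(p)]
        )
        if len(self.exog_names) != p:
            raise ValidationError("exog_names length mismatch")

        J = len(uniques)
        self.n_obs, self.n_params_fixed, self.n_groups = n, p, J
        # Per-cluster sufficient statistics: everything the profiled
        # likelihood needs at any lambda.
        self._m = np.bincount(codes, minlength=J).astype(float)
        self._xtx = np.einsum("ni,nj->ij", X, X)
        self._xty = X.T @ y
        self._yty = float(y @ y)
        xs = np.zeros((J, p))
        ys = np.zeros(J)
        np.add.at(xs, codes, X)
        np.add.at(ys, codes, y)
        self._xs = xs  # X_j' 1, per cluster
        self._ys = ys  # 1' y_j, per cluster

    @classmethod
    def from_dataframe(
        cls, data: pd.DataFrame, response: str, terms: Sequence[str], cluster: str
    ) -> "RandomInterceptLM":
        """Build from a tidy frame; adds an intercept, drops incomplete rows."""
        cols = [response, *terms, cluster]
        missing = [c for c in cols if c not in data.columns]
        if missing:
            raise ValidationError(f"columns not in data: {missing}")
        sub = data[cols].dropna()
        X = np.column_stack(
            [np.ones(len(sub))] + [sub[t].to_numpy(dtype=float) for t in terms]
        )
        return cls(
            sub[response].to_numpy(dtype=float),
            X,
            sub[cluster].to_numpy(),
            exog_names=["intercept", *terms],
        )

    # -- profiled likelihood ------------------------------------------------

    def _profile(self, lam: float, reml: bool) -> _Profile:
        m, xs, ys = self._m, self._xs, self._ys
        c = lam / (1.0 + lam * m)  # Sherman–Morrison weight per cluster
        A = self._xtx - np.einsum("j,ji,jk->ik", c, xs, xs)
        b = self._xty - (c * ys) @ xs
        yvy = self._yty - float(c @ (ys**2))
        try:
            beta = np.linalg.solve(A, b)
        except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded by rank check
            raise RankError(f"normal equations singular at lambda={lam}") from exc
        q = yvy - float(beta @ b)
        q = max(q, 1e-300)
        n, p = self.n_obs, self.n_params_fixed
        logdet_v = float(np.sum(np.log1p(lam * m)))
        if reml:
            df = n - p
            sigma_e2 = q / df
            sign, logdet_a = np.linalg.slogdet(A)
            ll = -0.5 * (
                df * (math.log(2 * math.pi * sigma_e2) + 1.0) + logdet_v + logdet_a
            )
        else:
            sigma_e2 = q / n
            ll = -0.5 * (n * (math.log(2 * math.pi * sigma_e2) + 1.0) + logdet_v)
        return _Profile(lam=lam, beta=beta, sigma_e2=sigma_e2, loglik=ll, xtvix=A)

    def loglike(self, sigma_u2: float, sigma_e2: float, beta=None, reml: bool = False) -> float:
        """Log-likelihood at explicit variance components (beta profiled if None).

        Useful for diagnostics and independent cross-checks; :meth:`fit`
        maximizes the internally profiled criterion instead.
        """
        if sigma_e2 <= 0 or sigma_u2 < 0:
            raise ValueError("need sigma_e2 > 0 and sigma_u2 >= 0")
        lam = sigma_u2 / sigma_e2
        m, xs, ys = self._m, self._xs, self._ys
        c = lam / (1.0 + lam * m)
        A = self._xtx - np.einsum("j,ji,jk->ik", c, xs, xs)
        bb = self._xty - (c * ys) @ xs
        yvy = self._yty - float(c @ (ys**2))
        b = np.asarray(beta, float) if beta is not None else np.linalg.solve(A, bb)
        q = yvy - 2 * float(b @ bb) + float(b @ A @ b)
        n, p = self.n_obs, self.n_params_fixed
        logdet_v = float(np.sum(np.log1p(lam * m)))
        ll = -0.5 * (n * math.log(2 * math.pi * sigma_e2) + logdet_v + q / sigma_e2)
        if reml:
            # restricted likelihood: + p/2 log(2*pi*sigma_e2) - 1/2 log|X'V^-1 X|
            # with X'V^-1 X = A / sigma_e2
            logdet_a = float(np.linalg.slogdet(A)[1]) - p * math.log(sigma_e2)
            ll += 0.5 * p * math.log(2 * math.pi) - 0.5 * logdet_a
        return ll

    def fit(
        self,
        method: str = "ml",
        lam_bounds: tuple[float, float] = (_LAM_LO, _LAM_HI),
        grid_size: int = 61,
        ci_level: float = 0.95,
    ) -> "RandomInterceptLMResults":
        """Maximize the profiled (restricted) likelihood over log(lambda)."""
        method = method.lower()
        if method not in {"ml", "reml"}:
            raise ValidationError("method must be 'ml' or 'reml'")
        reml = method == "reml"

        lo, hi = lam_bounds
        grid = np.exp(np.linspace(math.log(lo), math.log(hi), grid_size))
        lls = np.array([self._profile(l, reml).loglik for l in grid])
        k = int(np.argmax(lls))
        left = grid[max(k - 1, 0)]
        right = grid[min(k + 1, grid_size - 1)]

        converged = True
        if k == 0:
            lam_hat = lo
        elif k == grid_size - 1:
            lam_hat = hi
            converged = False  # ran into the upper bound
        else:
            res = optimize.minimize_scalar(
                lambda t: -self._profile(math.exp(t), reml).loglik,
                bounds=(math.log(left), math.log(right)),
                method="bounded",
                options={"xatol": 1e-12},
            )
            lam_hat = math.exp(res.x)
            converged = bool(res.success)

        at_boundary = lam_hat <= lo * (1 + 1e-6)
        prof = self._profile(0.0 if at_boundary else lam_hat, reml)
        sigma_e2 = prof.sigma_e2
        sigma_u2 = 0.0 if at_boundary else lam_hat * sigma_e2

        cov_beta = sigma_e2 * np.linalg.inv(prof.xtvix)
        se = np.sqrt(np.diag(cov_beta))

        all_singletons = bool(np.all(self._m == 1))
        if all_singletons:
            # sigma_u^2 is unidentified when every cluster has one member.
            converged = False

        p = self.n_params_fixed
        k_params = p + 2
        ll = prof.loglik
        n_for_bic = self.n_obs
        return RandomInterceptLMResults(
            model=self,
            method=method,
            beta=prof.beta,
            se=se,
            cov_beta=cov_beta,
            sigma_u2=sigma_u2,
            sigma_e2=sigma_e2,
            loglik=ll,
            aic=-2 * ll + 2 * k_params,
            bic=-2 * ll + math.log(n_for_bic) * k_params,
            n_obs=self.n_obs,
            n_clusters=self.n_groups,
            converged=converged,
            ci_level=ci_level,
        )


@dataclass
class RandomInterceptLMResults:
    """Fitted random-intercept model: estimates, uncertainty, diagnostics."""

    model: RandomInterceptLM
    method: str
    beta: np.ndarray
    se: np.ndarray
    cov_beta: np.ndarray
    sigma_u2: float
    sigma_e2: float
    loglik: float
    aic: float
    bic: float
    n_obs: int
    n_clusters: int
    converged: bool
    ci_level: float = 0.95

    @property
    def exog_names(self) -> list[str]:
        return self.model.exog_names

    @property
    def params(self) -> pd.Series:
        return pd.Series(self.beta, index=self.exog_names, name="estimate")

    @property
    def bse(self) -> pd.Series:
        return pd.Series(self.se, index=self.exog_names, name="se")

    @property
    def icc(self) -> float:
        total = self.sigma_u2 + self.sigma_e2
        return self.sigma_u2 / total if total > 0 else 0.0

    @property
    def n_params(self) -> int:
        return self.model.n_params_fixed + 2

    def conf_int(self, level: Optional[float] = None) -> pd.DataFrame:
        """Wald intervals beta ± z·se (large-sample normal multiplier)."""
        from scipy import stats

        level = self.ci_level if level is None else level
        z = float(stats.norm.ppf(0.5 + level / 2))
        lo = self.beta - z * self.se
        hi = self.beta + z * self.se
        return pd.DataFrame({"ci_low": lo, "ci_high": hi}, index=self.exog_names)

    def fittedvalues(self) -> np.ndarray:
        return self.model.exog @ self.beta

    def to_dict(self) -> dict:
        ci = self.conf_int()
        return {
            "method": self.method,
            "coefficients": {
                name: {
                    "estimate": float(b),
                    "se": float(s),
                    "ci_low": float(ci.loc[name, "ci_low"]),
                    "ci_high": float(ci.loc[name, "ci_high"]),
                }
                for name, b, s in zip(self.exog_names, self.beta, self.se)
            },
            "sigma_u2": float(self.sigma_u2),
            "sigma_e2": float(self.sigma_e2),
            "icc": float(self.icc),
            "loglik": float(self.loglik),
            "aic": float(self.aic),
            "bic": float(self.bic),
            "n_obs": int(self.n_obs),
            "n_clusters": int(self.n_clusters),
            "converged": bool(self.converged),
            "ci_level": float(self.ci_level),
        }

    def summary(self) -> str:
        ci = self.conf_int()
        lines = [
            "Random-intercept linear mixed model",
            f"  method: {self.method.upper()}   n_obs: {self.n_obs}   "
            f"clusters: {self.n_clusters}   converged: {self.converged}",
            f"  loglik: {self.loglik:.4f}   AIC: {self.aic:.4f}   BIC: {self.bic:.4f}",
            f"  sigma_u2: {self.sigma_u2:.6f}   sigma_e2: {self.sigma_e2:.6f}   "
            f"ICC: {self.icc:.4f}",
            "",
            f"{'term':<28}{'estimate':>12}{'se':>10}"
            f"{'ci_low':>12}{'ci_high':>12}",
        ]
        for name, b, s in zip(self.exog_names, self.beta, self.se):
            lines.append(
                f"{name:<28}{b:>12.4f}{s:>10.4f}"
                f"{ci.loc[name, 'ci_low']:>12.4f}{ci.loc[name, 'ci_high']:>12.4f}"
            )
        return "\n".join(lines)
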