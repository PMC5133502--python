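"""Linear mixed model with a kinship-structured polygenic random effect.

Model:  y = X B + g + e,   g ~ N(0, sigma_g^2 * 2*Phi),  e ~ N(0, sigma_e^2 * I)

so that Var(y) = Sigma = sigma_g^2 * A + sigma_e^2 * I with A = 2*Phi the
additive relationship matrix. The fit eigendecomposes A once (A = V D V')
and profiles the (restricted) log-likelihood over the single variance ratio
delta = sigma_g^2 / sigma_e^2; in the rotated basis the model is a weighted
least-squares problem, so each profile evaluation is O(n c^2).

The fitted object exposes everything downstream score tests and the
permutation engine need: B-hat, the variance components, Sigma^-1 (and
matrix-free products with Sigma^-1 and Sigma^-1/2), marginal residuals
y - X B-hat, conditional residuals y - X B-hat - BLUP(g), and the whitened
residuals Sigma^-1/2 (y - X B-hat) that are exchangeable under the fitted
null and therefore safe to permute across individuals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .pedigree import KinshipMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "PhenotypeData",
    "FamilialLMM",
    "FamilialLMMResults",
    "FitError",
    "fit_null_model",
    "decorrelated_residuals",
]

_LOG_DELTA_LO = np.log(1e-6)
_LOG_DELTA_HI = np.log(1e6)


class FitError(RuntimeError):
    """Mixed-model fit failed (non-convergence or degenerate covariance)."""


@dataclass
class PhenotypeData:
    """Quantitative trait, covariates (with intercept) and sample IDs."""

    y: np.ndarray
    X: np.ndarray
    sample_order: list[str]
    covariate_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float).ravel()
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        n = self.y.shape[0]
        if self.X.shape[0] != n or len(self.sample_order) != n:
            raise ValueError("y, X and sample_order lengths disagree")
        if np.isnan(self.y).any() or np.isnan(self.X).any():
            raise ValueError("missing values must be dropped before constructing PhenotypeData")
        if np.linalg.matrix_rank(self.X) < self.X.shape[1]:
            raise ValueError("covariate matrix X is rank deficient")

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        trait: str,
        covariates: list[str] | None = None,
        id_col: str | None = None,
        add_intercept: bool = True,
    ) -> "PhenotypeData":
        """Build from a table, dropping rows with missing trait/covariates."""
        covariates = list(covariates or [])
        ids = df[id_col].astype(str) if id_col is not None else df.index.astype(str)
        sub = df[[trait] + covariates].copy()
        keep = sub.notna().all(axis=1)
        n_drop = int((~keep).sum())
        if n_drop:
            logger.info("dropping %d samples with missing phenotype/covariates", n_drop)
        sub, ids = sub[keep], ids[keep]
        X = sub[covariates].to_numpy(dtype=float)
        names = list(covariates)
        if add_intercept:
            X = np.column_stack([np.ones(len(sub)), X])
            names = ["intercept"] + names
        return cls(sub[trait].to_numpy(dtype=float), X, list(ids), names)


class FamilialLMM:
    """Gaussian mixed model ``y ~ X`` with covariance sigma_g^2*A + sigma_e^2*I.

    Parameters
    ----------
    y, X : trait vector and covariate matrix (intercept included by caller).
    relationship : additive relationship matrix A = 2*Phi, aligned with y.
    eig : optional precomputed ``(eigenvalues, eigenvectors)`` of A; pass it
        when fitting many traits on the same pedigree to avoid repeating the
        O(n^3) eigendecomposition.
    """

    def __init__(
        self,
        y: np.ndarray,
        X: np.ndarray,
        relationship: np.ndarray,
        sample_order: list[str] | None = None,
        eig: tuple[np.ndarray, np.ndarray] | None = None,
    ) -> None:
        self.y = np.asarray(y, dtype=float).ravel()
        self.X = np.atleast_2d(np.asarray(X, dtype=float))
        self.A = np.asarray(relationship, dtype=float)
        n = self.y.shape[0]
        if self.X.shape[0] != n or self.A.shape != (n, n):
            raise ValueError("y, X and relationship dimensions disagree")
        if n < self.X.shape[1] + 2:
            raise FitError(f"need n >= c + 2 samples (n={n}, c={self.X.shape[1]})")
        self.sample_order = sample_order
        if eig is None:
            d, V = np.linalg.eigh(self.A)
            d = np.clip(d, 0.0, None)
        else:
            d, V = eig
        self._d, self._V = np.asarray(d, float), np.asarray(V, float)
        self._yt = self._V.T @ self.y
        self._Xt = self._V.T @ self.X

    @classmethod
    def from_phenotype_data(
        cls, data: PhenotypeData, K: KinshipMatrix, eig=None
    ) -> "FamilialLMM":
        """Align the kinship matrix to the phenotype sample order."""
        kin = K.subset(data.sample_order)
        return cls(data.y, data.X, kin.relationship(), data.sample_order, eig=eig)

    # -- profile likelihood over delta = sigma_g^2 / sigma_e^2 ---------------

    def _profile(self, log_delta: float, reml: bool):
        n, c = self.y.shape[0], self.X.shape[1]
        lam = np.exp(log_delta) * self._d + 1.0
        Xw = self._Xt / lam[:, None]
        XtWX = self._Xt.T @ Xw
        beta = np.linalg.solve(XtWX, Xw.T @ self._yt)
        resid = self._yt - self._Xt @ beta
        rss = float(resid @ (resid / lam))
        dof = n - c if reml else n
        sigma_e2 = max(rss / dof, 0.0)
        log_s = np.log(max(sigma_e2, 1e-300))
        ll = -0.5 * (dof * (np.log(2 * np.pi) + log_s + 1.0) + np.log(lam).sum())
        if reml:
            ll -= 0.5 * np.linalg.slogdet(XtWX)[1]
        return ll, beta, sigma_e2

    def fit(self, method: str = "ML") -> "FamilialLMMResults":
        """Maximise the (restricted) likelihood; deterministic given inputs.

        Profiles over log delta in [log 1e-6, log 1e6] with Brent tolerance
        1e-8, and keeps the boundary solution sigma_g^2 = 0 when it is at
        least as good (guaranteeing loglik >= the OLS loglik).
        """
        if method not in ("ML", "REML"):
            raise ValueError(f"method must be 'ML' or 'REML', got {method!r}")
        reml = method == "REML"
        opt = minimize_scalar(
            lambda ld: -self._profile(ld, reml)[0],
            bounds=(_LOG_DELTA_LO, _LOG_DELTA_HI),
            method="bounded",
            options={"xatol": 1e-8, "maxiter": 500},
        )
        if not opt.success:  # pragma: no cover - bounded Brent rarely fails
            raise FitError(f"variance-ratio optimisation failed: {opt.message}")
        ll_opt = -opt.fun
        # sigma_g^2 = 0 boundary: lam = 1 exactly
        ll0, beta0, s0 = self._profile(-np.inf, reml)
        if ll0 >= ll_opt - 1e-8 * (1.0 + abs(ll_opt)):  # prefer parsimony on ties
            delta, ll, beta, sigma_e2 = 0.0, ll0, beta0, s0
        else:
            delta = float(np.exp(opt.x))
            ll, beta, sigma_e2 = self._profile(opt.x, reml)
        if sigma_e2 <= 0.0:
            sigma_e2 = 1e-12  # degenerate zero-residual trait; keep Sigma invertible
        sigma_g2 = delta * sigma_e2
        if not np.isfinite(ll):
            raise FitError("non-finite likelihood at optimum")
        return FamilialLMMResults(self, method, beta, sigma_g2, sigma_e2, float(ll))


class FamilialLMMResults:
    """Fitted quantities of a :class:`FamilialLMM`.

    Attributes
    ----------
    beta_hat : fixed-effect estimates B-hat.
    sigma_g2, sigma_e2 : polygenic and residual variance components.
    loglik : maximised (restricted) log-likelihood.
    """

    def __init__(self, model, method, beta_hat, sigma_g2, sigma_e2, loglik):
        self.model = model
        self.method = method
        self.beta_hat = np.asarray(beta_hat, float)
        self.sigma_g2 = float(sigma_g2)
        self.sigma_e2 = float(sigma_e2)
        self.loglik = float(loglik)
        # eigenvalues of Sigma in the relationship eigenbasis
        self._s = self.sigma_g2 * model._d + self.sigma_e2

    # -- derived quantities ---------------------------------------------------

    @property
    def nobs(self) -> int:
        return self.model.y.shape[0]

    @property
    def h2(self) -> float:
        """Narrow-sense heritability sigma_g^2 / (sigma_g^2 + sigma_e^2)."""
        return self.sigma_g2 / (self.sigma_g2 + self.sigma_e2)

    @property
    def marginal_residuals(self) -> np.ndarray:
        return self.model.y - self.model.X @ self.beta_hat

    @property
    def blup(self) -> np.ndarray:
        """BLUP of the polygenic effect: sigma_g^2 * A * Sigma^-1 * r."""
        V, d = self.model._V, self.model._d
        r = self.marginal_residuals
        return V @ ((self.sigma_g2 * d / self._s) * (V.T @ r))

    @property
    def conditional_residuals(self) -> np.ndarray:
        return self.marginal_residuals - self.blup

    @property
    def Sigma_inv(self) -> np.ndarray:
        V = self.model._V
        return (V / self._s) @ V.T

    def inv_matmul(self, M: np.ndarray) -> np.ndarray:
        """Sigma^-1 @ M without forming Sigma^-1."""
        V = self.model._V
        return V @ ((V.T @ M).T / self._s).T

    def half_inv_matmul(self, M: np.ndarray) -> np.ndarray:
        """Sigma^-1/2 @ M (symmetric square root)."""
        V = self.model._V
        return V @ ((V.T @ M).T / np.sqrt(self._s)).T

    def fe_cov(self) -> np.ndarray:
        """Covariance of B-hat: (X' Sigma^-1 X)^-1."""
        Xw = self.model._Xt / self._s[:, None]
        return np.linalg.inv(self.model._Xt.T @ Xw)

    @property
    def bse(self) -> np.ndarray:
        return np.sqrt(np.diag(self.fe_cov()))

    def decorrelated_residuals(self, kind: str = "whitened") -> np.ndarray:
        """Residuals treated as exchangeable across individuals.

        ``whitened`` (default): Sigma^-1/2 (y - X B-hat), mean-centred —
        exactly uncorrelated with unit variance under the fitted model.
        ``conditional``: y - X B-hat - BLUP(g), mean-centred — residuals
        after removing the predicted polygenic effect.
        """
        if kind == "whitened":
            r = self.half_inv_matmul(self.marginal_residuals)
        elif kind == "conditional":
            r = self.conditional_residuals
        else:
            raise ValueError(f"residual kind must be 'whitened' or 'conditional', got {kind!r}")
        return r - r.mean()

    def summary(self) -> str:
        names = ["x%d" % j for j in range(self.beta_hat.size)]
        lines = [
            "Familial linear mixed model (%s)" % self.method,
            "n = %d, covariates = %d" % (self.nobs, self.beta_hat.size),
            "log-likelihood = %.4f" % self.loglik,
            "sigma_g^2 = %.6g   sigma_e^2 = %.6g   h2 = %.4f"
            % (self.sigma_g2, self.sigma_e2, self.h2),
            "",
            pd.DataFrame(
                {"coef": self.beta_hat, "std err": self.bse}, index=names
            ).to_string(),
        ]
        return "\n".join(lines)


def fit_null_model(
    data: PhenotypeData, K: KinshipMatrix, method: str = "ML", eig=None
) -> FamilialLMMResults:
    """Functional wrapper: align, build and fit the familial LMM."""
    return FamilialLMM.from_phenotype_data(data, K, eig=eig).fit(method=method)


def decorrelated_residuals(fit: FamilialLMMResults, kind: str = "whitened") -> np.ndarray:
    return fit.decorrelated_residuals(kind=kind)
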