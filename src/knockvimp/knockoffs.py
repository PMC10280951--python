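"""Second-order multivariate Gaussian knockoffs.

A knockoff matrix X~ is a simulated copy of the feature matrix X whose
joint second moments with X match the exchangeable target

    G = [[Sigma, Sigma - diag(s)],
         [Sigma - diag(s), Sigma]],

while X~ is generated without any reference to the outcome, so it carries no
association with the outcome beyond what the other features explain. Rows of
X~ are drawn from the Gaussian conditional

    X~ | X = x  ~  N(mu + (x - mu) @ Sigma^-1 (Sigma - diag(s)),
                     2 diag(s) - diag(s) Sigma^-1 diag(s)).

The decorrelation vector s controls how strongly each knockoff is decoupled
from its original (s = 0 gives an exact copy; larger s gives more power),
constrained by G remaining positive semidefinite. The default rule is the
equicorrelated closed form s_j = min(2 lambda_min(corr(Sigma)), 1) on the
correlation scale; an SDP rule maximizing sum_j s_j is available when a
solver is installed.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.covariance import ledoit_wolf_shrinkage
from sklearn.utils.validation import check_is_fitted

logger = logging.getLogger(__name__)

__all__ = [
    "GaussianKnockoffSampler",
    "solve_s_equicorrelated",
    "solve_s_sdp",
]

_PSD_TOL = 1e-10


def _corr_from_cov(sigma: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    d = np.sqrt(np.diag(sigma))
    corr = sigma / np.outer(d, d)
    np.fill_diagonal(corr, 1.0)
    return corr, d


def _joint_min_eig(corr: np.ndarray, s_corr: np.ndarray) -> float:
    # G is PSD iff diag(s) >= 0 and 2*corr - diag(s) is PSD
    m = 2.0 * corr - np.diag(s_corr)
    return float(np.linalg.eigvalsh(m).min())


def _backoff(corr: np.ndarray, s_corr: np.ndarray) -> np.ndarray:
    """Shrink s multiplicatively until the joint matrix is numerically PSD."""
    s = s_corr.copy()
    for _ in range(60):
        if _joint_min_eig(corr, s) >= -_PSD_TOL:
            return s
        s *= 1.0 - 1e-6
    raise RuntimeError("could not restore positive semidefiniteness of G")


def solve_s_equicorrelated(sigma: np.ndarray) -> np.ndarray:
    """Equicorrelated decorrelation vector for covariance ``sigma``.

    On the correlation scale every coordinate equals
    ``min(2 * lambda_min(corr), 1)``; the result is rescaled by the
    variances so it applies to ``sigma`` directly.
    """
    sigma = np.asarray(sigma, dtype=float)
    lam_sigma = np.linalg.eigvalsh(sigma).min()
    if lam_sigma <= 0:
        raise ValueError(
            f"covariance is not positive definite (min eigenvalue {lam_sigma:.3g})"
        )
    corr, d = _corr_from_cov(sigma)
    lam = float(np.linalg.eigvalsh(corr).min())
    s_corr = np.full(sigma.shape[0], min(2.0 * lam, 1.0))
    s_corr = _backoff(corr, s_corr)
    return s_corr * d**2


def solve_s_sdp(sigma: np.ndarray) -> np.ndarray:
    """SDP decorrelation vector: maximize sum(s) subject to G PSD, 0 <= s <= 1.

    Requires cvxpy; when no solver is available this falls back to the
    equicorrelated rule with a logged warning rather than failing — the
    fallback point is always feasible for the SDP.
    """
    sigma = np.asarray(sigma, dtype=float)
    if np.linalg.eigvalsh(sigma).min() <= 0:
        raise ValueError("covariance is not positive definite")
    corr, d = _corr_from_cov(sigma)
    try:
        import cvxpy as cp

        p = corr.shape[0]
        s = cp.Variable(p)
        constraints = [s >= 0, s <= 1, 2.0 * corr - cp.diag(s) >> 0]
        prob = cp.Problem(cp.Maximize(cp.sum(s)), constraints)
        prob.solve()
        if prob.status not in ("optimal", "optimal_inaccurate") or s.value is None:
            raise RuntimeError(f"SDP solve failed with status {prob.status}")
        s_corr = np.clip(np.asarray(s.value, dtype=float), 0.0, 1.0)
        s_corr = _backoff(corr, s_corr)
        return s_corr * d**2
    except (ImportError, RuntimeError) as exc:
        warnings.warn(
            f"SDP s-rule unavailable ({exc}); falling back to the "
            "equicorrelated closed form",
            RuntimeWarning,
            stacklevel=2,
        )
        logger.warning("SDP s-rule unavailable (%s); using equicorrelated", exc)
        return solve_s_equicorrelated(sigma)


class GaussianKnockoffSampler(BaseEstimator):
    """Fit and sample second-order Gaussian knockoffs.

    Parameters
    ----------
    s_rule : {"equi", "sdp"}, default "equi"
        Rule for the decorrelation vector s.
    shrinkage : "auto" or float in [0, 1], default "auto"
        Intensity gamma of the convex covariance shrinkage
        ``(1 - gamma) * S + gamma * diag(S)``. ``"auto"`` starts from the
        analytic Ledoit–Wolf intensity and escalates until the shrunk
        covariance is positive definite (min eigenvalue > 1e-8); a float is
        used as given (and escalated only if the result is not PD).
    random_state : int or numpy Generator, optional
        Stream used by :meth:`transform` when no explicit seed is passed to
        :meth:`sample`.

    Attributes
    ----------
    mu_ : (p,) column means.
    Sigma_ : (p, p) shrunk covariance (positive definite).
    s_ : (p,) decorrelation vector on the covariance scale.
    cond_coef_ : (p, p) matrix ``Sigma^-1 (Sigma - diag(s))``; the
        conditional mean of a row is ``mu_ + (x - mu_) @ cond_coef_``.
    cond_cov_ : (p, p) conditional covariance
        ``2 diag(s) - diag(s) Sigma^-1 diag(s)``.
    shrinkage_ : float, the intensity actually applied.
    """

    def __init__(
        self,
        s_rule: str = "equi",
        shrinkage: float | str = "auto",
        random_state=None,
    ):
        self.s_rule = s_rule
        self.shrinkage = shrinkage
        self.random_state = random_state

    # -- fitting ----------------------------------------------------------

    def fit(self, X, y=None) -> "GaussianKnockoffSampler":
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D")
        n, p = X.shape
        if n <= 1:
            raise ValueError("need n > 1 rows to estimate a covariance")
        if not np.isfinite(X).all():
            raise ValueError("X contains missing or non-finite values")
        stds = X.std(axis=0)
        dead = np.where(stds == 0.0)[0]
        if dead.size:
            raise ValueError(
                f"constant column(s) at index {dead.tolist()} — knockoffs are "
                "undefined for zero-variance features"
            )
        self.mu_ = X.mean(axis=0)
        emp = np.cov(X, rowvar=False, ddof=1).reshape(p, p)
        target = np.diag(np.diag(emp))

        if self.shrinkage == "auto":
            gamma = float(ledoit_wolf_shrinkage(X))
        else:
            gamma = float(self.shrinkage)
            if not 0.0 <= gamma <= 1.0:
                raise ValueError("shrinkage must lie in [0, 1] or be 'auto'")
        sigma = (1.0 - gamma) * emp + gamma * target
        while np.linalg.eigvalsh(sigma).min() <= 1e-8 and gamma < 1.0:
            gamma = min(1.0, max(2.0 * gamma, 1e-3))
            logger.warning(
                "covariance ill-conditioned; escalating shrinkage to %.4g", gamma
            )
            sigma = (1.0 - gamma) * emp + gamma * target
        if np.linalg.eigvalsh(sigma).min() <= 0:
            raise ValueError("covariance could not be made positive definite")
        self.shrinkage_ = gamma
        self.Sigma_ = sigma

        if self.s_rule == "equi":
            self.s_ = solve_s_equicorrelated(sigma)
        elif self.s_rule == "sdp":
            self.s_ = solve_s_sdp(sigma)
        else:
            raise ValueError(f"unknown s_rule {self.s_rule!r}")
        self._finalize()
        return self

    def _finalize(self) -> None:
        """Derive conditional-sampling parameters from (Sigma_, s_)."""
        sigma = self.Sigma_
        s = self.s_
        p = sigma.shape[0]
        sigma_inv_s = np.linalg.solve(sigma, np.diag(s))
        self.cond_coef_ = np.eye(p) - sigma_inv_s
        cond_cov = 2.0 * np.diag(s) - np.diag(s) @ sigma_inv_s
        cond_cov = 0.5 * (cond_cov + cond_cov.T)
        lam, vec = np.linalg.eigh(cond_cov)
        if lam.min() < -_PSD_TOL:
            raise ValueError(
                f"conditional covariance not PSD (min eigenvalue {lam.min():.3g})"
            )
        lam = np.clip(lam, 0.0, None)
        self.cond_cov_ = cond_cov
        self._cond_sqrt = vec * np.sqrt(lam)

    def set_s(self, s: np.ndarray) -> "GaussianKnockoffSampler":
        """Override the decorrelation vector (e.g. s = 0 for the copy limit)."""
        check_is_fitted(self, "Sigma_")
        s = np.asarray(s, dtype=float)
        if s.shape != (self.Sigma_.shape[0],) or (s < 0).any():
            raise ValueError("s must be a nonnegative length-p vector")
        self.s_ = s
        self._finalize()
        return self

    # -- sampling ---------------------------------------------------------

    def sample(self, X, seed=None) -> np.ndarray:
        """Draw one knockoff matrix for ``X`` (same shape, same column order)."""
        check_is_fitted(self, "Sigma_")
        X = np.asarray(X, dtype=float)
        p = self.Sigma_.shape[0]
        if X.ndim != 2 or X.shape[1] != p:
            raise ValueError(
                f"X has {X.shape[1] if X.ndim == 2 else 'wrong'} columns; "
                f"sampler was fitted with p={p}"
            )
        rng = np.random.default_rng(
            self.random_state if seed is None else seed
        )
        mean = self.mu_ + (X - self.mu_) @ self.cond_coef_
        z = rng.standard_normal(X.shape)
        return mean + z @ self._cond_sqrt.T

    def transform(self, X) -> np.ndarray:
        return self.sample(X)

    def joint_covariance(self) -> np.ndarray:
        """The 2p x 2p exchangeable target G used by sampling."""
        check_is_fitted(self, "Sigma_")
        cross = self.Sigma_ - np.diag(self.s_)
        return np.block([[self.Sigma_, cross], [cross, self.Sigma_]])
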