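"""Semi-supervised two-component inverse-Gaussian mixture model.

Normalized tag-count sums x_i > 0 are modeled as a mixture of an
inverse-Gaussian "promoter" component IG(mu1, lambda1) and a "background"
component IG(mu0, lambda0). The mixing probability is *per example*: each
observation carries its own belief prior (pi_i1, pi_i2) computed from
sequence features, which is held fixed during fitting. Sampled background
regions enter as exact negatives: their labels are known and stay fixed at
p(bg) = 1 throughout EM. After convergence the posterior promoter
probability of a region is obtained by Bayes' theorem,

    p(prom | x) = pi_1(x) f1(x) / (pi_1(x) f1(x) + pi_2(x) f0(x)).

The inverse Gaussian was preferred over Poisson/negative-binomial count
models because the observations are continuous after quantile normalization
and their distribution has a long right tail from highly expressed promoters.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.special import logsumexp
from sklearn.base import BaseEstimator

from promcage.features import PriorPair

_LAMBDA_FLOOR = 1e-6
_WEIGHT_FLOOR = 1e-8


class ComponentCollapseError(RuntimeError):
    """A mixture component lost essentially all responsibility mass."""


@dataclass(frozen=True)
class MixtureParams:
    """Inverse-Gaussian parameters of the promoter (1) and background (0)
    components."""

    mu1: float
    lambda1: float
    mu0: float
    lambda0: float

    def __post_init__(self) -> None:
        if min(self.mu1, self.lambda1, self.mu0, self.lambda0) <= 0:
            raise ValueError(f"non-positive mixture parameter: {self}")


@dataclass(frozen=True)
class Observation:
    x: float
    prior: PriorPair
    fixed_label: str = "none"  # "none" | "background"

    def __post_init__(self) -> None:
        if self.x <= 0:
            raise ValueError(f"observation outside IG support: {self.x}")
        if self.fixed_label not in ("none", "background"):
            raise ValueError(f"bad fixed_label: {self.fixed_label}")


@dataclass(frozen=True)
class PosteriorResult:
    p_prom: float
    label: str  # "promoter" | "background"

    @property
    def p_bg(self) -> float:
        return 1.0 - self.p_prom


# ---------------------------------------------------------------------------
# Inverse-Gaussian density


def ig_logpdf(x, mu: float, lam: float):
    """Log density of the inverse Gaussian IG(mu, lambda) at x (> 0)."""
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValueError("inverse Gaussian support is x > 0")
    if mu <= 0 or lam <= 0:
        raise ValueError("mu and lambda must be positive")
    return 0.5 * (np.log(lam) - np.log(2 * np.pi) - 3 * np.log(x)) - lam * (
        x - mu
    ) ** 2 / (2 * mu**2 * x)


def ig_pdf(x, mu: float, lam: float):
    """Density sqrt(lambda/(2 pi x^3)) exp(-lambda (x-mu)^2 / (2 mu^2 x))."""
    return np.exp(ig_logpdf(x, mu, lam))


def ig_mle(x: np.ndarray, weights: np.ndarray | None = None) -> tuple[float, float]:
    """(Weighted) maximum-likelihood estimate of (mu, lambda).

    mu = sum(w x)/sum(w); 1/lambda = sum(w (1/x - 1/mu))/sum(w).
    """
    x = np.asarray(x, dtype=float)
    w = np.ones_like(x) if weights is None else np.asarray(weights, dtype=float)
    wsum = w.sum()
    if wsum < _WEIGHT_FLOOR:
        raise ComponentCollapseError("component weight underflow in IG MLE")
    mu = float((w * x).sum() / wsum)
    inv_lam = float((w * (1.0 / x - 1.0 / mu)).sum() / wsum)
    if inv_lam <= 0:
        warnings.warn("lambda MLE non-positive; floored", stacklevel=2)
        return mu, 1.0 / _LAMBDA_FLOOR
    return mu, 1.0 / inv_lam


# ---------------------------------------------------------------------------
# Estimator


class InverseGaussianBeliefMixture(BaseEstimator):
    """Two-component inverse-Gaussian mixture with per-example priors.

    EM with fixed per-example mixing probabilities and optional fixed-label
    background observations (exact negatives, responsibility pinned to the
    background component). All density arithmetic is in log space.

    Parameters
    ----------
    tol : float
        Convergence threshold on the relative log-likelihood change.
    max_iter : int
        Maximum EM iterations.
    cutoff : float
        Posterior cutoff c for classification; a region is called a
        promoter iff p(prom|x) > c (ties resolve to background).

    Attributes
    ----------
    params_ : MixtureParams
    log_likelihood_ : float
    trajectory_ : list of per-iteration log-likelihoods
    n_iter_ : int
    """

    def __init__(
        self,
        tol: float = 1e-6,
        max_iter: int = 500,
        cutoff: float = 0.5,
        update_mixing: bool = False,
    ):
        self.tol = tol
        self.max_iter = max_iter
        self.cutoff = cutoff
        # update_mixing=True turns the model into the standard mixture with a
        # single global mixing proportion re-estimated each M-step (the
        # counts-only baseline); per-example beliefs are then ignored.
        self.update_mixing = update_mixing

    # -- internals ---------------------------------------------------------

    @staticmethod
    def _validate(X, prior, fixed_background):
        x = np.asarray(X, dtype=float).ravel()
        if np.any(x <= 0):
            raise ValueError("all observations must be > 0")
        n = len(x)
        if prior is None:
            p1 = np.full(n, 0.5)
        else:
            p1 = np.asarray(prior, dtype=float).ravel()
            if len(p1) != n:
                raise ValueError("prior length mismatch")
            if np.any((p1 < 0) | (p1 > 1)):
                raise ValueError("priors must lie in [0, 1]")
        if fixed_background is None:
            fixed = np.zeros(n, dtype=bool)
        else:
            fixed = np.asarray(fixed_background, dtype=bool).ravel()
            if len(fixed) != n:
                raise ValueError("fixed_background length mismatch")
        return x, p1, fixed

    @staticmethod
    def _split_threshold(values: np.ndarray) -> float:
        """Deterministic two-class split of log-counts maximizing the
        between-class variance (Otsu's criterion on log x).

        A plain median split sits inside the background mode whenever noise
        observations dominate, seeding both components on noise; the
        variance-maximizing split finds the gap between the background and
        promoter modes instead.
        """
        v = np.sort(np.log(values))
        n = len(v)
        cum = np.cumsum(v)
        k = np.arange(1, n)  # split after k-th smallest
        m0 = cum[:-1] / k
        m1 = (cum[-1] - cum[:-1]) / (n - k)
        between = k * (n - k) * (m0 - m1) ** 2
        return float(np.exp((v[np.argmax(between)] + v[np.argmax(between) + 1]) / 2))

    @classmethod
    def _init_params(cls, x: np.ndarray, fixed: np.ndarray) -> MixtureParams:
        """Split the unlabeled observations at the Otsu log-count threshold,
        closed-form IG MLE per half (deterministic and scale-free)."""
        free = x[~fixed]
        thr = cls._split_threshold(free)
        hi = free[free > thr]
        lo = free[free <= thr]
        if len(hi) == 0 or len(lo) == 0:  # degenerate: nearly constant data
            mu, lam = ig_mle(free)
            return MixtureParams(mu * 1.5, lam, mu * 0.75, lam)
        mu1, lam1 = ig_mle(hi)
        mu0, lam0 = ig_mle(np.concatenate([lo, x[fixed]]))
        return MixtureParams(mu1, lam1, mu0, lam0)

    def _log_joint(self, x, p1, params):
        """Per-observation log(pi_k f_k), shape (n, 2): columns (bg, prom)."""
        with np.errstate(divide="ignore"):
            lg1 = np.log(p1) + ig_logpdf(x, params.mu1, params.lambda1)
            lg0 = np.log1p(-p1) + ig_logpdf(x, params.mu0, params.lambda0)
        return np.column_stack([lg0, lg1])

    def _loglik_and_resp(self, x, p1, fixed, params):
        lj = self._log_joint(x, p1, params)
        # fixed negatives: only the background component is allowed
        ll_terms = np.where(fixed, lj[:, 0], logsumexp(lj, axis=1))
        with np.errstate(over="ignore"):
            gamma1 = np.where(
                fixed, 0.0, 1.0 / (1.0 + np.exp(lj[:, 0] - lj[:, 1]))
            )
        return float(ll_terms.sum()), gamma1

    # -- API ---------------------------------------------------------------

    def fit(self, X, prior=None, fixed_background=None, init: MixtureParams | None = None):
        """Run EM on observations ``X`` with fixed per-example priors.

        Parameters
        ----------
        X : array of positive observations (normalized tag-count sums)
        prior : array of per-example promoter priors pi_i1 (default flat 0.5)
        fixed_background : boolean array marking exact negatives
        init : optional starting parameters
        """
        x, p1, fixed = self._validate(X, prior, fixed_background)
        if len(np.unique(x[~fixed])) < 2:
            raise ValueError("need >= 2 unlabeled observations with distinct x")
        params = init if init is not None else self._init_params(x, fixed)
        if self.update_mixing:
            thr = self._split_threshold(x[~fixed])
            pi1 = float((x[~fixed] > thr).mean())

        trajectory = []
        ll_prev = -np.inf
        for it in range(self.max_iter):
            if self.update_mixing:
                p1 = np.where(fixed, 0.0, pi1)
            ll, gamma1 = self._loglik_and_resp(x, p1, fixed, params)
            trajectory.append(ll)
            if np.isfinite(ll_prev) and abs(ll - ll_prev) <= self.tol * abs(ll_prev):
                break
            ll_prev = ll
            g1 = gamma1
            g0 = 1.0 - gamma1  # fixed negatives contribute weight 1 here
            if g1.sum() < _WEIGHT_FLOOR or g0.sum() < _WEIGHT_FLOOR:
                raise ComponentCollapseError(
                    f"component collapsed at iteration {it}"
                )
            mu1, lam1 = ig_mle(x, g1)
            mu0, lam0 = ig_mle(x, g0)
            params = MixtureParams(mu1, lam1, mu0, lam0)
            if self.update_mixing:
                pi1 = float(np.clip(g1.mean(), 1e-6, 1 - 1e-6))

        self.params_ = params
        self.mixing_ = (1.0 - pi1, pi1) if self.update_mixing else None
        self.trajectory_ = trajectory
        self.log_likelihood_ = trajectory[-1]
        self.n_iter_ = len(trajectory)
        return self

    def predict_proba(self, X, prior=None):
        """Posterior promoter probability for each observation.

        When no per-example prior is given, the fitted global mixing
        proportion is used if the model was fit with ``update_mixing``,
        otherwise a flat 0.5.
        """
        if prior is None and getattr(self, "mixing_", None) is not None:
            prior = np.full(np.asarray(X, dtype=float).ravel().shape, self.mixing_[1])
        x, p1, _ = self._validate(X, prior, None)
        lj = self._log_joint(x, p1, self.params_)
        # handle degenerate priors (0 or 1) exactly
        with np.errstate(over="ignore"):
            post = np.where(
                p1 == 1.0,
                1.0,
                np.where(p1 == 0.0, 0.0, 1.0 / (1.0 + np.exp(lj[:, 0] - lj[:, 1]))),
            )
        return post

    def predict(self, X, prior=None):
        """Label: 1 (promoter) iff posterior > cutoff, else 0."""
        return (self.predict_proba(X, prior) > self.cutoff).astype(int)

    # -- serialization -----------------------------------------------------

    def to_json(self, path: str | Path, extra: dict | None = None) -> None:
        doc = {
            "params": {
                "mu1": self.params_.mu1,
                "lambda1": self.params_.lambda1,
                "mu0": self.params_.mu0,
                "lambda0": self.params_.lambda0,
            },
            "trajectory": self.trajectory_,
            "n_iter": self.n_iter_,
            "tol": self.tol,
            "cutoff": self.cutoff,
            "mixing": getattr(self, "mixing_", None),
        }
        if extra:
            doc.update(extra)
        Path(path).write_text(json.dumps(doc, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "InverseGaussianBeliefMixture":
        doc = json.loads(Path(path).read_text())
        est = cls(tol=doc.get("tol", 1e-6), cutoff=doc.get("cutoff", 0.5))
        p = doc["params"]
        est.params_ = MixtureParams(p["mu1"], p["lambda1"], p["mu0"], p["lambda0"])
        mixing = doc.get("mixing")
        est.mixing_ = tuple(mixing) if mixing else None
        est.update_mixing = est.mixing_ is not None
        est.trajectory_ = doc.get("trajectory", [])
        est.log_likelihood_ = est.trajectory_[-1] if est.trajectory_ else float("nan")
        est.n_iter_ = doc.get("n_iter", 0)
        return est


# ---------------------------------------------------------------------------
# Functional wrappers


def em_fit(
    observations: Sequence[Observation],
    init: MixtureParams | None = None,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> tuple[MixtureParams, list[float]]:
    """Fit the mixture on :class:`Observation` records; returns the fitted
    parameters and the log-likelihood trajectory."""
    x = np.array([o.x for o in observations])
    p1 = np.array([o.prior.p_prom for o in observations])
    fixed = np.array([o.fixed_label == "background" for o in observations])
    p1 = np.where(fixed, 0.0, p1)
    est = InverseGaussianBeliefMixture(tol=tol, max_iter=max_iter).fit(
        x, prior=p1, fixed_background=fixed, init=init
    )
    return est.params_, est.trajectory_


def posterior(x0: float, prior: PriorPair, params: MixtureParams, cutoff: float = 0.5) -> PosteriorResult:
    """Posterior promoter probability of a new observation by Bayes' theorem."""
    est = InverseGaussianBeliefMixture(cutoff=cutoff)
    est.params_ = params
    p = float(est.predict_proba([x0], prior=[prior.p_prom])[0])
    return PosteriorResult(p_prom=p, label="promoter" if p > cutoff else "background")


def classify(results: Sequence[PosteriorResult], c: float = 0.5) -> list[PosteriorResult]:
    """Relabel posterior results at cutoff ``c`` (promoter iff p > c)."""
    if not 0 < c < 1:
        raise ValueError("cutoff must lie in (0, 1)")
    return [
        PosteriorResult(r.p_prom, "promoter" if r.p_prom > c else "background")
        for r in results
    ]
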