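"""Sequence features of candidate regions and the belief (prior) model.

Four features summarize the 1 kb window around a candidate TSS:

- ``cpg``: normalized CpG content, observed over expected CG dinucleotides,
  (CG/L) / ((C+G)/(2L))^2 — ~1 for random sequence, ~2 for a pure CpG island;
- ``cons``: mean per-base conservation probability over the window, in [0,1];
- ``tata``: TRAP binding affinity of the window for a TATA-box matrix —
  expected occupancy under a biophysical mismatch-energy model, summed over
  both strands and all offsets;
- ``proximity``: a linear ramp (window - d)/window of the strand-aware
  distance d from the TSS to the precursor 5' end, in [0,1].

The per-example prior probability that region i is a promoter is a logistic
function of these features,
pi_i1 = logistic(b0 + b1*cpg + b2*cons + b3*tata + b4*proximity),
with coefficients fit by ridge-penalized logistic regression on a small set
of labelled promoter and background examples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.special import expit
from sklearn.base import BaseEstimator, ClassifierMixin

from promcage.io import DataError, GenomicInterval, Pssm

#: default TRAP parameters from the original affinity-prediction method
TRAP_LAMBDA = 0.7
TRAP_LNR0_SLOPE = 0.584
TRAP_LNR0_INTERCEPT = -5.66

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass(frozen=True)
class FeatureVector:
    cpg: float
    cons: float
    tata: float
    proximity: float

    def __post_init__(self) -> None:
        vals = (self.cpg, self.cons, self.tata, self.proximity)
        if not all(np.isfinite(vals)):
            raise DataError(f"non-finite feature: {vals}")
        if not 0.0 <= self.cons <= 1.0:
            raise DataError(f"conservation outside [0,1]: {self.cons}")

    def as_array(self) -> np.ndarray:
        return np.array([self.cpg, self.cons, self.tata, self.proximity])


@dataclass(frozen=True)
class PriorBeta:
    beta0: float
    beta1: float
    beta2: float
    beta3: float
    beta4: float

    def as_array(self) -> np.ndarray:
        return np.array([self.beta0, self.beta1, self.beta2, self.beta3, self.beta4])


@dataclass(frozen=True)
class PriorPair:
    p_prom: float

    @property
    def p_bg(self) -> float:
        return 1.0 - self.p_prom


# ---------------------------------------------------------------------------
# Features


def cpg_score(seq: str) -> float:
    """Observed/expected CG dinucleotide ratio of ``seq``.

    Returns (CG/L) / ((C+G)/(2L))^2 with CG counted over overlapping
    positions; 0 when the sequence contains no C or G.
    """
    seq = seq.upper()
    L = len(seq)
    if L < 2:
        raise DataError("sequence too short for CpG score")
    c = seq.count("C")
    g = seq.count("G")
    if c + g == 0:
        return 0.0
    cg = seq.count("CG")
    return (cg / L) / (((c + g) / (2 * L)) ** 2)


def mean_conservation(window: GenomicInterval, track) -> float:
    """Mean conservation over ``window``; unaligned bases contribute 0."""
    return track.mean(window)


def _energy_profile(seq: str, penalties: np.ndarray, w: int) -> np.ndarray:
    """Mismatch energies E_i for every offset of the matrix on ``seq``."""
    idx = np.fromiter(
        (_BASE_INDEX.get(b, -1) for b in seq), dtype=np.int64, count=len(seq)
    )
    n_off = len(seq) - w + 1
    E = np.zeros(n_off)
    # ambiguous bases get the column-average penalty
    col_avg = penalties.mean(axis=0)
    for j in range(w):
        col = idx[j : j + n_off]
        pen = np.where(col >= 0, penalties[np.clip(col, 0, 3), j], col_avg[j])
        E += pen
    return E


def trap_affinity(
    seq: str,
    pssm: Pssm,
    lam: float = TRAP_LAMBDA,
    ln_r0: float | None = None,
    pseudocount: float = 1.0,
) -> float:
    """TRAP expected occupancy of the matrix on ``seq``, both strands.

    Each offset i contributes p_i = R0 e^{-E_i} / (1 + R0 e^{-E_i}) with the
    mismatch energy E_i = (1/lambda) * sum_j ln(c_max,j / c_j(s_{i+j})) on
    pseudocount-regularized columns. By default ln R0 = 0.584 w - 5.66.
    """
    seq = seq.upper()
    w = pssm.width
    if len(seq) < w:
        raise DataError(f"sequence shorter than motif width {w}")
    if ln_r0 is None:
        ln_r0 = TRAP_LNR0_SLOPE * w + TRAP_LNR0_INTERCEPT
    counts = pssm.counts + pseudocount
    penalties = (np.log(counts.max(axis=0)) - np.log(counts)) / lam  # (4, w)
    total = 0.0
    for s in (seq, seq.translate(_COMPLEMENT)[::-1]):
        E = _energy_profile(s, penalties, w)
        total += float(expit(ln_r0 - E).sum())
    return total


def mirna_proximity(
    tss: int, precursor: GenomicInterval, window: int = 50_000
) -> float:
    """Linear-ramp proximity of a TSS to the precursor 5' end, in [0,1]."""
    p5 = precursor.five_prime()
    d = (p5 - tss) if precursor.strand != "-" else (tss - p5)
    if d < 0:
        warnings.warn(
            f"TSS {tss} downstream of precursor 5' end {p5}; proximity set to 1",
            stacklevel=2,
        )
        return 1.0
    return float(np.clip((window - d) / window, 0.0, 1.0))


ProximityFunction = Callable[[int, GenomicInterval, int], float]


# ---------------------------------------------------------------------------
# Prior


def prior_probability(fv: FeatureVector, beta: PriorBeta) -> PriorPair:
    """Logistic belief that a region is a promoter given its features."""
    b = beta.as_array()
    y = b[0] + float(b[1:] @ fv.as_array())
    return PriorPair(p_prom=float(expit(y)))


class BeliefLogisticPrior(ClassifierMixin, BaseEstimator):
    """Ridge-penalized logistic regression for the per-example prior.

    Fit by iteratively reweighted least squares (IRLS / Newton) with an L2
    penalty on the non-intercept coefficients. Features may optionally be
    standardized internally; coefficients are always reported on the
    original feature scale.

    Parameters
    ----------
    ridge : float
        L2 penalty weight on the (standardized-scale) coefficients.
    standardize : bool
        Standardize features internally before fitting.

    Attributes
    ----------
    coef_ : ndarray of shape (n_features,)
        Feature coefficients (original scale).
    intercept_ : float
    se_ : ndarray of shape (n_features + 1,)
        Standard errors (intercept first) from the penalized Fisher
        information, on the original scale.
    """

    def __init__(self, ridge: float = 1e-4, standardize: bool = True,
                 max_iter: int = 100, tol: float = 1e-10):
        self.ridge = ridge
        self.standardize = standardize
        self.max_iter = max_iter
        self.tol = tol

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValueError("X must be 2-D with one row per label")
        if not np.isfinite(X).all():
            raise ValueError("non-finite feature values")
        classes = np.unique(y)
        if set(classes) - {0.0, 1.0}:
            raise ValueError("labels must be 0 (background) / 1 (promoter)")
        if len(classes) < 2:
            raise ValueError("both promoter and background examples required")

        if self.standardize:
            mu = X.mean(axis=0)
            sd = X.std(axis=0)
            sd[sd == 0] = 1.0
        else:
            mu = np.zeros(X.shape[1])
            sd = np.ones(X.shape[1])
        Z = (X - mu) / sd
        D = np.hstack([np.ones((Z.shape[0], 1)), Z])
        k = D.shape[1]
        pen = np.full(k, self.ridge)
        pen[0] = 0.0  # intercept unpenalized

        b = np.zeros(k)
        for it in range(self.max_iter):
            eta = D @ b
            p = expit(eta)
            W = np.clip(p * (1 - p), 1e-10, None)
            H = D.T @ (D * W[:, None]) + np.diag(pen)
            grad = D.T @ (y - p) - pen * b
            step = np.linalg.solve(H, grad)
            b = b + step
            if np.max(np.abs(step)) < self.tol:
                break
        self.n_iter_ = it + 1

        cov_z = np.linalg.inv(H)
        # back-transform to the original feature scale
        coef = b[1:] / sd
        intercept = b[0] - float((b[1:] * mu / sd).sum())
        J = np.zeros((k, k))  # d(original)/d(standardized)
        J[0, 0] = 1.0
        J[0, 1:] = -mu / sd
        J[1:, 1:] = np.diag(1.0 / sd)
        cov = J @ cov_z @ J.T
        self.coef_ = coef
        self.intercept_ = float(intercept)
        self.se_ = np.sqrt(np.diag(cov))
        self.classes_ = np.array([0.0, 1.0])
        return self

    def decision_function(self, X):
        X = np.asarray(X, dtype=float)
        return self.intercept_ + X @ self.coef_

    def predict_proba(self, X):
        p = expit(self.decision_function(X))
        return np.column_stack([1 - p, p])

    def predict(self, X):
        return (self.decision_function(X) > 0).astype(float)

    def to_prior_beta(self) -> PriorBeta:
        return PriorBeta(self.intercept_, *self.coef_)


def fit_beta(
    examples: Sequence[tuple[FeatureVector, str]],
    ridge: float = 1e-4,
    standardize: bool = True,
) -> tuple[PriorBeta, np.ndarray]:
    """Fit prior coefficients from labelled (features, "prom"/"bg") examples.

    Returns the coefficients and their standard errors (intercept first).
    Deterministic; the ridge penalty keeps separable data finite.
    """
    if len(examples) < 10:
        raise DataError("need at least 10 labelled examples")
    labels = {lab for _, lab in examples}
    if not labels <= {"prom", "bg"}:
        raise DataError(f"labels must be 'prom'/'bg', got {labels}")
    if len(labels) < 2:
        raise DataError("both promoter and background examples required")
    X = np.array([fv.as_array() for fv, _ in examples])
    y = np.array([1.0 if lab == "prom" else 0.0 for _, lab in examples])
    est = BeliefLogisticPrior(ridge=ridge, standardize=standardize).fit(X, y)
    return est.to_prior_beta(), est.se_
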