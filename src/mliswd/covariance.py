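"""Working correlation structures and working covariance assembly.

The within-cluster dependence of a cohort stepped wedge trial is described by
three correlations: different individuals measured in the same period
(``alpha0``, within-period), different individuals in different periods
(``alpha1``, inter-period) and the same individual in different periods
(``alpha2``, within-individual).  The *block exchangeable* family holds each
of these constant; the *block autoregressive* variant decays the
within-individual correlation as ``alpha2 ** |lag|`` (and optionally the
inter-period correlations as ``alpha1 ** |lag|``).

The working covariance of a cluster is ``V = phi * A^{1/2} R A^{1/2}`` with
``A = diag(v(mu))`` the variance function of the outcome family.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.linalg import cholesky, LinAlgError

__all__ = [
    "CorrelationSpec",
    "VarianceSpec",
    "NotPositiveDefiniteError",
    "build_correlation",
    "build_covariance",
    "variance_function",
    "mean_derivative",
]

_PD_TOL = 1e-10


class NotPositiveDefiniteError(ValueError):
    """Working correlation is not positive definite for the given layout."""


@dataclass(frozen=True)
class CorrelationSpec:
    """Working correlation family and parameters.

    ``alpha = (alpha0, alpha1, alpha2)`` = (within-period, inter-period,
    within-individual).  The independence family ignores ``alpha``.
    ``decay_inter_period`` lets the autoregressive family also decay the
    inter-period (different-individual) correlation with lag.
    """

    family: Literal["block_exchangeable", "block_autoregressive", "independence"]
    alpha: tuple[float, float, float] = (0.0, 0.0, 0.0)
    decay_inter_period: bool = False

    def __post_init__(self) -> None:
        if self.family not in ("block_exchangeable", "block_autoregressive", "independence"):
            raise ValueError(f"unknown correlation family {self.family!r}")
        if self.family != "independence":
            if len(self.alpha) != 3:
                raise ValueError("alpha must be (within_period, inter_period, within_individual)")
            if any(not -1.0 < a < 1.0 for a in self.alpha):
                raise ValueError(f"correlation parameters must lie in (-1, 1): {self.alpha}")


@dataclass(frozen=True)
class VarianceSpec:
    """Outcome family variance function ``v(mu)`` and dispersion ``phi``.

    gaussian: v = 1 (phi is the outcome variance); binomial: v = mu(1-mu)
    with phi = 1 by convention; poisson: v = mu.
    """

    family: Literal["gaussian", "binomial", "poisson"]
    dispersion: float = 1.0

    def __post_init__(self) -> None:
        if self.family not in ("gaussian", "binomial", "poisson"):
            raise ValueError(f"unknown variance family {self.family!r}")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")


def build_correlation(
    spec: CorrelationSpec,
    n_individuals: int,
    n_periods: int,
    cohort_type: str = "closed_cohort",
) -> np.ndarray:
    """Working correlation over ``N * J`` observations (individual-major).

    For cross-sectional sampling every observation comes from a distinct
    person, so same-"slot" different-period entries use the inter-period
    correlation rather than the within-individual one.
    """
    N, J = int(n_individuals), int(n_periods)
    if N < 1 or J < 1:
        raise ValueError("need at least one individual and one period")
    n = N * J
    if spec.family == "independence":
        return np.eye(n)

    a0, a1, a2 = spec.alpha
    idx_ind = np.repeat(np.arange(N), J)
    idx_per = np.tile(np.arange(J), N)
    same_ind = idx_ind[:, None] == idx_ind[None, :]
    same_per = idx_per[:, None] == idx_per[None, :]
    lag = np.abs(idx_per[:, None] - idx_per[None, :])

    if spec.family == "block_autoregressive":
        within = np.sign(a2) ** lag * np.abs(a2) ** lag if a2 != 0 else np.where(lag == 0, 1.0, 0.0)
        inter = a1 * (np.abs(a1) ** (lag - 1)) if spec.decay_inter_period and a1 != 0 else np.full_like(
            lag, a1, dtype=float
        )
    else:
        within = np.full_like(lag, a2, dtype=float)
        inter = np.full_like(lag, a1, dtype=float)

    if cohort_type == "cross_sectional":
        # a fresh sample each period: there is no "same individual" pair
        within = inter

    R = np.where(
        same_ind & same_per,
        1.0,
        np.where(same_ind, within, np.where(same_per, a0, inter)),
    )
    _assert_positive_definite(R, spec, (N, J))
    return R


def _assert_positive_definite(R: np.ndarray, spec: CorrelationSpec, dims: tuple[int, int]) -> None:
    try:
        cholesky(R, lower=True)
    except LinAlgError:
        pass
    else:
        return
    # factorization failed: report the smallest eigenvalue for diagnostics
    lam_min = float(np.linalg.eigvalsh(R).min())
    if lam_min > _PD_TOL:
        return  # borderline but acceptable
    raise NotPositiveDefiniteError(
        f"correlation {spec.family} with alpha={spec.alpha} is not positive "
        f"definite for N={dims[0]}, J={dims[1]} (min eigenvalue {lam_min:.3e})"
    )


def variance_function(mu: np.ndarray, vspec: VarianceSpec) -> np.ndarray:
    """Elementwise ``v(mu)``; validates the mean range for the family."""
    mu = np.asarray(mu, dtype=float)
    if vspec.family == "gaussian":
        return np.ones_like(mu)
    if vspec.family == "binomial":
        if np.any((mu <= 0) | (mu >= 1)):
            raise ValueError("binomial variance requires means strictly inside (0, 1)")
        return mu * (1.0 - mu)
    if np.any(mu <= 0):
        raise ValueError("poisson variance requires strictly positive means")
    return mu


def mean_derivative(mu: np.ndarray, link: str) -> np.ndarray:
    """d mu / d eta evaluated at mu, for the canonical links used here."""
    mu = np.asarray(mu, dtype=float)
    if link == "identity":
        return np.ones_like(mu)
    if link == "log":
        return mu
    if link == "logit":
        return mu * (1.0 - mu)
    raise ValueError(f"unknown link {link!r}")


def build_covariance(R: np.ndarray, mu: np.ndarray, vspec: VarianceSpec) -> np.ndarray:
    """Working covariance ``V = phi * A^{1/2} R A^{1/2}``, ``A = diag(v(mu))``."""
    R = np.asarray(R)
    mu = np.asarray(mu, dtype=float)
    if R.shape[0] != R.shape[1] or R.shape[0] != mu.shape[0]:
        raise ValueError("dimension mismatch between R and mu")
    sd = np.sqrt(variance_function(mu, vspec))
    # outer(sd, sd) is bitwise symmetric, keeping V = V.T exact
    return vspec.dispersion * (np.outer(sd, sd) * R)
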