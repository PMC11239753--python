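"""GEE model-based covariance, Wald noncentrality and power.

Power follows the model-based Wald-test route: the asymptotic covariance of
the GEE estimate ``theta_hat`` is

    Omega = ( sum_i D_i' V_i^{-1} D_i )^{-1},    D_i = Delta_i X_i,

with ``Delta_i = diag(d mu / d eta)``, ``X_i`` the cluster design matrix and
``V_i`` the working covariance; incomplete designs enter through the
incidence row-selection of ``X_i`` and ``V_i``.  A hypothesis
``H0: L theta = ell`` with ``q = rank(L)`` constraints has noncentrality

    lambda = (L theta - ell)' [ L Omega L' ]^{-1} (L theta - ell)

and attained power ``P(chi2_{q, lambda} > chi2_{q, 1 - alpha})`` under the
asymptotic chi-square reference, or the noncentral-F analogue
``P(F_{q, I-d, lambda} > F_{q, I-d, 1-alpha})`` with denominator degrees of
freedom ``I - d`` (clusters minus mean-model dimension) recommended when the
number of clusters is small.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .covariance import (
    CorrelationSpec,
    VarianceSpec,
    build_correlation,
    build_covariance,
    mean_derivative,
)
from .design import DesignLayout, ObservationPattern, apply_incidence, build_incidence
from .meanmodel import MeanModelSpec, build_cluster_design, linear_predictor_and_mean

__all__ = [
    "ContrastSpec",
    "PowerResult",
    "MultiplicityPlan",
    "SingularInformationError",
    "model_covariance",
    "wald_power",
    "multi_test_power",
]

Method = Literal["chisq", "f_small_sample"]


class SingularInformationError(np.linalg.LinAlgError):
    """Design information matrix is singular: some effect is not identified."""


@dataclass(frozen=True)
class ContrastSpec:
    """Wald hypothesis ``H0: L theta = ell`` at a per-test significance level."""

    L: tuple[tuple[float, ...], ...]
    ell: tuple[float, ...] = ()
    alpha: float | None = 0.05
    label: str = ""
    in_goal: bool = True  # whether a sample-size search must power this test

    @classmethod
    def single(cls, index: int, dim: int, alpha: float | None = 0.05, label: str = "") -> "ContrastSpec":
        """Test of one coefficient ``theta[index] = 0``."""
        row = [0.0] * dim
        row[index] = 1.0
        return cls(L=(tuple(row),), ell=(0.0,), alpha=alpha, label=label)

    def __post_init__(self) -> None:
        L = np.asarray(self.L, dtype=float)
        if L.ndim != 2 or L.shape[0] < 1:
            raise ValueError("L must be a q x d matrix with q >= 1")
        if np.linalg.matrix_rank(L) != L.shape[0]:
            raise ValueError("contrast rows must be linearly independent")
        if self.ell and len(self.ell) != L.shape[0]:
            raise ValueError("ell must have one entry per contrast row")
        if self.alpha is not None and not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")

    @property
    def q(self) -> int:
        return len(self.L)

    def matrix(self) -> np.ndarray:
        return np.asarray(self.L, dtype=float)

    def null_vector(self) -> np.ndarray:
        return np.asarray(self.ell, dtype=float) if self.ell else np.zeros(self.q)


@dataclass(frozen=True)
class PowerResult:
    """Outcome of a Wald power evaluation for one contrast."""

    omega: np.ndarray
    noncentrality: float
    df: int
    power: float
    method: Method
    alpha: float
    q: int
    label: str = ""


@dataclass(frozen=True)
class MultiplicityPlan:
    """How per-test significance levels are resolved across a family of tests.

    Either every contrast carries its own ``alpha`` (set ``family_alpha`` to
    None), or a family-wise ``family_alpha`` is divided equally (Bonferroni)
    among the contrasts whose own ``alpha`` is None.  Supplying both a family
    level and a per-test level for the same contrast is rejected as
    contradictory.
    """

    family_alpha: float | None = None
    power_goal: float | None = None

    def resolve(self, contrasts: Sequence[ContrastSpec]) -> list[float]:
        if self.family_alpha is None:
            missing = [c.label or f"#{i}" for i, c in enumerate(contrasts) if c.alpha is None]
            if missing:
                raise ValueError(f"no significance level for contrasts: {missing}")
            return [float(c.alpha) for c in contrasts]  # type: ignore[arg-type]
        clashing = [c.label or f"#{i}" for i, c in enumerate(contrasts) if c.alpha is not None]
        if clashing:
            raise ValueError(
                f"contrasts {clashing} specify a per-test alpha while a family "
                f"alpha is also set; give one or the other"
            )
        return [self.family_alpha / len(contrasts)] * len(contrasts)


def model_covariance(
    layout: DesignLayout,
    mspec: MeanModelSpec,
    cspec: CorrelationSpec,
    vspec: VarianceSpec,
    patterns: dict[int, ObservationPattern] | None = None,
) -> np.ndarray:
    """Model-based covariance ``Omega`` of the GEE estimate over all clusters.

    ``patterns`` maps cluster index to its planned observation pattern;
    clusters absent from the mapping are treated as completely observed.
    Identical clusters (same sequence, cohort composition and pattern) share
    one information contribution, so complete designs with many replicate
    clusters cost a handful of dense solves.
    """
    d = mspec.dim
    info = np.zeros((d, d))
    cache: dict[tuple, np.ndarray] = {}
    theta = np.asarray(mspec.theta)

    for i in range(layout.n_clusters):
        key = (
            layout.sequence_of_cluster(i),
            layout.cohort_size[i],
            layout.il_allocation[i],
            id(patterns.get(i)) if patterns and i in patterns else None,
        )
        if key not in cache:
            cache[key] = _cluster_information(layout, mspec, cspec, vspec, i, patterns)
        info += cache[key]

    # guard against non-identified columns before inverting
    rank = np.linalg.matrix_rank(info, tol=None)
    if rank < d:
        _, _, vt = np.linalg.svd(info)
        null_weights = np.abs(vt[rank:]).sum(axis=0)
        names = np.array(mspec.column_names())[null_weights > 1e-8]
        raise SingularInformationError(
            f"information matrix is rank {rank} < d={d}; columns involved in "
            f"the null space: {list(names)} (effect not identified by the design)"
        )
    return np.linalg.inv(info)


def _cluster_information(
    layout: DesignLayout,
    mspec: MeanModelSpec,
    cspec: CorrelationSpec,
    vspec: VarianceSpec,
    cluster: int,
    patterns: dict[int, ObservationPattern] | None,
) -> np.ndarray:
    X = build_cluster_design(layout, mspec, cluster)
    if X.shape[0] == 0:
        return np.zeros((mspec.dim, mspec.dim))
    R = build_correlation(
        cspec, layout.cohort_size[cluster], layout.n_periods, layout.cohort_type
    )
    if patterns is not None and cluster in patterns:
        inc = build_incidence(patterns[cluster], layout, cluster)
        X, R = apply_incidence(inc, X, R)
        if X.shape[0] == 0:
            return np.zeros((mspec.dim, mspec.dim))
    _, mu = linear_predictor_and_mean(X, mspec)
    V = build_covariance(R, mu, vspec)
    D = mean_derivative(mu, mspec.link)[:, None] * X
    return D.T @ np.linalg.solve(V, D)


def wald_power(
    omega: np.ndarray,
    theta: Sequence[float],
    contrast: ContrastSpec,
    n_clusters: int,
    method: Method = "f_small_sample",
    alpha: float | None = None,
) -> PowerResult:
    """Attained power of the Wald test of ``H0: L theta = ell``.

    ``method="chisq"`` uses the asymptotic noncentral chi-square reference;
    ``method="f_small_sample"`` the noncentral F with ``I - d`` denominator
    degrees of freedom (for ``q = 1`` this equals the two-sided noncentral-t
    test).  ``alpha`` overrides the contrast's own level when given.
    """
    omega = np.asarray(omega)
    theta = np.asarray(theta, dtype=float)
    d = omega.shape[0]
    if theta.shape[0] != d:
        raise ValueError("theta and omega dimensions differ")
    L = contrast.matrix()
    if L.shape[1] != d:
        raise ValueError(f"contrast has {L.shape[1]} columns, theta has {d}")
    level = alpha if alpha is not None else contrast.alpha
    if level is None:
        raise ValueError("no significance level supplied for the contrast")

    diff = L @ theta - contrast.null_vector()
    middle = L @ omega @ L.T
    try:
        lam = float(diff @ np.linalg.solve(middle, diff))
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(f"L Omega L' is singular for {contrast.label!r}") from err
    lam = max(lam, 0.0)

    q = contrast.q
    df = n_clusters - d
    if method == "chisq":
        crit = stats.chi2.ppf(1.0 - level, q)
        power = float(stats.ncx2.sf(crit, q, lam)) if lam > 0 else float(level)
    elif method == "f_small_sample":
        if df <= 0:
            raise ValueError(
                f"small-sample F needs I - d > 0 (I={n_clusters}, d={d}); "
                f"use method='chisq'"
            )
        crit = stats.f.ppf(1.0 - level, q, df)
        power = float(stats.ncf.sf(crit, q, df, lam)) if lam > 0 else float(level)
    else:
        raise ValueError(f"unknown method {method!r}")

    return PowerResult(
        omega=omega,
        noncentrality=lam,
        df=df,
        power=min(max(power, 0.0), 1.0),
        method=method,
        alpha=float(level),
        q=q,
        label=contrast.label,
    )


def multi_test_power(
    layout: DesignLayout,
    mspec: MeanModelSpec,
    cspec: CorrelationSpec,
    vspec: VarianceSpec,
    contrasts: Sequence[ContrastSpec],
    plan: MultiplicityPlan | None = None,
    method: Method = "f_small_sample",
    patterns: dict[int, ObservationPattern] | None = None,
) -> pd.DataFrame:
    """Power for a family of contrasts with multiplicity-resolved levels.

    Returns one row per contrast: label, q, per-test alpha, noncentrality,
    degrees of freedom, attained power and (when the plan carries a goal)
    whether the goal is met.
    """
    plan = plan or MultiplicityPlan()
    levels = plan.resolve(contrasts)
    omega = model_covariance(layout, mspec, cspec, vspec, patterns)
    rows = []
    for contrast, level in zip(contrasts, levels):
        res = wald_power(omega, mspec.theta, contrast, layout.n_clusters, method, alpha=level)
        row = {
            "label": contrast.label or f"contrast_{len(rows)}",
            "q": res.q,
            "alpha": res.alpha,
            "noncentrality": res.noncentrality,
            "df": res.df,
            "power": res.power,
            "method": res.method,
        }
        if plan.power_goal is not None:
            row["meets_goal"] = res.power >= plan.power_goal
        rows.append(row)
    return pd.DataFrame(rows)
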