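"""Marginal mean model: exposure histories, design matrices, links.

The expected response for individual ``k`` of cluster ``i`` at calendar
period ``j`` is, on the scale of the link ``g``,

    g(mu_ijk) = f(T_ijk, A_ijk^IL, A_ijk^CL, A_ijk^Int) . theta

where the design function ``f`` concatenates a time-trend block with three
intervention-effect covariates built from the exposure history:

* ``A^IL`` — periods the individual has been on the IL intervention
  (including the current one),
* ``A^CL`` — periods the cluster has been on the CL intervention,
* ``A^Int`` — periods during which both were active simultaneously.

Two effect models are supported.  The *average* model (AIM) uses exposure
indicators ``1{A >= 1}``, so each delta is a time-constant effect of being on
treatment.  The *incremental* model (IIM) uses ``A / c`` with user-chosen
scaling constants ``c``, so each delta is the effect after ``c`` periods on
treatment; the interaction covariate is the cumulative count of jointly
exposed periods (linear in calendar time, unlike the product ``A^IL A^CL``).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .design import DesignLayout

__all__ = [
    "ExposureHistory",
    "MeanModelSpec",
    "exposure_from_layout",
    "design_row",
    "build_cluster_design",
    "design_matrix_frame",
    "linear_predictor_and_mean",
]

EffectModel = Literal["average", "incremental"]
Link = Literal["identity", "log", "logit"]


@dataclass(frozen=True)
class ExposureHistory:
    """Treatment exposure state of one observation."""

    period: int                # calendar period T_ijk (1-based)
    il_periods_on: int         # A^IL
    cl_periods_on: int         # A^CL
    joint_periods_on: int      # A^Int

    def __post_init__(self) -> None:
        if self.period < 1:
            raise ValueError("calendar period is 1-based")
        if not (0 <= self.il_periods_on <= self.period):
            raise ValueError("A^IL must lie in [0, T]")
        if not (0 <= self.cl_periods_on <= self.period):
            raise ValueError("A^CL must lie in [0, T]")
        if not 0 <= self.joint_periods_on <= min(self.il_periods_on, self.cl_periods_on):
            raise ValueError("A^Int cannot exceed min(A^IL, A^CL)")


@dataclass(frozen=True)
class MeanModelSpec:
    """Mean-model configuration.

    ``theta`` is ordered (time-trend coefficients, delta_IL, delta_CL,
    delta_Int).  ``scaling`` holds the strictly positive constants
    ``(c_IL, c_CL, c_Int)`` used by the incremental model; they are ignored
    by the average model.  ``time_trend`` is ``"categorical"`` (intercept +
    T-1 period indicators, reference period 1), ``"linear"`` (intercept +
    period index) or ``"polynomial"`` with ``poly_degree`` raw powers of the
    1-based period index.
    """

    effect_model: EffectModel
    time_trend: Literal["categorical", "linear", "polynomial"]
    link: Link
    theta: tuple[float, ...]
    scaling: tuple[float, float, float] = (1.0, 1.0, 1.0)
    poly_degree: int = 2
    n_periods: int = 0

    def __post_init__(self) -> None:
        if self.effect_model not in ("average", "incremental"):
            raise ValueError(f"unknown effect model {self.effect_model!r}")
        if self.link not in ("identity", "log", "logit"):
            raise ValueError(f"unknown link {self.link!r}")
        if self.time_trend not in ("categorical", "linear", "polynomial"):
            raise ValueError(f"unknown time trend {self.time_trend!r}")
        if any(c <= 0 for c in self.scaling):
            raise ValueError("scaling constants must be strictly positive")
        if self.time_trend == "polynomial" and self.poly_degree < 1:
            raise ValueError("polynomial degree must be >= 1")
        if self.time_trend == "categorical" and self.n_periods < 1:
            raise ValueError("categorical time trend needs n_periods")
        if len(self.theta) != self.dim:
            raise ValueError(
                f"theta has {len(self.theta)} entries, design function emits {self.dim}"
            )

    @property
    def n_time_columns(self) -> int:
        if self.time_trend == "categorical":
            return self.n_periods          # intercept + T-1 indicators
        if self.time_trend == "linear":
            return 2                       # intercept + period
        return 1 + self.poly_degree        # intercept + raw powers

    @property
    def dim(self) -> int:
        """d = number of mean-model columns (time block + 3 effects)."""
        return self.n_time_columns + 3

    @property
    def treatment_slice(self) -> slice:
        """Columns of (delta_IL, delta_CL, delta_Int) within the design row."""
        return slice(self.n_time_columns, self.n_time_columns + 3)

    def column_names(self) -> list[str]:
        if self.time_trend == "categorical":
            time = ["intercept"] + [f"period_{j}" for j in range(2, self.n_periods + 1)]
        elif self.time_trend == "linear":
            time = ["intercept", "period"]
        else:
            time = ["intercept"] + [f"period^{p}" for p in range(1, self.poly_degree + 1)]
        return time + ["il", "cl", "interaction"]


def exposure_from_layout(
    layout: DesignLayout, cluster: int, individual: int, period: int
) -> ExposureHistory:
    """Exposure history of one (cluster, individual, period) cell.

    Individuals are indexed within their cluster in the module row order
    (IL-control first).  The IL exposure clock starts at period 1 for
    IL-treated members of a closed cohort: both randomizations happen
    concurrently at study start, so a treated individual has been on the IL
    intervention for ``j`` periods at calendar period ``j``.
    """
    if not 1 <= period <= layout.n_periods:
        raise IndexError(f"period {period} outside 1..{layout.n_periods}")
    n0, n1 = layout.il_allocation[cluster]
    if not 0 <= individual < n0 + n1:
        raise IndexError(f"individual {individual} outside cluster of size {n0 + n1}")
    treated = individual >= n0
    crossover = layout.crossover_of_cluster(cluster)

    a_cl = max(0, period - crossover + 1)
    a_il = period if treated else 0
    # periods j' <= j with both exposures active; with the IL clock at
    # baseline this is simply A^CL for treated individuals
    a_int = sum(
        1
        for jp in range(1, period + 1)
        if (jp if treated else 0) >= 1 and max(0, jp - crossover + 1) >= 1
    )
    return ExposureHistory(
        period=period, il_periods_on=a_il, cl_periods_on=a_cl, joint_periods_on=a_int
    )


def design_row(exposure: ExposureHistory, spec: MeanModelSpec, n_periods: int | None = None) -> np.ndarray:
    """One row of the design matrix for a given exposure history."""
    T = exposure.period
    if spec.time_trend == "categorical":
        n_p = n_periods if n_periods is not None else spec.n_periods
        time = [1.0] + [1.0 if T == j else 0.0 for j in range(2, n_p + 1)]
    elif spec.time_trend == "linear":
        time = [1.0, float(T)]
    else:
        time = [1.0] + [float(T) ** p for p in range(1, spec.poly_degree + 1)]

    if spec.effect_model == "average":
        eff = [
            1.0 if exposure.il_periods_on >= 1 else 0.0,
            1.0 if exposure.cl_periods_on >= 1 else 0.0,
            1.0 if exposure.joint_periods_on >= 1 else 0.0,
        ]
    else:
        c_il, c_cl, c_int = spec.scaling
        eff = [
            exposure.il_periods_on / c_il,
            exposure.cl_periods_on / c_cl,
            exposure.joint_periods_on / c_int,
        ]
    return np.array(time + eff)


def build_cluster_design(layout: DesignLayout, spec: MeanModelSpec, cluster: int) -> np.ndarray:
    """Complete design matrix of one cluster, ``N_i * T`` rows.

    Rows follow the package convention: IL-control individuals first, each
    individual's periods ``1..T`` contiguous.
    """
    T = layout.n_periods
    n_i = layout.cohort_size[cluster]
    rows = [
        design_row(exposure_from_layout(layout, cluster, k, j), spec, T)
        for k in range(n_i)
        for j in range(1, T + 1)
    ]
    return np.array(rows).reshape(n_i * T, spec.dim) if rows else np.zeros((0, spec.dim))


def design_matrix_frame(layout: DesignLayout, spec: MeanModelSpec, cluster: int):
    """Cluster design matrix as a DataFrame with named columns (CSV-ready)."""
    import pandas as pd

    return pd.DataFrame(build_cluster_design(layout, spec, cluster),
                        columns=spec.column_names())


def linear_predictor_and_mean(X: np.ndarray, spec: MeanModelSpec) -> tuple[np.ndarray, np.ndarray]:
    """Linear predictor ``eta = X theta`` and mean ``mu = g^{-1}(eta)``."""
    X = np.asarray(X)
    if X.shape[1] != spec.dim:
        raise ValueError(f"X has {X.shape[1]} columns, mean model dimension is {spec.dim}")
    eta = X @ np.asarray(spec.theta, dtype=float)
    if spec.link == "identity":
        mu = eta.copy()
    elif spec.link == "log":
        mu = np.exp(eta)
    else:
        mu = 1.0 / (1.0 + np.exp(-eta))
    return eta, mu
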