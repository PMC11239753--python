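"""Sample-size search: minimal cohort size and the cluster/cohort frontier."""

from __future__ import annotations

from dataclasses import replace
from typing import Sequence

import numpy as np
import pandas as pd

from .covariance import CorrelationSpec, VarianceSpec
from .design import DesignLayout, make_standard_swd
from .meanmodel import MeanModelSpec
from .power import ContrastSpec, MultiplicityPlan, SingularInformationError, multi_test_power

__all__ = ["InfeasibleDesignError", "solve_cohort_size", "power_frontier", "resize_cohort"]


class InfeasibleDesignError(RuntimeError):
    """The power goal is unreachable within the allowed cohort size."""

    def __init__(self, message: str, power_at_max: pd.DataFrame | None = None):
        super().__init__(message)
        self.power_at_max = power_at_max


def resize_cohort(layout: DesignLayout, cohort_size: int, il_split: float = 0.5) -> DesignLayout:
    """Same topology with every cluster resized to ``cohort_size``."""
    n1 = int(np.ceil(cohort_size * il_split))
    return replace(
        layout,
        cohort_size=(cohort_size,) * layout.n_clusters,
        il_allocation=((cohort_size - n1, n1),) * layout.n_clusters,
    )


def _min_power(
    layout: DesignLayout,
    mspec: MeanModelSpec,
    cspec: CorrelationSpec,
    vspec: VarianceSpec,
    contrasts: Sequence[ContrastSpec],
    plan: MultiplicityPlan,
    method: str,
) -> tuple[float, pd.DataFrame]:
    table = multi_test_power(layout, mspec, cspec, vspec, contrasts, plan, method)  # type: ignore[arg-type]
    return float(table["power"].min()), table


def solve_cohort_size(
    layout: DesignLayout,
    mspec: MeanModelSpec,
    cspec: CorrelationSpec,
    vspec: VarianceSpec,
    contrasts: Sequence[ContrastSpec],
    power_goal: float,
    n_max: int = 1000,
    il_split: float = 0.5,
    method: str = "f_small_sample",
    plan: MultiplicityPlan | None = None,
) -> int:
    """Smallest per-cluster cohort size meeting ``power_goal`` on every test.

    Power is monotone nondecreasing in the cohort size for the standard
    designs handled here, so the search brackets exponentially and bisects;
    if the bracketing detects non-monotone behaviour it falls back to a
    linear scan.  Raises :class:`InfeasibleDesignError` (reporting the power
    table at ``n_max``) when the goal cannot be met.
    """
    if not 0.0 < power_goal < 1.0:
        raise ValueError("power_goal must lie in (0, 1)")
    if n_max < 1:
        raise ValueError("n_max must be >= 1")
    plan = plan or MultiplicityPlan()

    _cache: dict[int, float] = {}

    def attained(n: int) -> float:
        if n not in _cache:
            try:
                _cache[n] = _min_power(
                    resize_cohort(layout, n, il_split), mspec, cspec, vspec,
                    contrasts, plan, method,
                )[0]
            except SingularInformationError:
                # e.g. a cohort of one leaves the IL contrast unidentified
                _cache[n] = 0.0
        return _cache[n]

    if attained(1) >= power_goal:
        return 1
    p_max, table_max = _min_power(
        resize_cohort(layout, n_max, il_split), mspec, cspec, vspec, contrasts, plan, method
    )
    if p_max < power_goal:
        raise InfeasibleDesignError(
            f"power goal {power_goal} unreachable with N <= {n_max}: "
            f"minimum attained power {p_max:.4f}",
            power_at_max=table_max,
        )

    # exponential bracketing
    lo, hi = 1, 2
    prev = attained(1)
    monotone = True
    while hi < n_max and attained(hi) < power_goal:
        cur = attained(hi)
        if cur < prev - 1e-12:
            monotone = False
            break
        prev, lo, hi = cur, hi, min(hi * 2, n_max)

    if not monotone:
        for n in range(2, n_max + 1):  # robustness fallback
            if attained(n) >= power_goal:
                return n
        raise InfeasibleDesignError(f"power goal {power_goal} unreachable with N <= {n_max}")

    while hi - lo > 1:
        mid = (lo + hi) // 2
        if attained(mid) >= power_goal:
            hi = mid
        else:
            lo = mid
    return hi


def distribute_clusters(n_clusters: int, n_sequences: int) -> tuple[int, ...]:
    """Spread ``I`` clusters over ``S`` sequences; remainders go to the earliest."""
    base, rem = divmod(n_clusters, n_sequences)
    if base < 1:
        raise ValueError(f"cannot place {n_clusters} clusters on {n_sequences} sequences")
    return tuple(base + (1 if s < rem else 0) for s in range(n_sequences))


def power_frontier(
    n_periods: int,
    n_sequences: int,
    cluster_range: Sequence[int],
    mspec: MeanModelSpec,
    cspec: CorrelationSpec,
    vspec: VarianceSpec,
    contrasts: Sequence[ContrastSpec],
    power_goal: float,
    n_max: int = 1000,
    il_split: float = 0.5,
    method: str = "f_small_sample",
    plan: MultiplicityPlan | None = None,
    cohort_type: str = "closed_cohort",
) -> pd.DataFrame:
    """Feasibility frontier: minimal cohort size for each candidate ``I``.

    Each row gives the cluster count, its per-sequence distribution, the
    minimal cohort size (NaN when infeasible at ``n_max``) and the per-test
    power at that size.
    """
    if len(cluster_range) == 0:
        raise ValueError("cluster_range must be nonempty")
    plan = plan or MultiplicityPlan()
    rows = []
    for n_clusters in cluster_range:
        per_seq = distribute_clusters(int(n_clusters), n_sequences)
        layout = make_standard_swd(
            n_periods, n_sequences, per_seq, cohort_size=1, il_split=il_split,
            cohort_type=cohort_type,  # type: ignore[arg-type]
        )
        row: dict = {"clusters": int(n_clusters), "per_sequence": per_seq}
        try:
            n_star = solve_cohort_size(
                layout, mspec, cspec, vspec, contrasts, power_goal,
                n_max=n_max, il_split=il_split, method=method, plan=plan,
            )
            row["cohort_size"] = n_star
            table = multi_test_power(
                resize_cohort(layout, n_star, il_split), mspec, cspec, vspec,
                contrasts, plan, method,  # type: ignore[arg-type]
            )
            for _, r in table.iterrows():
                row[f"power[{r['label']}]"] = r["power"]
        except InfeasibleDesignError:
            row["cohort_size"] = float("nan")
        rows.append(row)
    return pd.DataFrame(rows)
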