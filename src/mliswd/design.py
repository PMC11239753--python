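"""Trial topology for multilevel-intervention stepped wedge designs.

A stepped wedge design (SWD) assigns clusters to *sequences*; all clusters in
sequence ``s`` switch from control to the cluster-level (CL) intervention at
the same calendar period and stay on it.  In the multilevel variant the
individuals inside each cluster are additionally randomized, independently of
the cluster's sequence, to an individual-level (IL) intervention arm.

This module represents that topology (:class:`DesignLayout`), the planned
observation pattern (:class:`ObservationPattern`) and the incidence machinery
that maps an incomplete design onto the complete observation-level layout
(:class:`IncidenceMatrix`).

Row-ordering convention
-----------------------
Everything downstream (design matrices, correlation matrices, simulated
outcome vectors) orders a cluster's observations *individual-major,
period-minor*: individual 1 at periods ``1..J``, then individual 2, and so
on, with IL-control individuals listed before IL-treated ones.  Calendar
periods are 1-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "DesignLayout",
    "ObservationPattern",
    "IncidenceMatrix",
    "InvalidDesignError",
    "make_standard_swd",
    "build_incidence",
    "apply_incidence",
    "schematic",
]

CohortType = Literal["closed_cohort", "cross_sectional", "open_cohort"]


class InvalidDesignError(ValueError):
    """Raised when a design specification is internally inconsistent."""


@dataclass(frozen=True)
class DesignLayout:
    """Randomization topology of a multilevel stepped wedge trial.

    Parameters
    ----------
    n_periods:
        Total number of calendar periods ``T`` (equal to the number of
        observation periods ``J`` for a complete design).
    n_sequences:
        Number of distinct crossover sequences ``S``.
    clusters_per_sequence:
        ``m_s`` for each sequence; the trial has ``I = sum(m_s)`` clusters.
    crossover_period:
        First calendar period each sequence spends on the CL intervention.
        The value ``T + 1`` encodes a sequence that never crosses over.
    cohort_type:
        ``closed_cohort`` (same individuals every period), ``cross_sectional``
        (fresh sample each period) or ``open_cohort`` (per-individual
        observation windows supplied through an :class:`ObservationPattern`).
    cohort_size:
        Individuals per cluster, one entry per cluster (``N_i``).
    il_allocation:
        ``(N_i0, N_i1)`` counts of IL-control and IL-treated individuals per
        cluster; rows must sum to ``cohort_size``.
    """

    n_periods: int
    n_sequences: int
    clusters_per_sequence: tuple[int, ...]
    crossover_period: tuple[int, ...]
    cohort_type: CohortType = "closed_cohort"
    cohort_size: tuple[int, ...] = field(default=())
    il_allocation: tuple[tuple[int, int], ...] = field(default=())

    def __post_init__(self) -> None:
        T, S = self.n_periods, self.n_sequences
        if T < 1 or S < 1:
            raise InvalidDesignError("n_periods and n_sequences must be positive")
        if len(self.clusters_per_sequence) != S:
            raise InvalidDesignError("clusters_per_sequence must have one entry per sequence")
        if any(m < 1 for m in self.clusters_per_sequence):
            raise InvalidDesignError("each sequence needs at least one cluster")
        if len(self.crossover_period) != S:
            raise InvalidDesignError("crossover_period must have one entry per sequence")
        for c in self.crossover_period:
            if not 2 <= c <= T + 1:
                raise InvalidDesignError(
                    f"crossover period {c} outside {{2, ..., {T + 1}}} "
                    f"(T+1 encodes 'never crosses over')"
                )
        if self.cohort_type not in ("closed_cohort", "cross_sectional", "open_cohort"):
            raise InvalidDesignError(f"unknown cohort_type {self.cohort_type!r}")
        I = self.n_clusters
        if len(self.cohort_size) != I:
            raise InvalidDesignError("cohort_size must have one entry per cluster")
        if any(n < 0 for n in self.cohort_size):
            raise InvalidDesignError("cohort sizes must be nonnegative")
        if len(self.il_allocation) != I:
            raise InvalidDesignError("il_allocation must have one entry per cluster")
        for i, (n0, n1) in enumerate(self.il_allocation):
            if n0 < 0 or n1 < 0 or n0 + n1 != self.cohort_size[i]:
                raise InvalidDesignError(
                    f"cluster {i}: IL allocation ({n0}, {n1}) does not sum to N_i="
                    f"{self.cohort_size[i]}"
                )

    @property
    def n_clusters(self) -> int:
        return int(sum(self.clusters_per_sequence))

    def sequence_of_cluster(self, cluster: int) -> int:
        """0-based sequence index of a 0-based cluster index."""
        if not 0 <= cluster < self.n_clusters:
            raise IndexError(f"cluster {cluster} out of range")
        bounds = np.cumsum(self.clusters_per_sequence)
        return int(np.searchsorted(bounds, cluster, side="right"))

    def crossover_of_cluster(self, cluster: int) -> int:
        return self.crossover_period[self.sequence_of_cluster(cluster)]

    def is_standard_wedge(self) -> bool:
        """Strictly increasing crossover times across sequences."""
        c = self.crossover_period
        return all(a < b for a, b in zip(c, c[1:]))


@dataclass(frozen=True)
class ObservationPattern:
    """Planned observation schedule for one cluster.

    ``individual_patterns`` holds one boolean row per observation slot
    (length ``T``); ``True`` marks a calendar period in which that slot is
    observed.  For closed cohorts a single shared row may be given and is
    replicated over the cohort via the Kronecker construction.  Cross
    sectional sampling is expressed as an open cohort whose individuals are
    each observed in exactly one period.
    """

    individual_patterns: tuple[tuple[bool, ...], ...]
    shared: bool = False

    @classmethod
    def complete(cls, n_periods: int) -> "ObservationPattern":
        return cls(((True,) * n_periods,), shared=True)

    @classmethod
    def from_matrix(cls, mat: Sequence[Sequence[bool]], shared: bool = False) -> "ObservationPattern":
        return cls(tuple(tuple(bool(x) for x in row) for row in mat), shared=shared)

    @property
    def n_periods(self) -> int:
        return len(self.individual_patterns[0])

    def is_complete(self) -> bool:
        return all(all(row) for row in self.individual_patterns)


@dataclass(frozen=True)
class IncidenceMatrix:
    """Binary map from a cluster's observations to calendar periods.

    ``K`` has one row per planned observation and one column per calendar
    period; each row contains a single 1.  ``selector`` gives, for each row of
    ``K``, the index of the corresponding row in the complete
    observation-level layout of the cluster, so that an incomplete design
    matrix is ``X[selector]`` and an incomplete correlation matrix is
    ``R[np.ix_(selector, selector)]``.
    """

    K: np.ndarray
    selector: np.ndarray

    def __post_init__(self) -> None:
        K = np.asarray(self.K)
        if K.ndim != 2 or not np.isin(K, (0, 1)).all():
            raise InvalidDesignError("incidence matrix must be binary")
        if not (K.sum(axis=1) == 1).all():
            raise InvalidDesignError("each incidence row must contain exactly one 1")
        if len(self.selector) != K.shape[0]:
            raise InvalidDesignError("selector length must match incidence rows")

    @property
    def n_observations(self) -> int:
        return self.K.shape[0]

    def period_counts(self) -> np.ndarray:
        """Observations per calendar period (column sums of ``K``)."""
        return self.K.sum(axis=0)


def _default_allocation(n: int, split: float) -> tuple[int, int]:
    # deterministic: treated count rounds up on ties so a 50/50 split of an
    # odd cohort favours the treated arm by one
    n1 = int(np.ceil(n * split))
    return n - n1, n1


def make_standard_swd(
    n_periods: int,
    n_sequences: int,
    clusters_per_sequence: int | Sequence[int],
    cohort_size: int | Sequence[int],
    il_split: float = 0.5,
    cohort_type: CohortType = "closed_cohort",
) -> DesignLayout:
    """Build a complete standard stepped wedge layout.

    Sequence ``s`` (1-based) crosses over at calendar period ``s + 1``; all
    clusters are observed in every period.  ``il_split`` is the fraction of
    each cluster's cohort randomized to the IL intervention; with an odd
    cohort the treated arm receives the extra individual.

    Raises
    ------
    InvalidDesignError
        If ``n_sequences > n_periods - 1`` (the standard wedge needs a
        control-only first period and at least one post-crossover period per
        sequence) or dimensions are non-positive.
    ValueError
        If ``il_split`` is outside ``[0, 1]``.
    """
    if n_periods < 2 or n_sequences < 1:
        raise InvalidDesignError("need n_periods >= 2 and n_sequences >= 1")
    if n_sequences > n_periods - 1:
        raise InvalidDesignError(
            f"standard wedge requires n_sequences <= n_periods - 1 "
            f"(got S={n_sequences}, T={n_periods})"
        )
    if not 0.0 <= il_split <= 1.0:
        raise ValueError(f"il_split must lie in [0, 1], got {il_split}")

    if isinstance(clusters_per_sequence, (int, np.integer)):
        m = (int(clusters_per_sequence),) * n_sequences
    else:
        m = tuple(int(x) for x in clusters_per_sequence)
        if len(m) != n_sequences:
            raise InvalidDesignError("clusters_per_sequence length must equal n_sequences")
    I = sum(m)
    if isinstance(cohort_size, (int, np.integer)):
        sizes = (int(cohort_size),) * I
    else:
        sizes = tuple(int(x) for x in cohort_size)
        if len(sizes) != I:
            raise InvalidDesignError("cohort_size length must equal the number of clusters")

    return DesignLayout(
        n_periods=n_periods,
        n_sequences=n_sequences,
        clusters_per_sequence=m,
        crossover_period=tuple(s + 2 for s in range(n_sequences)),
        cohort_type=cohort_type,
        cohort_size=sizes,
        il_allocation=tuple(_default_allocation(n, il_split) for n in sizes),
    )


def build_incidence(
    pattern: ObservationPattern,
    layout: DesignLayout,
    cluster: int,
) -> IncidenceMatrix:
    """Incidence matrix ``K_i`` for one cluster under a planned pattern.

    For closed cohorts with a shared single-individual pattern ``K_s`` the
    cluster matrix is the Kronecker product ``K_s (x) 1_{N_i}`` — the same
    observation window replicated over the cohort.  For open cohorts the
    per-individual incidence blocks are stacked in cohort order.
    """
    T = layout.n_periods
    if pattern.n_periods != T:
        raise InvalidDesignError(
            f"pattern spans {pattern.n_periods} periods, layout has {T}"
        )
    n_i = layout.cohort_size[cluster]

    if pattern.shared:
        if len(pattern.individual_patterns) != 1:
            raise InvalidDesignError("shared pattern must contain a single row")
        K_s = _rows_to_incidence(pattern.individual_patterns[0], T)
        # K_i = K_s (x) 1_{N_i}: replicate the individual block per cohort member
        K = np.kron(np.ones((n_i, 1)), K_s) if n_i else np.zeros((0, T))
        sel_one = np.flatnonzero(pattern.individual_patterns[0])
        selector = np.concatenate(
            [sel_one + k * T for k in range(n_i)]
        ) if n_i else np.zeros(0, dtype=int)
    else:
        if len(pattern.individual_patterns) != n_i:
            raise InvalidDesignError(
                f"pattern has {len(pattern.individual_patterns)} rows, "
                f"cluster {cluster} has N_i={n_i} individuals"
            )
        blocks, sels = [], []
        for k, row in enumerate(pattern.individual_patterns):
            blocks.append(_rows_to_incidence(row, T))
            sels.append(np.flatnonzero(row) + k * T)
        K = np.vstack(blocks) if blocks else np.zeros((0, T))
        selector = np.concatenate(sels) if sels else np.zeros(0, dtype=int)

    return IncidenceMatrix(K=K, selector=np.asarray(selector, dtype=int))


def _rows_to_incidence(row: Sequence[bool], T: int) -> np.ndarray:
    periods = np.flatnonzero(row)
    if periods.size == 0:
        return np.zeros((0, T))
    out = np.zeros((periods.size, T))
    out[np.arange(periods.size), periods] = 1.0
    return out


def apply_incidence(
    incidence: IncidenceMatrix,
    design_matrix: np.ndarray,
    correlation: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Restrict a complete design/correlation pair to the observed rows.

    The complete matrices are laid out over every (individual, period) cell of
    the cluster; incompleteness acts as the row-selection operator ``S``
    induced by the incidence matrix, returning ``S X`` and ``S R S^T``.
    """
    X = np.asarray(design_matrix)
    R = np.asarray(correlation)
    if R.shape[0] != R.shape[1]:
        raise InvalidDesignError("correlation matrix must be square")
    if X.shape[0] != R.shape[0]:
        raise InvalidDesignError(
            f"design matrix has {X.shape[0]} rows, correlation {R.shape[0]}"
        )
    sel = incidence.selector
    if sel.size and sel.max() >= X.shape[0]:
        raise InvalidDesignError("selector indexes beyond the complete layout")
    return X[sel], R[np.ix_(sel, sel)]


def schematic(layout: DesignLayout, pattern_by_sequence: dict[int, ObservationPattern] | None = None) -> str:
    """Plain-text wedge diagram: rows are sequences, columns calendar periods.

    Cells: ``.`` control, ``X`` on the CL intervention, a blank cell
    unobserved (incomplete designs).
    """
    lines = ["sequence (m_s) | " + " ".join(f"{j:>2d}" for j in range(1, layout.n_periods + 1))]
    lines.append("-" * len(lines[0]))
    for s in range(layout.n_sequences):
        cells = []
        for j in range(1, layout.n_periods + 1):
            observed = True
            if pattern_by_sequence is not None and s in pattern_by_sequence:
                pat = pattern_by_sequence[s]
                observed = any(row[j - 1] for row in pat.individual_patterns)
            if not observed:
                cells.append("  ")
            elif j >= layout.crossover_period[s]:
                cells.append(" X")
            else:
                cells.append(" .")
        lines.append(f"{s + 1:>8d} ({layout.clusters_per_sequence[s]:>2d}) |" + " ".join(cells))
    return "\n".join(lines)
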