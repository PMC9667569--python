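"""Core containers for sparse longitudinal screening histories.

A screening history is a sparse sequence of exam-derived states for one
individual, binned on a regular 3-month age grid.  States are encoded
1 = normal, 2 = low-risk, 3 = high-risk, 4 = cancer, ordered by clinical
severity.  Histories for a cohort are stacked into a partially observed
integer matrix ``Y`` (one row per individual, one column per time bin)
with an observation mask ``Ω``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

STATES = (1, 2, 3, 4)
STATE_NAMES = {1: "normal", 2: "low-risk", 3: "high-risk", 4: "cancer"}

#: width of one time bin, in years (3 months)
BIN_WIDTH_YEARS = 0.25


@dataclass(frozen=True)
class TimeGrid:
    """Regular 3-month time grid shared by all rows of a state matrix.

    Parameters
    ----------
    n_bins:
        Number of columns ``T``; at least 2.
    origin_age:
        Age in years at the left edge of column 0 (default 25, the
        recommended age to start screening).

    Bins are 0-based and half-open: bin ``t`` covers ages
    ``[origin_age + t/4, origin_age + (t+1)/4)`` years.
    """

    n_bins: int
    origin_age: float = 25.0

    def __post_init__(self) -> None:
        if self.n_bins < 2:
            raise ValueError(f"n_bins must be >= 2, got {self.n_bins}")

    @property
    def times(self) -> np.ndarray:
        """Left bin edges in years since ``origin_age``."""
        return np.arange(self.n_bins) * BIN_WIDTH_YEARS

    @property
    def ages(self) -> np.ndarray:
        """Left bin edges as ages in years."""
        return self.origin_age + self.times


@dataclass
class StateMatrix:
    """Partially observed integer state matrix with its observation mask.

    ``values[n, t]`` is meaningful only where ``mask[n, t]`` is True and
    then lies in {1, 2, 3, 4}.  Unobserved entries are stored as 0 and
    ignored by every computation.
    """

    values: np.ndarray
    mask: np.ndarray
    grid: TimeGrid
    subjects: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.ndim != 2 or self.values.shape != self.mask.shape:
            raise ValueError("values and mask must be 2-d arrays of equal shape")
        n, t = self.values.shape
        if n < 1:
            raise ValueError("need at least one subject row")
        if t != self.grid.n_bins:
            raise ValueError(
                f"matrix has {t} columns but grid declares {self.grid.n_bins} bins"
            )
        observed = self.values[self.mask]
        if observed.size and (
            not np.issubdtype(self.values.dtype, np.integer)
            and not np.all(observed == np.round(observed))
        ):
            raise ValueError("observed states must be integers")
        if observed.size and (observed.min() < 1 or observed.max() > 4):
            raise ValueError("observed states must lie in {1, 2, 3, 4}")
        if not self.subjects:
            self.subjects = list(range(n))
        elif len(self.subjects) != n:
            raise ValueError("subjects must match the number of rows")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, StateMatrix):
            return NotImplemented
        return (
            self.grid == other.grid
            and self.subjects == other.subjects
            and np.array_equal(self.mask, other.mask)
            and np.array_equal(
                np.where(self.mask, self.values, 0),
                np.where(other.mask, other.values, 0),
            )
        )


@dataclass
class WeightMatrix:
    """Non-negative discrepancy weights, zero exactly off the observed set."""

    weights: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if np.any(self.weights < 0):
            raise ValueError("weights must be non-negative")

    def validate_against(self, m: StateMatrix) -> None:
        if self.weights.shape != m.values.shape:
            raise ValueError("weight shape does not match state matrix")
        if np.any(self.weights[~m.mask] != 0):
            raise ValueError("weights must be zero on unobserved entries")
        if np.any(self.weights[m.mask] <= 0):
            raise ValueError("weights must be strictly positive on observed entries")


def load_histories(records, grid: TimeGrid) -> StateMatrix:
    """Materialize triplet records ``(subject, bin, state)`` as a StateMatrix.

    Rows follow first appearance order of subject keys.  Duplicate
    ``(subject, bin)`` pairs keep the clinically worst (maximum) state.
    """
    order: dict = {}
    entries = []
    for rec in records:
        subject, t, s = rec
        t = int(t)
        s = int(s)
        if not 0 <= t < grid.n_bins:
            raise ValueError(
                f"record {rec!r}: time bin {t} outside [0, {grid.n_bins})"
            )
        if s not in STATES:
            raise ValueError(f"record {rec!r}: state {s} not in {{1, 2, 3, 4}}")
        if subject not in order:
            order[subject] = len(order)
        entries.append((order[subject], t, s))
    n = max(len(order), 1)
    values = np.zeros((n, grid.n_bins), dtype=np.int64)
    mask = np.zeros((n, grid.n_bins), dtype=bool)
    for row, t, s in entries:
        if mask[row, t]:
            values[row, t] = max(values[row, t], s)
        else:
            values[row, t] = s
            mask[row, t] = True
    return StateMatrix(values, mask, grid, subjects=list(order))


def to_records(m: StateMatrix) -> list[tuple]:
    """Triplet records ``(subject, bin, state)`` for the observed entries."""
    out = []
    for row, subject in enumerate(m.subjects):
        for t in np.flatnonzero(m.mask[row]):
            out.append((subject, int(t), int(m.values[row, t])))
    return out


def write_histories(m: StateMatrix, sink) -> None:
    """Write a StateMatrix as delimited triplets (header ``subject,bin,state``).

    Round-trips with :func:`read_histories` / :func:`load_histories` up to
    row order.  Gzip output is selected by a ``.gz`` suffix, as usual for
    pandas sinks.
    """
    df = pd.DataFrame(to_records(m), columns=["subject", "bin", "state"])
    df.to_csv(sink, index=False)


def read_histories(source, grid: TimeGrid | None = None) -> StateMatrix:
    """Read triplet CSV/TSV (gzip transparently accepted) into a StateMatrix.

    If ``grid`` is omitted, the number of bins is taken as ``max(bin) + 1``.
    """
    df = pd.read_csv(source, sep=None, engine="python")
    expected = {"subject", "bin", "state"}
    if not expected.issubset(df.columns):
        raise ValueError(f"history file must have columns {sorted(expected)}")
    if grid is None:
        if len(df) == 0:
            raise ValueError("cannot infer grid from an empty history file")
        grid = TimeGrid(n_bins=max(int(df["bin"].max()) + 1, 2))
    return load_histories(
        df[["subject", "bin", "state"]].itertuples(index=False, name=None), grid
    )


def density(m: StateMatrix) -> float:
    """Fraction of observed entries, ``|Ω| / (N·T)``."""
    return float(m.mask.mean())
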