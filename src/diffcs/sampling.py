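"""Non-uniform sampling schedules for the indirect dimension.

Schedules are ordered sets of indirect-dimension grid indices.  The
generator implements sinusoidally weighted Poisson-gap sampling: gaps
between consecutive sampled points are Poisson draws whose mean grows
towards late evolution times, and the underlying rate is adjusted until
exactly M points land inside the grid.  The first increment (index 0) is
always sampled, which is what makes nested schedules and first-increment
alignment possible downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "SamplingSchedule",
    "poisson_gap_schedule",
    "nest_schedule",
    "undersample",
    "read_schedule",
    "write_schedule",
]


@dataclass(eq=False)
class SamplingSchedule:
    """Strictly increasing indices in [0, n-1] out of an n-point grid."""

    indices: np.ndarray
    n: int
    seed: int | None = None
    kind: str = "explicit"

    def __post_init__(self) -> None:
        idx = np.asarray(self.indices, dtype=np.intp)
        if idx.ndim != 1 or idx.size < 1:
            raise ValueError("schedule needs at least one index")
        if np.any(np.diff(idx) <= 0):
            raise ValueError("schedule indices must be strictly increasing")
        if idx[0] < 0 or idx[-1] > self.n - 1:
            raise ValueError(f"schedule indices must lie in [0, {self.n - 1}]")
        self.indices = idx

    @property
    def m(self) -> int:
        return int(self.indices.size)

    def mask(self) -> np.ndarray:
        out = np.zeros(self.n, dtype=bool)
        out[self.indices] = True
        return out

    def is_full(self) -> bool:
        return self.m == self.n

    def issubset(self, other: "SamplingSchedule") -> bool:
        return bool(np.isin(self.indices, other.indices).all())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SamplingSchedule):
            return NotImplemented
        return self.n == other.n and np.array_equal(self.indices, other.indices)

    def __len__(self) -> int:
        return self.m


def full_schedule(n: int) -> SamplingSchedule:
    return SamplingSchedule(np.arange(n), n=n, kind="uniform")


def _sin_weight(pos: np.ndarray | float, n: int) -> np.ndarray | float:
    # mean weight over the grid is ~2/pi; normalise so the rate parameter
    # keeps the interpretation "average extra gap".
    return np.sin(np.pi / 2.0 * (np.asarray(pos) + 0.5) / n) * (np.pi / 2.0)


def poisson_gap_schedule(
    n: int,
    m: int,
    seed: int = 0,
    sinusoidal_weight: bool = True,
) -> SamplingSchedule:
    """Draw an M-of-N Poisson-gap schedule (deterministic in ``seed``)."""
    if m < 1:
        raise ValueError("m must be >= 1")
    if m > n:
        raise ValueError(f"cannot sample m={m} points from an n={n} grid")
    if m == n:
        return SamplingSchedule(np.arange(n), n=n, seed=seed, kind="poisson_gap")

    rng = np.random.default_rng(seed)
    lam = max((n - m) / m, 1e-3)
    for _ in range(20000):
        idx = []
        pos = 0
        while pos < n:
            idx.append(pos)
            w = _sin_weight(pos, n) if sinusoidal_weight else 1.0
            gap = rng.poisson(lam * w)
            pos += 1 + int(gap)
        if len(idx) == m:
            return SamplingSchedule(
                np.asarray(idx, dtype=np.intp), n=n, seed=seed, kind="poisson_gap"
            )
        # too many points -> gaps too small -> raise the rate, and vice versa
        lam = max(lam * len(idx) / m, 1e-6)
    # extremely unlikely; deterministic fallback keeping index 0
    fallback = np.unique(np.round(np.linspace(0, n - 1, m)).astype(np.intp))
    extra = np.setdiff1d(np.arange(n), fallback)
    fallback = np.sort(np.concatenate([fallback, extra[: m - fallback.size]]))
    return SamplingSchedule(fallback, n=n, seed=seed, kind="poisson_gap")


def nest_schedule(parent: SamplingSchedule, m_child: int, seed: int = 0) -> SamplingSchedule:
    """Poisson-gap-weighted subsampling of ``parent``'s positions.

    The child's indices are a subset of the parent's, which is the
    requirement for forming difference FIDs between data sets measured
    on the two schedules.
    """
    if m_child > parent.m:
        raise ValueError(
            f"child schedule ({m_child} points) cannot exceed parent ({parent.m} points)"
        )
    if m_child == parent.m:
        return SamplingSchedule(parent.indices.copy(), n=parent.n, seed=seed, kind=parent.kind)
    positions = poisson_gap_schedule(parent.m, m_child, seed=seed)
    child = parent.indices[positions.indices]
    return SamplingSchedule(child, n=parent.n, seed=seed, kind="poisson_gap")


def undersample(fid_full, schedule: SamplingSchedule):
    """Restrict a fully sampled FID to the rows of a schedule."""
    from .signal_model import TimeDomain2D

    if not fid_full.is_fully_sampled():
        raise ValueError("undersample expects a fully sampled FID")
    if schedule.n != fid_full.axis1.n_points:
        raise ValueError(
            f"schedule grid size {schedule.n} != indirect dimension "
            f"{fid_full.axis1.n_points}"
        )
    return TimeDomain2D(
        data=fid_full.data[schedule.indices].copy(),
        axis1=fid_full.axis1,
        axis2=fid_full.axis2,
        schedule=schedule,
        temperature=fid_full.temperature,
        label=fid_full.label,
    )


def write_schedule(schedule: SamplingSchedule, path, one_based: bool = False) -> None:
    """Write a nuslist-style file: one grid index per line, ascending."""
    offset = 1 if one_based else 0
    Path(path).write_text("".join(f"{i + offset}\n" for i in schedule.indices))


def read_schedule(path, n: int, one_based: bool = False) -> SamplingSchedule:
    lines = [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
    idx = np.asarray([int(ln.split()[0]) for ln in lines], dtype=np.intp)
    if one_based:
        idx = idx - 1
    return SamplingSchedule(np.sort(idx), n=n, kind="explicit")
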