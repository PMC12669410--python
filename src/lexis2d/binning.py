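"""Binning of individual two-time-scale records on a regular Lexis grid.

Each individual enters follow-up at age-at-diagnosis ``u`` (time since
diagnosis ``s = 0``, or ``s_entry > 0`` for late entry) and leaves at
``s_exit`` by an event of one of two competing causes or by right-censoring.
On a regular grid over the ``(u, s)`` plane the individual occupies a single
``u``-row; events contribute a count of one to the cell containing
``(u, s_exit)`` and person-time at risk is apportioned to the ``s``-cells of
that row by exact interval overlap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

N_CAUSES = 2


@dataclass(frozen=True)
class IndividualRecord:
    """One subject's follow-up on the (u, s) plane.

    Parameters
    ----------
    id : object
        Opaque identifier, used only in error messages.
    u : float
        Age at the origin of the second time scale (age at diagnosis), years.
    s_exit : float
        Time since diagnosis at exit from the risk set, years.
    cause : int
        0 = right-censored, 1 or 2 = cause of the event at ``s_exit``.
    s_entry : float
        Time since diagnosis at entry into the risk set (late entry), years.
    """

    id: object
    u: float
    s_exit: float
    cause: int
    s_entry: float = 0.0

    def __post_init__(self):
        if not self.s_entry < self.s_exit:
            raise ValueError(
                f"record {self.id!r}: s_entry ({self.s_entry}) must be "
                f"< s_exit ({self.s_exit})"
            )
        if self.u < 0:
            raise ValueError(f"record {self.id!r}: u must be nonnegative")
        if self.cause not in (0, 1, 2):
            raise ValueError(f"record {self.id!r}: cause must be in {{0,1,2}}")


@dataclass(frozen=True)
class TwoTimeGrid:
    """Regular rectangular binning of the (u, s) plane.

    Bins are half-open ``[lower, upper)`` on both axes; the last bin may
    extend past the requested maximum to complete the tiling.
    """

    u_min: float
    u_max: float
    s_min: float
    s_max: float
    h_u: float
    h_s: float
    n_u: int
    n_s: int

    @property
    def u_edges(self) -> np.ndarray:
        return self.u_min + self.h_u * np.arange(self.n_u + 1)

    @property
    def s_edges(self) -> np.ndarray:
        return self.s_min + self.h_s * np.arange(self.n_s + 1)

    @property
    def u_mid(self) -> np.ndarray:
        return self.u_min + self.h_u * (np.arange(self.n_u) + 0.5)

    @property
    def s_mid(self) -> np.ndarray:
        return self.s_min + self.h_s * (np.arange(self.n_s) + 0.5)


@dataclass
class BinnedCompRisks:
    """Exposure matrix R and per-cause event-count matrices on a grid.

    ``R[j, k]`` is the person-years at risk in cell ``(j, k)``;
    ``Y[l][j, k]`` the event count of cause ``l + 1``.
    """

    grid: TwoTimeGrid
    R: np.ndarray
    Y: list = field(default_factory=list)

    def __post_init__(self):
        if self.R.shape != (self.grid.n_u, self.grid.n_s):
            raise ValueError("R has wrong shape for the grid")
        for Yl in self.Y:
            if Yl.shape != self.R.shape:
                raise ValueError("event matrix shape differs from R")

    @property
    def total_exposure(self) -> float:
        return float(self.R.sum())

    @property
    def total_events(self) -> np.ndarray:
        return np.array([Yl.sum() for Yl in self.Y])

    def to_long_frame(self) -> pd.DataFrame:
        """Long-format view (u_mid, s_mid, r, y1, y2)."""
        uu, ss = np.meshgrid(self.grid.u_mid, self.grid.s_mid, indexing="ij")
        return pd.DataFrame(
            {
                "u_mid": uu.ravel(),
                "s_mid": ss.ravel(),
                "r": self.R.ravel(),
                "y1": self.Y[0].ravel(),
                "y2": self.Y[1].ravel(),
            }
        )


def build_grid(u_range, s_range, h_u: float, h_s: float) -> TwoTimeGrid:
    """Build a regular (u, s) grid of half-open bins tiling the given ranges.

    The number of bins per axis is ``ceil(range / width)``, so the final bin
    may extend past the range maximum.
    """
    u_min, u_max = float(u_range[0]), float(u_range[1])
    s_min, s_max = float(s_range[0]), float(s_range[1])
    if not (u_max > u_min and s_max > s_min):
        raise ValueError("ranges must be nondegenerate (max > min)")
    if not (h_u > 0 and h_s > 0):
        raise ValueError("bin widths must be positive")
    # tiny relative tolerance so e.g. 10.5/0.5 does not yield 22 bins
    n_u = int(np.ceil((u_max - u_min) / h_u - 1e-9))
    n_s = int(np.ceil((s_max - s_min) / h_s - 1e-9))
    return TwoTimeGrid(u_min, u_max, s_min, s_max, h_u, h_s, n_u, n_s)


def _u_index(u: np.ndarray, grid: TwoTimeGrid) -> np.ndarray:
    return np.floor((u - grid.u_min) / grid.h_u).astype(int)


def bin_individuals(records, grid: TwoTimeGrid) -> BinnedCompRisks:
    """Bin individual records into event-count and exposure matrices.

    Events land in the single cell whose half-open bin contains
    ``(u, s_exit)``; an exit exactly at ``s_max`` is placed in the last bin.
    Exposure is apportioned to the cells of the record's ``u``-row by exact
    overlap of ``[s_entry, s_exit)`` with each ``s``-bin.  Follow-up beyond
    ``s_max`` is truncated (the record becomes censored within the grid) with
    a logged warning.

    Raises
    ------
    ValueError
        If any record's ``u`` lies outside the grid's u-range.
    """
    records = list(records)
    n = len(records)
    u = np.array([r.u for r in records], dtype=float)
    s_en = np.array([r.s_entry for r in records], dtype=float)
    s_ex = np.array([r.s_exit for r in records], dtype=float)
    cause = np.array([r.cause for r in records], dtype=int)

    u_hi = grid.u_min + grid.n_u * grid.h_u  # actual tiled upper edge
    bad = (u < grid.u_min) | (u >= u_hi)
    if bad.any():
        i = int(np.flatnonzero(bad)[0])
        raise ValueError(
            f"record {records[i].id!r}: u={records[i].u} outside the grid "
            f"u-range [{grid.u_min}, {u_hi})"
        )

    s_hi = grid.s_min + grid.n_s * grid.h_s
    n_trunc = int((s_ex > s_hi).sum())
    if n_trunc:
        logger.warning(
            "%d record(s) exit after s=%g; follow-up truncated and events "
            "beyond the grid dropped", n_trunc, s_hi,
        )

    j = _u_index(u, grid)
    R = np.zeros((grid.n_u, grid.n_s))
    Y = [np.zeros((grid.n_u, grid.n_s), dtype=float) for _ in range(N_CAUSES)]

    # exposure: overlap of [s_entry, min(s_exit, s_hi)) with every s-bin
    lo = grid.s_edges[:-1][None, :]
    hi = grid.s_edges[1:][None, :]
    s_stop = np.minimum(s_ex, s_hi)
    overlap = np.clip(
        np.minimum(s_stop[:, None], hi) - np.maximum(s_en[:, None], lo), 0.0, None
    )
    np.add.at(R, j, overlap)

    # events: cell containing s_exit; exact s_max goes to the last bin
    for ell in (1, 2):
        sel = (cause == ell) & (s_ex <= s_hi)
        if not sel.any():
            continue
        k = np.floor((s_ex[sel] - grid.s_min) / grid.h_s).astype(int)
        k = np.minimum(k, grid.n_s - 1)  # exit exactly at s_max
        np.add.at(Y[ell - 1], (j[sel], k), 1.0)

    return BinnedCompRisks(grid=grid, R=R, Y=Y)


def read_records(path, time_unit: str = "years") -> list:
    """Read individual records from delimited text.

    Expected columns: ``id``, ``u``, ``s_exit``, ``cause`` and optionally
    ``s_entry`` (default 0).  With ``time_unit='months'`` the s-columns are
    divided by 12.
    """
    df = pd.read_csv(path)
    required = {"id", "u", "s_exit", "cause"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"missing required columns: {sorted(missing)}")
    if "s_entry" not in df.columns:
        df["s_entry"] = 0.0
    scale = 1.0 / 12.0 if time_unit == "months" else 1.0
    if time_unit not in ("years", "months"):
        raise ValueError("time_unit must be 'years' or 'months'")
    return [
        IndividualRecord(
            id=row.id,
            u=float(row.u),
            s_exit=float(row.s_exit) * scale,
            cause=int(row.cause),
            s_entry=float(row.s_entry) * scale,
        )
        for row in df.itertuples(index=False)
    ]


def write_records(records, path) -> None:
    pd.DataFrame(
        {
            "id": [r.id for r in records],
            "u": [r.u for r in records],
            "s_entry": [r.s_entry for r in records],
            "s_exit": [r.s_exit for r in records],
            "cause": [r.cause for r in records],
        }
    ).to_csv(path, index=False)
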