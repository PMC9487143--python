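"""The snake: time -> coordinate mapping for one frame, plus the axial map.

The beam's traversal of a frame is modeled as an ordered 1D vector of
cells, one per pixel, each carrying the end time after which photons no
longer belong to it and the pixel coordinate it renders to.  Within a
line only the central ``fill_fraction`` of the period maps to visible
columns; the flanks (mirror turnaround) belong to no cell and photons
arriving there are discarded.  In bidirectional mode odd lines run
right-to-left and may carry an extra window shift (``bidir_phase_ps``,
the offline line-shift correction).

Volumes stay lazy: the snake itself is always 2D, and the axial (TAG
lens) coordinate is computed per photon from :class:`AxialPhaseMap` at
the photon's arrival time — the focal depth sweeps sinusoidally at the
lens frequency, unsynchronized with the scanners.

All times are integer picoseconds; cell end times are strictly
increasing along the snake, which makes allocation a binary search.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import NamedTuple

import numpy as np

from .config import ExperimentConfig

__all__ = [
    "SnakeCell",
    "Snake",
    "AxialPhaseMap",
    "SnakeError",
    "ResolutionError",
    "build_snake_2d",
    "build_snake_from_line_starts",
    "advance_snake",
    "plane_of",
    "planes_of",
]


class SnakeError(ValueError):
    pass


class ResolutionError(SnakeError):
    """Pixel dwell shrank below the 1 ps timestamp resolution."""


class SnakeCell(NamedTuple):
    end_time_ps: int
    row: int
    col: int


@dataclass(frozen=True)
class Snake:
    """Ordered cells for one frame, stored columnar for fast allocation.

    ``start_times``/``end_times`` bound each cell's half-open active
    interval ``[start, end)``; gaps between lines (turnaround) are not
    covered by any cell.
    """

    end_times: np.ndarray    # int64, strictly increasing
    start_times: np.ndarray  # int64, start_times[i] < end_times[i]
    row_index: np.ndarray    # int32
    col_index: np.ndarray    # int32
    frame_start_ps: int
    first_cell_start_ps: int
    line_period_ps: int
    rows: int
    cols: int

    def __len__(self) -> int:
        return self.end_times.size

    @property
    def cells(self) -> list[SnakeCell]:
        return [
            SnakeCell(int(e), int(r), int(c))
            for e, r, c in zip(self.end_times, self.row_index, self.col_index)
        ]

    @property
    def last_end_ps(self) -> int:
        return int(self.end_times[-1])


def _line_window(line_period_ps: int, fill_fraction: float,
                 columns: int) -> tuple[int, np.ndarray, np.ndarray]:
    """Offsets of the active window and per-column bin edges within a line.

    Returns ``(t0, starts, ends)`` where ``t0`` is the window start
    offset ((1-ff)/2 of the period: the window is centered) and
    ``starts``/``ends`` are per-column offsets from the line start.
    """
    active = fill_fraction * line_period_ps
    tau = active / columns
    if tau < 1.0:
        raise ResolutionError(
            f"pixel dwell {tau:.3f} ps < 1 ps: too many columns "
            f"({columns}) for the active window ({active:.0f} ps)"
        )
    t0 = round((1.0 - fill_fraction) / 2.0 * line_period_ps)
    edges = np.rint(np.arange(columns + 1) * tau).astype(np.int64) + t0
    return t0, edges[:-1], edges[1:]


def build_snake_from_line_starts(cfg: ExperimentConfig,
                                 line_starts: np.ndarray,
                                 line_period_ps: int,
                                 frame_start_ps: int | None = None) -> Snake:
    """Build a snake from explicit line start times (one per row).

    This is the general constructor: :func:`build_snake_2d` uses nominal
    equally spaced lines, while frame-sync-only replay divides each
    measured frame interval into ``rows`` equal lines.
    """
    line_starts = np.asarray(line_starts, dtype=np.int64)
    if line_starts.size != cfg.rows:
        raise SnakeError(f"expected {cfg.rows} line starts, got {line_starts.size}")
    _, col_starts, col_ends = _line_window(
        line_period_ps, cfg.fill_fraction, cfg.columns
    )
    rows, cols = cfg.rows, cfg.columns

    starts = line_starts[:, None] + col_starts[None, :]
    ends = line_starts[:, None] + col_ends[None, :]
    if cfg.bidir_phase_ps and cfg.bidirectional:
        starts[1::2] += cfg.bidir_phase_ps
        ends[1::2] += cfg.bidir_phase_ps

    row_index = np.repeat(np.arange(rows, dtype=np.int32), cols)
    sweep = np.arange(cols, dtype=np.int32)
    col_index = np.tile(sweep, (rows, 1))
    if cfg.bidirectional:
        col_index[1::2] = sweep[::-1]

    end_flat = ends.reshape(-1)
    start_flat = starts.reshape(-1)
    if np.any(np.diff(end_flat) <= 0) or np.any(start_flat >= end_flat):
        raise SnakeError(
            "cell end times are not strictly increasing "
            "(check bidir_phase_ps against the turnaround gap)"
        )
    return Snake(
        end_times=end_flat,
        start_times=start_flat,
        row_index=row_index,
        col_index=col_index.reshape(-1),
        frame_start_ps=int(frame_start_ps if frame_start_ps is not None
                           else line_starts[0]),
        first_cell_start_ps=int(start_flat[0]),
        line_period_ps=int(line_period_ps),
        rows=rows,
        cols=cols,
    )


def build_snake_2d(cfg: ExperimentConfig, frame_start_ps: int) -> Snake:
    """Snake for one frame starting at ``frame_start_ps``.

    Line ``k`` occupies ``[frame_start + k*T_line, frame_start +
    (k+1)*T_line)``; within it, column ``c'`` (sweep order) ends at
    ``line_start + t0 + round((c'+1) * ff*T_line/columns)``.
    """
    if frame_start_ps < 0:
        raise SnakeError("frame_start_ps must be non-negative")
    T = cfg.line_period_ps
    line_starts = frame_start_ps + np.arange(cfg.rows, dtype=np.int64) * T
    return build_snake_2d_lines(cfg, line_starts, frame_start_ps)


def build_snake_2d_lines(cfg: ExperimentConfig, line_starts: np.ndarray,
                         frame_start_ps: int) -> Snake:
    return build_snake_from_line_starts(
        cfg, line_starts, cfg.line_period_ps, frame_start_ps
    )


def advance_snake(snake: Snake, cfg: ExperimentConfig,
                  next_frame_start_ps: int) -> Snake:
    """Rebuild the snake for the next frame; no state leaks between frames.

    End times track the measured frame start (jittered syncs shift the
    whole frame), not an accumulated nominal schedule.
    """
    if next_frame_start_ps <= snake.frame_start_ps:
        raise SnakeError("next frame must start after the current one")
    return build_snake_2d(cfg, next_frame_start_ps)


@dataclass(frozen=True)
class AxialPhaseMap:
    """Sinusoidal focal sweep of the varifocal (TAG) lens.

    The lens phase is anchored to the most recent TAG sync pulse
    (``last_sync_ps``); ``phase0_rad`` is the lens phase at that pulse.
    Depth is normalized, ``z = (1 + sin phi)/2``, and binned uniformly in
    z into ``planes`` slabs, so the arcsine dwell-time law (outer planes
    visited longer) emerges naturally.
    """

    tag_period_ps: int
    last_sync_ps: int
    phase0_rad: float
    planes: int

    def __post_init__(self):
        if self.planes < 2 or self.planes % 2 != 0:
            raise ValueError("planes must be even and >= 2 for an axial map")
        if self.tag_period_ps <= 0:
            raise ValueError("tag_period_ps must be positive")

    def with_sync(self, t_sync_ps: int) -> "AxialPhaseMap":
        return replace(self, last_sync_ps=int(t_sync_ps))


def planes_of(axmap: AxialPhaseMap, t_ps: np.ndarray) -> np.ndarray:
    """Vectorized plane index at times ``t_ps`` (all >= last sync).

    Periodicity in ``tag_period_ps`` is exact for integer-multiple
    offsets because the phase is computed from ``(t - last_sync) mod
    period`` before any float division.
    """
    t = np.asarray(t_ps, dtype=np.int64)
    if np.any(t < axmap.last_sync_ps):
        raise ValueError("plane requested before the anchoring TAG sync")
    frac = np.mod(t - axmap.last_sync_ps, axmap.tag_period_ps) / axmap.tag_period_ps
    phi = 2.0 * np.pi * frac + axmap.phase0_rad
    z = (1.0 + np.sin(phi)) / 2.0
    plane = np.minimum(
        np.floor(z * axmap.planes).astype(np.int64), axmap.planes - 1
    )
    return plane


def plane_of(axmap: AxialPhaseMap, t_ps: int) -> int:
    """Plane index of a single arrival time (see :func:`planes_of`)."""
    return int(planes_of(axmap, np.asarray([t_ps]))[0])
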