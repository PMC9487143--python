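"""Count accumulation: photon records -> frame/volume buffers -> display.

Brightness values are photon counts, exactly: each allocated photon adds
1 to its voxel, per (spectral channel, demux stream) pair, and the pairs
are never blended.  The rolling display view keeps the integer SUM over
the last N frames; the divisor is applied only at export time so counts
stay exact.  The offline depth projection is the maximum over planes of
the per-plane sums across frames.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .config import ExperimentConfig
from .stream_io import PhotonRecord, PhotonRecordArray

__all__ = [
    "FrameBuffer",
    "RollingView",
    "AllocationContractError",
    "increment",
    "push_frame",
    "summed_projection",
    "z_normalized_projection",
    "axial_dwell_weights",
    "accumulate_run",
    "buffers_to_stack",
]

BufferKey = tuple[int, int]  # (spectral_channel, demux_stream); demux -1 = off


class AllocationContractError(RuntimeError):
    """A record landed outside the buffer — the allocator broke its contract."""


@dataclass
class FrameBuffer:
    """Per-channel non-negative count arrays for one frame/volume."""

    rows: int
    cols: int
    planes: int
    frame_index: int
    counts: dict[BufferKey, np.ndarray] = field(default_factory=dict)

    @classmethod
    def for_config(cls, cfg: ExperimentConfig, frame_index: int) -> "FrameBuffer":
        return cls(cfg.rows, cfg.columns, cfg.planes, frame_index)

    def _array_for(self, key: BufferKey) -> np.ndarray:
        if key not in self.counts:
            self.counts[key] = np.zeros(
                (self.rows, self.cols, self.planes), dtype=np.int64
            )
        return self.counts[key]

    def total(self) -> int:
        return int(sum(a.sum() for a in self.counts.values()))

    def copy(self) -> "FrameBuffer":
        out = FrameBuffer(self.rows, self.cols, self.planes, self.frame_index)
        out.counts = {k: v.copy() for k, v in self.counts.items()}
        return out


def increment(buffer: FrameBuffer,
              records: PhotonRecordArray | Iterable[PhotonRecord]
              ) -> FrameBuffer:
    """Add one count per record; duplicates accumulate, order is irrelevant.

    All records must carry the buffer's frame index and lie within its
    bounds; violations are hard errors (the allocator guarantees both).
    """
    if not isinstance(records, PhotonRecordArray):
        records = PhotonRecordArray.from_records(records)
    if len(records) == 0:
        return buffer
    if np.any(records.frame != buffer.frame_index):
        raise AllocationContractError(
            f"records for frames {np.unique(records.frame).tolist()} pushed "
            f"into buffer for frame {buffer.frame_index}"
        )
    out_of_bounds = (
        (records.row < 0) | (records.row >= buffer.rows)
        | (records.col < 0) | (records.col >= buffer.cols)
        | (records.plane < 0) | (records.plane >= buffer.planes)
    )
    if np.any(out_of_bounds):
        bad = int(np.argmax(out_of_bounds))
        raise AllocationContractError(
            f"record out of bounds: (row={records.row[bad]}, "
            f"col={records.col[bad]}, plane={records.plane[bad]}) for a "
            f"{buffer.rows}x{buffer.cols}x{buffer.planes} buffer"
        )
    keys = np.stack(
        [records.spectral_channel, records.demux_stream.astype(np.int32)], axis=1
    )
    for chan, stream in np.unique(keys, axis=0).tolist():
        mask = (records.spectral_channel == chan) & (records.demux_stream == stream)
        arr = buffer._array_for((int(chan), int(stream)))
        np.add.at(
            arr,
            (records.row[mask], records.col[mask], records.plane[mask]),
            1,
        )
    return buffer


@dataclass
class RollingView:
    """Ring of the last N frame buffers plus their maintained sum."""

    window: int
    ring: deque = field(default_factory=deque)
    sum_counts: dict[BufferKey, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        if self.window < 1:
            raise ValueError("window must be positive")

    def push_frame(self, buffer: FrameBuffer) -> dict[BufferKey, np.ndarray]:
        """Advance the ring; return the display buffer (sum over the window).

        During warm-up (fewer than N frames seen) the sum covers what
        exists.  The average, when wanted, is ``display / len(ring)`` at
        render time.
        """
        self.ring.append(buffer)
        for key, arr in buffer.counts.items():
            if key in self.sum_counts:
                self.sum_counts[key] = self.sum_counts[key] + arr
            else:
                self.sum_counts[key] = arr.copy()
        if len(self.ring) > self.window:
            evicted = self.ring.popleft()
            for key, arr in evicted.counts.items():
                self.sum_counts[key] = self.sum_counts[key] - arr
        return {k: v.copy() for k, v in self.sum_counts.items()}

    def verify_sum(self) -> bool:
        """Recompute the sum from the ring and compare (debugging aid)."""
        fresh: dict[BufferKey, np.ndarray] = {}
        for buf in self.ring:
            for key, arr in buf.counts.items():
                fresh[key] = fresh.get(key, 0) + arr
        keys = set(fresh) | {k for k, v in self.sum_counts.items() if np.any(v)}
        return all(np.array_equal(fresh.get(k, 0), self.sum_counts.get(k, 0))
                   for k in keys)


def push_frame(view: RollingView, buffer: FrameBuffer) -> dict[BufferKey, np.ndarray]:
    return view.push_frame(buffer)


def summed_projection(buffers: Sequence[FrameBuffer]
                      ) -> dict[BufferKey, np.ndarray]:
    """Depth projection of a recording: sum frames, then max over planes."""
    if not buffers:
        raise ValueError("at least one frame buffer is required")
    total: dict[BufferKey, np.ndarray] = {}
    for buf in buffers:
        for key, arr in buf.counts.items():
            total[key] = total.get(key, 0) + arr
    return {key: _depth_project(arr) for key, arr in total.items()}


def _depth_project(volume: np.ndarray) -> np.ndarray:
    # single-plane data projects to itself; volumes take the max across z
    if volume.shape[-1] == 1:
        return volume[..., 0].copy()
    return volume.max(axis=-1)


def axial_dwell_weights(planes: int) -> np.ndarray:
    """Fraction of sweep time spent in each uniform-z plane slab.

    The varifocal lens sweeps ``z = (1 + sin phi)/2``, so dwell time per
    slab follows the arcsine law — outer planes are visited longer.
    Used to equalize per-plane brightness before depth projection
    (optional post-export step; projections are raw by default).
    """
    edges = np.linspace(0.0, 1.0, planes + 1)
    cdf = np.arcsin(2.0 * edges - 1.0) / np.pi + 0.5
    return np.diff(cdf)


def z_normalized_projection(buffers: Sequence[FrameBuffer]
                            ) -> dict[BufferKey, np.ndarray]:
    """Depth projection after analytic per-plane brightness equalization."""
    if not buffers:
        raise ValueError("at least one frame buffer is required")
    planes = buffers[0].planes
    w = axial_dwell_weights(planes) if planes > 1 else np.ones(1)
    total: dict[BufferKey, np.ndarray] = {}
    for buf in buffers:
        for key, arr in buf.counts.items():
            total[key] = total.get(key, 0) + arr
    return {key: (arr / w).max(axis=-1) for key, arr in total.items()}


def accumulate_run(records: PhotonRecordArray, cfg: ExperimentConfig,
                   n_frames: int | None = None) -> list[FrameBuffer]:
    """Group records by frame and accumulate one buffer per frame.

    ``n_frames`` pads with empty trailing buffers (frames that received
    no photons); by default the last populated frame closes the run.
    """
    if len(records) == 0:
        count = n_frames or 0
        return [FrameBuffer.for_config(cfg, i) for i in range(count)]
    last = int(records.frame.max())
    count = max(n_frames or 0, last + 1)
    buffers = [FrameBuffer.for_config(cfg, i) for i in range(count)]
    order = np.argsort(records.frame, kind="stable")
    sorted_recs = records.select(order)
    boundaries = np.searchsorted(
        sorted_recs.frame, np.arange(count + 1), side="left"
    )
    for i in range(count):
        lo, hi = boundaries[i], boundaries[i + 1]
        if hi > lo:
            increment(buffers[i], sorted_recs.select(slice(lo, hi)))
    return buffers


def buffers_to_stack(buffers: Sequence[FrameBuffer],
                     key: BufferKey) -> np.ndarray:
    """Stack one channel's buffers as (frames, planes, rows, cols)."""
    if not buffers:
        raise ValueError("no buffers")
    rows, cols, planes = buffers[0].rows, buffers[0].cols, buffers[0].planes
    out = np.zeros((len(buffers), planes, rows, cols), dtype=np.int64)
    for i, buf in enumerate(buffers):
        arr = buf.counts.get(key)
        if arr is not None:
            out[i] = np.moveaxis(arr, -1, 0)
    return out
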