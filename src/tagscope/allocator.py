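"""The event loop: sync tracking and photon-to-voxel allocation.

Each detected photon is assigned to the first snake cell whose
pre-computed end time exceeds the photon's arrival time — "exceeds"
read strictly, so a photon exactly on a cell boundary belongs to the
next cell (exact and testable in integer picoseconds).  The search is a
binary search over the strictly increasing end times, contractually
identical to a left-to-right linear scan.

Sync semantics: every ``rows`` line syncs start a new frame with a
freshly built snake anchored to the measured sync time; frame-sync-only
configurations infer line starts by dividing each measured frame
interval into ``rows`` equal lines (nominal period for the trailing
frame).  Sync gaps larger than 1.5 nominal line periods are bridged by
inferred syncs at nominal spacing, so a dropped tag costs one line, not
a frame.  TAG syncs anchor the axial phase map; laser syncs feed the
demultiplexing phase tracker.

Every spectral tag ends up in exactly one of four classes — allocated,
discarded-early (turnaround/leading margin), after-frame, or pre-sync —
and the classes always sum to the spectral tag count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .config import ExperimentConfig, Role
from .demux import DemuxConfig, demux_stream_indices
from .snake import Snake, build_snake_2d, build_snake_from_line_starts
from .stream_io import PhotonRecordArray, TagStream, TimeTag

__all__ = [
    "DISCARDED_EARLY",
    "AFTER_FRAME",
    "PRE_SYNC",
    "SyncState",
    "RunStats",
    "find_cell",
    "allocate_times",
    "infer_line_starts",
    "process_stream",
]

DISCARDED_EARLY = -1   # before the first cell, or in a turnaround gap
AFTER_FRAME = -2       # at/after the frame's last end time
PRE_SYNC = -3          # before any usable sync reference

_GAP_FACTOR = 1.5      # line-sync gaps beyond this many nominal periods
                       # are bridged with inferred syncs


@dataclass
class SyncState:
    """Mutable sync bookkeeping carried through the stream."""

    lines_seen_in_frame: int = 0
    last_line_sync_ps: int = -1
    last_frame_start_ps: int = -1
    last_tag_sync_ps: int = -1
    last_laser_pulse_ps: int = -1
    nominal_line_period_ps: int = 0


@dataclass
class RunStats:
    """Photon-conservation accounting for one processed stream."""

    total_tags: int = 0
    spectral_tags: int = 0
    allocated: int = 0
    discarded_early: int = 0
    after_frame: int = 0
    pre_sync: int = 0
    line_syncs: int = 0
    inferred_lines: int = 0
    frames_completed: int = 0
    per_channel: dict = field(default_factory=dict)
    unknown_channel_tags: int = 0

    def check_conservation(self) -> None:
        total = self.allocated + self.discarded_early + self.after_frame + self.pre_sync
        if total != self.spectral_tags:
            raise AssertionError(
                f"photon accounting broken: {total} classified vs "
                f"{self.spectral_tags} spectral tags"
            )


def find_cell(snake: Snake, t_ps: int) -> int:
    """Index of the photon's cell, or a sentinel.

    Returns the smallest ``i`` with ``end_time[i] > t_ps`` provided
    ``t_ps`` lies inside cell ``i``'s own active interval;
    ``DISCARDED_EARLY`` for the leading margin and inter-line turnaround
    gaps; ``AFTER_FRAME`` at or beyond the last end time.
    """
    return int(allocate_times(snake, np.asarray([t_ps], dtype=np.int64))[0])


def allocate_times(snake: Snake, t_ps: np.ndarray) -> np.ndarray:
    """Vectorized :func:`find_cell` (binary search over end times)."""
    t = np.asarray(t_ps, dtype=np.int64)
    idx = np.searchsorted(snake.end_times, t, side="right")
    out = np.empty(t.shape, dtype=np.int64)
    after = idx >= len(snake)
    out[after] = AFTER_FRAME
    inside = ~after
    cell = idx[inside]
    ok = t[inside] >= snake.start_times[cell]
    res = np.where(ok, cell, DISCARDED_EARLY)
    out[inside] = res
    return out


def infer_line_starts(frame_sync_times, rows: int,
                      cfg: ExperimentConfig) -> np.ndarray:
    """Equally spaced line starts for frame-sync-only acquisitions.

    Each measured frame interval is divided into ``rows`` lines; the
    last frame (no closing sync) uses the nominal frame period.
    """
    syncs = np.asarray(list(frame_sync_times), dtype=np.int64)
    if syncs.size < 1:
        raise ValueError("at least one frame sync is required")
    starts: list[np.ndarray] = []
    k = np.arange(rows, dtype=np.int64)
    for i in range(syncs.size):
        if i + 1 < syncs.size:
            period = syncs[i + 1] - syncs[i]
        else:
            period = cfg.frame_period_ps
        starts.append(syncs[i] + np.rint(k * (period / rows)).astype(np.int64))
    return np.concatenate(starts)


class _PhotonBuffer:
    """Per-frame buffer of spectral tags awaiting vectorized allocation."""

    def __init__(self):
        self.channels: list[int] = []
        self.times: list[int] = []

    def append(self, channel: int, t: int) -> None:
        self.channels.append(channel)
        self.times.append(t)

    def take(self) -> tuple[np.ndarray, np.ndarray]:
        ch = np.asarray(self.channels, dtype=np.int32)
        t = np.asarray(self.times, dtype=np.int64)
        self.channels, self.times = [], []
        return ch, t

    def __len__(self) -> int:
        return len(self.times)


def process_stream(tags: Iterable[TimeTag] | TagStream,
                   cfg: ExperimentConfig
                   ) -> tuple[PhotonRecordArray, RunStats]:
    """Run the full allocation pipeline over a time-ordered tag stream.

    Returns the allocated :class:`PhotonRecordArray` (time-ordered,
    deterministic for identical input) and the :class:`RunStats`
    accounting, whose conservation identity is asserted before return.
    """
    from .config import validate_config

    violations = validate_config(cfg)
    if violations:
        raise ValueError("invalid config: " + "; ".join(violations))

    role_of = {ch.input_number: ch.role for ch in cfg.channels}
    line_mode = cfg.channel_for(Role.LINE_SYNC) is not None
    volumetric = cfg.planes > 1
    dcfg = DemuxConfig(cfg.laser_period_ps) if cfg.demultiplex else None

    stats = RunStats()
    state = SyncState(nominal_line_period_ps=cfg.line_period_ps)
    tag_syncs: list[int] = []
    laser_refs: list[int] = []
    frame_syncs: list[int] = []
    buffer = _PhotonBuffer()
    parts: list[PhotonRecordArray] = []
    snake: Snake | None = None
    frame_idx = -1
    warned_channels: set[int] = set()

    T_line = cfg.line_period_ps

    def flush(current_snake: Snake | None, current_frame: int) -> None:
        if not len(buffer):
            return
        ch, t = buffer.take()
        part, n_alloc, n_early, n_after, n_presync = _allocate_batch(
            ch, t, current_snake, current_frame, cfg, volumetric, dcfg,
            np.asarray(tag_syncs, dtype=np.int64),
            np.asarray(laser_refs, dtype=np.int64),
        )
        stats.allocated += n_alloc
        stats.discarded_early += n_early
        stats.after_frame += n_after
        stats.pre_sync += n_presync
        if part is not None and len(part):
            parts.append(part)

    def start_frame(t_start: int) -> None:
        nonlocal snake, frame_idx
        flush(snake, frame_idx)
        frame_idx += 1
        snake = build_snake_2d(cfg, t_start)
        state.last_frame_start_ps = t_start
        state.lines_seen_in_frame = 0

    def on_line_sync(t: int, inferred: bool) -> None:
        stats.line_syncs += 1
        if inferred:
            stats.inferred_lines += 1
        if state.lines_seen_in_frame == 0 or state.lines_seen_in_frame >= cfg.rows:
            start_frame(t)
        state.lines_seen_in_frame += 1
        state.last_line_sync_ps = t

    for tag in tags:
        channel, t = tag.channel, tag.time_ps
        stats.total_tags += 1
        stats.per_channel[channel] = stats.per_channel.get(channel, 0) + 1
        role = role_of.get(channel)
        if role is None:
            if channel not in warned_channels:
                warned_channels.add(channel)
                warnings.warn(f"tag on undeclared channel {channel}; passed through")
            stats.unknown_channel_tags += 1
            continue
        if role is Role.LINE_SYNC:
            if state.last_line_sync_ps >= 0:
                gap = t - state.last_line_sync_ps
                if gap > _GAP_FACTOR * T_line:
                    n_missing = int(round(gap / T_line)) - 1
                    for k in range(1, n_missing + 1):
                        on_line_sync(state.last_line_sync_ps + k * T_line, True)
            on_line_sync(t, False)
        elif role is Role.FRAME_SYNC:
            frame_syncs.append(t)
            if not line_mode and len(frame_syncs) >= 2:
                # the new sync closes the previous frame: build its snake
                # from the measured interval and drain the buffer
                f0, f1 = frame_syncs[-2], frame_syncs[-1]
                closed = build_snake_from_line_starts(
                    cfg, _divide_interval(f0, f1 - f0, cfg.rows),
                    max(1, round((f1 - f0) / cfg.rows)), f0,
                )
                flush(closed, len(frame_syncs) - 2)
        elif role is Role.TAG_SYNC:
            tag_syncs.append(t)
            state.last_tag_sync_ps = t
        elif role is Role.LASER_SYNC:
            laser_refs.append(t)
            state.last_laser_pulse_ps = t
        else:  # spectral
            stats.spectral_tags += 1
            if snake is None and line_mode:
                stats.pre_sync += 1
                continue
            if not line_mode and not frame_syncs:
                stats.pre_sync += 1
                continue
            buffer.append(channel, t)

    # end of stream
    if line_mode:
        flush(snake, frame_idx)
        stats.frames_completed = stats.line_syncs // cfg.rows
    else:
        if frame_syncs:
            f0 = frame_syncs[-1]
            nominal = cfg.frame_period_ps
            trailing = build_snake_from_line_starts(
                cfg, _divide_interval(f0, nominal, cfg.rows),
                max(1, round(nominal / cfg.rows)), f0,
            )
            flush(trailing, len(frame_syncs) - 1)
        stats.frames_completed = len(frame_syncs)

    stats.check_conservation()
    records = (PhotonRecordArray.concatenate(parts) if parts
               else PhotonRecordArray.empty())
    return records, stats


def _divide_interval(start: int, span: int, rows: int) -> np.ndarray:
    k = np.arange(rows, dtype=np.int64)
    return start + np.rint(k * (span / rows)).astype(np.int64)


def _allocate_batch(channels: np.ndarray, times: np.ndarray,
                    snake: Snake | None, frame_idx: int,
                    cfg: ExperimentConfig, volumetric: bool,
                    dcfg: DemuxConfig | None,
                    tag_syncs: np.ndarray, laser_refs: np.ndarray):
    """Allocate one frame's buffered spectral tags (vectorized)."""
    n = times.size
    if snake is None:
        return None, 0, 0, 0, n
    idx = allocate_times(snake, times)

    keep = idx >= 0
    n_early = int(np.count_nonzero(idx == DISCARDED_EARLY))
    n_after = int(np.count_nonzero(idx == AFTER_FRAME))
    n_presync = 0

    ch = channels[keep]
    t = times[keep]
    cell = idx[keep]

    plane = np.zeros(t.size, dtype=np.int64)
    if volumetric:
        anchor = np.searchsorted(tag_syncs, t, side="right") - 1
        no_ref = anchor < 0
        if np.any(no_ref):
            n_presync += int(np.count_nonzero(no_ref))
            ok = ~no_ref
            ch, t, cell, anchor = ch[ok], t[ok], cell[ok], anchor[ok]
        if t.size:
            delta = t - tag_syncs[anchor]
            frac = np.mod(delta, cfg.tag_period_ps) / cfg.tag_period_ps
            phi = 2.0 * np.pi * frac + cfg.tag_phase0_rad
            z = (1.0 + np.sin(phi)) / 2.0
            plane = np.minimum(
                np.floor(z * cfg.planes).astype(np.int64), cfg.planes - 1
            )
        else:
            plane = np.zeros(0, dtype=np.int64)

    demux = np.full(t.size, -1, dtype=np.int8)
    if dcfg is not None:
        anchor = np.searchsorted(laser_refs, t, side="right") - 1
        no_ref = anchor < 0
        if np.any(no_ref):
            n_presync += int(np.count_nonzero(no_ref))
            ok = ~no_ref
            ch, t, cell, plane = ch[ok], t[ok], cell[ok], plane[ok]
            anchor = anchor[ok]
        if t.size:
            virtual = laser_refs[anchor] + (
                (t - laser_refs[anchor]) // dcfg.laser_period_ps
            ) * dcfg.laser_period_ps
            demux = demux_stream_indices(t, virtual, dcfg)
        else:
            demux = np.zeros(0, dtype=np.int8)

    part = PhotonRecordArray(
        spectral_channel=ch,
        demux_stream=demux,
        frame=np.full(t.size, frame_idx, dtype=np.int64),
        row=snake.row_index[cell],
        col=snake.col_index[cell],
        plane=plane,
        time_ps=t,
    )
    return part, len(part), n_early, n_after, n_presync
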