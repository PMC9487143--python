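import numpy as np
import pytest

from tagscope.allocator import (
    AFTER_FRAME,
    DISCARDED_EARLY,
    allocate_times,
    find_cell,
    infer_line_starts,
    process_stream,
)
from tagscope.snake import build_snake_2d
from tagscope.stream_io import TagStream, TimeTag
from .conftest import make_cfg


def linear_scan_find(snake, t):
    """Reference implementation: first end time exceeding t, left to right."""
    for i in range(len(snake)):
        if snake.end_times[i] > t:
            return i if t >= snake.start_times[i] else DISCARDED_EARLY
    return AFTER_FRAME


def test_photon_on_cell_boundary_goes_to_next_cell():
    # contiguous integer cells ending at 1,2,3,4: "exceeds" is strict
    cfg = make_cfg(rows=1, cols=4, line_period_ps=4, fill_fraction=1.0,
                   bidirectional=False)
    snake = build_snake_2d(cfg, 0)
    assert find_cell(snake, 0) == 0
    assert find_cell(snake, 1) == 1  # exactly at cell 0's end time
    assert find_cell(snake, 3) == 3
    assert find_cell(snake, 4) == AFTER_FRAME


def test_margins_and_turnaround_are_discarded():
    cfg = make_cfg(rows=2, cols=2, line_period_ps=1_000_000,
                   fill_fraction=0.8, bidirectional=False)
    snake = build_snake_2d(cfg, 0)
    assert find_cell(snake, 0) == DISCARDED_EARLY          # leading margin
    assert find_cell(snake, 99_999) == DISCARDED_EARLY
    assert find_cell(snake, 100_000) == 0                  # window opens
    assert find_cell(snake, 950_000) == DISCARDED_EARLY    # turnaround gap
    assert find_cell(snake, 1_100_000) == 2                # next line opens
    assert find_cell(snake, 1_900_000) == AFTER_FRAME


def test_binary_search_equals_linear_scan_on_random_cases():
    rng = np.random.default_rng(7)
    checked = 0
    for _ in range(20):
        cfg = make_cfg(
            rows=int(rng.integers(1, 6)),
            cols=int(rng.integers(1, 12)),
            line_period_ps=int(rng.integers(10**4, 10**6)),
            fill_fraction=float(rng.uniform(0.3, 1.0)),
            bidirectional=bool(rng.integers(0, 2)),
        )
        snake = build_snake_2d(cfg, int(rng.integers(0, 10**6)))
        span = snake.last_end_ps - snake.frame_start_ps
        ts = rng.integers(
            max(0, snake.frame_start_ps - span // 4),
            snake.last_end_ps + span // 4,
            size=500,
        )
        fast = allocate_times(snake, ts)
        for t, got in zip(ts.tolist(), fast.tolist()):
            assert got == linear_scan_find(snake, t)
        checked += ts.size
    assert checked >= 10_000


def _sync_stream(cfg, n_frames, extra=()):
    T = cfg.line_period_ps
    syncs = [TimeTag(1, k * T) for k in range(n_frames * cfg.rows)]
    tags = sorted(list(extra) + syncs, key=lambda t: (t.time_ps, t.channel != 1))
    return tags


def test_syncs_only_yield_empty_records_and_frame_count(cfg_small):
    records, stats = process_stream(_sync_stream(cfg_small, 3), cfg_small)
    assert len(records) == 0
    assert stats.frames_completed == 3
    assert stats.line_syncs == 3 * cfg_small.rows


def test_single_photon_lands_mid_cell(cfg_small):
    snake = build_snake_2d(cfg_small, 0)
    cell = 2 * cfg_small.columns + 3  # row 2, col 3 (unidirectional)
    t_mid = int(snake.start_times[cell] + snake.end_times[cell]) // 2
    tags = _sync_stream(cfg_small, 2, extra=[TimeTag(2, t_mid)])
    records, stats = process_stream(tags, cfg_small)
    assert stats.allocated == 1
    assert len(records) == 1
    rec = next(iter(records))
    assert (rec.row, rec.col, rec.frame, rec.plane) == (2, 3, 0, 0)


def test_every_spectral_tag_is_classified_exactly_once(cfg_small):
    snake = build_snake_2d(cfg_small, 0)
    T = cfg_small.line_period_ps
    frame_span = cfg_small.rows * T
    photons = [
        TimeTag(2, 10),                                     # leading margin
        TimeTag(2, int(snake.start_times[0]) + 5),          # allocated
        TimeTag(2, int(snake.end_times[cfg_small.columns - 1]) + 1),  # turnaround
        TimeTag(2, frame_span + int(snake.start_times[5]) + 1),       # frame 1
        TimeTag(2, 2 * frame_span + 10**9),                 # after everything
    ]
    records, stats = process_stream(
        _sync_stream(cfg_small, 2, extra=photons), cfg_small
    )
    assert stats.spectral_tags == 5
    assert (stats.allocated + stats.discarded_early
            + stats.after_frame + stats.pre_sync) == 5
    assert stats.allocated == 2
    assert stats.discarded_early == 2
    assert stats.after_frame == 1
    assert len(records) == 2


def test_photon_before_any_sync_is_pre_sync(cfg_small):
    T = cfg_small.line_period_ps
    tags = [TimeTag(2, 5)] + [
        TimeTag(1, 1000 + k * T) for k in range(cfg_small.rows)
    ]
    records, stats = process_stream(tags, cfg_small)
    assert stats.pre_sync == 1
    assert len(records) == 0


def test_dropped_line_sync_is_inferred_not_fatal(cfg_small):
    T = cfg_small.line_period_ps
    syncs = [TimeTag(1, k * T) for k in range(2 * cfg_small.rows)
             if k != 2]  # lose one line sync mid-frame
    records, stats = process_stream(syncs, cfg_small)
    assert stats.inferred_lines == 1
    assert stats.frames_completed == 2


def test_determinism_identical_stream_identical_records(cfg_small):
    rng = np.random.default_rng(11)
    snake = build_snake_2d(cfg_small, 0)
    ts = np.sort(rng.integers(0, snake.last_end_ps, 200))
    photons = [TimeTag(2, int(t)) for t in ts]
    tags = _sync_stream(cfg_small, 1, extra=photons)
    rec1, _ = process_stream(tags, cfg_small)
    rec2, _ = process_stream(tags, cfg_small)
    for f in ("spectral_channel", "frame", "row", "col", "plane", "time_ps"):
        assert np.array_equal(getattr(rec1, f), getattr(rec2, f))


def test_unknown_channel_tag_warns_and_is_counted(cfg_small):
    tags = _sync_stream(cfg_small, 1, extra=[TimeTag(17, 50)])
    with pytest.warns(UserWarning, match="channel 17"):
        _, stats = process_stream(tags, cfg_small)
    assert stats.unknown_channel_tags == 1


# ---------------------------------------------------------------------------
# frame-sync-only wiring
# ---------------------------------------------------------------------------

def test_infer_line_starts_divides_measured_interval():
    cfg = make_cfg(rows=4, frame_sync_only=True)
    starts = infer_line_starts([0, 1_000_000], 4, cfg)
    assert starts[:4].tolist() == [0, 250_000, 500_000, 750_000]


def test_single_frame_sync_uses_nominal_period():
    cfg = make_cfg(rows=4, line_period_ps=1_000_000, frame_sync_only=True)
    starts = infer_line_starts([10], 4, cfg)
    assert starts.tolist() == [10 + k * 1_000_000 for k in range(4)]


def test_jittered_frame_syncs_track_measured_interval():
    cfg = make_cfg(rows=5, frame_sync_only=True)
    syncs = [0, 1_003_000, 1_998_000]
    starts = infer_line_starts(syncs, 5, cfg)
    # arithmetic oracle: straight division of each measured interval
    expect = []
    periods = [1_003_000, 995_000, cfg.frame_period_ps]
    for s, p in zip(syncs, periods):
        expect += [s + round(k * p / 5) for k in range(5)]
    assert starts.tolist() == expect


def test_frame_sync_only_stream_allocates_photons():
    cfg = make_cfg(rows=4, cols=8, line_period_ps=1_000_000,
                   frame_sync_only=True)
    F = cfg.frame_period_ps
    snake = build_snake_2d(cfg, 0)
    cell = 1 * cfg.columns + 2
    t_mid = int(snake.start_times[cell] + snake.end_times[cell]) // 2
    tags = sorted(
        [TimeTag(1, 0), TimeTag(1, F), TimeTag(2, t_mid), TimeTag(2, F + t_mid)],
        key=lambda t: (t.time_ps, t.channel != 1),
    )
    records, stats = process_stream(tags, cfg)
    assert stats.frames_completed == 2
    assert stats.allocated == 2
    rows = list(records)
    assert {(r.frame, r.row, r.col) for r in rows} == {(0, 1, 2), (1, 1, 2)}
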