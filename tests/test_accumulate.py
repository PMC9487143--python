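import numpy as np
import pytest

from tagscope.accumulate import (
    AllocationContractError,
    FrameBuffer,
    RollingView,
    accumulate_run,
    axial_dwell_weights,
    increment,
    summed_projection,
)
from tagscope.stream_io import PhotonRecord, PhotonRecordArray
from .conftest import make_cfg


def _buf(rows=8, cols=8, planes=1, frame=0):
    return FrameBuffer(rows, cols, planes, frame)


def _rec(row, col, plane=0, frame=0, chan=2, demux=-1, t=0):
    return PhotonRecord(chan, demux, frame, row, col, plane, t)


def test_duplicate_voxel_counts_accumulate():
    buf = increment(_buf(), [_rec(3, 4), _rec(3, 4), _rec(3, 4)])
    assert buf.counts[(2, -1)][3, 4, 0] == 3
    assert buf.total() == 3


def test_batch_order_is_irrelevant():
    rng = np.random.default_rng(1)
    recs = [_rec(int(r), int(c)) for r, c in rng.integers(0, 8, (300, 2))]
    a = increment(_buf(), recs)
    b = increment(_buf(), recs[::-1])
    assert np.array_equal(a.counts[(2, -1)], b.counts[(2, -1)])


def test_large_batch_conserves_count_and_splits_merge():
    rng = np.random.default_rng(2)
    n = 100_000
    recs = PhotonRecordArray(
        spectral_channel=np.full(n, 2),
        demux_stream=np.full(n, -1),
        frame=np.zeros(n),
        row=rng.integers(0, 8, n),
        col=rng.integers(0, 8, n),
        plane=np.zeros(n),
        time_ps=np.arange(n),
    )
    whole = increment(_buf(), recs)
    assert whole.total() == n
    # monoid action: splitting the batch changes nothing
    split = _buf()
    increment(split, recs.select(slice(0, n // 3)))
    increment(split, recs.select(slice(n // 3, n)))
    assert np.array_equal(whole.counts[(2, -1)], split.counts[(2, -1)])


def test_channels_and_demux_streams_stay_separate():
    buf = increment(_buf(), [
        _rec(0, 0, chan=2, demux=0), _rec(0, 0, chan=2, demux=1),
        _rec(0, 0, chan=3, demux=0),
    ])
    assert set(buf.counts) == {(2, 0), (2, 1), (3, 0)}
    assert all(arr.sum() == 1 for arr in buf.counts.values())


def test_out_of_bounds_record_is_a_contract_breach():
    with pytest.raises(AllocationContractError, match="out of bounds"):
        increment(_buf(rows=4, cols=4), [_rec(4, 0)])


def test_wrong_frame_record_is_a_contract_breach():
    with pytest.raises(AllocationContractError, match="frame"):
        increment(_buf(frame=1), [_rec(0, 0, frame=0)])


# ---------------------------------------------------------------------------
# rolling display window
# ---------------------------------------------------------------------------

def _const_frame(value, frame, rows=4, cols=4):
    buf = _buf(rows, cols, frame=frame)
    arr = buf._array_for((2, -1))
    arr += value
    return buf


def test_window_of_one_shows_the_frame_itself():
    view = RollingView(window=1)
    disp = view.push_frame(_const_frame(5, 0))
    assert np.all(disp[(2, -1)] == 5)
    disp = view.push_frame(_const_frame(9, 1))
    assert np.all(disp[(2, -1)] == 9)


def test_window_sums_and_evicts_oldest():
    N = 4
    view = RollingView(window=N)
    for i in range(N + 1):  # one extra push evicts the first frame
        disp = view.push_frame(_const_frame(3, i))
    assert np.all(disp[(2, -1)] == 3 * N)
    assert view.verify_sum()


def test_warm_up_sums_what_exists():
    view = RollingView(window=10)
    view.push_frame(_const_frame(2, 0))
    disp = view.push_frame(_const_frame(2, 1))
    assert np.all(disp[(2, -1)] == 4)
    assert view.verify_sum()


# ---------------------------------------------------------------------------
# projections
# ---------------------------------------------------------------------------

def test_zero_volume_projects_to_zero():
    proj = summed_projection([_buf(planes=4)])
    assert proj == {}  # no photons ever arrived -> no channel buffers
    buf = _buf(planes=4)
    buf._array_for((2, -1))
    proj = summed_projection([buf])
    assert not proj[(2, -1)].any()


def test_single_photon_projects_to_single_pixel():
    buf = increment(_buf(planes=4), [_rec(2, 5, plane=3)])
    proj = summed_projection([buf])[(2, -1)]
    assert proj[2, 5] == 1
    assert proj.sum() == 1


def test_projection_is_max_over_planes_of_summed_frames():
    b0 = increment(_buf(planes=2, frame=0), [_rec(1, 1, plane=0)])
    b1 = increment(_buf(planes=2, frame=1),
                   [_rec(1, 1, plane=0, frame=1), _rec(1, 1, plane=1, frame=1)])
    proj = summed_projection([b0, b1])[(2, -1)]
    assert proj[1, 1] == 2  # plane 0 summed over frames wins the max


def test_axial_dwell_weights_follow_arcsine_shape():
    w = axial_dwell_weights(8)
    assert w.sum() == pytest.approx(1.0)
    assert np.allclose(w, w[::-1])          # symmetric sweep
    assert w[0] > w[3]                      # outer slabs dwell longest


# ---------------------------------------------------------------------------
# offline re-accumulation
# ---------------------------------------------------------------------------

def test_reaccumulating_serialized_records_reproduces_buffers(tmp_path):
    from tagscope.allocator import process_stream
    from tagscope.simulate import SimParams, make_phantom, simulate_acquisition
    from tagscope.stream_io import read_photon_records, write_photon_records

    cfg = make_cfg(rows=8, cols=8, line_period_ps=1_000_000)
    gt = make_phantom("blobs", (8, 8))
    stream, _ = simulate_acquisition(
        gt, SimParams(cfg, n_frames=3, seed=21, brightness=0.8))
    records, stats = process_stream(stream, cfg)
    online = accumulate_run(records, cfg, n_frames=stats.frames_completed)
    assert sum(b.total() for b in online) == stats.allocated

    path = tmp_path / "photons.arrow"
    write_photon_records(records, path)
    offline = accumulate_run(read_photon_records(path), cfg,
                             n_frames=stats.frames_completed)
    assert len(online) == len(offline)
    for a, b in zip(online, offline):
        assert set(a.counts) == set(b.counts)
        for key in a.counts:
            assert np.array_equal(a.counts[key], b.counts[key])
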