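"""Virtual microscope: synthetic time-tag streams with known ground truth.

The simulator emits exactly the event structure the reconstruction
assumes: line (or frame) syncs at the scanner rate, TAG-lens syncs at
the lens frequency with a random initial offset (the lens free-runs,
unsynchronized with the scanners), sparse laser reference pulses, and
photon tags drawn per laser pulse as a Bernoulli trial with probability
``brightness * p_pulse_max * I(x, z)`` — the excitation probability per
pulse is kept low (P_pulse < 0.1 by default) as in real photon-counting
acquisitions.  Scan position is uniform in time across each line's
active window, and excitation is blanked during turnaround, so with
zero jitter and zero emission lifetime the reconstruction inverts the
simulation photon-for-photon.

The :class:`EmissionLedger` records every photon's true voxel and beam;
:func:`round_trip_report` scores a reconstruction against it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .allocator import allocate_times
from .config import ExperimentConfig, Role, validate_config
from .snake import build_snake_2d
from .stream_io import PhotonRecordArray, TagStream

__all__ = [
    "GroundTruth",
    "SimParams",
    "EmissionLedger",
    "make_phantom",
    "simulate_acquisition",
    "round_trip_report",
    "trajectory_plane_coverage",
]

# merge priority: syncs strictly before photons at equal timestamps, so a
# frame boundary takes effect before a photon carrying the same time
_PRIORITY = {
    Role.LINE_SYNC: 0,
    Role.FRAME_SYNC: 1,
    Role.TAG_SYNC: 2,
    Role.LASER_SYNC: 3,
    Role.SPECTRAL: 4,
}


@dataclass(frozen=True)
class GroundTruth:
    """Non-negative intensity field, normalized so the maximum is 1."""

    intensity: np.ndarray  # (rows, cols) or (rows, cols, planes)

    def __post_init__(self):
        arr = np.asarray(self.intensity, dtype=np.float64)
        if not np.all(np.isfinite(arr)) or np.any(arr < 0):
            raise ValueError("intensity must be finite and non-negative")
        peak = arr.max(initial=0.0)
        if peak > 0:
            arr = arr / peak
        object.__setattr__(self, "intensity", arr)

    @property
    def is_volume(self) -> bool:
        return self.intensity.ndim == 3

    def sample(self, row, col, plane) -> np.ndarray:
        if self.is_volume:
            return self.intensity[row, col, plane]
        return self.intensity[row, col]


def make_phantom(kind: str, dims, *, spacing: int = 8,
                 n_blobs: int = 9, n_vessels: int = 3) -> GroundTruth:
    """Deterministic test objects.

    ``grid``: bright rows/columns every ``spacing`` pixels.
    ``blobs``: Gaussian spots (soma-like) on a jittered lattice.
    ``vessels3d``: connected bright tubes threading every plane.
    ``uniform``: constant field (a dye-bath analogue).
    """
    dims = tuple(int(d) for d in dims)
    if any(d <= 0 for d in dims):
        raise ValueError("phantom dims must be positive")
    if kind == "uniform":
        return GroundTruth(np.ones(dims))
    if kind == "grid":
        img = np.zeros(dims[:2])
        img[::spacing, :] = 1.0
        img[:, ::spacing] = 1.0
        if len(dims) == 3:
            img = np.repeat(img[:, :, None], dims[2], axis=2)
        return GroundTruth(img)
    if kind == "blobs":
        rows, cols = dims[:2]
        rr, cc = np.mgrid[0:rows, 0:cols]
        img = np.zeros((rows, cols))
        side = max(1, int(round(np.sqrt(n_blobs))))
        sigma = min(rows, cols) / (4.0 * side)
        for i in range(n_blobs):
            gr, gc = divmod(i, side)
            # fixed pseudo-jitter keeps the phantom deterministic
            jr = ((i * 2654435761) % 101 - 50) / 50.0
            jc = ((i * 40503) % 101 - 50) / 50.0
            r0 = rows * (gr + 0.5 + 0.25 * jr) / side
            c0 = cols * (gc + 0.5 + 0.25 * jc) / side
            img += np.exp(-(((rr - r0) ** 2 + (cc - c0) ** 2)
                            / (2.0 * sigma ** 2)))
        if len(dims) == 3:
            img = np.repeat(img[:, :, None], dims[2], axis=2)
        return GroundTruth(img)
    if kind == "vessels3d":
        if len(dims) != 3:
            raise ValueError("vessels3d requires (rows, cols, planes)")
        return GroundTruth(_vessel_volume(dims, n_vessels))
    raise ValueError(f"unknown phantom kind {kind!r}")


def _vessel_volume(dims, n_vessels: int) -> np.ndarray:
    rows, cols, planes = dims
    vol = np.zeros(dims)
    s = np.linspace(0.0, 1.0, 4096)
    for v in range(n_vessels):
        phase = 2.0 * np.pi * v / max(n_vessels, 1)
        r = rows * (0.15 + 0.7 * s + 0.06 * np.sin(2 * np.pi * (v + 1) * s + phase))
        c = cols * (0.5 + 0.35 * np.sin(2 * np.pi * (v + 2) * s + phase))
        p = planes * s  # every vessel threads the full depth
        ri = np.clip(np.rint(r).astype(int), 0, rows - 1)
        ci = np.clip(np.rint(c).astype(int), 0, cols - 1)
        pi = np.clip(np.floor(p).astype(int), 0, planes - 1)
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                vol[np.clip(ri + dr, 0, rows - 1),
                    np.clip(ci + dc, 0, cols - 1), pi] = 1.0
    return vol


@dataclass
class SimParams:
    """Acquisition-simulation settings; defaults mirror a real session.

    ``p_pulse_max`` is the excitation-probability ceiling per laser
    pulse (kept at 0.1); effective probability per pulse is
    ``brightness * p_pulse_max * I`` with I the normalized ground-truth
    intensity at the beam position.
    """

    cfg: ExperimentConfig
    n_frames: int = 10
    seed: int = 0
    p_pulse_max: float = 0.1
    brightness: float = 1.0
    two_beam: bool = False
    beam_delay_ps: int | None = None   # default: laser_period / 2
    beam_delay_error_ps: int = 0
    sync_jitter_ps: int = 0
    lifetime_ps: int = 0               # optional exponential emission delay
    laser_ref_every: int = 1000        # store every Nth reference pulse
    second_gt: GroundTruth | None = None

    def __post_init__(self):
        if not (0.0 < self.p_pulse_max < 1.0):
            raise ValueError("p_pulse_max must lie in (0, 1)")
        if self.brightness < 0:
            raise ValueError("brightness must be non-negative")
        if self.brightness * self.p_pulse_max > 1.0:
            raise ValueError(
                "brightness * p_pulse_max exceeds 1: not a probability"
            )
        if self.n_frames < 1:
            raise ValueError("n_frames must be positive")


@dataclass
class EmissionLedger:
    """Ground truth per emitted photon, the reconstruction oracle."""

    time_ps: np.ndarray
    channel: np.ndarray
    frame: np.ndarray
    row: np.ndarray
    col: np.ndarray
    plane: np.ndarray
    beam: np.ndarray
    tag_phase_origin_ps: int = 0

    def __len__(self) -> int:
        return self.time_ps.size

    def sorted_by_time(self) -> "EmissionLedger":
        order = np.argsort(self.time_ps, kind="stable")
        return EmissionLedger(
            self.time_ps[order], self.channel[order], self.frame[order],
            self.row[order], self.col[order], self.plane[order],
            self.beam[order], self.tag_phase_origin_ps,
        )

    def to_csv(self, path) -> None:
        import csv

        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["time_ps", "channel", "frame", "row", "col",
                             "plane", "beam"])
            for i in range(len(self)):
                writer.writerow([
                    int(self.time_ps[i]), int(self.channel[i]),
                    int(self.frame[i]), int(self.row[i]), int(self.col[i]),
                    int(self.plane[i]), int(self.beam[i]),
                ])

    @classmethod
    def from_csv(cls, path) -> "EmissionLedger":
        import csv

        with open(path, newline="") as fh:
            reader = csv.reader(fh)
            next(reader)
            rows = [[int(v) for v in row] for row in reader if row]
        if not rows:
            z = np.empty(0, np.int64)
            return cls(z, z.copy(), z.copy(), z.copy(), z.copy(), z.copy(),
                       z.copy())
        cols = [np.asarray(c, dtype=np.int64) for c in zip(*rows)]
        return cls(*cols)


def simulate_acquisition(gt: GroundTruth, p: SimParams
                         ) -> tuple[TagStream, EmissionLedger]:
    """Generate a full time-merged tag stream plus its emission ledger."""
    cfg = p.cfg
    violations = validate_config(cfg)
    if violations:
        raise ValueError("invalid config: " + "; ".join(violations))
    if gt.is_volume != (cfg.planes > 1):
        raise ValueError("ground-truth dimensionality does not match planes")
    if gt.is_volume and gt.intensity.shape != (cfg.rows, cfg.columns, cfg.planes):
        raise ValueError("volume phantom must match rows x columns x planes")
    if not gt.is_volume and gt.intensity.shape != (cfg.rows, cfg.columns):
        raise ValueError("2D phantom must match rows x columns")

    rng = np.random.default_rng(p.seed)
    T_line = cfg.line_period_ps
    frame_period = cfg.rows * T_line
    duration = p.n_frames * frame_period
    T_laser = cfg.laser_period_ps
    volumetric = cfg.planes > 1
    P_tag = cfg.tag_period_ps

    chan_times: list[np.ndarray] = []
    chan_ids: list[np.ndarray] = []
    chan_prio: list[np.ndarray] = []

    def emit(role: Role, input_number: int, times: np.ndarray) -> None:
        chan_times.append(times.astype(np.int64))
        chan_ids.append(np.full(times.size, input_number, dtype=np.int32))
        chan_prio.append(np.full(times.size, _PRIORITY[role], dtype=np.int8))

    line_ch = cfg.channel_for(Role.LINE_SYNC)
    frame_ch = cfg.channel_for(Role.FRAME_SYNC)
    tag_ch = cfg.channel_for(Role.TAG_SYNC)
    laser_ch = cfg.channel_for(Role.LASER_SYNC)

    if line_ch is not None:
        t = np.arange(p.n_frames * cfg.rows, dtype=np.int64) * T_line
        if p.sync_jitter_ps:
            t = t + np.rint(
                rng.normal(0.0, p.sync_jitter_ps, t.size)
            ).astype(np.int64)
            t[0] = max(t[0], 0)
            t = np.maximum.accumulate(t)
        emit(Role.LINE_SYNC, line_ch.input_number, t)
    if frame_ch is not None:
        t = np.arange(p.n_frames, dtype=np.int64) * frame_period
        emit(Role.FRAME_SYNC, frame_ch.input_number, t)

    tag_origin = 0
    if volumetric:
        if tag_ch is None:
            raise ValueError("volumetric simulation needs a tag_sync channel")
        tag_origin = int(rng.integers(0, P_tag))  # free-running lens phase
        t = np.arange(tag_origin, duration, P_tag, dtype=np.int64)
        emit(Role.TAG_SYNC, tag_ch.input_number, t)

    # beam pulse trains
    beam_delay = (T_laser // 2 if p.beam_delay_ps is None else p.beam_delay_ps)
    offsets = [0]
    if p.two_beam:
        offsets.append(beam_delay + p.beam_delay_error_ps)
    pulse0 = np.arange(0, duration, T_laser, dtype=np.int64)
    if laser_ch is not None:
        emit(Role.LASER_SYNC, laser_ch.input_number,
             pulse0[:: max(1, p.laser_ref_every)])

    base_snake = build_snake_2d(cfg, 0)
    spectral = cfg.spectral_channels()

    led_cols = {name: [] for name in
                ("time_ps", "channel", "frame", "row", "col", "plane", "beam")}

    for beam_index, offset in enumerate(offsets):
        beam_gt = gt if (beam_index == 0 or p.second_gt is None) else p.second_gt
        pulses = pulse0 + offset
        pulses = pulses[(pulses >= 0) & (pulses < duration)]
        if volumetric:
            pulses = pulses[pulses >= tag_origin]  # no phase reference yet
        rel = np.mod(pulses, frame_period)
        idx = allocate_times(base_snake, rel)
        active = idx >= 0
        t_act = pulses[active]
        cell = idx[active]
        row = base_snake.row_index[cell].astype(np.int64)
        col = base_snake.col_index[cell].astype(np.int64)
        if volumetric:
            frac = np.mod(t_act - tag_origin, P_tag) / P_tag
            phi = 2.0 * np.pi * frac + cfg.tag_phase0_rad
            z = (1.0 + np.sin(phi)) / 2.0
            plane = np.minimum(
                np.floor(z * cfg.planes).astype(np.int64), cfg.planes - 1
            )
        else:
            plane = np.zeros(t_act.size, dtype=np.int64)
        prob = p.brightness * p.p_pulse_max * beam_gt.sample(row, col, plane)
        for spec in spectral:
            hit = rng.random(t_act.size) < prob
            t_ph = t_act[hit]
            if p.lifetime_ps:
                t_ph = t_ph + np.rint(
                    rng.exponential(p.lifetime_ps, t_ph.size)
                ).astype(np.int64)
            emit(Role.SPECTRAL, spec.input_number, t_ph)
            led_cols["time_ps"].append(t_ph)
            led_cols["channel"].append(
                np.full(t_ph.size, spec.input_number, dtype=np.int64))
            led_cols["frame"].append(t_act[hit] // frame_period)
            led_cols["row"].append(row[hit])
            led_cols["col"].append(col[hit])
            led_cols["plane"].append(plane[hit])
            led_cols["beam"].append(
                np.full(t_ph.size, beam_index, dtype=np.int64))

    times = np.concatenate(chan_times)
    ids = np.concatenate(chan_ids)
    prio = np.concatenate(chan_prio)
    order = np.lexsort((prio, times))
    stream = TagStream(ids[order], times[order])

    def _cat(name):
        cols = led_cols[name]
        return (np.concatenate(cols).astype(np.int64) if cols
                else np.empty(0, np.int64))

    ledger = EmissionLedger(
        _cat("time_ps"), _cat("channel"), _cat("frame"), _cat("row"),
        _cat("col"), _cat("plane"), _cat("beam"), tag_origin,
    ).sorted_by_time()
    return stream, ledger


def round_trip_report(gt: GroundTruth, records: PhotonRecordArray,
                      ledger: EmissionLedger, stats=None) -> dict:
    """Score a reconstruction against the emission ledger.

    Returns: ``photon_conservation`` (1.0 iff every spectral tag was
    classified and the spectral tag count equals the emitted count),
    ``per_voxel_exactness`` (fraction of emitted photons reconstructed
    at their true voxel), ``crosstalk`` (fraction of matched photons in
    the wrong demux stream; NaN when demultiplexing was off), and
    ``ncc`` (normalized cross-correlation of the summed reconstruction
    with the ground truth).
    """
    conserved = True
    if stats is not None:
        classified = (stats.allocated + stats.discarded_early
                      + stats.after_frame + stats.pre_sync)
        conserved = (classified == stats.spectral_tags
                     and stats.spectral_tags == len(ledger))

    led = ledger.sorted_by_time()
    rec = records.sorted_by_time()
    n_exact = 0
    n_matched = 0
    n_crosstalk = 0
    demux_active = len(rec) > 0 and bool(np.any(rec.demux_stream >= 0))
    for chan in np.unique(led.channel).tolist():
        lm = led.channel == chan
        rm = rec.spectral_channel == chan
        lt = led.time_ps[lm]
        rt = rec.time_ps[rm]
        # two-pointer merge on arrival time (duplicates paired in order)
        li = ri = 0
        lidx = np.flatnonzero(lm)
        ridx = np.flatnonzero(rm)
        while li < lt.size and ri < rt.size:
            if lt[li] == rt[ri]:
                i, j = lidx[li], ridx[ri]
                n_matched += 1
                if (led.row[i] == rec.row[j] and led.col[i] == rec.col[j]
                        and led.plane[i] == rec.plane[j]):
                    n_exact += 1
                if demux_active and rec.demux_stream[j] >= 0 \
                        and rec.demux_stream[j] != led.beam[i]:
                    n_crosstalk += 1
                li += 1
                ri += 1
            elif lt[li] < rt[ri]:
                li += 1
            else:
                ri += 1

    n_emitted = len(led)
    exactness = n_exact / n_emitted if n_emitted else 1.0
    crosstalk = (n_crosstalk / n_matched
                 if (demux_active and n_matched) else float("nan"))

    ncc = float("nan")
    if len(rec) and n_emitted:
        shape = gt.intensity.shape
        recon = np.zeros(shape)
        if gt.is_volume:
            np.add.at(recon, (rec.row, rec.col, rec.plane), 1)
        else:
            np.add.at(recon, (rec.row, rec.col), 1)
        a = recon.ravel().astype(float)
        b = gt.intensity.ravel()
        if a.std() > 0 and b.std() > 0:
            ncc = float(np.corrcoef(a, b)[0, 1])

    return {
        "photon_conservation": 1.0 if conserved else 0.0,
        "per_voxel_exactness": exactness,
        "crosstalk": crosstalk,
        "ncc": ncc,
        "n_emitted": n_emitted,
        "n_matched": n_matched,
    }


def trajectory_plane_coverage(cfg: ExperimentConfig, n_volumes: int,
                              seed: int = 0) -> dict:
    """Which voxels does the scan trajectory visit, volume by volume?

    The trajectory is sampled at the excitation (laser pulse) clock — a
    voxel counts as visited in a volume iff some pulse falls in its
    pixel's active window while the lens phase sits in its plane slab.
    Because the lens free-runs against the scanners, a single volume
    leaves voxels unvisited while consecutive volumes sample different
    planes; the union fills in.

    Returns per-volume unvisited fractions and the cumulative visited
    mask.
    """
    if cfg.planes < 2:
        raise ValueError("coverage analysis needs a volumetric config")
    rng = np.random.default_rng(seed)
    T_line = cfg.line_period_ps
    frame_period = cfg.rows * T_line
    P_tag = cfg.tag_period_ps
    tag_origin = int(rng.integers(0, P_tag))
    base_snake = build_snake_2d(cfg, 0)

    unvisited_fractions = []
    cumulative = np.zeros((cfg.rows, cfg.columns, cfg.planes), dtype=bool)
    n_vox = cumulative.size
    for v in range(n_volumes):
        start, stop = v * frame_period, (v + 1) * frame_period
        pulses = np.arange(start, stop, cfg.laser_period_ps, dtype=np.int64)
        pulses = pulses[pulses >= tag_origin]
        rel = np.mod(pulses, frame_period)
        idx = allocate_times(base_snake, rel)
        active = idx >= 0
        t_act = pulses[active]
        cell = idx[active]
        frac = np.mod(t_act - tag_origin, P_tag) / P_tag
        phi = 2.0 * np.pi * frac + cfg.tag_phase0_rad
        z = (1.0 + np.sin(phi)) / 2.0
        plane = np.minimum(
            np.floor(z * cfg.planes).astype(np.int64), cfg.planes - 1
        )
        visited = np.zeros_like(cumulative)
        visited[base_snake.row_index[cell], base_snake.col_index[cell],
                plane] = True
        unvisited_fractions.append(1.0 - visited.sum() / n_vox)
        cumulative |= visited
    return {
        "per_volume_unvisited_fraction": np.asarray(unvisited_fractions),
        "cumulative_visited": cumulative,
        "cumulative_unvisited_fraction": 1.0 - cumulative.sum() / n_vox,
        "planes_all_visited": bool(
            np.all(cumulative.any(axis=(0, 1)))
        ),
        "all_voxels_visited": bool(cumulative.all()),
    }
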