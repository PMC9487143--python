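"""Temporal demultiplexing of interleaved excitation beams.

Two pulse trains, offset by half the laser inter-pulse period (6.25 ns
for an 80 MHz source), excite the sample alternately.  A photon is
sorted into a per-beam stream by its arrival time relative to the most
recent reference pulse: the first half-period gates stream 0, the second
gates stream 1.  Gate boundaries are half-open, ``[0, shift)`` /
``[shift, T)`` — a photon exactly on the boundary joins the later
stream, matching the allocator's strict-"exceeds" convention.

The conditional filter of the digitizer is modeled by
:func:`pair_with_last_pulse`: only the last pulse preceding each photon
is recorded, so the recorded event rate tracks the (low) photon rate
rather than the pulse repetition rate.  :class:`PhaseTracker`
extrapolates virtual pulses at the nominal period when only every Nth
reference pulse is stored in a replayed stream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "DemuxConfig",
    "demux_stream_index",
    "demux_stream_indices",
    "pair_with_last_pulse",
    "phase_track",
    "PhaseTracker",
]


@dataclass(frozen=True)
class DemuxConfig:
    laser_period_ps: int
    n_streams: int = 2
    shift_ps: int | None = None

    def __post_init__(self):
        if self.laser_period_ps <= 0:
            raise ValueError("laser_period_ps must be positive")
        if self.n_streams != 2:
            raise ValueError("only two interleaved streams are supported")
        if self.shift_ps is None:
            object.__setattr__(self, "shift_ps", self.laser_period_ps // self.n_streams)

    @property
    def gate_shift_ps(self) -> int:
        return int(self.shift_ps)  # type: ignore[arg-type]


def demux_stream_index(t_photon_ps: int, t_ref_pulse_ps: int,
                       dcfg: DemuxConfig) -> int:
    """Stream (0 or 1) of a photon given its most recent reference pulse."""
    if t_photon_ps < t_ref_pulse_ps:
        raise ValueError("photon precedes its reference pulse")
    delta = (t_photon_ps - t_ref_pulse_ps) % dcfg.laser_period_ps
    return 0 if delta < dcfg.gate_shift_ps else 1


def demux_stream_indices(t_photons: np.ndarray, t_refs: np.ndarray,
                         dcfg: DemuxConfig) -> np.ndarray:
    """Vectorized :func:`demux_stream_index`."""
    delta = np.mod(
        np.asarray(t_photons, np.int64) - np.asarray(t_refs, np.int64),
        dcfg.laser_period_ps,
    )
    return (delta >= dcfg.gate_shift_ps).astype(np.int8)


def pair_with_last_pulse(photons, pulses) -> tuple[list[tuple[int, int]], int]:
    """Pair each photon with the latest pulse not after it (single merged pass).

    Returns ``(pairs, n_dropped)`` where ``pairs`` is a list of
    ``(photon_time, pulse_time)`` and ``n_dropped`` counts photons that
    preceded every pulse.  Both inputs must be time-ordered.
    """
    pairs: list[tuple[int, int]] = []
    dropped = 0
    it = iter(pulses)
    last_pulse: int | None = None
    next_pulse = next(it, None)
    for ph in photons:
        while next_pulse is not None and next_pulse <= ph:
            last_pulse = next_pulse
            next_pulse = next(it, None)
        if last_pulse is None:
            dropped += 1
        else:
            pairs.append((ph, last_pulse))
    return pairs, dropped


class PhaseTracker:
    """Most-recent-(possibly virtual)-pulse lookup from sparse references.

    Between stored reference pulses, virtual pulses are extrapolated at
    the nominal period from the latest reference — exact when the true
    train is perfectly periodic.  Supports streaming updates
    (:meth:`update` with monotone reference times, :meth:`last_pulse`
    with monotone or arbitrary ``t`` at/after the first reference).
    """

    def __init__(self, period_nominal_ps: int):
        if period_nominal_ps <= 0:
            raise ValueError("nominal period must be positive")
        self.period = int(period_nominal_ps)
        self.last_ref: int | None = None

    def update(self, t_ref_ps: int) -> None:
        self.last_ref = int(t_ref_ps)

    def last_pulse(self, t_ps: int) -> int | None:
        if self.last_ref is None or t_ps < self.last_ref:
            return None
        return self.last_ref + ((t_ps - self.last_ref) // self.period) * self.period


def phase_track(pulse_times, period_nominal_ps: int):
    """Return ``f(t) -> most recent (possibly virtual) pulse time``.

    ``pulse_times`` are the stored (sparse) references, time-ordered.
    Queries before the first reference raise ``ValueError``.
    """
    refs = np.asarray(list(pulse_times), dtype=np.int64)
    if refs.size == 0:
        raise ValueError("at least one reference pulse is required")
    period = int(period_nominal_ps)

    def most_recent(t_ps: int) -> int:
        i = int(np.searchsorted(refs, t_ps, side="right")) - 1
        if i < 0:
            raise ValueError("query precedes the first reference pulse")
        ref = int(refs[i])
        return ref + ((t_ps - ref) // period) * period

    return most_recent
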