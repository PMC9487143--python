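"""Time-tag stream and result-artifact I/O.

Two stream dialects are supported:

* an open binary dialect — a 16-byte header (``b"TTAGSTR1"`` magic,
  uint32 version, uint32 reserved) followed by little-endian fixed-width
  records ``(int32 channel, uint64 time_ps)`` — used for replayable
  recordings;
* a CSV dialect (``channel,time_ps`` header) for human-readable fixtures.

Photon-coordinate records are written as Arrow-IPC columnar files (one
partition per spectral channel) with a CSV fallback, and count buffers
are exported as multi-page 16-bit TIFF stacks.
"""

from __future__ import annotations

import csv
import struct
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, NamedTuple, Sequence

import numpy as np

__all__ = [
    "TimeTag",
    "TagStream",
    "PhotonRecord",
    "PhotonRecordArray",
    "StreamFormatError",
    "TruncatedStreamError",
    "MonotonicityError",
    "read_tag_stream",
    "read_tag_array",
    "write_tag_stream",
    "write_photon_records",
    "read_photon_records",
    "photon_record_partitions",
    "write_stack",
    "read_stack",
]

MAGIC = b"TTAGSTR1"
VERSION = 1
_HEADER = struct.Struct("<8sII")
_RECORD_DTYPE = np.dtype([("channel", "<i4"), ("time_ps", "<u8")])
_BATCH_RECORDS = 1 << 16  # bounded-memory batch size for stream replay


class StreamFormatError(ValueError):
    """The file is not a recognizable tag stream."""


class TruncatedStreamError(StreamFormatError):
    """A record was cut short; ``byte_offset`` locates the damage."""

    def __init__(self, byte_offset: int):
        self.byte_offset = byte_offset
        super().__init__(f"truncated tag record at byte offset {byte_offset}")


class MonotonicityError(ValueError):
    """Timestamps went backwards; ``record_index`` names the offender."""

    def __init__(self, record_index: int, t_prev: int, t_now: int):
        self.record_index = record_index
        super().__init__(
            f"tag stream not time-ordered: record {record_index} has "
            f"time {t_now} ps after {t_prev} ps"
        )


class TimeTag(NamedTuple):
    """One discriminated event: signed channel id + picosecond timestamp."""

    channel: int
    time_ps: int


@dataclass
class TagStream:
    """Columnar tag stream (fast path for the simulator and replay)."""

    channels: np.ndarray  # int32
    times: np.ndarray     # int64/uint64, non-decreasing

    def __post_init__(self):
        self.channels = np.asarray(self.channels, dtype=np.int32)
        self.times = np.asarray(self.times, dtype=np.int64)
        if self.channels.shape != self.times.shape:
            raise ValueError("channels/times length mismatch")

    def __len__(self) -> int:
        return self.channels.size

    def __iter__(self) -> Iterator[TimeTag]:
        for c, t in zip(self.channels.tolist(), self.times.tolist()):
            yield TimeTag(c, t)


def _is_csv(path: Path) -> bool:
    return path.suffix.lower() == ".csv"


def write_tag_stream(tags: Iterable[TimeTag] | TagStream, path) -> int:
    """Write a time-ordered tag stream; returns the number of tags written."""
    path = Path(path)
    if _is_csv(path):
        return _write_tag_csv(tags, path)
    count = 0
    with open(path, "wb") as fh:
        fh.write(_HEADER.pack(MAGIC, VERSION, 0))
        if isinstance(tags, TagStream):
            rec = np.empty(len(tags), dtype=_RECORD_DTYPE)
            rec["channel"] = tags.channels
            rec["time_ps"] = tags.times.astype(np.uint64)
            rec.tofile(fh)
            return len(tags)
        batch: list[TimeTag] = []
        for tag in tags:
            batch.append(tag)
            if len(batch) >= _BATCH_RECORDS:
                count += _flush_binary(batch, fh)
                batch = []
        count += _flush_binary(batch, fh)
    return count


def _flush_binary(batch: Sequence[TimeTag], fh) -> int:
    if not batch:
        return 0
    rec = np.empty(len(batch), dtype=_RECORD_DTYPE)
    rec["channel"] = [t.channel for t in batch]
    rec["time_ps"] = [t.time_ps for t in batch]
    rec.tofile(fh)
    return len(batch)


def _write_tag_csv(tags: Iterable[TimeTag] | TagStream, path: Path) -> int:
    count = 0
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["channel", "time_ps"])
        for tag in tags:
            writer.writerow([tag.channel, tag.time_ps])
            count += 1
    return count


def read_tag_stream(path, *, monotonic_slack_ps: int = 0,
                    known_channels: set[int] | None = None
                    ) -> Iterator[TimeTag]:
    """Yield tags in stored order, verifying time ordering.

    Timestamps may decrease by at most ``monotonic_slack_ps`` (default 0)
    before a :class:`MonotonicityError` is raised.  If ``known_channels``
    is given, tags on other channels trigger a warning but are passed
    through untouched.
    """
    path = Path(path)
    prev = None
    index = 0
    warned: set[int] = set()
    for channels, times in _iter_batches(path):
        for c, t in zip(channels.tolist(), times.tolist()):
            if prev is not None and t < prev - monotonic_slack_ps:
                raise MonotonicityError(index, prev, t)
            if known_channels is not None and c not in known_channels \
                    and c not in warned:
                warned.add(c)
                warnings.warn(f"tag stream contains undeclared channel {c}")
            prev = t
            index += 1
            yield TimeTag(c, t)


def read_tag_array(path) -> TagStream:
    """Load a whole tag stream as a columnar :class:`TagStream`."""
    chunks = list(_iter_batches(Path(path)))
    if not chunks:
        return TagStream(np.empty(0, np.int32), np.empty(0, np.int64))
    channels = np.concatenate([c for c, _ in chunks])
    times = np.concatenate([t for _, t in chunks])
    return TagStream(channels, times)


def _iter_batches(path: Path):
    if _is_csv(path):
        with open(path, newline="") as fh:
            reader = csv.reader(fh)
            header = next(reader, None)
            if header is not None and header[:2] != ["channel", "time_ps"]:
                raise StreamFormatError(f"{path}: unrecognized CSV header {header}")
            chans: list[int] = []
            times: list[int] = []
            for row in reader:
                if not row:
                    continue
                chans.append(int(row[0]))
                times.append(int(row[1]))
                if len(chans) >= _BATCH_RECORDS:
                    yield (np.asarray(chans, np.int32), np.asarray(times, np.int64))
                    chans, times = [], []
            if chans:
                yield (np.asarray(chans, np.int32), np.asarray(times, np.int64))
        return
    with open(path, "rb") as fh:
        head = fh.read(_HEADER.size)
        if len(head) < _HEADER.size:
            if len(head) == 0:
                raise StreamFormatError(f"{path}: empty file (missing header)")
            raise TruncatedStreamError(len(head))
        magic, version, _ = _HEADER.unpack(head)
        if magic != MAGIC:
            raise StreamFormatError(f"{path}: bad magic {magic!r}")
        if version != VERSION:
            raise StreamFormatError(f"{path}: unsupported version {version}")
        offset = _HEADER.size
        while True:
            buf = fh.read(_RECORD_DTYPE.itemsize * _BATCH_RECORDS)
            if not buf:
                break
            rem = len(buf) % _RECORD_DTYPE.itemsize
            if rem:
                raise TruncatedStreamError(offset + len(buf) - rem)
            rec = np.frombuffer(buf, dtype=_RECORD_DTYPE)
            offset += len(buf)
            yield (rec["channel"].astype(np.int32),
                   rec["time_ps"].astype(np.int64))


# ---------------------------------------------------------------------------
# photon records
# ---------------------------------------------------------------------------

class PhotonRecord(NamedTuple):
    """One allocated photon: spectral channel, voxel coordinate, frame, time.

    ``demux_stream`` is 0/1 when demultiplexing was active, -1 otherwise.
    """

    spectral_channel: int
    demux_stream: int
    frame: int
    row: int
    col: int
    plane: int
    time_ps: int


_PHOTON_FIELDS = ("spectral_channel", "demux_stream", "frame",
                  "row", "col", "plane", "time_ps")
_PHOTON_NP_TYPES = (np.int32, np.int8, np.int64,
                    np.int32, np.int32, np.int32, np.int64)


@dataclass
class PhotonRecordArray:
    """Columnar batch of :class:`PhotonRecord` (numpy-backed)."""

    spectral_channel: np.ndarray
    demux_stream: np.ndarray
    frame: np.ndarray
    row: np.ndarray
    col: np.ndarray
    plane: np.ndarray
    time_ps: np.ndarray

    def __post_init__(self):
        for name, typ in zip(_PHOTON_FIELDS, _PHOTON_NP_TYPES):
            setattr(self, name, np.asarray(getattr(self, name), dtype=typ))
        n = self.time_ps.size
        for name in _PHOTON_FIELDS:
            if getattr(self, name).size != n:
                raise ValueError("photon record columns differ in length")

    @classmethod
    def empty(cls) -> "PhotonRecordArray":
        return cls(*[np.empty(0, t) for t in _PHOTON_NP_TYPES])

    @classmethod
    def from_records(cls, records: Iterable[PhotonRecord]) -> "PhotonRecordArray":
        rows = list(records)
        if not rows:
            return cls.empty()
        cols = list(zip(*rows))
        return cls(*[np.asarray(c) for c in cols])

    @classmethod
    def concatenate(cls, parts: Sequence["PhotonRecordArray"]) -> "PhotonRecordArray":
        parts = [p for p in parts if len(p)]
        if not parts:
            return cls.empty()
        return cls(*[
            np.concatenate([getattr(p, f) for p in parts]) for f in _PHOTON_FIELDS
        ])

    def __len__(self) -> int:
        return self.time_ps.size

    def __iter__(self) -> Iterator[PhotonRecord]:
        cols = [getattr(self, f).tolist() for f in _PHOTON_FIELDS]
        for vals in zip(*cols):
            yield PhotonRecord(*vals)

    def select(self, mask_or_idx) -> "PhotonRecordArray":
        return PhotonRecordArray(
            *[getattr(self, f)[mask_or_idx] for f in _PHOTON_FIELDS]
        )

    def sorted_by_time(self) -> "PhotonRecordArray":
        order = np.argsort(self.time_ps, kind="stable")
        return self.select(order)


def _partition_path(path: Path, channel: int) -> Path:
    return path.with_name(f"{path.stem}.ch{channel}{path.suffix}")


def write_photon_records(records: Iterable[PhotonRecord] | PhotonRecordArray,
                         path) -> int:
    """Write photon records, one file partition per spectral channel.

    ``path`` is a template such as ``out.arrow`` (Arrow IPC) or
    ``out.csv``; each spectral channel ``N`` lands in ``out.chN.arrow``.
    Returns the total row count across partitions.
    """
    path = Path(path)
    if not isinstance(records, PhotonRecordArray):
        records = PhotonRecordArray.from_records(records)
    channels = np.unique(records.spectral_channel)
    total = 0
    written_any = False
    for chan in channels.tolist():
        part = records.select(records.spectral_channel == chan)
        _write_one_partition(part, _partition_path(path, chan))
        total += len(part)
        written_any = True
    if not written_any:
        # keep the artifact re-renderable: an empty run still produces a
        # schema-complete (zero-row) file
        _write_one_partition(records, path)
    return total


def _write_one_partition(part: PhotonRecordArray, path: Path) -> None:
    if _is_csv(path):
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(_PHOTON_FIELDS)
            for rec in part:
                writer.writerow(rec)
        return
    import pyarrow as pa

    table = pa.table({f: getattr(part, f) for f in _PHOTON_FIELDS})
    with pa.OSFile(str(path), "wb") as sink:
        with pa.ipc.new_file(sink, table.schema) as writer:
            writer.write_table(table)


def photon_record_partitions(path) -> list[Path]:
    """List the per-channel partition files written for ``path``."""
    path = Path(path)
    hits = sorted(path.parent.glob(f"{path.stem}.ch*{path.suffix}"))
    if not hits and path.exists():
        hits = [path]
    return hits


def read_photon_records(path) -> PhotonRecordArray:
    """Read all partitions of a photon-record artifact back into one array."""
    parts = []
    for part_path in photon_record_partitions(path):
        parts.append(_read_one_partition(part_path))
    if not parts:
        raise FileNotFoundError(f"no photon-record partitions found for {path}")
    return PhotonRecordArray.concatenate(parts).sorted_by_time()


def _read_one_partition(path: Path) -> PhotonRecordArray:
    if _is_csv(path):
        with open(path, newline="") as fh:
            reader = csv.reader(fh)
            header = next(reader, None)
            if header != list(_PHOTON_FIELDS):
                raise StreamFormatError(f"{path}: unexpected columns {header}")
            rows = [[int(v) for v in row] for row in reader if row]
        if not rows:
            return PhotonRecordArray.empty()
        return PhotonRecordArray(*[np.asarray(c) for c in zip(*rows)])
    import pyarrow as pa

    with pa.memory_map(str(path)) as source:
        table = pa.ipc.open_file(source).read_all()
    return PhotonRecordArray(
        *[table.column(f).to_numpy(zero_copy_only=False) for f in _PHOTON_FIELDS]
    )


# ---------------------------------------------------------------------------
# TIFF stacks
# ---------------------------------------------------------------------------

def write_stack(stack: np.ndarray, path, *, rows: int | None = None,
                cols: int | None = None, planes: int | None = None) -> None:
    """Write count data as a multi-page 16-bit unsigned TIFF.

    ``stack`` is ``(frames, planes, rows, cols)`` (or any array whose
    trailing two axes are rows/cols); pages are emitted plane-major
    within each frame.  Counts above 65535 saturate with a warning.
    """
    import tifffile

    data = np.asarray(stack)
    if data.ndim == 2:
        data = data[None, None]
    elif data.ndim == 3:  # (frames, rows, cols) — single plane
        data = data[:, None]
    if data.ndim != 4:
        raise ValueError("expected a (frames, planes, rows, cols) array")
    if np.any(data < 0):
        raise ValueError("counts must be non-negative")
    if data.max(initial=0) > np.iinfo(np.uint16).max:
        warnings.warn("counts exceed 65535; saturating to the 16-bit ceiling")
        data = np.minimum(data, np.iinfo(np.uint16).max)
    frames, n_planes, n_rows, n_cols = data.shape
    pages = data.astype(np.uint16).reshape(frames * n_planes, n_rows, n_cols)
    meta = {
        "rows": rows or n_rows,
        "cols": cols or n_cols,
        "planes": planes or n_planes,
        "frames": frames,
    }
    tifffile.imwrite(str(path), pages, metadata=meta)


def read_stack(path) -> np.ndarray:
    import tifffile

    return tifffile.imread(str(path))
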