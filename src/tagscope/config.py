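"""Experiment configuration: parsing, validation, serialization.

The configuration describes the acquisition geometry (rows, columns,
planes), the scanner/laser/TAG-lens timing, and the wiring of the
digitizer inputs.  Every other module consumes an
:class:`ExperimentConfig`; nothing downstream re-reads the TOML file.

Timing convention: all periods are integer picoseconds (the digitizer's
native resolution).  Frequencies given in Hz are converted once, at
access time, by rounding ``1e12 / f`` to the nearest picosecond, so the
whole pipeline runs on exact integer arithmetic.
"""

from __future__ import annotations

import enum
import tomllib
from dataclasses import dataclass, field, replace

__all__ = [
    "Role",
    "ChannelSpec",
    "ExperimentConfig",
    "ConfigError",
    "parse_config",
    "serialize_config",
    "validate_config",
]

MAX_INPUTS = 18  # the digitizer exposes up to 18 discriminated inputs


class ConfigError(ValueError):
    """Raised for syntactically or structurally unusable configuration text."""


class Role(str, enum.Enum):
    LINE_SYNC = "line_sync"
    FRAME_SYNC = "frame_sync"
    TAG_SYNC = "tag_sync"
    LASER_SYNC = "laser_sync"
    SPECTRAL = "spectral"


@dataclass(frozen=True)
class ChannelSpec:
    """One digitizer input.

    ``input_number`` is signed: a negative value means the channel
    triggers on the falling edge of its signal; the magnitude is the
    physical input index (1..18).  ``threshold`` (volts) is carried as
    metadata only — discrimination happens in hardware.
    """

    input_number: int
    role: Role
    threshold: float = 0.5
    label: str = ""

    @property
    def falling_edge(self) -> bool:
        return self.input_number < 0


# fields with spec-defined defaults, applied when omitted from the file
_DEFAULTS = {
    "planes": 1,
    "bidirectional": True,
    "fill_fraction": 0.8,
    "line_frequency_hz": 15_778.0,
    "frame_rate_hz": 30.0,
    "laser_period_ps": 12_500,
    "tag_frequency_hz": 1.89e5,
    "tag_phase0_rad": 0.0,
    "demultiplex": False,
    "bidir_phase_ps": 0,
    "rolling_window_frames": 1,
    "filename": "run",
    "replay_existing": False,
}

_REQUIRED = ("rows", "columns", "channels")


@dataclass(frozen=True)
class ExperimentConfig:
    channels: tuple[ChannelSpec, ...]
    rows: int
    columns: int
    planes: int = 1
    bidirectional: bool = True
    fill_fraction: float = 0.8
    line_frequency_hz: float = 15_778.0
    frame_rate_hz: float = 30.0
    laser_period_ps: int = 12_500
    tag_frequency_hz: float = 1.89e5
    tag_phase0_rad: float = 0.0
    demultiplex: bool = False
    bidir_phase_ps: int = 0
    rolling_window_frames: int = 1
    filename: str = "run"
    replay_existing: bool = False

    # -- integer-picosecond timing, derived once from the Hz fields -------
    @property
    def line_period_ps(self) -> int:
        return round(1e12 / self.line_frequency_hz)

    @property
    def frame_period_ps(self) -> int:
        if self.channel_for(Role.LINE_SYNC) is not None:
            return self.rows * self.line_period_ps
        return round(1e12 / self.frame_rate_hz)

    @property
    def tag_period_ps(self) -> int:
        return round(1e12 / self.tag_frequency_hz)

    # -- channel lookup ----------------------------------------------------
    def channel_for(self, role: Role) -> ChannelSpec | None:
        for ch in self.channels:
            if ch.role is role:
                return ch
        return None

    def spectral_channels(self) -> tuple[ChannelSpec, ...]:
        return tuple(c for c in self.channels if c.role is Role.SPECTRAL)

    def role_of(self, input_number: int) -> Role | None:
        for ch in self.channels:
            if ch.input_number == input_number:
                return ch.role
        return None

    def with_updates(self, **kwargs) -> "ExperimentConfig":
        return replace(self, **kwargs)


def _coerce_channel(raw: dict, index: int, strict: bool,
                    warnings_out: list[str]) -> ChannelSpec:
    known = {"input_number", "role", "threshold", "label"}
    unknown = set(raw) - known
    if unknown:
        msg = f"channel #{index}: unknown key(s) {sorted(unknown)}"
        if strict:
            raise ConfigError(msg)
        warnings_out.append(msg)
    try:
        role = Role(raw["role"])
    except KeyError:
        raise ConfigError(f"channel #{index}: missing 'role'") from None
    except ValueError:
        raise ConfigError(
            f"channel #{index}: unknown role {raw['role']!r} "
            f"(expected one of {[r.value for r in Role]})"
        ) from None
    if "input_number" not in raw:
        raise ConfigError(f"channel #{index}: missing 'input_number'")
    return ChannelSpec(
        input_number=int(raw["input_number"]),
        role=role,
        threshold=float(raw.get("threshold", 0.5)),
        label=str(raw.get("label", "")),
    )


def parse_config(text: str, *, strict: bool = True,
                 warnings_out: list[str] | None = None) -> ExperimentConfig:
    """Parse TOML configuration text into an :class:`ExperimentConfig`.

    Strict mode (default) rejects unknown keys so typos surface
    immediately; with ``strict=False`` they are reported into
    ``warnings_out`` and ignored.  Defaults are applied for omitted
    optional fields.  Semantic invariants are *not* enforced here — use
    :func:`validate_config`.
    """
    if warnings_out is None:
        warnings_out = []
    try:
        data = tomllib.loads(text)
    except tomllib.TOMLDecodeError as exc:
        raise ConfigError(f"configuration syntax error: {exc}") from exc

    known = set(_DEFAULTS) | {"rows", "columns", "channels"}
    unknown = set(data) - known
    if unknown:
        msg = f"unknown configuration key(s): {sorted(unknown)}"
        if strict:
            raise ConfigError(msg)
        warnings_out.append(msg)
        for k in unknown:
            data.pop(k)

    for key in _REQUIRED:
        if key not in data:
            raise ConfigError(f"missing required key {key!r}")

    raw_channels = data.pop("channels")
    if not isinstance(raw_channels, list):
        raise ConfigError("'channels' must be an array of tables")
    channels = tuple(
        _coerce_channel(raw, i, strict, warnings_out)
        for i, raw in enumerate(raw_channels)
    )

    kwargs: dict = {"channels": channels}
    kwargs["rows"] = int(data.pop("rows"))
    kwargs["columns"] = int(data.pop("columns"))
    for key, default in _DEFAULTS.items():
        value = data.pop(key, default)
        if isinstance(default, bool):
            if not isinstance(value, bool):
                raise ConfigError(f"{key!r} must be a boolean")
            kwargs[key] = value
        elif isinstance(default, int):
            kwargs[key] = int(value)
        elif isinstance(default, float):
            kwargs[key] = float(value)
        else:
            kwargs[key] = str(value)
    return ExperimentConfig(**kwargs)


def _toml_value(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (int, float)):
        return repr(v)
    return '"' + str(v).replace("\\", "\\\\").replace('"', '\\"') + '"'


def serialize_config(cfg: ExperimentConfig) -> str:
    """Emit TOML text such that ``parse_config(serialize_config(cfg)) == cfg``."""
    lines = []
    scalar_fields = ["rows", "columns"] + list(_DEFAULTS)
    for key in scalar_fields:
        lines.append(f"{key} = {_toml_value(getattr(cfg, key))}")
    for ch in cfg.channels:
        lines.append("")
        lines.append("[[channels]]")
        lines.append(f"input_number = {ch.input_number}")
        lines.append(f'role = "{ch.role.value}"')
        lines.append(f"threshold = {_toml_value(ch.threshold)}")
        lines.append(f'label = {_toml_value(ch.label)}')
    return "\n".join(lines) + "\n"


def validate_config(cfg: ExperimentConfig) -> list[str]:
    """Return a human-readable message per violated invariant (empty = valid).

    Violations are data, not exceptions: callers decide whether to abort.
    """
    v: list[str] = []

    for ch in cfg.channels:
        if ch.input_number == 0:
            v.append(f"channel {ch.label or ch.role.value}: input_number must be nonzero")
        elif abs(ch.input_number) > MAX_INPUTS:
            v.append(
                f"channel {ch.label or ch.role.value}: |input_number| = "
                f"{abs(ch.input_number)} exceeds the {MAX_INPUTS}-input bound"
            )
    if len(cfg.channels) > MAX_INPUTS:
        v.append(
            f"{len(cfg.channels)} channels declared; the digitizer has at most "
            f"{MAX_INPUTS} inputs"
        )
    seen: set[int] = set()
    for ch in cfg.channels:
        if abs(ch.input_number) in seen:
            v.append(f"input {abs(ch.input_number)} declared more than once")
        seen.add(abs(ch.input_number))

    for role in (Role.LINE_SYNC, Role.FRAME_SYNC, Role.TAG_SYNC, Role.LASER_SYNC):
        n = sum(1 for c in cfg.channels if c.role is role)
        if n > 1:
            v.append(f"at most one {role.value} channel allowed (found {n})")

    has_line = cfg.channel_for(Role.LINE_SYNC) is not None
    has_frame = cfg.channel_for(Role.FRAME_SYNC) is not None
    if has_line and has_frame:
        v.append("a line_sync and a frame_sync channel are mutually exclusive: "
                 "exactly one sync source is required, not both")
    if not has_line and not has_frame:
        v.append("one sync channel (line_sync or frame_sync) is required")
    if not cfg.spectral_channels():
        v.append("at least one spectral channel is required")

    if cfg.rows < 1:
        v.append("rows must be positive")
    if cfg.columns < 1:
        v.append("columns must be positive")
    if cfg.planes < 1:
        v.append("planes must be positive")
    elif cfg.planes > 1:
        if cfg.planes % 2 != 0:
            v.append("planes must be even and >1 for volumetric mode")
        if cfg.channel_for(Role.TAG_SYNC) is None:
            v.append("volumetric mode (planes > 1) requires a tag_sync channel")
    if not (0.0 < cfg.fill_fraction <= 1.0):
        v.append("fill_fraction must lie in (0, 1]")
    if cfg.line_frequency_hz <= 0:
        v.append("line_frequency_hz must be positive")
    if cfg.frame_rate_hz <= 0:
        v.append("frame_rate_hz must be positive")
    if cfg.tag_frequency_hz <= 0:
        v.append("tag_frequency_hz must be positive")
    if cfg.rolling_window_frames < 1:
        v.append("rolling_window_frames must be positive")
    if cfg.demultiplex:
        if cfg.channel_for(Role.LASER_SYNC) is None:
            v.append("demultiplexing requires a laser_sync channel")
        if cfg.laser_period_ps <= 0:
            v.append("demultiplexing requires laser_period_ps > 0")
    elif cfg.laser_period_ps <= 0:
        v.append("laser_period_ps must be positive")

    return v
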