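from pathlib import Path

import pytest
from hypothesis import HealthCheck, settings

from tagscope.config import ChannelSpec, ExperimentConfig, Role

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

EXAMPLES = Path(__file__).resolve().parent.parent / "examples"


def make_cfg(rows=4, cols=8, *, line_period_ps=1_000_000, fill_fraction=0.8,
             bidirectional=False, planes=1, demultiplex=False,
             tag_frequency_hz=1.89e5, bidir_phase_ps=0,
             extra_channels=(), frame_sync_only=False) -> ExperimentConfig:
    """Small synthetic acquisition geometry for unit tests."""
    channels = []
    if frame_sync_only:
        channels.append(ChannelSpec(1, Role.FRAME_SYNC, label="frame sync"))
    else:
        channels.append(ChannelSpec(1, Role.LINE_SYNC, label="line sync"))
    channels.append(ChannelSpec(2, Role.SPECTRAL, label="pmt"))
    if planes > 1:
        channels.append(ChannelSpec(5, Role.TAG_SYNC, label="tag sync"))
    if demultiplex:
        channels.append(ChannelSpec(4, Role.LASER_SYNC, label="laser sync"))
    channels.extend(extra_channels)
    return ExperimentConfig(
        channels=tuple(channels),
        rows=rows,
        columns=cols,
        planes=planes,
        bidirectional=bidirectional,
        fill_fraction=fill_fraction,
        line_frequency_hz=1e12 / line_period_ps,
        frame_rate_hz=1e12 / (rows * line_period_ps),
        laser_period_ps=12_500,
        tag_frequency_hz=tag_frequency_hz,
        demultiplex=demultiplex,
        bidir_phase_ps=bidir_phase_ps,
    )


@pytest.fixture
def cfg_small():
    return make_cfg()


@pytest.fixture(params=sorted(EXAMPLES.glob("*.toml")), ids=lambda p: p.name)
def example_config_text(request):
    return request.param.read_text()
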