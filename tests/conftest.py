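import pytest
from hypothesis import HealthCheck, settings

from pvstrand.ionic import ChannelScaling
from pvstrand.tissue import PacingProtocol, TissueConfig, build_tissue, simulate

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


#: 40-cell test strand (full 2 cm geometry scaled to 10 cells per layer)
SMALL_CONFIG = TissueConfig(cells_per_layer=10, length_cm=0.4)


@pytest.fixture(scope="session")
def control_small():
    """Control run on the 40-cell strand, CL = 750 ms."""
    tissue = build_tissue(SMALL_CONFIG, ChannelScaling())
    return simulate(tissue, PacingProtocol(cl=750.0, n_beats=6,
                                           record_last=2))


@pytest.fixture(scope="session")
def blocked_small():
    """70% I_Kr block on the 40-cell strand, CL = 1000 ms (EAD regime)."""
    tissue = build_tissue(SMALL_CONFIG, ChannelScaling(s_kr=0.3))
    return simulate(tissue, PacingProtocol(cl=1000.0, n_beats=6,
                                           record_last=2))


@pytest.fixture(scope="session")
def control_full():
    """Control run on the full 200-cell strand, CL = 750 ms."""
    tissue = build_tissue(TissueConfig(), ChannelScaling())
    return simulate(tissue, PacingProtocol(cl=750.0, n_beats=6,
                                           record_last=2))
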