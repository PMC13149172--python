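import pytest

from cardiomap import recovery
from cardiomap.synth import RhythmScript, SimulationConfig, simulate_trace


@pytest.fixture(scope="session")
def wt_voltage_template():
    return recovery.wt_voltage_template()


@pytest.fixture(scope="session")
def fd_voltage_template():
    return recovery.fd_voltage_template()


@pytest.fixture(scope="session")
def wt_calcium_template():
    return recovery.wt_calcium_template()


@pytest.fixture(scope="session")
def fd_calcium_template():
    return recovery.fd_calcium_template()


@pytest.fixture(scope="session")
def clean_wt_trace(wt_voltage_template):
    """Noiseless 10-s voltage trace at the WT spontaneous rate."""
    cfg = SimulationConfig(
        duration=10.0,
        waveform=wt_voltage_template,
        rhythm=RhythmScript(base_frequency=0.67),
        noise_sd=0.0,
        seed=12,
    )
    return simulate_trace(cfg)


@pytest.fixture(scope="session")
def noisy_wt_trace(wt_voltage_template):
    """SNR-20 voltage trace at the WT rate (default generator noise)."""
    cfg = SimulationConfig(
        duration=10.0,
        waveform=wt_voltage_template,
        rhythm=RhythmScript(base_frequency=0.67, jitter_cv=0.03),
        seed=12,
    )
    return simulate_trace(cfg)
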