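import numpy as np
import pytest

from pvloop import SimConfig, analyze_recording, make_protocol, simulate_run
from pvloop.beats import Beat


@pytest.fixture(scope="session")
def vload_off_run():
    """Noiseless preload reduction with shortening deactivation off:
    the classical single-mechanism ESPVR sweep (Ees_true=1.2, V0_base=10)."""
    cfg = SimConfig(Ees_true=1.2, V0_base=10.0, sda_enabled=False)
    rec = simulate_run(cfg, make_protocol("vload_normal", cfg))
    return cfg, rec


@pytest.fixture(scope="session")
def vload_off_analysis(vload_off_run):
    cfg, rec = vload_off_run
    return cfg, rec, analyze_recording(rec, vp=0.0, alpha=1.0)


@pytest.fixture(scope="session")
def pload_on_run():
    """Noiseless afterload increase with shortening deactivation on."""
    cfg = SimConfig(sda_enabled=True)
    rec = simulate_run(cfg, make_protocol("pload", cfg))
    return cfg, rec


@pytest.fixture(scope="session")
def pload_on_analysis(pload_on_run):
    cfg, rec = pload_on_run
    return cfg, rec, analyze_recording(rec, vp=0.0, alpha=1.0)


def make_synthetic_beat(ves, pes, ved=None, ped=5.0, n=200, fs=1000.0, start=0):
    """A stylized beat whose maximal-elastance point is (ves, pes): volume
    falls monotonically to ves while pressure rises to pes, then both
    return; end-diastole is (ved, ped) at the first sample."""
    ved = ves + 40.0 if ved is None else ved
    half = n // 2
    v = np.concatenate([np.linspace(ved, ves, half), np.linspace(ves, ved, n - half)])
    p = np.concatenate([np.linspace(ped, pes, half), np.linspace(pes, ped, n - half)])
    return Beat(start=start, end=start + n, fs=fs, lvp=p, lvv=v)
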