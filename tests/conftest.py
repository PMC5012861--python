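import numpy as np
import pytest

from barmkit import SimulationConfig, simulate_block
from barmkit.detect import detect_blinks, reference_torsion, segment_nystagmus


@pytest.fixture(scope="session")
def short_config():
    """A cut-down four-phase block (fast to simulate, same structure)."""
    return SimulationConfig(phase_durations=(40.0, 80.0, 40.0, 80.0), seed=7)


@pytest.fixture(scope="session")
def noiseless_config(short_config):
    """All stochastic observation/latent noise silenced; events remain."""
    return short_config.replace(
        barm_noise_sd=0.0,
        torsion_wander_sd=0.0,
        hv_wander_sd=0.0,
        slow_velocity_wander_sd=0.0,
        video_noise_drift=(0.0, 0.0, 0.0),
        video_noise_white=(0.0, 0.0, 0.0),
        coil_noise_white=(0.0, 0.0, 0.0),
        eye_artifact_rate=0.0,
        fast_phase_amp_noise_sigma=0.0,
        slow_phase_velocity_sd=0.0,
    )


@pytest.fixture(scope="session")
def short_block(short_config):
    block, log = simulate_block(short_config)
    return block, log


@pytest.fixture(scope="session")
def analyzed_short_block(short_block):
    block, log = short_block
    ref = reference_torsion(block)
    blinks = detect_blinks(ref)
    phases = segment_nystagmus(ref, blinks)
    return ref, log, blinks, phases


def make_trace_block(
    torsion,
    fs=50.0,
    valid_left=None,
    valid_right=None,
    phase=None,
    stim=None,
    h=None,
    v=None,
):
    """Hand-constructed EyeTraceBlock for oracle tests."""
    from barmkit.types import EyeTraceBlock

    torsion = np.asarray(torsion, dtype=float)
    n = len(torsion)
    ones = np.ones(n, dtype=bool)
    h = np.zeros(n) if h is None else np.asarray(h, float)
    v = np.zeros(n) if v is None else np.asarray(v, float)
    phase = np.array(["flow1"] * n, dtype=object) if phase is None else np.asarray(phase, dtype=object)
    stim = np.array(["flow_cw"] * n, dtype=object) if stim is None else np.asarray(stim, dtype=object)
    vl = ones.copy() if valid_left is None else np.asarray(valid_left, bool)
    vr = ones.copy() if valid_right is None else np.asarray(valid_right, bool)
    t_masked = torsion.copy()
    t_masked[~(vl & vr)] = np.nan
    chans = lambda: {"h": h.copy(), "v": v.copy(), "t": t_masked.copy()}
    return EyeTraceBlock(
        time=np.arange(n) / fs,
        left=chans(),
        right=chans(),
        valid_left=vl,
        valid_right=vr,
        phase_label=phase,
        stimulus_state=stim,
        modality="video",
        sampling_rate=fs,
    )
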