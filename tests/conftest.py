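import numpy as np
import pytest

from scg_beatkit import SimConfig, generate_recording, run_pipeline
from scg_beatkit.preprocess import BeatSegment


@pytest.fixture(scope="session")
def short_recording():
    """Two minutes at a steady 60 bpm with the default noise and modulation."""
    cfg = SimConfig(duration_s=120.0, hr_profile=((0.0, 60.0),), seed=7)
    return generate_recording(cfg)


@pytest.fixture(scope="session")
def short_run(short_recording):
    record, ann, truth = short_recording
    table, summary = run_pipeline(record, ann)
    return table, summary


def make_beat(scg, fs=200.0, r_time=1000.0, rri=1000.0, ecg=None, t0_ms=0.0):
    """BeatSegment over a full signal array whose sample 0 sits at ``t0_ms``.

    The beat window is [r_time-200, r_time+rri-200) with the extended window
    reaching r_time+rri, clipped to the array.
    """
    scg = np.asarray(scg, dtype=float)
    if ecg is None:
        ecg = np.zeros_like(scg)
    dt = 1000.0 / fs
    start_idx = int(round((r_time - 200.0 - t0_ms) / dt))
    end_idx = int(round((r_time + rri - 200.0 - t0_ms) / dt))
    ext_idx = min(int(round((r_time + rri - t0_ms) / dt)), scg.size)
    start_idx = max(start_idx, 0)
    return BeatSegment(
        index=0, r_time=r_time, rri=rri,
        start_time=r_time - 200.0, end_time=r_time + rri - 200.0,
        fs=fs, start_idx=start_idx, end_idx=end_idx, ext_end_idx=ext_idx,
        ecg=ecg[start_idx:end_idx], scg=scg[start_idx:end_idx],
        ecg_ext=ecg[start_idx:ext_idx], scg_ext=scg[start_idx:ext_idx])


def gauss_signal(bumps, fs=200.0, duration_ms=2000.0):
    """Sampled sum of Gaussian bumps [(centre_ms, sigma_ms, amplitude), ...]."""
    t = np.arange(0.0, duration_ms, 1000.0 / fs)
    out = np.zeros_like(t)
    for c, s, a in bumps:
        out += a * np.exp(-0.5 * ((t - c) / s) ** 2)
    return out
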