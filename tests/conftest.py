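"""Shared fixtures and trace builders for the test suite."""
from __future__ import annotations

import numpy as np
import pytest

from cnephys.recordings import RecordingSeries, Sweep

DT = 1e-4  # 10 kHz default for hand-built traces
BASE_S = 0.1
DUR_S = 0.5
TAIL_S = 0.2


def rc_sweep(
    amp_na: float,
    r_mohm: float = 100.0,
    tau_s: float = 0.010,
    rest: float = -65.0,
    b: float = 1.0,
    tau_h_s: float = 0.050,
    dt: float = DT,
    dur: float = DUR_S,
    noise: float = 0.0,
    seed: int = 0,
    sweep_id: str = "",
) -> Sweep:
    """Analytic RC (optionally sagging) response to a square step.

    Deflection: amp * r * (1 - exp(-t/tau)) * (b + (1-b) exp(-t/tau_h)),
    so the steady state is ~ amp * r * b and the sag relaxes with tau_h.
    """
    n = int(round((BASE_S + dur + TAIL_S) / dt))
    t = np.arange(n) * dt
    v = np.full(n, rest, dtype=float)
    step = (t >= BASE_S) & (t < BASE_S + dur)
    ts = t[step] - BASE_S
    v[step] += amp_na * r_mohm * (1 - np.exp(-ts / tau_s)) * (b + (1 - b) * np.exp(-ts / tau_h_s))
    post = t >= BASE_S + dur
    v[post] += (v[step][-1] - rest) * np.exp(-(t[post] - BASE_S - dur) / tau_s)
    if noise > 0:
        v += np.random.default_rng(seed).normal(0, noise, n)
    return Sweep(sample_interval=dt, voltage=v, step_amplitude=amp_na,
                 step_onset=BASE_S, step_duration=dur, sweep_id=sweep_id or f"rc{amp_na:+.3f}")


def add_spikes(sweep: Sweep, times_s, height: float = 45.0, width_s: float = 0.0008,
               rest: float | None = None) -> Sweep:
    """Insert Gaussian spike lobes (relative to the local trace) at given times."""
    v = sweep.voltage.copy()
    t = sweep.time()
    for ts in times_s:
        v += height * np.exp(-((t - ts) ** 2) / (2 * width_s**2))
    return Sweep(sample_interval=sweep.sample_interval, voltage=v,
                 step_amplitude=sweep.step_amplitude, step_onset=sweep.step_onset,
                 step_duration=sweep.step_duration, sweep_id=sweep.sweep_id)


def series_of(sweeps, cell_id="cell0", **kw) -> RecordingSeries:
    return RecordingSeries(sweeps=tuple(sweeps), cell_id=cell_id, **kw)


@pytest.fixture(scope="session")
def cohort_table():
    """One default synthetic 162-cell feature cohort, shared across tests."""
    from cnephys.synth import sample_feature_table

    return sample_feature_table(seed=11)
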