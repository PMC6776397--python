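"""Passive measures from subthreshold / hyperpolarizing sweeps.

Five measures: resting membrane potential (RMP, mV), input resistance
(R_in, MOhm), membrane time constant (tau_m, ms), sag time constant
(tau_h, ms) and the sag ratio B/A (steady-state over peak hyperpolarizing
deflection; 1 means no sag, smaller means stronger Ih).

Conventions (fixed once, stated here because the primary literature leaves
them open):

* "steady state" is the mean over the final 10% of the step;
* R_in uses sweeps whose steady-state deflection lies in (0, -15] mV
  ("just below rest");
* tau_h uses the sweep whose steady state is nearest -80 mV, within
  +/-10 mV;
* tau fits are single-exponential least squares, initial tau from the
  1 - 1/e crossing of the (lightly smoothed) deflection; the tau_m fit
  window is [onset, onset + min(5 * tau_init, 0.5 * step_duration)].
"""
from __future__ import annotations

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.optimize import curve_fit

from .recordings import RecordingSeries, Sweep

MIN_BASELINE_S = 0.020
STEADY_STATE_FRACTION = 0.10
RIN_DEFLECTION_RANGE_MV = (0.0, 15.0)   # magnitude of hyperpolarizing SS deflection
TAUM_DEFLECTION_RANGE_MV = (2.0, 10.0)  # magnitude of peak deflection
TAUM_WINDOW_TAUS = 5.0                  # fit-window length in units of tau_init
SAG_TARGET_MV = -80.0
SAG_WINDOW_MV = 10.0
MIN_SAG_DEFLECTION_MV = 3.0


class MeasureUnavailable(ValueError):
    """A measure cannot be computed for this cell; carries the reason."""

    @property
    def reason(self) -> str:
        return str(self)


def steady_state_voltage(sweep: Sweep) -> float:
    """Mean voltage over the final 10% of the current step."""
    i1 = sweep.index_at(sweep.step_offset)
    i0 = sweep.index_at(sweep.step_offset - STEADY_STATE_FRACTION * sweep.step_duration)
    return float(np.mean(sweep.voltage[i0:i1]))


PEAK_SMOOTH_S = 0.005


def _smoothed_step(sweep: Sweep) -> np.ndarray:
    """Step-window voltage, low-passed with a 5 ms boxcar.

    The subthreshold extremum sits on a slowly varying response (tens of
    ms); smoothing keeps recording noise from biasing it deeper.
    """
    seg = sweep.voltage[sweep.step_window()]
    w = max(1, int(round(PEAK_SMOOTH_S / sweep.sample_interval)))
    return uniform_filter1d(seg, size=w, mode="nearest")


def peak_deflection(sweep: Sweep, rest: float) -> float:
    """Extremal deflection from rest during the step (signed, mV).

    The extremum is taken in the direction of the current step, on a
    lightly smoothed trace so it is robust to baseline noise.
    """
    seg = _smoothed_step(sweep)
    if sweep.step_amplitude < 0:
        return float(np.min(seg) - rest)
    return float(np.max(seg) - rest)


def resting_potential(series: RecordingSeries) -> float:
    """RMP (mV): mean pre-step baseline voltage pooled over all sweeps."""
    baselines = []
    for sw in series:
        b = sw.baseline()
        if b.size * sw.sample_interval >= MIN_BASELINE_S:
            baselines.append(b)
    if not baselines:
        raise MeasureUnavailable(
            f"no sweep with >= {MIN_BASELINE_S * 1e3:.0f} ms of pre-step baseline"
        )
    return float(np.mean(np.concatenate(baselines)))


def input_resistance(series: RecordingSeries, rest: float | None = None) -> float:
    """R_in (MOhm): slope of steady-state voltage vs current just below rest.

    Uses sweeps whose steady-state deflection is hyperpolarizing by at most
    15 mV; the least-squares line includes an intercept so a small rest
    offset does not bias the slope.  mV/nA = MOhm.
    """
    if rest is None:
        rest = resting_potential(series)
    currents, volts = [], []
    for sw in series.hyperpolarizing():
        ss = steady_state_voltage(sw)
        lo, hi = RIN_DEFLECTION_RANGE_MV
        if lo < rest - ss <= hi:
            currents.append(sw.step_amplitude)
            volts.append(ss)
    if len(currents) < 2:
        if not series.hyperpolarizing():
            raise MeasureUnavailable("no subthreshold sweeps")
        raise MeasureUnavailable(
            f"fewer than 2 sweeps with steady-state deflection in "
            f"(0, -{RIN_DEFLECTION_RANGE_MV[1]:.0f}] mV"
        )
    slope = np.polyfit(currents, volts, 1)[0]
    if slope <= 0:
        raise MeasureUnavailable(f"non-positive I-V slope ({slope:.3g} MOhm)")
    return float(slope)


def _exp_decay(t, v_ss, a, tau):
    return v_ss + a * np.exp(-t / tau)


def _fit_exponential(
    t: np.ndarray, v: np.ndarray, tau0: float, tau_max: float = np.inf
) -> tuple[float, float, float]:
    """Least-squares fit of v(t) = v_ss + a*exp(-t/tau); returns (v_ss, a, tau)."""
    v_ss0 = float(v[-1])
    a0 = float(v[0] - v_ss0)
    popt, _ = curve_fit(
        _exp_decay,
        t,
        v,
        p0=(v_ss0, a0, min(max(tau0, t[1] - t[0]), tau_max * 0.99)),
        bounds=([-np.inf, -np.inf, 1e-6], [np.inf, np.inf, tau_max]),
        maxfev=10000,
    )
    return float(popt[0]), float(popt[1]), float(popt[2])


def _tau_initial(t: np.ndarray, deflection: np.ndarray) -> float:
    """Initial tau estimate from the 1 - 1/e crossing of the deflection."""
    target = (1.0 - np.exp(-1.0)) * deflection[-1]
    sign = np.sign(deflection[-1]) or 1.0
    crossed = np.flatnonzero(sign * deflection >= sign * target)
    if crossed.size == 0:
        return float(t[-1] / 2)
    return float(max(t[crossed[0]], t[1] - t[0]))


def membrane_tau(series: RecordingSeries, rest: float | None = None) -> float:
    """tau_m (ms) from small hyperpolarizing steps (2-10 mV peak deflection).

    Each qualifying sweep is fit with a single exponential over
    [onset, onset + min(5*tau_init, 0.5*step_duration)]; the fitted taus
    are averaged with weights proportional to the squared deflection, so
    the best-resolved sweeps dominate.
    """
    if rest is None:
        rest = resting_potential(series)
    taus, weights = [], []
    lo, hi = TAUM_DEFLECTION_RANGE_MV
    for sw in series.hyperpolarizing():
        defl = abs(peak_deflection(sw, rest))
        if not (lo <= defl <= hi):
            continue
        i0 = sw.index_at(sw.step_onset)
        t_full = sw.time()[i0:] - sw.step_onset
        v_full = sw.voltage[i0:]
        n_step = sw.index_at(sw.step_offset) - i0
        # rough tau from the smoothed early rise, then restrict the fit window
        w_sm = max(1, int(round(0.001 / sw.sample_interval)))
        v_sm = uniform_filter1d(v_full, size=w_sm, mode="nearest")
        probe = min(n_step, max(8, int(round(0.2 * n_step))))
        tau0 = _tau_initial(t_full[:probe], v_sm[:probe] - v_sm[0])
        n_win = min(
            n_step,
            max(8, int(round(min(TAUM_WINDOW_TAUS * tau0, 0.5 * sw.step_duration)
                             / sw.sample_interval))),
        )
        tau_max = 0.25 * sw.step_duration
        try:
            _, _, tau = _fit_exponential(t_full[:n_win], v_full[:n_win], tau0, tau_max)
        except RuntimeError:
            continue
        if tau >= 0.8 * tau_max:  # fit ran away; ignore this sweep
            continue
        taus.append(tau)
        weights.append(defl**2)
    if not taus:
        raise MeasureUnavailable(
            f"no hyperpolarizing sweep with peak deflection in [{lo:.0f}, {hi:.0f}] mV"
        )
    return float(np.average(taus, weights=weights) * 1e3)


def sag_ratio(sweep: Sweep, rest: float) -> float:
    """B/A: steady-state over peak hyperpolarizing deflection from rest.

    1.0 for a pure RC response; < 1 indicates a depolarizing sag (Ih).
    Requires a hyperpolarizing sweep with >= 3 mV peak deflection.
    """
    if sweep.step_amplitude >= 0:
        raise ValueError(
            f"sag ratio requires a hyperpolarizing sweep "
            f"(sweep {sweep.sweep_id or '?'} has I = {sweep.step_amplitude:+.3g} nA)"
        )
    peak = peak_deflection(sweep, rest)
    if peak > -MIN_SAG_DEFLECTION_MV:
        raise MeasureUnavailable(
            f"peak deflection {abs(peak):.2f} mV < {MIN_SAG_DEFLECTION_MV:.0f} mV"
        )
    ss = steady_state_voltage(sweep) - rest
    return float(ss / peak)


def select_sag_sweep(series: RecordingSeries) -> Sweep:
    """The hyperpolarizing sweep whose steady state is nearest -80 mV (+/-10)."""
    best, best_d = None, np.inf
    for sw in series.hyperpolarizing():
        d = abs(steady_state_voltage(sw) - SAG_TARGET_MV)
        if d < best_d:
            best, best_d = sw, d
    if best is None or best_d > SAG_WINDOW_MV:
        raise MeasureUnavailable(
            f"no hyperpolarizing sweep with steady state within "
            f"+/-{SAG_WINDOW_MV:.0f} mV of {SAG_TARGET_MV:.0f} mV"
        )
    return best


def sag_tau(series: RecordingSeries, rest: float | None = None) -> float:
    """tau_h (ms): relaxation time constant of the sag near -80 mV.

    Fits a single exponential to the depolarizing relaxation from the peak
    of the hyperpolarizing deflection to the end of the step, on the sweep
    selected by :func:`select_sag_sweep`.
    """
    if rest is None:
        rest = resting_potential(series)
    sw = select_sag_sweep(series)
    win = sw.step_window()
    seg = sw.voltage[win]
    t = sw.time()[win]
    i_pk = int(np.argmin(_smoothed_step(sw)))  # smoothed argmin resists noise
    v_pk = float(_smoothed_step(sw)[i_pk])
    v_ss = steady_state_voltage(sw)
    if v_ss - v_pk < 0.5:  # no resolvable relaxation (B/A ~ 1)
        raise MeasureUnavailable("no sag to fit")
    t_fit = t[i_pk:] - t[i_pk]
    v_fit = seg[i_pk:]
    tau0 = _tau_initial(t_fit, v_fit - v_pk)
    try:
        _, _, tau = _fit_exponential(t_fit, v_fit, tau0)
    except RuntimeError as exc:
        raise MeasureUnavailable(f"sag fit did not converge: {exc}")
    return float(tau * 1e3)
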