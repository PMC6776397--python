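"""Action-potential detection and the seven active measures.

Detection criterion (somatic whole-cell recordings): an upward dV/dt
crossing of 20 mV/ms whose following local maximum rises at least 15 mV
above rest, with events closer than 1 ms merged.  Both thresholds are safe
for the narrowest half-widths seen in these cell classes (~0.26 ms) and
reject baseline noise of a few hundred microvolts RMS.

Measure conventions:

* AP shape is taken from the FIRST spike of the lowest suprathreshold
  sweep; the absolute peak and AHP potentials are reported (these are what
  enter the classifier), alongside the rest-relative height.
* The adaptation index -(2/N) * sum(t_i/t_d - 1/2) is computed on the
  second-lowest spiking sweep (the threshold-level train is uninformative);
  t_i are spike times from step onset, t_d the step duration.
* The ISI CV uses the sweep with the most spikes and needs >= 4 intervals,
  so onset-only cells come out missing.
* Rebound spikes are counted in a 100 ms window after the offset of
  hyperpolarizing steps; the maximum over sweeps is reported.
* The f-I slope is fit to the 3 lowest suprathreshold levels, with rate =
  spike count / step duration.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .passive import MeasureUnavailable
from .recordings import RecordingSeries, Sweep

DVDT_THRESHOLD_MV_PER_MS = 20.0
MIN_HEIGHT_MV = 15.0
REFRACTORY_S = 0.001
PEAK_SEARCH_S = 0.004
REBOUND_WINDOW_S = 0.100
MIN_REBOUND_TAIL_S = 0.050
MIN_CV_INTERVALS = 4


@dataclass(frozen=True)
class SpikeEvent:
    """One detected action potential and its shape landmarks."""

    time: float          # s from sweep start, at the voltage peak
    index: int           # sample index of the peak
    peak_V: float        # mV, absolute
    threshold_V: float   # mV at the dV/dt criterion crossing
    halfwidth: float     # ms, width at rest + (peak - rest)/2
    ahp_V: float         # mV, minimum after the peak (NaN if unresolvable)


def _interp_crossing(t0: float, t1: float, v0: float, v1: float, level: float) -> float:
    if v1 == v0:
        return t0
    return t0 + (level - v0) / (v1 - v0) * (t1 - t0)


def _halfwidth(sweep: Sweep, i_pk: int, rest: float) -> float:
    v = sweep.voltage
    dt = sweep.sample_interval
    level = rest + (v[i_pk] - rest) / 2.0
    span = max(1, int(round(0.010 / dt)))
    i = i_pk
    lo = max(0, i_pk - span)
    while i > lo and v[i] >= level:
        i -= 1
    t_left = _interp_crossing((i) * dt, (i + 1) * dt, v[i], v[i + 1], level)
    j = i_pk
    hi = min(v.size - 1, i_pk + span)
    while j < hi and v[j] >= level:
        j += 1
    t_right = _interp_crossing((j - 1) * dt, j * dt, v[j - 1], v[j], level)
    return (t_right - t_left) * 1e3


def detect_spikes(
    sweep: Sweep,
    rest: float | None = None,
    dvdt_threshold: float = DVDT_THRESHOLD_MV_PER_MS,
    min_height: float = MIN_HEIGHT_MV,
) -> list[SpikeEvent]:
    """Detect action potentials in one sweep, in time order.

    Returns an empty list when nothing crosses the criterion.
    """
    v = sweep.voltage
    dt = sweep.sample_interval
    if rest is None:
        base = sweep.baseline()
        rest = float(np.mean(base)) if base.size else float(v[0])
    dvdt = np.diff(v) / (dt * 1e3)  # mV/ms
    above = dvdt >= dvdt_threshold
    crossings = np.flatnonzero(above[1:] & ~above[:-1]) + 1
    if above.size and above[0]:
        crossings = np.concatenate([[0], crossings])
    w = max(1, int(round(PEAK_SEARCH_S / dt)))
    peaks: dict[int, int] = {}
    for c in crossings:
        # peak search ends at the falling-phase dV/dt crossing so that a
        # close-following spike is never mistaken for this one's peak
        end = min(c + w, v.size)
        falling = np.flatnonzero(dvdt[c : end - 1] <= -dvdt_threshold)
        if falling.size:
            end = min(end, c + int(falling[0]) + 2)
        i_pk = c + int(np.argmax(v[c:end]))
        if v[i_pk] < rest + min_height:
            continue
        peaks.setdefault(i_pk, c)
    if not peaks:
        return []
    # merge peaks closer than the refractory window, keeping the taller one
    items = sorted(peaks.items())
    merged: list[tuple[int, int]] = []
    ref = max(1, int(round(REFRACTORY_S / dt)))
    for i_pk, c in items:
        if merged and i_pk - merged[-1][0] < ref:
            if v[i_pk] > v[merged[-1][0]]:
                merged[-1] = (i_pk, merged[-1][1])
            continue
        merged.append((i_pk, c))
    i_end_step = sweep.index_at(sweep.step_offset)
    events: list[SpikeEvent] = []
    for k, (i_pk, c) in enumerate(merged):
        nxt = merged[k + 1][0] if k + 1 < len(merged) else None
        if nxt is None:
            bound = i_end_step if i_pk < i_end_step else v.size
        else:
            bound = nxt
        ahp = float(np.min(v[i_pk + 1 : bound])) if bound > i_pk + 1 else float("nan")
        events.append(
            SpikeEvent(
                time=i_pk * dt,
                index=i_pk,
                peak_V=float(v[i_pk]),
                threshold_V=float(v[c]),
                halfwidth=_halfwidth(sweep, i_pk, rest),
                ahp_V=ahp,
            )
        )
    return events


def spikes_in_step(sweep: Sweep, events: list[SpikeEvent]) -> list[SpikeEvent]:
    """Events whose peak lies within the current step."""
    return [e for e in events if sweep.step_onset <= e.time <= sweep.step_offset]


def _spiking_depolarizing(series: RecordingSeries, rest: float) -> list[tuple[Sweep, list[SpikeEvent]]]:
    out = []
    for sw in series.depolarizing():
        ev = spikes_in_step(sw, detect_spikes(sw, rest=rest))
        if ev:
            out.append((sw, ev))
    return out


def ap_shape(series: RecordingSeries, rest: float) -> dict:
    """AP shape from the first spike at the lowest suprathreshold current.

    Returns ``peak_V`` (absolute, mV), ``height`` (peak - rest, mV),
    ``halfwidth`` (ms), ``ahp_V`` (absolute, mV) and the sweep id used.
    """
    spiking = _spiking_depolarizing(series, rest)
    if not spiking:
        raise MeasureUnavailable("no spikes in any depolarizing sweep")
    sw, events = spiking[0]
    first = events[0]
    return {
        "peak_V": first.peak_V,
        "height": first.peak_V - rest,
        "halfwidth": first.halfwidth,
        "ahp_V": first.ahp_V,
        "sweep_id": sw.sweep_id,
    }


def adaptation_index(spike_times: np.ndarray, t_d: float) -> float:
    """-(2/N) * sum(t_i/t_d - 1/2), in [-1, 1].

    ``spike_times`` are seconds from step onset; ``t_d`` is the step
    duration.  +1 for a train at the very onset, -1 at the very end,
    0 for a time-symmetric train.
    """
    t = np.asarray(spike_times, dtype=float)
    if t.size == 0:
        raise MeasureUnavailable("no spikes")
    if t_d <= 0:
        raise ValueError("t_d must be positive")
    if np.any(t < -1e-9) or np.any(t > t_d + 1e-9):
        raise ValueError("spike times must lie within [0, t_d]")
    return float(-(2.0 / t.size) * np.sum(t / t_d - 0.5))


def select_adaptation_sweep(
    series: RecordingSeries, rest: float
) -> tuple[Sweep, list[SpikeEvent], bool]:
    """Second-lowest spiking depolarizing sweep (fallback: the only one).

    Returns (sweep, in-step events, fallback_flag); the flag is True when
    only one spiking sweep existed and it was used instead.
    """
    spiking = _spiking_depolarizing(series, rest)
    if not spiking:
        raise MeasureUnavailable("no spiking depolarizing sweep")
    if len(spiking) == 1:
        sw, ev = spiking[0]
        return sw, ev, True
    sw, ev = spiking[1]
    return sw, ev, False


def adaptation(series: RecordingSeries, rest: float) -> tuple[float, str, bool]:
    """Adaptation index on the selected sweep; returns (value, sweep_id, fallback)."""
    sw, events, fallback = select_adaptation_sweep(series, rest)
    times = np.array([e.time - sw.step_onset for e in events])
    return adaptation_index(times, sw.step_duration), sw.sweep_id, fallback


def isi_cv(series: RecordingSeries, rest: float) -> tuple[float, str]:
    """Coefficient of variation of ISIs on the sweep with the most spikes.

    Needs at least 4 intervals; onset-only cells are reported missing.
    Returns (CV, sweep_id).
    """
    spiking = _spiking_depolarizing(series, rest)
    if not spiking:
        raise MeasureUnavailable("no spiking depolarizing sweep")
    sw, events = max(spiking, key=lambda p: len(p[1]))
    if len(events) < MIN_CV_INTERVALS + 1:
        raise MeasureUnavailable(
            f"fewer than {MIN_CV_INTERVALS} interspike intervals "
            f"(max {len(events)} spikes on one sweep)"
        )
    isis = np.diff([e.time for e in events])
    return float(np.std(isis, ddof=1) / np.mean(isis)), sw.sweep_id


def rebound_count(
    series: RecordingSeries, rest: float, window: float = REBOUND_WINDOW_S
) -> int:
    """Maximum number of spikes within ``window`` after hyperpolarizing offsets."""
    hyper = [
        sw
        for sw in series.hyperpolarizing()
        if sw.duration - sw.step_offset >= MIN_REBOUND_TAIL_S
    ]
    if not hyper:
        raise MeasureUnavailable("no hyperpolarizing sweep with a post-step window")
    best = 0
    for sw in hyper:
        events = detect_spikes(sw, rest=rest)
        n = sum(1 for e in events if sw.step_offset < e.time <= sw.step_offset + window)
        best = max(best, n)
    return best


def fi_slope(series: RecordingSeries, rest: float) -> tuple[float, bool]:
    """Slope of firing rate vs current over the 3 lowest suprathreshold levels.

    Rate = in-step spike count / step duration (spikes/s); slope in
    spikes/s per nA.  With only two spiking levels the slope comes from two
    points and the provenance flag is set.
    """
    spiking = _spiking_depolarizing(series, rest)
    if len(spiking) < 2:
        raise MeasureUnavailable("fewer than 2 suprathreshold current levels with spikes")
    pts = [(sw.step_amplitude, len(ev) / sw.step_duration) for sw, ev in spiking[:3]]
    currents, rates = zip(*pts)
    slope = float(np.polyfit(currents, rates, 1)[0])
    return slope, len(pts) == 2
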