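"""Synthetic cohorts for the six cochlear-nucleus cell classes.

Two levels of synthesis, both anchored to the reference class-mean profiles
of the six principal classes (bushy, planar multipolar, radiate multipolar,
pyramidal, cartwheel, tuberculoventral):

* :func:`sample_feature_table` draws feature vectors directly from
  per-class multivariate distributions (Gaussian copula; normal margins on
  unbounded measures, lognormal on strictly positive ones, logit-normal on
  the sag ratio).  Bushy ISI-CV is emitted as missing, as it is for real
  onset-only cells.
* :func:`simulate_recording` builds full current-clamp sweep series.  The
  subthreshold response is a phenomenological kernel
  ``D(t) = A * (1 - exp(-t/tau_m)) * (B + (1-B) * exp(-t/tau_h))`` whose
  sag parameter ``B`` is calibrated so the *measured* steady-state/peak
  ratio equals the class B/A target (the finite membrane rise otherwise
  inflates the measured ratio).  Suprathreshold sweeps insert stereotyped
  action-potential templates whose amplitude and width are solved per spike
  from the local baseline so that the extracted peak, half-width and AHP
  hit their targets; spike times follow the class program (onset-only
  bursts, or sustained trains whose time-warp fixes the adaptation index
  and whose renewal-ISI shape fixes the CV).  Traces are emitted raw
  (junction potential not yet applied): the resting level is offset by
  +11 mV so that correction recovers the target RMP.

Depolarizing drive saturates at 12 mV above rest — a stand-in for the
rectification that keeps real cells from depolarizing linearly at 4 nA —
while hyperpolarizing responses stay linear, as the passive measures assume.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml
from scipy.optimize import brentq

from .io import write_recording_h5
from .passive import membrane_tau
from .recordings import PRINCIPAL_CLASSES, RecordingSeries, Sweep
from .tables import MEASURES, FeatureTable, feature_table_from_rows, write_feature_table

#: Per-class target means for the 12 measures (classification units:
#: mV, ms, MOhm, dimensionless, counts, spikes/s/nA).  Bushy CV is
#: undefined (onset-only firing).
CLASS_TARGETS: dict[str, dict[str, float]] = {
    "bushy": dict(RMP=-62.5, tau_m=1.29, R_in=27.5, tau_h=27.5, BA_ratio=0.50,
                  AP_peak=-27.6, AP_halfwidth=1.32, AHP=-57.7, adaptation=0.96,
                  rebound=0.33, CV=math.nan, I_rate=5.8),
    "planar_multipolar": dict(RMP=-62.7, tau_m=4.90, R_in=87.9, tau_h=40.0, BA_ratio=0.63,
                              AP_peak=6.7, AP_halfwidth=0.26, AHP=-69.2, adaptation=0.05,
                              rebound=1.10, CV=0.05, I_rate=1232.0),
    "radiate_multipolar": dict(RMP=-63.1, tau_m=2.83, R_in=60.1, tau_h=12.1, BA_ratio=0.39,
                               AP_peak=5.9, AP_halfwidth=0.28, AHP=-68.3, adaptation=0.21,
                               rebound=1.17, CV=0.07, I_rate=1158.0),
    "pyramidal": dict(RMP=-68.5, tau_m=8.04, R_in=68.8, tau_h=51.0, BA_ratio=0.59,
                      AP_peak=2.2, AP_halfwidth=0.40, AHP=-64.6, adaptation=0.10,
                      rebound=1.37, CV=0.10, I_rate=412.0),
    "cartwheel": dict(RMP=-75.2, tau_m=5.25, R_in=79.6, tau_h=56.9, BA_ratio=0.95,
                      AP_peak=2.9, AP_halfwidth=0.83, AHP=-53.8, adaptation=0.22,
                      rebound=1.37, CV=0.71, I_rate=768.0),
    "tuberculoventral": dict(RMP=-67.9, tau_m=12.71, R_in=155.6, tau_h=74.4, BA_ratio=0.71,
                             AP_peak=-6.9, AP_halfwidth=0.35, AHP=-62.1, adaptation=0.13,
                             rebound=11.41, CV=0.14, I_rate=1148.0),
}

#: Qualitative firing program per class.
CLASS_PROGRAMS = {
    "bushy": "onset",
    "planar_multipolar": "regular",
    "radiate_multipolar": "adapting",
    "pyramidal": "regular",
    "cartwheel": "bursting",
    "tuberculoventral": "regular",
}

#: Default per-class cell counts (cohort of 162).
DEFAULT_COUNTS = {
    "bushy": 18,
    "planar_multipolar": 31,
    "radiate_multipolar": 32,
    "pyramidal": 38,
    "cartwheel": 12,
    "tuberculoventral": 31,
}

LOGNORMAL_MEASURES = {"tau_m", "R_in", "tau_h", "AP_halfwidth", "CV", "I_rate", "rebound"}
LOGIT_MEASURES = {"BA_ratio"}        # bounded in (0, 1)
SYM_LOGIT_MEASURES = {"adaptation"}  # bounded in (-1, 1)

DISPERSION_FACTOR = 0.4
JP_OFFSET_MV = 11.0  # raw traces sit this far above corrected targets
V_SAT_MV = 12.0      # depolarizing-drive saturation above rest
R_MAX_SPIKES_S = 350.0
ONSET_MAX_SPIKES = 3
ONSET_SPACING_S = 0.005
REBOUND_DELAY_S = 0.004
REBOUND_SPACING_S = 0.008
THRESHOLD_RATE_SUSTAINED = 20.0  # spikes/s at the threshold level
THRESHOLD_RATE_ONSET = 4.0


class ProgramInfeasible(ValueError):
    """The requested firing program cannot be realized as a trace."""


def default_dispersions(targets: dict[str, dict[str, float]] | None = None) -> dict[str, float]:
    """Within-class SD per measure: 0.4 x the between-class SD of the means."""
    targets = targets or CLASS_TARGETS
    out = {}
    for m in MEASURES:
        vals = np.array([t[m] for t in targets.values()])
        vals = vals[np.isfinite(vals)]
        out[m] = DISPERSION_FACTOR * float(np.std(vals, ddof=1))
    return out


@dataclass(frozen=True)
class ClassArchetype:
    """Targets and firing program for one cell class."""

    name: str
    targets: dict[str, float]
    program: str
    dispersion: dict[str, float]
    rin_taum_correlation: float = 0.5

    def __post_init__(self) -> None:
        t = self.targets
        if not (-90.0 <= t["RMP"] <= -45.0):
            raise ValueError(f"{self.name}: RMP {t['RMP']} mV outside [-90, -45]")
        for key in ("tau_m", "tau_h", "R_in"):
            if not t[key] > 0:
                raise ValueError(f"{self.name}: {key} must be positive")
        if not (0.0 < t["BA_ratio"] <= 1.0):
            raise ValueError(f"{self.name}: BA_ratio {t['BA_ratio']} outside (0, 1]")
        if any(s < 0 for s in self.dispersion.values()):
            raise ValueError(f"{self.name}: dispersions must be >= 0")

    @property
    def rebound_n(self) -> int:
        return int(round(self.targets["rebound"]))


def default_archetypes(dispersion_scale: float = 1.0) -> dict[str, ClassArchetype]:
    disp = default_dispersions()
    return {
        name: ClassArchetype(
            name=name,
            targets=dict(CLASS_TARGETS[name]),
            program=CLASS_PROGRAMS[name],
            dispersion={m: dispersion_scale * s for m, s in disp.items()},
        )
        for name in PRINCIPAL_CLASSES
    }


def load_archetypes(path) -> dict[str, ClassArchetype]:
    """Load archetype definitions from a YAML file (same schema as shipped)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    disp_default = default_dispersions()
    out = {}
    for name, spec in raw["classes"].items():
        targets = {m: (math.nan if spec["targets"].get(m) is None else float(spec["targets"][m]))
                   for m in MEASURES}
        out[name] = ClassArchetype(
            name=name,
            targets=targets,
            program=spec.get("program", "regular"),
            dispersion={m: float(spec.get("dispersion", {}).get(m, disp_default[m]))
                        for m in MEASURES},
        )
    return out


@dataclass(frozen=True)
class ProtocolSpec:
    """Square-step stimulation protocol."""

    baseline_s: float = 0.100
    step_duration_s: float = 0.500
    tail_s: float = 0.200
    sample_rate_hz: float = 20000.0
    delta_i_na: float = 0.1
    deep_step_na: float = -1.0
    max_step_na: float = 4.0
    small_deflections_mv: tuple[float, ...] = (1.5, 2.5, 3.5, 6.0, 9.0)
    n_graded_levels: int = 4
    noise_sd_mv: float = 0.3


@dataclass(frozen=True)
class CohortManifest:
    """Per-class counts plus the protocol and seed of a synthetic cohort."""

    counts: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_COUNTS))
    seed: int = 0
    protocol: ProtocolSpec = field(default_factory=ProtocolSpec)
    strains: tuple[str, str] = ("CBA", "NF107")

    def __post_init__(self) -> None:
        if any(n < 0 for n in self.counts.values()):
            raise ValueError("cell counts must be >= 0")

    @property
    def total(self) -> int:
        return sum(self.counts.values())


# ---------------------------------------------------------------------------
# feature-level sampling


_GH_X, _GH_W = np.polynomial.hermite.hermgauss(41)
_logit_mu_cache: dict[tuple, float] = {}


def _logit_mu_for_mean(m: float, s: float) -> float:
    """Location on the logit scale so E[sigmoid(mu + s*Z)] equals ``m``.

    Solved by Gauss-Hermite quadrature; the naive delta-method location is
    badly off near the interval bounds (e.g. a 0.95 target with our default
    dispersion would otherwise come out around 0.88).
    """
    key = (round(m, 6), round(s, 6))
    if key not in _logit_mu_cache:
        gx = _GH_X * math.sqrt(2.0) * s

        def mean_of(mu):
            return float(np.sum(_GH_W / (1.0 + np.exp(-(mu + gx))))) / math.sqrt(math.pi)

        _logit_mu_cache[key] = brentq(lambda mu: mean_of(mu) - m, -60.0, 60.0)
    return _logit_mu_cache[key]


def _margin_draw(measure: str, mean: float, sd: float, z: np.ndarray) -> np.ndarray:
    """Map standard-normal draws onto the measure's marginal distribution.

    Every margin is mean-exact: lognormal and logit-normal parameters are
    chosen so the distribution's mean equals the target, not its median.
    """
    if not math.isfinite(mean):
        return np.full(z.shape, np.nan)
    if sd == 0:
        return np.full(z.shape, mean)
    if measure in LOGNORMAL_MEASURES:
        if mean <= 0:
            return np.full(z.shape, mean)
        sigma2 = math.log1p((sd / mean) ** 2)
        mu = math.log(mean) - sigma2 / 2.0
        return np.exp(mu + math.sqrt(sigma2) * z)
    if measure in LOGIT_MEASURES or measure in SYM_LOGIT_MEASURES:
        # map a (-1,1)-bounded measure onto (0,1) and back
        lo, span = (-1.0, 2.0) if measure in SYM_LOGIT_MEASURES else (0.0, 1.0)
        m = min(max((mean - lo) / span, 1e-4), 1 - 1e-4)
        s = sd / span / (m * (1 - m))  # delta-method scale on the logit axis
        mu = _logit_mu_for_mean(m, s)
        return lo + span / (1.0 + np.exp(-(mu + s * z)))
    return mean + sd * z


def sample_feature_table(
    archetypes: dict[str, ClassArchetype] | None = None,
    manifest: CohortManifest | None = None,
    seed: int | None = None,
) -> FeatureTable:
    """Draw a cells x 12-measures cohort from the class archetypes.

    Correlation structure is a Gaussian copula; by default only R_in and
    tau_m are correlated (rho = 0.5).
    """
    archetypes = archetypes or default_archetypes()
    manifest = manifest or CohortManifest()
    rng = np.random.default_rng(manifest.seed if seed is None else seed)
    rows = []
    for name, n in manifest.counts.items():
        arch = archetypes[name]
        corr = np.eye(len(MEASURES))
        i_rin, i_taum = MEASURES.index("R_in"), MEASURES.index("tau_m")
        corr[i_rin, i_taum] = corr[i_taum, i_rin] = arch.rin_taum_correlation
        try:
            L = np.linalg.cholesky(corr)
        except np.linalg.LinAlgError:
            raise ValueError(f"{name}: correlation matrix is not positive definite")
        Z = rng.standard_normal((n, len(MEASURES))) @ L.T
        draws = {
            m: _margin_draw(m, arch.targets[m], arch.dispersion[m], Z[:, j])
            for j, m in enumerate(MEASURES)
        }
        for i in range(n):
            row = {"cell_id": f"{name}_{i:03d}", "class_label": name,
                   "strain": manifest.strains[0] if i < n / 2 else manifest.strains[1],
                   "sex": ""}
            row.update({m: float(draws[m][i]) for m in MEASURES})
            rows.append(row)
    return feature_table_from_rows(rows)


# ---------------------------------------------------------------------------
# trace-level simulation


def _sag_factor(t: np.ndarray, tau_m: float, tau_h: float, b: float) -> np.ndarray:
    return (1.0 - np.exp(-t / tau_m)) * (b + (1.0 - b) * np.exp(-t / tau_h))


def calibrate_sag(tau_m_s: float, tau_h_s: float, duration_s: float, ba_target: float):
    """Solve the kernel sag parameter so the measured B/A hits the target.

    Returns (b, ss_factor, peak_factor): the steady-state factor is the mean
    over the final 10% of the step (matching the measurement convention) and
    the peak factor the kernel maximum.
    """
    t = np.linspace(1e-6, duration_s, 2001)
    n_ss = max(1, int(0.1 * t.size))

    def measured(b):
        f = _sag_factor(t, tau_m_s, tau_h_s, b)
        return float(np.mean(f[-n_ss:])) / float(np.max(f))

    lo, hi = 1e-4, 0.9999
    if measured(hi) < ba_target:  # essentially no sag resolvable
        b = hi
    else:
        b = brentq(lambda x: measured(x) - ba_target, lo, hi, xtol=1e-8)
    f = _sag_factor(t, tau_m_s, tau_h_s, b)
    return b, float(np.mean(f[-n_ss:])), float(np.max(f))


def _measured_tau_m(tau_g_s: float, tau_h_s: float, b: float, t_d: float,
                    dt: float = 5e-5) -> float:
    """tau_m (ms) the extraction pipeline reports for a noiseless kernel."""
    n_base = int(round(0.025 / dt))
    t = np.arange(int(round(t_d / dt))) * dt
    f = _sag_factor(np.maximum(t, 1e-9), tau_g_s, tau_h_s, b)
    defl = -6.0 * f / f.max()
    tail = defl[-1] * np.exp(-np.arange(int(round(0.05 / dt))) * dt / tau_g_s)
    v = np.concatenate([np.zeros(n_base), defl, tail])
    sw = Sweep(sample_interval=dt, voltage=v, step_amplitude=-0.1,
               step_onset=n_base * dt, step_duration=t_d, sweep_id="cal")
    series = RecordingSeries(sweeps=(sw,), cell_id="cal", corrected=True)
    return membrane_tau(series, rest=0.0)


_kernel_cache: dict[tuple, tuple] = {}


def calibrate_kernel(tau_m_ms: float, tau_h_ms: float, ba: float, t_d: float):
    """Joint calibration of the subthreshold kernel.

    Solves (kernel tau, sag parameter b) so that the *extracted* tau_m and
    B/A equal the targets: the product kernel rises faster than its tau and
    sags past its nominal steady-state/peak ratio, so both parameters need
    an inverse correction.  Returns (tau_gen_s, b, ss_factor).
    """
    key = (round(tau_m_ms, 3), round(tau_h_ms, 2), round(ba, 4), round(t_d, 4))
    if key in _kernel_cache:
        return _kernel_cache[key]
    tau_h_s = tau_h_ms * 1e-3
    tau_t = tau_m_ms * 1e-3
    tau_g = tau_t
    b = ba
    for _ in range(3):
        b, ssf, _ = calibrate_sag(tau_g, tau_h_s, t_d, ba)

        def err(g):
            return _measured_tau_m(g, tau_h_s, b, t_d) - tau_m_ms

        lo, hi = 0.6 * tau_t, 4.0 * tau_t
        if err(hi) < 0:
            tau_g = hi
        elif err(lo) > 0:
            tau_g = lo
        else:
            tau_g = brentq(err, lo, hi, rtol=1e-3)
    b, ssf, _ = calibrate_sag(tau_g, tau_h_s, t_d, ba)
    _kernel_cache[key] = (tau_g, b, ssf)
    return _kernel_cache[key]


def _hyper_amplitudes(targets: dict, protocol: ProtocolSpec) -> list[float]:
    r_in = targets["R_in"]
    amps = [protocol.deep_step_na]
    amps += [-d / r_in for d in protocol.small_deflections_mv]
    i_sag = (-80.0 - targets["RMP"]) / r_in
    if i_sag < 0:
        amps.append(i_sag)
    amps = sorted(set(round(a, 9) for a in amps))
    # nudge near-duplicates apart so amplitudes stay strictly ascending
    out = []
    for a in amps:
        while out and a - out[-1] < 1e-4:
            a += 1.5e-4
        out.append(a)
    return out


def _depol_amplitudes(i_threshold: float, protocol: ProtocolSpec) -> list[float]:
    amps = [i_threshold + k * protocol.delta_i_na for k in range(protocol.n_graded_levels)]
    if protocol.max_step_na > amps[-1] + protocol.delta_i_na / 2:
        amps.append(protocol.max_step_na)
    return amps


def _warped_regular_times(n: int, t_d: float, ai: float) -> np.ndarray:
    """Deterministic adapting train with mean spike time t_d*(1 - ai)/2.

    Spike times are the quantiles of an exponentially decaying rate profile
    r(t) ~ exp(-t/tau_a) whose tau_a is solved from the target mean; unlike
    a power-law warp the density stays bounded at onset, so early intervals
    never collapse.  A final shift makes the realized mean exact.
    """
    m = (1.0 - ai) / 2.0 * t_d
    if n == 1:
        return np.array([m])
    u = (np.arange(n) + 0.5) / n
    m_frac = m / t_d
    flip = m_frac > 0.5
    if flip:
        m_frac = 1.0 - m_frac
    if abs(m_frac - 0.5) < 5e-3:
        t = u * t_d
    else:
        # mean/t_d of the exponential profile with x = t_d / tau_a
        def g(x):
            return 1.0 / x - math.exp(-x) / (1.0 - math.exp(-x))

        x = brentq(lambda x: g(x) - m_frac, 1e-6, 600.0)
        t = -(t_d / x) * np.log1p(-u * (1.0 - math.exp(-x)))
    if flip:
        t = t_d - t[::-1]
    t = t + ((1.0 - ai) / 2.0 * t_d - t.mean())
    return np.clip(t, 5e-4, t_d - 5e-4)


def _onset_times(n: int, t_d: float, ai: float) -> np.ndarray:
    m = (1.0 - ai) / 2.0 * t_d
    t = m + (np.arange(n) - (n - 1) / 2.0) * ONSET_SPACING_S
    return np.clip(t, 0.001, t_d - 0.001)


def _renewal_times(n: int, t_d: float, cv: float, rng: np.random.Generator) -> np.ndarray:
    """Gamma-renewal train with exactly n spikes and ISI CV ~ cv.

    ISIs are a refractory floor plus a gamma variate; the cumulative train
    is rescaled to span the step, which preserves the CV exactly and makes
    the realized count (hence the measured rate) deterministic.
    """
    mean_isi = t_d / n
    floor = min(0.002, 0.5 * mean_isi)
    if cv <= 0.005:
        return (np.arange(n) + 1.0) * mean_isi - mean_isi / 2.0
    sd = cv * mean_isi
    mean_g = mean_isi - floor
    shape = (mean_g / sd) ** 2
    scale = sd**2 / mean_g
    isis = floor + rng.gamma(shape, scale, size=n)
    t = np.cumsum(isis)
    return t * ((t_d - mean_isi / 2.0) / t[-1])


def _insert_spike(
    v: np.ndarray,
    dt: float,
    t_spike: float,
    peak_raw: float,
    level_raw: float,
    ahp_raw: float,
    halfwidth_ms: float,
) -> None:
    """Add one AP template at t_spike, solving width from the local base."""
    i_s = int(round(t_spike / dt))
    if not (0 <= i_s < v.size):
        return
    b = v[i_s]
    a = peak_raw - b
    if a < 1.0:
        return
    denom = level_raw - b
    hw_s = halfwidth_ms * 1e-3
    if denom > 0.05 * a:
        sigma = hw_s / (2.0 * math.sqrt(2.0 * math.log(a / denom)))
    else:
        sigma = hw_s / 2.355
    sigma = min(max(sigma, 1.2 * dt), 2e-3)
    half = int(math.ceil(5 * sigma / dt))
    i0, i1 = max(0, i_s - half), min(v.size, i_s + half + 1)
    tt = (np.arange(i0, i1) - i_s) * dt
    v[i0:i1] += a * np.exp(-(tt**2) / (2 * sigma**2))
    # afterhyperpolarization: alpha-function lobe starting only after the
    # falling phase has crossed the half-height level, so the lobe cannot
    # narrow the measured half-width; its minimum sits at t_start + delta
    delta = max(2.5 * sigma, 0.8e-3)
    t_start = 1.3 * hw_s / 2.0 + 2 * dt
    t_min = t_start + delta
    d_ahp = (b + a * math.exp(-(t_min**2) / (2 * sigma**2))) - ahp_raw
    if d_ahp > 0.3:
        j0 = i_s + int(math.ceil(t_start / dt))
        j1 = min(v.size, j0 + int(math.ceil(10 * delta / dt)) + 1)
        if j0 < v.size:
            ta = (np.arange(j0, j1) - i_s) * dt - t_start
            v[j0:j1] -= d_ahp * (ta / delta) * np.exp(1.0 - ta / delta)


def _sustained_counts(i_levels, slope, t_d):
    """Spike counts per depolarizing level for a sustained program."""
    i0 = i_levels[0]
    counts = []
    for i in i_levels:
        rate = min(R_MAX_SPIKES_S, THRESHOLD_RATE_SUSTAINED + slope * (i - i0))
        counts.append(max(1, int(round(rate * t_d))))
    return counts


def _onset_counts(i_levels, slope, t_d):
    i0 = i_levels[0]
    counts = []
    for i in i_levels:
        rate = THRESHOLD_RATE_ONSET + slope * (i - i0)
        counts.append(int(np.clip(round(rate * t_d), 1, ONSET_MAX_SPIKES)))
    return counts


def simulate_recording(
    archetype: ClassArchetype,
    manifest: CohortManifest | None = None,
    seed: int = 0,
    cell_id: str | None = None,
    return_truth: bool = False,
):
    """Simulate one cell's full current-clamp series from its archetype.

    The protocol adapts to the cell: small hyperpolarizing steps sized for
    3/6/9 mV steady-state deflections (input resistance and tau_m), one
    step targeting -80 mV steady state (sag), a deep step at -1 nA
    (rebound carrier), and graded depolarizing levels from threshold up to
    4 nA.  Traces are raw; apply the junction correction before measuring.
    """
    manifest = manifest or CohortManifest()
    protocol = manifest.protocol
    rng = np.random.default_rng(seed)
    t = archetype.targets
    fs, dt = protocol.sample_rate_hz, 1.0 / protocol.sample_rate_hz
    t_d = protocol.step_duration_s
    onset = protocol.baseline_s
    n_samp = int(round((protocol.baseline_s + t_d + protocol.tail_s) * fs))

    tau_h_s = t["tau_h"] * 1e-3
    tau_m_s, b_kernel, ss_factor = calibrate_kernel(
        t["tau_m"], t["tau_h"], t["BA_ratio"], t_d
    )
    r_pk = t["R_in"] / ss_factor
    rest_raw = t["RMP"] + JP_OFFSET_MV
    peak_raw = t["AP_peak"] + JP_OFFSET_MV
    ahp_raw = t["AHP"] + JP_OFFSET_MV
    height = t["AP_peak"] - t["RMP"]
    level_raw = rest_raw + height / 2.0

    hyper = _hyper_amplitudes(t, protocol)
    i_threshold = 1.2 * V_SAT_MV / r_pk
    depol = _depol_amplitudes(i_threshold, protocol)
    onset_prog = archetype.program == "onset"
    counter = (_onset_counts if onset_prog else _sustained_counts)
    counts = counter(depol, max(t["I_rate"], 0.0), t_d)
    cv_target = t.get("CV", math.nan)
    if not math.isfinite(cv_target):
        cv_target = 0.05
    ai = float(np.clip(t["adaptation"], -0.9, 0.97))

    time = np.arange(n_samp) * dt
    in_step = (time >= onset) & (time < onset + t_d)
    post = time >= onset + t_d
    tt_step = time[in_step] - onset
    tt_post = time[post] - (onset + t_d)
    kernel = _sag_factor(np.maximum(tt_step, 1e-9), tau_m_s, tau_h_s, b_kernel)

    sweeps = []
    truth_spikes: dict[str, np.ndarray] = {}
    deep_amp = hyper[0]
    all_amps = hyper + depol
    for k, amp in enumerate(all_amps):
        if amp <= 0:
            drive = amp * r_pk
        else:
            drive = V_SAT_MV * math.tanh(amp * r_pk / V_SAT_MV)
        v = np.full(n_samp, rest_raw)
        v[in_step] += drive * kernel
        v[post] += drive * kernel[-1] * np.exp(-tt_post / tau_m_s)
        sweep_id = f"sw{k:02d}_{amp:+.4f}nA"
        spike_rel = np.empty(0)
        if amp > 0:
            level_idx = depol.index(amp)
            n_spikes = counts[level_idx]
            if onset_prog:
                spike_rel = _onset_times(n_spikes, t_d, ai)
            elif level_idx <= 1:
                spike_rel = _warped_regular_times(n_spikes, t_d, ai)
            else:
                spike_rel = _renewal_times(n_spikes, t_d, cv_target, rng)
            sigma_nominal = t["AP_halfwidth"] * 1e-3 / 2.355
            if spike_rel.size > 1 and np.min(np.diff(spike_rel)) < 2.8 * sigma_nominal:
                raise ProgramInfeasible(
                    f"{archetype.name}: AP template (halfwidth {t['AP_halfwidth']} ms) "
                    f"wider than the shortest ISI at {amp:+.3f} nA"
                )
            for ts in spike_rel:
                _insert_spike(v, dt, onset + ts, peak_raw, level_raw, ahp_raw,
                              t["AP_halfwidth"])
        elif amp == deep_amp and archetype.rebound_n > 0:
            reb = onset + t_d + REBOUND_DELAY_S + np.arange(archetype.rebound_n) * REBOUND_SPACING_S
            spike_rel = reb - onset
            for ts in reb:
                _insert_spike(v, dt, ts, peak_raw, level_raw, ahp_raw, t["AP_halfwidth"])
        if protocol.noise_sd_mv > 0:
            v = v + rng.normal(0.0, protocol.noise_sd_mv, size=n_samp)
        truth_spikes[sweep_id] = spike_rel
        sweeps.append(
            Sweep(sample_interval=dt, voltage=v, step_amplitude=amp,
                  step_onset=onset, step_duration=t_d, sweep_id=sweep_id)
        )
    series = RecordingSeries(
        sweeps=tuple(sweeps),
        cell_id=cell_id or f"{archetype.name}_sim{seed}",
        class_label=archetype.name if archetype.name in PRINCIPAL_CLASSES else "other",
        junction_potential=-JP_OFFSET_MV,
        corrected=False,
    )
    if not return_truth:
        return series
    rates = [c / t_d for c in counts]
    truth = {
        "targets": dict(t),
        "rebound_n": archetype.rebound_n if archetype.rebound_n > 0 else 0,
        "spike_times": truth_spikes,
        "depol_levels": depol,
        "counts": counts,
        "realized_fi_slope": float(np.polyfit(depol[:3], rates[:3], 1)[0]),
    }
    return series, truth


# ---------------------------------------------------------------------------
# fixture cohorts


_FEASIBLE_CLIPS = {
    "RMP": (-85.0, -50.0),
    "tau_m": (0.4, 20.0),
    "R_in": (10.0, 400.0),
    "tau_h": (5.0, 120.0),
    "BA_ratio": (0.15, 0.92),
    "AP_halfwidth": (0.15, 1.8),
    "CV": (0.02, 1.2),
    "I_rate": (0.0, 2000.0),
    "rebound": (0.0, 12.0),
}


def _feasible_cell_targets(arch: ClassArchetype, row: dict) -> dict:
    """Clip a sampled feature row into trace-program-feasible ranges."""
    t = {}
    for m in MEASURES:
        val = row[m]
        if m in _FEASIBLE_CLIPS and math.isfinite(val):
            lo, hi = _FEASIBLE_CLIPS[m]
            val = float(np.clip(val, lo, hi))
        t[m] = val
    if arch.program == "onset":
        t["adaptation"] = float(np.clip(t["adaptation"], 0.90, 0.97))
        t["CV"] = math.nan
    else:
        t["adaptation"] = float(np.clip(t["adaptation"], -0.30, 0.60))
        # sustained trains at the capped rate need templates narrower than
        # the refractory floor of the renewal program
        t["AP_halfwidth"] = min(t["AP_halfwidth"], 1.0)
    t["AP_peak"] = max(t["AP_peak"], t["RMP"] + 25.0)
    t["AHP"] = float(np.clip(t["AHP"], t["RMP"] - 12.0, t["RMP"] + 8.0))
    t["rebound"] = float(round(t["rebound"]))
    return t


def make_fixture_cohort(
    outdir,
    seed: int = 0,
    n_per_class: int = 5,
    manifest: CohortManifest | None = None,
    dispersion_scale: float = 0.5,
    write: bool = True,
):
    """Simulate a small on-disk cohort plus its ground-truth table.

    Per-cell targets are drawn from the class archetypes (at reduced
    dispersion so every drawn program stays feasible) and each cell is
    simulated at its own targets.  Returns (recordings, truth_table).
    """
    outdir = Path(outdir)
    archetypes = default_archetypes(dispersion_scale=dispersion_scale)
    counts = {name: n_per_class for name in PRINCIPAL_CLASSES}
    manifest = manifest or CohortManifest(counts=counts, seed=seed)
    manifest = replace(manifest, counts=counts, seed=seed)
    sampled = sample_feature_table(archetypes, manifest, seed=seed)
    recordings = []
    truth_rows = []
    for i, cell_id in enumerate(sampled.cell_ids):
        name = sampled.labels[cell_id]
        arch = archetypes[name]
        row = sampled.values.loc[cell_id].to_dict()
        targets = _feasible_cell_targets(arch, row)
        cell_arch = ClassArchetype(
            name=name, targets=targets, program=arch.program, dispersion=arch.dispersion
        )
        series = simulate_recording(
            cell_arch, manifest=manifest, seed=seed * 100003 + i, cell_id=cell_id
        )
        recordings.append(series)
        truth_rows.append({"cell_id": cell_id, "class_label": name,
                           "program": arch.program, **targets})
    truth = feature_table_from_rows(
        [{k: v for k, v in r.items() if k != "program"} for r in truth_rows]
    )
    if write:
        outdir.mkdir(parents=True, exist_ok=True)
        for series in recordings:
            write_recording_h5(series, outdir / f"{series.cell_id}.h5")
        write_feature_table(truth, outdir / "truth.tsv")
    return recordings, truth
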