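"""Data model for current-clamp step recordings.

A recording is an ordered set of sweeps, each pairing a membrane-voltage
trace with the square current step that evoked it.  Internal units are
fixed: voltages in mV, currents in nA, times in seconds.  Converters live
at the I/O boundary (:mod:`cnephys.io`), never here.

Absolute voltages carry a liquid-junction-potential error for K-gluconate
electrodes; :func:`apply_junction_correction` shifts every sample by the
junction potential (default -11 mV) exactly once.  Differential measures
(spike height, step deflections) are unaffected by the shift.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import numpy as np

#: The six principal cell classes that enter classification.
PRINCIPAL_CLASSES = (
    "bushy",
    "planar_multipolar",
    "radiate_multipolar",
    "pyramidal",
    "cartwheel",
    "tuberculoventral",
)

#: Closed label vocabulary; rare excluded types are carried as "other".
CLASS_LABELS = PRINCIPAL_CLASSES + ("other", "unknown")

DEFAULT_JUNCTION_POTENTIAL_MV = -11.0


class RecordingError(ValueError):
    """Raised for structurally invalid recordings or sweeps."""


@dataclass(frozen=True)
class Sweep:
    """One voltage trace with its square current-step command.

    Parameters
    ----------
    sample_interval : float
        Sampling interval in seconds (e.g. 5e-5 for 20 kHz).
    voltage : numpy.ndarray
        Membrane voltage in mV, one value per sample.
    step_amplitude : float
        Current-step amplitude in nA (negative = hyperpolarizing).
    step_onset, step_duration : float
        Step timing in seconds from the start of the trace.
    sweep_id : str
        Opaque label used in provenance and error messages.
    """

    sample_interval: float
    voltage: np.ndarray
    step_amplitude: float
    step_onset: float
    step_duration: float
    sweep_id: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.voltage, dtype=float)
        object.__setattr__(self, "voltage", v)
        sid = self.sweep_id or "<unnamed sweep>"
        if not self.sample_interval > 0:
            raise RecordingError(f"sweep {sid}: sample_interval must be > 0")
        if v.ndim != 1 or v.size == 0:
            raise RecordingError(f"sweep {sid}: voltage must be a non-empty 1-D array")
        if not np.all(np.isfinite(v)):
            raise RecordingError(f"sweep {sid}: voltage contains non-finite samples")
        if self.step_onset < 0:
            raise RecordingError(f"sweep {sid}: step_onset must be >= 0")
        if self.step_onset + self.step_duration > self.duration + 1e-12:
            raise RecordingError(
                f"sweep {sid}: step extends past the end of the trace "
                f"({self.step_onset + self.step_duration:.4f} s > {self.duration:.4f} s)"
            )

    @property
    def n_samples(self) -> int:
        return self.voltage.size

    @property
    def duration(self) -> float:
        """Trace duration in seconds."""
        return self.voltage.size * self.sample_interval

    @property
    def step_offset(self) -> float:
        return self.step_onset + self.step_duration

    def time(self) -> np.ndarray:
        """Sample times in seconds from the trace start."""
        return np.arange(self.voltage.size) * self.sample_interval

    def index_at(self, t: float) -> int:
        """Sample index at time ``t`` (clipped into the trace)."""
        return int(np.clip(round(t / self.sample_interval), 0, self.voltage.size - 1))

    def baseline(self) -> np.ndarray:
        """Pre-step voltage samples (empty if the step starts at t=0)."""
        return self.voltage[: self.index_at(self.step_onset)]

    def step_window(self) -> slice:
        """Slice covering the step, from onset to offset."""
        return slice(self.index_at(self.step_onset), self.index_at(self.step_offset) + 1)


@dataclass(frozen=True)
class RecordingSeries:
    """Ordered sweeps from one cell, with identity metadata.

    Invariants: all sweeps share sampling geometry (interval, onset,
    duration) and step amplitudes are strictly ascending.  The junction
    correction can be applied at most once (tracked by ``corrected``).
    """

    sweeps: tuple[Sweep, ...]
    cell_id: str
    class_label: str = "unknown"
    strain: str = ""
    sex: str = ""
    junction_potential: float = DEFAULT_JUNCTION_POTENTIAL_MV
    corrected: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "sweeps", tuple(self.sweeps))
        if not self.sweeps:
            raise RecordingError(f"cell {self.cell_id}: series has no sweeps")
        if self.class_label not in CLASS_LABELS:
            raise RecordingError(
                f"cell {self.cell_id}: unknown class label {self.class_label!r}; "
                f"expected one of {CLASS_LABELS}"
            )
        ref = self.sweeps[0]
        for sw in self.sweeps[1:]:
            for attr in ("sample_interval", "step_onset", "step_duration"):
                if not np.isclose(getattr(sw, attr), getattr(ref, attr), rtol=1e-9, atol=1e-12):
                    raise RecordingError(
                        f"cell {self.cell_id}: sweep {sw.sweep_id or '?'} disagrees in {attr} "
                        f"({getattr(sw, attr)!r} vs {getattr(ref, attr)!r})"
                    )
        amps = [sw.step_amplitude for sw in self.sweeps]
        if not all(a < b for a, b in zip(amps, amps[1:])):
            raise RecordingError(
                f"cell {self.cell_id}: step amplitudes must be strictly ascending, got {amps}"
            )

    def __iter__(self) -> Iterator[Sweep]:
        return iter(self.sweeps)

    def __len__(self) -> int:
        return len(self.sweeps)

    @property
    def sample_interval(self) -> float:
        return self.sweeps[0].sample_interval

    @property
    def step_onset(self) -> float:
        return self.sweeps[0].step_onset

    @property
    def step_duration(self) -> float:
        return self.sweeps[0].step_duration

    def hyperpolarizing(self) -> tuple[Sweep, ...]:
        return tuple(sw for sw in self.sweeps if sw.step_amplitude < 0)

    def depolarizing(self) -> tuple[Sweep, ...]:
        return tuple(sw for sw in self.sweeps if sw.step_amplitude > 0)


def apply_junction_correction(
    series: RecordingSeries, jp_mV: float | None = None
) -> RecordingSeries:
    """Shift every voltage sample by the junction potential.

    ``jp_mV`` defaults to the series' own ``junction_potential``.  Raises
    :class:`RecordingError` if the series was already corrected, so the
    shift can never be applied twice.
    """
    if series.corrected:
        raise RecordingError(
            f"cell {series.cell_id}: junction correction already applied"
        )
    jp = series.junction_potential if jp_mV is None else float(jp_mV)
    sweeps = tuple(replace(sw, voltage=sw.voltage + jp) for sw in series.sweeps)
    return replace(series, sweeps=sweeps, junction_potential=jp, corrected=True)
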