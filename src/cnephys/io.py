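"""Readers and writers for recording containers.

Two on-disk dialects are supported, both defined by this package:

``hdf5`` sweep-table
    One HDF5 file per cell.  Root attributes: ``cell_id``, ``class_label``,
    ``strain``, ``sex``, ``junction_potential`` (mV), ``corrected``,
    ``voltage_unit`` ("mV" or "V"), ``current_unit`` ("nA" or "pA" or "A").
    Group ``/sweeps/<name>`` holds a 1-D ``voltage`` dataset with attributes
    ``sample_interval`` (s), ``step_amplitude``, ``step_onset`` (s),
    ``step_duration`` (s), and ``order`` (integer position).

``tsv`` sweep dump
    A plain-text file: ``#``-prefixed JSON header lines (one ``meta`` object
    and one ``sweeps`` list carrying the step metadata), then a tab-separated
    matrix ``time`` + one voltage column per sweep.

Voltages are normalized to mV and currents to nA on read regardless of the
on-disk unit, so unit normalization is idempotent by construction.
"""
from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from .recordings import RecordingSeries, Sweep

_VOLT_SCALE = {"mV": 1.0, "V": 1000.0}
_CURR_SCALE = {"nA": 1.0, "pA": 1e-3, "A": 1e9}


class UnsupportedDialect(ValueError):
    """Raised for a recording dialect this package does not read."""


def _scale(unit: str, table: dict, kind: str) -> float:
    try:
        return table[unit]
    except KeyError:
        raise UnsupportedDialect(f"unknown {kind} unit {unit!r}; expected one of {sorted(table)}")


def write_recording_h5(series: RecordingSeries, path) -> None:
    """Write a series in the HDF5 sweep-table layout (mV / nA on disk)."""
    with h5py.File(path, "w") as f:
        f.attrs["cell_id"] = series.cell_id
        f.attrs["class_label"] = series.class_label
        f.attrs["strain"] = series.strain
        f.attrs["sex"] = series.sex
        f.attrs["junction_potential"] = series.junction_potential
        f.attrs["corrected"] = bool(series.corrected)
        f.attrs["voltage_unit"] = "mV"
        f.attrs["current_unit"] = "nA"
        g = f.create_group("sweeps")
        for i, sw in enumerate(series):
            # track_times=False keeps repeated writes byte-identical
            d = g.create_dataset(
                sw.sweep_id or f"sweep_{i:03d}", data=sw.voltage, track_times=False
            )
            d.attrs["order"] = i
            d.attrs["sample_interval"] = sw.sample_interval
            d.attrs["step_amplitude"] = sw.step_amplitude
            d.attrs["step_onset"] = sw.step_onset
            d.attrs["step_duration"] = sw.step_duration


def _read_h5(path) -> RecordingSeries:
    with h5py.File(path, "r") as f:
        vscale = _scale(str(f.attrs.get("voltage_unit", "mV")), _VOLT_SCALE, "voltage")
        cscale = _scale(str(f.attrs.get("current_unit", "nA")), _CURR_SCALE, "current")
        entries = []
        for name, d in f["sweeps"].items():
            for attr in ("sample_interval", "step_amplitude", "step_onset", "step_duration"):
                if attr not in d.attrs:
                    raise UnsupportedDialect(f"sweep {name!r} lacks step metadata {attr!r}")
            entries.append(
                (
                    int(d.attrs.get("order", len(entries))),
                    Sweep(
                        sample_interval=float(d.attrs["sample_interval"]),
                        voltage=np.asarray(d[...], dtype=float) * vscale,
                        step_amplitude=float(d.attrs["step_amplitude"]) * cscale,
                        step_onset=float(d.attrs["step_onset"]),
                        step_duration=float(d.attrs["step_duration"]),
                        sweep_id=name,
                    ),
                )
            )
        entries.sort(key=lambda e: e[0])
        return RecordingSeries(
            sweeps=tuple(sw for _, sw in entries),
            cell_id=str(f.attrs.get("cell_id", Path(path).stem)),
            class_label=str(f.attrs.get("class_label", "unknown")),
            strain=str(f.attrs.get("strain", "")),
            sex=str(f.attrs.get("sex", "")),
            junction_potential=float(f.attrs.get("junction_potential", -11.0)),
            corrected=bool(f.attrs.get("corrected", False)),
        )


def write_recording_tsv(series: RecordingSeries, path) -> None:
    """Write a series as a plain-text sweep dump."""
    meta = {
        "cell_id": series.cell_id,
        "class_label": series.class_label,
        "strain": series.strain,
        "sex": series.sex,
        "junction_potential": series.junction_potential,
        "corrected": series.corrected,
        "voltage_unit": "mV",
        "current_unit": "nA",
    }
    sweeps_meta = [
        {
            "sweep_id": sw.sweep_id or f"sweep_{i:03d}",
            "sample_interval": sw.sample_interval,
            "step_amplitude": sw.step_amplitude,
            "step_onset": sw.step_onset,
            "step_duration": sw.step_duration,
        }
        for i, sw in enumerate(series)
    ]
    n = max(sw.n_samples for sw in series)
    dt = series.sample_interval
    with open(path, "w") as fh:
        fh.write("# meta " + json.dumps(meta) + "\n")
        fh.write("# sweeps " + json.dumps(sweeps_meta) + "\n")
        fh.write("time\t" + "\t".join(m["sweep_id"] for m in sweeps_meta) + "\n")
        for i in range(n):
            row = [f"{i * dt:.9g}"]
            for sw in series:
                row.append(f"{sw.voltage[i]:.6g}" if i < sw.n_samples else "")
            fh.write("\t".join(row) + "\n")


def _read_tsv(path) -> RecordingSeries:
    meta = None
    sweeps_meta = None
    with open(path) as fh:
        lines = fh.readlines()
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("# meta "):
            meta = json.loads(line[len("# meta "):])
        elif line.startswith("# sweeps "):
            sweeps_meta = json.loads(line[len("# sweeps "):])
        elif not line.startswith("#"):
            body_start = i
            break
    if meta is None or sweeps_meta is None:
        raise UnsupportedDialect(f"{path}: missing '# meta'/'# sweeps' header lines")
    vscale = _scale(meta.get("voltage_unit", "mV"), _VOLT_SCALE, "voltage")
    cscale = _scale(meta.get("current_unit", "nA"), _CURR_SCALE, "current")
    header = lines[body_start].rstrip("\n").split("\t")
    cols = {name: [] for name in header}
    for line in lines[body_start + 1 :]:
        parts = line.rstrip("\n").split("\t")
        for name, val in zip(header, parts):
            if val != "":
                cols[name].append(float(val))
    sweeps = []
    for m in sweeps_meta:
        sid = m["sweep_id"]
        if sid not in cols:
            raise UnsupportedDialect(f"{path}: sweep {sid!r} has metadata but no data column")
        sweeps.append(
            Sweep(
                sample_interval=float(m["sample_interval"]),
                voltage=np.asarray(cols[sid], dtype=float) * vscale,
                step_amplitude=float(m["step_amplitude"]) * cscale,
                step_onset=float(m["step_onset"]),
                step_duration=float(m["step_duration"]),
                sweep_id=sid,
            )
        )
    return RecordingSeries(
        sweeps=tuple(sweeps),
        cell_id=meta.get("cell_id", Path(path).stem),
        class_label=meta.get("class_label", "unknown"),
        strain=meta.get("strain", ""),
        sex=meta.get("sex", ""),
        junction_potential=float(meta.get("junction_potential", -11.0)),
        corrected=bool(meta.get("corrected", False)),
    )


_READERS = {"hdf5": _read_h5, "tsv": _read_tsv}


def read_recording(path, dialect: str = "hdf5") -> RecordingSeries:
    """Read a validated :class:`RecordingSeries` from ``path``.

    ``dialect`` is one of ``"hdf5"`` or ``"tsv"``.  Voltages are returned in
    mV and currents in nA regardless of on-disk units.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        reader = _READERS[dialect]
    except KeyError:
        raise UnsupportedDialect(
            f"unknown dialect {dialect!r}; supported: {sorted(_READERS)}"
        )
    return reader(path)
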