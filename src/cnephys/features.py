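"""Assembly of the full 12-measure feature vector for one cell."""
from __future__ import annotations

from dataclasses import dataclass, field
from math import nan

from .passive import (
    MeasureUnavailable,
    input_resistance,
    membrane_tau,
    resting_potential,
    sag_ratio,
    sag_tau,
    select_sag_sweep,
)
from .recordings import RecordingSeries, apply_junction_correction
from .spikes import adaptation, ap_shape, fi_slope, isi_cv, rebound_count
from .tables import MEASURES


@dataclass
class CellFeatures:
    """The 12 measures for one cell, plus identity and provenance.

    Individual measures that could not be computed are NaN; the reason is
    recorded in ``provenance`` under the measure name.
    """

    cell_id: str
    class_label: str
    strain: str = ""
    sex: str = ""
    RMP: float = nan
    tau_m: float = nan
    R_in: float = nan
    tau_h: float = nan
    BA_ratio: float = nan
    AP_peak: float = nan
    AP_height: float = nan
    AP_halfwidth: float = nan
    AHP: float = nan
    adaptation: float = nan
    rebound: float = nan
    CV: float = nan
    I_rate: float = nan
    provenance: dict = field(default_factory=dict)

    def to_row(self) -> dict:
        row = {
            "cell_id": self.cell_id,
            "class_label": self.class_label,
            "strain": self.strain,
            "sex": self.sex,
        }
        row.update({m: getattr(self, m) for m in MEASURES})
        return row


def extract_all(series: RecordingSeries) -> CellFeatures:
    """Run every passive and active measure on one recording.

    The junction correction is applied first (if not already), so absolute
    potentials (RMP, AP peak, AHP) are reported corrected.  A failing
    measure becomes NaN with its reason in provenance; it never aborts the
    cell.
    """
    if not series.corrected:
        series = apply_junction_correction(series)
    feats = CellFeatures(
        cell_id=series.cell_id,
        class_label=series.class_label,
        strain=series.strain,
        sex=series.sex,
    )
    prov = feats.provenance

    try:
        feats.RMP = resting_potential(series)
        rest = feats.RMP
        prov["RMP"] = {"note": "mean pre-step baseline over all sweeps"}
    except MeasureUnavailable as exc:
        prov["RMP"] = {"missing": exc.reason}
        return feats  # nothing else is interpretable without a rest level

    def attempt(name, fn):
        try:
            return fn()
        except MeasureUnavailable as exc:
            prov[name] = {"missing": exc.reason}
            return None

    val = attempt("R_in", lambda: input_resistance(series, rest))
    if val is not None:
        feats.R_in = val
    val = attempt("tau_m", lambda: membrane_tau(series, rest))
    if val is not None:
        feats.tau_m = val
    val = attempt("tau_h", lambda: sag_tau(series, rest))
    if val is not None:
        feats.tau_h = val

    def _ba():
        try:
            sw = select_sag_sweep(series)
        except MeasureUnavailable:
            # fall back to the deepest hyperpolarizing sweep
            hyper = series.hyperpolarizing()
            if not hyper:
                raise MeasureUnavailable("no hyperpolarizing sweep")
            sw = hyper[0]
        prov["BA_ratio"] = {"sweeps": [sw.sweep_id]}
        return sag_ratio(sw, rest)

    val = attempt("BA_ratio", _ba)
    if val is not None:
        feats.BA_ratio = val

    def _shape():
        shape = ap_shape(series, rest)
        prov["AP_shape"] = {"sweeps": [shape["sweep_id"]]}
        return shape

    shape = attempt("AP_shape", _shape)
    if shape is not None:
        feats.AP_peak = shape["peak_V"]
        feats.AP_height = shape["height"]
        feats.AP_halfwidth = shape["halfwidth"]
        feats.AHP = shape["ahp_V"]

    def _adapt():
        value, sweep_id, fallback = adaptation(series, rest)
        prov["adaptation"] = {"sweeps": [sweep_id], "fallback": fallback}
        return value

    val = attempt("adaptation", _adapt)
    if val is not None:
        feats.adaptation = val

    def _cv():
        value, sweep_id = isi_cv(series, rest)
        prov["CV"] = {"sweeps": [sweep_id]}
        return value

    val = attempt("CV", _cv)
    if val is not None:
        feats.CV = val

    val = attempt("rebound", lambda: rebound_count(series, rest))
    if val is not None:
        feats.rebound = float(val)

    def _fi():
        slope, two_point = fi_slope(series, rest)
        prov["I_rate"] = {"two_point": two_point}
        return slope

    val = attempt("I_rate", _fi)
    if val is not None:
        feats.I_rate = val

    return feats
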