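"""Synthetic cohort generator: statistics, trace realism, closed loops."""
import math

import numpy as np
import pytest

from cnephys.features import extract_all
from cnephys.recordings import PRINCIPAL_CLASSES, apply_junction_correction
from cnephys.spikes import detect_spikes, spikes_in_step
from cnephys.synth import (
    CLASS_TARGETS,
    ClassArchetype,
    CohortManifest,
    ProgramInfeasible,
    ProtocolSpec,
    _sag_factor,
    default_archetypes,
    default_dispersions,
    load_archetypes,
    make_fixture_cohort,
    sample_feature_table,
    simulate_recording,
)
from cnephys.tables import MEASURES


class TestFeatureSampling:
    def test_default_cohort_size_and_counts(self):
        t = sample_feature_table(seed=0)
        assert len(t) == 162
        counts = t.labels.value_counts()
        assert counts["bushy"] == 18 and counts["planar_multipolar"] == 31
        assert counts["radiate_multipolar"] == 32 and counts["pyramidal"] == 38
        assert counts["cartwheel"] == 12 and counts["tuberculoventral"] == 31

    def test_zero_dispersion_reproduces_targets_exactly(self):
        archs = default_archetypes(dispersion_scale=0.0)
        man = CohortManifest(counts={"bushy": 3}, seed=0)
        t = sample_feature_table(archs, man)
        for m in MEASURES:
            tgt = CLASS_TARGETS["bushy"][m]
            if math.isfinite(tgt):
                np.testing.assert_allclose(t.values[m], tgt, atol=1e-12)
            else:
                assert t.values[m].isna().all()

    def test_bushy_cv_always_missing(self):
        t = sample_feature_table(seed=2)
        assert t.values.loc[t.labels == "bushy", "CV"].isna().all()
        assert t.values.loc[t.labels != "bushy", "CV"].notna().all()

    def test_sample_means_converge_to_targets(self):
        """Law of large numbers: class means within ~3 SE at n = 2000."""
        archs = default_archetypes()
        man = CohortManifest(counts={c: 2000 for c in PRINCIPAL_CLASSES}, seed=0)
        t = sample_feature_table(archs, man, seed=5)
        checked = violations = 0
        for name in PRINCIPAL_CLASSES:
            vals = t.values[t.labels == name]
            for m in MEASURES:
                tgt = archs[name].targets[m]
                if not math.isfinite(tgt):
                    continue
                x = vals[m]
                se = x.std(ddof=1) / np.sqrt(len(x))
                checked += 1
                violations += abs(x.mean() - tgt) > 3 * se
        assert checked == 71  # 6 classes x 12 measures minus bushy CV
        assert violations <= 3  # ~4% of 3-SE checks may exceed by chance

    def test_same_seed_reproduces_table(self):
        a = sample_feature_table(seed=9)
        b = sample_feature_table(seed=9)
        assert a.values.equals(b.values)

    def test_dispersion_defaults_scale_between_class_sd(self):
        disp = default_dispersions()
        for m in MEASURES:
            vals = [CLASS_TARGETS[c][m] for c in PRINCIPAL_CLASSES]
            vals = [v for v in vals if math.isfinite(v)]
            assert disp[m] == pytest.approx(0.4 * np.std(vals, ddof=1))

    def test_shipped_archetype_config_round_trips(self):
        from importlib import resources

        with resources.as_file(
            resources.files("cnephys") / "data" / "archetypes.yaml"
        ) as p:
            archs = load_archetypes(p)
        assert set(archs) == set(PRINCIPAL_CLASSES)
        for name, arch in archs.items():
            for m in MEASURES:
                tgt = CLASS_TARGETS[name][m]
                if math.isfinite(tgt):
                    assert arch.targets[m] == pytest.approx(tgt)

    def test_invalid_archetype_rejected(self):
        targets = dict(CLASS_TARGETS["bushy"], RMP=-20.0)
        with pytest.raises(ValueError, match="RMP"):
            ClassArchetype("bad", targets, "onset", default_dispersions())


class TestKernel:
    def test_steady_state_over_peak_converges_to_b(self):
        """In the separated-time-scale limit (tau_m << tau_h << duration)
        the kernel's steady-state/peak ratio approaches b exactly."""
        tau_h, b = 20e-3, 0.6
        errs = []
        for tau_m, mult in ((2e-3, 10), (2e-4, 30), (2e-5, 100)):
            t = np.linspace(1e-8, mult * tau_h, 400001)
            f = _sag_factor(t, tau_m, tau_h, b)
            errs.append(abs(f[-1] / f.max() - b))
        assert errs[0] > errs[1] > errs[2]
        assert errs[2] < 5e-3


class TestTraceSimulation:
    def test_planar_step_range_spans_minus1_to_4na(self):
        s = simulate_recording(default_archetypes()["planar_multipolar"], seed=0)
        amps = [sw.step_amplitude for sw in s]
        assert min(amps) == pytest.approx(-1.0)
        assert max(amps) == pytest.approx(4.0)
        assert sum(a < 0 for a in amps) >= 2 and sum(a > 0 for a in amps) >= 4

    def test_requested_spike_counts_are_detected(self):
        """Closed loop: every inserted in-step spike is found."""
        arch = default_archetypes()["tuberculoventral"]
        series, truth = simulate_recording(arch, seed=3, return_truth=True)
        series = apply_junction_correction(series)
        rest = arch.targets["RMP"]
        for sw in series.depolarizing():
            ev = spikes_in_step(sw, detect_spikes(sw, rest=rest))
            assert len(ev) == len(truth["spike_times"][sw.sweep_id])

    def test_noiseless_cartwheel_sag_ratio_on_target(self):
        man = CohortManifest(protocol=ProtocolSpec(noise_sd_mv=0.0))
        arch = default_archetypes()["cartwheel"]
        f = extract_all(simulate_recording(arch, manifest=man, seed=0))
        assert f.BA_ratio == pytest.approx(0.95, abs=0.01)

    def test_bushy_program_is_onset_dominated(self):
        f = extract_all(simulate_recording(default_archetypes()["bushy"], seed=4))
        assert f.adaptation >= 0.9
        assert math.isnan(f.CV)

    def test_same_seed_identical_traces(self):
        arch = default_archetypes()["pyramidal"]
        a = simulate_recording(arch, seed=7)
        b = simulate_recording(arch, seed=7)
        for sa, sb in zip(a, b):
            np.testing.assert_array_equal(sa.voltage, sb.voltage)

    def test_infeasible_program_rejected(self):
        targets = dict(CLASS_TARGETS["planar_multipolar"], AP_halfwidth=5.0)
        arch = ClassArchetype("wide", targets, "regular", default_dispersions())
        with pytest.raises(ProgramInfeasible, match="wider than"):
            simulate_recording(arch, seed=0)


class TestFixtureCohort:
    def test_fixture_written_and_recoverable(self, tmp_path):
        recs, truth = make_fixture_cohort(tmp_path, seed=1, n_per_class=2)
        assert len(recs) == 12
        assert (tmp_path / "truth.tsv").exists()
        assert len(list(tmp_path.glob("*.h5"))) == 12
        assert set(truth.labels) == set(PRINCIPAL_CLASSES)

    def test_fixture_is_byte_identical_across_runs(self, tmp_path):
        a_dir, b_dir = tmp_path / "a", tmp_path / "b"
        make_fixture_cohort(a_dir, seed=2, n_per_class=1)
        make_fixture_cohort(b_dir, seed=2, n_per_class=1)
        for pa in sorted(a_dir.iterdir()):
            assert pa.read_bytes() == (b_dir / pa.name).read_bytes()

    def test_end_to_end_recovery_against_truth(self, tmp_path):
        """Extraction on the fixture recovers >= 90% of defined measures."""
        tolerances = {
            "RMP": ("abs", 0.5), "R_in": ("rel", 0.05), "tau_m": ("rel", 0.15),
            "tau_h": ("rel", 0.30), "BA_ratio": ("abs", 0.05),
            "AP_peak": ("abs", 1.5), "AP_halfwidth": ("abs", 0.05),
            "AHP": ("abs", 2.5), "adaptation": ("abs", 0.05),
            "rebound": ("abs", 0.0), "CV": ("abs", 0.15), "I_rate": ("rel", 0.10),
        }
        recs, truth = make_fixture_cohort(tmp_path, seed=3, n_per_class=5, write=False)
        total = hits = 0
        for series in recs:
            feats = extract_all(series)
            for m, (kind, tol) in tolerances.items():
                tgt = truth.values.loc[series.cell_id, m]
                got = getattr(feats, m)
                if not math.isfinite(tgt) or not math.isfinite(got):
                    continue
                total += 1
                err = abs(got - tgt) if kind == "abs" else abs(got / tgt - 1)
                hits += err <= tol + 1e-12
        assert total >= 250
        assert hits / total >= 0.90


class TestSeparabilityVsDispersion:
    def test_accuracy_non_increasing_in_dispersion(self):
        """More within-class spread can only blur the classes."""
        from cnephys.classify import cross_validate

        means = []
        for scale in (0.5, 1.0, 2.0, 4.0):
            accs = []
            for seed in (1, 2, 3):
                t = sample_feature_table(default_archetypes(dispersion_scale=scale),
                                         seed=seed)
                accs.append(cross_validate(t, k=10, seed=seed)[0])
            means.append(np.mean(accs))
        for a, b in zip(means, means[1:]):
            assert b <= a + 0.02  # small slack for fold noise
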