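"""I/O, rupture detection and QC tests."""

import json

import numpy as np
import pytest

from dfsbind import (
    ConditionLabel,
    DetectionConfig,
    ExperimentDesign,
    ForceCurve,
    NoiseModel,
    QCRules,
    RuptureEvent,
    detect_rupture,
    generate_experiment,
    loading_rate_for,
    qc_filter,
    read_force_curves,
    synthesize_force_curve,
)
from dfsbind.curves_io import (
    events_from_dataframe,
    events_to_dataframe,
    read_events,
    write_dataset,
    write_events,
)


@pytest.fixture
def small_dataset(params_a, tmp_path):
    design = ExperimentDesign(curves_per_velocity=2)
    ds = generate_experiment(params_a, design, NoiseModel(), seed=21)
    ds.write(tmp_path / "ds")
    return ds, tmp_path / "ds"


class TestDatasetIO:
    def test_round_trip_counts_and_values(self, small_dataset):
        ds, path = small_dataset
        curves = read_force_curves(path)
        assert len(curves) == len(ds.curves)
        by_id = {c.curve_id: c for c in curves}
        for orig in ds.curves:
            back = by_id[orig.curve_id]
            assert np.allclose(back.separation, orig.separation, rtol=1e-8)
            assert np.allclose(back.force, orig.force, rtol=1e-8)
            assert back.condition == orig.condition
            assert back.velocity == pytest.approx(orig.velocity)

    def test_missing_manifest(self, tmp_path):
        with pytest.raises(FileNotFoundError, match="manifest"):
            read_force_curves(tmp_path)

    def test_missing_curve_file_named_in_error(self, small_dataset):
        _, path = small_dataset
        manifest = json.loads((path / "manifest.json").read_text())
        victim = manifest["curves"][0]["file"]
        (path / victim).unlink()
        with pytest.raises(FileNotFoundError, match=victim.split("/")[-1]):
            read_force_curves(path)

    def test_invalid_curve_skipped_with_warning(self, small_dataset, caplog):
        _, path = small_dataset
        manifest = json.loads((path / "manifest.json").read_text())
        victim = path / manifest["curves"][0]["file"]
        # corrupt: make retract separation non-monotone
        lines = victim.read_text().splitlines()
        # swap two retract data rows' separations
        import pandas as pd

        df = pd.read_csv(victim)
        ret = df.index[df.segment == "retract"]
        df.loc[ret[5], "separation_m"], df.loc[ret[50], "separation_m"] = (
            df.loc[ret[50], "separation_m"],
            df.loc[ret[5], "separation_m"],
        )
        df.to_csv(victim, index=False)
        with caplog.at_level("WARNING"):
            curves = read_force_curves(path)
        assert len(curves) == len(manifest["curves"]) - 1
        assert any("monotone" in r.message for r in caplog.records)

    def test_ground_truth_sidecar(self, small_dataset):
        ds, path = small_dataset
        truth = json.loads((path / "ground_truth.json").read_text())
        assert truth["params"]["f_eq_N"] == pytest.approx(50e-12)
        assert set(truth["events"]) == {c.curve_id for c in ds.curves}


class TestDetection:
    def test_flat_noisy_curve_returns_none(self, default_design):
        curve = synthesize_force_curve(None, default_design, NoiseModel(), seed=31)
        assert detect_rupture(curve) is None

    def test_round_trip_at_snr_10(self, default_design):
        # recall >= 0.99 and 95% of detections within 3 noise SD at SNR 10
        rng = np.random.default_rng(32)
        F, sd = 137e-12, 13.7e-12
        errs, detected = [], 0
        n_curves = 200
        for i in range(n_curves):
            ev = RuptureEvent(force=F, loading_rate=6e-10, curve_id=f"c{i}")
            curve = synthesize_force_curve(
                ev, default_design, NoiseModel(force_noise_sd=sd), seed=rng,
                velocity=10e-9, curve_id=f"c{i}",
            )
            det = detect_rupture(curve)
            if det is not None:
                detected += 1
                errs.append(abs(det.force - F))
        errs = np.array(errs)
        assert detected / n_curves >= 0.99
        assert (errs <= 3 * sd).mean() >= 0.95

    def test_config_validation(self):
        with pytest.raises(ValueError):
            DetectionConfig(baseline_fraction=0.6)
        with pytest.raises(ValueError):
            DetectionConfig(noise_k=2.0)
        with pytest.raises(ValueError):
            DetectionConfig(event_choice="first")

    def test_short_retract_rejected(self):
        n = 12
        curve = ForceCurve(
            separation=np.r_[np.linspace(1e-8, 0, n), np.linspace(0, 1e-8, n)],
            force=np.zeros(2 * n),
            segment=np.array(["approach"] * n + ["retract"] * n),
            spring_constant=0.06,
            velocity=1e-8,
            curve_id="short",
        )
        with pytest.raises(ValueError, match="baseline window"):
            detect_rupture(curve)

    def test_event_choice_last_vs_deepest(self, default_design, quiet_noise):
        # two adhesion wells: deeper one near contact, shallower one farther out
        x = np.linspace(-1e-9, 3e-8, 1500)
        f = np.zeros_like(x)
        well1 = (x > 1e-9) & (x < 4e-9)
        f[well1] = -200e-12
        well2 = (x > 8e-9) & (x < 1.1e-8)
        f[well2] = -120e-12
        curve = ForceCurve(
            separation=np.r_[x[::-1], x],
            force=np.r_[np.zeros_like(x), f],
            segment=np.array(["approach"] * x.size + ["retract"] * x.size),
            spring_constant=0.06,
            velocity=1e-8,
            curve_id="two-events",
        )
        last = detect_rupture(curve, DetectionConfig(event_choice="last"))
        deepest = detect_rupture(curve, DetectionConfig(event_choice="deepest"))
        assert last.force == pytest.approx(120e-12, rel=1e-6)
        assert deepest.force == pytest.approx(200e-12, rel=1e-6)
        assert "multiple_events" in last.detection_flags


class TestLoadingRate:
    def test_nominal_arithmetic(self, default_design, quiet_noise):
        ev = RuptureEvent(force=150e-12, loading_rate=6e-9, curve_id="c")
        curve = synthesize_force_curve(
            ev, default_design, quiet_noise, seed=41, velocity=100e-9
        )
        assert loading_rate_for(curve, "nominal") == pytest.approx(6e-9)
        ev2 = RuptureEvent(force=150e-12, loading_rate=6e-10, curve_id="c2")
        curve2 = synthesize_force_curve(
            ev2, default_design, quiet_noise, seed=42, velocity=10e-9
        )
        assert loading_rate_for(curve2, "nominal") == pytest.approx(6e-10)

    def test_measured_recovers_ramp_slope(self, default_design, quiet_noise):
        ev = RuptureEvent(force=150e-12, loading_rate=6e-10, curve_id="c")
        curve = synthesize_force_curve(
            ev, default_design, quiet_noise, seed=43, velocity=10e-9
        )
        det = detect_rupture(curve)
        measured = loading_rate_for(curve, "measured", event=det)
        assert measured == pytest.approx(0.06 * 10e-9, rel=1e-6)

    def test_measured_without_event_errors(self, default_design, quiet_noise):
        curve = synthesize_force_curve(None, default_design, quiet_noise, seed=44)
        with pytest.raises(ValueError, match="event"):
            loading_rate_for(curve, "measured")


class TestQC:
    def _ev(self, force, flags=()):
        return RuptureEvent(
            force=force, loading_rate=1e-9, curve_id="x", detection_flags=frozenset(flags)
        )

    def test_empty_input(self):
        kept, report = qc_filter([])
        assert kept == []
        assert report["input"] == report["retained"] == 0

    def test_rules_applied_and_counted(self):
        events = [
            self._ev(50e-12),
            self._ev(1e-15),              # below 1 pN physical floor
            self._ev(50e-12, {"low_snr"}),
            self._ev(60e-12, {"multiple_events"}),  # retained by default
        ]
        kept, report = qc_filter(events)
        assert len(kept) == 2
        assert report["force_range"] == 1
        assert report["flag"] == 1
        assert report["input"] - report["retained"] == report["flag"] + report["force_range"]

    def test_never_increases_count(self, params_a):
        rng = np.random.default_rng(45)
        events = [self._ev(float(f)) for f in
                  np.abs(rng.normal(5e-11, 2e-11, size=50)) + 1e-12]
        kept, _ = qc_filter(events, QCRules())
        assert len(kept) <= len(events)


class TestEventTables:
    def test_round_trip(self, tmp_path):
        cond = ConditionLabel(ligand="PO3-", mineral="goethite(010)", ph=4.0,
                              ionic_strength_mm=100.0, electrolyte="CaCl2")
        events = [
            RuptureEvent(force=1e-10, loading_rate=1e-9, curve_id="a",
                         detection_flags=frozenset({"multiple_events"}),
                         condition=cond),
            RuptureEvent(force=2e-10, loading_rate=2e-9, curve_id="b",
                         condition=cond),
        ]
        path = tmp_path / "events.csv"
        write_events(events, path)
        back = read_events(path)
        assert len(back) == 2
        assert back[0].force == pytest.approx(events[0].force)
        assert back[0].detection_flags == events[0].detection_flags
        assert back[0].condition == cond

    def test_dataframe_columns(self):
        ev = RuptureEvent(force=1e-10, loading_rate=1e-9, curve_id="a")
        df = events_to_dataframe([ev])
        for col in ("curve_id", "loading_rate_N_per_s", "rupture_force_N",
                    "flags", "ligand", "mineral"):
            assert col in df.columns
        assert events_from_dataframe(df)[0].force == pytest.approx(1e-10)


class TestConditionLabel:
    def test_validation(self):
        with pytest.raises(ValueError):
            ConditionLabel(ph=15.0)
        with pytest.raises(ValueError):
            ConditionLabel(ionic_strength_mm=-1.0)
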