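import numpy as np
import pytest

import wearcal as wc
from wearcal.protocol import ActivityCategory, PatientGroup
from wearcal.synthetic import _device_rng

from oracles import brute_hampel


def _profile(weight=70.0, group=PatientGroup.CAD, tau=30.0):
    return wc.PatientProfile(
        id="p0", group=group, age=60.0, sex="male", height_cm=175.0, weight_kg=weight,
        resting_vo2_lmin=3.5 * weight / 1000.0, kinetics_tau_s=tau,
    )


class TestSampleCohort:
    def test_balanced_and_deterministic(self):
        cfg = wc.SimulationConfig(n_per_group=19, seed=1)
        cohort = wc.sample_cohort(cfg)
        assert len(cohort) == 38
        assert sum(p.group is PatientGroup.CAD for p in cohort) == 19
        again = wc.sample_cohort(wc.SimulationConfig(n_per_group=19, seed=1))
        assert cohort == again

    def test_age_mean_recovers_sampling_target(self):
        cohort = wc.sample_cohort(wc.SimulationConfig(n_per_group=200, seed=7))
        ages = [p.age for p in cohort if p.group is PatientGroup.CAD]
        se = 6.9 / np.sqrt(len(ages))
        assert abs(np.mean(ages) - 61.4) < 3 * se

    def test_hfref_kinetics_slower_on_average(self):
        cohort = wc.sample_cohort(wc.SimulationConfig(n_per_group=100, seed=3))
        tau = lambda g: np.mean([p.kinetics_tau_s for p in cohort if p.group is g])
        assert tau(PatientGroup.HFREF) > tau(PatientGroup.CAD)

    def test_nonpositive_n_rejected(self):
        with pytest.raises(ValueError):
            wc.SimulationConfig(n_per_group=0)


class TestTargetVo2:
    def test_monotone_in_cycling_load(self, cad_protocol):
        prof = _profile()
        acts = [a for a in cad_protocol.activities if a.category is ActivityCategory.CYCLING]
        targets = [wc.target_vo2(a, prof) for a in acts]
        assert targets == sorted(targets) and targets[0] < targets[-1]

    def test_monotone_in_grade(self, cad_protocol):
        prof = _profile()
        flat = cad_protocol.activity("walking_slow")  # 4 km/h, 0%
        incline = cad_protocol.activity("walking_incline")  # 4 km/h, 5%
        assert wc.target_vo2(incline, prof) > wc.target_vo2(flat, prof)

    def test_cycling_hand_value(self, cad_protocol):
        # 70 kg at 40 W: (10.8*40 + 7*70)/1000 L/min
        act = cad_protocol.activity("cycling_mid")
        assert wc.target_vo2(act, _profile(70.0)) == pytest.approx(0.922, abs=1e-12)

    def test_walking_hand_value(self, cad_protocol):
        # 4 km/h = 66.667 m/min at 0%: (0.1*66.667 + 3.5) ml/kg/min * 70 kg
        act = cad_protocol.activity("walking_slow")
        expected = (0.1 * (4000 / 60) + 3.5) * 70 / 1000
        assert wc.target_vo2(act, _profile(70.0)) == pytest.approx(expected, rel=1e-12)


class TestSimulateGasExchange:
    def test_noise_free_segment_means_hit_targets(self, cad_protocol):
        prof = _profile(tau=1e-12)
        cfg = wc.SimulationConfig(n_per_group=1, noise_cv=0.0, outlier_rate=0.0)
        trace = wc.simulate_gas_exchange(
            cad_protocol, prof, cfg, rng=np.random.default_rng(0)
        )
        for seg in cad_protocol.segments:
            mask = (trace.times >= seg.start_s) & (trace.times < seg.end_s)
            target = wc.target_vo2(cad_protocol.activity(seg.activity_id), prof)
            assert np.mean(trace.vo2[mask]) == pytest.approx(target, rel=1e-3)

    def test_outlier_free_trace_is_hampel_quiet(self, cad_protocol):
        """Without injected spikes, the Hampel stage stays near its intrinsic
        false-positive rate (~5% for a 7-point MAD window on Gaussian noise)
        and the harmless median replacements barely move the total energy."""
        prof = _profile()
        cfg = wc.SimulationConfig(n_per_group=1, noise_cv=0.02, outlier_rate=0.0)
        trace = wc.simulate_gas_exchange(
            cad_protocol, prof, cfg, rng=np.random.default_rng(1)
        )
        rate = np.asarray(wc.weir_rate(trace.vo2, trace.vco2))
        cleaned, flagged = brute_hampel(rate)
        assert len(flagged) / rate.size < 0.06
        assert np.sum(cleaned) == pytest.approx(np.sum(rate), rel=1e-3)

    def test_seeded_determinism(self, cad_protocol):
        prof = _profile()
        cfg = wc.SimulationConfig(n_per_group=1, seed=5)
        t1 = wc.simulate_gas_exchange(cad_protocol, prof, cfg, rng=np.random.default_rng(9))
        t2 = wc.simulate_gas_exchange(cad_protocol, prof, cfg, rng=np.random.default_rng(9))
        np.testing.assert_array_equal(t1.times, t2.times)
        np.testing.assert_array_equal(t1.vo2, t2.vo2)
        np.testing.assert_array_equal(t1.vco2, t2.vco2)

    def test_truth_conserved_against_quadrature(self, noise_free_record):
        """Stored per-segment truth equals a fine numeric integral of the clean rate."""
        rec = noise_free_record
        for seg in rec.protocol.segments:
            t = np.linspace(seg.start_s, seg.end_s, 20001)
            vo2 = np.interp(t, rec.trace.times, rec.trace.vo2)
            vco2 = np.interp(t, rec.trace.times, rec.trace.vco2)
            numeric = np.trapezoid(wc.weir_rate(vo2, vco2), t) / 60.0
            assert rec.trace.truth_ee_per_segment[seg.activity_id] == pytest.approx(
                numeric, rel=2e-3
            )

    def test_group_mismatch_rejected(self, hf_protocol):
        with pytest.raises(ValueError, match="group"):
            wc.simulate_gas_exchange(hf_protocol, _profile(), wc.SimulationConfig())

    def test_group_contrast_lower_hf_workload(self, small_records):
        by_group = {}
        for rec in small_records:
            peak = max(rec.trace.truth_ee_per_segment.values())
            by_group.setdefault(rec.profile.group, []).append(peak)
        assert np.mean(by_group[PatientGroup.HFREF]) < np.mean(by_group[PatientGroup.CAD])


class TestSimulateTracker:
    def test_identity_model_recovers_truth(self, noise_free_record):
        rec = noise_free_record
        model = wc.DeviceBiasModel(gain=1.0, resolution_kcal=0.0)
        log = wc.simulate_tracker(rec.trace, rec.protocol, model, rng=0)
        for seg in rec.protocol.segments:
            assert log.activity_kcal(seg.activity_id) == pytest.approx(
                rec.trace.truth_ee_per_segment[seg.activity_id], abs=1e-9
            )

    def test_gain_recovered_over_many_patients(self):
        cfg = wc.SimulationConfig(
            n_per_group=100, seed=13, device_models={"g12": wc.DeviceBiasModel(gain=1.2)}
        )
        records = wc.simulate_study(cfg)
        ratios = [
            rec.logs[0].total_kcal / rec.trace.truth_ee_total_kcal for rec in records
        ]
        # quantisation to 1 kcal leaves only a small wobble around the gain
        assert np.mean(ratios) == pytest.approx(1.2, abs=0.01)

    def test_quantisation_bound(self, noise_free_record):
        rec = noise_free_record
        exact = wc.simulate_tracker(
            rec.trace, rec.protocol, wc.DeviceBiasModel(resolution_kcal=0.0), rng=0
        )
        coarse = wc.simulate_tracker(
            rec.trace, rec.protocol, wc.DeviceBiasModel(resolution_kcal=1.0), rng=0
        )
        for aid, start, end in coarse.rows:
            assert float(start).is_integer() and float(end).is_integer()
            assert abs((end - start) - exact.activity_kcal(aid)) <= 1.0

    def test_missing_segments_rejected(self, noise_free_record):
        other = wc.ActivityProtocol(
            group="CAD",
            activities=(
                wc.Activity("rowing", "Rowing", ActivityCategory.HOUSEHOLD, 180.0),
            ),
        )
        with pytest.raises(ValueError, match="rowing"):
            wc.simulate_tracker(noise_free_record.trace, other, wc.DeviceBiasModel(), rng=0)


class TestSimulateStudy:
    def test_reproducible_end_to_end(self):
        cfg = wc.SimulationConfig(n_per_group=2, seed=21)
        r1, r2 = wc.simulate_study(cfg), wc.simulate_study(cfg)
        for a, b in zip(r1, r2):
            assert a.profile == b.profile
            np.testing.assert_array_equal(a.trace.vo2, b.trace.vo2)
            assert a.logs == b.logs

    def test_device_substreams_stable(self):
        # the same (seed, patient, device) triple always yields the same stream
        a = _device_rng(3, 1, "wristA").normal(size=4)
        b = _device_rng(3, 1, "wristA").normal(size=4)
        c = _device_rng(3, 1, "wristB").normal(size=4)
        np.testing.assert_array_equal(a, b)
        assert not np.array_equal(a, c)
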