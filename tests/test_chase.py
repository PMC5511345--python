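import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sheathchase import (BleachChaseModel, TimepointSet, eligible_for_chase,
                         normalize_intensity)
from sheathchase.chase import ChaseThresholds, infer_mechanism
from sheathchase.kymograph import background_stats, extract_kymogram
from sheathchase.presets import chase_experiment
from tests.conftest import fit_chase


class TestTimepoints:
    def test_standard_protocol_times(self):
        tps = TimepointSet.from_bleach_and_end(30.0, 96.0, 2.0)
        assert (tps.t1_s, tps.t2_s, tps.t3_s, tps.t4_s) == (30, 32, 76, 96)
        assert not tps.t3_skipped

    def test_short_post_bleach_assembly_skips_t3(self):
        with pytest.warns(UserWarning, match="skipping t3"):
            tps = TimepointSet.from_bleach_and_end(30.0, 44.0, 2.0)
        assert tps.t3_skipped and tps.t3_s is None
        assert [lbl for lbl, _ in tps.post_bleach()] == ["t2", "t4"]


class TestNormalizeIntensity:
    def test_endpoints_by_definition(self):
        assert normalize_intensity(120.0, 120.0, 160.0) == pytest.approx(0.0)
        assert normalize_intensity(160.0, 120.0, 160.0) == \
            pytest.approx(100.0)

    @given(gain=st.floats(0.2, 5.0), offset=st.floats(-50.0, 50.0))
    @settings(max_examples=25, deadline=None)
    def test_affine_camera_rescaling_invariance(self, gain, offset):
        raw, bg, ref = 141.0, 118.0, 157.0
        base = normalize_intensity(raw, bg, ref)
        scaled = normalize_intensity(gain * raw + offset, gain * bg + offset,
                                     gain * ref + offset)
        assert scaled == pytest.approx(base)

    def test_reference_must_exceed_background(self):
        with pytest.raises(ValueError):
            normalize_intensity(100.0, 120.0, 110.0)


class TestEligibility:
    def test_compliant_event_accepted(self, distal_event_clean):
        exp = distal_event_clean
        kym = extract_kymogram(exp.stack, exp.line)
        bg = background_stats(exp.stack)
        el = eligible_for_chase(kym, exp.t_bleach_s, bg)
        assert el.eligible and el.reasons == []

    def test_fully_bleached_sheath_rejected(self):
        # a footprint far wider than the sheath erases it completely;
        # nothing remains to chase
        from sheathchase import render_stack
        from sheathchase.presets import default_optics
        from sheathchase.simulate import simulate
        exp = chase_experiment("distal", seed=31, noise=False)
        exp.sim.config.bleach.footprint_fwhm_um = 8.0
        sim = simulate(exp.sim.config)
        stack = render_stack(sim, default_optics(seed=1, noise=False))
        kym = extract_kymogram(stack, exp.line)
        bg = background_stats(stack)
        el = eligible_for_chase(kym, 30.0, bg)
        assert not el.eligible
        assert el.reasons

    def test_nucleation_after_bleach_rejected(self):
        exp = chase_experiment("distal", seed=32, noise=False,
                               t_nucleation_s=40.0, bleach_back_um=0.0)
        kym = extract_kymogram(exp.stack, exp.line)
        bg = background_stats(exp.stack)
        el = eligible_for_chase(kym, 30.0, bg)
        assert not el.eligible
        assert any("before the bleach" in r for r in el.reasons)

    def test_noop_bleach_has_no_bleached_span(self):
        from sheathchase import render_stack
        from sheathchase.presets import default_optics
        from sheathchase.simulate import simulate
        exp = chase_experiment("distal", seed=33, noise=False)
        exp.sim.config.bleach.polymer_survival = 1.0
        exp.sim.config.bleach.pool_survival = 1.0
        sim = simulate(exp.sim.config)
        stack = render_stack(sim, default_optics(seed=1, noise=False))
        kym = extract_kymogram(stack, exp.line)
        bg = background_stats(stack)
        el = eligible_for_chase(kym, 30.0, bg)
        assert not el.eligible
        assert "no bleached span" in el.reasons


class TestSections:
    def test_noiseless_distal_triple_ordered(self, distal_event_clean_fit):
        _, res = distal_event_clean_fit
        classes = [s.klass for s in res.sections]
        assert classes == ["bright", "bleached", "dim"]
        spans = [s.span_nm for s in res.sections]
        assert spans[0][1] <= spans[1][0] <= spans[1][1] <= spans[2][0]

    def test_noisy_distal_triples_recovered(self):
        ok = 0
        for seed in range(600, 625):
            res = fit_chase("distal", seed)
            if res.status != "ok":
                continue
            classes = [s.klass for s in res.sections]
            if classes == ["bright", "bleached", "dim"]:
                ok += 1
        assert ok >= 23  # >= 90% of 25 seeded events

    def test_distal_sections_stationary_and_dark(self,
                                                 distal_event_clean_fit):
        _, res = distal_event_clean_fit
        t = res.table
        post = t[t.timepoint != "t1"]
        for klass in ("bright", "bleached"):
            cent = post[post.section == klass].centroid_nm
            assert cent.max() - cent.min() <= 65.0
        bl = post[post.section == "bleached"].sort_values("t_s")
        assert np.all(np.abs(bl.intensity_pct) <= 10.0)
        # no fluorescence recovery of the bleached span
        assert bl.intensity_pct.iloc[-1] - bl.intensity_pct.iloc[0] < 5.0

    def test_proximal_mark_moves_at_polymerization_speed(self):
        res = fit_chase("proximal", seed=601, noise=False)
        assert res.label == "proximal"
        drift = res.call.bleached_drift_nm_per_s
        assert drift == pytest.approx(res.speed.v_a_nm_per_s, rel=0.25)

    def test_intercalation_mark_spreads_with_length(self):
        res = fit_chase("intercalation", seed=602, noise=False)
        assert res.label == "intercalation"
        assert res.call.bleached_width_change_fraction > 0.3
        assert res.call.bleached_intensity_change_pct > 5.0

    def test_flip_invariance_of_chase_fit(self, distal_event_clean):
        exp = distal_event_clean
        fwd = BleachChaseModel.from_stack(exp.stack, exp.line).fit()
        rev = BleachChaseModel.from_stack(exp.stack,
                                          exp.line.reversed()).fit()
        assert rev.status == fwd.status == "ok"
        assert rev.label == fwd.label
        b_f = fwd.table[fwd.table.section == "bleached"].centroid_nm.values
        b_r = rev.table[rev.table.section == "bleached"].centroid_nm.values
        assert np.allclose(b_f, b_r, atol=1e-6)


class TestInference:
    def make_table(self, drift_nm_s=0.0, width_change=0.0, d_int=0.0):
        import pandas as pd
        w2 = 700.0
        rows = []
        for lbl, t in (("t2", 32.0), ("t3", 76.0), ("t4", 96.0)):
            frac = (t - 32.0) / 64.0
            rows.append({"section": "bleached", "timepoint": lbl, "t_s": t,
                         "centroid_nm": 1000.0 + drift_nm_s * (t - 32.0),
                         "width_nm": w2 * (1 + width_change * frac),
                         "intensity_pct": 2.0 + d_int * frac})
        return pd.DataFrame(rows)

    def test_decision_boundaries(self):
        th = ChaseThresholds()
        assert infer_mechanism(self.make_table(), 55.0, th).label == "distal"
        assert infer_mechanism(self.make_table(drift_nm_s=55.0), 55.0,
                               th).label == "proximal"
        assert infer_mechanism(
            self.make_table(drift_nm_s=25.0, width_change=1.2, d_int=12.0),
            55.0, th).label == "intercalation"
        # moving mark that also gains intensity but does not spread: no
        # mechanism predicts it
        assert infer_mechanism(
            self.make_table(drift_nm_s=55.0, d_int=12.0),
            55.0, th).label == "ambiguous"

    def test_insufficient_timepoints_raise(self):
        import pandas as pd
        t = self.make_table().iloc[:2]
        with pytest.raises(ValueError, match="timepoints"):
            infer_mechanism(t, 55.0)

    def test_call_is_pure_function_of_evidence(self):
        t = self.make_table(drift_nm_s=55.0)
        a = infer_mechanism(t, 55.0)
        b = infer_mechanism(t.copy(), 55.0)
        assert (a.label, a.bleached_drift_nm_per_s) == \
            (b.label, b.bleached_drift_nm_per_s)


class TestRecovery:
    @pytest.mark.parametrize("mechanism", ["distal", "proximal",
                                           "intercalation"])
    def test_noiseless_mechanism_recovered(self, mechanism):
        res = fit_chase(mechanism, seed=700, noise=False)
        assert res.status == "ok"
        assert res.label == mechanism

    def test_noisy_recovery_no_end_confusion(self):
        # smaller batch here; the full 50-per-mechanism run lives in the
        # acceptance suite
        for mechanism in ("distal", "proximal", "intercalation"):
            labels = [fit_chase(mechanism, seed).label
                      for seed in range(710, 720)]
            correct = sum(lbl == mechanism for lbl in labels)
            assert correct >= 9
            if mechanism == "distal":
                assert "proximal" not in labels
            if mechanism == "proximal":
                assert "distal" not in labels

    def test_pre_and_post_bleach_speeds_agree(self, distal_event_clean_fit):
        _, res = distal_event_clean_fit
        ratio = res.speed_pre.v_a_nm_per_s / res.speed_post.v_a_nm_per_s
        assert ratio == pytest.approx(1.0, abs=0.05)
        assert res.speed_pre.r_squared > 0.99
        assert res.speed_post.r_squared > 0.99
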