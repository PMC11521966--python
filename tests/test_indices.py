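"""Post-processing: envelope extraction, event timing, cycles, indices."""

import warnings

import numpy as np
import pytest

from fetaldoppler import indices as ix
from fetaldoppler.calibration import Calibration
from fetaldoppler.indices import CardiacCycle, EnvelopeCurve, PhysioEvent


def curve_from_values(values, cal=None):
    return EnvelopeCurve(velocity=np.asarray(values, dtype=float), calibration=cal or Calibration(1.0, 1.0, 10))


class TestSmoothing:
    def test_solid_rectangle_roughly_unchanged(self):
        m = np.zeros((20, 20), dtype=bool)
        m[5:15, 5:15] = True
        out = ix.smooth_envelope_mask(m)
        assert out[5:15, 5:15].all()  # nothing inside lost
        grown = out & ~m
        # growth confined to a 1-pixel boundary ring
        ring = np.zeros_like(m)
        ring[4:16, 4:16] = True
        assert not (grown & ~ring).any()

    def test_single_pixel_holes_closed(self):
        m = np.zeros((20, 20), dtype=bool)
        m[5:15, 5:15] = True
        m[8, 8] = m[10, 12] = False
        out = ix.smooth_envelope_mask(m)
        assert out[8, 8] and out[10, 12]

    def test_isolated_pixels_removed(self):
        m = np.zeros((10, 10), dtype=bool)
        m[2, 2] = True
        m[7, 8] = True
        out = ix.smooth_envelope_mask(m)
        assert not out.any()


class TestDominantSide:
    def test_larger_extent_wins(self):
        cal = Calibration(1.0, 1.0, 50)
        m = np.zeros((100, 10), dtype=bool)
        m[10:50, :] = True  # extent 40 above
        m[51:61, :] = True  # extent 10 below
        out = ix.select_dominant_side(m, cal, "single")
        assert out[10:50].any() and not out[51:61].any()

    def test_one_sided_identity(self):
        cal = Calibration(1.0, 1.0, 50)
        m = np.zeros((100, 10), dtype=bool)
        m[20:50, 2:8] = True
        out = ix.select_dominant_side(m, cal, "single")
        assert np.array_equal(out, m)

    def test_lvio_partition(self):
        cal = Calibration(1.0, 1.0, 50)
        m = np.zeros((100, 10), dtype=bool)
        m[10:50, 0:4] = True
        m[51:80, 6:9] = True
        dom, opp = ix.select_dominant_side(m, cal, "lvio")
        assert np.array_equal(dom | opp, m)
        assert not (dom & opp).any()

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            ix.select_dominant_side(np.zeros((4, 4), dtype=bool), Calibration(1, 1, 2), "single")

    def test_bad_mode_rejected(self):
        m = np.ones((4, 4), dtype=bool)
        with pytest.raises(ValueError, match="mode"):
            ix.select_dominant_side(m, Calibration(1, 1, 2), "both")


class TestEnvelopeCurve:
    def test_rectangle_gives_constant_velocity(self):
        cal = Calibration(1.0, 1.0, 50)
        m = np.zeros((100, 10), dtype=bool)
        m[40:50, :] = True  # rows 40..49 above the zero line at 50
        curve = ix.extract_envelope_curve(m, cal)
        assert np.allclose(curve.velocity, 10.0)

    def test_single_column_support(self):
        cal = Calibration(1.0, 1.0, 50)
        m = np.zeros((100, 10), dtype=bool)
        m[45:50, 3] = True
        curve = ix.extract_envelope_curve(m, cal)
        assert curve.support.sum() == 1
        assert curve.velocity[3] == 5.0

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            ix.extract_envelope_curve(np.zeros((4, 4), dtype=bool), Calibration(1, 1, 2))

    def test_refinement_recovers_raw_boundary(self):
        cal = Calibration(1.0, 1.0, 50)
        raw = np.zeros((100, 10), dtype=bool)
        raw[40:50, :] = True
        dilated = np.zeros_like(raw)
        dilated[39:50, :] = True  # one-pixel outward bias
        curve = ix.extract_envelope_curve(dilated, cal, refine_mask=raw)
        assert np.allclose(curve.velocity, 10.0)


class TestEventTimes:
    def test_single_band_centroid(self):
        cal = Calibration(2.0, 1.0, 50)
        ch = np.zeros((100, 120), dtype=bool)
        ch[40:60, 48:53] = True  # centred on column 50
        assert ix.extract_event_times(ch, cal) == [pytest.approx(100.0)]

    def test_min_separation_rule_application(self):
        # candidates at 100/150/400 ms with areas 10/5/8 -> keep 100, 400
        out = ix.enforce_min_separation([(100.0, 10), (150.0, 5), (400.0, 8)])
        assert out == [100.0, 400.0]

    def test_exactly_80ms_apart_both_kept(self):
        out = ix.enforce_min_separation([(100.0, 5), (180.0, 5)])
        assert out == [100.0, 180.0]

    def test_gap_filling_merges_split_band(self):
        cal = Calibration(1.0, 1.0, 50)
        ch = np.zeros((100, 200), dtype=bool)
        ch[40:50, 95:98] = True
        ch[40:50, 102:106] = True  # 4-column gap, fillable
        times = ix.extract_event_times(ch, cal)
        assert len(times) == 1

    def test_empty_channel_empty_list(self):
        assert ix.extract_event_times(np.zeros((5, 5), dtype=bool), Calibration(1, 1, 2)) == []

    def test_fuzz_pairwise_separation_and_oracle(self, rng):
        def brute(cands):
            order = sorted(cands, key=lambda ta: (-ta[1], ta[0]))
            kept = []
            for t, _ in order:
                if all(abs(t - k) >= 80.0 for k in kept):
                    kept.append(t)
            return sorted(kept)

        for _ in range(1000):
            n = int(rng.integers(1, 7))
            cands = [(float(rng.uniform(0, 600)), int(rng.integers(1, 50))) for _ in range(n)]
            out = ix.enforce_min_separation(cands)
            gaps = np.diff(out)
            assert np.all(gaps >= 80.0)
            assert out == brute(cands)
            # removing any kept candidate cannot re-admit a violation
            for i in range(len(out)):
                rest = out[:i] + out[i + 1 :]
                assert np.all(np.diff(rest) >= 80.0)


class TestAttachMagnitudes:
    def test_constant_curve(self):
        curve = curve_from_values([10.0] * 200, Calibration(1.0, 1.0, 50))
        evs = ix.attach_magnitudes([100.0], curve, name="S peak")
        assert evs == [PhysioEvent("S peak", 100.0, 10.0)]

    def test_snaps_to_nearest_support_within_tolerance(self):
        v = np.full(50, np.nan)
        v[20] = 7.0
        curve = curve_from_values(v, Calibration(1.0, 1.0, 50))
        evs = ix.attach_magnitudes([18.0], curve, name="onset S")
        assert evs[0].v_cms == 7.0

    def test_event_far_from_support_dropped_with_warning(self):
        v = np.full(50, np.nan)
        v[40] = 7.0
        curve = curve_from_values(v, Calibration(1.0, 1.0, 50))
        with pytest.warns(UserWarning, match="dropped"):
            evs = ix.attach_magnitudes([10.0], curve, name="onset S")
        assert evs == []


class TestCycles:
    def test_consecutive_onsets_delimit_cycles(self):
        evs = [PhysioEvent("onset S", t, 1.0) for t in (0.0, 500.0, 1000.0)]
        cycles = ix.segment_cycles(evs)
        assert [c.length_ms for c in cycles] == [500.0, 500.0]

    def test_peak_assigned_to_containing_cycle(self):
        evs = [
            PhysioEvent("onset S", 0.0, 1.0),
            PhysioEvent("S peak", 120.0, 5.0),
            PhysioEvent("onset S", 500.0, 1.0),
        ]
        cycles = ix.segment_cycles(evs)
        assert cycles[0].event("S peak").t_ms == 120.0

    def test_fewer_than_two_onsets_rejected(self):
        with pytest.raises(ValueError, match="insufficient cycles"):
            ix.segment_cycles([PhysioEvent("onset S", 0.0, 1.0)])


class TestPI:
    def test_constant_envelope_zero_pi(self):
        curve = curve_from_values([10.0] * 100)
        pi = ix.compute_pi(curve, CardiacCycle(0.0, 100.0))
        assert pi["pi"] == 0.0

    def test_sine_envelope_closed_form(self):
        # v(t) = 60 + 20 sin(2 pi t / T): PI = (80 - 40) / 60
        T = 500.0
        cal = Calibration(1.0, 1.0, 200)
        t = np.arange(0, int(T)) * cal.time_per_px
        curve = curve_from_values(60 + 20 * np.sin(2 * np.pi * t / T), cal)
        cycle = CardiacCycle(0.0, T)
        out = ix.compute_pi(curve, cycle)
        v = 60 + 20 * np.sin(2 * np.pi * np.linspace(0, T, 100001) / T)
        expected = (v.max() - v.min()) / np.trapezoid(v, dx=T / 100000) * T
        assert out["pi"] == pytest.approx(expected, abs=1e-3)
        assert out["pi"] == pytest.approx(40.0 / 60.0, abs=1e-3)

    def test_scaling_invariance(self):
        cal = Calibration(1.0, 1.0, 200)
        t = np.arange(0, 500)
        v = 50 + 10 * np.sin(2 * np.pi * t / 500)
        c1 = curve_from_values(v, cal)
        c2 = curve_from_values(3.7 * v, cal)
        cycle = CardiacCycle(0.0, 500.0)
        assert ix.compute_pi(c1, cycle)["pi"] == pytest.approx(ix.compute_pi(c2, cycle)["pi"])

    def test_vertical_flip_invariance(self):
        cal = Calibration(1.0, 1.0, 200)
        t = np.arange(0, 500)
        v = 50 + 10 * np.sin(2 * np.pi * t / 500)
        cycle = CardiacCycle(0.0, 500.0)
        assert ix.compute_pi(curve_from_values(v, cal), cycle)["pi"] == pytest.approx(
            ix.compute_pi(curve_from_values(-v, cal), cycle)["pi"]
        )

    def test_zero_mean_rejected(self):
        curve = curve_from_values([0.0] * 100)
        with pytest.raises(ValueError, match="PI"):
            ix.compute_pi(curve, CardiacCycle(0.0, 100.0))


class TestLvioDurations:
    def test_hand_computed_differences(self):
        cyc = CardiacCycle(0.0, 500.0, [
            PhysioEvent("onset S", 0.0, 5.0),
            PhysioEvent("end S", 180.0, 4.0),
            PhysioEvent("onset E", 220.0, -5.0),
            PhysioEvent("end A", 430.0, -5.0),
        ])
        out = ix.compute_lvio_durations(cyc)
        assert out == {"s_duration": 180.0, "d_duration": 210.0}

    def test_missing_end_a_omits_d_with_warning(self):
        cyc = CardiacCycle(0.0, 500.0, [
            PhysioEvent("onset S", 0.0, 5.0),
            PhysioEvent("end S", 180.0, 4.0),
            PhysioEvent("onset E", 220.0, -5.0),
        ])
        with pytest.warns(UserWarning, match="D duration omitted"):
            out = ix.compute_lvio_durations(cyc)
        assert "d_duration" not in out and out["s_duration"] == 180.0


class TestEvaluateIndices:
    @staticmethod
    def report(medians, view="UA"):
        return ix.DopplerIndexReport(view=view, per_cycle=[], medians=medians)

    def test_median_across_cycles_example(self):
        # cycles pred [1.0, 1.2, 1.1] vs truth [1.0, 1.0, 1.0]:
        # medians 1.1 vs 1.0 -> image MAPE 10%
        pred = ix.DopplerIndexReport(
            view="UA",
            per_cycle=[{"pi": v} for v in (1.0, 1.2, 1.1)],
            medians={"pi": float(np.median([1.0, 1.2, 1.1]))},
        )
        truth = self.report({"pi": 1.0})
        table = ix.evaluate_indices([pred], [truth])
        assert table["pi"]["mape_mean"] == pytest.approx(10.0)
        assert table["pi"]["n"] == 1

    def test_identical_reports_zero_error(self):
        a = [self.report({"pi": 0.9, "v_max": 60.0})]
        table = ix.evaluate_indices(a, a)
        for key in ("pi", "v_max"):
            assert table[key]["mape_mean"] == 0.0
            assert table[key]["rmse_mean"] == 0.0

    def test_zero_truth_excluded_and_counted(self):
        pred = [self.report({"pi": 0.5})]
        truth = [self.report({"pi": 0.0})]
        table = ix.evaluate_indices(pred, truth)
        assert table["pi"]["n_zero_truth_excluded"] == 1
        assert np.isnan(table["pi"]["mape_mean"])

    def test_unpaired_rejected(self):
        with pytest.raises(ValueError):
            ix.evaluate_indices([], [])


class TestEndToEndRecovery:
    def test_noiseless_truth_masks_recover_events(self, ua_studies):
        from fetaldoppler import delineation as dl

        for st in ua_studies[:6]:
            mask = dl.encode_truth_mask(st.truth, "UA", st.calibration)
            curve, events = ix.postprocess_masks(mask, st.calibration)
            cal = st.calibration
            recovered = {e.name: [] for e in events}
            for e in events:
                recovered[e.name].append(e)
            for tev in st.truth["events"]:
                cands = recovered[tev["name"]]
                best = min(cands, key=lambda e: abs(e.t_ms - tev["t_ms"]))
                assert abs(best.t_ms - tev["t_ms"]) <= cal.time_per_px
                assert abs(best.v_cms - tev["v_cms"]) <= cal.vel_per_px

    def test_full_report_on_synthetic_study(self, ua_studies):
        from fetaldoppler import delineation as dl

        st = ua_studies[0]
        mask = dl.encode_truth_mask(st.truth, "UA", st.calibration)
        curve, events = ix.postprocess_masks(mask, st.calibration)
        rep = ix.compute_report(curve, events, "UA")
        assert len(rep.per_cycle) == st.truth["n_cycles"] - 1
        assert "pi" in rep.medians and rep.medians["pi"] > 0
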