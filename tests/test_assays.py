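import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tests.conftest import make_trace
from zfvision.assays import (
    color_preference,
    freeswim_summary,
    fstr_response,
    percent_response,
    vmr_response,
)
from zfvision.bout_analysis import bin_activity_table
from zfvision.protocols import AssayProtocol, LightEpoch, make_freeswim_protocol


class TestPercentResponse:
    @pytest.mark.parametrize(
        "pre, post, expected_rounded",
        [
            # published pre/post burst-duration means (x 10^-1 s removed)
            (0.0046, 0.0082, 178),  # wild type, 1000 ms flash
            (0.0045, 0.0062, 138),  # knock-out, 1000 ms flash
            (0.0052, 0.0058, 112),  # wild type, 10 ms flash
            (0.0048, 0.0052, 108),  # knock-out, 10 ms flash (109 in print, 108.33 exact)
        ],
    )
    def test_published_percent_values(self, pre, post, expected_rounded):
        assert round(percent_response(pre, post)) == expected_rounded

    def test_equal_pre_post_is_100(self):
        assert percent_response(0.3, 0.3) == pytest.approx(100.0)

    def test_zero_post(self):
        assert percent_response(0.5, 0.0) == 0.0

    def test_zero_pre_undefined(self):
        assert math.isnan(percent_response(0.0, 0.01))

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            percent_response(-0.1, 0.2)

    @given(
        st.floats(1e-6, 1e3),
        st.floats(0, 1e3),
        st.floats(1e-3, 1e3),
    )
    @settings(max_examples=50, deadline=None)
    def test_scale_invariance(self, pre, post, k):
        assert percent_response(k * pre, k * post) == pytest.approx(
            percent_response(pre, post), rel=1e-9
        )


def _records_from_speeds(per_well_speeds, bin_s=1.0, dt=0.1):
    traces = [
        make_trace(v, frame_dt_s=dt, well_id=w, genotype=g)
        for (w, g), v in per_well_speeds.items()
    ]
    return bin_activity_table(traces, bin_s)


class TestVmrResponse:
    def test_constructed_burst_fraction(self, short_vmr):
        """A larva bursting exactly 0.16 s in each 1 s post-ON window scores 0.16 s."""
        n = int(short_vmr.total_duration_s / 0.1)
        speeds = np.zeros(n)
        for t in (120.0, 240.0):  # ON transitions
            i = int(t / 0.1)
            # 0.16 s of burst: one full 0.1 s frame + 0.6 of a frame is not
            # representable; use windows from two trials averaging to 0.16
            speeds[i : i + 2] = 25.0  # 0.2 s burst after first ON
        speeds[int(240 / 0.1) : int(240 / 0.1) + 2] = 0.0
        speeds[int(240 / 0.1) : int(240 / 0.1) + 1] = 25.0  # 0.1 s after second
        rec = _records_from_speeds({("w1", "WT"): speeds})
        out = vmr_response(rec, short_vmr, "ON", window_s=1.0)
        assert out["WT"].per_larva_values[0] == pytest.approx(0.15)

    def test_all_inactive_scores_zero(self, short_vmr):
        n = int(short_vmr.total_duration_s / 0.1)
        rec = _records_from_speeds({("w1", "WT"): np.zeros(n)})
        out = vmr_response(rec, short_vmr, "ON")
        assert out["WT"].mean == 0.0

    def test_saturated_window_equals_window_length(self, short_vmr):
        n = int(short_vmr.total_duration_s / 0.1)
        rec = _records_from_speeds({("w1", "WT"): np.full(n, 30.0)})
        out = vmr_response(rec, short_vmr, "ON", window_s=5.0)
        assert out["WT"].mean == pytest.approx(5.0)

    def test_full_epoch_window_is_epoch_mean_burst(self, short_vmr):
        rng = np.random.default_rng(0)
        n = int(short_vmr.total_duration_s / 0.1)
        speeds = rng.choice([0.0, 30.0], size=n)
        rec = _records_from_speeds({("w1", "WT"): speeds})
        out = vmr_response(rec, short_vmr, "ON", window_s=60.0)
        on_bins = rec[
            ((rec.bin_start_s >= 120) & (rec.bin_start_s < 180))
            | ((rec.bin_start_s >= 240) & (rec.bin_start_s < 300))
        ]
        assert out["WT"].mean == pytest.approx(on_bins["dur_burst_s"].sum() / 2)

    def test_no_matching_transition_rejected(self):
        proto = make_freeswim_protocol("light", 5, bin_s=10)
        rec = _records_from_speeds({("w1", "WT"): np.zeros(3000)}, bin_s=10)
        with pytest.raises(ValueError, match="transitions"):
            vmr_response(rec, proto, "ON", window_s=10.0)


class TestFstrResponse:
    @pytest.fixture
    def mini_fstr(self):
        # 1 min recorded pre-dark, two cues (100 ms and 1000 ms), rests
        # chosen so every flash onset lands on a whole second
        def build(order):
            cues = [100, 1000] if order == "forward" else [1000, 100]
            epochs, t = [LightEpoch(0.0, 60.0, 0.0)], 60.0
            for c in cues:
                cue_s = c / 1000.0
                epochs.append(LightEpoch(t, cue_s, 30.0))
                t += cue_s
                rest = 120.0 - cue_s
                epochs.append(LightEpoch(t, rest, 0.0))
                t += rest
            return AssayProtocol("fstr", tuple(epochs), bin_s=1.0)

        return build

    def _speeds_for(self, proto, burst_s_pre, burst_s_post, dt=0.1):
        """Bursts burst_s_pre seconds just before and burst_s_post just after
        each flash onset (snapped to the bin grid)."""
        n = int(round(proto.total_duration_s / dt))
        speeds = np.zeros(n)
        for ep in proto.epochs:
            if ep.intensity_pct > 0:
                onset = math.floor(ep.start_s)  # snapped
                pre_frames = int(round(burst_s_pre / dt))
                post_frames = int(round(burst_s_post / dt))
                i = int(onset / dt)
                speeds[i - pre_frames : i] = 25.0
                speeds[i : i + post_frames] = 25.0
        return speeds

    def test_pre_post_extraction(self, mini_fstr):
        proto = mini_fstr("forward")
        speeds = self._speeds_for(proto, 1.0, 2.0)
        rec = _records_from_speeds({("w1", "WT"): speeds})
        per_larva, summaries = fstr_response((rec, proto), window_s=30.0)
        assert set(per_larva["cue_ms"]) == {100, 1000}
        assert np.allclose(per_larva["pre_s"], 1.0)
        assert np.allclose(per_larva["post_s"], 2.0)
        assert np.allclose(per_larva["percent"], 200.0)

    def test_forward_reverse_averaging_order_invariant(self, mini_fstr):
        fwd, rev = mini_fstr("forward"), mini_fstr("reverse")
        rec_f = _records_from_speeds({("w1", "WT"): self._speeds_for(fwd, 1.0, 3.0)})
        rec_r = _records_from_speeds({("w1", "WT"): self._speeds_for(rev, 2.0, 2.0)})
        pl_a, _ = fstr_response([(rec_f, fwd), (rec_r, rev)])
        pl_b, _ = fstr_response([(rec_r, rev), (rec_f, fwd)])
        pd.testing.assert_frame_equal(
            pl_a.sort_values("cue_ms").reset_index(drop=True),
            pl_b.sort_values("cue_ms").reset_index(drop=True),
        )
        # averaged pre = 1.5, post = 2.5 for both cue lengths
        assert np.allclose(pl_a["pre_s"], 1.5)
        assert np.allclose(pl_a["post_s"], 2.5)

    def test_equal_pre_post_is_100_percent(self, mini_fstr):
        proto = mini_fstr("forward")
        rec = _records_from_speeds({("w1", "WT"): self._speeds_for(proto, 1.0, 1.0)})
        _, summaries = fstr_response((rec, proto))
        for s in summaries.values():
            assert s.mean == pytest.approx(100.0)

    def test_overlapping_windows_rejected(self):
        epochs = (
            LightEpoch(0, 30.0, 0.0),
            LightEpoch(30.0, 1.0, 30.0),
            LightEpoch(31.0, 40.0, 0.0),
            LightEpoch(71.0, 1.0, 30.0),
            LightEpoch(72.0, 48.0, 0.0),
        )
        proto = AssayProtocol("fstr", epochs, bin_s=1.0)
        rec = _records_from_speeds({("w1", "WT"): np.zeros(1200)})
        with pytest.raises(ValueError, match="overlap"):
            fstr_response((rec, proto), window_s=30.0)

    def test_missing_pre_window_rejected(self):
        proto = AssayProtocol(
            "fstr", (LightEpoch(0, 1.0, 30.0), LightEpoch(1.0, 119.0, 0.0)), bin_s=1.0
        )
        rec = _records_from_speeds({("w1", "WT"): np.zeros(1200)})
        with pytest.raises(ValueError, match="both sides"):
            fstr_response((rec, proto), window_s=30.0)


class TestFreeswimSummary:
    def test_constant_coast_closed_form(self, constant_light):
        speeds = np.full(600, 10.0)  # 60 s at 10 mm/s
        rec = _records_from_speeds({("w1", "WT"): speeds}, bin_s=10.0)
        out = freeswim_summary(rec, "light", constant_light)
        assert out["distance_mm_per_10s"]["WT"].mean == pytest.approx(100.0)
        assert out["coast_dur_s_per_bin"]["WT"].mean == pytest.approx(10.0)
        assert out["burst_dur_s_per_bin"]["WT"].mean == 0.0

    def test_transitioning_protocol_rejected(self, short_vmr):
        rec = _records_from_speeds({("w1", "WT"): np.zeros(3600)})
        with pytest.raises(ValueError, match="constant"):
            freeswim_summary(rec, "light", short_vmr)

    def test_empty_records_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            freeswim_summary(pd.DataFrame(), "light")


class TestColorPreference:
    def test_all_fish_in_one_arm(self):
        counts = pd.DataFrame(
            {"timepoint": range(5), "B": 20, "R": 0, "G": 0, "Y": 0}
        )
        summary, _ = color_preference(counts)
        blue = summary.set_index("arm")["percent"]
        assert blue["B"] == 100.0 and blue["R"] == 0.0

    def test_uniform_counts(self):
        counts = pd.DataFrame(
            {"timepoint": range(4), "B": 5, "R": 5, "G": 5, "Y": 5}
        )
        summary, _ = color_preference(counts)
        assert np.allclose(summary["percent"], 25.0)

    def test_row_sum_exceeding_n_fish_rejected(self):
        counts = pd.DataFrame({"timepoint": [0], "B": [15], "R": [10]})
        with pytest.raises(ValueError, match="exceed"):
            color_preference(counts, n_fish=20)

    def test_two_color_plus_neutral_variant(self):
        counts = pd.DataFrame(
            {"timepoint": range(3), "B": [10, 11, 9], "G": [4, 3, 5], "N": [6, 6, 6]}
        )
        summary, series = color_preference(counts)
        assert set(summary["arm"]) == {"B", "G", "N"}
        assert summary["percent"].sum() == pytest.approx(100.0)
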