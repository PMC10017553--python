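import numpy as np
import pandas as pd
import pytest
from dataclasses import replace

from zfvision.bout_analysis import bin_activity_table, classify_speeds
from zfvision.protocols import AssayProtocol, LightEpoch
from zfvision.assays import vmr_response
from zfvision.simulator import (
    GenotypeConfig,
    LocomotorParams,
    PlateSpec,
    ko_genotype,
    simulate_biometry,
    simulate_cohort,
    simulate_color_maze,
    simulate_ct_table,
    simulate_morphometry,
    simulate_plate,
    simulate_trace,
    wt_genotype,
)


class TestLocomotorParams:
    def test_occupancies_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            LocomotorParams(occupancy_light=(0.5, 0.4, 0.2))

    def test_negative_gain_rejected(self):
        with pytest.raises(ValueError, match="gain"):
            LocomotorParams(startle_gain_on=-1.0)

    def test_nonpositive_dwell_rejected(self):
        with pytest.raises(ValueError, match="dwell"):
            LocomotorParams(dwell_light_s=(0.0, 1.0, 0.3))


class TestSimulateTrace:
    def test_determinism(self, short_vmr):
        p = LocomotorParams()
        a = simulate_trace(short_vmr, p, seed=42)
        b = simulate_trace(short_vmr, p, seed=42)
        np.testing.assert_array_equal(a.speeds, b.speeds)
        c = simulate_trace(short_vmr, p, seed=43)
        assert not np.array_equal(a.speeds, c.speeds)

    def test_no_burst_state_means_no_burst_speeds(self, short_vmr):
        p = LocomotorParams(
            occupancy_light=(0.4, 0.6, 0.0),
            occupancy_dark=(0.5, 0.5, 0.0),
            startle_gain_on=0.0,
            startle_gain_on_mesopic=0.0,
            startle_gain_off=0.0,
        )
        tr = simulate_trace(short_vmr, p, seed=0)
        assert np.all(tr.speeds < 20.0)

    def test_speed_state_consistency(self, short_vmr):
        """Coast frames lie strictly in (0, 20) and burst frames >= 20."""
        tr = simulate_trace(short_vmr, LocomotorParams(), seed=1)
        codes = classify_speeds(tr.speeds)
        coast = tr.speeds[codes == 1]
        burst = tr.speeds[codes == 2]
        assert np.all((coast > 0) & (coast < 20.0))
        assert np.all(burst >= 20.0)
        assert np.all(tr.speeds[codes == 0] == 0.0)

    def test_null_startle_no_transition_effect(self, short_vmr):
        """With zero gains and equal occupancies, the post-transition burst
        duration matches the pre-transition level within Monte-Carlo error."""
        occ = (0.45, 0.50, 0.05)
        p = LocomotorParams(
            occupancy_light=occ,
            occupancy_dark=occ,
            startle_gain_on=0.0,
            startle_gain_on_mesopic=0.0,
            startle_gain_off=0.0,
        )
        traces = simulate_cohort(short_vmr, p, 200, seed=9)
        rec = bin_activity_table(traces, 1.0)
        on = vmr_response(rec, short_vmr, "ON")["WT"]
        # pre-transition dark baseline, same 1 s scale
        base = rec[(rec.bin_start_s >= 60) & (rec.bin_start_s < 120)]
        base_mean = base.groupby("well_id")["dur_burst_s"].mean()
        diff = on.mean - base_mean.mean()
        se = np.sqrt(on.sem**2 + base_mean.sem() ** 2)
        assert abs(diff) < 4 * se


class TestSimulatePlate:
    def test_counts_and_determinism(self, short_vmr):
        plate = PlateSpec(n_wells=48, batch_ids=("b1", "b2"), seed=5)
        traces, meta = simulate_plate(
            short_vmr, [wt_genotype(), ko_genotype()], 48, plate
        )
        assert len(traces) == 96 and len(meta) == 96
        assert set(meta["genotype"]) == {"WT", "KO"}
        traces2, meta2 = simulate_plate(
            short_vmr, [wt_genotype(), ko_genotype()], 48, plate
        )
        pd.testing.assert_frame_equal(meta, meta2)
        np.testing.assert_array_equal(traces[0].speeds, traces2[0].speeds)

    def test_zero_sds_give_unit_multipliers(self, short_vmr):
        plate = PlateSpec(well_light_sd=0.0, batch_effect_sd=0.0, seed=1)
        _, meta = simulate_plate(short_vmr, [wt_genotype()], 10, plate)
        assert (meta["well_light_factor"] == 1.0).all()
        assert (meta["batch_factor"] == 1.0).all()

    def test_capacity_enforced(self, short_vmr):
        plate = PlateSpec(n_wells=48, batch_ids=("b1",))
        with pytest.raises(ValueError, match="capacity"):
            simulate_plate(short_vmr, [wt_genotype(), ko_genotype()], 48, plate)


class TestSimulateBiometry:
    def test_cohort_mean_within_3_se(self):
        geno = wt_genotype()
        df = simulate_biometry(26, geno, seed=2)
        mu, sd = geno.biometry["lens_radius_um"]
        assert abs(df["lens_radius_um"].mean() - mu) < 3 * sd / np.sqrt(26)

    def test_zero_correlation_large_sample(self):
        geno = replace(wt_genotype(), biometry_corr=0.0)
        df = simulate_biometry(10_000, geno, seed=3)
        r = np.corrcoef(df["lens_radius_um"], df["retinal_radius_um"])[0, 1]
        assert abs(r) < 0.03

    def test_high_correlation_recovered(self):
        geno = replace(wt_genotype(), biometry_corr=0.9)
        df = simulate_biometry(5_000, geno, seed=4)
        r = np.corrcoef(df["lens_radius_um"], df["retinal_radius_um"])[0, 1]
        assert r == pytest.approx(0.9, abs=0.03)

    def test_invalid_correlation_rejected(self):
        with pytest.raises(ValueError):
            replace(wt_genotype(), biometry_corr=1.5)

    def test_determinism(self):
        a = simulate_biometry(10, wt_genotype(), seed=7)
        b = simulate_biometry(10, wt_genotype(), seed=7)
        pd.testing.assert_frame_equal(a, b)


class TestSimulateMorphometry:
    def test_zero_replicate_sd_gives_identical_triplicates(self):
        df = simulate_morphometry(5, wt_genotype(), replicate_sd=0.0, seed=1)
        for trait in ("body_mm", "head_mm", "midbrain_mm"):
            assert (df[f"{trait}_1"] == df[f"{trait}_2"]).all()
            assert (df[f"{trait}_2"] == df[f"{trait}_3"]).all()

    def test_cohort_means_within_3_se(self):
        geno = wt_genotype()
        df = simulate_morphometry(19, geno, replicate_sd=0.02, seed=11)
        for trait, (mu, sd) in geno.morphometry.items():
            avg = df[[f"{trait}_{r}" for r in (1, 2, 3)]].mean(axis=1)
            assert abs(avg.mean() - mu) < 3 * sd / np.sqrt(19) + 0.02

    def test_determinism(self):
        a = simulate_morphometry(8, ko_genotype(), seed=3)
        b = simulate_morphometry(8, ko_genotype(), seed=3)
        pd.testing.assert_frame_equal(a, b)


class TestSimulateCtTable:
    def test_unit_fold_no_noise_gives_identical_groups(self):
        df = simulate_ct_table(
            ["18s", "drd3"], {"drd3": 1.0}, {}, references=["18s"],
            ct_noise_sd=0.0, seed=0,
        )
        piv = df.pivot_table(index=["gene", "replicate"], columns="group", values="ct")
        assert np.allclose(piv["control"], piv["treated"])

    def test_half_fold_shifts_one_cycle(self):
        df = simulate_ct_table(
            ["18s", "g"], {"g": 0.5}, {"g": 2.0, "18s": 2.0}, references=["18s"],
            ct_noise_sd=0.0, seed=0,
        )
        g = df[df.gene == "g"]
        delta = (
            g.loc[g.group == "treated", "ct"].mean()
            - g.loc[g.group == "control", "ct"].mean()
        )
        assert delta == pytest.approx(1.0)

    def test_reference_with_fold_change_rejected(self):
        with pytest.raises(ValueError, match="reference"):
            simulate_ct_table(["18s"], {"18s": 0.5}, {}, references=["18s"])

    def test_bad_efficiency_rejected(self):
        with pytest.raises(ValueError, match="efficiency"):
            simulate_ct_table(["18s", "g"], {}, {"g": 0.9}, references=["18s"])


class TestSimulateColorMaze:
    def test_counts_sum_to_n_fish(self):
        df = simulate_color_maze(20, {"B": 2, "R": 1, "G": 1, "Y": 1}, 18, seed=0)
        assert (df[["B", "R", "G", "Y"]].sum(axis=1) == 20).all()

    def test_single_arm_takes_all(self):
        df = simulate_color_maze(15, {"B": 1.0, "R": 0.0}, 10, seed=1)
        assert (df["B"] == 15).all() and (df["R"] == 0).all()

    def test_equal_weights_symmetric(self):
        df = simulate_color_maze(20, {a: 1.0 for a in "BRGY"}, 2000, seed=2)
        pct = 100 * df[list("BRGY")].mean() / 20
        assert np.allclose(pct, 25.0, atol=1.5)

    def test_too_many_fish_rejected(self):
        with pytest.raises(ValueError):
            simulate_color_maze(21, {"B": 1}, 5)
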