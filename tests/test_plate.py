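"""Plate pipeline: I/O, corrections, calibration, IC90s, rank-sum test."""

import itertools

import numpy as np
import pytest
from scipy import stats

from commpharm.plate import (
    CHANNELS,
    Ic90Estimate,
    PlateFormatError,
    PlateTimeSeries,
    WellMeta,
    blank_correct,
    calibrate_fluorescence,
    empirical_ic90,
    estimated_od,
    exact_mann_whitney,
    read_plate,
    relative_drug_content,
    write_layout,
    write_plate,
)


def make_plate(well_specs, times=None, channels=("OD600", "YFP"),
               strain_channels=None):
    """Tiny hand-built plate; well_specs maps well -> (meta, values)."""
    times = np.asarray([0.0, 1.0, 2.0] if times is None else times, float)
    wells = list(well_specs)
    values = np.stack([np.asarray(v, float).reshape(len(times),
                                                    len(channels))
                       for _, v in well_specs.values()])
    return PlateTimeSeries(
        wells=wells, times=times, channels=list(channels), values=values,
        metadata={w: m for w, (m, _) in well_specs.items()},
        strain_channels=strain_channels or {"A": "YFP"})


def sample_meta(conc=0.0, rep=1, strains=("A",)):
    return WellMeta(strains=tuple(strains), concentration=conc,
                    replicate=rep)


BLANK = WellMeta(strains=(), concentration=None, replicate=1, blank=True)


class TestIO:
    def test_minimal_roundtrip_is_exact(self, tmp_path):
        rng = np.random.default_rng(0)
        plate = make_plate({
            "b1": (BLANK, rng.uniform(0, 0.1, (3, 2))),
            "w1": (sample_meta(), rng.uniform(0, 2, (3, 2))),
        })
        write_plate(plate, tmp_path / "p.csv")
        write_layout(plate, tmp_path / "l.yaml")
        rt = read_plate(tmp_path / "p.csv", tmp_path / "l.yaml")
        idx = [rt.well_index(w) for w in plate.wells]
        assert np.array_equal(rt.values[idx], plate.values)
        assert rt.metadata["w1"] == plate.metadata["w1"]

    def test_unmapped_well_named_in_error(self, tmp_path):
        plate = make_plate({"b1": (BLANK, np.zeros((3, 2))),
                            "w9": (sample_meta(), np.ones((3, 2)))})
        write_plate(plate, tmp_path / "p.csv")
        layout = ({"b1": BLANK}, {"A": "YFP"})
        with pytest.raises(PlateFormatError, match="w9"):
            read_plate(tmp_path / "p.csv", layout)

    def test_duplicate_rows_rejected(self, tmp_path):
        plate = make_plate({"b1": (BLANK, np.zeros((3, 2))),
                            "w1": (sample_meta(), np.ones((3, 2)))})
        write_plate(plate, tmp_path / "p.csv")
        with open(tmp_path / "p.csv", "a") as fh:
            fh.write("w1,0.0,YFP,1.0\n")
        with pytest.raises(PlateFormatError, match="duplicate"):
            read_plate(tmp_path / "p.csv",
                       (dict(plate.metadata), plate.strain_channels))

    def test_nonuniform_time_grid_rejected(self, tmp_path):
        plate = make_plate({"b1": (BLANK, np.zeros((3, 2))),
                            "w1": (sample_meta(), np.ones((3, 2)))},
                           times=[0.0, 1.0, 2.0])
        df = plate.to_frame()
        df.loc[df.time_h == 2.0, "time_h"] = 2.5
        df.to_csv(tmp_path / "p.csv", index=False)
        with pytest.raises(PlateFormatError, match="non-uniform"):
            read_plate(tmp_path / "p.csv",
                       (dict(plate.metadata), plate.strain_channels))

    def test_missing_strain_channel_rejected(self, tmp_path):
        plate = make_plate({"b1": (BLANK, np.zeros((3, 1))),
                            "w1": (sample_meta(), np.ones((3, 1)))},
                           channels=("OD600",))
        write_plate(plate, tmp_path / "p.csv")
        with pytest.raises(PlateFormatError, match="YFP"):
            read_plate(tmp_path / "p.csv",
                       (dict(plate.metadata), {"A": "YFP"}))

    def test_generator_output_parses_cleanly(self, tmp_path,
                                             noisy_equal_plate, recwarn):
        plate, _ = noisy_equal_plate
        write_plate(plate, tmp_path / "p.csv")
        write_layout(plate, tmp_path / "l.yaml")
        rt = read_plate(tmp_path / "p.csv", tmp_path / "l.yaml")
        assert len(rt.wells) == len(plate.wells)
        assert len(recwarn) == 0


class TestBlankCorrection:
    def test_samples_equal_to_blanks_become_zero(self):
        v = np.tile([[0.05, 7.0]], (3, 1))
        plate = make_plate({"b1": (BLANK, v), "w1": (sample_meta(), v)})
        bc = blank_correct(plate)
        assert np.allclose(bc.values[bc.well_index("w1")], 0.0)

    def test_zero_blanks_leave_data_unchanged(self):
        sig = np.arange(6.0).reshape(3, 2)
        plate = make_plate({"b1": (BLANK, np.zeros((3, 2))),
                            "w1": (sample_meta(), sig)})
        bc = blank_correct(plate)
        assert np.array_equal(bc.values[bc.well_index("w1")], sig)

    def test_constant_offset_recovered(self, silent_equal_plate, presets):
        # generator adds a constant blank level; correction removes it,
        # so corrected OD equals the model biomass exactly
        plate, truth = silent_equal_plate
        design = presets["equal-sensitivity"]
        traj = truth.trajectories[("pure-A", 0.0)]
        well = "pure-A-c00-r1"
        od = plate.series(well, "OD600")
        assert np.allclose(od, traj.S.sum(axis=0), atol=1e-12)

    def test_readding_blank_series_roundtrips(self):
        rng = np.random.default_rng(1)
        blanks = rng.uniform(0.02, 0.06, (3, 2))
        sig = rng.uniform(0.5, 2.0, (3, 2))
        plate = make_plate({"b1": (BLANK, blanks),
                            "w1": (sample_meta(), sig)})
        bc = blank_correct(plate)
        restored = bc.values + blanks[None, :, :]
        assert np.allclose(restored[plate.well_index("w1")], sig)

    def test_requires_blank_wells(self):
        with pytest.raises(PlateFormatError):
            make_plate({"w1": (sample_meta(), np.ones((3, 2)))})


class TestCalibration:
    def _pure_plate(self, factor=100.0, n_wells=2):
        wells = {"b1": (BLANK, np.zeros((3, 2)))}
        rng = np.random.default_rng(2)
        for i in range(n_wells):
            od = rng.uniform(0.2, 1.0, (3, 1))
            wells[f"w{i}"] = (sample_meta(rep=i + 1),
                              np.hstack([od, od * factor]))
        return blank_correct(make_plate(wells))

    def test_proportional_fluorescence_recovers_ratio(self):
        cal = calibrate_fluorescence(self._pure_plate(100.0), "A")
        assert cal.ratio == pytest.approx(0.01)
        assert cal.cv == pytest.approx(0.0, abs=1e-12)

    def test_noisy_ratio_recovered_within_two_percent(self,
                                                      noisy_equal_plate):
        plate, truth = noisy_equal_plate
        cal = calibrate_fluorescence(plate, "S1")
        assert cal.ratio == pytest.approx(truth.ratios["S1"], rel=0.02)
        assert cal.n_points > 100

    def test_points_below_detection_floor_excluded(self):
        plate = self._pure_plate(100.0)
        # raise the floor artificially: all points excluded -> error
        plate.blank_sd = {"OD600": 10.0, "YFP": 10.0}
        with pytest.raises(PlateFormatError, match="detection floor"):
            calibrate_fluorescence(plate, "A")

    def test_requires_pure_wells(self):
        plate = blank_correct(make_plate({
            "b1": (BLANK, np.zeros((3, 2))),
            "m1": (sample_meta(strains=("A", "B")), np.ones((3, 2)))}))
        with pytest.raises(PlateFormatError, match="pure"):
            calibrate_fluorescence(plate, "A")


class TestEstimatedOD:
    def test_eod_reproduces_od600_in_pure_culture(self):
        plate = TestCalibration()._pure_plate(50.0)
        cal = calibrate_fluorescence(plate, "A")
        eod = estimated_od(plate, "A", cal.ratio)
        for w in ("w0", "w1"):
            assert np.allclose(eod.loc[w].to_numpy(),
                               plate.series(w, "OD600"))

    def test_mixed_eods_sum_to_od600_noise_free(self,
                                                silent_resistant_plate):
        plate, truth = silent_resistant_plate
        e1 = estimated_od(plate, "S1", truth.ratios["S1"])
        e2 = estimated_od(plate, "S2", truth.ratios["S2"])
        mixed = [w for w in plate.wells
                 if plate.metadata[w].composition == "mixed"]
        for w in mixed[:5]:
            total = e1.loc[w].to_numpy() + e2.loc[w].to_numpy()
            assert np.allclose(total, plate.series(w, "OD600"),
                               rtol=1e-9, atol=1e-12)

    def test_zero_fluorescence_gives_zero_eod(self):
        plate = blank_correct(make_plate({
            "b1": (BLANK, np.zeros((3, 2))),
            "w1": (sample_meta(), np.hstack([np.ones((3, 1)),
                                             np.zeros((3, 1))]))}))
        eod = estimated_od(plate, "A", 0.01)
        assert np.allclose(eod.loc["w1"].to_numpy(), 0.0)


class TestEmpiricalIc90:
    def test_noise_free_matches_generating_truth(self, silent_equal_plate):
        plate, truth = silent_equal_plate
        est = empirical_ic90(plate, "S1", "pure")
        assert est.mean == pytest.approx(truth.ic90_grid[("S1", "pure")],
                                         rel=1e-9)
        assert np.ptp(est.replicate_ic90) == pytest.approx(0.0, abs=1e-9)

    def test_flat_replicate_reports_absent(self):
        specs = {"b1": (BLANK, np.zeros((3, 2)))}
        for ci, conc in enumerate([0.0, 1.0, 2.0]):
            specs[f"w{ci}"] = (sample_meta(conc=conc),
                               np.full((3, 2), 1.0))  # no inhibition
        est = empirical_ic90(blank_correct(make_plate(specs)), "A", "pure")
        assert np.isnan(est.replicate_ic90).all()
        assert est.n == 0

    def test_missing_zero_drug_well_is_an_error(self):
        specs = {"b1": (BLANK, np.zeros((3, 2))),
                 "w1": (sample_meta(conc=1.0), np.ones((3, 2)))}
        with pytest.raises(PlateFormatError, match="zero-drug"):
            empirical_ic90(blank_correct(make_plate(specs)), "A", "pure")

    def test_pipeline_is_deterministic(self, tmp_path, noisy_equal_plate):
        plate, _ = noisy_equal_plate
        write_plate(plate, tmp_path / "p.csv")
        write_layout(plate, tmp_path / "l.yaml")
        runs = []
        for _ in range(2):
            p = blank_correct(read_plate(tmp_path / "p.csv",
                                         tmp_path / "l.yaml"))
            runs.append(empirical_ic90(p, "S1", "mixed").replicate_ic90)
        assert np.array_equal(runs[0], runs[1])


def brute_force_mwu(x, y):
    """Enumerate all C(n+m, n) assignments of the pooled mid-ranks."""
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    n, total = len(x), len(pooled)
    obs = ranks[:n].sum()
    sums = np.array([ranks[list(c)].sum()
                     for c in itertools.combinations(range(total), n)])
    p_le = np.mean(sums <= obs + 1e-9)
    p_ge = np.mean(sums >= obs - 1e-9)
    return obs, min(1.0, 2.0 * min(p_le, p_ge))


class TestExactMannWhitney:
    def test_complete_separation_of_two_octets(self):
        res = exact_mann_whitney(np.arange(1, 9), np.arange(9, 17))
        assert res.ranksum == 36
        assert res.pvalue == pytest.approx(2 / 12870)
        assert res.pvalue == pytest.approx(1.554e-4, rel=1e-3)
        assert res.exact

    def test_single_observations(self):
        assert exact_mann_whitney([1.0], [2.0]).pvalue == 1.0

    def test_identical_samples_are_null(self):
        res = exact_mann_whitney([3.0, 1.0, 2.0], [3.0, 1.0, 2.0])
        assert res.pvalue == 1.0

    def test_ranksum_bounds_and_p_in_unit_interval(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            n, m = rng.integers(1, 6, size=2)
            x = rng.integers(0, 5, size=n).astype(float)
            y = rng.integers(0, 5, size=m).astype(float)
            res = exact_mann_whitney(x, y)
            assert n * (n + 1) / 2 <= res.ranksum <= n * m + n * (n + 1) / 2
            assert 0.0 < res.pvalue <= 1.0

    def test_agrees_with_enumeration_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(1000):
            n, m = rng.integers(1, 6, size=2)
            x = rng.integers(0, 6, size=n).astype(float)
            y = rng.integers(0, 6, size=m).astype(float)
            res = exact_mann_whitney(x, y)
            obs, p = brute_force_mwu(x, y)
            assert res.ranksum == pytest.approx(obs)
            assert res.pvalue == pytest.approx(p)

    def test_agrees_with_scipy_on_tie_free_samples(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            x = rng.normal(size=6)
            y = rng.normal(loc=0.5, size=7)
            res = exact_mann_whitney(x, y)
            ref = stats.mannwhitneyu(x, y, alternative="two-sided",
                                     method="exact")
            assert res.pvalue == pytest.approx(ref.pvalue)
            # U statistic and rank sum are offset by n(n+1)/2
            assert res.ranksum - 6 * 7 / 2 == pytest.approx(ref.statistic)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            exact_mann_whitney([], [1.0])

    def test_tail_sum_method_bounded_by_doubled(self):
        x, y = [1.0, 2.0, 5.0], [3.0, 4.0, 6.0]
        doubled = exact_mann_whitney(x, y, method="doubled").pvalue
        tail = exact_mann_whitney(x, y, method="tail-sum").pvalue
        assert 0 < tail <= doubled + 1e-12

    def test_large_samples_use_normal_approximation(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=15)
        y = rng.normal(loc=1.0, size=15)
        res = exact_mann_whitney(x, y)
        assert not res.exact
        ref = stats.mannwhitneyu(x, y, alternative="two-sided",
                                 method="asymptotic", use_continuity=False)
        assert res.pvalue == pytest.approx(ref.pvalue, rel=1e-6)


class TestRelativeDrugContent:
    def _est(self, mean, density):
        return Ic90Estimate(strain="A", composition="pure",
                            replicate_ic90=np.array([mean]), mean=mean,
                            ci95=0.0, n=1, density_at_ic90=density,
                            metric="OD600")

    def test_identical_conditions_give_zero(self):
        assert relative_drug_content(self._est(2.0, 0.5),
                                     self._est(2.0, 0.5)) == 0.0

    def test_halved_density_gives_minus_fifty(self):
        assert relative_drug_content(
            self._est(2.0, 0.5), self._est(2.0, 0.25)) == pytest.approx(-50)

    def test_zero_density_rejected(self):
        with pytest.raises(ValueError):
            relative_drug_content(self._est(2.0, 0.0), self._est(2.0, 0.5))

    def test_resistant_neighbour_shifts_content_up_vs_sensitive(
            self, noisy_equal_plate, noisy_resistant_plate):
        eq, _ = noisy_equal_plate
        rs, _ = noisy_resistant_plate
        shift_sens = relative_drug_content(
            empirical_ic90(eq, "S1", "pure"),
            empirical_ic90(eq, "S1", "mixed"))
        shift_res = relative_drug_content(
            empirical_ic90(rs, "S1", "pure"),
            empirical_ic90(rs, "S1", "mixed"))
        assert shift_res > shift_sens
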