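import warnings

import numpy as np
import pytest

from emgvestal.evaluate import (
    LocalizationResult,
    PipelineConfig,
    ThresholdSpec,
    empty_room_threshold,
    localize_peak,
    run_pipeline,
    to_mni,
)
from emgvestal.geometry import SourceGrid
from emgvestal.preprocess import BANDS, Recording, bandpass, condition_emg
from emgvestal.projection import build_delay_matrix
from emgvestal.simulate import Scenario, CouplingSpec, simulate_dataset
from emgvestal.solver import SourceImage


@pytest.fixture(scope="module")
def theta_run(toy_geometry):
    """One short healthy run through the full pipeline on the toy grid."""
    grid, sensors, lf = toy_geometry
    scn = Scenario(name="toy", seed=0, duration=30.0,
                   couplings=[CouplingSpec("theta", -50.0)])
    data = simulate_dataset(scn, grid, sensors, lf)
    cfg = PipelineConfig(bands=("theta", "gamma"))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = run_pipeline(data["meg"], data["emg"], data["empty_room"], lf, grid,
                           cfg, truth_mm=data["truth"].target_coord_mm)
    return data, cfg, res


class TestThresholdSpec:
    def test_default_factors_arithmetic(self):
        spec = ThresholdSpec(empty_room_max=2.0)
        assert spec.threshold == 3.0  # 1.5 x
        assert spec.saturation == 6.0  # 3.0 x

    def test_configurable_factor(self):
        assert ThresholdSpec(empty_room_max=2.0, threshold_factor=2.0,
                             saturation_factor=4.0).threshold == 4.0

    def test_saturation_below_threshold_rejected(self):
        with pytest.raises(ValueError):
            ThresholdSpec(empty_room_max=1.0, threshold_factor=2.0, saturation_factor=1.0)


def line_grid():
    coords = np.array([[0.0, 0.0, 0.0], [0.003, 0.004, 0.0], [0.02, 0.0, 0.0]])
    return SourceGrid(node_coords=coords, spacing=0.005)


class TestLocalizePeak:
    def img(self, A):
        return SourceImage(A=np.asarray(A, float), map_kind="max_over_delays",
                           winning_delay_ms=np.full(len(A), -50.0))

    def test_single_suprathreshold_node_at_truth(self):
        res = localize_peak(self.img([5.0, 0.1, 0.1]), ThresholdSpec(1.0), line_grid(),
                            truth_mm=[0.0, 0.0, 0.0])
        assert res.success and res.distance_mm == 0.0 and res.peak_node == 0
        assert res.winning_delay_ms == -50.0

    def test_three_four_five_distance(self):
        res = localize_peak(self.img([0.1, 5.0, 0.1]), ThresholdSpec(1.0), line_grid(),
                            truth_mm=[0.0, 0.0, 0.0])
        assert res.distance_mm == pytest.approx(5.0)
        assert res.success  # within the default 10 mm
        res2 = localize_peak(self.img([0.1, 5.0, 0.1]), ThresholdSpec(1.0), line_grid(),
                             truth_mm=[0.0, 0.0, 0.0], radius_mm=4.0)
        assert not res2.success

    def test_below_threshold_status(self):
        res = localize_peak(self.img([0.5, 0.4, 0.3]), ThresholdSpec(1.0), line_grid(),
                            truth_mm=[0.0, 0.0, 0.0])
        assert res.status == "below_threshold" and res.success is False
        assert res.peak_node is None and res.raw_peak_node == 0

    def test_no_criterion_leaves_success_undefined(self):
        res = localize_peak(self.img([5.0, 0.1, 0.1]), ThresholdSpec(1.0), line_grid())
        assert res.success is None

    def test_roi_criterion(self):
        roi = np.array([False, True, False])
        res = localize_peak(self.img([0.1, 5.0, 0.1]), ThresholdSpec(1.0), line_grid(),
                            roi_mask=roi)
        assert res.success is True


class TestToMNI:
    def test_identity(self):
        pts = np.array([[1.0, 2.0, 3.0]])
        np.testing.assert_allclose(to_mni(pts, np.eye(4)), pts)

    def test_translation(self):
        aff = np.eye(4)
        aff[0, 3] = 10.0
        np.testing.assert_allclose(to_mni([1.0, 2.0, 3.0], aff), [11.0, 2.0, 3.0])

    def test_round_trip(self):
        rng = np.random.default_rng(0)
        aff = np.eye(4)
        aff[:3, :3] = rng.standard_normal((3, 3)) + 3 * np.eye(3)
        aff[:3, 3] = rng.standard_normal(3)
        pts = rng.standard_normal((5, 3))
        back = to_mni(to_mni(pts, aff), np.linalg.inv(aff))
        np.testing.assert_allclose(back, pts, atol=1e-9)

    def test_singular_affine_rejected(self):
        with pytest.raises(ValueError, match="singular"):
            to_mni([0.0, 0.0, 0.0], np.zeros((4, 4)))


class TestPipeline:
    def test_coupled_band_localizes_uncoupled_band_does_not(self, theta_run):
        data, cfg, res = theta_run
        assert res.bands["theta"].localization.success is True
        gamma = res.bands["gamma"].localization
        assert gamma.success is False

    def test_provenance_records_settings_and_hashes(self, theta_run):
        data, cfg, res = theta_run
        prov = res.provenance
        assert prov["config"]["threshold_factor"] == 1.5
        assert set(prov["inputs"]) == {"meg", "emg", "empty_room", "gain"}
        assert set(prov["bands"]) == {"theta", "gamma"}

    def test_winning_delay_near_true_lag(self, theta_run):
        data, cfg, res = theta_run
        assert abs(res.bands["theta"].localization.winning_delay_ms - (-50.0)) <= 10.0

    def test_scaling_task_and_empty_room_together_preserves_flags(self, toy_geometry):
        """Multiplying all sensor data by c>0 rescales maps and threshold
        together, so suprathreshold flags and success are unchanged."""
        grid, sensors, lf = toy_geometry
        scn = Scenario(name="toy", seed=1, duration=20.0,
                       couplings=[CouplingSpec("theta", -50.0)])
        data = simulate_dataset(scn, grid, sensors, lf)
        cfg = PipelineConfig(bands=("theta",))
        out = []
        for c in (1.0, 7.3):
            meg = data["meg"].copy_with(c * data["meg"].data)
            er = data["empty_room"].copy_with(c * data["empty_room"].data)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = run_pipeline(meg, data["emg"], er, lf, grid, cfg,
                                   truth_mm=data["truth"].target_coord_mm)
            br = res.bands["theta"]
            out.append((br.localization.success, br.localization.peak_node,
                        br.image.A.max() / br.threshold.threshold))
        assert out[0][0] == out[1][0] and out[0][1] == out[1][1]
        assert out[0][2] == pytest.approx(out[1][2], rel=1e-6)

    def test_truncated_input_still_runs_with_metadata(self, toy_geometry):
        grid, sensors, lf = toy_geometry
        scn = Scenario(name="toy", seed=2, duration=30.0,
                       couplings=[CouplingSpec("theta", -50.0)])
        data = simulate_dataset(scn, grid, sensors, lf)
        short = data["meg"].copy_with(data["meg"].data[:, :5000])
        cfg = PipelineConfig(bands=("theta",))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = run_pipeline(short, data["emg"], data["empty_room"], lf, grid, cfg,
                               truth_mm=data["truth"].target_coord_mm)
        assert res.provenance["common_samples"] == 5000
        assert "theta" in res.bands


class TestEmptyRoomThreshold:
    def test_deterministic_and_configurable(self, toy_geometry):
        grid, sensors, lf = toy_geometry
        scn = Scenario(name="toy", seed=3, duration=20.0)
        data = simulate_dataset(scn, grid, sensors, lf)
        emg_b = bandpass(condition_emg(data["emg"]), BANDS["theta"])
        ems = [build_delay_matrix(emg_b, channel=c) for c in range(2)]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            s1, _ = empty_room_threshold(data["empty_room"], lf, ems, BANDS["theta"])
            s2, _ = empty_room_threshold(data["empty_room"], lf, ems, BANDS["theta"])
            s3, _ = empty_room_threshold(data["empty_room"], lf, ems, BANDS["theta"],
                                         config=PipelineConfig(threshold_factor=2.0,
                                                               saturation_factor=4.0))
        assert s1.threshold == s2.threshold
        assert s1.threshold == pytest.approx(1.5 * s1.empty_room_max)
        assert s3.threshold == pytest.approx(2.0 * s3.empty_room_max)

    def test_duration_mismatch_warns(self, toy_geometry):
        grid, sensors, lf = toy_geometry
        scn = Scenario(name="toy", seed=4, duration=20.0)
        data = simulate_dataset(scn, grid, sensors, lf)
        emg_b = bandpass(condition_emg(data["emg"]), BANDS["theta"])
        ems = [build_delay_matrix(emg_b, channel=0)]
        with pytest.warns(UserWarning, match="50-200%"):
            empty_room_threshold(data["empty_room"], lf, ems, BANDS["theta"],
                                 task_duration=100.0)
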