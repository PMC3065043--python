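"""Discrete Laplacian, initial conditions, stepping, and volume readout."""

import json

import numpy as np
import pytest

from nanocell import (
    AdministrationSchedule,
    Grid,
    VolumeCurve,
    build_arm,
    calibrate_grid,
    crossing_day,
    initialize_state,
    laplacian_noflux,
    run_arm,
    stability_dt,
    step,
    tumor_volume,
    tumor_fixed_point,
    vasculature_fixed_points,
)
from nanocell.pharmacokinetics import DrugFields
from nanocell.simulator import SimulationState


class TestLaplacian:
    def test_constant_field_maps_to_zero(self):
        f = np.full((6, 6, 6), 3.7)
        np.testing.assert_allclose(laplacian_noflux(f, 0.5), 0.0, atol=1e-12)

    def test_quadratic_is_exact_in_the_interior(self):
        h = 0.25
        x = h * np.arange(8)
        f = np.broadcast_to((x**2)[:, None, None], (8, 8, 8)).copy()
        lap = laplacian_noflux(f, h)
        np.testing.assert_allclose(lap[1:-1, :, :], 2.0, atol=1e-10)

    def test_conservation_for_random_field(self):
        rng = np.random.default_rng(3)
        f = rng.uniform(0.0, 1.0, (12, 12, 12))
        lap = laplacian_noflux(f, 0.3)
        assert abs(lap.sum()) < 1e-10 * np.linalg.norm(f)

    def test_non_3d_rejected(self):
        with pytest.raises(ValueError, match="3D"):
            laplacian_noflux(np.zeros((4, 4)), 0.5)


class TestInitialState:
    def test_same_seed_bit_identical(self, lung, smoke_grid):
        a = initialize_state(smoke_grid, lung, 11)
        b = initialize_state(smoke_grid, lung, 11)
        assert np.array_equal(a.n, b.n) and np.array_equal(a.m, b.m)

    def test_unit_peak_gaussian(self, lung, smoke_grid):
        s = initialize_state(smoke_grid, lung, 0)
        assert s.n.max() == 1.0
        c = tuple(k // 2 for k in smoke_grid.shape)
        assert s.n[c] == 1.0
        assert s.n.min() >= 0.0

    def test_vessel_mosaic_mean_is_half(self, lung):
        grid = Grid.for_params(lung)  # full 50^3
        for seed in (0, 1, 2):
            s = initialize_state(grid, lung, seed)
            assert abs(s.m.mean() - 0.5) < 0.005  # CLT bound for U(0,1)

    def test_drug_fields_start_empty(self, lung, smoke_grid):
        s = initialize_state(smoke_grid, lung, 0)
        assert s.drugs.carriers == [] and s.drugs.c is None


class TestStep:
    def test_control_run_never_creates_drugs(self, lung, smoke_grid, schedule):
        curve = run_arm("V", lung, smoke_grid, seed=0, t_end_day=17)
        assert curve.arm == "V" and np.all(curve.volume_mm3 >= 0)

    def test_uniform_coupled_fixed_point_is_stationary(self, lung, smoke_grid, schedule):
        _, m_star = vasculature_fixed_points(lung)
        n_star = tumor_fixed_point(m_star, lung.alpha1_t)
        state = SimulationState(
            t=0.0, n=np.full(smoke_grid.shape, n_star),
            m=np.full(smoke_grid.shape, m_star), drugs=DrugFields(), rng_seed=0,
            day_offset=0.0)
        spec = build_arm("V")
        for _ in range(40):
            step(state, 0.05, spec, lung, schedule, smoke_grid)
        assert np.max(np.abs(state.n - n_star)) < 1e-9
        assert np.max(np.abs(state.m - m_star)) < 1e-9

    def test_single_euler_step_decays_drugs_exactly(self, lung, smoke_grid, schedule):
        # uniform free drug, zero carriers, m = 0: one step multiplies c by
        # (1 - nu_C dt) and d by (1 - nu_D dt)
        shape = smoke_grid.shape
        drugs = DrugFields()
        drugs.add_administration(shape, 8.0)  # zero carrier: no release
        drugs.c[:] = 0.5
        drugs.d[:] = 0.25
        state = SimulationState(t=0.0, n=np.zeros(shape), m=np.zeros(shape),
                                drugs=drugs, rng_seed=0, day_offset=0.0,
                                doses_applied=1)
        dt = 0.02
        step(state, dt, build_arm("L_CD"), lung, schedule, smoke_grid)
        np.testing.assert_allclose(state.drugs.c, 0.5 * (1 - lung.nuC_t * dt), rtol=1e-13)
        np.testing.assert_allclose(state.drugs.d, 0.25 * (1 - lung.nuD_t * dt), rtol=1e-13)

    def test_fields_stay_nonnegative_under_strong_therapy(self, melanoma, smoke_grid, schedule):
        shape = smoke_grid.shape
        drugs = DrugFields()
        drugs.add_administration(shape, 8.0)
        drugs.carriers[0][:] = 5.0
        drugs.c[:] = 50.0
        drugs.d[:] = 5.0
        state = SimulationState(t=melanoma.rho * 10.0, n=np.full(shape, 2.0),
                                m=np.full(shape, 1.5), drugs=drugs, rng_seed=0,
                                day_offset=0.0, doses_applied=1)
        for _ in range(20):
            step(state, 0.05, build_arm("NC_CD"), melanoma, schedule, smoke_grid)
        for f in (state.n, state.m, state.drugs.c, state.drugs.d):
            assert np.all(f >= 0.0)

    def test_dt_above_stability_bound_refused(self, lung, smoke_grid, schedule):
        state = initialize_state(smoke_grid, lung, 0)
        state.day_offset = 0.0
        bad_dt = smoke_grid.h**2  # 6x the bound
        with pytest.raises(ValueError, match="stability"):
            step(state, bad_dt, build_arm("V"), lung, schedule, smoke_grid)
        step(state, bad_dt, build_arm("V"), lung, schedule, smoke_grid,
             allow_unstable=True)  # explicit override

    def test_carriers_require_anchored_clock(self, lung, smoke_grid, schedule):
        state = initialize_state(smoke_grid, lung, 0)
        state.drugs.add_administration(smoke_grid.shape, 8.0)
        with pytest.raises(RuntimeError, match="anchored"):
            step(state, 0.01, build_arm("NC_D"), lung, schedule, smoke_grid)


class TestVolumeReadout:
    def test_empty_and_full_domain(self, lung, smoke_grid):
        assert tumor_volume(np.zeros(smoke_grid.shape), lung.c_th, smoke_grid) == 0.0
        full = np.ones(smoke_grid.shape)
        expect = np.prod(smoke_grid.shape) * smoke_grid.voxel_volume_mm3
        assert tumor_volume(full, lung.c_th, smoke_grid) == pytest.approx(expect)

    def test_threshold_counts_half(self, lung, smoke_grid):
        n = np.full(smoke_grid.shape, 0.05)
        half = np.prod(smoke_grid.shape) // 2
        n.ravel()[:half] = 0.1
        expect = half * smoke_grid.voxel_volume_mm3
        assert tumor_volume(n, 0.09, smoke_grid) == pytest.approx(expect)

    def test_crossing_interpolation(self):
        curve = VolumeCurve(days=[0.0, 10.0], volume_mm3=[0.0, 100.0], arm="V")
        assert crossing_day(curve, 50.0) == pytest.approx(5.0)
        flat = VolumeCurve(days=[0.0, 10.0], volume_mm3=[0.0, 0.0], arm="V")
        assert crossing_day(flat, 50.0) is None
        already = VolumeCurve(days=[2.0, 3.0], volume_mm3=[80.0, 90.0], arm="V")
        assert crossing_day(already, 50.0) == 2.0


class TestRunArm:
    def test_control_volume_non_decreasing(self, lung, smoke_grid):
        # the thresholded readout can jitter by a few voxels while the
        # initial profile relaxes and again near saturation; growth itself
        # must never lose more than that
        tol = 3 * smoke_grid.voxel_volume_mm3
        for seed in (0, 1, 2):
            curve = run_arm("V", lung, smoke_grid, seed=seed, t_end_day=17)
            assert np.all(np.diff(curve.volume_mm3) >= -tol)
            assert curve.volume_mm3[-1] > 10 * curve.volume_mm3[0]

    def test_matched_seed_run_is_deterministic(self, lung, smoke_grid):
        a = run_arm("NC_CD", lung, smoke_grid, seed=4, t_end_day=17)
        b = run_arm("NC_CD", lung, smoke_grid, seed=4, t_end_day=17)
        assert np.array_equal(a.volume_mm3, b.volume_mm3)

    def test_no_delivery_collapses_onto_control(self, lung, smoke_grid):
        p = lung.replace(delta_t=0.0)
        control = run_arm("V", p, smoke_grid, seed=2, t_end_day=17)
        treated = run_arm("NC_CD", p, smoke_grid, seed=2, t_end_day=17)
        assert np.array_equal(control.volume_mm3, treated.volume_mm3)

    def test_protocol_anchoring_places_crossing_at_start_day(self, lung, smoke_grid):
        curve = run_arm("V", lung, smoke_grid, seed=0, t_end_day=17,
                        align="crossing")
        # anchoring resolution is one recording interval (>= one step)
        assert crossing_day(curve, 50.0) == pytest.approx(8.0, abs=0.2)

    def test_horizon_before_last_dose_rejected(self, lung, smoke_grid):
        with pytest.raises(ValueError, match="last scheduled dose"):
            run_arm("V", lung, smoke_grid, seed=0, t_end_day=10.0)

    def test_run_artifacts_written(self, lung, smoke_grid, tmp_path):
        run_arm("NC_D", lung, smoke_grid, seed=1, t_end_day=17, out_dir=tmp_path)
        vols = (tmp_path / "volumes.csv").read_text().splitlines()
        assert vols[0] == "day,volume_mm3,arm,seed"
        manifest = json.loads((tmp_path / "manifest.json").read_text())
        assert manifest["arm"]["name"] == "NC_D"
        assert manifest["params"]["AD_t"] == lung.AD_t
        assert manifest["grid"]["h"] == smoke_grid.h
        assert manifest["doses_applied"] == 5


def test_calibrate_grid_reports_crossing_per_spacing(lung):
    best, table, achieved = calibrate_grid(
        lung, [0.8, 1.0], shape=(16, 16, 16), seed=0, max_days=20.0)
    assert set(table.columns) == {"h", "crossing_day"}
    assert len(table) == 2
    assert best in (0.8, 1.0)
    assert isinstance(achieved, bool)


def test_stability_dt_scales_with_grid(lung):
    fine = Grid.for_params(lung, h=0.1)
    coarse = Grid.for_params(lung, h=0.2)
    assert stability_dt(fine, lung) == pytest.approx(stability_dt(coarse, lung) / 4)
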