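from dataclasses import replace

import numpy as np
import pytest

from mbkit.mechanics import (
    Grid,
    LayerModel,
    fs_force_curve,
    fs_from_field,
    neighbor_coupling,
    roi_placement_sensitivity,
    solve_displacement_field,
    surface_response,
    thickness_decoupling_sweep,
)


@pytest.fixture(scope="module")
def solution():
    model = LayerModel()
    return model, solve_displacement_field(model)


class TestSurfaceResponse:
    def test_half_space_limit_matches_boussinesq(self):
        """Point-load displacement vs. u = P (1-nu^2)/(pi E r), referenced far away."""
        E, nu, h = 8.0, 0.49, 3000.0  # h >> domain: half-space regime
        n, d = 128, 4.0
        tau = np.zeros((n, n))
        P = 1.0  # kPa um^2
        tau[n // 2, n // 2] = P / d**2
        u = surface_response(tau, d, E, nu, h)
        yy, xx = np.mgrid[0:n, 0:n]
        r = np.hypot(yy - n // 2, xx - n // 2) * d

        def analytic(rr):
            return P * (1 - nu**2) / (np.pi * E * rr)

        r_ref = 200.0
        row = u[n // 2]
        order = np.argsort(r[n // 2])
        u_ref = np.interp(r_ref, r[n // 2][order], row[order])
        sel = (r > 3 * d) & (r < 100.0)
        rel = np.abs((u[sel] - u_ref) - (analytic(r[sel]) - analytic(r_ref)))
        rel /= analytic(r[sel]) - analytic(r_ref)
        assert rel.max() < 0.05

    def test_thinner_layer_is_stiffer(self):
        n, d = 64, 4.0
        tau = np.zeros((n, n))
        tau[n // 2, n // 2] = 1.0
        u_thick = surface_response(tau, d, 8.0, 0.49, 200.0)
        u_thin = surface_response(tau, d, 8.0, 0.49, 10.0)
        assert np.abs(u_thin).max() < np.abs(u_thick).max()


class TestSolve:
    def test_zero_eigenstrain_gives_zero_field_and_force(self):
        sol = solve_displacement_field(LayerModel(eigenstrain=0.0))
        assert np.abs(sol.ux).max() == 0.0
        assert sol.force_uN == 0.0
        assert sol.realized_fs == 0.0

    def test_linearity_doubling_eigenstrain_doubles_force(self, solution):
        model, sol = solution
        sol2 = solve_displacement_field(replace(model, eigenstrain=2 * model.eigenstrain))
        assert sol2.force_uN / sol.force_uN == pytest.approx(2.0, rel=0.01)
        assert sol2.realized_fs / sol.realized_fs == pytest.approx(2.0, rel=0.01)

    def test_superposition_of_load_cases(self, solution):
        model, _ = solution
        sA = solve_displacement_field(replace(model, eigenstrain=0.03))
        sB = solve_displacement_field(replace(model, eigenstrain=0.07))
        sAB = solve_displacement_field(replace(model, eigenstrain=0.10))
        err = np.abs(sA.ux + sB.ux - sAB.ux).max() / np.abs(sAB.ux).max()
        assert err < 1e-8

    def test_grid_refinement_changes_peak_under_2pct(self, solution):
        model, coarse = solution
        fine = solve_displacement_field(model, Grid(spacing=2.0))
        change = abs(np.abs(fine.ux).max() - np.abs(coarse.ux).max()) / np.abs(fine.ux).max()
        assert change < 0.02

    def test_force_positive_and_displacement_contractile(self, solution):
        _, sol = solution
        assert sol.force_uN > 0
        mid = len(sol.y) // 2
        # inward motion: u < 0 on the +x half, u > 0 on the -x half
        assert sol.u_at(140.0, 0.0) < 0 < sol.u_at(-140.0, 0.0)


class TestNeighborCoupling:
    def test_metric_decreases_with_gap_and_small_at_layout_gaps(self, solution):
        model, sol = solution
        nc = neighbor_coupling(model, gaps_um=(0.0, 40.0, 80.0, 160.0, 240.0), solution=sol)
        vals = [nc[g] for g in sorted(nc)]
        assert all(a >= b for a, b in zip(vals, vals[1:]))
        assert nc[0.0] == pytest.approx(1.0, abs=0.05)  # by construction
        # the micropattern layout: 240 um long-axis gap, 80 um short-axis gap
        assert nc[240.0] < 0.1
        short = neighbor_coupling(model, gaps_um=(80.0,), axis="short", solution=sol)
        assert short[80.0] < 0.1


class TestThicknessSweep:
    def test_deviation_monotone_decreasing_with_thickness(self):
        model = LayerModel()
        sweep = thickness_decoupling_sweep(model, h_values=(10.0, 20.0, 40.0, 70.0, 150.0))
        hs = sorted(sweep)
        devs = [sweep[h] for h in hs]
        assert all(a > b for a, b in zip(devs, devs[1:]))
        assert sweep[70.0] <= sweep[40.0]  # the paper's working thickness


class TestFsForceCurve:
    def test_curve_through_origin_strictly_increasing(self):
        model = LayerModel()
        out = fs_force_curve(model, eigenstrains=(0.02, 0.05, 0.08, 0.11))
        curve = out["curve"]
        assert np.all(np.diff(curve[:, 0]) > 0)
        assert np.all(np.diff(curve[:, 1]) > 0)
        # linear model: the curve extrapolates through the origin
        slope = curve[0, 1] / curve[0, 0]
        np.testing.assert_allclose(curve[:, 1] / curve[:, 0], slope, rtol=0.01)

    def test_modulus_sensitivity_reported_and_subproportional(self):
        model = LayerModel()
        out = fs_force_curve(model, eigenstrains=(0.03, 0.08))
        # E_tissue spans 8-12 kPa (a 40% relative spread); "minor" influence
        # means the force spread at fixed shortening stays well below that
        assert 0.0 <= out["modulus_sensitivity"] < 0.4

    def test_substrate_modulus_scales_response(self):
        # the layer kernel is exactly proportional to 1/E: a fixed traction
        # field on a doubled-modulus substrate produces half the motion
        n, d = 64, 4.0
        tau = np.zeros((n, n))
        tau[n // 2, n // 2] = 1.0
        u8 = surface_response(tau, d, 8.0, 0.49, 70.0)
        u16 = surface_response(tau, d, 16.0, 0.49, 70.0)
        np.testing.assert_allclose(u16, 0.5 * u8, atol=1e-15)
        # and in the coupled problem a stiffer substrate demands more force
        # per unit of realized shortening
        base = fs_force_curve(LayerModel(), eigenstrains=(0.05,))
        stiff = fs_force_curve(LayerModel(E_substrate=16.0), eigenstrains=(0.05,))
        f0 = base["curve"][0]
        f1 = stiff["curve"][0]
        assert f1[1] / f1[0] > f0[1] / f0[0]


class TestRoiPlacement:
    def test_uniform_strain_field_has_zero_error_everywhere(self):
        x = np.linspace(-200, 200, 401)
        u = -0.05 * x  # exact uniform-strain displacement profile
        for sep in (80.0, 150.0, 300.0):
            for off in (0.0, 10.0, -25.0):
                assert fs_from_field(u, x, sep, off) == pytest.approx(0.05, rel=1e-9)

    def test_inner50_gradient_smallest_ends_largest(self, solution):
        model, sol = solution
        out = roi_placement_sensitivity(sol, model.geometry, separations_frac=(0.5, 0.8, 1.0))
        g50 = out[0.5]["gradient_per_um"]
        g80 = out[0.8]["gradient_per_um"]
        g100 = out[1.0]["gradient_per_um"]
        assert g50 <= g80 <= g100
        assert g100 > 5 * g50  # end placement is by far the most sensitive


class TestValidation:
    @pytest.mark.parametrize(
        "kw",
        [dict(E_substrate=-1.0), dict(nu_substrate=0.6), dict(thickness=0.0), dict(eigenstrain=0.5)],
    )
    def test_invalid_model_rejected(self, kw):
        with pytest.raises(ValueError):
            LayerModel(**kw)


class TestExport:
    def test_solution_round_trips_to_csv_and_json(self, solution, tmp_path):
        import json

        import pandas as pd

        from mbkit.mechanics import write_solution

        model, sol = solution
        write_solution(sol, tmp_path / "run")
        df = pd.read_csv(tmp_path / "run_field.csv")
        assert len(df) == sol.ux.size
        np.testing.assert_allclose(
            df["ux_um"].to_numpy().reshape(sol.ux.shape), sol.ux, atol=1e-8
        )
        summary = json.loads((tmp_path / "run_summary.json").read_text())
        assert summary["force_uN"] == pytest.approx(sol.force_uN)
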