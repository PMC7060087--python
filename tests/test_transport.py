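import numpy as np
import pytest

from conftest import make_slab_strip
from oxchip.geometry import MATERIALS, DeviceSpec, Material, build_cross_section
from oxchip.transport import (
    BoundarySet,
    channel_axis_model,
    equilibration_time,
    gel_gradient_profile,
    pe_to_flow,
    region_flux_balance,
    slab_series_solution,
    solve_steady,
    solve_transient,
    sweep_steady,
)


class TestPeToFlow:
    @pytest.mark.parametrize(
        "pe,fluid,width,expect_attr,expect",
        [
            # printed gas-supply conversions
            (100, "gas", 1e-3, "Q", 18.0),
            (10, "gas", 1e-3, "Q", 1.8),
            # printed medium conversions
            (100, "medium", 500e-6, "Q", 1.8e-3),
            (500, "medium", 500e-6, "U", 2.0e-3),
        ],
    )
    def test_printed_conversions(self, pe, fluid, width, expect_attr, expect):
        flow = pe_to_flow(pe, fluid, width, 150e-6)
        assert getattr(flow, expect_attr) == pytest.approx(expect, rel=1e-12)

    def test_zero_pe_is_no_flow(self):
        flow = pe_to_flow(0, "medium", 500e-6, 150e-6)
        assert flow.U == 0 and flow.Q == 0

    def test_unknown_fluid_rejected(self):
        with pytest.raises(ValueError, match="unknown fluid"):
            pe_to_flow(10, "syrup", 1e-3, 150e-6)
        with pytest.raises(ValueError, match="medium or gas"):
            pe_to_flow(10, Material.GEL, 1e-3, 150e-6)


class TestSteady:
    def test_uniform_boundaries_constant_solution(self, coarse_grid):
        fld = solve_steady(coarse_grid, BoundarySet(21.0, 21.0))
        assert np.allclose(fld.phi, 21.0, atol=1e-8)

    def test_three_slab_column_matches_series_resistance(self):
        """Interior values of a gel|PDMS|film stack match the closed-form
        series-resistance solution to < 0.5% relative."""
        slabs = [
            (Material.GEL, 0.5e-3),
            (Material.PDMS, 1.0e-3),
            (Material.PC_FILM, 0.3e-3),
        ]
        grid, xc, interfaces = make_slab_strip(slabs)
        bc = BoundarySet(gas_left=2.0, gas_right=18.0, ambient_surfaces=())
        fld = solve_steady(grid, bc)
        iface_phi = slab_series_solution(
            [t for _, t in slabs],
            [MATERIALS[m].permeability for m, _ in slabs],
            2.0,
            18.0,
        )
        analytic = np.interp(xc, interfaces, iface_phi)
        sel = (xc >= interfaces[0]) & (xc < interfaces[-1])
        rel = np.abs(fld.phi[0, sel] - analytic[sel]) / np.abs(analytic[sel])
        assert rel.max() < 5e-3

    def test_maximum_principle(self, steady_gradient):
        assert steady_gradient.phi.min() >= -1e-9
        assert steady_gradient.phi.max() <= 21.0 + 1e-9

    def test_symmetric_bc_symmetric_field(self, steady_h0):
        phi = steady_h0.phi
        assert np.allclose(phi, phi[:, ::-1], atol=1e-8)

    def test_aqueous_flux_balance(self, steady_gradient):
        """At steady state the oxygen entering the aqueous layer leaves it
        again; the imbalance is < 0.1% of the gross exchange."""
        fb = region_flux_balance(
            steady_gradient, [Material.GEL, Material.MEDIUM]
        )
        assert abs(fb["net"]) < 1e-3 * fb["gross"]

    def test_center_value_linear_in_supply(self, coarse_grid):
        """The governing equations are linear in phi, so the gel-center
        value is affine in a uniform supply value."""
        cg = np.array([0.0, 1.0, 3.0, 5.0, 10.0, 21.0])
        centers = np.array(
            [solve_steady(coarse_grid, BoundarySet(c, c)).center_gel() for c in cg]
        )
        slope, intercept = np.polyfit(cg, centers, 1)
        pred = slope * cg + intercept
        ss_res = np.sum((centers - pred) ** 2)
        ss_tot = np.sum((centers - centers.mean()) ** 2)
        assert 1 - ss_res / ss_tot > 0.999

    def test_singular_without_dirichlet(self):
        grid, _, _ = make_slab_strip([(Material.PDMS, 1e-3)], gas_pad=0.1e-3)
        grid.material[:] = int(Material.PDMS)  # no gas cells anywhere
        with pytest.raises(ValueError, match="singular"):
            solve_steady(grid, BoundarySet(0.0, 0.0, ambient_surfaces=()))

    def test_low_gas_pe_warns(self):
        with pytest.warns(UserWarning, match="Pe < 10"):
            BoundarySet(0.0, 0.0, gas_pe=1.0)


class TestGelProfile:
    def test_uniform_field_flat_profile(self, coarse_grid):
        fld = solve_steady(coarse_grid, BoundarySet(21.0, 21.0))
        prof = gel_gradient_profile(fld)
        assert prof["slope_per_mm"] == pytest.approx(0.0, abs=1e-8)
        assert prof["endpoints"] == pytest.approx((21.0, 21.0))

    def test_slope_consistent_with_endpoints(self, steady_gradient):
        """For the near-linear gradient profile the fitted slope agrees
        with the endpoint difference over the gel span."""
        prof = gel_gradient_profile(steady_gradient)
        table = prof["table"]
        span_mm = (table["x_um"].iloc[-1] - table["x_um"].iloc[0]) / 1000.0
        slope_from_ends = (prof["endpoints"][1] - prof["endpoints"][0]) / span_mm
        assert prof["slope_per_mm"] == pytest.approx(slope_from_ends, rel=0.05)


class TestSweepSteady:
    def test_single_cell_sweep_matches_direct_solve(self, default_spec, coarse_grid):
        bc = BoundarySet(0.0, 0.0)
        table = sweep_steady([default_spec], {"H0": bc}, resolution=50e-6)
        assert len(table) == 1
        direct = solve_steady(coarse_grid, bc).center_gel()
        assert table["center_phi"].iloc[0] == pytest.approx(direct, rel=1e-12)

    def test_solver_failure_annotates_row(self, default_spec):
        bad = BoundarySet(0.0, 0.0)
        good = BoundarySet(0.0, 21.0)
        table = sweep_steady(
            [default_spec],
            [("bad", bad), ("good", good)],
            resolution=50e-6,
        )
        assert table["error"].isna().all()  # both solvable: no annotations
        assert len(table) == 2


class TestTransient:
    def test_initial_snapshot_preserved(self, coarse_grid):
        fld = solve_transient(
            coarse_grid, BoundarySet(0.0, 0.0), initial=21.0, t_end=20.0, dt=10.0
        )
        assert fld.times[0] == 0.0
        assert np.allclose(fld.phi[0], 21.0)

    def test_monotone_approach_to_steady(self, coarse_grid, steady_h0):
        fld = solve_transient(
            coarse_grid, BoundarySet(0.0, 0.0), initial=21.0, t_end=600.0, dt=10.0
        )
        assert np.all(np.diff(fld.trace_center) <= 1e-9)
        assert fld.trace_center[-1] >= steady_h0.center_gel() - 1e-6

    def test_equilibration_time_self_convergence(self, coarse_grid, steady_h0):
        """Halving dt moves the reported equilibration time by < 5%."""
        target = steady_h0.center_gel()
        times = {}
        for dt in (5.0, 2.5):
            fld = solve_transient(
                coarse_grid, BoundarySet(0.0, 0.0), initial=21.0, t_end=900.0, dt=dt
            )
            times[dt] = equilibration_time(fld, target, tol=0.5)
        assert abs(times[2.5] - times[5.0]) / times[2.5] < 0.05

    @pytest.mark.parametrize("kwargs", [dict(dt=0.0), dict(dt=-1.0), dict(dt=10.0, t_end=5.0)])
    def test_bad_stepping_rejected(self, coarse_grid, kwargs):
        kwargs.setdefault("t_end", 100.0)
        with pytest.raises(ValueError):
            solve_transient(coarse_grid, BoundarySet(0.0, 0.0), 21.0, **kwargs)


class TestChannelAxisModel:
    def test_no_flow_equilibrates_to_wall(self):
        flow = pe_to_flow(0, "medium", 500e-6, 150e-6)
        prof = channel_axis_model(flow, wall_value=5.0, inlet_value=21.0, length=0.01)
        assert np.allclose(prof["phi"], 5.0)

    def test_matches_closed_form_relaxation(self):
        flow = pe_to_flow(100, "medium", 500e-6, 150e-6)
        props = MATERIALS[Material.MEDIUM]
        h = 150e-6
        k_ex = props.permeability / (h / 2)
        lam = flow.U * props.solubility * h / k_ex
        prof = channel_axis_model(flow, wall_value=0.0, inlet_value=21.0, length=0.01)
        closed = 21.0 * np.exp(-prof["y"] / lam)
        assert np.abs(prof["phi"] - closed).max() < 1e-6

    def test_exit_value_monotone_in_pe(self):
        """Faster supply carries more of the inlet composition to the exit."""
        exits = []
        for pe in (1.0, 10.0, 100.0, 500.0):
            flow = pe_to_flow(pe, "medium", 500e-6, 150e-6)
            prof = channel_axis_model(flow, 0.0, 21.0, length=0.01)
            exits.append(prof["phi"].iloc[-1])
        assert np.all(np.diff(exits) > 0)
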