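import dataclasses

import numpy as np
import pytest

from isd3.config import GridSpec, InitialDistribution
from isd3.presets import preset
from isd3.solver import init_number_density, simulate
from isd3.transport import transport_coefficients

from oracles import diffusion_survival_fraction, transport_reference

D44_M2H = 1.394727785374969e-11 * 3600.0  # diffusivity of the coated 20 nm core


class TestInitialCondition:
    @pytest.mark.parametrize(
        "name,count",
        [("ag20_12.5", 8.9525e11), ("ag110_9.15", 3.9388e9)],
    )
    def test_monodisperse_counts_match_mass_balance(self, name, count):
        field = init_number_density(preset(name))
        assert field.total_count() == pytest.approx(count, rel=5e-5)

    def test_administered_mass_is_met_exactly(self, small_cfg):
        field = init_number_density(small_cfg)
        assert field.total_mass(small_cfg.particle) == pytest.approx(
            small_cfg.particle.C0 * small_cfg.media.V, rel=1e-12
        )

    def test_zero_dose_gives_empty_field(self, small_cfg):
        cfg = small_cfg.replace(
            particle=dataclasses.replace(small_cfg.particle, C0=0.0)
        )
        assert np.all(init_number_density(cfg).values == 0.0)

    def test_truncated_gaussian_is_normalized_above_primary_size(self, small_cfg):
        cfg = small_cfg.replace(
            init=InitialDistribution(kind="gaussian", mean=20.0, sigma=2.0)
        )
        field = init_number_density(cfg)
        assert field.total_mass(cfg.particle) == pytest.approx(
            cfg.particle.C0 * cfg.media.V, rel=1e-9
        )
        below = field.dp_nodes < cfg.particle.Dp1 - 1e-9
        assert np.all(field.values[:, below] == 0.0)

    def test_empirical_table_is_renormalized(self, small_cfg):
        cfg = small_cfg.replace(
            init=InitialDistribution(
                kind="empirical", table=[(20.0, 2.0), (22.0, 2.0)]
            )
        )
        field = init_number_density(cfg)
        assert field.total_mass(cfg.particle) == pytest.approx(
            cfg.particle.C0 * cfg.media.V, rel=1e-9
        )


class TestTransportStep:
    def test_frozen_coefficients_leave_field_unchanged(self, small_cfg, frozen_coeffs):
        cfg = small_cfg.replace(dissolution_enabled=False)
        field0 = init_number_density(cfg)
        co = frozen_coeffs(field0.dp_nodes, D=0.0, V=0.0)
        res = simulate(cfg, coeffs_override=co)
        # interior untouched; the absorbing wall claims only the initial
        # bottom half-cell (the N(L)=0 condition applied to the uniform IC)
        assert np.allclose(res.final_field.values[:-1], field0.values[:-1])
        wall_layer = 0.5 * cfg.grid.dx / cfg.media.L
        assert res.cell_count[-1] <= res.media_count[0] * wall_layer * 1.01
        assert res.media_count[-1] == pytest.approx(res.media_count[1], rel=1e-12)

    def test_matches_independent_single_size_reference(self, small_cfg, frozen_coeffs):
        # no dissolution: each bin is an independent advection-diffusion
        # column; compare against an exact-in-time matrix-exponential oracle
        cfg = small_cfg.replace(dissolution_enabled=False)
        field0 = init_number_density(cfg)
        V = 2e-5  # m/h, mildly sedimentation-influenced
        co = frozen_coeffs(field0.dp_nodes, D=D44_M2H, V=V)
        res = simulate(cfg, coeffs_override=co)
        n0 = field0.values[:, -1]
        for k, t in enumerate(res.times):
            if t == 0.0:
                continue
            _, surviving = transport_reference(field0.x_nodes, D44_M2H, V, n0, t)
            assert res.media_count[k] == pytest.approx(
                surviving * field0.dp_weights[-1], rel=1e-3
            )

    def test_pure_diffusion_matches_eigenfunction_series(self, small_cfg, frozen_coeffs):
        cfg = small_cfg.replace(dissolution_enabled=False)
        field0 = init_number_density(cfg)
        co = frozen_coeffs(field0.dp_nodes, D=D44_M2H, V=0.0)
        res = simulate(cfg, coeffs_override=co)
        k = list(res.times).index(10.0)  # ~77% deposited by then
        surv = res.media_count[k] / res.media_count[0]
        assert surv == pytest.approx(
            diffusion_survival_fraction(D44_M2H, cfg.media.L, 10.0), rel=1e-3
        )

    def test_pure_sedimentation_plug_empties_on_schedule(self, small_cfg, frozen_coeffs):
        cfg = small_cfg.replace(
            dissolution_enabled=False,
            grid=GridSpec(dx=small_cfg.grid.dx, dDp=1.0, t_max=15.0,
                          output_times=[10.0, 15.0]),
        )
        field0 = init_number_density(cfg)
        V = 1e-4  # m/h -> clears the 1 mm column in 10 h
        co = frozen_coeffs(field0.dp_nodes, D=0.0, V=V)
        res = simulate(cfg, coeffs_override=co)
        dep = res.cell_count / res.media_count[0]
        assert dep[1] > 0.90   # at t = L/V (upwind smears the trailing edge)
        assert dep[2] > 0.995  # at t = 1.5 L/V


class TestBoundaries:
    def test_zero_resistance_robin_equals_absorptive(self, small_cfg, frozen_coeffs):
        cfg_a = small_cfg.replace(dissolution_enabled=False)
        cfg_r = cfg_a.replace(boundary="robin", robin_alpha=0.0)
        co = frozen_coeffs(
            init_number_density(cfg_a).dp_nodes, D=D44_M2H, V=2e-5
        )
        res_a = simulate(cfg_a, coeffs_override=co)
        res_r = simulate(cfg_r, coeffs_override=co)
        assert np.allclose(res_a.cell_count, res_r.cell_count, rtol=1e-12)

    def test_deposition_monotone_in_robin_resistance(self, small_cfg, frozen_coeffs):
        co = frozen_coeffs(
            init_number_density(small_cfg).dp_nodes, D=D44_M2H, V=2e-5
        )
        deposited = []
        for alpha in (0.0, 1.0, 100.0, 1e4, 1e5, 1e6):
            cfg = small_cfg.replace(
                dissolution_enabled=False,
                boundary="robin" if alpha > 0 else "absorptive",
                robin_alpha=alpha,
            )
            deposited.append(simulate(cfg, coeffs_override=co).cell_count[-1])
        assert all(a >= b * (1.0 - 1e-12) for a, b in zip(deposited, deposited[1:]))
        assert deposited[-1] < 0.2 * deposited[0]  # strong resistance blocks uptake

    def test_noflux_bottom_retains_all_particles(self, small_cfg, frozen_coeffs):
        cfg = small_cfg.replace(dissolution_enabled=False, boundary="noflux")
        co = frozen_coeffs(init_number_density(cfg).dp_nodes, D=D44_M2H, V=2e-5)
        res = simulate(cfg, coeffs_override=co)
        assert res.media_count[-1] == pytest.approx(res.media_count[0], rel=1e-9)


class TestCoupledRun:
    def test_conservation_and_monotone_deposition(self, full_runs):
        for res in full_runs.values():
            drift_m, drift_n = res.ledger.max_relative_drift()
            assert drift_m < 1e-9   # silver mass, exact by construction
            assert drift_n < 1e-9   # particle number (floor prevents loss)
            assert np.all(np.diff(res.deposited_fraction) >= -1e-12)
            assert np.all(res.deposited_fraction <= 1.0 + 1e-12)

    def test_sizes_never_exceed_initial_maximum(self, full_runs):
        for res in full_runs.values():
            dp1 = res.config.particle.Dp1
            assert res.dp_nodes.max() == pytest.approx(dp1)
            assert np.all(res.final_field.values >= 0.0)

    def test_dissolution_off_deposits_more_particle_silver(self):
        # the dashed-curve comparison: without dissolution the cells see more
        # particulate silver by 24 h
        cfg = preset("ag110_9.15", grid=GridSpec(
            dx=3.1532e-6, dDp=1.0, t_max=24.0, output_times=[24.0]))
        with_diss = simulate(cfg)
        without = simulate(cfg.replace(dissolution_enabled=False))
        assert (
            without.cell_particle_mass[-1] > with_diss.cell_total_silver[-1]
        )

    def test_grid_refinement_changes_deposit_under_one_percent(self):
        coarse = preset("ag20_12.5", grid=GridSpec(
            dx=3.1532e-6, dDp=1.0, t_max=24.0, output_times=[24.0]))
        fine = preset("ag20_12.5", grid=GridSpec(
            dx=3.1532e-6 / 2.0, dDp=0.5, t_max=24.0, output_times=[24.0]))
        d_coarse = simulate(coarse).cell_particle_mass[-1]
        d_fine = simulate(fine).cell_particle_mass[-1]
        assert abs(d_fine - d_coarse) / d_coarse < 0.01

    def test_deterministic_rerun(self, small_cfg):
        a = simulate(small_cfg)
        b = simulate(small_cfg)
        assert np.array_equal(a.final_field.values, b.final_field.values)
        assert np.array_equal(a.cell_ion_mass, b.cell_ion_mass)

    def test_coupled_ions_track_well_mixed_vial_when_transport_is_frozen(
        self, small_cfg, frozen_coeffs
    ):
        # with transport frozen the column is a uniform suspension: the PBE
        # solver must reproduce the Lagrangian vial integrator (no cells
        # there, so shut uptake down with a tiny membrane diffusivity)
        from isd3.dissolution import dissolve_well_mixed

        cfg = small_cfg.replace(
            uptake=dataclasses.replace(small_cfg.uptake, D12=1e-30),
            grid=GridSpec(dx=small_cfg.grid.dx, dDp=0.25, t_max=10.0,
                          output_times=[5.0, 10.0]),
        )
        co = frozen_coeffs(init_number_density(cfg).dp_nodes, D=0.0, V=0.0)
        res = simulate(cfg, coeffs_override=co)
        vial = dissolve_well_mixed(cfg, times=res.times)
        assert res.C_diss[-1] == pytest.approx(vial.C_diss[-1], rel=2e-2)
        assert res.media_particle_mass[-1] == pytest.approx(
            vial.particle_mass[-1], rel=2e-2
        )


def test_transport_coefficients_used_are_for_the_coated_size(small_cfg):
    field = init_number_density(small_cfg)
    co = transport_coefficients(small_cfg.particle, small_cfg.media, field.dp_nodes)
    assert np.allclose(co.dpc_nodes, field.dp_nodes + 2 * small_cfg.particle.dRc)
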