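import dataclasses

import numpy as np
import pytest

from isd3.config import DissolutionParams, ParticleSpec, UptakeParams
from isd3.dissolution import (
    GCM3_TO_UGNM3,
    IonState,
    area_per_particle,
    dissolve_well_mixed,
    ion_rhs_media_only,
    ion_rhs_with_cells,
    ion_uptake_only,
    mass_per_particle,
    particle_surface_area,
    shrink_rate,
    simple_dissolution_rhs,
)
from isd3.presets import preset
from isd3.solver import init_number_density

PARAMS = DissolutionParams()
UPTAKE = UptakeParams()
P0, V = 10.0, 3.0
N2P0 = PARAMS.n2(P0) * P0
NP0 = PARAMS.n * P0


class TestSurfaceArea:
    def test_empty_field_has_no_area(self):
        cfg = preset("ag20_12.5")
        cfg = cfg.replace(particle=dataclasses.replace(cfg.particle, C0=0.0))
        acct = particle_surface_area(init_number_density(cfg), cfg.particle)
        assert acct.area_total == 0.0
        assert np.all(acct.per_bin == 0.0)

    def test_monodisperse_silver_area(self):
        # ~8.9525e11 particles of 20 nm: area = N * pi * 400 nm^2
        cfg = preset("ag20_12.5")
        field = init_number_density(cfg)
        acct = particle_surface_area(field, cfg.particle)
        expected = field.total_count() * np.pi * 400.0
        assert acct.area_total == pytest.approx(expected, rel=1e-12)
        assert acct.area_total == pytest.approx(1.125e15, rel=1e-3)
        assert acct.area_total == pytest.approx(acct.per_bin.sum(), rel=1e-12)

    def test_mass_equivalent_agglomerate_exposes_eight_primaries(self):
        # a fully dense agglomerate of twice the diameter holds 8 primaries
        p = ParticleSpec(Dp1=20.0, state="agglomerate", DF=3.0, Dmin=10.0, C0=1.0)
        assert area_per_particle(40.0, p) == pytest.approx(
            8.0 * np.pi * 20.0**2, rel=1e-12
        )

    def test_floor_bins_are_excluded(self):
        cfg = preset("ag20_12.5")
        field = init_number_density(cfg)
        field.values = field.values[:, ::-1].copy()  # move everything to Dmin
        acct = particle_surface_area(field, cfg.particle)
        assert acct.area_total == 0.0


class TestIonKinetics:
    def test_no_particles_no_ions_is_stationary(self):
        d = ion_rhs_media_only(IonState(), 0.0, PARAMS, P0, V)
        assert np.all(d == 0.0)

    def test_joint_saturation_is_a_fixed_point(self):
        # needs matching slow and fast capacities: n2c = P0**0.403 gives n2 = n
        params = dataclasses.replace(PARAMS, n2c=P0**0.403)
        assert params.n2(P0) == pytest.approx(params.n)
        st = IonState(C_f=params.C_sat, C_p=params.n * P0)
        d = ion_rhs_media_only(st, 1e15, params, P0, V)
        assert np.allclose(d, 0.0, atol=1e-18)

    def test_fresh_media_bound_rate_term_by_term(self):
        area = 1.125e15
        d = ion_rhs_media_only(IonState(), area, PARAMS, P0, V)
        k_p2_term = PARAMS.k_p2 * area / V * N2P0
        k_p_term = PARAMS.k_p * area / V * NP0
        assert d[1] == pytest.approx(k_p2_term + k_p_term, rel=1e-12)
        assert k_p2_term > 10 * k_p_term  # the fast pathway dominates at t=0
        assert d[0] == pytest.approx(PARAMS.k_f * area / V * PARAMS.C_sat, rel=1e-12)
        assert d[2] == 0.0

    def test_two_compartment_collapses_to_one_without_protein_terms(self):
        params = dataclasses.replace(PARAMS, k_p=0.0, k_p2=0.0, k_f2p=0.0, k_p2f=0.0)
        st = IonState(C_f=0.3, C_p=0.7)
        d = ion_rhs_media_only(st, 5e14, params, P0, V)
        assert d[0] == pytest.approx(
            simple_dissolution_rhs(0.3, 5e14, params.k_f, params.C_sat, V), rel=1e-15
        )
        assert d[1] == 0.0

    def test_uptake_decouples_at_zero_membrane_diffusivity(self):
        upt = dataclasses.replace(UPTAKE, D12=1e-30)
        st = IonState(0.2, 1.1, 0.05)
        with_cells = ion_rhs_with_cells(st, 1e14, PARAMS, upt, P0, V)
        media_only = ion_rhs_media_only(st, 1e14, PARAMS, P0, V)
        assert np.allclose(with_cells, media_only, atol=1e-20)

    def test_uptake_flux_hand_value(self):
        # D12*SA2/(V*Dis2) * C_f at C_f=1, C_cell=0
        st = IonState(C_f=1.0)
        d = ion_rhs_with_cells(st, 0.0, PARAMS, UPTAKE, P0, V)
        k = UPTAKE.D12 * UPTAKE.SA2 / (V * UPTAKE.Dis2)
        assert k == pytest.approx(0.036699, rel=1e-4)
        assert d[2] == pytest.approx(k * 1.0, rel=1e-12)

    def test_uptake_vanishes_at_per_phase_partition_equilibrium(self):
        cc = 0.01
        e = (cc * V / UPTAKE.V_cell) / UPTAKE.PC21
        st = IonState(C_f=e, C_p=e, C_cell=cc)
        with_cells = ion_rhs_with_cells(st, 2e14, PARAMS, UPTAKE, P0, V)
        media_only = ion_rhs_media_only(st, 2e14, PARAMS, P0, V)
        assert np.allclose(with_cells, media_only, atol=1e-16)

    def test_kinetic_subsystem_conserves_silver_against_surface_flux(self):
        # V * d(total ions)/dt must equal the mass flux off particle surfaces
        cfg = preset("ag20_12.5")
        field = init_number_density(cfg)
        st = IonState(0.2, 0.9, 0.0)
        acct = particle_surface_area(field, cfg.particle)
        d = ion_rhs_media_only(st, acct.area_total, cfg.dissolution, P0, V)
        lhs = V * d.sum()
        # -sum_bins N * dm_p/dt with dm_p/dt = (rho pi/2 Dp^2) dDp/dt
        counts = field.bin_counts()
        dp = field.dp_nodes
        s = np.asarray(shrink_rate(dp, st, cfg.dissolution, P0, cfg.particle))
        dm = (
            cfg.particle.rho_p1 * GCM3_TO_UGNM3 * np.pi / 2.0 * dp**2 * s
        )
        assert lhs == pytest.approx(-(counts @ dm), rel=1e-9)


class TestShrinkRate:
    def test_floor_is_inert(self):
        p = preset("ag20_1").particle
        assert shrink_rate(p.Dmin, IonState(), PARAMS, P0, p) == 0.0

    def test_saturated_media_halts_dissolution(self):
        p = preset("ag20_1").particle
        st = IonState(C_f=PARAMS.C_sat, C_p=NP0)
        params = dataclasses.replace(PARAMS, n2c=P0**0.403)  # n2*P0 == n*P0
        assert shrink_rate(20.0, st, params, P0, p) == pytest.approx(0.0, abs=1e-18)

    def test_fresh_media_rate_term_by_term(self):
        p = preset("ag20_1").particle
        ksum = (
            PARAMS.k_f * PARAMS.C_sat + PARAMS.k_p * NP0 + PARAMS.k_p2 * N2P0
        )
        expected = -2.0 / (p.rho_p1 * GCM3_TO_UGNM3) * ksum
        got = shrink_rate(20.0, IonState(), PARAMS, P0, p)
        assert got == pytest.approx(expected, rel=1e-12)
        assert got == pytest.approx(-0.42164, rel=1e-3)  # nm/h

    def test_agglomerates_shrink_faster_by_size_ratio(self):
        p = ParticleSpec(Dp1=20.0, state="agglomerate", DF=2.3, Dmin=10.0, C0=1.0)
        r20 = shrink_rate(20.0, IonState(), PARAMS, P0, p)
        r40 = shrink_rate(40.0, IonState(), PARAMS, P0, p)
        assert r40 == pytest.approx(2.0 * r20, rel=1e-12)

    def test_simple_model_signs(self):
        assert simple_dissolution_rhs(PARAMS.C_sat, 1e15, PARAMS.k_f, PARAMS.C_sat, V) == 0
        assert simple_dissolution_rhs(0.5, 0.0, PARAMS.k_f, PARAMS.C_sat, V) == 0
        assert simple_dissolution_rhs(0.5, 1e15, PARAMS.k_f, PARAMS.C_sat, V) > 0


class TestWellMixedVial:
    def test_biphasic_dissolution_rate(self):
        # total dissolution rate at t=0 exceeds the rate at 12 h
        cfg = preset("ag20_12.5")
        res = dissolve_well_mixed(cfg, times=np.linspace(0, 24, 49))

        def total_rate(k):
            st = IonState(res.C_f[k], res.C_p[k])
            d = ion_rhs_media_only(st, res.area[k], cfg.dissolution, P0, V)
            return d[0] + d[1]

        assert total_rate(0) > total_rate(24)  # index 24 <-> t = 12 h

    def test_pool_capacities_are_invariant_bounds(self):
        cfg = preset("ag20_12.5")
        res = dissolve_well_mixed(cfg, times=np.linspace(0, 48, 97))
        assert res.C_f.max() <= cfg.dissolution.C_sat + 1e-9
        cap = max(cfg.dissolution.n, cfg.dissolution.n2(P0)) * P0
        assert res.C_p.max() <= cap + 1e-9

    def test_silver_is_conserved_and_sizes_never_grow(self):
        cfg = preset("ag20_12.5")
        res = dissolve_well_mixed(cfg, times=np.linspace(0, 24, 25))
        total = res.particle_mass + cfg.media.V * res.C_diss
        assert np.abs(total - total[0]).max() / total[0] < 1e-6
        assert np.all(np.diff(res.diameters[:, 0]) <= 1e-12)
        assert res.diameters.min() >= cfg.particle.Dmin - 1e-6

    def test_dissolution_disabled_freezes_everything(self):
        cfg = preset("ag20_12.5").replace(dissolution_enabled=False)
        res = dissolve_well_mixed(cfg, times=np.linspace(0, 24, 7))
        assert np.all(res.diameters == res.diameters[0])
        assert np.all(res.C_diss == 0.0)


class TestIonOnlyUptake:
    def test_long_time_partition_ratio(self):
        cfg = preset("ag20_1")
        res = ion_uptake_only(cfg, 1.0, times=np.linspace(0, 300, 11))
        ratio = res.C_cell[-1] / (res.C_f[-1] + res.C_p[-1])
        expected = cfg.uptake.PC21 * cfg.uptake.V_cell / cfg.media.V
        assert ratio == pytest.approx(expected, rel=1e-6)

    def test_initial_bound_fraction_applied(self):
        cfg = preset("ag20_1")
        res = ion_uptake_only(cfg, 2.0, times=np.linspace(0, 1e-6, 3))
        assert res.C_p[0] == pytest.approx(2.0 * 0.85)
        assert res.C_f[0] == pytest.approx(2.0 * 0.15)

    def test_total_silver_conserved(self):
        cfg = preset("ag20_1")
        res = ion_uptake_only(cfg, 1.5, times=np.linspace(0, 24, 25))
        total = res.C_f + res.C_p + res.C_cell
        assert np.abs(total - 1.5).max() < 1e-7


def test_mass_per_particle_silver_core():
    p = preset("ag20_1").particle
    # 20 nm silver sphere: 10 g/cm^3 * pi/6 * 8000 nm^3 in ug
    assert mass_per_particle(20.0, p) == pytest.approx(
        10.0 * 1e-15 * np.pi / 6.0 * 8000.0, rel=1e-12
    )
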