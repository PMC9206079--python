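import numpy as np
import pytest

from gluquanta.allosteric import AllostericParams, allosteric_ps
from gluquanta.calcium import (
    BufferSpec,
    GridSolver,
    gaussian_influx,
    load_buffer_set,
    simulate_calcium,
)
from gluquanta.geometry import (
    CASE_LAYOUTS,
    PvMap,
    build_geometry,
    build_pv_map,
    place_rrp_sites,
)


class TestGeometry:
    def test_single_cluster_density_is_500(self):
        _, az = build_geometry("i")
        assert az.az_area == pytest.approx(0.032)
        assert az.channel_density == pytest.approx(500.0)

    def test_rrp_size_from_density(self):
        _, az = build_geometry("iv", az_area=0.10)
        assert az.rrp_size == 10  # 100 vesicles/um^2 * 0.10 um^2

    def test_rrp_size_clamped_to_range(self):
        _, az_small = build_geometry("i", az_area=0.03)
        assert az_small.rrp_size == 3

    def test_cluster_radius_30nm_everywhere(self):
        for case in CASE_LAYOUTS:
            _, az = build_geometry(case)
            assert az.cluster_radius == pytest.approx(0.030)

    def test_all_nine_cases_valid(self):
        for case, (n_cl, layout) in CASE_LAYOUTS.items():
            bouton, az = build_geometry(case)
            assert az.n_clusters == n_cl
            r = np.hypot(az.cluster_centers[:, 0], az.cluster_centers[:, 1])
            assert np.all(r + az.cluster_radius <= az.az_radius + 1e-9)
            assert abs(az.channel_density - 500.0) <= 100.0  # within 20%
            if layout.startswith("central"):
                assert r.min() < 1e-9  # one cluster at the centre
            else:
                assert np.all(r > 0.5 * az.az_radius)

    def test_invalid_case_rejected(self):
        with pytest.raises(ValueError):
            build_geometry("x")

    def test_az_area_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            build_geometry("i", az_area=0.2)

    def test_rrp_sites_inside_az(self, rng):
        _, az = build_geometry("v")
        pts = place_rrp_sites(az, rng)
        assert pts.shape[0] == az.rrp_size
        assert np.all(np.hypot(pts[:, 0], pts[:, 1]) <= az.az_radius)


class TestPvMap:
    @pytest.mark.parametrize(
        "p_s,p_a,expected",
        [(0.0, 0.03, 0.03), (1.0, 0.03, 1.0), (0.5, 0.03, 0.515)],
    )
    def test_overall_release_probability_formula(self, p_s, p_a, expected):
        pv = PvMap(positions=np.zeros((1, 2)), p_s=np.array([p_s]), p_a=p_a)
        assert pv.p_v[0] == pytest.approx(expected)

    def test_probability_bounds_enforced(self):
        with pytest.raises(ValueError):
            PvMap(positions=np.zeros((1, 2)), p_s=np.array([1.2]), p_a=0.03)

    def test_sync_fraction(self):
        pv = build_pv_map(np.zeros((1, 2)), np.array([0.5]), 0.03)
        assert pv.sync_fraction[0] == pytest.approx(0.5 / 0.515)


class TestBuffers:
    def test_shipped_buffer_sets_load(self):
        endo = load_buffer_set("endogenous")
        pip = load_buffer_set("pipette")
        assert {b.name for b in endo} == {"calmodulin", "calbindin_d28k", "atp"}
        assert {b.name for b in pip} == {"egta", "atp"}
        for b in endo + pip:
            assert b.total > 0 and b.kon > 0 and b.koff > 0 and b.D > 0

    def test_influx_waveform_integrates_to_n_ions(self):
        dt = 0.002
        t = np.arange(0, 3.0, dt) + dt / 2
        w = gaussian_influx(t, 2000.0, t0=0.5, fwhm=0.3)
        assert w.sum() == pytest.approx(2000.0)


class TestCalciumSolver:
    def test_rest_state_is_stationary(self):
        bouton, az = build_geometry("i", mesh_um=0.08)
        field = simulate_calcium(
            bouton, az, duration=2.0, dt=0.02, n_ions_per_cluster=0.0
        )
        assert np.max(np.abs(field.ca - 0.05)) < 0.01 * 0.05

    def test_mass_conserved_without_extrusion(self):
        # cube, buffers on, influx pulse, no extrusion: total Ca (free +
        # bound) is conserved within 0.5% over the run
        mask = np.ones((12, 12, 12), dtype=bool)
        buffers = load_buffer_set("endogenous")
        s = GridSolver(mask, 0.05, buffers=buffers, k_extr=0.0, dt=0.01)
        t0 = s.total_ca()
        n_steps = 300
        rate = np.zeros((n_steps, 1))
        rate[:50, 0] = 1000.0 / (50 * 0.01)  # 1000 ions over 0.5 ms
        src = np.array([s.voxel_index(6, 6, 6)])
        s.run(3.0, source_idx=src, source_rate=rate, record_every=50)
        added = 1000.0 / 602.2
        drift = abs(s.total_ca() - (t0 + added)) / (t0 + added)
        assert drift < 0.005

    def test_extrusion_relaxes_toward_rest(self):
        mask = np.ones((10, 10, 10), dtype=bool)
        s = GridSolver(mask, 0.05, buffers=[], k_extr=0.64, dt=0.01)
        s.ca[:] = 1.0  # uniformly elevated
        s.run(5.0)
        assert np.all(s.ca < 0.5)
        assert np.all(s.ca >= 0.05 - 1e-9)

    def test_point_source_matches_greens_function(self):
        # free diffusion, no buffers/extrusion: compare with the closed-form
        # point-source solution q/(4 pi D t)^{3/2} exp(-r^2/4Dt)
        h, D = 0.035, 0.220
        n = 33  # ~1.15 um box; probe early so the boundaries stay invisible
        mask = np.ones((n, n, n), dtype=bool)
        s = GridSolver(mask, h, buffers=[], k_extr=0.0, ca_rest=0.0, dt=0.002)
        c = n // 2
        amount = 1.0  # uM * um^3
        s.ca[s.voxel_index(c, c, c)] = amount / s.voxel_volume
        checks = []
        s.run(0.1)
        for k in (2, 3):  # probes at 70 and 105 nm, t = 0.1 ms
            r = k * h
            expect = amount / (4 * np.pi * D * 0.1) ** 1.5 * np.exp(-(r**2) / (4 * D * 0.1))
            checks.append((s.ca[s.voxel_index(c + k, c, c)], expect))
        s.run(0.15)  # t = 0.25 ms; probe at 175 nm
        r = 5 * h
        expect = amount / (4 * np.pi * D * 0.25) ** 1.5 * np.exp(-(r**2) / (4 * D * 0.25))
        checks.append((s.ca[s.voxel_index(c + 5, c, c)], expect))
        for got, expect in checks:
            assert got == pytest.approx(expect, rel=0.10)


class TestAllosteric:
    def test_zero_calcium_gives_basal_probability(self):
        t = np.linspace(0, 10, 50)
        ps = allosteric_ps(t, np.zeros(50))
        assert ps[0] < 1e-4
        assert ps[0] > 0

    def test_saturating_calcium_fuses_fully(self):
        t = np.linspace(0, 10, 50)
        ps = allosteric_ps(t, np.full(50, 1000.0))  # far above Kd = 40 uM
        assert ps[0] > 0.999

    def test_matches_fine_explicit_euler_oracle(self):
        params = AllostericParams.published()
        t = np.linspace(0, 10, 101)
        ca = 20.0 * np.exp(-((t - 1.0) ** 2) / 0.5)  # transient peaking 20 uM
        got = allosteric_ps(t, ca, params=params, dt=0.002)[0]
        # independent fine-step explicit Euler on the same master equation
        n = np.arange(6)
        off = n * params.koff * params.b ** np.maximum(n - 1, 0)
        fuse = params.l_plus * params.f**n
        p = np.zeros(7)
        p[0] = 1.0
        dt = 1e-4
        for step in range(int(10.0 / dt)):
            c = np.interp((step + 0.5) * dt, t, ca)
            on = (5 - n) * params.kon * c
            dp = np.zeros(7)
            dp[:6] -= (on + off + fuse) * p[:6]
            dp[1:6] += on[:-1] * p[:5]
            dp[:5] += off[1:] * p[1:6]
            dp[6] = np.sum(fuse * p[:6])
            p = p + dt * dp
        assert got == pytest.approx(p[6], abs=1e-4)

    def test_negative_calcium_rejected(self):
        with pytest.raises(ValueError):
            allosteric_ps(np.array([0.0, 1.0]), np.array([1.0, -1.0]))

    def test_monotone_in_calcium_amplitude(self):
        t = np.linspace(0, 10, 50)
        ps = [allosteric_ps(t, np.full(50, a))[0] for a in (1.0, 5.0, 20.0, 80.0)]
        assert np.all(np.diff(ps) > 0)


@pytest.fixture(scope="module")
def field_ii():
    bouton, az = build_geometry("ii", mesh_um=0.05)
    f = simulate_calcium(bouton, az, duration=5.0, dt=0.01)
    return f, az


class TestModelProperties:

    def test_ps_decreases_with_cluster_distance(self, field_ii):
        from gluquanta.allosteric import ps_map_from_field
        from scipy.stats import spearmanr

        f, az = field_ii
        ps = ps_map_from_field(f)
        d = np.min(
            np.linalg.norm(
                f.az_positions[:, None, :] - az.cluster_centers[None, :, :], axis=2
            ),
            axis=1,
        )
        rho = spearmanr(d, ps).statistic
        assert rho < -0.8

    def test_mesh_refinement_consistency(self, field_ii):
        # desk-scale approximation check: refining the mesh from 50 to
        # 40 nm moves the mean p_s by a bounded amount (the convergence
        # sequence is documented in the methods note)
        from gluquanta.allosteric import ps_map_from_field

        f50, _ = field_ii
        ps50 = ps_map_from_field(f50).mean()
        bouton, az = build_geometry("ii", mesh_um=0.04)
        f40 = simulate_calcium(bouton, az, duration=5.0, dt=0.01)
        ps40 = ps_map_from_field(f40).mean()
        assert abs(ps40 - ps50) / ps40 < 0.25
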