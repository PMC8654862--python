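"""Unit and property tests for the mechanism energy model and simulator."""

import numpy as np
import pytest
from scipy import stats

from camrotor import mechanics as M


@pytest.fixture(scope="module")
def geo():
    return M.MechanismGeometry()


def near_circular(a, b, tol):
    return np.all(np.abs(M.wrapdiff(np.asarray(a) - np.asarray(b))) < tol)


# --------------------------------------------------------------------------
# geometry and variant topology


class TestGeometry:
    def test_default_layout(self, geo):
        assert geo.n_pawls == 6
        assert geo.pawl_angles == (25.0, 95.0, 145.0, 215.0, 265.0, 335.0)
        # slots alternate: inter at 60/180/300, intra at unit centers
        assert near_circular(np.sort(geo.inter_slot_angles), [60, 180, 300], 1e-9)
        assert near_circular(np.sort(geo.intra_slot_angles), [0, 120, 240], 1e-9)
        assert list(geo.pawl_unit) == [0, 1, 1, 2, 2, 0]

    def test_halfwidth_must_fit_between_pawls(self):
        with pytest.raises(ValueError):
            M.MechanismGeometry(cam_halfwidth=55.0)

    def test_pawl_angles_must_be_sorted(self):
        with pytest.raises(ValueError):
            M.MechanismGeometry(pawl_angles=(95, 25, 145, 215, 265, 335))

    def test_cam_height_positive(self):
        with pytest.raises(ValueError):
            M.MechanismGeometry(cam_height=0.0)

    def test_adjacent_pairs_split(self, geo):
        assert geo.adjacent_pairs("intra") == [(1, 2), (3, 4), (5, 0)]
        assert geo.adjacent_pairs("inter") == [(0, 1), (2, 3), (4, 5)]
        assert len(geo.adjacent_pairs("all")) == 6


class TestVariants:
    def test_presets(self, geo):
        v1 = M.VariantSpec.preset(1)
        assert v1.coupled_pairs == () and v1.stacking_enabled
        v2 = M.VariantSpec.preset(2)
        assert v2.coupled_pairs == () and not v2.stacking_enabled
        for vid, kind, where in [(3, "rigid", "intra"), (4, "rigid", "inter"),
                                 (5, "spacer", "inter")]:
            v = M.VariantSpec.preset(vid)
            assert {(j, k) for j, k, _ in v.coupled_pairs} == \
                set(geo.adjacent_pairs(where))
            assert all(knd == kind for _, _, knd in v.coupled_pairs)
        assert len(M.VariantSpec.preset(6).coupled_pairs) == 6

    def test_unknown_variant(self):
        with pytest.raises(ValueError):
            M.VariantSpec.preset(7)

    def test_bad_coupling_pair(self, geo):
        bad = M.VariantSpec(id=3, coupled_pairs=((0, 9, "rigid"),))
        with pytest.raises(ValueError):
            M.build_mechanism(bad, geo, M.MechanicalParams())

    def test_model_has_seven_degrees_of_freedom(self):
        assert M.build_mechanism(1).n_dof == 7


# --------------------------------------------------------------------------
# potential energy


class TestPotential:
    def test_zero_when_cam_clear_and_pawls_relaxed(self):
        model = M.build_mechanism(2)  # no stacking, no couplings
        state = M.MechanismState(60.0, np.zeros(6))   # inter slot: c_j = 0
        assert model.potential_energy(state) == pytest.approx(0.0, abs=1e-12)

    def test_single_pawl_spring_energy(self):
        model = M.build_mechanism(2)
        h = model.geometry.cam_height
        d = np.zeros(6)
        d[0] = h
        state = M.MechanismState(model.geometry.pawl_angles[0], d)
        expected = 0.5 * model.params.k_pawl * h ** 2
        assert model.potential_energy(state) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("variant", [1, 2, 3, 4, 5, 6])
    def test_gradient_matches_finite_differences(self, variant):
        model = M.build_mechanism(variant)
        rng = np.random.default_rng(42 + variant)
        eps = 1e-6
        for _ in range(25):
            theta = rng.uniform(0, 360)
            d = rng.uniform(-1.0, 6.0, 6)
            state = M.MechanismState(theta, d)
            gt, gd = model.energy_gradient(state)
            fd_t = (model.energy_at(theta + eps, d) -
                    model.energy_at(theta - eps, d)) / (2 * eps)
            assert fd_t == pytest.approx(gt, rel=1e-5, abs=1e-6)
            for j in range(6):
                dp, dm = d.copy(), d.copy()
                dp[j] += eps
                dm[j] -= eps
                fd = (model.energy_at(theta, dp) -
                      model.energy_at(theta, dm)) / (2 * eps)
                assert fd == pytest.approx(gd[j], rel=1e-5, abs=1e-6)

    @pytest.mark.parametrize("variant", [1, 3, 5, 6])
    def test_c3_symmetry(self, variant):
        model = M.build_mechanism(variant)
        rng = np.random.default_rng(7)
        for _ in range(10):
            theta = rng.uniform(0, 360)
            d = rng.uniform(-0.5, 5.5, 6)
            u0 = model.energy_at(theta, d)
            # +120 deg maps pawl j -> j+2 in the sorted layout
            u1 = model.energy_at(theta + 120.0, np.roll(d, 2))
            assert u1 == pytest.approx(u0, rel=1e-12, abs=1e-12)

    def test_rigid_pairs_equalized_at_equilibrium(self):
        model = M.build_mechanism(3)
        for theta in (25.0, 60.0, 100.0):
            d, _ = model.minimize_pawls(theta)
            for j, k in model.geometry.adjacent_pairs("intra"):
                assert abs(d[j] - d[k]) < 0.05

    def test_variant6_all_equalized_any_theta(self):
        model = M.build_mechanism(6)
        for theta in (0.0, 37.0, 60.0, 200.0):
            d, _ = model.minimize_pawls(theta)
            assert np.ptp(d) < 0.25  # finite stiff-spring tolerance


# --------------------------------------------------------------------------
# equilibrium dynamics


def flat_model(D_theta=2.0e4, D_pawl=5.0e3, k_pawl=0.12, **kw):
    """Geometry with a vanishing cam: free rotation, independent pawls."""
    geo = M.MechanismGeometry(cam_height=1e-9)
    params = M.MechanicalParams(k_pawl=k_pawl, k_steric_factor=0.0,
                                stack_depth=0.0, D_theta=D_theta,
                                D_pawl=D_pawl, **kw)
    return M.build_mechanism(M.VariantSpec(2, (), False), geo, params)


class TestEquilibrium:
    def test_free_diffusion_variance(self):
        model = flat_model()
        traj = M.simulate_equilibrium(model, 20.0, seed=11)
        lag = 100  # 0.1 s at the default recording interval
        inc = traj.theta[lag::lag] - traj.theta[:-lag:lag]
        expected = 2.0 * model.params.D_theta * lag * traj.record_dt
        n = len(inc)
        lo, hi = stats.chi2.ppf([0.005, 0.995], n - 1) / (n - 1)
        assert lo < inc.var(ddof=1) / expected < hi

    def test_same_seed_bit_identical(self):
        model = M.build_mechanism(1)
        t1 = M.simulate_equilibrium(model, 0.5, seed=3)
        t2 = M.simulate_equilibrium(model, 0.5, seed=3)
        assert np.array_equal(t1.theta, t2.theta)
        assert np.array_equal(t1.d, t2.d)
        t3 = M.simulate_equilibrium(model, 0.5, seed=4)
        assert not np.array_equal(t1.theta, t3.theta)

    def test_boltzmann_sampling_single_well(self):
        # harmonic pawl wells with dt << relaxation time: the stationary
        # deflections must be Gaussian with variance kBT / k_pawl; the six
        # uncoupled pawls sampled every ~4 relaxation times give ~1e5
        # effectively independent draws
        k = 2.0
        model = flat_model(D_pawl=2.0e4, k_pawl=k)
        traj = M.simulate_equilibrium(model, 2.5, dt=2.5e-7, seed=21,
                                      record_every=400)
        samples = traj.d[20:, :].ravel()
        assert len(samples) >= 9e4
        _, p = stats.kstest(samples, "norm", args=(0.0, np.sqrt(1.0 / k)))
        assert p > 0.01

    def test_zero_net_drift(self):
        model = M.build_mechanism(1)
        means = []
        for seed in range(6):
            traj = M.simulate_equilibrium(model, 4.0, seed=seed)
            means.append((traj.theta[-1] - traj.theta[0]) / traj.times[-1])
        means = np.asarray(means)
        sem = means.std(ddof=1) / np.sqrt(len(means))
        assert abs(means.mean()) < 3.5 * sem + 1e-9

    def test_dt_must_be_positive(self):
        with pytest.raises(ValueError):
            M.simulate_equilibrium(M.build_mechanism(1), 0.1, dt=-1e-6, seed=0)

    def test_boltzmann_two_well_occupancy(self):
        # pawls closer to the unit center make the intra-unit slots cost
        # energy; window occupancies must follow the exact marginal
        # Boltzmann weight of theta.  With uncoupled pawls the partition
        # function factorizes, so F(theta) = -sum_j ln int exp(-u_j) dd_j
        # is computable by 1D quadrature - an oracle independent of the
        # integrator.
        geo = M.MechanismGeometry(pawl_offset=18.0)
        params = M.MechanicalParams(stack_depth=0.0)
        model = M.build_mechanism(M.VariantSpec(2, (), False), geo, params)

        dgrid = np.arange(-8.0, 12.0, 0.02)
        thetas = np.arange(0.0, 360.0, 1.0)
        k, kst = params.k_pawl, params.k_steric
        logZ = np.zeros_like(thetas)
        for i, th in enumerate(thetas):
            c = model.clearance(th)
            for cj in c:
                u = 0.5 * k * dgrid ** 2
                pen = dgrid < cj
                u[pen] += 0.5 * kst * (cj - dgrid[pen]) ** 2
                logZ[i] += np.log(np.trapezoid(np.exp(-u), dgrid))
        w = np.exp(logZ - logZ.max())
        intra_th = np.min(np.abs(M.wrapdiff(
            thetas[:, None] - geo.intra_slot_angles)), axis=1) < 20
        inter_th = np.min(np.abs(M.wrapdiff(
            thetas[:, None] - geo.inter_slot_angles)), axis=1) < 20
        expected = w[intra_th].sum() / w[inter_th].sum()

        traj = M.simulate_equilibrium(model, 40.0, seed=9)
        th = traj.theta_wrapped
        intra = np.min(np.abs(M.wrapdiff(th[:, None] - geo.intra_slot_angles)), axis=1) < 20
        inter = np.min(np.abs(M.wrapdiff(th[:, None] - geo.inter_slot_angles)), axis=1) < 20
        # block bootstrap over tenths of the trajectory
        rng = np.random.default_rng(0)
        blocks = np.array_split(np.arange(len(th)), 10)
        boots = []
        for _ in range(200):
            pick = rng.integers(0, 10, 10)
            ii = np.concatenate([blocks[b] for b in pick])
            boots.append(intra[ii].sum() / max(inter[ii].sum(), 1))
        lo, hi = np.percentile(boots, [1, 99])
        assert lo * 0.9 < expected < hi * 1.1


# --------------------------------------------------------------------------
# steered rotation


class TestSteered:
    def test_static_trap_variance(self):
        model = flat_model()
        k_spring = 0.5 * M.KCAL_PER_MOL_IN_KBT
        traj = M._run(model, 3.0, M.DEFAULT_DT, 5, None, 60.0, None,
                      bias_on=True, k_spring=k_spring, rest0=60.0, rate=0.0)
        dev = traj.theta - 60.0
        assert abs(dev.mean()) < 3.5 * dev.std() / np.sqrt(len(dev) / 5)
        assert dev.var() == pytest.approx(1.0 / k_spring, rel=0.25)

    def test_linear_response_lag(self):
        model = flat_model(D_theta=2000.0)
        k_spring = 0.5 * M.KCAL_PER_MOL_IN_KBT
        protocol = M.SteeredProtocol(rate=2000.0, n_turns=3)
        fwd, bwd = M.simulate_steered(model, protocol, seed=2)
        expected = protocol.rate / (model.params.D_theta * k_spring)
        lag_f = (fwd.theta_rest - fwd.theta)[50:]
        lag_b = (bwd.theta_rest - bwd.theta)[50:]
        assert lag_f.mean() == pytest.approx(expected, abs=0.25)
        assert lag_b.mean() == pytest.approx(-expected, abs=0.25)

    def test_three_turns_roundtrip(self):
        model = M.build_mechanism(1)
        protocol = M.SteeredProtocol(rate=360.0, n_turns=3)
        fwd, bwd = M.simulate_steered(model, protocol, seed=8)
        t0 = fwd.theta[0]
        assert fwd.theta[-1] - t0 == pytest.approx(3 * 360.0, abs=15.0)
        assert bwd.theta[-1] - t0 == pytest.approx(-3 * 360.0, abs=15.0)
        net = (fwd.theta[-1] - t0) + (bwd.theta[-1] - t0)
        assert abs(net) < 20.0

    def test_protocol_requires_three_turns(self):
        with pytest.raises(ValueError):
            M.SteeredProtocol(n_turns=2)


# --------------------------------------------------------------------------
# effective landscape and mobility


class TestLandscape:
    def test_flat_without_cam(self):
        prof = M.effective_landscape(flat_model(), 5.0)
        assert prof.U.max() < 1e-6

    def test_variant1_six_minima_at_slots(self):
        prof = M.effective_landscape(M.build_mechanism(1), 2.0)
        assert len(prof.minima) == 6
        slots = np.sort(M.MechanismGeometry().slot_angles)
        assert near_circular(np.sort(prof.minima), slots, 5.0)

    def test_variant3_three_minima_at_inter_slots(self):
        prof = M.effective_landscape(M.build_mechanism(3), 2.0)
        assert len(prof.minima) == 3
        assert near_circular(np.sort(prof.minima),
                             np.sort(M.MechanismGeometry().inter_slot_angles), 5.0)
        assert np.all(prof.barriers > 1.0)

    def test_grid_resolution_guard(self):
        with pytest.raises(ValueError):
            M.effective_landscape(M.build_mechanism(1), 10.0)


class TestMobility:
    def test_free_rotor_recovers_bare_diffusion(self):
        model = flat_model()
        runs = [M.mobility(model, 20.0, seed=s) for s in (5, 6, 7)]
        assert not any(r.stalled for r in runs)
        D = np.mean([r.D_eff for r in runs])
        assert D == pytest.approx(model.params.D_theta, rel=0.2)

    def test_monotonic_in_cam_height(self):
        Ds = []
        for h in (3.0, 5.0, 7.0):
            geo = M.MechanismGeometry(cam_height=h)
            model = M.build_mechanism(M.VariantSpec.preset(1, geo), geo,
                                      M.MechanicalParams())
            Ds.append(np.mean([M.mobility(model, 20.0, seed=31 + s).D_eff
                               for s in (0, 1)]))
        assert Ds[0] > Ds[1] > Ds[2]

    def test_locked_variant_flagged_stalled(self):
        res = M.mobility(M.build_mechanism(6), 10.0, seed=3)
        assert res.stalled
        assert res.n_hops < 5


# --------------------------------------------------------------------------
# steered cycle averages


@pytest.fixture(scope="module")
def summary():
    model = M.build_mechanism(1)
    protocol = M.SteeredProtocol(rate=180.0, n_turns=3)
    fwd, bwd = M.simulate_steered(model, protocol, seed=12)
    return M.cycle_average([fwd, bwd], model.geometry, 10.0)


class TestCycleAverage:

    def test_one_minimum_per_subunit_at_its_center(self, summary):
        geo = M.MechanismGeometry()
        for u in range(3):
            argmin = summary.bin_centers[np.argmin(summary.cam_unit_distance[:, u])]
            assert abs(M.wrapdiff(argmin - geo.unit_centers[u])) < 25.0

    def test_phase_offsets_near_120(self, summary):
        assert np.all(np.abs(summary.phase_offsets - 120.0) < 10.0)
        assert np.sum(summary.phase_offsets) == pytest.approx(360.0, abs=1e-6)

    def test_deflection_peaks_at_clearance_peak(self, summary):
        geo = M.MechanismGeometry()
        for j, phi in enumerate(geo.pawl_angles):
            peak = summary.bin_centers[np.argmax(summary.pawl_deflection[:, j])]
            assert abs(M.wrapdiff(peak - phi)) < 25.0

    def test_deflection_amplitude_matches_design(self, summary):
        # forced rotation must push each pawl out by roughly the cam height
        assert np.nanmax(summary.pawl_deflection) == pytest.approx(5.0, abs=1.5)

    def test_bin_width_must_divide_circle(self, summary):
        with pytest.raises(ValueError):
            M.cycle_average([], M.MechanismGeometry(), 7.0)
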