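import numpy as np
import pytest

from turingmix import (
    BlowUpError,
    FieldState,
    Grid,
    ModelParams,
    SimConfig,
    dynamical_matrix,
    initial_condition,
    simulate,
    simulate_ideal,
    stable_dt,
    step,
    total_free_energy,
)
from turingmix.simulator import (
    ConfigError,
    _run_kernel,
    flux_divergence,
    full_chemical_potentials,
    load_state,
    save_result,
)


def make_state(grid, phiA, phiI):
    return FieldState(grid, np.broadcast_to(phiA, grid.shape).copy(),
                      np.broadcast_to(phiI, grid.shape).copy())


class TestGrid:
    def test_properties(self):
        g = Grid((100,), dx=0.5)
        assert g.dims == 1 and g.lengths == (50.0,) and g.cell_volume == 0.5

    def test_2d(self):
        g = Grid((64, 32), dx=2.0)
        assert g.dims == 2 and g.lengths == (128.0, 64.0) and g.cell_volume == 4.0

    @pytest.mark.parametrize("shape,dx", [((4,), 1.0), ((64,), 0.0), ((8, 8, 8), 1.0)])
    def test_invalid(self, shape, dx):
        with pytest.raises(ValueError):
            Grid(shape, dx)


class TestInitialCondition:
    def test_zero_noise_homogeneous(self, base_params, grid_1d):
        cfg = SimConfig(t_end=1.0, noise_amplitude=0.0)
        state = initial_condition(base_params, grid_1d, cfg)
        assert np.all(state.phiA == 0.2) and np.all(state.phiI == 0.2)

    def test_seed_determinism(self, base_params, grid_1d):
        cfg = SimConfig(t_end=1.0, seed=99)
        s1 = initial_condition(base_params, grid_1d, cfg)
        s2 = initial_condition(base_params, grid_1d, cfg)
        np.testing.assert_array_equal(s1.phiA, s2.phiA)
        np.testing.assert_array_equal(s1.phiI, s2.phiI)
        s3 = initial_condition(base_params, grid_1d, SimConfig(t_end=1.0, seed=100))
        assert np.any(s3.phiA != s1.phiA)

    def test_mean_close_to_phi0(self, base_params):
        cfg = SimConfig(t_end=1.0, seed=0, noise_amplitude=1e-3)
        state = initial_condition(base_params, Grid((400,)), cfg)
        assert abs(state.phiA.mean() - 0.2) < 1e-4
        assert abs(state.phiI.mean() - 0.2) < 1e-4

    def test_too_large_noise_rejected(self, grid_1d):
        p = ModelParams(phi0=0.48)
        with pytest.raises(ConfigError):
            initial_condition(p, grid_1d, SimConfig(t_end=1.0, noise_amplitude=0.05))


class TestChemicalPotentialField:
    def test_uniform_equals_local(self, base_params, grid_1d):
        state = make_state(grid_1d, 0.2, 0.2)
        muA, muI = full_chemical_potentials(state, base_params)
        np.testing.assert_allclose(muA, np.log(0.2) - np.log(0.6), rtol=1e-14)
        np.testing.assert_allclose(muI, muA, rtol=1e-14)

    @pytest.mark.parametrize("dx", [1.0, 0.5])
    def test_discrete_fourier_symbol(self, base_params, dx):
        # mu_A of a single mode contains w^2 * q_eff^2 * mode with the
        # discrete symbol q_eff^2 = (2 - 2 cos(q dx)) / dx^2
        N = int(round(200 / dx))
        grid = Grid((N,), dx=dx)
        x = np.arange(N) * dx
        q = 2 * np.pi * 8 / (N * dx)
        a = 1e-6
        mode = np.sin(q * x)
        state = FieldState(grid, 0.2 + a * mode, np.full(N, 0.2))
        muA, _ = full_chemical_potentials(state, base_params)
        muA0, _ = full_chemical_potentials(make_state(grid, 0.2, 0.2), base_params)
        q_eff2 = (2 - 2 * np.cos(q * dx)) / dx**2
        # linearize: delta muA = (1/phiA + 1/phiS + q_eff^2 w^2) * a * mode
        expected = (1 / 0.2 + 1 / 0.6 + q_eff2) * a * mode
        # tolerance allows the O(a^2) nonlinearity of the log terms
        np.testing.assert_allclose(muA - muA0[0], expected, atol=3e-10)

    def test_symbol_converges_to_continuum(self):
        q = 0.7
        errs = []
        for dx in (0.5, 0.25):
            q_eff2 = (2 - 2 * np.cos(q * dx)) / dx**2
            errs.append(abs(q_eff2 - q**2))
        assert errs[1] < errs[0] / 3.5  # O(dx^2)

    def test_blowup_error_mentions_dt(self, base_params, grid_1d):
        state = make_state(grid_1d, 0.2, 0.2)
        state.phiA[5] = -0.01
        with pytest.raises(BlowUpError, match="dt"):
            full_chemical_potentials(state, base_params)


class TestFluxDivergence:
    def test_uniform_zero(self, base_params, grid_1d):
        state = make_state(grid_1d, 0.2, 0.2)
        mu = full_chemical_potentials(state, base_params)
        divA, divI = flux_divergence(state, mu, base_params)
        assert np.all(divA == 0.0) and np.all(divI == 0.0)

    @pytest.mark.parametrize("dims", [1, 2])
    def test_conservation_by_construction(self, base_params, dims):
        grid = Grid((64,) * dims)
        cfg = SimConfig(t_end=1.0, seed=7, noise_amplitude=0.05)
        state = initial_condition(base_params.with_(chi=3.0), grid, cfg)
        mu = full_chemical_potentials(state, base_params.with_(chi=3.0))
        divA, divI = flux_divergence(state, mu, base_params.with_(chi=3.0))
        scale = np.max(np.abs(divA))
        assert abs(divA.sum()) < 1e-13 * scale * divA.size
        assert abs(divI.sum()) < 1e-13 * scale * divI.size

    def test_single_mode_linearization(self, base_params):
        # d_t phiA ~ -q_eff^2 * D_A*phi0 * muA-mode to first order
        N = 128
        grid = Grid((N,))
        x = np.arange(N, dtype=float)
        q = 2 * np.pi * 5 / N
        a = 1e-6
        phiA = 0.2 + a * np.sin(q * x)
        state = FieldState(grid, phiA, np.full(N, 0.2))
        muA, muI = full_chemical_potentials(state, base_params)
        divA, _ = flux_divergence(state, (muA, muI), base_params)
        q_eff2 = 2 - 2 * np.cos(q)
        mu_mode = muA - muA.mean()
        expected = -q_eff2 * base_params.D_A * 0.2 * mu_mode
        np.testing.assert_allclose(divA, expected, atol=a * 1e-4)


class TestStableDt:
    def test_quartic_dx_scaling(self, base_params):
        dt1 = stable_dt(base_params, Grid((64,), dx=1.0))
        dt2 = stable_dt(base_params, Grid((128,), dx=0.5))
        assert dt1 / dt2 == pytest.approx(16, rel=0.35)

    def test_magnitude(self):
        p = ModelParams(phi0=0.2, chi=0.0, h=5.0, k=0.1, D_I=10.0)
        dt = stable_dt(p, Grid((64,), dx=1.0))
        assert 1e-4 < dt < 1e-2

    def test_safety_linear(self, base_params, grid_1d):
        assert stable_dt(base_params, grid_1d, 1.0) == pytest.approx(
            2 * stable_dt(base_params, grid_1d, 0.5), rel=1e-12
        )

    def test_invalid_safety(self, base_params, grid_1d):
        with pytest.raises(ValueError):
            stable_dt(base_params, grid_1d, 0.0)


class TestStep:
    def test_homogeneous_fixed_point(self, base_params, grid_1d):
        state = make_state(grid_1d, 0.2, 0.2)
        out = step(state, base_params, 1e-3)
        np.testing.assert_array_equal(out.phiA, state.phiA)
        np.testing.assert_array_equal(out.phiI, state.phiI)
        assert out.time == pytest.approx(1e-3)

    def test_mass_conserved_reactionless(self, grid_1d):
        p = ModelParams(phi0=0.2, chi=4.0, h=2.0, k=0.0, D_I=3.0)
        cfg = SimConfig(t_end=1.0, seed=1, noise_amplitude=1e-2)
        state = initial_condition(p, grid_1d, cfg)
        total0 = state.phiA.sum()
        _run_kernel(state, p, stable_dt(p, grid_1d), 1000)
        assert abs(state.phiA.sum() - total0) / total0 < 1e-12

    def test_blowup_raises(self, base_params, grid_1d, quick_config):
        state = initial_condition(base_params.with_(chi=7.0), grid_1d, quick_config)
        with pytest.raises(BlowUpError, match="dt"):
            for _ in range(500):
                state = step(state, base_params.with_(chi=7.0), 0.5)

    def test_invalid_dt(self, base_params, grid_1d):
        state = make_state(grid_1d, 0.2, 0.2)
        with pytest.raises(ValueError):
            step(state, base_params, -1e-3)


class TestKernelMatchesReference:
    @pytest.mark.parametrize("dims", [1, 2])
    def test_agreement(self, dims):
        p = ModelParams(phi0=0.2, chi=2.0, h=5.0, k=0.1, D_I=5.0)
        grid = Grid((32,) * dims)
        cfg = SimConfig(t_end=1.0, seed=4, noise_amplitude=1e-2)
        init = initial_condition(p, grid, cfg)
        dt = stable_dt(p, grid)
        ref = init.copy()
        for _ in range(50):
            ref = step(ref, p, dt)
        fast = init.copy()
        _run_kernel(fast, p, dt, 50)
        np.testing.assert_allclose(fast.phiA, ref.phiA, rtol=0, atol=1e-13)
        np.testing.assert_allclose(fast.phiI, ref.phiI, rtol=0, atol=1e-13)
        assert fast.time == pytest.approx(ref.time)

    def test_kernel_blowup_reports_time(self, base_params, grid_1d, quick_config):
        state = initial_condition(base_params.with_(chi=7.0), grid_1d, quick_config)
        with pytest.raises(BlowUpError):
            _run_kernel(state, base_params.with_(chi=7.0), 0.5, 500)


class TestTranslationEquivariance:
    @pytest.mark.parametrize("dims", [1, 2])
    def test_shift_commutes(self, dims):
        p = ModelParams(phi0=0.2, chi=3.0, h=5.0, k=0.1, D_I=5.0)
        grid = Grid((32,) * dims)
        cfg = SimConfig(t_end=1.0, seed=8, noise_amplitude=1e-2)
        init = initial_condition(p, grid, cfg)
        dt = stable_dt(p, grid)
        a = init.copy()
        _run_kernel(a, p, dt, 200)
        shifted = FieldState(grid, np.roll(init.phiA, 5, axis=0), np.roll(init.phiI, 5, axis=0))
        b = shifted
        _run_kernel(b, p, dt, 200)
        np.testing.assert_array_equal(b.phiA, np.roll(a.phiA, 5, axis=0))
        np.testing.assert_array_equal(b.phiI, np.roll(a.phiI, 5, axis=0))


class TestLyapunov:
    def test_free_energy_non_increasing_quick(self, grid_1d):
        p = ModelParams(phi0=0.2, chi=5.0, h=1.0, k=0.0, D_I=2.0)
        cfg = SimConfig(t_end=1.0, seed=2, noise_amplitude=5e-3)
        state = initial_condition(p, grid_1d, cfg)
        dt = stable_dt(p, grid_1d, 0.5)
        F = total_free_energy(state, p)
        for _ in range(500):
            state = step(state, p, dt)
            F_new = total_free_energy(state, p)
            assert F_new <= F + 1e-13 * abs(F)
            F = F_new


class TestSimulate:
    def test_snapshots_and_provenance(self, base_params, grid_1d):
        cfg = SimConfig(t_end=1.0, snapshot_every=0.25, seed=5)
        init = initial_condition(base_params, grid_1d, cfg)
        res = simulate(init, base_params, cfg)
        assert res.params == base_params
        assert res.config.seed == 5
        # 4 full intervals plus possibly one trailing partial chunk
        assert len(res.snapshots) in (4, 5)
        assert res.snapshots[0].time == pytest.approx(0.25, rel=1e-2)
        assert res.state.time == pytest.approx(1.0, rel=1e-2)

    def test_stable_regime_decays(self, grid_1d):
        # chi=0, h=2, ratio 5: LSA-stable; noise amplitude shrinks
        p = ModelParams(phi0=0.2, chi=0.0, h=2.0, k=0.1, D_I=5.0)
        cfg = SimConfig(t_end=200.0, seed=6, noise_amplitude=1e-3)
        init = initial_condition(p, grid_1d, cfg)
        res = simulate(init, p, cfg)
        from turingmix.metrics import amplitude

        assert amplitude(res.state.phiA) < amplitude(init.phiA)

    def test_early_stop_on_stationarity(self, grid_1d):
        p = ModelParams(phi0=0.2, chi=0.0, h=1.0, k=0.5, D_I=1.0)
        cfg = SimConfig(
            t_end=2000.0, snapshot_every=1.0, seed=3, noise_amplitude=1e-4, early_stop=True
        )
        init = initial_condition(p, grid_1d, cfg)
        res = simulate(init, p, cfg)
        assert res.stopped_early
        assert res.state.time < 2000.0

    def test_linear_growth_matches_lsa(self):
        # single-mode perturbation grows at the dynamical-matrix rate
        from _oracles import growth_matrix_from_simulation

        p = ModelParams(phi0=0.2, chi=1.0, h=5.0, k=0.1, D_I=10.0)
        grid = Grid((64,))
        mode = 3
        q = 2 * np.pi * mode / 64
        q_eff = np.sqrt(2 - 2 * np.cos(q))
        J_expected = dynamical_matrix(p, q_eff)
        dt = stable_dt(p, grid, 0.25)
        J_sim = growth_matrix_from_simulation(p, grid, mode, t_total=100 * dt, n_steps=100)
        np.testing.assert_allclose(np.sort(np.linalg.eigvals(J_sim).real),
                                   np.sort(np.linalg.eigvals(J_expected).real), rtol=2e-2)


class TestIdealLimit:
    def test_reduces_to_ideal_diffusion_at_chi0(self):
        # chi=0 and LSA wavelength >> w: full non-ideal dynamics and the
        # constant-matrix ideal model agree in final pattern amplitude
        from turingmix.metrics import amplitude
        from turingmix.stability import lsa_length_scale

        p = ModelParams(phi0=0.2, chi=0.0, h=8.0, k=0.05, D_I=20.0)
        assert lsa_length_scale(p) > 20.0
        grid = Grid((256,))
        cfg = SimConfig(t_end=400.0, seed=17, noise_amplitude=1e-3, safety=1.0)
        init = initial_condition(p, grid, cfg)
        full = simulate(init, p, cfg)
        ideal = simulate_ideal(init, p, cfg)
        a_full = amplitude(full.state.phiA)
        a_ideal = amplitude(ideal.state.phiA)
        assert a_full > 10 * cfg.noise_amplitude  # a pattern actually formed
        assert abs(a_full - a_ideal) / a_full < 0.05

    def test_ideal_2d_unsupported(self, base_params, grid_2d, quick_config):
        init = initial_condition(base_params, grid_2d, quick_config)
        with pytest.raises(NotImplementedError):
            simulate_ideal(init, base_params, quick_config)


class TestPersistence:
    def test_h5_roundtrip(self, base_params, grid_1d, quick_config, tmp_path):
        init = initial_condition(base_params, grid_1d, quick_config)
        res = simulate(init, base_params, quick_config)
        f = tmp_path / "out.h5"
        save_result(f, res)
        state, params = load_state(f)
        assert params == base_params
        np.testing.assert_array_equal(state.phiA, res.state.phiA)
        assert state.time == res.state.time
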