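"""Surface-hopping propagator: integrators, hops, decoherence, termination."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from todyn.constants import AMU_A2_FS2_EV, HBAR_EV_FS
from todyn.fssh import (DynamicsConfig, IC_TO_S0, TIMEOUT, TRAPPED_T1,
                        TerminationOutcome, apply_decoherence, check_termination,
                        electronic_step, run_ensemble, run_trajectory)
from todyn.surfaces import (ElectronicState, SurfaceModel, build_lz_model,
                            diagonalize_potential)


class TwoLevelHarmonic(SurfaceModel):
    """Uncoupled 1-D harmonic ground state + displaced harmonic excited state."""

    coord_names = ("x",)

    def __init__(self, k0=5.0, k1=5.0, x1=0.0, e1=3.0, mass=6.0):
        self.k0, self.k1, self.x1, self.e1 = k0, k1, x1, e1
        self.masses = np.array([float(mass)])
        self.states = [ElectronicState("singlet", 0, "closed-shell"),
                       ElectronicState("singlet", 1, "pi_pi*")]
        self.f_diabat = np.zeros(2)
        self.reference = np.zeros(1)

    def diabatic(self, q):
        x = self.coords_of(q)[0]
        h = np.diag([0.5 * self.k0 * x**2,
                     self.e1 + 0.5 * self.k1 * (x - self.x1) ** 2])
        dh = np.zeros((1, 2, 2))
        dh[0, 0, 0] = self.k0 * x
        dh[0, 1, 1] = self.k1 * (x - self.x1)
        return h, dh


class FreeParticle(SurfaceModel):
    coord_names = ("x",)

    def __init__(self):
        self.masses = np.array([2.0])
        self.states = [ElectronicState("singlet", 0, "closed-shell"),
                       ElectronicState("singlet", 1, "pi_pi*")]
        self.f_diabat = np.zeros(2)
        self.reference = np.zeros(1)

    def diabatic(self, q):
        return np.diag([0.0, 1.0]), np.zeros((1, 2, 2))


def _quiet_config(**kw):
    base = dict(dt_fs=0.5, max_time_fs=500.0, termination_gap_ev=0.0,
                allow_hops_to_ground=True, decoherence_hartree=None, seed=0)
    base.update(kw)
    return DynamicsConfig(**base)


class TestNuclearStep:
    def test_harmonic_energy_conservation(self):
        m = TwoLevelHarmonic()
        cfg = _quiet_config(max_time_fs=500.0)   # 1000 steps at 0.5 fs
        tr = run_trajectory(m, [0.01], [0.0], 1, cfg, initial_manifold="full")
        e = tr.total_energy()
        assert len(e) >= 1000
        assert np.abs(e - e[0]).max() < 1e-6

    def test_stationary_at_minimum(self):
        m = TwoLevelHarmonic()
        tr = run_trajectory(m, [0.0], [0.0], 1, _quiet_config(max_time_fs=50.0),
                            initial_manifold="full")
        assert np.abs(tr.coords).max() < 1e-12
        assert np.abs(tr.momenta).max() < 1e-12

    def test_free_particle_uniform_motion(self):
        m = FreeParticle()
        p0 = 0.4
        tr = run_trajectory(m, [0.0], [p0], 1, _quiet_config(max_time_fs=50.0),
                            initial_manifold="full")
        v = p0 / m.masses[0]
        assert np.allclose(tr.coords[:, 0], tr.times * v, atol=1e-12)


class TestElectronicStep:
    def test_static_hamiltonian_stationary_state(self):
        e = np.array([0.0, 2.0])
        u = np.eye(2)
        c = np.array([0.0, 1.0], complex)
        c2, sigma, _ = electronic_step(c, e, e, u, u, 0.5, 25)
        assert np.allclose(sigma, 0.0)
        assert np.allclose(np.abs(c2) ** 2, [0.0, 1.0], atol=1e-12)
        # only a phase accumulated
        phase = np.angle(c2[1])
        assert np.isclose(phase % (2 * np.pi),
                          (-e[1] * 0.5 / HBAR_EV_FS) % (2 * np.pi), atol=1e-10)

    def test_unitarity_over_random_steps(self, rng):
        n = 5
        c = rng.normal(size=n) + 1j * rng.normal(size=n)
        c /= np.linalg.norm(c)
        u = np.eye(n)
        for _ in range(1000):
            a = rng.normal(size=(n, n)) * 0.3
            h = 0.5 * (a + a.T) + np.diag(np.arange(n, dtype=float))
            e2, u2 = diagonalize_potential(h, previous=u)
            c, _, _ = electronic_step(c, np.arange(n, dtype=float), e2, u, u2,
                                      0.5, 25)
            u = u2
        assert abs(np.sum(np.abs(c) ** 2) - 1.0) < 1e-6

    def test_lz_sweep_matches_numerical_tdse(self):
        """Forced linear sweep through the avoided crossing: the propagated
        adiabatic passage probability matches an independently integrated
        two-state Schrödinger equation to better than 1%."""
        model = build_lz_model(0.01, 1.0)
        v = 0.01

        h0, _ = model.diabatic([-0.5])
        e, u = diagonalize_potential(h0)
        c_dia0 = u[:, 1].astype(complex)       # upper adiabat, diabatic basis

        def rhs(t, y):
            h, _ = model.diabatic([-0.5 + v * t])
            c = y[:2] + 1j * y[2:]
            dc = -1j / HBAR_EV_FS * (h @ c)
            return np.concatenate([dc.real, dc.imag])

        sol = solve_ivp(rhs, (0, 100), np.concatenate([c_dia0.real, c_dia0.imag]),
                        rtol=1e-11, atol=1e-13)
        cf = sol.y[:2, -1] + 1j * sol.y[2:, -1]
        hf, _ = model.diabatic([0.5])
        _, uf = diagonalize_potential(hf)
        p_exact = abs((uf.T @ cf)[0]) ** 2      # ended on the lower adiabat

        c = np.array([0.0, 1.0], complex)
        prev_e, prev_u = e, u
        for x in np.arange(-0.5, 0.5 + 1e-9, 0.5 * v)[1:]:
            h, _ = model.diabatic([x])
            e2, u2 = diagonalize_potential(h, previous=prev_u)
            c, _, _ = electronic_step(c, prev_e, e2, prev_u, u2, 0.5, 25)
            prev_e, prev_u = e2, u2
        p_ours = abs(c[0]) ** 2
        assert abs(p_ours - p_exact) < 0.01
        # and both agree with the analytic Landau–Zener expression
        assert abs(p_ours - model.lz_probability(v)) < 0.01

    def test_zero_couplings_give_zero_hop_probability(self):
        e = np.array([0.0, 1.0, 2.0])
        u = np.eye(3)
        c = np.array([0.3, 0.6, np.sqrt(1 - 0.45)], complex)
        _, sigma, g = electronic_step(c, e, e, u, u, 0.5, 25, active=1)
        assert np.allclose(sigma, 0.0)
        assert np.allclose(g, 0.0)


class TestDecoherence:
    def test_degenerate_states_untouched(self):
        c = np.array([0.6, 0.8], complex)
        out = apply_decoherence(c, np.array([1.0, 1.0]), 0, 0.5, 0.5, 0.1)
        assert np.allclose(out, c)

    def test_norm_restored_exactly(self, rng):
        for _ in range(50):
            c = rng.normal(size=4) + 1j * rng.normal(size=4)
            c /= np.linalg.norm(c)
            e = rng.normal(size=4)
            out = apply_decoherence(c, e, 1, abs(rng.normal()) + 0.1, 0.5, 0.1)
            assert abs(np.sum(np.abs(out) ** 2) - 1.0) < 1e-12

    def test_damping_time_constants_arithmetic(self):
        """C = 0.1 Hartree, |ΔE| = 1 eV, E_kin = 1 eV:
        τ = (ħ/1 eV)·(1 + 2.7211386) — checked against independent arithmetic."""
        tau_expected = HBAR_EV_FS * (1.0 + 0.1 * 27.211386)
        dt = 0.5
        c = np.array([np.sqrt(0.5), np.sqrt(0.5)], complex)
        out = apply_decoherence(c, np.array([0.0, 1.0]), 1, 1.0, dt, 0.1)
        damp = abs(out[0]) / abs(c[0])
        assert np.isclose(damp, np.exp(-dt / tau_expected), rtol=1e-12)

    def test_zero_kinetic_energy_means_no_damping(self):
        c = np.array([0.6, 0.8], complex)
        out = apply_decoherence(c, np.array([0.0, 1.0]), 1, 0.0, 0.5, 0.1)
        assert np.allclose(out, c)


class TestTermination:
    CFG = DynamicsConfig()

    def test_singlet_gap_closure_is_internal_conversion(self):
        out = check_termination(np.array([0.0, 0.14]), 1, 0, 1, 10.0, self.CFG)
        assert out.reason == IC_TO_S0
        assert out.final_manifold == "singlet"

    def test_triplet_gap_closure_is_trapping(self):
        out = check_termination(np.array([0.0, 0.10]), 1, 1, 0, 10.0, self.CFG)
        assert out.reason == TRAPPED_T1
        assert out.final_state_label == "T1"

    def test_open_gap_continues(self):
        assert check_termination(np.array([0.0, 0.5]), 1, 0, 1, 10.0, self.CFG) is None

    def test_timeout(self):
        out = check_termination(np.array([0.0, 0.5]), 1, 0, 1, 1000.0, self.CFG)
        assert out.reason == TIMEOUT

    def test_outcome_class_consistency_enforced(self):
        with pytest.raises(ValueError):
            TerminationOutcome(IC_TO_S0, 1.0, "triplet", "T1")
        with pytest.raises(ValueError):
            TerminationOutcome(TRAPPED_T1, 1.0, "singlet", "S1")


class TestHops:
    def test_frustrated_hop_keeps_momentum_and_state(self):
        """At the crossing with almost no kinetic energy, upward flux exists
        but every attempted upward hop must be rejected with momenta kept."""
        # enough energy to reach the crossing (uphill ~0.11 eV on the lower
        # adiabat) but less than the 2V = 0.1 eV gap once there; upward flux
        # exists (the upper state gains ~25% population) so attempts occur,
        # and every one must be rejected with state and momentum unchanged
        m = build_lz_model(0.05, 1.0, mass=5.0)
        cfg = _quiet_config(max_time_fs=120.0)
        attempted, accepted = 0, 0
        for seed in range(12):
            tr = run_trajectory(m, [-0.3], [5.0 * 0.0248], 0, cfg, seed=seed,
                                initial_manifold="full")
            assert np.all(tr.active == 0)
            attempted += sum(1 for h in tr.hops if not h["accepted"])
            accepted += sum(1 for h in tr.hops if h["accepted"])
            e = tr.total_energy()
            assert np.abs(e - e[0]).max() < 1e-3
        assert accepted == 0
        assert attempted >= 1, "expected frustrated upward attempts at the crossing"

    def test_energy_conserved_across_accepted_hops(self, model):
        from todyn.wigner import normal_modes, sample_wigner, select_excitation_window
        modes = normal_modes(model)
        ens = sample_wigner(modes, 30, seed=5)
        ics, _ = select_excitation_window(ens, model, (4.5, 4.7), seed=6)
        cfg = DynamicsConfig(max_time_fs=150.0, seed=7)
        tr = run_trajectory(model, ics[0].coords, ics[0].momenta, ics[0].state,
                            cfg, seed=8)
        e = tr.total_energy()
        # energy is conserved through hops by the rescaling construction and
        # between hops by the symplectic integrator
        assert np.abs(np.diff(e)).max() < 5e-3
        drift_rate = abs(e[-1] - e[0]) / max(tr.times[-1], 1.0)
        assert drift_rate < 1e-2


class TestEnsembles:
    def test_same_seed_reproduces_byte_identical_ensembles(self, model):
        from todyn.wigner import normal_modes, sample_wigner, select_excitation_window
        modes = normal_modes(model)
        ens = sample_wigner(modes, 60, seed=1)
        ics, _ = select_excitation_window(ens, model, (4.5, 4.7), seed=2)
        ics = ics[:8]
        cfg = DynamicsConfig(max_time_fs=100.0, seed=3)
        a = run_ensemble(model, ics, cfg)
        b = run_ensemble(model, ics, cfg)
        for x, y in zip(a, b):
            assert np.array_equal(x.coords, y.coords)
            assert np.array_equal(x.populations, y.populations)
            assert np.array_equal(x.active, y.active)
            assert x.outcome.reason == y.outcome.reason

    def test_zero_soc_never_occupies_triplets(self, model):
        from todyn.surfaces import SurrogateParams, TwoThiooxazoleSurrogate
        from todyn.wigner import normal_modes, sample_wigner, select_excitation_window
        p = SurrogateParams.from_dict(model.params.to_dict())
        s, t = model.singlet_indices, model.triplet_indices
        p.coupling[np.ix_(s, t)] = 0.0
        p.coupling[np.ix_(t, s)] = 0.0
        no_soc = TwoThiooxazoleSurrogate(p)
        modes = normal_modes(no_soc)
        ens = sample_wigner(modes, 60, seed=4)
        ics, _ = select_excitation_window(ens, no_soc, (4.5, 4.7), seed=5)
        cfg = DynamicsConfig(max_time_fs=300.0, seed=6)
        trajs = run_ensemble(no_soc, ics[:10], cfg)
        for tr in trajs:
            assert np.all(tr.active_multiplicity == 0)

    def test_injected_failures_are_counted_not_fatal(self, model):
        class Failing:
            """Wraps the surrogate; raises after a set number of evaluations."""

            def __init__(self, inner, fail_after):
                self._inner = inner
                self._n = 0
                self._fail_after = fail_after

            def __getattr__(self, name):
                return getattr(self._inner, name)

            def diabatic(self, q):
                self._n += 1
                if self._n > self._fail_after:
                    raise FloatingPointError("injected electronic-structure failure")
                return self._inner.diabatic(q)

        from todyn.analysis import summarize_ensemble
        from todyn.wigner import normal_modes, sample_wigner, select_excitation_window
        modes = normal_modes(model)
        ens = sample_wigner(modes, 60, seed=7)
        ics, _ = select_excitation_window(ens, model, (4.5, 4.7), seed=8)
        ics = ics[:6]
        cfg = DynamicsConfig(max_time_fs=100.0, seed=9)
        healthy = run_ensemble(model, ics, cfg)
        # fail two specific trajectories by a per-trajectory wrapped model
        out = []
        for k, ic in enumerate(ics):
            m = Failing(model, 10) if k in (2, 4) else model
            out.append(run_trajectory(m, ic.coords, ic.momenta, ic.state, cfg,
                                      seed=healthy[k].seed))
        summary = summarize_ensemble(out)
        assert summary.n_excluded == 2
        assert sum(summary.counts.values()) == len(ics) - 2

    def test_fssh_internal_consistency_single_passage(self):
        """Without decoherence, the fraction of trajectories per surface
        tracks the ensemble-averaged electronic populations (one passage)."""
        m = build_lz_model(0.01, 1.0, mass=2000.0)
        v = 0.01
        cfg = _quiet_config(max_time_fs=80.0, seed=0)
        n = 400
        switched = 0
        pops = np.zeros(2)
        for s in range(n):
            tr = run_trajectory(m, [-0.4], [2000.0 * v], 1, cfg, seed=s,
                                initial_manifold="full")
            switched += int(tr.active[-1] != 1)
            pops += tr.populations[-1]
        frac = switched / n
        mean_pop0 = pops[0] / n
        se = np.sqrt(frac * (1 - frac) / n)
        assert abs(frac - mean_pop0) < 3 * se
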