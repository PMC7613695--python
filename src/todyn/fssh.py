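"""Fewest-switches surface hopping across singlet and triplet manifolds.

Nuclei move by velocity Verlet on one spin-adiabatic surface (eigenstates of
the diabatic potential including the spin–orbit block); the electronic
coefficients follow the time-dependent Schrödinger equation in that basis
with time-derivative couplings built from finite-difference overlaps of
consecutive eigenvector sets.  Hopping probabilities use Tully's
fewest-switches expression accumulated over electronic substeps; accepted
hops rescale the momenta along the velocity to conserve total energy, and
the energy-based decoherence correction damps non-active amplitudes after
every nuclear step.

Trajectories end the way the underlying electronic-structure protocol
demands: when the gap between the active state and the ground state falls
below a threshold the molecule is assumed to return to S0 (singlet manifold)
or to remain trapped in T1 (triplet manifold); hops into the ground state
itself are disabled by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm, logm

from .constants import AMU_A2_FS2_EV, EV_AMU_A2_FS2, HARTREE_EV, HBAR_EV_FS
from .surfaces import SurfaceModel, diagonalize_potential

__all__ = ["DynamicsConfig", "Trajectory", "TerminationOutcome",
           "run_trajectory", "run_ensemble", "electronic_step",
           "apply_decoherence", "check_termination", "hop_probabilities"]

try:                                       # optional JIT of the substep loop
    from numba import njit as _njit
except ImportError:                        # pragma: no cover
    _njit = None

IC_TO_S0 = "internal-conversion-to-S0"
TRAPPED_T1 = "triplet-trapped-T1"
TIMEOUT = "timeout"
FAILED = "failed"


@dataclass
class DynamicsConfig:
    """Propagation settings (times fs, decoherence constant Hartree)."""

    dt_fs: float = 0.5
    substeps: int = 25
    max_time_fs: float = 1000.0
    decoherence_hartree: float | None = 0.1   # None disables the correction
    termination_gap_ev: float = 0.15
    seed: int = 0
    allow_hops_to_ground: bool = False
    frustrated_policy: str = "keep"       # momentum unchanged at frustrated hops
    rescaling: str = "velocity"           # scalar rescale along the velocity

    def __post_init__(self):
        if self.dt_fs <= 0:
            raise ValueError("nuclear time step must be positive")
        if self.substeps < 1:
            raise ValueError("need at least one electronic substep")
        if self.termination_gap_ev < 0:
            raise ValueError("termination gap must be >= 0")
        if self.frustrated_policy != "keep":
            raise ValueError("only the 'keep' frustrated-hop policy is implemented")
        if self.rescaling != "velocity":
            raise ValueError("only velocity-direction rescaling is implemented")

    @property
    def decoherence_ev(self) -> float | None:
        if self.decoherence_hartree is None:
            return None
        return self.decoherence_hartree * HARTREE_EV


@dataclass
class TerminationOutcome:
    """How and why a trajectory ended."""

    reason: str                  # one of IC_TO_S0 / TRAPPED_T1 / TIMEOUT / FAILED
    time_fs: float
    final_manifold: str          # 'singlet' | 'triplet' | 'unknown'
    final_state_label: str
    detail: str = ""

    def __post_init__(self):
        if self.reason == IC_TO_S0 and self.final_manifold != "singlet":
            raise ValueError("internal conversion requires a singlet active state")
        if self.reason == TRAPPED_T1 and self.final_manifold != "triplet":
            raise ValueError("triplet trapping requires a triplet active state")


@dataclass
class Trajectory:
    """Time series of one surface-hopping trajectory."""

    times: np.ndarray            # (nt,)
    coords: np.ndarray           # (nt, ncoord)
    momenta: np.ndarray          # (nt, ncoord)
    energies: np.ndarray         # (nt, nstates) spin-adiabatic energies
    active: np.ndarray           # (nt,) active-state index (energy ordered)
    populations: np.ndarray      # (nt, nstates) |c_k|^2
    active_multiplicity: np.ndarray  # (nt,) 0=singlet, 1=triplet
    active_rank: np.ndarray      # (nt,) rank within the manifold (S_rank / T_rank+1)
    gap_to_ground: np.ndarray    # (nt,)
    hops: list = field(default_factory=list)
    outcome: TerminationOutcome | None = None
    seed: int = 0
    initial_state_label: str = ""

    @property
    def failed(self) -> bool:
        return self.outcome is not None and self.outcome.reason == FAILED

    def total_energy(self) -> np.ndarray:
        """Kinetic + active-surface potential energy at every stored step (eV)."""
        ke = 0.5 * np.sum(self.momenta**2 / self._masses, axis=1) * AMU_A2_FS2_EV
        pot = self.energies[np.arange(len(self.active)), self.active]
        return ke + pot

    _masses: np.ndarray = field(default_factory=lambda: np.array([1.0]))


def _kinetic_energy_ev(p, masses) -> float:
    return float(0.5 * np.sum(p * p / masses) * AMU_A2_FS2_EV)


def _manifold_info(model: SurfaceModel, vectors: np.ndarray):
    """Dominant multiplicity (0/1) and within-manifold rank of each adiabat."""
    singlet_weight = np.sum(vectors[model.singlet_indices, :] ** 2, axis=0)
    mult = (singlet_weight < 0.5).astype(int)
    rank = np.zeros(vectors.shape[1], dtype=int)
    counters = [0, 0]
    for k in range(vectors.shape[1]):          # adiabats are energy ordered
        rank[k] = counters[mult[k]]
        counters[mult[k]] += 1
    return mult, rank


def _state_label(mult: int, rank: int) -> str:
    return f"S{rank}" if mult == 0 else f"T{rank + 1}"


def _substep_loop_py(c, kick, sigma_tally, e_old, e_new, dt_sub, substeps,
                     active, hop):
    """Symmetric split-operator substeps with fewest-switches flux tally."""
    n = c.size
    hbar = HBAR_EV_FS
    for m in range(substeps):
        if active >= 0:
            ca2 = (c[active].real ** 2 + c[active].imag ** 2)
            if ca2 > 1e-12:
                for k in range(n):
                    flux = 2.0 * dt_sub * sigma_tally[active, k] * (
                        c[active].real * c[k].real + c[active].imag * c[k].imag)
                    if flux > 0.0:
                        hop[k] += flux / ca2
        frac = (m + 0.5) / substeps
        e_mid = e_old + frac * (e_new - e_old)
        half_phase = np.exp(-0.5j * e_mid * dt_sub / hbar)
        c = half_phase * (kick @ (half_phase * c))
    return c


if _njit is not None:
    _substep_loop = _njit(_substep_loop_py)
else:                                      # pragma: no cover
    _substep_loop = _substep_loop_py


def electronic_step(coeffs, e_old, e_new, u_old, u_new, dt, substeps,
                    active=None, forbidden=()):
    """Propagate electronic coefficients across one nuclear step.

    Uses a symmetric split-operator: the time-derivative coupling matrix
    σ = (S − Sᵀ)/(2Δt) from the (sign-aligned) eigenvector overlap
    S = U(t)ᵀU(t+Δt) is constant over the step, while the adiabatic energies
    are interpolated linearly over ``substeps`` substeps.  Each substep is
    exactly unitary.  When ``active`` is given, fewest-switches hop
    probabilities out of it are accumulated substep by substep.

    Returns ``(coeffs, sigma, hop_prob)``.
    """
    n = coeffs.size
    s_ov = u_old.T @ u_new
    det = np.linalg.det(s_ov)
    if abs(det) < 0.5:
        raise FloatingPointError(
            f"eigenvector overlap far from orthogonal (|det|={abs(det):.3f}); "
            "nuclear step too large across this crossing")
    if np.max(np.abs(s_ov - np.eye(n))) < 0.25:
        # small rotation: midpoint finite-difference coupling
        sigma = (s_ov - s_ov.T) / (2.0 * dt)
    else:
        # large rotation within one step (trivial/near-exact crossing): the
        # antisymmetrised overlap underestimates the rotation and leaks flux
        # between unrelated states; the matrix logarithm of the orthogonal
        # overlap is the exact generator and makes the propagation follow
        # the state characters through the swap.
        gen = logm(s_ov)
        sigma = np.real(gen) / dt
        sigma = 0.5 * (sigma - sigma.T)
    dt_sub = dt / substeps
    kick = expm(-sigma * dt_sub)             # orthogonal: sigma is antisymmetric
    # hop-probability tally: exclude generator elements that merely relabel
    # trivially-swapped states (|S_jk| ~ 1 off the diagonal) — the coefficient
    # rotation through a near-exact crossing is bookkeeping, not nonadiabatic
    # population flux
    sigma_tally = sigma.copy()
    swap = (s_ov**2 > 0.5) & ~np.eye(n, dtype=bool)
    if swap.any():
        sigma_tally[swap] = 0.0
        sigma_tally[swap.T] = 0.0
    hop = np.zeros(n)
    c = _substep_loop(coeffs.astype(np.complex128),
                      kick.astype(np.complex128), sigma_tally,
                      np.asarray(e_old, float), np.asarray(e_new, float),
                      dt_sub, substeps,
                      -1 if active is None else int(active), hop)
    if active is not None:
        hop[active] = 0.0
        for k in forbidden:
            hop[k] = 0.0
        total = hop.sum()
        if total > 1.0:                      # clip guard; probabilities partition
            hop *= 1.0 / total
    return c, sigma, hop


def hop_probabilities(coeffs, sigma, active, dt):
    """Single-interval fewest-switches probabilities g(active→k)."""
    ca2 = abs(coeffs[active]) ** 2
    if ca2 <= 1e-12:
        return np.zeros(coeffs.size)
    flux = 2.0 * dt * sigma[active, :] * np.real(np.conj(coeffs[active]) * coeffs)
    g = np.maximum(0.0, flux) / ca2
    g[active] = 0.0
    return g


def apply_decoherence(coeffs, energies, active, kinetic_energy_ev, dt,
                      c_hartree: float = 0.1):
    """Energy-based decoherence: damp non-active amplitudes, restore the norm.

    τ_k = (ħ/|E_k − E_a|)·(1 + C/E_kin); degenerate states are untouched and
    zero kinetic energy gives τ → ∞ (no damping) rather than a division
    error.  The active amplitude is rescaled so the total norm is exactly 1.
    """
    c = coeffs.astype(complex).copy()
    e_act = energies[active]
    if abs(c[active]) == 0:
        raise ValueError("decoherence requires a populated active state")
    if kinetic_energy_ev > 0:
        c_ev = c_hartree * HARTREE_EV
        factor = 1.0 + c_ev / kinetic_energy_ev
        for k in range(c.size):
            if k == active:
                continue
            de = abs(energies[k] - e_act)
            if de == 0:
                continue
            tau = (HBAR_EV_FS / de) * factor
            c[k] *= np.exp(-dt / tau)
    other = np.sum(np.abs(c) ** 2) - np.abs(c[active]) ** 2
    c[active] *= np.sqrt(max(0.0, 1.0 - other)) / np.abs(c[active])
    return c


def ground_state_index(vectors: np.ndarray) -> int:
    """Index of the adiabat dominated by the closed-shell ground diabat.

    Usually the lowest adiabat, but excited diabats (notably T1) cross below
    the rising S0 surface at strongly tilted or stretched geometries, so the
    protocol's rules (no hops into S0; gap-based termination) must follow
    the S0 *character*, not the energetic ordering.
    """
    return int(np.argmax(vectors[0, :] ** 2))


def check_termination(energies, active, mult, rank, t, config: DynamicsConfig,
                      ground_index: int = 0):
    """Gap/time termination rule. Returns None to continue, else an outcome."""
    gap = abs(float(energies[active] - energies[ground_index]))
    if active != ground_index and gap < config.termination_gap_ev:
        if mult == 0:
            return TerminationOutcome(IC_TO_S0, t, "singlet", _state_label(mult, rank),
                                      detail=f"gap {gap:.3f} eV")
        return TerminationOutcome(TRAPPED_T1, t, "triplet", _state_label(mult, rank),
                                  detail=f"gap {gap:.3f} eV")
    if t >= config.max_time_fs:
        return TerminationOutcome(TIMEOUT, t, "singlet" if mult == 0 else "triplet",
                                  _state_label(mult, rank))
    return None


def run_trajectory(model: SurfaceModel, coords, momenta, initial_state: int,
                   config: DynamicsConfig, seed: int = 0,
                   initial_manifold: str = "singlet") -> Trajectory:
    """Propagate one trajectory from an initial condition.

    ``initial_state`` indexes the adiabatic basis of ``initial_manifold``
    (window selection works with spin-pure singlets); it is mapped onto the
    spin-adiabatic basis by maximum eigenvector overlap before propagation.
    """
    rng = np.random.default_rng(seed)
    masses = model.masses
    nq = model.n_coords
    dt = config.dt_fs
    q = model.coords_of(coords).copy()
    p = np.asarray(momenta, float).copy()
    if p.shape != (nq,):
        raise ValueError("momentum vector shape mismatch")

    rec: dict = {k: [] for k in ("t", "q", "p", "e", "act", "pop", "mult",
                                 "rank", "gap")}
    hops: list = []
    outcome = None

    def evaluate(qq, u_prev=None):
        h, dh = model.diabatic(qq)
        e, u = diagonalize_potential(h, u_prev, validate=False)
        return e, u, dh

    def force(dh, u, state):
        v = u[:, state]
        return -np.einsum("cij,i,j->c", dh, v, v)

    try:
        e, u, dh = evaluate(q)
        # map the spin-pure initial state onto the spin-adiabatic basis
        if initial_manifold == "full":
            active = int(initial_state)
        else:
            idx = (model.singlet_indices if initial_manifold == "singlet"
                   else model.triplet_indices)
            from .surfaces import adiabatize as _ad
            pure = _ad(model, q, manifold=initial_manifold)
            vec = np.zeros(model.n_states)
            vec[idx] = pure.vectors[:, initial_state]
            active = int(np.argmax((u.T @ vec) ** 2))
        c = np.zeros(model.n_states, dtype=complex)
        c[active] = 1.0
        mult_all, rank_all = _manifold_info(model, u)
        label0 = _state_label(mult_all[active], rank_all[active])
        f = force(dh, u, active)

        t = 0.0
        step = 0
        max_steps = int(np.ceil(config.max_time_fs / dt)) + 1
        while True:
            mult_all, rank_all = _manifold_info(model, u)
            rec["t"].append(t)
            rec["q"].append(q.copy())
            rec["p"].append(p.copy())
            rec["e"].append(e.copy())
            rec["act"].append(active)
            rec["pop"].append(np.abs(c) ** 2)
            rec["mult"].append(mult_all[active])
            rec["rank"].append(rank_all[active])
            g_idx = ground_state_index(u)
            rec["gap"].append(abs(e[active] - e[g_idx]))

            outcome = check_termination(e, active, mult_all[active],
                                        rank_all[active], t, config,
                                        ground_index=g_idx)
            if outcome is not None or step >= max_steps:
                break

            # velocity Verlet on the active surface
            accel = f * EV_AMU_A2_FS2 / masses
            p_half = p + 0.5 * dt * accel * masses
            q_new = q + dt * p_half / masses
            e_new, u_new, dh_new = evaluate(q_new, u_prev=u)
            if not np.all(np.isfinite(e_new)):
                raise FloatingPointError("non-finite adiabatic energies")
            f_new = force(dh_new, u_new, active)
            if not np.all(np.isfinite(f_new)):
                raise FloatingPointError("non-finite force")
            p_new = p_half + 0.5 * dt * f_new * EV_AMU_A2_FS2

            # trivial-crossing handling: when the active adiabat swaps energy
            # order with another state within one step (near-exact crossing,
            # |<active(t)|active(t+dt)>| small), follow the state's character
            # by reassigning the index — not a hop, no momentum rescaling.
            s_ov = u.T @ u_new
            if s_ov[active, active] ** 2 < 0.5:
                partner = int(np.argmax(s_ov[active, :] ** 2))
                if partner != active and s_ov[active, partner] ** 2 > 0.5:
                    active = partner
                    f_new = force(dh_new, u_new, active)

            forbidden = () if config.allow_hops_to_ground \
                else (ground_state_index(u_new),)
            c, sigma, g = electronic_step(c, e, e_new, u, u_new, dt,
                                          config.substeps, active=active,
                                          forbidden=forbidden)

            # fewest-switches hop decision: one uniform draw per nuclear step
            xi = rng.uniform()
            cum = 0.0
            target = None
            for k in range(model.n_states):
                cum += g[k]
                if xi < cum:
                    target = k
                    break
            if target is not None and target != active:
                de = float(e_new[target] - e_new[active])
                ke = _kinetic_energy_ev(p_new, masses)
                if de <= ke:
                    scale = np.sqrt(max(0.0, 1.0 - de / ke)) if ke > 0 else 0.0
                    p_new = p_new * scale
                    hops.append({"time_fs": t + dt, "from": active, "to": target,
                                 "accepted": True, "delta_e_ev": de})
                    active = target
                    f_new = force(dh_new, u_new, active)
                else:
                    hops.append({"time_fs": t + dt, "from": active, "to": target,
                                 "accepted": False, "delta_e_ev": de})

            if config.decoherence_hartree is not None:
                ke = _kinetic_energy_ev(p_new, masses)
                c = apply_decoherence(c, e_new, active, ke, dt,
                                      config.decoherence_hartree)

            q, p, e, u, dh, f = q_new, p_new, e_new, u_new, dh_new, f_new
            t += dt
            step += 1
    except (FloatingPointError, np.linalg.LinAlgError, RuntimeError) as err:
        outcome = TerminationOutcome(FAILED, t if rec["t"] else 0.0, "unknown",
                                     "none", detail=str(err))

    traj = Trajectory(
        times=np.array(rec["t"]),
        coords=np.array(rec["q"]).reshape(-1, nq),
        momenta=np.array(rec["p"]).reshape(-1, nq),
        energies=np.array(rec["e"]).reshape(-1, model.n_states),
        active=np.array(rec["act"], dtype=int),
        populations=np.array(rec["pop"]).reshape(-1, model.n_states),
        active_multiplicity=np.array(rec["mult"], dtype=int),
        active_rank=np.array(rec["rank"], dtype=int),
        gap_to_ground=np.array(rec["gap"]),
        hops=hops,
        outcome=outcome,
        seed=seed,
        initial_state_label=label0 if rec["t"] else "none",
    )
    traj._masses = masses.copy()
    return traj


def run_ensemble(model: SurfaceModel, initial_conditions,
                 config: DynamicsConfig) -> list:
    """Run independent trajectories, one per initial condition.

    Per-trajectory seeds are spawned deterministically from ``config.seed``,
    so identical master seeds give identical ensembles regardless of
    execution order; failed trajectories are retained with their failure
    flag so ensemble statistics can exclude and count them.
    """
    if not initial_conditions:
        raise ValueError("need at least one initial condition")
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(len(initial_conditions))
    out = []
    for ic, child in zip(initial_conditions, children):
        seed = int(child.generate_state(1)[0] % (2**31))
        traj = run_trajectory(model, ic.coords, ic.momenta, ic.state, config,
                              seed=seed)
        out.append(traj)
    return out
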