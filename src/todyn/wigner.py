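"""Wigner-distribution initial conditions and excitation-window selection.

Initial geometries and momenta for the dynamics are drawn from the Wigner
density of the harmonic vibrational ground state: for every normal mode the
dimensionless position and momentum are independent Gaussians of variance ½,
which reproduces both the coordinate spread and the zero-point momentum of
the quantum ground state.  Initial electronic states are then assigned by
stochastic selection inside an excitation window, with acceptance probability
proportional to the oscillator strength of each in-window transition.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .constants import EV_AMU_A2_FS2, HBAR_EV_FS, WAVENUMBER_FS
from .surfaces import SurfaceModel, adiabatize, adiabatic_gradient

__all__ = ["NormalModeSet", "WignerEnsemble", "InitialCondition",
           "normal_modes", "sample_wigner", "select_excitation_window",
           "save_initial_conditions", "load_initial_conditions"]

#: ħ in amu·Å²/fs (action in the mechanical unit system).
_HBAR_MECH = HBAR_EV_FS * EV_AMU_A2_FS2


@dataclass
class NormalModeSet:
    """Harmonic normal modes of a reference geometry.

    ``displacements`` columns are the mass-weighted mode vectors L_k
    (orthonormal); ``frequencies_cm`` are the harmonic wavenumbers.  Modes
    with non-positive frequency are carried (so a parsed file can be
    inspected) but rejected by the sampler.
    """

    reference: np.ndarray        # (ncoord,)
    masses: np.ndarray           # (ncoord,) effective masses, amu
    frequencies_cm: np.ndarray   # (nmode,)
    displacements: np.ndarray    # (ncoord, nmode), mass-weighted, orthonormal
    coord_names: tuple = ()

    def __post_init__(self):
        self.reference = np.asarray(self.reference, float)
        self.masses = np.asarray(self.masses, float)
        self.frequencies_cm = np.asarray(self.frequencies_cm, float)
        self.displacements = np.asarray(self.displacements, float)
        n, m = self.displacements.shape
        if self.reference.size != n or self.masses.size != n:
            raise ValueError("displacement rows must match coordinate count")
        if self.frequencies_cm.size != m:
            raise ValueError("one frequency per mode required")
        gram = self.displacements.T @ self.displacements
        if not np.allclose(gram, np.eye(m), atol=1e-8):
            raise ValueError("mode vectors must be orthonormal in the "
                             "mass-weighted metric")

    @property
    def omega_fs(self) -> np.ndarray:
        """Angular frequencies in rad/fs."""
        return self.frequencies_cm * WAVENUMBER_FS


@dataclass
class WignerEnsemble:
    """Sampled phase-space points, both dimensionless and in coordinates."""

    coords: np.ndarray       # (n, ncoord)
    momenta: np.ndarray      # (n, ncoord) conjugate momenta, amu·Å/fs
    q_dimless: np.ndarray    # (n, nmode) dimensionless mode positions
    p_dimless: np.ndarray    # (n, nmode) dimensionless mode momenta
    seed: int = 0


@dataclass
class InitialCondition:
    """One (geometry, momenta, electronic state) triple for the dynamics."""

    coords: np.ndarray
    momenta: np.ndarray
    state: int               # index in the singlet-manifold adiabatic basis
    e_exc: float             # vertical excitation energy at this geometry, eV
    f_osc: float
    sample_index: int = -1

    def __post_init__(self):
        if self.state < 1:
            raise ValueError("initial state must be an excited state")

    @property
    def label(self) -> str:
        return f"S{self.state}"


def normal_modes(model: SurfaceModel, q0=None, state: int = 0,
                 manifold: str = "singlet", step: float = 1e-4) -> NormalModeSet:
    """Harmonic normal modes of one adiabatic surface at (or near) ``q0``.

    The Hessian is taken by central finite differences of the analytic
    gradient, mass-weighted with the model's effective masses and
    diagonalised; eigenvalues convert to wavenumbers via
    ω = sqrt(λ/m) with the energy unit change folded in.
    """
    q0 = model.coords_of(model.reference if q0 is None else q0).copy()
    n = model.n_coords
    hess = np.zeros((n, n))
    for i in range(n):
        qp, qm = q0.copy(), q0.copy()
        qp[i] += step
        qm[i] -= step
        gp = adiabatic_gradient(model, qp, state, manifold=manifold)
        gm = adiabatic_gradient(model, qm, state, manifold=manifold)
        hess[i] = (gp - gm) / (2 * step)
    hess = 0.5 * (hess + hess.T)
    inv_sqrt_m = 1.0 / np.sqrt(model.masses)
    hmw = hess * np.outer(inv_sqrt_m, inv_sqrt_m)          # eV / (amu Å²)
    evals, vecs = np.linalg.eigh(hmw)
    omega2 = evals * EV_AMU_A2_FS2                          # fs^-2
    freqs = np.sign(omega2) * np.sqrt(np.abs(omega2)) / WAVENUMBER_FS
    return NormalModeSet(reference=q0, masses=model.masses.copy(),
                         frequencies_cm=freqs, displacements=vecs,
                         coord_names=tuple(model.coord_names))


def sample_wigner(modes: NormalModeSet, n_samples: int = 500,
                  seed: int = 0) -> WignerEnsemble:
    """Draw geometries and momenta from the ground-state Wigner density.

    Per mode the dimensionless position and momentum are independent normal
    deviates of variance ½; they are converted to mass-weighted displacements
    ``x = sqrt(ħ/ω)·Q`` and momenta ``p = sqrt(ħω)·P`` and transformed back
    to the model's coordinates.  Deterministic for a given seed.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    bad = np.where(modes.frequencies_cm <= 0)[0]
    if bad.size:
        raise ValueError(
            f"cannot Wigner-sample imaginary/zero-frequency mode(s) {bad.tolist()} "
            f"(wavenumbers {modes.frequencies_cm[bad].round(2).tolist()} cm^-1)")
    rng = np.random.default_rng(seed)
    nm = modes.frequencies_cm.size
    q_dim = rng.normal(0.0, np.sqrt(0.5), size=(n_samples, nm))
    p_dim = rng.normal(0.0, np.sqrt(0.5), size=(n_samples, nm))
    omega = modes.omega_fs
    x_mw = q_dim * np.sqrt(_HBAR_MECH / omega)       # amu^0.5 Å
    p_mw = p_dim * np.sqrt(_HBAR_MECH * omega)       # amu^0.5 Å / fs
    inv_sqrt_m = 1.0 / np.sqrt(modes.masses)
    sqrt_m = np.sqrt(modes.masses)
    coords = modes.reference + (x_mw @ modes.displacements.T) * inv_sqrt_m
    momenta = (p_mw @ modes.displacements.T) * sqrt_m
    return WignerEnsemble(coords=coords, momenta=momenta,
                          q_dimless=q_dim, p_dimless=p_dim, seed=seed)


def select_excitation_window(ensemble: WignerEnsemble, model: SurfaceModel,
                             window=(4.5, 4.7), states=None,
                             seed: int = 0) -> tuple:
    """Stochastic selection of initial conditions inside an excitation window.

    For every sample and every considered excited singlet adiabat whose
    vertical excitation falls inside ``window``, the (sample, state) pair is
    accepted with probability f_osc / f_max, where f_max is the largest
    oscillator strength among all in-window pairs.  Returns
    ``(initial_conditions, counts_by_state)``; an empty window yields an
    empty list, not an error.
    """
    e_min, e_max = window
    if not e_min < e_max:
        raise ValueError("window must satisfy E_min < E_max")
    n_singlet = len(model.singlet_indices)
    if states is None:
        states = list(range(1, n_singlet))
    if 0 in states:
        raise ValueError("the ground state cannot be an initial state")
    pairs = []
    for i, q in enumerate(ensemble.coords):
        ad = adiabatize(model, q, manifold="singlet")
        exc = ad.energies - ad.energies[0]
        for k in states:
            if e_min <= exc[k] <= e_max:
                pairs.append((i, k, float(exc[k]), float(ad.f_osc[k])))
    if not pairs:
        return [], {}
    f_max = max(p[3] for p in pairs)
    rng = np.random.default_rng(seed)
    selected = []
    counts: dict = {}
    for i, k, e, f in pairs:
        if f_max > 0 and rng.uniform() < f / f_max:
            selected.append(InitialCondition(
                coords=ensemble.coords[i].copy(),
                momenta=ensemble.momenta[i].copy(),
                state=k, e_exc=e, f_osc=f, sample_index=i))
            counts[f"S{k}"] = counts.get(f"S{k}", 0) + 1
    return selected, counts


def save_initial_conditions(path, conditions) -> None:
    """Serialise an initial-condition ensemble to JSON."""
    payload = {
        "schema": "todyn-initial-conditions/1",
        "conditions": [
            {"coords": ic.coords.tolist(), "momenta": ic.momenta.tolist(),
             "state": ic.state, "e_exc": ic.e_exc, "f_osc": ic.f_osc,
             "sample_index": ic.sample_index}
            for ic in conditions
        ],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def load_initial_conditions(path):
    with open(path) as fh:
        payload = json.load(fh)
    if payload.get("schema") != "todyn-initial-conditions/1":
        raise ValueError("unsupported initial-condition schema")
    return [InitialCondition(coords=np.array(c["coords"]),
                             momenta=np.array(c["momenta"]),
                             state=c["state"], e_exc=c["e_exc"],
                             f_osc=c["f_osc"],
                             sample_index=c.get("sample_index", -1))
            for c in payload["conditions"]]
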