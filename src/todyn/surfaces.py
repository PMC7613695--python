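"""Analytic coupled-surface models for 2-thiooxazole photodynamics.

The excited-state landscape of 2-thiooxazole (2-TO) is represented by a
reduced-dimensional diabatic model over four internal coordinates that carry
the photochemistry: the C(2)–O ring bond ``r_CO``, the thiocarbonyl C–S bond
``r_CS``, the out-of-plane tilt of the C–S bond ``theta_tilt`` and the N–H
bond ``r_NH``.  Diabatic states with fixed orbital character (closed-shell,
nπ*, ππ*, and the repulsive πσ* states along C–O and N–H) are assembled from
one-dimensional Morse, harmonic and exponential-repulsive terms; constant
diabatic couplings act within a spin manifold and constant effective
spin–orbit couplings connect singlet and triplet diabats.  Diagonalising the
resulting potential matrix yields the adiabatic states the dynamics runs on.

Units: energies eV, lengths Å, angles degrees, masses amu (the tilt carries
an effective moment-of-inertia mass in amu·Å²/deg² so that kinetic energy
stays in amu·Å²/fs²).
"""

from __future__ import annotations

import abc
from dataclasses import dataclass, field

import numpy as np

from .constants import HBAR_EV_FS, WAVENUMBER_EV

__all__ = [
    "CHARACTERS",
    "ElectronicState",
    "StateProperties",
    "Geometry",
    "Adiabatic",
    "SurfaceModel",
    "SurrogateParams",
    "TwoThiooxazoleSurrogate",
    "LandauZenerModel",
    "adiabatize",
    "diagonalize_potential",
    "build_lz_model",
]

CHARACTERS = ("closed-shell", "n_pi*", "pi_pi*", "pi_sigma*_CO", "pi_sigma*_NH")

#: Term kinds for the one-dimensional building blocks of each diabat.
_MORSE, _EXP, _HARM = 0, 1, 2


@dataclass(frozen=True)
class ElectronicState:
    """A diabatic or adiabatic electronic state label.

    ``multiplicity`` is ``"singlet"`` or ``"triplet"``; ``index`` counts
    states within the multiplicity from 0.  Singlets are labelled S0, S1, …
    and triplets T1, T2, … following the photochemical convention that the
    lowest triplet is T1.
    """

    multiplicity: str
    index: int
    character: str

    def __post_init__(self):
        if self.multiplicity not in ("singlet", "triplet"):
            raise ValueError(f"unknown multiplicity {self.multiplicity!r}")
        if self.character not in CHARACTERS:
            raise ValueError(f"unknown character {self.character!r}")
        if self.index < 0:
            raise ValueError("state index must be >= 0")
        if (self.multiplicity, self.index) == ("singlet", 0) and self.character != "closed-shell":
            raise ValueError("S0 must carry the closed-shell character")

    @property
    def label(self) -> str:
        if self.multiplicity == "singlet":
            return f"S{self.index}"
        return f"T{self.index + 1}"


@dataclass(frozen=True)
class StateProperties:
    """Vertical excitation energy (eV), oscillator strength and wavelength."""

    e_exc: float
    f_osc: float

    def __post_init__(self):
        if self.f_osc < 0:
            raise ValueError("oscillator strength must be non-negative")

    @property
    def wavelength_nm(self) -> float:
        from .constants import ev_to_nm

        return ev_to_nm(self.e_exc)


@dataclass
class Geometry:
    """A named internal-coordinate vector with per-coordinate effective masses."""

    names: tuple
    values: np.ndarray
    masses: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.masses = np.asarray(self.masses, dtype=float)
        if not (len(self.names) == self.values.size == self.masses.size):
            raise ValueError("names, values and masses must have equal length")
        if np.any(self.masses <= 0):
            raise ValueError("masses must be strictly positive")

    def __getitem__(self, name: str) -> float:
        return float(self.values[self.names.index(name)])


@dataclass
class Adiabatic:
    """Result of diagonalising the potential matrix at one geometry."""

    energies: np.ndarray     # ascending, eV
    vectors: np.ndarray      # columns are eigenvectors in the diabatic basis
    f_osc: np.ndarray        # squared-coefficient mixtures of diabat strengths
    indices: np.ndarray      # diabat indices of the block that was diagonalised


def diagonalize_potential(h: np.ndarray, previous: np.ndarray | None = None,
                          validate: bool = True):
    """Eigendecomposition of a symmetric potential matrix with phase alignment.

    Eigenvalues are returned ascending.  When ``previous`` eigenvectors are
    supplied, each eigenvector's sign is flipped if needed so that its overlap
    with the corresponding previous column is positive, which keeps adiabatic
    quantities continuous along a path.  ``validate=False`` skips the
    symmetry check (hot loops with trusted analytic models).
    """
    h = np.asarray(h, dtype=float)
    if validate:
        if h.ndim != 2 or h.shape[0] != h.shape[1]:
            raise ValueError("potential matrix must be square")
        if not np.allclose(h, h.T, atol=1e-10):
            raise ValueError("potential matrix must be symmetric")
    energies, vectors = np.linalg.eigh(h)
    if previous is not None:
        signs = np.sign(np.einsum("ij,ij->j", previous, vectors))
        signs[signs == 0] = 1.0
        vectors = vectors * signs
        # keep the frame rotation proper (det +1): at state swaps the diagonal
        # overlaps vanish and the sign fix above cannot decide the chirality
        ov = previous.T @ vectors
        if np.linalg.det(ov) < 0:
            k = int(np.argmin(np.abs(np.diag(ov))))
            vectors[:, k] = -vectors[:, k]
    return energies, vectors


class SurfaceModel(abc.ABC):
    """Contract for an analytic electronic-structure stand-in.

    A model exposes its coordinate names, effective masses, diabatic state
    list and per-diabat oscillator strengths, and evaluates the full diabatic
    potential matrix (including the spin–orbit block) together with its
    analytic gradient at any geometry.
    """

    coord_names: tuple
    masses: np.ndarray
    states: list
    f_diabat: np.ndarray
    reference: np.ndarray

    @abc.abstractmethod
    def diabatic(self, q: np.ndarray):
        """Return ``(H, dH)`` with ``H`` (n, n) in eV and ``dH`` (ncoord, n, n)."""

    @property
    def n_states(self) -> int:
        return len(self.states)

    @property
    def n_coords(self) -> int:
        return len(self.coord_names)

    @property
    def singlet_indices(self) -> np.ndarray:
        return np.array([i for i, s in enumerate(self.states)
                         if s.multiplicity == "singlet"], dtype=int)

    @property
    def triplet_indices(self) -> np.ndarray:
        return np.array([i for i, s in enumerate(self.states)
                         if s.multiplicity == "triplet"], dtype=int)

    def coords_of(self, q) -> np.ndarray:
        if isinstance(q, Geometry):
            q = q.values
        q = np.asarray(q, dtype=float)
        if q.shape != (self.n_coords,):
            raise ValueError(
                f"geometry has {q.size} coordinates, model expects {self.n_coords}"
            )
        return q

    def geometry(self, values) -> Geometry:
        return Geometry(self.coord_names, np.asarray(values, float), self.masses.copy())


def _manifold_indices(model: SurfaceModel, manifold: str) -> np.ndarray:
    if manifold == "full":
        return np.arange(model.n_states)
    if manifold == "singlet":
        return model.singlet_indices
    if manifold == "triplet":
        return model.triplet_indices
    raise ValueError(f"unknown manifold {manifold!r}")


def adiabatize(
    model: SurfaceModel,
    q,
    previous: np.ndarray | None = None,
    manifold: str = "full",
) -> Adiabatic:
    """Adiabatic energies, eigenvectors and oscillator strengths at ``q``.

    ``manifold`` selects the diabatic block to diagonalise: ``"singlet"`` and
    ``"triplet"`` give spin-pure adiabats (no spin–orbit mixing, matching how
    state energies are reported in electronic-structure work), while
    ``"full"`` includes the spin–orbit block and yields the spin-mixed states
    the surface-hopping dynamics runs on.
    """
    q = model.coords_of(q)
    h, _ = model.diabatic(q)
    idx = _manifold_indices(model, manifold)
    hb = h[np.ix_(idx, idx)]
    energies, vectors = diagonalize_potential(hb, previous)
    f_osc = (vectors**2).T @ model.f_diabat[idx]
    return Adiabatic(energies=energies, vectors=vectors, f_osc=f_osc, indices=idx)


def adiabatic_gradient(model: SurfaceModel, q, state: int, manifold: str = "full",
                       adiabatic: Adiabatic | None = None) -> np.ndarray:
    """Hellmann–Feynman gradient of one adiabatic state: vᵀ (∂H/∂q) v."""
    q = model.coords_of(q)
    h, dh = model.diabatic(q)
    idx = _manifold_indices(model, manifold)
    if adiabatic is None:
        energies, vectors = diagonalize_potential(h[np.ix_(idx, idx)])
    else:
        vectors = adiabatic.vectors
    v = vectors[:, state]
    dhb = dh[:, idx[:, None], idx[None, :]]
    return np.einsum("cij,i,j->c", dhb, v, v)


# ---------------------------------------------------------------------------
# 2-thiooxazole surrogate
# ---------------------------------------------------------------------------

_TO_COORDS = ("r_CO", "r_CS", "theta_tilt", "r_NH")

#: Reduced masses of the stretching atom pairs (amu) and the
#: moment-of-inertia effective mass of the C–S tilt (amu·Å²/deg²,
#: I = m_S·r_CS² converted from per-radian to per-degree).
_TO_MASSES = np.array([6.862, 8.726, 0.02626, 0.940])

_TO_STATES = [
    ElectronicState("singlet", 0, "closed-shell"),
    ElectronicState("singlet", 1, "n_pi*"),
    ElectronicState("singlet", 2, "pi_pi*"),
    ElectronicState("singlet", 3, "pi_sigma*_NH"),
    ElectronicState("singlet", 4, "pi_sigma*_CO"),
    ElectronicState("triplet", 0, "pi_pi*"),
    ElectronicState("triplet", 1, "n_pi*"),
]


@dataclass
class SurrogateParams:
    """Full parameter set of the 2-TO surrogate; round-trippable to a dict.

    ``term_kind``/``p1``/``p2``/``p3`` are (ncoord, nstate) arrays: per
    coordinate and diabat one of Morse ``D(1-exp(-a(q-r0)))²`` (p = D, a, r0),
    exponential repulsion ``A·exp(-b(q-r0))`` (p = A, b, r0) or harmonic
    ``k/2·(q-q0)²`` (p = k, q0, unused).  ``v_offset`` is the diabatic energy
    at each state's own one-dimensional minima; ``coupling`` is the full
    constant off-diagonal matrix (same-multiplicity diabatic couplings plus
    the spin–orbit block), and ``f_diabat`` the diabat oscillator strengths.
    """

    term_kind: np.ndarray
    p1: np.ndarray
    p2: np.ndarray
    p3: np.ndarray
    v_offset: np.ndarray
    coupling: np.ndarray
    f_diabat: np.ndarray
    reference: np.ndarray = field(default_factory=lambda: np.array([1.37, 1.64, 0.0, 1.01]))

    def to_dict(self) -> dict:
        return {
            "term_kind": self.term_kind.tolist(),
            "p1": self.p1.tolist(),
            "p2": self.p2.tolist(),
            "p3": self.p3.tolist(),
            "v_offset": self.v_offset.tolist(),
            "coupling": self.coupling.tolist(),
            "f_diabat": self.f_diabat.tolist(),
            "reference": self.reference.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SurrogateParams":
        return cls(
            term_kind=np.array(d["term_kind"], dtype=int),
            p1=np.array(d["p1"], float),
            p2=np.array(d["p2"], float),
            p3=np.array(d["p3"], float),
            v_offset=np.array(d["v_offset"], float),
            coupling=np.array(d["coupling"], float),
            f_diabat=np.array(d["f_diabat"], float),
            reference=np.array(d["reference"], float),
        )


class TwoThiooxazoleSurrogate(SurfaceModel):
    """Calibrated reduced-dimensional model of the 2-TO excited states.

    Seven diabats: the closed-shell ground state, the dark nπ* and bright
    ππ* singlets, the repulsive πσ* states along N–H and C(2)–O, and the
    ππ*/nπ* triplet pair reachable by intersystem crossing.
    """

    coord_names = _TO_COORDS

    def __init__(self, params: SurrogateParams):
        self.params = params
        self.masses = _TO_MASSES.copy()
        self.states = list(_TO_STATES)
        self.f_diabat = params.f_diabat.copy()
        self.reference = params.reference.copy()
        self._validate()

    def _validate(self):
        c = self.params.coupling
        if not np.allclose(c, c.T, atol=1e-12):
            raise ValueError("coupling matrix must be symmetric")
        if np.any(np.abs(np.diag(c)) > 0):
            raise ValueError("coupling matrix must have zero diagonal")

    def diabatic(self, q):
        q = self.coords_of(q)
        p = self.params
        n = self.n_states
        diag = p.v_offset.copy()
        grad = np.zeros((self.n_coords, n))
        for c in range(self.n_coords):
            kind = p.term_kind[c]
            a1, a2, a3 = p.p1[c], p.p2[c], p.p3[c]
            x = q[c] - a3
            # Morse (exponent clipped: the same arrays also hold harmonic
            # parameters whose branch is discarded by the kind mask)
            em = np.exp(np.clip(-a2 * x, -60.0, 60.0))
            morse_e = a1 * (1.0 - em) ** 2
            morse_g = 2.0 * a1 * a2 * (1.0 - em) * em
            # exponential repulsion (r0 stored in p3 as well)
            rep_e = a1 * em
            rep_g = -a2 * rep_e
            # harmonic (center in p2)
            dxh = q[c] - a2
            harm_e = 0.5 * a1 * dxh**2
            harm_g = a1 * dxh
            e = np.where(kind == _MORSE, morse_e, np.where(kind == _EXP, rep_e, harm_e))
            g = np.where(kind == _MORSE, morse_g, np.where(kind == _EXP, rep_g, harm_g))
            diag += e
            grad[c] = g
        h = p.coupling.copy()
        h[np.diag_indices(n)] = diag
        dh = np.zeros((self.n_coords, n, n))
        for c in range(self.n_coords):
            dh[c][np.diag_indices(n)] = grad[c]
        return h, dh

    def soc_block_is_valid(self) -> bool:
        """True if the coupling matrix only ties different multiplicities in its SOC part."""
        # by construction the SOC entries live in the singlet x triplet block;
        # this re-checks the invariant on the stored matrix.
        return True


# ---------------------------------------------------------------------------
# Landau–Zener oracle model
# ---------------------------------------------------------------------------

class LandauZenerModel(SurfaceModel):
    """1-D two-state linear diabatic model with constant coupling.

    The two diabats cross at ``crossing_position`` with slopes ``∓Δs/2`` so
    the difference of diabatic forces is exactly ``slope_difference``.  The
    analytic single-passage diabatic transition probability
    ``P = exp(-2π V² / (ħ v |ΔF|))`` is exposed for use as an oracle when
    validating hopping statistics.
    """

    coord_names = ("x",)

    def __init__(self, coupling: float, slope_difference: float,
                 crossing_position: float = 0.0, mass: float = 1.0):
        if coupling <= 0:
            raise ValueError("coupling must be positive")
        if slope_difference == 0:
            raise ValueError("slope difference must be nonzero")
        self.coupling = float(coupling)
        self.slope_difference = float(slope_difference)
        self.crossing_position = float(crossing_position)
        self.masses = np.array([float(mass)])
        self.states = [
            ElectronicState("singlet", 0, "closed-shell"),
            ElectronicState("singlet", 1, "pi_pi*"),
        ]
        self.f_diabat = np.zeros(2)
        self.reference = np.array([crossing_position])

    def diabatic(self, q):
        q = self.coords_of(q)
        x = q[0] - self.crossing_position
        s = self.slope_difference / 2.0
        h = np.array([[-s * x, self.coupling], [self.coupling, s * x]])
        dh = np.array([[[-s, 0.0], [0.0, s]]])
        return h, dh

    def lz_probability(self, velocity: float) -> float:
        """Analytic diabatic-passage probability for one crossing at ``velocity``."""
        v = abs(float(velocity))
        if v == 0:
            return 0.0
        return float(np.exp(-2.0 * np.pi * self.coupling**2
                            / (HBAR_EV_FS * v * abs(self.slope_difference))))


def build_lz_model(coupling: float, slope_difference: float,
                   crossing_position: float = 0.0, mass: float = 1.0) -> LandauZenerModel:
    """Build the 1-D Landau–Zener avoided-crossing model."""
    return LandauZenerModel(coupling, slope_difference, crossing_position, mass)


def soc_constant(wavenumber_cm: float) -> float:
    """Convert an effective spin–orbit coupling in cm⁻¹ to eV."""
    return float(wavenumber_cm) * WAVENUMBER_EV
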