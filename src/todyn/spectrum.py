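"""Nuclear-ensemble absorption spectra and energy/wavelength utilities.

The UV-vis spectrum is approximated by broadening every vertical transition
of a geometry ensemble with a normalised Gaussian and averaging: the
intensity carries the oscillator strength of each transition, so the
integral of the spectrum equals the ensemble-mean total oscillator strength.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import HC_EV_NM
from .surfaces import SurfaceModel, adiabatize

__all__ = ["SpectrumGrid", "ensemble_spectrum", "ev_nm_convert"]


@dataclass
class SpectrumGrid:
    """An absorption spectrum on a uniform energy grid (arbitrary units)."""

    energies: np.ndarray
    intensities: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.energies = np.asarray(self.energies, float)
        self.intensities = np.asarray(self.intensities, float)
        if np.any(np.diff(self.energies) <= 0):
            raise ValueError("energy grid must be strictly increasing")
        if np.any(self.intensities < -1e-300):
            raise ValueError("intensities must be non-negative")

    @property
    def peak_ev(self) -> float:
        return float(self.energies[int(np.argmax(self.intensities))])

    def window_overlap(self, window) -> float:
        """Fraction of the spectral area inside an energy window."""
        lo, hi = window
        mask = (self.energies >= lo) & (self.energies <= hi)
        total = np.trapezoid(self.intensities, self.energies)
        if total == 0:
            return 0.0
        return float(np.trapezoid(self.intensities[mask], self.energies[mask]) / total)

    def to_frame(self, wavelength_column: bool = False):
        import pandas as pd

        data = {"energy_eV": self.energies, "intensity": self.intensities}
        if wavelength_column:
            data["wavelength_nm"] = HC_EV_NM / self.energies
        return pd.DataFrame(data)


def ev_nm_convert(value: float) -> float:
    """Photon energy ↔ wavelength conversion, λ·E = 1239.841984 eV·nm.

    The conversion is involutive: applying it twice returns the input.
    """
    value = float(value)
    if value <= 0:
        raise ValueError(f"photon energy/wavelength must be positive, got {value}")
    return HC_EV_NM / value


def ensemble_spectrum(samples, model: SurfaceModel, states=None,
                      broadening_fwhm: float = 0.1,
                      grid=(2.0, 8.0, 1201)) -> SpectrumGrid:
    """Nuclear-ensemble spectrum from sampled geometries.

    ``samples`` is an (n, ncoord) array (or an object with ``coords``);
    ``states`` the singlet adiabats to include (all excited singlets by
    default; including S0 is an error — there is no S0→S0 absorption).
    ``grid`` is either an (emin, emax, npoints) tuple or an explicit array.
    """
    coords = getattr(samples, "coords", samples)
    coords = np.asarray(coords, float)
    if coords.ndim == 1:
        coords = coords[None, :]
    if coords.shape[0] < 1:
        raise ValueError("need at least one sample")
    if broadening_fwhm <= 0:
        raise ValueError("broadening FWHM must be positive")
    n_singlet = len(model.singlet_indices)
    if states is None:
        states = list(range(1, n_singlet))
    if 0 in states:
        raise ValueError("S0 cannot absorb into itself; remove state 0")
    if isinstance(grid, tuple):
        energies = np.linspace(*grid)
    else:
        energies = np.asarray(grid, float)
    sigma = broadening_fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    norm = 1.0 / (sigma * np.sqrt(2.0 * np.pi))
    intensity = np.zeros_like(energies)
    lines = []
    for q in coords:
        ad = adiabatize(model, q, manifold="singlet")
        exc = ad.energies - ad.energies[0]
        for k in states:
            e, f = exc[k], ad.f_osc[k]
            lines.append((e, f))
            if f > 0:
                intensity += f * norm * np.exp(-0.5 * ((energies - e) / sigma) ** 2)
    intensity /= coords.shape[0]
    meta = {
        "n_samples": int(coords.shape[0]),
        "broadening_fwhm_eV": float(broadening_fwhm),
        "states": list(states),
        "mean_total_f": float(sum(f for _, f in lines) / coords.shape[0]),
    }
    spec = SpectrumGrid(energies=energies, intensities=intensity, metadata=meta)
    meta["peak_eV"] = spec.peak_ev
    return spec
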