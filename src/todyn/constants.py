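"""Physical constants and unit conversions.

Internal unit system: energies in eV, lengths in Å, times in fs, masses in amu.
Angular coordinates are carried in degrees with effective masses in amu·Å²/deg²,
which keeps kinetic energy ``p²/2m`` in the same amu·Å²/fs² unit as stretches.
Hartree appears only where a configuration value is quoted in it (the
energy-based decoherence constant) and is converted at parse time.
"""

from __future__ import annotations

#: Planck constant over 2π, in eV·fs.
HBAR_EV_FS = 0.6582119569

#: hc, in eV·nm (photon energy–wavelength conversion).
HC_EV_NM = 1239.841984

#: 1 Hartree in eV.
HARTREE_EV = 27.211386

#: 1 amu·Å²/fs² expressed in eV.
AMU_A2_FS2_EV = 103.642697

#: 1 eV expressed in amu·Å²/fs².
EV_AMU_A2_FS2 = 1.0 / AMU_A2_FS2_EV

#: Angular frequency (rad/fs) of a 1 cm⁻¹ vibration: 2π·c with c in cm/fs.
WAVENUMBER_FS = 1.8836515673e-4

#: 1 cm⁻¹ in eV (ħ·ω for a 1 cm⁻¹ mode).
WAVENUMBER_EV = HBAR_EV_FS * WAVENUMBER_FS

#: Standard atomic weights (amu) for the elements this package encounters.
ATOMIC_MASSES = {
    "H": 1.008,
    "D": 2.014,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "F": 18.998,
    "P": 30.974,
    "S": 32.06,
    "Cl": 35.45,
    "Se": 78.971,
}


def ev_to_nm(energy_ev: float) -> float:
    """Convert a photon energy in eV to its wavelength in nm."""
    if energy_ev <= 0:
        raise ValueError(f"photon energy must be positive, got {energy_ev}")
    return HC_EV_NM / energy_ev


def nm_to_ev(wavelength_nm: float) -> float:
    """Convert a wavelength in nm to photon energy in eV."""
    if wavelength_nm <= 0:
        raise ValueError(f"wavelength must be positive, got {wavelength_nm}")
    return HC_EV_NM / wavelength_nm
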