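"""Wigner sampling and the nuclear-ensemble UV absorption spectrum.

Samples 500 geometries from the harmonic ground-state Wigner distribution,
broadens every vertical transition with a 0.1 eV FWHM Gaussian, and reports
the band maximum and the overlap with the 4.5–4.7 eV excitation window used
to launch the dynamics.
"""

from todyn import build_to_surrogate
from todyn.spectrum import ensemble_spectrum
from todyn.wigner import normal_modes, sample_wigner

model = build_to_surrogate()
modes = normal_modes(model)
print("Ground-state harmonic wavenumbers (cm^-1):",
      ", ".join(f"{f:.0f}" for f in sorted(modes.frequencies_cm)))

ensemble = sample_wigner(modes, n_samples=500, seed=11)
spec = ensemble_spectrum(ensemble, model, broadening_fwhm=0.1)

print(f"\nBand maximum: {spec.peak_ev:.2f} eV "
      f"(the bright ππ* transition dominates; reported maximum ~4.65 eV)")
print(f"Fraction of spectral area inside the 4.5–4.7 eV excitation window: "
      f"{spec.window_overlap((4.5, 4.7)):.2f}")
print("\nFirst rows of the spectrum table:")
print(spec.to_frame(wavelength_column=True).iloc[500:505].to_string(index=False))
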