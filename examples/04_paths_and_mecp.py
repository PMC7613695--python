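"""Potential-energy profiles and minimum-energy crossing points.

Optimises the S1 minimum, locates the two S1/S0 crossings (C–S tilting and
C(2)–O ring opening) with the penalty-function MECP method, and builds the
mass-weighted LIIC profile connecting them — the ingredients of a
deactivation-pathway diagram.
"""

import numpy as np

from todyn import build_to_surrogate, liic_path, optimize_mecp
from todyn.pathways import minimize_state, relaxed_scan

model = build_to_surrogate()

q_s1, e_s1 = minimize_state(model, model.reference + [0.05, 0.15, 14, 0],
                            state=1, manifold="singlet")
print(f"S1 minimum at {np.round(q_s1, 3)} (E = {e_s1:.3f} eV)")

tilt = optimize_mecp(model, (("singlet", 1), ("singlet", 0)),
                     q_s1 + np.array([0.0, 0.05, 16.0, 0.0]),
                     reference_energy=e_s1,
                     bounds=[(1.30, 1.75), (None, None), (8.0, 75.0), (None, None)])
ring = optimize_mecp(model, (("singlet", 1), ("singlet", 0)),
                     model.reference + np.array([0.6, 0.1, 0.0, 0.0]),
                     reference_energy=e_s1,
                     bounds=[(1.70, 2.60), (None, None), (-8.0, 8.0), (None, None)])
print(f"nπ*/S0 crossing (tilting):      barrier {tilt.barrier:.3f} eV at "
      f"{np.round(tilt.geometry, 3)}")
print(f"πσ*CO/S0 crossing (ring open):  barrier {ring.barrier:.3f} eV at "
      f"{np.round(ring.geometry, 3)}")

profile = liic_path(model, [model.reference, q_s1, ring.geometry],
                    n_per_segment=8, labels=["S0 min", "S1 min", "MECP"])
print("\nLIIC profile (mass-weighted coordinate, singlet energies):")
frame = profile.to_frame()
print(frame[["path_coord_amu05_A", "E_S0_eV", "E_S1_eV", "E_S2_eV",
             "anchor_label"]].round(3).to_string(index=False))

scan = relaxed_scan(model, 1, "r_CO", np.linspace(q_s1[0], 2.0, 8), q_s1)
gaps = scan.energies["singlet"][:, 1] - scan.energies["singlet"][:, 0]
print("\nRelaxed S1 scan along r_CO — the S1–S0 gap closes toward the "
      "ring-opening crossing:")
for r, g in zip(scan.coords[:, 0], gaps):
    print(f"  r_CO = {r:.3f} Å   gap = {g:.3f} eV")
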