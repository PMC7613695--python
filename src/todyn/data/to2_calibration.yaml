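# Calibration table for the 2-thiooxazole surrogate surfaces.
# Pins are the printed gas-phase energetics of the molecule: vertical
# excitation energies at the ground-state minimum, excited-state barrier
# heights to the crossings with S0, the C-S elongation of the excited
# minima, and the location of the piσ*(CO)/S0 crossing along the ring C-O
# bond.  Triplet verticals, coupling strengths and oscillator strengths of
# states without a printed value are documented package defaults.
schema: todyn-calibration/1
reference_geometry:
  r_CO: 1.37        # Å, ground-state ring C(2)-O bond
  r_CS: 1.64        # Å, thiocarbonyl C=S bond
  theta_tilt: 0.0   # deg, C-S out-of-plane tilt
  r_NH: 1.01        # Å, N-H bond
vertical_energies_eV:   # adiabatic singlet excitations at the reference geometry
  S1: 4.23
  S2: 4.64
  S3: 5.06
triplet_vertical_energies_eV:   # chosen defaults (not printed), ordering pi_pi* < n_pi*
  T1: 3.60
  T2: 4.10
pi_sigma_co_vertical_eV: 5.81   # diabatic anchor for the C-O repulsive state
barriers_eV:            # excited-state minimum -> MECP with S0
  singlet_tilt: 0.3     # S1 min -> n_pi*/S0 crossing (C-S tilt + ring puckering)
  singlet_co: 0.4       # S1 min -> pi_sigma*_CO/S0 crossing (ring opening)
  triplet_tilt: 0.2     # T1 min -> pi_pi*/S0 crossing
  triplet_co: 0.2       # T1 min -> CO-stretch crossing with S0
excited_cs_elongation_A: 0.13   # C-S elongation of the S1 minimum
co_crossing_window_A: [1.8, 2.15]  # pi_sigma*_CO / S0 crossing along r_CO
tolerance_eV: 0.02
geometry_tolerance_A: 0.03
couplings:
  excited_same_multiplicity_eV: 0.15
  ground_to_excited_eV: 0.0
  soc_cm1: 50.0
  soc_same_character_factor: 0.1
oscillator_strengths:
  n_pi*: 3.65e-5
  pi_pi*: 0.364
  pi_sigma*_NH: 0.022
  pi_sigma*_CO: 0.003
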