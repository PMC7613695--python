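# todyn — surface-hopping photodynamics of 2-thiooxazole

2-thiooxazole (2-TO) is a five-membered O/N heteroaromatic with a
thiocarbonyl group, of interest as a prebiotically plausible precursor of
pyrimidine and 8-oxopurine RNA nucleotides.  Under UV irradiation it
photodegrades rapidly, and the mechanism — photochemical rupture of the
aromatic ring by C(2)–O bond breaking on a repulsive πσ* state, in
competition with a photostabilising C–S-tilting funnel, N–H fission, and
intersystem crossing into the triplet manifold — is accessible to
nonadiabatic molecular dynamics.

`todyn` implements that complete protocol at desk scale:

- **Analytic surrogate surfaces** (`todyn.surfaces`, `todyn.calibrate`): a
  reduced-dimensional diabatic model over the four photochemically active
  coordinates (r_CO, r_CS, the C–S out-of-plane tilt θ, r_NH) with seven
  diabats — S0, nπ*, ππ*, πσ*(NH), πσ*(CO) singlets and ππ*/nπ* triplets —
  calibrated so that the adiabatic vertical excitations (4.23/4.64/5.06 eV),
  the excited-minimum C–S elongation (+0.13 Å), the barriers from the S1 and
  T1 minima to their crossings with S0 (0.3/0.4 and 0.2/0.2 eV) and the
  location of the πσ*(CO)/S0 crossing reproduce the molecule's literature
  gas-phase energetics.
- **Wigner initial conditions** (`todyn.wigner`): harmonic ground-state
  Wigner sampling (independent Gaussians of variance ½ per mode in
  dimensionless units) and stochastic excitation-window selection with
  acceptance probability ∝ oscillator strength.
- **Nuclear-ensemble spectra** (`todyn.spectrum`): Gaussian-broadened
  vertical transitions; eV ↔ nm via λ·E = 1239.841984 eV·nm.
- **Fewest-switches surface hopping** (`todyn.fssh`): velocity-Verlet nuclei
  on spin-adiabatic surfaces (spin–orbit coupling in the diagonalised
  potential), a unitary split-operator electronic propagator with
  overlap-based time-derivative couplings, Tully hop probabilities
  g(a→k) = max(0, −2Δt Re(c_k c_a* σ_ka)/|c_a|²) accumulated over 0.02 fs
  substeps, momentum rescaling along the velocity at accepted hops, the
  Granucci–Persico energy-based decoherence correction
  (τ = ħ/|ΔE| · (1 + C/E_kin), C = 0.1 Hartree), and the gap-based
  termination rule: when E(active) − E(S0) < 0.15 eV a singlet trajectory is
  assumed to return to S0 and a triplet trajectory to remain trapped in T1.
- **Paths and crossings** (`todyn.pathways`): LIIC profiles against
  mass-weighted coordinates, relaxed scans, and penalty-function MECP
  optimisation (F_σ = Ē + σ·ΔE²/(|ΔE|+α)) needing no nonadiabatic couplings.
- **Ensemble analysis** (`todyn.analysis`): adiabatic population curves,
  internal-coordinate time series, and classification of terminated
  trajectories into photorelaxation channels (ring-opening-CO at
  r_CO > 1.8 Å, NH-fission, photostabilising, other).

## Worked example

`examples/03_surface_hopping_ensemble.py` runs the production-size ensemble
(500 Wigner samples → excitation window 4.5–4.7 eV → 141 trajectories of up
to 1 ps with 0.5 fs nuclear / 0.02 fs electronic steps):

```
256 initial conditions selected; per-state counts: {'S2': 247, 'S3': 9}

Photorelaxation channels:
         channel  count  fraction  percent  singlet  triplet
 ring-opening-CO     69  0.489362       49       68        1
      NH-fission     23  0.163121       16       22        1
photostabilising     45  0.319149       32       43        2
     CO5-opening      0  0.000000        0        0        0
           other      4  0.028369        3        4        0
```

Reading the numbers: photoexcitation is almost exclusively into the bright
ππ* adiabat; about half of the trajectories rupture the ring by C(2)–O bond
breaking (the experiment's photodegradation channel), a third return intact
through the C–S tilting funnel, N–H fission is a minority channel fed by
πσ*(NH) starts, and a few trajectories cross into the triplet manifold and
are trapped in T1.  `examples/01`–`05` cover the remaining capabilities
(calibration report, spectrum, LIIC/MECP energetics, and the Landau–Zener
hopping benchmark), and the `todyn` command line chains the stages
(`calibrate`, `sample`, `spectrum`, `run`, `analyze`, `liic`, `scan`,
`mecp`) with JSON run manifests for reproducibility.

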