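# Methods

## Scope and strategy

`todyn` reproduces, end to end, the trajectory-surface-hopping protocol used
to characterise 2-thiooxazole photodegradation: Wigner sampling of a
harmonic ground state, a nuclear-ensemble absorption spectrum, stochastic
excitation-window selection, Tully fewest-switches surface hopping across
coupled singlet and triplet manifolds with energy-based decoherence and
gap-based termination, channel classification, and the stationary-point /
crossing-point machinery (LIIC profiles, relaxed scans, penalty-function
MECP optimisation).  The ab initio electronic structure that normally feeds
such a protocol is replaced by an analytic surrogate calibrated to the
molecule's literature gas-phase energetics, so every stage is exactly
testable on one CPU in minutes.

## The surrogate surfaces

**Coordinates.** Four internal coordinates carry the photochemistry:
the ring C(2)–O bond `r_CO` (Å), the thiocarbonyl C–S bond `r_CS` (Å), the
out-of-plane tilt of the C–S bond `theta_tilt` (degrees) and the N–H bond
`r_NH` (Å).  Effective masses are the reduced masses of the atom pairs
(μ_CO = 6.862, μ_CS = 8.726, μ_NH = 0.940 amu) and, for the tilt, the
moment of inertia of the sulfur atom about the ring carbon
(m_S·r_CS² ≈ 86 amu Å², i.e. 0.02626 amu Å²/deg²), so kinetic energy is
uniformly ½p²/m in amu Å²/fs² (1 amu Å²/fs² = 103.642697 eV).

**Diabats.** Seven diabatic states with fixed orbital character: the
closed-shell ground state; the dark nπ* and bright ππ* singlets; the
repulsive πσ* states along N–H and C(2)–O; and the ππ*/nπ* triplet pair.
Each diabat is a sum of one-dimensional terms — Morse in the stretches for
bound states, a decaying exponential for the repulsive πσ* terms, harmonic
wells in `r_CS` and the tilt — with state-dependent minima: all excited
diabats elongate C–S (most strongly ππ*, per the excited-minimum
geometries) and tilt the C–S bond out of plane, and the excited states'
C–O wells are shallower and displaced outward by *different* amounts.  That
last choice matters dynamically: in a separable reduced model no
intramolecular vibrational redistribution exists, so state-dependent C–O
displacements are the mechanism by which electronic relaxation (each
internal conversion changes the force on C–O) pumps energy into the
ring-opening coordinate, standing in for the anharmonic IVR of the real
33-dimensional molecule.

**Couplings.** Constant diabatic couplings of 0.15 eV act between excited
diabats of the same multiplicity.  Couplings between S0 and the excited
diabats default to zero: the protocol never hops into S0 (the gap criterion
is the only ground-state-return mechanism), the S0 surface must be exactly
stationary at the reference geometry, and the crossings with S0 must become
genuinely near-degenerate for the 0.15 eV termination rule to fire.  The
spin–orbit block couples singlet and triplet diabats with a constant
effective 50 cm⁻¹, reduced ×0.1 between states of equal orbital character
(an El-Sayed-like rule); each triplet is a single effective state rather
than three M_S components.  SOC magnitudes and triplet vertical energies
are not available for this molecule; the defaults (T1/T2 vertical
3.60/4.10 eV, ordering ππ* below nπ*) are package choices, all exposed in
the calibration file.

**Calibration.** `build_to_surrogate` pins the model to the printed
energetics in two alternating stages: a Newton solve of the diabatic energy
offsets against the adiabatic vertical-excitation pins (S1/S2/S3 =
4.23/4.64/5.06 eV; T1/T2 = 3.60/4.10 eV), cold-started from
target-minus-reference-terms so the character assignment (nπ* below ππ*
for singlets, ππ* lowest for triplets) cannot flip; and one-dimensional
root finding on a designated shape knob per barrier pin, where each barrier
is evaluated by actually optimising the excited-state minimum and the
crossing on the assembled model.  The knobs are: the S0 tilt stiffness for
the S1→nπ*/S0 barrier (0.3 eV) — a softer ground-state tilt wall moves the
crossing to larger tilt where the nπ* state is higher; the πσ*(CO)
asymptote for the S1→πσ*CO/S0 barrier (0.4 eV); the T1 tilt minimum for
the T1 tilting crossing (0.2 eV); and the depth of T1's soft C–O Morse
wall for the T1 ring-opening crossing (0.2 eV).  Every pin is verified to
0.02 eV (geometries to 0.03 Å) and the build fails loudly otherwise.

Singlet MECPs use the penalty method (below) inside per-basin coordinate
bounds, because the S1/S0 seam has two minima (tilting and ring opening).
The two T1/S0 crossings are located by relaxed scans with bisection on the
gap: on the reduced-dimensional triplet surface the two channels merge into
a single unconstrained seam minimum, and a constrained scan — the same tool
the original protocol fell back on for the problematic C–O scan — defines
each channel's crossing unambiguously.

## Initial conditions and spectra

Normal modes come from a finite-difference Hessian of the adiabatic ground
state (270/700/1690/3400 cm⁻¹ for tilt/C–S/C–O/N–H).  Wigner sampling
draws dimensionless positions and momenta as independent normal deviates of
variance ½ (the exact harmonic ground-state Wigner density; 0 K, no thermal
excitation) and maps them through the mass-weighted mode vectors.  The
default ensemble is 500 geometries.

The spectrum is the ensemble average of oscillator-strength-weighted
normalised Gaussians (default FWHM 0.1 eV — the line shape and width are
not prescribed; Gaussian is the nuclear-ensemble default and 0.1 eV matches
the reported bandwidth visually).  Adiabatic oscillator strengths are
squared-coefficient mixtures of the diabat strengths (nπ* 3.65×10⁻⁵,
ππ* 0.364, πσ*NH 0.022; πσ*CO 0.003 chosen small).  The surrogate band
peaks at 4.61–4.64 eV depending on the sample (reported maximum ≈4.65 eV).

Initial conditions are (sample, state) pairs whose vertical excitation lies
in the 4.5–4.7 eV window, accepted with probability f/f_max over all
in-window pairs — the standard stochastic-selection rule of the nuclear-ensemble
method (no other rule is prescribed).  A sample may contribute several
states.  The bright adiabat dominates the selection (≈95%), with a πσ*NH
minority from N–H-stretched samples; the dark nπ* state is essentially
never selected.

## Dynamics

Nuclei follow velocity Verlet (0.5 fs) on one spin-adiabatic surface —
an eigenstate of the diabatic-plus-SOC potential matrix — with
Hellmann–Feynman forces.  Electronic coefficients are propagated in that
basis with a symmetric split-operator over 25 substeps (0.02 fs): the
time-derivative-coupling generator is taken from the overlap of consecutive
eigenvector sets, S = U(t)ᵀU(t+Δt), as (S−Sᵀ)/2Δt for small rotations and
as the matrix logarithm of S when the rotation within one step is large
(trivial or near-exact crossings), which keeps every substep exactly
unitary and makes the coefficients follow state characters through
crossings.  Two protections handle trivial crossings of the *active*
surface: the active index is reassigned (not hopped) when the overlap shows
the state's character moved to another index, and generator elements that
merely relabel swapped states are excluded from the hop-probability tally —
without this, near-exact crossings generate spurious stochastic hops onto
unpopulated surfaces.

Hops use Tully's fewest-switches probabilities accumulated over the
substeps, a single uniform draw per nuclear step, momentum rescaling along
the velocity at accepted hops (the overlap scheme yields scalar couplings,
so no nonadiabatic-coupling vector is available to rescale along), and
unchanged momenta at frustrated hops.  Hops into the S0-character adiabat
are disabled; note that "S0 character", not "lowest index" — at strongly
tilted or stretched geometries the T1 surface dips below the rising S0
surface, and both the hop ban and the termination gap follow the
closed-shell character.  The energy-based decoherence correction damps
non-active amplitudes each step with τ_k = ħ/|E_k−E_a| · (1 + C/E_kin),
C = 0.1 Hartree, restoring the norm exactly; zero kinetic energy means no
damping rather than a division error.

Trajectories terminate when the active-to-S0 gap drops below 0.15 eV
(singlet → assumed internal conversion to S0; triplet → assumed trapped in
T1), at 1000 fs (timeout), or on numerical failure (flagged, excluded from
statistics but counted).  Ensembles spawn per-trajectory seeds
deterministically from a master seed, so identical seeds give
byte-identical ensembles.

## Channel classification

A terminated trajectory is ring-opening-CO if r_CO > 1.8 Å at termination
(the printed criterion), NH-fission if r_NH > 1.8 Å (chosen by analogy;
config-exposed), photostabilising if it ended on the gap criterion with
intact bonds, otherwise "other"; the C(5)–O single-trajectory channel label
is reserved but the four-coordinate surrogate cannot express it.  Fractions
are reported both as exact rationals and nearest-percent roundings.

## What the surrogate does and does not show

With the shipped calibration the 141-trajectory ensemble reproduces the
qualitative photochemistry: C(2)–O ring opening is the modal channel
(≈50–60% across seeds; reported ≈50%), the C–S-tilting photostabilising
funnel takes ≈20–35% (reported 37%), N–H fission is a minority channel
(≈15–20%; reported 13%), and intersystem crossing populates the triplet
manifold with both trapped-T1 and triplet ring-opening outcomes.  Median
excited-state lifetimes are ≈80–120 fs, shorter than the real molecule's,
because four degrees of freedom funnel population to the seams far faster
than 33 would.

The triplet *yield* is the one headline quantity the surrogate does not
approach: ≈1–4% of trajectories end in the triplet manifold versus the
reported 32%.  With a single-component effective SOC of 50 cm⁻¹ the
per-passage crossing probabilities are ~10⁻³, and the short singlet
lifetimes leave too few seam passages; the real molecule's thiocarbonyl
SOCs (not printed) are substantially larger.  The SOC constant is
config-exposed, but the shipped default is kept and the limitation stated
rather than tuned away.

Other limitations: no vibronic fine structure or solvent shifts in the
spectrum; no T1→S0 intersystem-crossing rate (the protocol explicitly
cannot model repopulation of S0 from T1, so triplet-trapped is a terminal
class); no A-FSSH-style alternatives; energy conservation near the
surrogate's near-exact crossings carries local integration noise at the
0.5 fs step (net drift median ≈2×10⁻⁴ eV/fs across an ensemble, while on
smooth surfaces the integrator conserves to <10⁻⁶ eV over 1000 steps).

## Numerical choices

- Units: eV, Å, fs, amu; ħ = 0.6582119569 eV·fs; 1 Hartree = 27.211386 eV;
  λ·E = 1239.841984 eV·nm.
- MECP penalty: F_σ = (E_i+E_j)/2 + σ·ΔE²/(|ΔE|+α), α = 0.02 Hartree,
  σ doubling from 3.5, L-BFGS-B inner minimisation on analytic gradients,
  plus a projected-gradient seam polish (Newton step onto the seam +
  descent of the mean energy along it) because the stiff penalty valley
  limits quasi-Newton convergence; converged at gap < 1 meV and
  seam-projected mean gradient < 10⁻³ eV/Å.  Results are independent of
  the starting penalty on convex seams.
- Fewest-switches tally: flux rectified per 0.02 fs substep with the
  instantaneous |c_a|²; probabilities clipped to partition at 1.
  At a single Landau–Zener passage this faithful rectification carries a
  small intrinsic positive bias (≈+0.015 at P ≈ 0.91): the physical
  transient dip of the active-state population (a Stueckelberg feature,
  step-size independent) is "banked" by hops that the later coherent
  recovery cannot fully undo.  The electronic propagation itself matches a
  numerically exact two-state integration to four digits, and the
  benchmark switch fraction agrees with the analytic probability within
  three binomial standard errors at 2000 trajectories.
- The Landau–Zener benchmark uses V = 0.01 eV, |ΔF| = 1 eV/Å,
  v = 0.01 Å/fs, mass 2000 amu (negligible rescaling feedback), a
  −0.4…+0.4 Å sweep, and no decoherence (single coherent passage).
- Eigenvector continuity: sign alignment against the previous step plus a
  determinant guard that keeps the frame rotation proper at state swaps.
- Problem sizes used by the test-suite and the acceptance script — 500
  Wigner samples (10⁵ for the variance check), 141 trajectories of ≤1 ps,
  2000 Landau–Zener trajectories, 7-state electronic basis — were chosen
  to match the study design while keeping a full run in minutes on one
  CPU.
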