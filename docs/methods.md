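# Methods

## The surrogate model

`shbdecay` does not compute electronic structure. It replaces the ab
initio layer (forces, excitation energies, couplings) with a two-diabat,
two-nuclear-coordinate model chosen as the smallest system that exhibits
both signatures of the short-hydrogen-bond (SHB) fluorescence mechanism:
a proton-transfer double well whose barrier is controlled by the
donor–acceptor distance, and a gap-closing distortion mode whose
excited-state stiffness weakens as the hydrogen bond is stretched.
Everything downstream — amplitude propagation, hazard accumulation,
free-energy estimation, descriptors, spectra — operates only on
trajectory frames `(R, dR/dt, E_S0, E_S1, σ, f)` and applies unchanged to
data from a real excited-state MD engine.

### Coordinates and units

Two mass-weighted coordinates with unit effective masses (1 amu):

- `delta` (Å) — the proton-transfer coordinate d(O1–H) − d(O2–H);
- `q` (Å) — a collective distortion standing in for the carbonyl stretch
  plus ring deplanarization.

Working units are eV, Å, fs, amu, K throughout; 1 amu·Å²/fs² = 103.6427 eV
converts kinetic energy. ħ is carried as 0.6582119569 eV·fs, hc as
1239.84193 eV·nm, 1 Ry = 13.605693 eV (`shbdecay.constants`).

### Diabats

    V1(δ,q) = a·δ⁴ − b·δ²            + (k_q/2)·q²          (ground character)
    V2(δ,q) = E_v + (k_e/2)·δ²  − g·q + (s(hb)/2)·q²        (excited character)

mixed by a constant coupling c = 0.02 eV, so the adiabatic gap
√(ΔV² + 4c²) never falls below 2c and the surfaces never cross. The
quartic coefficients are set from the designed barrier B(hb) and the well
position δ₀ = 0.35 Å (b = 2B/δ₀², a = B/δ₀⁴).

**Barrier law.** B(hb) = B_SHB + B_sat·(1 − exp(−((hb−2.5)/w)²)) with
B_SHB = 0.020 eV, B_sat = 1.0 eV, w = 0.4 Å. The barrier is at thermal
energy for the natural short bond (so the proton shuttles at 300 K and the
sampled free-energy profile is a double well) and rises steeply past
~2.9 Å toward a ~1 eV plateau (the proton is locked on the donor; only one
well is ever sampled, hence a single-well classification). A plain
exponential law cannot do both: one steep enough to lock the 3.0 Å
condition reaches absurd barriers at 4.5 Å, one gentle enough at 4.5 Å
leaves 3.0 Å crossable within tens of picoseconds.

**Stiffening law.** s(hb) = 3.6·exp(−0.75·(hb−2.5)) eV/Å², against a
ground-state k_q = 1.0 eV/Å² and a gap-closing pull g = 1.3 eV/Å. At
2.5 Å the excited-state minimum along q sits at small q with a ~2.7 eV gap
(inside the configured visible-emission window E_v = 3.0 eV ± 0.5); by
4.5 Å the stiffening is weaker than the ground curvature, the diabats
cross at accessible q, and the minimum gap collapses to 2c. The minimum
gap over q is strictly decreasing across the four protocol conditions
(2.67 → 2.43 → 1.79 → 0.04 eV).

These coefficients were fixed once, at design time, to embody the
qualitative mechanism (thermal SHB barrier, ~3 eV gap, monotone
gap-closing with bond length); they are all configuration
(`SurfaceParams`) and none is adjusted anywhere else in the package.

### Dynamics

Velocity Verlet at dt = 0.5 fs on one adiabat (analytic gradients of the
2×2 eigenvalues). Temperature control uses the stochastic
velocity-rescaling (canonical-sampling) thermostat with relaxation time
τ = 50 fs by default; a Langevin option exists. Restraints are harmonic
penalties (default 10 eV/Å²) on named model coordinates — the bond-length
constraint itself is a surface parameter here, not a restrained
coordinate, so the restraint machinery mirrors the anchor-atom position
restraints of constrained-dimer protocols. The per-frame nonadiabatic
coupling is analytic: σ = ∇θ·dR/dt with θ = ½·atan2(2c, V1−V2), and the
surrogate oscillator strength is f = f₀·gap/E_v (largest at the vertical
gap, fading toward the degeneracy where the transition loses its
brightness) — a bookkeeping choice that only feeds the spectra layer.

## Decay probabilities

Amplitudes are integrated in the adiabatic basis with the antisymmetric
generator (σ_01 = −σ_10, diagonal −iω_i/ħ). Frame data are interpolated
linearly within each nuclear step and each electronic substep (default 10
per nuclear step) applies a fourth-order Magnus propagator (two Gauss
points, closed-form 2×2 exponential). The generator is anti-Hermitian and
the Magnus exponent inherits that, so the norm is conserved to machine
precision; accuracy against a dense adaptive integration of the same
interpolated equations is ~10⁻⁸ in the amplitudes over 1 ps, and the
Landau–Zener closed form is reproduced to <0.1% over a tenfold range of
sweep rates.

The per-step hopping probability divides the flux integral by the
population of the **occupied** state S1 (the standard fewest-switches
prescription). Printed forms of this expression sometimes carry the
ground-state population in the denominator instead; that variant is
selectable (`normalize_by="s0"`) but not the default. Negative raw values
(flux into S1) are clamped to zero by default; signed accumulation is
available (`clamp=False`). The survival recursion is algebraically
identical to the product form 1 − Π(1−NRP_k), which the tests verify to
10⁻¹².

Replica protocol: 3 ps ground equilibration → vertical excitation
(C_S1 = 1) → 1 ps excited propagation with no surface switches → hazard
accumulation; five replicas per condition, seeds `base + replica`, pooled
as a pointwise mean (replicas are exchangeable; no weighting information
exists to prefer anything else).

## Free energies and well classification

F(δ) = −k_BT ln ρ̂(δ) from a 50-bin histogram over the sampled range
padded by 5%; empty bins are NaN, the profile is shifted to min F = 0.
Classification considers local minima only in bins with ≥ 25 samples — a
bin visited once or twice sits ~k_BT·ln2 away from its neighbours on pure
counting noise and would otherwise fake shallow wells in the tails. A
profile is double-well iff two such minima are separated by a maximum
exceeding both by more than 0.4 k_BT. The threshold must sit below the
~0.8 k_BT barrier of the natural short bond (a 1 k_BT threshold can never
see a thermal-scale double well) and above the ~0.1–0.3 k_BT bin noise of
a 10⁴–10⁵-sample profile. The reported barrier is the separating maximum
relative to the global minimum; as a max-minus-min of a noisy curve it
carries a positive bias of a few tenths of k_BT at typical trajectory
lengths, which is why the protocol samples 50 ps of ground dynamics (10⁵
steps) per condition.

## Descriptors

Ring deplanarization sums the absolute values of the five intra-ring
torsions τ(i, i+1, i+2, i+3 mod 5): signed sums cancel for symmetric
puckers, and the quantity plotted in distortion histograms is
nonnegative; a signed mode exists. All geometric descriptors are
rotation/translation invariant (tested to 10⁻⁹). The toy-molecule
embedding maps (δ, q) onto a 9-atom fragment — O2, H, O1, carboxyl C, and
a C₄N ring — with d(O1,H)−d(O2,H) = δ exactly, C=O length 1.23 + 0.09·q Å
and a 0.45·q Å out-of-plane ring lift; the 0.09 Å/Å
stretch coefficient is sized so the C=O histogram mode of a decaying
(4.5 Å) trajectory sits ≈0.1 Å above the SHB one, the designed magnitude
of the carbonyl activation. Hydrogen-bond enumeration takes all O/N pairs
within 3.2 Å, flagging ≤ 2.6 Å as SHBs.

## Spectra

Lineshape is Lorentzian with HWHM equal to the intrinsic bandwidth
0.003 Ry ≈ 0.0408 eV (the Liouville–Lanczos response formalism yields
Lorentzian-broadened spectra); Gaussian is available. Thermal averaging
draws 25 frames uniformly without replacement — a thermostatted
trajectory already visits configurations with Boltzmann weight, so no
reweighting is applied. Peak positions are minima of a Savitzky–Golay
(window 7, order 3) second derivative below a 1%-of-extremum prominence
threshold, which resolves shoulders separated by ~1 bandwidth that the
direct curve merges.

## Franck–Condon factors

Single effective displaced harmonic mode; equal frequencies use the exact
Poisson form FC(0→n) = e^(−S)Sⁿ/n!, unequal-frequency 0–0 the closed-form
overlap, and every other case numerical quadrature of the oscillator
eigenfunctions (trapezoid on ±12 dimensionless units, 4001 points,
accurate to ~10⁻¹⁰ for the quantum numbers used). The displacement
convention for mixed frequencies places d in the dimensionless coordinate
of the mean frequency. Multi-mode 0–0 factors multiply per-mode factors
(independent-mode approximation; no Duschinsky rotation, no
anharmonicity).

## What the surrogate does and does not show

Passing tests demonstrate that the analysis layer is correct (propagator
accuracy, hazard identities, estimator consistency, exact conversions)
and that the designed mechanism behaves as intended: decay probability
strictly increasing with hydrogen-bond length, a double well only at the
short bond, carbonyl/ring distortion activation in the decaying
conditions. They do **not** validate the electronic structure of any real
crystal: the surfaces are caricatures with configured coefficients, the
absolute ANRP magnitudes (~10⁻⁷ at the short bond here) have no
quantitative meaning, and real systems have many more coupled modes,
anharmonicity, and state-dependent couplings the model omits.

## Problem sizes and numerical choices

Default protocol per condition: 50 ps ground sampling for the free-energy
profile, five replicas × (3 ps equilibration + 1 ps excited), 0.5 fs
steps, 10 electronic substeps — about 30 s for all four conditions on one
CPU. Degenerate inputs fail loudly: non-finite forces, norm drift
> 10⁻⁶, populations below 10⁻¹² in the hopping denominator, undefined
torsions, out-of-range probabilities. Ties in peak finding and well
ranking resolve toward lower energy/first occurrence; all RNG flows from
`numpy.random.default_rng` seeded per replica (`base + 1000·condition +
replica`).
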