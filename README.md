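# shbdecay

Nonaromatic peptide-like crystals can fluoresce in the visible without any
conventional chromophore. One proposed mechanism ties that emission to
**short hydrogen bonds (SHBs)**: a donor–acceptor O···O distance of
~2.45–2.6 Å puts the shared proton in a low-barrier double well, and the
stiffened hydrogen-bond network suppresses the vibrational distortions
(carbonyl stretch, ring deplanarization) that would otherwise carry the
photoexcited system to a conical intersection and quench it
nonradiatively. `shbdecay` packages that mechanism as a testable surrogate
pipeline for computational chemists and spectroscopists who want the
analysis layer — decay-probability accumulation, free-energy profiling,
distortion descriptors, spectra, Franck–Condon factors — without the ab
initio engines.

## What it computes

**Two-state model system.** A 2-DOF nuclear model (proton-transfer
coordinate δ, collective distortion q) with diabats mixed by a constant
coupling c > 0, parameterized by the hydrogen-bond length: the
ground-state δ-barrier is thermal (~k_BT) at 2.5 Å and rises steeply for
stretched bonds, while the excited-state stiffening along q weakens with
bond length, letting long-bond systems distort toward the S₁/S₀
near-degeneracy. Nuclei are propagated classically (velocity Verlet,
stochastic velocity-rescaling thermostat, 0.5 fs steps).

**Nonradiative decay hazard.** Along an excited trajectory the electronic
amplitudes obey

    iħ ∂C_i/∂t = C_i ω_i − iħ Σ_j C_j σ_ij ,

with σ = ⟨Ψ_S0|∇_R|Ψ_S1⟩·dR/dt the scalar nonadiabatic coupling (analytic
for the model: dθ/dt of the mixing angle). The fewest-switches per-step
hopping probability

    NRP(t) = −2 ∫_t^{t+Δt} Re[C_S1 C_S0* σ] dt′ / |C_S1|² ,   clamped to [0,1],

is accumulated with the survival recursion ANRP_{n+1} = ANRP_n +
(1−ANRP_n)·NRP_n ≡ 1 − Π_k(1−NRP_k): the total probability that the system
would have hopped to S₀ by time t. Low ANRP(1 ps) ⇒ long-lived S₁ ⇒
fluorescence.

**Descriptors and spectra.** Proton-transfer free energies −k_BT ln ρ(δ)
with single/double-well classification; C=O bond-length and
ring-deplanarization histograms (Σ|τ| over the five intra-ring torsions);
donor–acceptor distance enumeration with an SHB flag at ≤ 2.6 Å;
Lorentzian stick broadening at 0.003 Ry (≈0.0408 eV) HWHM, 25-frame
thermal averaging, second-derivative peak localization; Franck–Condon
factors of displaced harmonic modes, FC(0→0) = e^(−S).

## Worked example

```python
>>> import shbdecay as sd
>>> ens = sd.run_condition(2.5, n_replicas=5, seed_base=0)   # natural SHB
>>> ens.final_mean_anrp
7.0989682665612e-08
>>> sd.run_condition(4.5, n_replicas=5, seed_base=3000).final_mean_anrp
0.9998227241704596
```

At the natural short bond the mean accumulated decay probability after
1 ps of excited-state dynamics is ~10⁻⁷ — the system is trapped far from
the gap-closing region and stays fluorescent — while constraining the same
dimer to 4.5 Å lets the distortion mode reach the avoided crossing and the
decay probability saturates. The ground-state free-energy profile shows
why:

```python
>>> surf = sd.build_surface(2.5)
>>> traj = sd.sample_ground_trajectory(surf, 300.0, 0.5, 100_000, seed=0)
>>> fes = sd.free_energy_profile(traj.coords[:, 0], 300.0)
>>> fes.well_count, round(fes.barrier, 4)
(2, 0.0226)
```

a proton-transfer double well with a barrier below ~1 k_BT (0.026 eV) —
zero-point motion would make the transfer essentially barrierless. The
same run at 3.0–4.5 Å gives a single well. Unit bookkeeping for reporting:

```python
>>> round(sd.ev_to_nm(3.0)), round(sd.ev_to_nm(3.5))
(413, 354)
>>> round(sd.infer_huang_rhys(0.82), 3)   # 0-0 dominated emission
0.198
```

The same operations are available from the shell:
`shbdecay protocol --seed 0 --out runs/` executes the full four-condition
protocol (2.5/3.0/3.5/4.5 Å × 5 replicas × 1 ps) and writes per-replica
decay CSVs, free-energy profiles, spectra and a JSON summary; see
`shbdecay --help` for `simulate`, `decay`, `fes`, `descriptors`, `hbonds`,
`spectrum`, `fc`.

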