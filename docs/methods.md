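# Methods

This note records the physical model, the conventions that had to be fixed
where more than one self-consistent choice exists, the numerical decisions,
and the limits of what the synthetic test bed can demonstrate.

## Scattering model and frame hopping

The molecule is a deep-subwavelength scatterer described at dipole order
(l = 1) by a 6×6 T-matrix per photon energy, built from the four
bianisotropic polarizability tensors via the relation quoted in the README.
The host medium enters through `c_h = 1/√(ε_h μ_h)·c₀` and
`Z_h = Z₀√(μ_h/ε_h)`; the default is the vacuum choice `c_h = c₀`,
appropriate when the solvent is already folded into the quantum-chemistry
response (implicit-solvent models), and `MediumParams` exposes the general
case.

Relativistic motion is treated by frame hopping with *active* boosts along
z (the passive description is the map β → −β):

1. the incident −z plane wave of pure helicity is boosted into the molecule
   frame F′ (wavenumber × e^(−ξ); helicity exactly preserved — the boost is
   a Kronecker delta in helicity);
2. the scattering problem is solved in F′ with the (rotated) T-matrix;
3. the *forward plane-wave amplitudes* are boosted back.  Boosting
   spherical-wave coefficients directly would mix multipole orders and
   force a speed-dependent truncation, so it is deliberately avoided: in
   the plane-wave basis a collinear boost only rescales the wavenumber.
   The common helicity-independent amplitude factor s(β) acquired in this
   step cancels identically in the TCD ratio and is set to 1; the test
   suite asserts the scale invariance it relies on.

Only axial (±z) propagation is supported: the geometry of interest fixes
θ_i = π, φ_i = 0 and the transmission is observed along −z.  Oblique
incidence, aberration, and off-forward TCD distributions are out of scope.

## Conventions (each fixed once, in `boostcd.constants` / `boostcd.angular`)

* **Wigner functions.** `d^l_{mλ}(θ)` from the factorial series in the
  standard (Varshalovich) sign convention;
  `D^l_{mλ}(φ,θ,ψ) = e^{−imφ} d^l_{mλ}(θ) e^{−iλψ}` for active z-y-z
  rotations.  Spherical components are ordered m = (−1, 0, +1) everywhere.
* **Cartesian↔spherical bridge.** `C` has rows equal to the conjugated
  Condon–Shortley spherical basis vectors; the identity
  `C R₃ C† = D¹(R)` is asserted for random rotations, which pins the
  ordering, the phases and the Wigner convention against each other.  Since
  the T-matrix construction sandwiches `C…C⁻¹`, observables are independent
  of the residual phase freedom in `C`.
* **Parity↔helicity.** The positive-helicity channel is (N + M)/√2
  (`HELICITY_PLUS_IS_N_PLUS_M`).  The opposite choice flips the sign of
  every TCD/ACD spectrum; the synthetic-preset suite pins the shipped sign.
* **Orientation rotations.** An orientation (θ, Φ) acts as
  R = R_y(θ)·R_z(Φ): spin the molecule about its own z-axis by Φ, then tilt
  by θ.  The *omitted* third Euler angle is the rotation about the beam
  axis, which for an axial circularly polarized illumination multiplies the
  four forward co-/cross-helicity amplitudes by pure phases and cancels in
  every intensity.  With that omission, averaging (θ, Φ) over the uniform
  sphere measure reproduces the full rotational (Haar) average of the
  forward observables; this is verified operationally by the invariance of
  the averaged TCD under a global pre-rotation of the T-matrix stack.  (If
  the beam-axis angle were kept and the molecular spin omitted instead, the
  two-angle average would miss a physical degree of freedom and the
  invariance test fails by orders of magnitude.)
* **Forward normalization.** The radial δ/k² weights of the continuum
  expansions, the ½ incoming/outgoing split, the −√2 polar-component
  factor and the dropped e^{ikr}/(kr) envelope are absorbed into the single
  constant `FORWARD_NORM = −i√(12π)`, derived by stationary phase from the
  direction-integral definition of the outgoing helicity vector spherical
  wavefunctions consistent with the √(3/4π) plane-wave expansion constant.
  The constant is *validated*, not assumed: the test suite compares
  `farfield_forward` against a brute-force spherical-Hankel summation of
  the textbook l = 1 multipole fields at k r = 10⁶ (bridge constant 2π√2
  between the two VSWF normalizations, itself measured by quadrature at
  moderate k r).  Only amplitude *ratios* are physically meaningful
  downstream; the absolute TCD scale is arbitrary, as is inherent to a
  forward-amplitude formulation without the envelope.
* **Incoming field.** In the transmissions the incoming amplitude is added
  only to the co-helical scattered channel and is taken equal to the
  incident amplitude (unit by default).

## Units

Internally all four tensors are stored in *reduced* SI units sharing the
dimension of α_ee (C² m²/J): `α_em/Z₀`, `α_me/c₀`, `α_mm/(c₀Z₀)`.  In the
unreduced SI convention (p = α_ee E + α_em H, m = α_me E + α_mm H) the
em/me tensors carry *different* dimensions and the reciprocity relation
cannot be a bare transpose; in reduced units Onsager reciprocity is exactly
`α_me = −α_emᵀ` (with symmetric α_ee, α_mm), which is the invariant the
validator checks and the synthetic generator satisfies by construction.
Atomic-unit import multiplies all four tensors by the single CODATA
polarizability quantum e²a₀²/E_h = 1.64877727436·10⁻⁴¹ C² m²/J — a
common-dimension a.u. scheme chosen because quantum-chemistry outputs
report the four blocks on a common footing; the constant lives in one
table (`constants.AU_TO_INTERNAL`).

## Synthetic generator

The generator emulates damped molecular resonances with complex Lorentzian
line shapes Λ(E) = 1/(E₀ − E − iγ) (HWHM exactly γ, Im Λ > 0 on the whole
grid — the retarded sign that makes the scatterer lossy) and rank-one
moment outer products; chirality enters as α_em = i κ p mᵀ Λ with
α_me = −α_emᵀ.  |κ| ≤ 1 keeps the dissipative part of the 6×6 response
positive-semidefinite and hence the T-matrices passive.

Parameters and defaults:

| parameter | default | meaning |
|---|---|---|
| γ (HWHM) | 0.15 eV (broad presets) / 0.03 eV (narrow presets) | the two damping regimes of broad nucleic-acid-like UV bands vs narrow chlorophyll-like bands |
| orientation count n | 50 | rotational-average sample size |
| β grid | 500 equally spaced values on [0, 1) | CLI speed sweep |
| κ presets | 0.2–0.45 | mid-range chirality, far from the passivity boundary |
| `MOMENT_SCALE` | 10⁻¹⁸ | maps order-one moments to reduced units so preset \|T\| ≈ 10⁻⁴–10⁻² |

`MOMENT_SCALE` deserves a word: physical single-molecule T-matrix entries
are of order 10⁻⁸, at which the TCD (≈10⁻⁸) would sit only ~10⁴ above
double-precision rounding of the near-unity transmissions, making 10⁻⁶-level
equality tests numerically meaningless.  The presets therefore use moments
giving |T| ≈ 10⁻³ — still deeply in the weak-scatterer, passivity-safe
regime, but with the chiral signal ~10¹² above rounding.  Since every
pipeline guarantee tested (Doppler remap, magnitude invariance, mirror
antisymmetry, nulls) is exact at any weak coupling, nothing is lost by the
rescaling.

What the generator does *not* emulate: vibronic structure, inhomogeneous
broadening, Kramers–Kronig-complete response over an infinite band, or the
dense many-transition spectra of real biomolecules.  Passing tests
demonstrate the correctness of the *pipeline* (boosts, rotations, bases,
averaging), not the realism of any particular spectrum; real molecular
tensors enter through the same CSV interface.

## Numerical choices

* **Grid evaluation.** T-matrices are evaluated on the imported energy
  grid; requested rest-frame wavenumbers must hit a node to 10⁻⁶ relative.
  A linear interpolator in k exists but is off by default — the optical
  response is known only on the computed grid, and the speed sweep is
  designed around grid-exact lab wavelengths L = L′·e^(−ξ), which also
  makes the Doppler-equivalence check exact rather than
  interpolation-limited.
* **Admissible window.** For each β only lab wavelengths whose boosted
  counterparts lie inside the grid are evaluated; the rest are excluded and
  reported (the window shrinks toward L = 0 as β → 1).
* **Orientation sampler.** Inverse-chord-distance (Thomson-style) repulsion
  minimized by projected gradient descent with a monotone step-halving /
  1.1-growth schedule, max 2000 iterations, gradient tolerance 10⁻¹²;
  deterministic for fixed (n, seed).  n = 2 converges to an antipodal pair
  and n = 6 to the octahedron to ≲10⁻⁶; for large n the sampler is "good
  enough" by construction — the functional acceptance is the rotation
  invariance of the averaged TCD (≈10⁻⁴ relative at n = 200), not a
  particular point layout.  Uniform 1/n weights are used; the average is
  taken over the TCD values (the ratio), not over amplitudes.
* **Doppler factors** are computed as √((1∓β)/(1±β)) rather than
  exp(∓artanh β) for accuracy as β → 1.
* **Degenerate inputs.** Both transmissions zero → explicit
  undefined-ratio error; empty admissible window → error naming the
  admissible lab window; basis mismatches and non-axial waves are usage
  errors, not silent coercions.

## Known limitations

* Dipole order only; molecules large compared to the wavelength, or
  observables needing quadrupoles, are out of scope by design.
* The exact per-orientation achiral TCD null holds when all tensors share a
  common complex line shape (single resonance, or degenerate resonances as
  in the `achiral-iso` preset).  For multi-resonance achiral scatterers the
  co-helical (first-order) contributions still cancel exactly by
  reciprocity, but the forward *cross*-helicity intensities can differ at
  O(|T|²) (~10⁻⁹ at preset scales) because the transverse response tensor
  is no longer real up to a global phase.  The orientation-averaged null is
  correspondingly exact only in the same regime.
* The absolute TCD magnitude is arbitrary (envelope and normalization
  freedom); only wavelength structure, signs, ratios and β-dependence are
  physical outputs.
* The β sweep's per-speed wavelength column follows the boosted grid, so
  different speeds report different (though deterministically related)
  wavelength sets; fixed-wavelength comparisons across β require the
  interpolating mode.
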