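# boostcd

Transmission circular dichroism (TCD) of chiral molecules moving at
relativistic speed, computed by a multi-scale *frame-hopping* pipeline:
dipolar T-matrices built from bianisotropic polarizability tensors, active
Lorentz boosts of axial plane waves, and rotational averaging over
uniformly spread molecular orientations.

**Who it is for.** Researchers in chiroptical spectroscopy and electromagnetic
scattering who want to predict how the circular-dichroism signature of a
molecule (for detection of chiral biomolecules in astrophysical settings, or
for any fast-moving scatterer) deforms when the molecule moves toward the
observer at speed `v = βc`.

## Model

A molecule is represented at dipole order by four complex 3×3 dynamic
polarizability tensors α<sub>ee</sub>, α<sub>em</sub>, α<sub>me</sub>,
α<sub>mm</sub> on a photon-energy grid (from quantum chemistry, or from the
built-in synthetic Lorentzian-oscillator generator).  They define a 6×6
T-matrix

    T = (i c_h Z_h k_h³ / 6π) · [[ C α_ee C⁻¹,        C(−i α_em/Z_h) C⁻¹ ],
                                  [ C(i α_me/c_h) C⁻¹, C(α_mm/(c_h Z_h)) C⁻¹ ]]

with `C` the Cartesian→spherical basis matrix, converted to the helicity
basis (channels (N ± M)/√2) because helicity is invariant under Lorentz
boosts.  For an incident plane wave of pure helicity λ travelling along −z:

1. **Boost to the molecule frame** F′: the wavenumber scales by
   e^(−ξ) = √((1−β)/(1+β)), ξ = artanh β; helicity is unchanged.
2. **Scatter**: the l = 1 expansion of the axial wave populates the single
   (m = −λ, λ) channel with weight √(3/4π); B′ = T_R A′ with the T-matrix
   rotated to the molecular orientation, T_R = R T R⁻¹.
3. **Forward far field**: at θ = π each outgoing helicity keeps one channel,
   E_{s,λ} = −i√(12π)·B′_{1,−λ,λ} (envelope e^{ikr}/kr dropped).
4. **Inverse boost** back to the lab frame (wavelength rescaling only), add
   the co-helical incoming field, and form the transmissions
   T⁺ = |E⁺_{s,+1} + E_in|² + |E⁺_{s,−1}|² (and mirrored T⁻), giving

       TCD = (T⁻ − T⁺) / (T⁻ + T⁺).

5. **Rotational average**: arithmetic mean of the TCD over n uniformly
   spread orientations (default n = 50), generated by a Thomson-style
   repulsion sampler.

The net prediction: the TCD spectrum shifts rigidly to shorter wavelengths
as `L → L·√((1−β)/(1+β))` while its magnitude is speed-invariant.

## Worked example

```python
import numpy as np
from boostcd import BoostZ, build_tmatrix_stack, preset_polarizabilities
from boostcd.orientations import (grid_lab_wavelengths_nm,
                                  rotational_average_tcd, sample_orientations)

stack = build_tmatrix_stack(preset_polarizabilities("chiral-single"))
orients = sample_orientations(50, seed=1)
for beta in (0.0, 0.6):
    boost = BoostZ(beta)
    lab_l = grid_lab_wavelengths_nm(stack, boost)
    grid = rotational_average_tcd(stack, orients, boost, lab_l)
    i = np.abs(grid.tcd).argmax()
    print(f"beta={beta:4.2f}  window {lab_l.min():6.1f}-{lab_l.max():6.1f} nm  "
          f"peak TCD {grid.tcd[i]:+.3e} at {grid.wavelength_nm[i]:.1f} nm")
```

prints

```
beta=0.00  window  281.8- 688.8 nm  peak TCD +1.670e-04 at 394.9 nm
beta=0.60  window  140.9- 344.4 nm  peak TCD +1.670e-04 at 197.4 nm
```

The `chiral-single` preset has one chiral resonance at 3.1 eV (≈400 nm).  At
β = 0.6 the admissible lab window and the TCD peak sit at exactly half the
rest wavelengths (e^ξ = 2) while the peak value is unchanged — the
Doppler-shift phenomenology in two lines of output.

The same pipeline is available from the shell:

```sh
boostcd preset chiral-single --out pol.csv
boostcd build --polarizability pol.csv --out tmat.json
boostcd tcd --tmat tmat.json --beta 0,0.2,0.4,0.6,0.8,0.99 \
            --orientations 50 --seed 1 --out tcd.csv
boostcd spectra --tmat tmat.json --out acd.csv
```

`tcd.csv` holds `(beta, wavelength_nm_lab, tcd)` rows; `acd.csv` the
rotationally averaged absorption per incident helicity and their difference
(ACD).  Identical configurations reproduce identical bytes.

## Layout

- `src/boostcd/angular.py` — Wigner d/D functions, helical polarization
  vectors, Cartesian↔spherical bridge.
- `src/boostcd/tmatrix.py` — polarizability sets, T-matrix construction,
  parity↔helicity, rotation, enantiomer mirror, CSV/JSON I/O, passivity.
- `src/boostcd/relativity.py` — axial active boosts and Doppler factors.
- `src/boostcd/scattering.py` — plane-wave expansion, scattering, forward
  far fields, transmissions, TCD, absorption/ACD reconstruction.
- `src/boostcd/orientations.py` — Thomson-style orientation sampler and the
  rotational TCD average.
- `src/boostcd/synthetic.py` — Lorentzian-oscillator polarizability
  generator and the shipped presets.
- `src/boostcd/cli.py` — the `boostcd` command.
- `docs/methods.md` — modelling assumptions, conventions and numerical
  choices.
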