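# rrsolv

Solvation structure, fluctuating-charge embedding, and resonance-Raman
spectra of hydrogen-bonded chromophores in water — a desk-scale, fully
testable pipeline.

## The problem

Resonance Raman (RR) spectroscopy turns a weak scattering experiment into a
sensitive analytical probe by tuning the laser into an electronic
absorption band: modes coupled to that transition are enhanced by many
orders of magnitude.  Interpreting RR spectra of a chromophore in water —
the textbook case being caffeine, whose carbonyl oxygens and imidazole
nitrogen accept hydrogen bonds from the solvent — requires a chain of
models: solvent-structure analysis of snapshot ensembles, a polarizable
description of the water environment, and a vibronic theory connecting
excited-state geometry changes to per-mode scattering cross-sections.

`rrsolv` implements that chain for users who want every link verifiable on
a laptop: computational spectroscopists prototyping RR workflows, and
anyone needing reference implementations of the underlying primitives.
All inputs are generated synthetically with *planted* ground truth (exact
hydrogen-bond counts, exact mode displacements), so each analysis stage is
tested by exact recovery rather than against external data.

## Models at the core

* **Solvation analysis** — radial distribution functions g(r) and running
  coordination numbers n(r) = ρ∫4πr′²g(r′)dr′ around solute sites on
  solute-centered solvated spheres; geometric hydrogen-bond statistics
  with the criterion d(X···O_w) ≤ 3.5 Å, θ(H_w–O_w–X) ≤ 30°.
* **Fluctuating charges (FQ)** — electronegativity equalization: water
  site charges minimize χᵀq + ½qᵀJq + qᵀV_ext under per-molecule charge
  constraints (bordered linear system; Ohno-damped or bare Coulomb
  kernel), giving a polarizable reaction potential and linear
  solvatochromic shifts Δε = Σ_a Δq_a V(r_a).
* **VG|FC / IMDHO vibronic engine** — per-mode dimensionless displacements
  Δ_k = −g_k/ω_k^{3/2} from projecting the excited-state gradient onto the
  normal modes (Huang–Rhys S_k = Δ_k²/2); RR transition polarizabilities by
  a time-independent sum over states,

      α_j(ω₀) = μ² Σ_v ⟨1_j|v_j⟩⟨v_j|0⟩ Π_{k≠j}⟨0|v_k⟩⟨v_k|0⟩
                 / (ε₀₀ + Σ_k v_kω_k − ω₀ − iΓ),

  cross-checked against an independent time-dependent half-Fourier oracle;
  cross-sections σ ∝ ω₀ω_s³|α|²; Placzek-invariant spontaneous Raman at
  1064 nm; Gaussian-convolved UV-Vis (FWHM 0.6 eV); Lorentzian stick
  broadening (FWHM 8 cm⁻¹); ensemble averaging over snapshots; RR
  excitation profiles (RREP) over 30 000–65 000 cm⁻¹ and per-mode
  enhancement factors RR/Raman.

See `docs/methods.md` for conventions, defaults and limitations.

## Worked example

Enhancement factors from the packaged reference cross-section table
(Raman at 1064 nm vs RR at 266 nm), and band maxima of a 200-snapshot
synthetic ensemble:

```python
import numpy as np
from rrsolv import (caffeine_like_chromophore, make_ensemble, EnsembleSpec,
                    uvvis_spectrum, enhancement_factors)
from rrsolv.datasets import table1_stick_spectra
from rrsolv.units import cm_to_nm

sticks = table1_stick_spectra()
report = enhancement_factors(sticks["rr266"], sticks["raman"])
for lbl, f, ef in zip(report.labels, report.freqs_cm, report.factors):
    print(f"{lbl:>12s}  {f:6.0f} cm-1  enhancement {ef:9.3g}")

base = caffeine_like_chromophore(seed=0)
ens = make_ensemble(base, EnsembleSpec(n_snapshots=200, seed=1))
uv = uvvis_spectrum(ens)
lo = uv.axis < 42000
print(f"band 1 maximum: {cm_to_nm(uv.axis[lo][np.argmax(uv.intensities[lo])]):.0f} nm")
print(f"band 2 maximum: {cm_to_nm(uv.axis[~lo][np.argmax(uv.intensities[~lo])]):.0f} nm")
```

prints

```
  rho_CH3_M1    1049 cm-1  enhancement  4.54e+06
  rho_CH3_M3    1097 cm-1  enhancement  2.67e+06
    nu_rings    1313 cm-1  enhancement  1.22e+06
 nu_i-ring_2    1362 cm-1  enhancement  2.96e+05
 nu_i-ring_1    1394 cm-1  enhancement  8.19e+05
  delta_C8-H    1469 cm-1  enhancement  1.01e+06
    delta_CM    1536 cm-1  enhancement  8.23e+05
      nu_C-C    1583 cm-1  enhancement  3.39e+05
  nu_C=C+C=N    1624 cm-1  enhancement  1.42e+05
band 1 maximum: 267 nm
band 2 maximum: 205 nm
```

The methyl rocking modes near 1050–1100 cm⁻¹ are the most enhanced at
266 nm excitation (up to ~10⁶–10⁷ over off-resonance Raman), and the
synthetic ensemble's absorption bands peak at 267 and 205 nm — the
excitation regions where the RR excitation profiles predict the strongest
signals.

The whole pipeline (frames → solvation → FQ → spectra → RREP) also runs
from the command line:

```bash
rrsolv run                 # default demo config, writes runs/demo/*.csv
rrsolv selftest            # built-in property checks
rrsolv rr ensemble.json --w0 266nm --gamma 200
```

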