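# vibhole

Zero-point vibrational averaging of NMR chemical shieldings and molecular
geometry parameters, for computing **secondary isotope shifts** and the
**vibration hole** — the region of a molecule whose vibrational motif
(average geometry, mean-square amplitudes, amplitude covariances) changes
upon isotopic substitution.

An NMR isotope shift at a reporting nucleus, ⁿΔδ = δ(heavy) − δ(light) =
σ(light) − σ(heavy), is almost entirely a vibrational effect: substituting
H by D shrinks zero-point amplitudes and contracts the averaged bond, and
the shielding surface σ(**R**) samples that change.  The package implements
four ways to compute it from a potential-energy surface (PES) and a
shielding surface:

* **VPT2** — second-order vibrational perturbation theory per isotopologue:

      Δδ_harm(X) = −¼ Σᵢ D²σ[lᵢ],
      Δ**R**(X)  = −¼ Σᵢ (1/ωᵢ) Σₖ D^{1,2}V[lᵢ, lₖ] lᵢ,
      Δδ_anh(X)  = −Dσ[Δ**R**(X)],     ⁿΔδ = Δδ(B) − Δδ(A)

  with dimensionless normal modes lᵢ (⟨qᵢ²⟩ = ½ at T = 0) and directional
  derivatives D along mode vectors; D^{1,2}V is the semi-diagonal cubic
  force field, obtained numerically from 2(3N−6) displaced Hessians.
* **DD-VPT2** — the difference-dedicated reformulation.  Expanding B's
  modes in A's complete mode basis (coefficients J), the isotopologue
  difference collapses into a weight matrix M whose eigenvalues κᵢ measure
  how much each *difference-dedicated mode* lᵢ^(Δ) changes its amplitude
  under substitution; κᵢ decay fast (≈ −1+√(m_A/m_B) for the few modes at
  the substitution site, tiny elsewhere), so a cutoff on |κ| reduces the
  cost to a handful of displaced geometries while reproducing the full
  VPT2 difference **exactly** at cutoff 0.
* **loc-VPT2** — VPT2 restricted to the substituted nucleus, every other
  atom frozen (an *a-priori local* reference method).
* **LMZL (± centrifugal)** — independent 1D zero-point treatments of the
  bond length and the two bending angles (azimuth φ_az, altitude φ_alt) of
  the substituted atom in polar coordinates about its bonded partner; the
  optional centrifugal correction V_cent(r) = ⟨L²⟩/(2mr²) restores the
  bond stretch driven by angular zero-point motion that the uncoupled
  treatment misses.

Alongside the shifts, the package computes the vibration-hole descriptors:
r_z and r_g geometry parameters, harmonic mean-square amplitudes ⟨Δf²⟩,
amplitude covariances ⟨ΔfΔg⟩, their isotope effects (explicit-difference or
κ-weighted DD channels), decay profiles by topological distance, Molden
export of (DD) modes, and exaggerated R_e + λ·ⁿΔ**R** structures for
visualization.

Everything runs on synthetic model systems (Morse/polynomial internal-
coordinate force fields with polynomial shielding surfaces) that satisfy
the same evaluator contract an electronic-structure backend would, and a
1D/2D sinc-DVR eigensolver provides exact quantum averages as an oracle.

## Worked example

Compare all methods for a single H/D substitution in the methane-like
model system (shifts in ppb; deviation columns are against the first
method):

```bash
vibhole compare vpt2 ddvpt2 locvpt2 lmzl_cent --fixture methane_like --cutoff 1e-3
```

```
   method     1d(C0)     0d(H1)     2d(H2)     2d(H3)     2d(H4)       MSgD        RMS
     vpt2   -109.193   -111.284     -5.077     -5.077     -5.077      0.000      0.000
   ddvpt2   -109.163   -111.278     -5.067     -5.067     -5.067      0.013      0.015
 loc-vpt2   -127.085   -117.501     -9.896     -9.896     -9.896     -7.713      9.257
lmzl+cent   -125.706   -116.227     -9.789     -9.789     -9.789     -7.118      8.529
max |difference| vs vpt2: 0.029773 ppb
```

The column headers give the bond count n to the substitution site and the
nucleus (`0d(H1)` is the substituted hydrogen itself, `1d(C0)` the directly
bonded carbon).  DD-VPT2 with the default |κ| ≥ 10⁻³ cutoff reproduces the
explicit VPT2 difference to 0.03 ppb while evaluating 17 Hessians instead
of 37; the local methods deviate at the few-ppb level because the hole is
not perfectly localized.  All shifts are negative: deuteration increases
the shielding at every nucleus.

Other entry points: `vibhole run` (job files or fixtures, with `--molden`
and `--viz-xyz` exports), `vibhole profile` (hole decay by topological
distance), `vibhole fixtures`.  The same functionality is available as a
library — see `vibhole.pipeline.run_standard_vpt2` / `run_dd_vpt2`,
`vibhole.localmodels`, and `vibhole.geometry_stats`.

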