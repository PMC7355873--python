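# Methods

## Model and conventions

All internal computation is in Hartree atomic units with ħ = 1: lengths in
bohr, energies in hartree, masses in electron masses (amu × 1822.888486).
Shielding surfaces are handled in ppm; shifts are reported in ppb with the
sign convention ⁿΔδ = δ(B) − δ(A) = σ(A) − σ(B), A the light and B the
heavy isotopologue.  Both isotopologues share the equilibrium geometry
R_e and the PES; only masses differ.

Vibrations are described in dimensionless normal coordinates: the
Cartesian displacement is Δx = Σᵢ lᵢ qᵢ with lᵢ = M^(−1/2) eᵢ /√ωᵢ, eᵢ the
orthonormal eigenvectors of the mass-weighted Hessian.  This makes the
harmonic ground state satisfy ⟨qᵢ²⟩ = ½, which fixes the −¼ prefactors of
the averaging formulas.  Only T = 0 (zero-point) averaging is implemented;
finite-temperature occupation is out of scope.

The rigid space is identified by projection onto analytic translation and
rotation generators (built in the center-of-mass principal-axes frame),
not by an eigenvalue threshold, and the 3N−6 (3N−5 for collinear
geometries) vibrational frequencies must all be real; a negative
eigenvalue raises.  Degenerate eigenpairs are post-rotated against a fixed
reference and sign-fixed so repeated runs are reproducible.

## Numerical differentiation

The semi-diagonal cubic force field φ_(i,kk) = ∂³V/∂q_i∂q_k² is obtained
by central first differences of mode-projected Hessians along each
displaced mode ("Δk" route, two Hessians per mode), or equivalently by
central second differences of mode-projected gradients ("Δ²F" route); both
use displacements R_e + h·l_k in dimensionless coordinates.  Shielding
first/second directional derivatives use the same central stencils.
Default steps are h_FF = 0.005 and h_NMR = 0.05 (dimensionless q units).
The step is read as a dimensionless-coordinate step, which makes the
physical displacement scale with the mode's amplitude; this is the
convention under which a single step width is meaningful across modes.
Only the semi-diagonal cubic slice is ever formed, never the full tensor.

## Difference-dedicated construction

B's modes (vibrations, rotations, translations) are expanded exactly in
A's complete 3N-mode basis by a linear solve, J_{ii'}.  The weight matrix
over A's vibration+rotation coefficient range is

    M_kk' = Σ_{i ∈ v(B)} J_ik J_ik' − Θ_v(k) δ_kk'.

The i-sum runs over B's *vibrational* modes: with that range M vanishes
identically for A = B and the κ-weighted sums reproduce the explicit
B − A differences exactly, because the shielding Hessian, the cubic
tensor and internal-coordinate gradients all annihilate uniform
translations (the only components dropped from the k-range).

Two properties of M conflict if it is diagonalized naively:

* its vibrational block M_vv is exactly invariant under the (arbitrary)
  normalization of the rigid modes, and its eigenvalues carry the
  amplitude interpretation — κ ≈ −1+√(m_A/m_B) for modes localized at the
  substitution site;
* the coupling and rotational blocks scale with the rigid-mode
  normalization, because B's vibrations acquire coefficients on A's
  rotations whenever the Eckart frame rotates under substitution.  Those
  blocks are physically necessary (they carry a few-ppb contribution) but
  their eigenvalues are conventions, not amplitudes.

The package therefore decomposes M in two stages: the κ spectrum is the
eigendecomposition of M_vv (ordered by descending |κ|, cutoff applied
there; the values are negative for a heavier substitution), and the exact
residual [[0, M_vr], [M_rv, M_rr]] is diagonalized into at most six
*frame modes* that are always retained.  The sum of both stages equals M,
so at cutoff 0 DD-VPT2 equals standard VPT2 algebraically; rigid-mode
rescaling is absorbed exactly by an internal renormalization to unit
mass-weighted norm.  The curvature-weight matrix G is defined through
C G Cᵀ = diag(1/ω_v, 0) for the combined (non-orthogonal) coefficient
matrix C, which reduces to the textbook Σ_j K_ji K_ji'/ω_j form when the
coefficient matrix is orthogonal.

The κ mass-ratio limit deserves care: −1+√(m_A/m_B) assumes the frame
around the substituted atom does not recoil.  For heavy frames (aromatic
rings, the 10⁶-amu-partner diatomic fixture) the computed κ reach the
limit to high accuracy.  For methane-type systems the frame is light: the
C–H stretch κ sits at the two-body reduced-mass value (−0.269 rather than
−0.293), the bend pair lower still (−0.152, set by the rotational inertia
of the CH₃ frame), and a central-atom ¹²C/¹³C substitution sees the
carbon oscillating against a 4-amu hydrogen cage, giving a leading κ of
≈ −0.009 rather than the bare-mass −0.039.  These are physical
reduced-mass effects, not truncation artifacts.

The anharmonic shift needs the shielding gradient along the single
direction ⁿΔ**R**; it is measured with one extra central difference along
that direction (two evaluations), keeping the evaluation count
proportional to the number of retained modes.

ⁿΔ**R** is defined modulo rigid-body components (which contribute nothing
to shieldings or internal coordinates: Dσ along a translation or rotation
generator vanishes).  The standard-VPT2 and DD routes can therefore differ
by an infinitesimal rigid component; `harmonic.eckart_project` fixes the
convention when geometry vectors are compared.

## Comparator methods

**loc-VPT2** diagonalizes the mass-weighted 3×3 Hessian block of the
substituted atom (no Eckart projection — the frozen environment fixes the
frame) and runs the identical VPT2 code path on the resulting ≤3 local
modes.  Directions the environment cannot restrain (the transverse motion
of a diatomic partner) have zero restricted curvature and are dropped.

**LMZL** solves three independent 1D zero-point problems in the polar
coordinates (r, φ_az, φ_alt) of the substituted atom about its bonded
partner: angular cuts move the atom on the arc of radius r_e (mass
m·r_e²), the radial cut along the bond (mass m of the substituted atom by
default; a bond-reduced-mass variant is available behind a flag).  Each
1D problem is treated perturbatively — harmonic amplitude 1/(2mω), cubic
mean shift −c₃/(4m²ω³) — to stay commensurate with the VPT2 machinery.
If the partner has only one further neighbor the frame degenerates to a
single in-plane bending coordinate; a multiply-bonded substitution site
raises (the method is undefined there).  The centrifugal variant augments
the radial potential with V_cent(r) = ⟨L²⟩/(2mr²), ⟨L²⟩ = Σ m_φ ω_φ/2
over the angular modes, expanded to third order about r_e; it shifts the
radial minimum outward for the light isotopologue more than for the heavy
one and thereby restores most of the stretch-bend coupling the uncoupled
treatment discards, while leaving the amplitudes essentially unchanged.

## Geometry statistics

f_z = f(R_e + Δ**R**); f_g = f_z + ½ Σᵢ ⟨qᵢ²⟩ lᵢᵀ(∇²f)lᵢ (second-order
individual averaging); harmonic amplitudes ⟨Δf²⟩ = ½ Σᵢ (Df[lᵢ])² and
covariances ⟨ΔfΔg⟩ = ½ Σᵢ Df[lᵢ] Dg[lᵢ], all about R_e.  Isotope effects
come either from the explicit B − A difference or from κ-weighted DD sums;
the two channels agree exactly at cutoff 0.  Lengths are exported in
mÅ (mÅ² for squared amplitudes), angles in degrees.  The covariance
reference defaults to the substituted bond.  Hole profiles group bond
coordinates by the number of bonds between the bond and the substitution
site (0 = the substituted bond, 1 = geminal, …), keeping the sign as a
flag.

## Synthetic model systems

Fixtures are sums of internal-coordinate terms — Morse bonds
parameterized by (k, a) with D = k/(2a²) so a → 0 is the harmonic limit,
polynomial bends with cubic terms, bilinear and cubic couplings — plus
polynomial shielding surfaces per nucleus.  Force constants default to the
regime of C–H/O–H chemistry (stretches ≈ 2900–3700 cm⁻¹, bends ≈
900–1650 cm⁻¹, Morse range a ≈ 1 bohr⁻¹, shielding slopes of tens of
ppm/Å), chosen once as representative values; a seed jitters them ±10%
for randomized variants.  Planar fixtures carry explicit out-of-plane
(altitude) restraints so the harmonic problem is complete.  The
hydrogen-bond toy couples r(O–H) anharmonically to the donor–acceptor
distance with a switchable sign, reproducing bond-localized or delocalized
hole morphologies qualitatively.

What the fixtures do *not* emulate: real electronic-structure surfaces
(no quartic force constants, no Fermi resonances, no solvent or
temperature effects, shielding surfaces with only low-order internal-
coordinate dependence).  Passing tests therefore demonstrate the
correctness of the averaging algebra and the internal consistency of the
methods under controlled anharmonicity, not the accuracy of any particular
quantum-chemical model.

The DVR oracle uses sinc (Colbert–Miller) kinetic matrices on uniform
grids, with automatic range extension until the edge density is below
10⁻¹² and grid doubling until energies and observables move by less than
10⁻⁸ (1D); the 2D solver works on Cartesian tensor grids, where grid
errors largely cancel in isotope differences.

## Numerical choices and verification scales

The test suite runs the full pipelines on systems of 2–7 atoms (chain
length 6 for the decay profiles), where a complete VPT2 calculation costs
tens of Hessian evaluations and the whole suite finishes in about a
minute.  The DD↔VPT2 shift equivalence is verified at the default steps
(< 0.05 ppb observed, asserted < 1 ppb); the ⁿΔ**R** equivalence is an
algebraic identity and is probed at h_FF = 2.5·10⁻⁴, where the O(h²)
stencil difference between the two routes drops below the 10⁻⁸ bohr
assertion.  VPT2-vs-exact convergence is measured on the Morse diatomic
as the log-log slope of the relative error against the Morse range
parameter a (x_e ∝ a²): quadratic for both the geometry shift and a
linear-in-r shielding correction.

## Known limitations

* Cubic-only anharmonicity: strongly anharmonic potentials (low-barrier
  hydrogen bonds, double wells) are outside the radius of convergence of
  the treatment; the hydrogen-bond toy stays in the single-well regime.
* The κ spectrum reported for light frames differs from the heavy-frame
  mass-ratio intuition (see above); consumers who filter modes by an
  expected κ value should use the cutoff, not the limit value.
* LMZL is only defined for singly-bonded substitution sites and ignores
  all mode-mode couplings beyond the optional centrifugal term.
* No parsers for production quantum-chemistry outputs are included; any
  backend satisfying the evaluator contract (geometry → energy/gradient/
  Hessian/shieldings) can be plugged in directly.
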