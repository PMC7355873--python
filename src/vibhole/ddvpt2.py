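"""Difference-dedicated VPT2.

Builds a small set of non-canonical modes (the difference-dedicated, DD,
modes) that carry the whole isotopologue difference, then evaluates the
isotope effects directly, without ever computing the two full VPT2
corrections.

Construction (A = light/unsubstituted, B = substituted isotopologue; both
share the equilibrium geometry and the potential):

1. expand each mode of B in the complete v+r+t basis of A:
       l_i(B) = sum_i' J_ii' l_i'(A)
2. weight matrix over A's v+r range:
       M_kk' = sum_{i in v(B)} J_ik J_ik' - Theta_v(k) delta_kk'
3. diagonalize M -> eigenvalues kappa (ordered by descending magnitude;
   they are negative for a heavier substitution), eigenvectors K
4. DD modes l_i^D = sum_k K_ki l_k(A), curvature weights
       G_ii' = sum_{j in v(A)} K_ji K_ji' / omega_j(A)

kappa_i measures how much the zero-point amplitude along l_i^D differs
between the isotopologues; for a single substitution the three leading
kappa are close to -1 + sqrt(m_light/m_heavy) and the rest decay fast, so
a cutoff on |kappa| reduces the number of displaced geometries from
2(3N-6) per isotopologue to a handful.

With the DD modes:

    nDdelta_harm = -(1/4) sum_k kappa_k D^2 sigma[l_k^D]
    nDR          = -(1/4) sum_k kappa_k sum_ii' G_ii'
                       D^{1,2}V[l_i^D, l_k^D] l_i'^D
    nDdelta_anh  = -D sigma[nDR]

At cutoff 0 these reproduce the explicit VPT2 difference exactly (the
dropped translational components contribute nothing because the shielding
Hessian and the cubic tensor annihilate uniform translations).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from uuid import uuid4

import numpy as np

from .constants import PPM_TO_PPB
from .fields import CubicField, PropertySurface, check_basis
from .harmonic import NormalModeSet
from .system import MolecularSystem, evaluate_coordinate, topological_distances
from .vpt2 import IsotopeShiftReport

__all__ = [
    "DDBasis",
    "mode_jacobian",
    "dd_weight_matrix",
    "dd_modes",
    "dd_isotope_shift",
    "dd_geometry_report",
    "DEFAULT_CUTOFF",
]

DEFAULT_CUTOFF = 1e-3


@dataclass(frozen=True)
class DDBasis:
    """Difference-dedicated mode basis for one isotopologue pair.

    The weight matrix M (over A's v+r coefficient space) is decomposed in
    two stages:

    * the vibrational block M_vv is diagonalized; its eigenvalues are the
      kappa spectrum with the amplitude interpretation (they are exactly
      invariant under the arbitrary rigid-mode scaling), and the cutoff
      acts on them;
    * the residual [[0, M_vr], [M_rv, M_rr]] -- the exact coupling of the
      isotopologue difference to A's rotational coefficients, caused by
      the Eckart-frame change under substitution -- is diagonalized
      separately and its nonzero eigenpairs are kept as "frame" modes
      that are always retained.

    Together the two stages reproduce M exactly, so at cutoff 0 DD-VPT2
    is algebraically identical to the explicit VPT2 difference.

    ``kappa``/``mode_is_frame`` cover all DD modes (vibrational spectrum
    first, ordered by descending |kappa|, then frame modes); ``l_modes``
    are the corresponding Cartesian DD mode vectors; ``retained`` indexes
    the modes along which derivatives must be evaluated.
    """

    J: np.ndarray
    M: np.ndarray
    kappa: np.ndarray
    K: np.ndarray  # coefficient matrix over A's v+r basis (columns per DD mode)
    l_modes: np.ndarray  # (n_dd, N, 3) DD modes
    G: np.ndarray
    cutoff: float
    retained: np.ndarray
    mode_is_frame: np.ndarray
    omega_A: np.ndarray
    modesA: NormalModeSet = field(repr=False)
    basis_id: str = field(default_factory=lambda: uuid4().hex)

    @property
    def dd_modes(self) -> np.ndarray:
        return self.l_modes

    @property
    def kappa_vib(self) -> np.ndarray:
        return self.kappa[~self.mode_is_frame]

    @property
    def n_retained(self) -> int:
        return len(self.retained)


def _canonical_rigid(modes: NormalModeSet) -> NormalModeSet:
    """Renormalize rigid modes to unit mass-weighted norm.

    The scale of the rigid modes is an arbitrary convention; fixing it here
    makes every downstream quantity exactly invariant under external
    rescaling."""
    l = modes.l_modes.copy()
    m = modes.masses_me
    for i, kind in enumerate(modes.kind_flags):
        if kind == "v":
            continue
        norm = np.sqrt(np.einsum("a,ax,ax->", m, l[i], l[i]))
        l[i] /= norm
    return NormalModeSet(modes.omega, l, modes.kind_flags, modes.masses_me, modes.basis_id)


def mode_jacobian(modesA: NormalModeSet, modesB: NormalModeSet) -> np.ndarray:
    """Coefficients J_ii' of B's modes in A's complete v+r+t basis.

    Solved exactly in the full 3N-dimensional space; raises if A's basis is
    ill-conditioned (it cannot be for a valid mode set).
    """
    modesA = _canonical_rigid(modesA)
    modesB = _canonical_rigid(modesB)
    LA = modesA.l_modes.reshape(modesA.l_modes.shape[0], -1).T  # columns l_i'(A)
    LB = modesB.l_modes.reshape(modesB.l_modes.shape[0], -1).T
    if LA.shape[0] != LA.shape[1]:
        raise ValueError("mode basis of A is not complete (v+r+t != 3N)")
    cond = np.linalg.cond(LA)
    if cond > 1e10:
        raise ValueError(f"singular mode basis for A (condition number {cond:.2e})")
    J = np.linalg.solve(LA, LB).T  # J[i, i']
    resid = np.abs(J @ LA.T - LB.T).max()
    if resid > 1e-10:
        raise ValueError(f"mode expansion residual {resid:.2e} exceeds 1e-10")
    return J


def dd_weight_matrix(
    J: np.ndarray, kind_flags_A: np.ndarray, kind_flags_B: np.ndarray
) -> np.ndarray:
    """The symmetric DD weight matrix M over A's v+r index range.

    M_kk' = sum over B's vibrational modes of J_ik J_ik', minus the
    identity on A's vibrational block.  M vanishes identically for A = B.
    """
    vrA = np.flatnonzero((kind_flags_A == "v") | (kind_flags_A == "r"))
    vB = np.flatnonzero(kind_flags_B == "v")
    Jv = J[np.ix_(vB, vrA)]
    M = Jv.T @ Jv
    theta = (kind_flags_A[vrA] == "v").astype(float)
    M[np.diag_indices_from(M)] -= theta
    return 0.5 * (M + M.T)


def _fix_signs(vecs: np.ndarray) -> np.ndarray:
    for j in range(vecs.shape[1]):
        idx = np.argmax(np.abs(vecs[:, j]))
        if vecs[idx, j] < 0:
            vecs[:, j] = -vecs[:, j]
    return vecs


def dd_modes(
    M: np.ndarray,
    modesA: NormalModeSet,
    cutoff: float = DEFAULT_CUTOFF,
    J: np.ndarray = None,
    frame_tol: float = 1e-12,
) -> DDBasis:
    """Decompose M and assemble the DD basis.

    The vibrational-block eigenvalues (the kappa spectrum) are ordered by
    descending |kappa| (they are negative for a substitution with a
    heavier isotope, so the "monotonously decreasing" ordering coincides
    with descending magnitude); the cutoff compares |kappa|.  Frame modes
    (the exact vibration-rotation coupling residual) are appended and
    always retained.
    """
    modesA = _canonical_rigid(modesA)
    M = np.asarray(M, dtype=float)
    if np.abs(M - M.T).max() > 1e-10:
        raise ValueError("M must be symmetric")
    kinds_vr = modesA.kind_flags[(modesA.kind_flags == "v") | (modesA.kind_flags == "r")]
    nv = int(np.sum(kinds_vr == "v"))
    if M.shape[0] != len(kinds_vr):
        raise ValueError("M has wrong shape for A's v+r range")

    from .harmonic import _fix_degenerate_phases

    kap_v, X = np.linalg.eigh(M[:nv, :nv])
    X = _fix_degenerate_phases(kap_v, X)
    order = np.argsort(-np.abs(kap_v), kind="stable")
    kap_v = kap_v[order]
    X = _fix_signs(X[:, order])

    # exact residual: v-r coupling and rotational block
    R = M.copy()
    R[:nv, :nv] = 0.0
    kap_f, Y = np.linalg.eigh(R)
    Y = _fix_degenerate_phases(kap_f, Y)
    scale = max(np.abs(M).max(), 1.0)
    keep_f = np.flatnonzero(np.abs(kap_f) > frame_tol * scale)
    keep_f = keep_f[np.argsort(-np.abs(kap_f[keep_f]), kind="stable")]
    kap_f = kap_f[keep_f]
    Y = _fix_signs(Y[:, keep_f])

    # combined (non-orthogonal) coefficient matrix over A's v+r basis
    C = np.zeros((M.shape[0], nv + len(kap_f)))
    C[:nv, :nv] = X
    C[:, nv:] = Y
    kappa = np.concatenate([kap_v, kap_f])
    is_frame = np.zeros(len(kappa), dtype=bool)
    is_frame[nv:] = True

    vrA = np.flatnonzero((modesA.kind_flags == "v") | (modesA.kind_flags == "r"))
    l_vr = modesA.l_modes[vrA]  # (n_vr, N, 3)
    dd = np.einsum("kj,kax->jax", C, l_vr)

    # G per the curvature-weight definition: C G C^T = diag(1/omega_v, 0)
    # (reduces to sum_j K_ji K_ji' / omega_j for an orthogonal K)
    omega_inv = np.zeros(M.shape[0])
    omega_inv[:nv] = 1.0 / modesA.omega
    CCt_inv = np.linalg.pinv(C @ C.T, rcond=1e-12)
    G = C.T @ CCt_inv @ np.diag(omega_inv) @ CCt_inv @ C

    retained_v = np.flatnonzero((~is_frame) & (np.abs(kappa) >= cutoff))
    retained = np.concatenate([retained_v, np.flatnonzero(is_frame)])
    if len(retained) == 0 and np.abs(kappa).max() > 0:
        warnings.warn(
            "cutoff retains no DD modes although M is nonzero", RuntimeWarning, stacklevel=2
        )
    return DDBasis(
        J=J,
        M=M,
        kappa=kappa,
        K=C,
        l_modes=dd,
        G=G,
        cutoff=float(cutoff),
        retained=retained,
        mode_is_frame=is_frame,
        omega_A=modesA.omega.copy(),
        modesA=modesA,
    )


def build_dd_basis(
    modesA: NormalModeSet, modesB: NormalModeSet, cutoff: float = DEFAULT_CUTOFF
) -> DDBasis:
    """Convenience: J -> M -> DD basis in one call."""
    J = mode_jacobian(modesA, modesB)
    M = dd_weight_matrix(J, modesA.kind_flags, modesB.kind_flags)
    return dd_modes(M, modesA, cutoff=cutoff, J=J)


def dd_isotope_shift(
    dd: DDBasis,
    cubic: CubicField,
    prop: PropertySurface,
    system: MolecularSystem = None,
    substitution_atoms=None,
    sigma_evaluator=None,
    geometry: np.ndarray = None,
    h_nmr: float = 0.05,
) -> IsotopeShiftReport:
    """Isotope shifts from the DD basis.

    ``cubic``/``prop`` must have been evaluated in the DD basis with the
    retained modes displaced.  The anharmonic part needs the shielding
    gradient along nDR: when ``sigma_evaluator`` (and ``geometry``) are
    given it is measured directly with one extra central difference along
    that single direction; otherwise it is expanded over the retained DD
    mode gradients (a truncation-consistent approximation, exact at
    cutoff 0).
    """
    check_basis(dd, cubic)
    check_basis(dd, prop)
    retained = dd.retained
    if len(retained) == 0:
        raise ValueError("retained DD mode set is empty")
    col_of = {int(k): c for c, k in enumerate(cubic.displaced)}
    try:
        cols = [col_of[int(k)] for k in retained]
    except KeyError as exc:
        raise ValueError("cubic field does not cover the retained DD modes") from exc

    kap_r = dd.kappa[retained]

    # harmonic part
    if prop.curv.shape[1] == len(retained):
        pcols = np.arange(len(retained))
    elif prop.curv.shape[1] == dd.l_modes.shape[0]:
        pcols = retained
    else:
        raise ValueError("property surface does not cover the retained DD modes")
    shift_harm = -0.25 * (prop.curv[:, pcols] @ kap_r)  # ppm

    # geometry part: nDR = -(1/4) sum_k kappa_k sum_ii' G_ii' phi[i, k] l_i'^D
    phi = cubic.third_derivatives[:, cols]  # (n_vr, n_retained)
    w = dd.G @ phi  # (n_vr, n_retained): sum_i G_i'i phi[i, k]
    coeff = -0.25 * (w @ kap_r)  # expansion of nDR over DD modes (index i')
    L = dd.l_modes.reshape(dd.l_modes.shape[0], -1)
    nDR = (coeff @ L).reshape(dd.l_modes.shape[1:])

    # anharmonic part
    if sigma_evaluator is not None:
        if geometry is None:
            raise ValueError("geometry required with sigma_evaluator")
        norm = np.linalg.norm(nDR)
        if norm < 1e-300:
            dsig = np.zeros_like(prop.sigma_e)
        else:
            u = nDR / norm
            sp = np.asarray(sigma_evaluator(geometry + h_nmr * u), dtype=float)
            sm = np.asarray(sigma_evaluator(geometry - h_nmr * u), dtype=float)
            dsig = (sp - sm) / (2.0 * h_nmr) * norm
    else:
        dsig = prop.grad[:, pcols] @ coeff[retained]
    shift_anh = -dsig  # ppm

    if system is not None and substitution_atoms:
        dist = topological_distances(system, substitution_atoms)
        n_bonds = np.array(
            [int(dist[int(q)]) if np.isfinite(dist[int(q)]) else -1 for q in prop.nuclei]
        )
    else:
        n_bonds = np.full(len(prop.nuclei), -1, dtype=int)

    return IsotopeShiftReport(
        nuclei=prop.nuclei.copy(),
        n_bonds=n_bonds,
        shift_harm=shift_harm * PPM_TO_PPB,
        shift_anh=shift_anh * PPM_TO_PPB,
        dR=nDR,
        method="ddvpt2",
    )


def dd_geometry_report(
    system: MolecularSystem,
    nDR: np.ndarray,
    coords,
    lambda_viz: float = 400.0,
):
    """Isotope effects on r_z geometry parameters plus a visualization
    structure R_e + lambda * nDR (lambda >> 1 exaggerates the hole).

    Returns (dict label -> f(R_e + nDR) - f(R_e), visualization geometry).
    """
    R = system.coords_e
    deltas = {}
    for c in coords:
        deltas[c.label] = evaluate_coordinate(c, R + nDR) - evaluate_coordinate(c, R)
    return deltas, R + lambda_viz * np.asarray(nDR, dtype=float)
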