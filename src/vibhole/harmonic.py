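"""Harmonic normal-mode analysis per isotopologue.

Produces dimensionless-coordinate vibrational modes plus the rigid
translation/rotation modes that complete the Cartesian space.  The
dimensionless convention is

    Delta x = sum_i l_i q_i,   l_i = M^(-1/2) e_i / sqrt(omega_i)   (a.u.)

with e_i the orthonormal eigenvectors of the mass-weighted Hessian, so the
harmonic ground state has <q_i^2> = 1/2 at T = 0.  Rigid modes are
normalized to unit mass-weighted norm (the physical results never depend
on this scale).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from uuid import uuid4

import numpy as np

from .constants import AMU_TO_ME, HARTREE_TO_INVCM
from .system import Isotopologue, MolecularSystem

__all__ = [
    "NormalModeSet",
    "normal_modes",
    "principal_axes",
    "eckart_project",
    "SaddlePointError",
]

#: squared-frequency threshold separating rigid from vibrational space, as a
#: fraction of the largest vibrational eigenvalue
_ZERO_FRACTION = 1e-9
#: gap (cm^-1) below which the zero/vibration separation triggers a warning
_GAP_WARN_CM = 1.0
_COLLINEAR_TOL = 1e-10


class SaddlePointError(ValueError):
    """Raised when the projected Hessian has a negative vibrational eigenvalue."""


@dataclass(frozen=True)
class NormalModeSet:
    """Vibrational + rigid modes of one isotopologue.

    Attributes
    ----------
    omega : (n_vib,) array
        Harmonic angular frequencies in hartree (a.u.).
    l_modes : (n_modes, N, 3) array
        Cartesian displacement per unit dimensionless coordinate (bohr).
        Vibrations first, then rotations, then translations.
    kind_flags : (n_modes,) array of str
        'v', 'r' or 't' per mode.
    masses_me : (N,) array
        Atomic masses in electron masses (a.u.).
    """

    omega: np.ndarray
    l_modes: np.ndarray
    kind_flags: np.ndarray
    masses_me: np.ndarray
    basis_id: str = field(default_factory=lambda: uuid4().hex)

    @property
    def n_vib(self) -> int:
        return int(np.sum(self.kind_flags == "v"))

    @property
    def n_atoms(self) -> int:
        return self.l_modes.shape[1]

    @property
    def frequencies_invcm(self) -> np.ndarray:
        return self.omega * HARTREE_TO_INVCM

    def vib_modes(self) -> np.ndarray:
        return self.l_modes[self.kind_flags == "v"]

    def vr_modes(self) -> np.ndarray:
        keep = (self.kind_flags == "v") | (self.kind_flags == "r")
        return self.l_modes[keep]

    def rescale_rigid(self, factor: float) -> "NormalModeSet":
        """Return a copy with all rigid (r and t) modes multiplied by factor.

        Physical results must be invariant under this (the rigid-mode scale
        is an arbitrary convention)."""
        l = self.l_modes.copy()
        rigid = self.kind_flags != "v"
        l[rigid] *= factor
        return NormalModeSet(self.omega, l, self.kind_flags, self.masses_me)


def _is_collinear(coords: np.ndarray) -> bool:
    c = coords - coords.mean(axis=0)
    s = np.linalg.svd(c, compute_uv=False)
    return s[1] <= _COLLINEAR_TOL * max(s[0], 1.0)


def principal_axes(system: MolecularSystem, iso: Isotopologue):
    """Inertia eigenframe and rigid translation/rotation displacement fields.

    Returns
    -------
    axes : (3, 3) array
        Principal axes of inertia as rows (ascending moment).
    translations : (3, N, 3) array
        Uniform translations along the principal axes, unit mass-weighted
        norm (a.u. masses).
    rotations : (n_rot, N, 3) array
        Infinitesimal rotations about the principal axes through the center
        of mass, unit mass-weighted norm; n_rot = 2 for collinear geometries.
    """
    coords = system.coords_e
    m = iso.masses * AMU_TO_ME
    if len(m) != system.n_atoms:
        raise ValueError("isotopologue/system size mismatch")
    com = (m[:, None] * coords).sum(axis=0) / m.sum()
    x = coords - com
    inertia = np.einsum("a,aij->ij", m, np.einsum("ak,al->akl", x, x) * -1.0)
    inertia += np.eye(3) * np.einsum("a,ak,ak->", m, x, x)
    moments, vecs = np.linalg.eigh(inertia)
    axes = vecs.T  # rows

    def mw_normalize(vec: np.ndarray) -> np.ndarray:
        norm = np.sqrt(np.einsum("a,ak,ak->", m, vec, vec))
        if norm < 1e-300:
            raise ValueError("degenerate rigid mode (all atoms coincident?)")
        return vec / norm

    translations = np.array([mw_normalize(np.tile(ax, (len(m), 1))) for ax in axes])

    collinear = _is_collinear(coords)
    rotations = []
    for k, ax in enumerate(axes):
        field_ = np.cross(ax[None, :], x)
        norm2 = np.einsum("a,ak,ak->", m, field_, field_)
        if norm2 < 1e-12:  # rotation about the molecular axis of a collinear system
            continue
        rotations.append(mw_normalize(field_))
    rotations = np.array(rotations)
    expect = 2 if collinear else 3
    if rotations.shape[0] != expect:
        raise ValueError("unexpected number of rotational modes")
    return axes, translations, rotations


def eckart_project(system: MolecularSystem, iso: Isotopologue, displacement: np.ndarray) -> np.ndarray:
    """Remove net translation and infinitesimal rotation from a Cartesian
    displacement field, in the mass metric of the given isotopologue.

    Geometry-shift vectors (DR, nDR) are defined only modulo rigid-body
    components (which contribute nothing to any shielding or internal
    coordinate); this fixes the convention for comparisons.
    """
    _, trans, rots = principal_axes(system, iso)
    rigid = np.concatenate([rots, trans])
    m = np.repeat(iso.masses * AMU_TO_ME, 3)
    q, _ = np.linalg.qr((rigid.reshape(len(rigid), -1) * np.sqrt(m)).T)
    vm = np.asarray(displacement, dtype=float).ravel() * np.sqrt(m)
    vm = vm - q @ (q.T @ vm)
    return (vm / np.sqrt(m)).reshape(np.shape(displacement))


def _fix_degenerate_phases(evals: np.ndarray, evecs: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    """Deterministic post-rotation of (near-)degenerate eigenvector pairs.

    Within each degenerate cluster the eigenvectors are re-mixed by a QR
    decomposition of their projection onto a fixed reference (the leading
    coordinate axes), then sign-fixed, so repeated runs and different LAPACK
    backends give identical modes.
    """
    out = evecs.copy()
    n = len(evals)
    i = 0
    scale = max(np.abs(evals).max(), 1.0)
    while i < n:
        j = i + 1
        while j < n and abs(evals[j] - evals[i]) <= tol * scale:
            j += 1
        if j - i > 1:
            block = out[:, i:j]
            # project onto the first (j-i) canonical axes with largest overlap
            ref = np.argsort(-np.abs(block).sum(axis=1))[: j - i]
            q, _ = np.linalg.qr(block[ref, :].T)
            block = block @ q
            out[:, i:j] = block
        i = j
    # sign convention: largest-magnitude component positive
    for k in range(n):
        idx = np.argmax(np.abs(out[:, k]))
        if out[idx, k] < 0:
            out[:, k] = -out[:, k]
    return out


def normal_modes(
    system: MolecularSystem,
    iso: Isotopologue,
    hessian: np.ndarray,
    gap_warn_invcm: float = _GAP_WARN_CM,
) -> NormalModeSet:
    """Diagonalize the mass-weighted Hessian and build the full mode set.

    Parameters
    ----------
    hessian : (3N, 3N) array
        Cartesian second derivatives of the potential, hartree/bohr^2.
        The Hessian is a property of the potential-energy surface and is
        shared by all isotopologues; only the masses differ.
    """
    n = system.n_atoms
    H = np.asarray(hessian, dtype=float)
    if H.shape != (3 * n, 3 * n):
        raise ValueError("hessian has wrong shape")
    asym = np.abs(H - H.T).max()
    if asym > 1e-8:
        raise ValueError(f"hessian asymmetry {asym:.2e} exceeds 1e-8")
    H = 0.5 * (H + H.T)

    m = np.repeat(iso.masses * AMU_TO_ME, 3)
    Hmw = H / np.sqrt(np.outer(m, m))

    # rigid space from analytic generators, in mass-weighted coordinates
    _, trans, rots = principal_axes(system, iso)
    rigid = np.concatenate([rots, trans])  # (n_rigid, N, 3)
    rigid_mw = rigid.reshape(len(rigid), -1) * np.sqrt(m)
    q_rigid, _ = np.linalg.qr(rigid_mw.T)  # orthonormal basis of the rigid space

    proj = np.eye(3 * n) - q_rigid @ q_rigid.T
    Hp = proj @ Hmw @ proj
    Hp = 0.5 * (Hp + Hp.T)
    evals, evecs = np.linalg.eigh(Hp)

    n_rigid = len(rigid)
    n_vib = 3 * n - n_rigid
    # by construction the projected Hessian has exactly n_rigid zero modes
    order = np.argsort(np.abs(evals))
    vib_idx = np.sort(order[n_rigid:])
    w2 = evals[vib_idx]
    if np.any(w2 <= 0):
        raise SaddlePointError(
            f"negative vibrational eigenvalue {w2.min():.3e} hartree/bohr^2/me "
            "- geometry is not a minimum"
        )
    zero_scale = np.abs(evals[order[:n_rigid]]).max()
    gap_cm = (np.sqrt(w2.min()) - np.sqrt(max(zero_scale, 0.0))) * HARTREE_TO_INVCM
    if gap_cm < gap_warn_invcm:
        warnings.warn(
            f"zero/vibration separation only {gap_cm:.2f} cm^-1", RuntimeWarning, stacklevel=2
        )
    if zero_scale > _ZERO_FRACTION * w2.max():
        warnings.warn(
            "projected rigid eigenvalues unexpectedly large", RuntimeWarning, stacklevel=2
        )

    e = _fix_degenerate_phases(w2, evecs[:, vib_idx])
    omega = np.sqrt(w2)
    l_vib = (e / np.sqrt(m)[:, None] / np.sqrt(omega)[None, :]).T.reshape(n_vib, n, 3)

    l_modes = np.concatenate([l_vib, rots, trans])
    kinds = np.array(["v"] * n_vib + ["r"] * len(rots) + ["t"] * len(trans))
    return NormalModeSet(omega=omega, l_modes=l_modes, kind_flags=kinds, masses_me=m[::3].copy())
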