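"""Numerical differentiation along mode vectors.

Builds the semi-diagonal cubic force field phi_(i,kk) = D^{1,2}V[l_i, l_k]
(one derivative along mode i, two along mode k, in dimensionless
coordinates) and the shielding value/gradient/curvature table, from
evaluator callables.  Displacements are applied in dimensionless mode
coordinates: geometry = R_e + h * l_k.

Two routes to the cubic constants are provided: central first differences
of mode-projected Hessians (the "Delta-k" scheme, 2 Hessian calls per
mode) and central second differences of mode-projected gradients (the
"Delta-2F" scheme, 2 gradient calls per mode plus the equilibrium
gradient); for a smooth surface they agree to stencil error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "CubicField",
    "PropertySurface",
    "cubic_semidiagonal",
    "cubic_semidiagonal_forces",
    "property_derivatives",
    "BasisMismatchError",
    "EvaluatorError",
]

DEFAULT_H_FF = 0.005
DEFAULT_H_NMR = 0.05


class BasisMismatchError(ValueError):
    """Derived fields refused to combine with a foreign mode basis."""


class EvaluatorError(RuntimeError):
    """Evaluator failure at a displaced geometry (geometry attached)."""

    def __init__(self, message: str, geometry: np.ndarray):
        super().__init__(message)
        self.geometry = geometry


def check_basis(a, b) -> None:
    if a.basis_id != b.basis_id:
        raise BasisMismatchError(
            f"basis mismatch: {a.basis_id[:8]} vs {b.basis_id[:8]}"
        )


@dataclass(frozen=True)
class CubicField:
    """Semi-diagonal cubic force constants in dimensionless coordinates.

    third_derivatives[i, k] = D^{1,2}V[l_i, l_k] = d^3 V / dq_i dq_k^2
    (hartree).  Index i runs over all modes of the basis, k over the modes
    that were displaced.
    """

    third_derivatives: np.ndarray
    basis_id: str
    displaced: np.ndarray = None  # indices of the displaced (k) modes

    def __post_init__(self):
        t = np.asarray(self.third_derivatives, dtype=float)
        if not np.all(np.isfinite(t)):
            raise ValueError("cubic constants must be finite")
        object.__setattr__(self, "third_derivatives", t)
        d = self.displaced
        d = np.arange(t.shape[1]) if d is None else np.asarray(d, dtype=int)
        object.__setattr__(self, "displaced", d)


@dataclass(frozen=True)
class PropertySurface:
    """Per-nucleus shielding value, gradient and curvature along modes (ppm).

    sigma_e[n]; grad[n, i] = D sigma_n [l_i]; curv[n, i] = D^2 sigma_n [l_i].
    """

    sigma_e: np.ndarray
    grad: np.ndarray
    curv: np.ndarray
    basis_id: str
    nuclei: np.ndarray = None  # reporting-nucleus atom indices

    def __post_init__(self):
        for name in ("sigma_e", "grad", "curv"):
            v = np.asarray(getattr(self, name), dtype=float)
            if not np.all(np.isfinite(v)):
                raise ValueError(f"{name} must be finite")
            object.__setattr__(self, name, v)
        n = self.nuclei
        n = np.arange(len(self.sigma_e)) if n is None else np.asarray(n, dtype=int)
        object.__setattr__(self, "nuclei", n)


def _displaced_geometry(geometry: np.ndarray, vec: np.ndarray, step: float) -> np.ndarray:
    return geometry + step * vec


def _call(evaluator, geometry: np.ndarray, what: str):
    try:
        out = evaluator(geometry)
    except Exception as exc:  # propagate with the offending geometry attached
        raise EvaluatorError(f"{what} evaluator failed: {exc}", geometry) from exc
    return np.asarray(out, dtype=float)


def _mode_matrix(modes, indices=None) -> tuple:
    l = modes.l_modes
    if indices is None:
        indices = np.arange(l.shape[0])
    return l[indices].reshape(len(indices), -1), np.asarray(indices, dtype=int)


def cubic_semidiagonal(
    pes_hessian_evaluator,
    modes,
    geometry: np.ndarray,
    h_ff: float = DEFAULT_H_FF,
    displace: np.ndarray = None,
) -> CubicField:
    """Delta-k scheme: phi_(i,kk) from central differences of Hessians.

    Parameters
    ----------
    pes_hessian_evaluator : callable geometry -> (3N, 3N) Hessian
    modes : NormalModeSet or DDBasis-like (has l_modes and basis_id)
    geometry : (N, 3) equilibrium geometry
    displace : optional index array
        Modes to displace along (the k index); defaults to all modes of the
        basis.  The i index always covers the full basis.
    """
    if h_ff <= 0:
        raise ValueError("step must be positive")
    L_all = modes.l_modes.reshape(modes.l_modes.shape[0], -1)
    Lk, kidx = _mode_matrix(modes, displace)
    cubic = np.empty((L_all.shape[0], len(kidx)))
    for col, (k, lk) in enumerate(zip(kidx, Lk)):
        vec = lk.reshape(geometry.shape)
        Hp = _call(pes_hessian_evaluator, _displaced_geometry(geometry, vec, h_ff), "hessian")
        Hm = _call(pes_hessian_evaluator, _displaced_geometry(geometry, vec, -h_ff), "hessian")
        dH = (Hp - Hm) / (2.0 * h_ff)
        # d/dq_k of (l_i^T H l_k) = d^3V/dq_i dq_k^2 for every i at once
        cubic[:, col] = L_all @ (dH @ lk)
    return CubicField(cubic, modes.basis_id, displaced=kidx)


def cubic_semidiagonal_forces(
    pes_gradient_evaluator,
    modes,
    geometry: np.ndarray,
    h_ff: float = DEFAULT_H_FF,
    displace: np.ndarray = None,
) -> CubicField:
    """Delta-2F scheme: phi_(i,kk) from second differences of gradients."""
    if h_ff <= 0:
        raise ValueError("step must be positive")
    L_all = modes.l_modes.reshape(modes.l_modes.shape[0], -1)
    Lk, kidx = _mode_matrix(modes, displace)
    g0 = _call(pes_gradient_evaluator, geometry, "gradient").ravel()
    cubic = np.empty((L_all.shape[0], len(kidx)))
    for col, lk in enumerate(Lk):
        vec = lk.reshape(geometry.shape)
        gp = _call(pes_gradient_evaluator, _displaced_geometry(geometry, vec, h_ff), "gradient")
        gm = _call(pes_gradient_evaluator, _displaced_geometry(geometry, vec, -h_ff), "gradient")
        d2g = (gp.ravel() - 2.0 * g0 + gm.ravel()) / h_ff**2
        cubic[:, col] = L_all @ d2g
    return CubicField(cubic, modes.basis_id, displaced=kidx)


def property_derivatives(
    sigma_evaluator,
    modes,
    geometry: np.ndarray,
    h_nmr: float = DEFAULT_H_NMR,
    displace: np.ndarray = None,
    nuclei: np.ndarray = None,
) -> PropertySurface:
    """Directional first and second shielding derivatives along each mode.

    sigma_evaluator maps a geometry to per-nucleus shieldings (ppm).  Uses
    2 calls per displaced mode plus one at the equilibrium geometry.
    """
    if h_nmr <= 0:
        raise ValueError("step must be positive")
    Lk, kidx = _mode_matrix(modes, displace)
    s0 = _call(sigma_evaluator, geometry, "shielding")
    if nuclei is not None:
        nuclei = np.asarray(nuclei, dtype=int)
    grad = np.empty((len(s0), len(kidx)))
    curv = np.empty((len(s0), len(kidx)))
    for col, lk in enumerate(Lk):
        vec = lk.reshape(geometry.shape)
        sp = _call(sigma_evaluator, _displaced_geometry(geometry, vec, h_nmr), "shielding")
        sm = _call(sigma_evaluator, _displaced_geometry(geometry, vec, -h_nmr), "shielding")
        grad[:, col] = (sp - sm) / (2.0 * h_nmr)
        curv[:, col] = (sp - 2.0 * s0 + sm) / h_nmr**2
    return PropertySurface(s0, grad, curv, modes.basis_id, nuclei=nuclei)
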