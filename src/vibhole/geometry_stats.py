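"""Vibration-hole descriptors for internal coordinates.

For each geometry parameter f the module provides

* f_e = f(R_e), f_z = f(R_e + DR) (the parameter at the vibrationally
  averaged Cartesian geometry), and
* f_g = f_z + (1/2) sum_i^v <q_i^2> l_i^T (grad^2 f) l_i  with <q_i^2> = 1/2,
  the individually averaged parameter to second order,
* the harmonic mean-square amplitude  <Df^2> = (1/2) sum_i^v (Df[l_i])^2
  about r_e, and the amplitude covariance
  <Df Dg> = (1/2) sum_i^v Df[l_i] Dg[l_i] against a reference parameter,

together with their isotope effects, either as explicit B - A differences
("full" channel) or as kappa-weighted sums over difference-dedicated
modes ("dd" channel).  The two channels agree exactly at cutoff 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .constants import BOHR_TO_ANGSTROM
from .ddvpt2 import DDBasis
from .harmonic import NormalModeSet
from .system import (
    InternalCoordinate,
    MolecularSystem,
    coordinate_derivatives,
    coordinate_gradient,
    evaluate_coordinate,
    topological_distances,
)

__all__ = [
    "GeometryStats",
    "rz_parameters",
    "rg_parameters",
    "amplitudes_and_covariances",
    "dd_amplitude_effects",
    "build_geometry_stats",
    "hole_profile",
]

RAD_TO_DEG = 180.0 / np.pi
BOHR_TO_MILLI_ANGSTROM = BOHR_TO_ANGSTROM * 1e3
BOHR_TO_MICRO_ANGSTROM = BOHR_TO_ANGSTROM * 1e6


@dataclass(frozen=True)
class GeometryStats:
    """Per-coordinate vibrational geometry descriptors (internal units:
    bohr / rad; squared amplitudes in bohr^2 / rad^2).

    Isotope-effect fields (d_*) may be None when only a single
    isotopologue was analyzed.
    """

    coords: tuple
    f_e: np.ndarray
    f_z: np.ndarray
    f_g: np.ndarray
    msa: np.ndarray
    cov: np.ndarray
    reference: InternalCoordinate = None
    d_fz: np.ndarray = None
    d_fg: np.ndarray = None
    d_msa: np.ndarray = None
    d_cov: np.ndarray = None

    def __post_init__(self):
        if np.any(self.msa < -1e-14):
            raise ValueError("mean-square amplitudes must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        """Tabular export; lengths in mA (mean-squares in mA^2), angles in
        degrees (deg^2)."""
        rows = []
        for i, c in enumerate(self.coords):
            if c.is_length:
                s, s2, unit = BOHR_TO_MILLI_ANGSTROM, BOHR_TO_MILLI_ANGSTROM**2, "mAA"
            else:
                s, s2, unit = RAD_TO_DEG, RAD_TO_DEG**2, "deg"
            row = {
                "coordinate": c.label,
                "kind": c.kind,
                "unit": unit,
                "f_e": self.f_e[i] * s,
                "f_z": self.f_z[i] * s,
                "f_g": self.f_g[i] * s,
                "msa": self.msa[i] * s2,
                "cov": self.cov[i] * s2 if self.reference is not None else np.nan,
            }
            for name in ("d_fz", "d_fg"):
                v = getattr(self, name)
                row[name] = v[i] * s if v is not None else np.nan
            for name in ("d_msa", "d_cov"):
                v = getattr(self, name)
                row[name] = v[i] * s2 if v is not None else np.nan
            rows.append(row)
        return pd.DataFrame(rows)


def rz_parameters(coords, R_e: np.ndarray, dR: np.ndarray) -> np.ndarray:
    """f_z = f(R_e + DR) for each coordinate."""
    Rz = R_e + dR
    return np.array([evaluate_coordinate(c, Rz) for c in coords])


def _curvature_term(coords, R_e: np.ndarray, l_vib: np.ndarray) -> np.ndarray:
    """(1/2) sum_i <q_i^2> l_i^T (grad^2 f) l_i with <q^2> = 1/2, per coord."""
    L = l_vib.reshape(l_vib.shape[0], -1)
    out = np.empty(len(coords))
    for j, c in enumerate(coords):
        _, hess = coordinate_derivatives(c, R_e)
        out[j] = 0.25 * np.einsum("ix,xy,iy->", L, hess, L)
    return out


def rg_parameters(coords, R_e: np.ndarray, dR: np.ndarray, modes: NormalModeSet) -> np.ndarray:
    """f_g: individual vibrational average of f to second order."""
    fz = rz_parameters(coords, R_e, dR)
    return fz + _curvature_term(coords, R_e, modes.vib_modes())


def _mode_gradients(coords, R_e: np.ndarray, l_modes: np.ndarray) -> np.ndarray:
    """Df[l_i] for every coordinate (rows) and mode (columns)."""
    L = l_modes.reshape(l_modes.shape[0], -1)
    g = np.array([coordinate_gradient(c, R_e).ravel() for c in coords])
    return g @ L.T


def amplitudes_and_covariances(
    coords,
    reference: InternalCoordinate,
    R_e: np.ndarray,
    modes: NormalModeSet,
):
    """Harmonic <Df^2> and <Df Dg> (g = reference) for one isotopologue."""
    df = _mode_gradients(coords, R_e, modes.vib_modes())
    dg = _mode_gradients([reference], R_e, modes.vib_modes())[0]
    msa = 0.5 * (df**2).sum(axis=1)
    cov = 0.5 * df @ dg
    return msa, cov


def dd_amplitude_effects(
    coords,
    reference: InternalCoordinate,
    R_e: np.ndarray,
    dd: DDBasis,
):
    """Isotope effects on <Df^2> and <Df Dg> via the kappa-weighted DD sums
    over the retained modes."""
    l_ret = dd.l_modes[dd.retained]
    kap = dd.kappa[dd.retained]
    df = _mode_gradients(coords, R_e, l_ret)
    dg = _mode_gradients([reference], R_e, l_ret)[0]
    d_msa = 0.5 * (df**2) @ kap
    d_cov = 0.5 * (df * dg[None, :]) @ kap
    return d_msa, d_cov


def build_geometry_stats(
    system: MolecularSystem,
    coords,
    reference: InternalCoordinate,
    modesA: NormalModeSet,
    dR_A: np.ndarray,
    modesB: NormalModeSet = None,
    dR_B: np.ndarray = None,
    dd: DDBasis = None,
    nDR: np.ndarray = None,
) -> GeometryStats:
    """Assemble the full descriptor table for isotopologue A, with isotope
    effects from either the explicit B - A channel (pass modesB/dR_B) or
    the DD channel (pass dd/nDR)."""
    coords = tuple(coords)
    R = system.coords_e
    f_e = np.array([evaluate_coordinate(c, R) for c in coords])
    f_z = rz_parameters(coords, R, dR_A)
    f_g = rg_parameters(coords, R, dR_A, modesA)
    msa, cov = amplitudes_and_covariances(coords, reference, R, modesA)

    d_fz = d_fg = d_msa = d_cov = None
    if modesB is not None and dR_B is not None:
        fzB = rz_parameters(coords, R, dR_B)
        fgB = rg_parameters(coords, R, dR_B, modesB)
        msaB, covB = amplitudes_and_covariances(coords, reference, R, modesB)
        d_fz, d_fg = fzB - f_z, fgB - f_g
        d_msa, d_cov = msaB - msa, covB - cov
    elif dd is not None:
        d_msa, d_cov = dd_amplitude_effects(coords, reference, R, dd)
        if nDR is not None:
            d_fz = rz_parameters(coords, R, nDR) - f_e
            # curvature part of d_fg as the kappa-weighted DD sum
            l_ret = dd.l_modes[dd.retained]
            kap = dd.kappa[dd.retained]
            L = l_ret.reshape(len(l_ret), -1)
            d_curv = np.empty(len(coords))
            for j, c in enumerate(coords):
                _, hess = coordinate_derivatives(c, R)
                d_curv[j] = 0.25 * np.einsum("ix,xy,iy,i->", L, hess, L, kap)
            d_fg = d_fz + d_curv

    return GeometryStats(
        coords=coords,
        f_e=f_e,
        f_z=f_z,
        f_g=f_g,
        msa=msa,
        cov=cov,
        reference=reference,
        d_fz=d_fz,
        d_fg=d_fg,
        d_msa=d_msa,
        d_cov=d_cov,
    )


def hole_profile(
    stats: GeometryStats,
    system: MolecularSystem,
    substitution_atoms,
    column: str = "d_msa",
) -> pd.DataFrame:
    """Group |isotope effect| of bond coordinates by topological distance.

    The distance of a bond is the number of bonds between it and the
    substitution site: 0 for the substituted bond itself, 1 for geminal
    bonds, and so on.  The sign is retained as a flag.
    """
    values = getattr(stats, column)
    if values is None:
        raise ValueError(f"stats has no isotope-effect column {column!r}")
    dist = topological_distances(system, substitution_atoms)
    if any(not np.isfinite(d) for d in dist.values()):
        import warnings

        warnings.warn("topology is disconnected; distances per component", RuntimeWarning)
    rows = []
    for i, c in enumerate(stats.coords):
        if not c.is_length:
            continue
        a, b = c.atom_indices
        d = min(dist[a], dist[b])
        rows.append(
            {
                "coordinate": c.label,
                "distance": int(d) if np.isfinite(d) else -1,
                "magnitude": abs(values[i]),
                "positive": bool(values[i] > 0),
            }
        )
    return pd.DataFrame(rows).sort_values(["distance", "coordinate"]).reset_index(drop=True)
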