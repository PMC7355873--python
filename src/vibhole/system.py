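"""Molecular systems, isotopologues and internal coordinates.

Internal coordinates (bond lengths, bond angles, and the azimuth/altitude
bending angles of a bond about its apex atom) are implemented as pure
functions of the Cartesian geometry together with their first and second
Cartesian derivatives, which the vibrational-averaging formulas contract
with normal-mode vectors.

All geometries are in bohr; angle coordinates in radians.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MolecularSystem",
    "Isotopologue",
    "InternalCoordinate",
    "DegenerateCoordinateError",
    "evaluate_coordinate",
    "coordinate_derivatives",
    "coordinate_gradient",
    "topological_distances",
]

_COORD_KINDS = ("bond", "interatomic_distance", "angle", "azimuth", "altitude")

#: geometry is considered degenerate below this length (bohr)
_DEGEN_LENGTH = 1e-8
#: |sin| of the frame angle below which an angular frame is collinear
_DEGEN_SIN = 1e-7


class DegenerateCoordinateError(ValueError):
    """Raised when an internal coordinate is evaluated at a degenerate geometry
    (zero-length bond or collinear angular reference frame)."""


@dataclass(frozen=True)
class MolecularSystem:
    """Atoms plus the equilibrium Cartesian geometry shared by all isotopologues.

    Parameters
    ----------
    atom_symbols : sequence of str
        Element labels, length N.
    coords_e : (N, 3) array
        Equilibrium positions in bohr.
    bonds : sequence of (int, int), optional
        Connectivity used for topological-distance reporting.  Supplied by
        the user; no bond perception is attempted.
    """

    atom_symbols: tuple
    coords_e: np.ndarray
    bonds: tuple = field(default_factory=tuple)

    def __post_init__(self):
        symbols = tuple(self.atom_symbols)
        coords = np.asarray(self.coords_e, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ValueError("coords_e must have shape (N, 3)")
        n = coords.shape[0]
        if len(symbols) != n:
            raise ValueError("atom_symbols and coords_e disagree on N")
        if n < 2:
            raise ValueError("need at least two atoms")
        if not np.all(np.isfinite(coords)):
            raise ValueError("coordinates must be finite")
        d = coords[:, None, :] - coords[None, :, :]
        dist = np.sqrt((d**2).sum(-1))
        if np.any(dist[~np.eye(n, dtype=bool)] < _DEGEN_LENGTH):
            raise ValueError("two atoms coincide")
        bonds = tuple((int(a), int(b)) for a, b in self.bonds)
        for a, b in bonds:
            if not (0 <= a < n and 0 <= b < n) or a == b:
                raise ValueError(f"bond index out of range: {(a, b)}")
        object.__setattr__(self, "atom_symbols", symbols)
        object.__setattr__(self, "coords_e", coords)
        object.__setattr__(self, "bonds", bonds)

    @property
    def n_atoms(self) -> int:
        return self.coords_e.shape[0]


@dataclass(frozen=True)
class Isotopologue:
    """Per-atom masses (amu) defining one isotopologue of a system."""

    masses: np.ndarray
    label: str = ""
    substitutions: tuple = field(default_factory=tuple)

    def __post_init__(self):
        m = np.asarray(self.masses, dtype=float)
        if m.ndim != 1:
            raise ValueError("masses must be one-dimensional")
        if np.any(m <= 0) or not np.all(np.isfinite(m)):
            raise ValueError("all masses must be positive and finite")
        object.__setattr__(self, "masses", m)
        object.__setattr__(self, "substitutions", tuple(self.substitutions))

    def substitute(self, atom_index: int, new_mass: float, label: str = "") -> "Isotopologue":
        """Return a copy with one atom's mass replaced."""
        m = self.masses.copy()
        old = m[atom_index]
        m[atom_index] = new_mass
        return Isotopologue(
            m,
            label=label or f"{self.label}[{atom_index}:{new_mass:g}]",
            substitutions=self.substitutions + ((int(atom_index), float(old), float(new_mass)),),
        )


@dataclass(frozen=True)
class InternalCoordinate:
    """A scalar geometry function f(R).

    kind
        ``bond`` / ``interatomic_distance``: Euclidean distance between two
        atoms.  ``angle``: interior angle, apex is the middle index.
        ``azimuth`` / ``altitude``: signed bending angles of the
        apex->mobile direction relative to the frame built from two
        partner atoms adjacent to the apex (azimuth: angle to the bisecting
        plane of the two adjacent bonds; altitude: angle to the plane
        spanned by them).
    atom_indices
        ``bond``: (a, b).  ``angle``: (a, apex, b).
        ``azimuth``/``altitude``: (apex, mobile).
    reference_frame
        For azimuth/altitude: the two partner atoms (p1, p2) bonded to the
        apex.  Order fixes the sign convention.
    """

    kind: str
    atom_indices: tuple
    reference_frame: tuple = ()
    label: str = ""

    def __post_init__(self):
        if self.kind not in _COORD_KINDS:
            raise ValueError(f"unknown coordinate kind {self.kind!r}")
        idx = tuple(int(i) for i in self.atom_indices)
        frame = tuple(int(i) for i in self.reference_frame)
        need = {"bond": 2, "interatomic_distance": 2, "angle": 3, "azimuth": 2, "altitude": 2}
        if len(idx) != need[self.kind]:
            raise ValueError(f"{self.kind} needs {need[self.kind]} atom indices")
        if self.kind in ("azimuth", "altitude"):
            if len(frame) != 2:
                raise ValueError("azimuth/altitude need a 2-atom reference frame")
        elif frame:
            raise ValueError("reference_frame only applies to azimuth/altitude")
        allidx = idx + frame
        if len(set(allidx)) != len(allidx):
            raise ValueError("coordinate atom indices must be distinct")
        object.__setattr__(self, "atom_indices", idx)
        object.__setattr__(self, "reference_frame", frame)
        if not self.label:
            object.__setattr__(self, "label", f"{self.kind}{idx}")

    @property
    def atoms(self) -> tuple:
        return self.atom_indices + self.reference_frame

    @property
    def is_length(self) -> bool:
        return self.kind in ("bond", "interatomic_distance")


# ----------------------------------------------------------------------
# coordinate values


def _check_geometry(geometry: np.ndarray) -> np.ndarray:
    geo = np.asarray(geometry, dtype=float)
    if geo.ndim != 2 or geo.shape[1] != 3:
        raise ValueError("geometry must have shape (N, 3)")
    if not np.all(np.isfinite(geo)):
        raise ValueError("geometry must be finite")
    return geo


def _unit(v: np.ndarray, what: str) -> tuple:
    n = np.linalg.norm(v)
    if n < _DEGEN_LENGTH:
        raise DegenerateCoordinateError(f"zero-length {what}")
    return v / n, n


def _frame_vectors(coord: InternalCoordinate, geo: np.ndarray):
    """Unit vectors (u, b1, b2) for an azimuth/altitude coordinate."""
    apex, mob = coord.atom_indices
    p1, p2 = coord.reference_frame
    u, _ = _unit(geo[mob] - geo[apex], "apex-mobile bond")
    b1, _ = _unit(geo[p1] - geo[apex], "frame bond 1")
    b2, _ = _unit(geo[p2] - geo[apex], "frame bond 2")
    cross = np.cross(b1, b2)
    if np.linalg.norm(cross) < _DEGEN_SIN:
        raise DegenerateCoordinateError("collinear reference frame")
    return u, b1, b2


def evaluate_coordinate(coord: InternalCoordinate, geometry: np.ndarray) -> float:
    """Value of an internal coordinate at a Cartesian geometry (bohr / rad)."""
    geo = _check_geometry(geometry)
    if coord.is_length:
        a, b = coord.atom_indices
        _, r = _unit(geo[a] - geo[b], "bond")
        return float(r)
    if coord.kind == "angle":
        a, apex, b = coord.atom_indices
        u, _ = _unit(geo[a] - geo[apex], "angle arm 1")
        v, _ = _unit(geo[b] - geo[apex], "angle arm 2")
        # numerically stable interior angle
        return float(np.arctan2(np.linalg.norm(np.cross(u, v)), np.dot(u, v)))
    u, b1, b2 = _frame_vectors(coord, geo)
    if coord.kind == "altitude":
        # angle to the plane spanned by the two adjacent bonds
        n, _ = _unit(np.cross(b1, b2), "frame normal")
        return float(np.arcsin(np.clip(np.dot(u, n), -1.0, 1.0)))
    # azimuth: angle to the bisecting plane, whose normal is b1 - b2
    m, _ = _unit(b1 - b2, "bisecting-plane normal")
    return float(np.arcsin(np.clip(np.dot(u, m), -1.0, 1.0)))


# ----------------------------------------------------------------------
# derivatives


def coordinate_gradient(coord: InternalCoordinate, geometry: np.ndarray) -> np.ndarray:
    """Analytic gradient of the coordinate, shape (N, 3)."""
    geo = _check_geometry(geometry)
    grad = np.zeros_like(geo)
    if coord.is_length:
        a, b = coord.atom_indices
        u, _ = _unit(geo[a] - geo[b], "bond")
        grad[a] = u
        grad[b] = -u
        return grad
    if coord.kind == "angle":
        a, apex, b = coord.atom_indices
        u, ra = _unit(geo[a] - geo[apex], "angle arm 1")
        v, rb = _unit(geo[b] - geo[apex], "angle arm 2")
        w = np.cross(u, v)
        sw = np.linalg.norm(w)
        if sw < _DEGEN_SIN:
            raise DegenerateCoordinateError("collinear angle")
        wn = w / sw
        ga = np.cross(u, wn) / ra
        gb = np.cross(wn, v) / rb
        grad[a] = ga
        grad[b] = gb
        grad[apex] = -ga - gb
        return grad
    # azimuth / altitude: differentiate arcsin(u . n) by the chain rule
    return _bend_gradient(coord, geo)


def _bend_gradient(coord: InternalCoordinate, geo: np.ndarray) -> np.ndarray:
    apex, mob = coord.atom_indices
    p1, p2 = coord.reference_frame
    u, ru = _unit(geo[mob] - geo[apex], "apex-mobile bond")
    b1, r1 = _unit(geo[p1] - geo[apex], "frame bond 1")
    b2, r2 = _unit(geo[p2] - geo[apex], "frame bond 2")
    if coord.kind == "altitude":
        w = np.cross(b1, b2)
    else:
        w = b1 - b2
    nw = np.linalg.norm(w)
    if nw < _DEGEN_SIN:
        raise DegenerateCoordinateError("collinear reference frame")
    n = w / nw
    s = float(np.dot(u, n))
    c = np.sqrt(max(1.0 - s * s, 0.0))
    if c < _DEGEN_SIN:
        raise DegenerateCoordinateError("bond perpendicular to frame plane")
    pref = 1.0 / c

    grad = np.zeros_like(geo)

    # d/dx of u (mobile and apex move u)
    du = (np.eye(3) - np.outer(u, u)) / ru  # d u / d r_mob
    g_u = du @ n * pref
    grad[mob] += g_u
    grad[apex] -= g_u

    # d/dx of n through b1 and b2; n = w/|w| so dn = (1 - nn^T) dw / |w|
    P = np.eye(3) - np.outer(n, n)
    db1 = (np.eye(3) - np.outer(b1, b1)) / r1  # d b1 / d r_p1
    db2 = (np.eye(3) - np.outer(b2, b2)) / r2
    if coord.kind == "altitude":
        # w = b1 x b2;  dw = db1 x b2 + b1 x db2
        # (u . dn) = u^T P (dw)/|w|
        uP = (P @ u) / nw
        # derivative wrt p1: dw/dr_p1[j] = (db1[:,j]) x b2  -> u.P dw = uP . (db1_col x b2)
        g1 = np.array([np.dot(uP, np.cross(db1[:, j], b2)) for j in range(3)]) * pref
        g2 = np.array([np.dot(uP, np.cross(b1, db2[:, j])) for j in range(3)]) * pref
    else:
        uP = (P @ u) / nw
        g1 = (db1 @ uP) * pref
        g2 = -(db2 @ uP) * pref
    grad[p1] += g1
    grad[p2] += g2
    grad[apex] -= g1 + g2
    return grad


def _gradient_fd_hessian(coord: InternalCoordinate, geo: np.ndarray, h: float = 1e-4) -> np.ndarray:
    """Hessian by Richardson-extrapolated central differences of the analytic
    gradient; only the atoms entering the coordinate are displaced."""
    n = geo.shape[0]
    hess = np.zeros((3 * n, 3 * n))
    atoms = coord.atoms

    def col(a: int, x: int, step: float) -> np.ndarray:
        gp = geo.copy()
        gp[a, x] += step
        gm = geo.copy()
        gm[a, x] -= step
        return (coordinate_gradient(coord, gp) - coordinate_gradient(coord, gm)).ravel() / (2 * step)

    for a in atoms:
        for x in range(3):
            c_h = col(a, x, h)
            c_h2 = col(a, x, h / 2)
            hess[3 * a + x] = (4.0 * c_h2 - c_h) / 3.0
    return 0.5 * (hess + hess.T)


def coordinate_derivatives(coord: InternalCoordinate, geometry: np.ndarray):
    """Gradient and Hessian of the coordinate w.r.t. Cartesian positions.

    Returns
    -------
    grad : (N, 3) array
    hess : (3N, 3N) symmetric array
        Analytic for bond lengths; for angular coordinates obtained by
        Richardson-extrapolated central differences of the analytic
        gradient (accurate to ~1e-11).
    """
    geo = _check_geometry(geometry)
    grad = coordinate_gradient(coord, geo)
    n = geo.shape[0]
    if coord.is_length:
        a, b = coord.atom_indices
        u, r = _unit(geo[a] - geo[b], "bond")
        blk = (np.eye(3) - np.outer(u, u)) / r
        hess = np.zeros((3 * n, 3 * n))
        sa, sb = slice(3 * a, 3 * a + 3), slice(3 * b, 3 * b + 3)
        hess[sa, sa] = blk
        hess[sb, sb] = blk
        hess[sa, sb] = -blk
        hess[sb, sa] = -blk
        return grad, hess
    return grad, _gradient_fd_hessian(coord, geo)


# ----------------------------------------------------------------------
# topology


def topological_distances(system: MolecularSystem, source_atoms) -> dict:
    """Breadth-first bond-path distance of every atom from a set of atoms.

    Atoms in disconnected components get distance ``inf``.
    """
    adj: dict = {i: [] for i in range(system.n_atoms)}
    for a, b in system.bonds:
        adj[a].append(b)
        adj[b].append(a)
    dist = {i: np.inf for i in range(system.n_atoms)}
    frontier = list(source_atoms)
    for s in frontier:
        dist[s] = 0
    d = 0
    while frontier:
        d += 1
        nxt = []
        for a in frontier:
            for b in adj[a]:
                if dist[b] > d:
                    dist[b] = d
                    nxt.append(b)
        frontier = nxt
    return dist
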