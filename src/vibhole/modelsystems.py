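"""Synthetic model systems with analytic potential and shielding surfaces.

The fixtures stand in for ab initio surfaces: potentials are sums of
Morse/polynomial terms in internal coordinates (bond lengths, angles) with
optional bilinear and cubic couplings, and shielding surfaces are
low-order polynomials in the same coordinates, so every directional
derivative the averaging formulas need is exactly checkable.  Evaluators
are deterministic pure functions of the geometry.

A discrete-variable-representation (DVR) eigensolver provides exact
ground-state expectation values for 1D and 2D cuts, used as the oracle for
the perturbative results.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .constants import AMU_TO_ME, MASS_C12, MASS_H1, MASS_H2, MASS_O16
from .system import (
    InternalCoordinate,
    Isotopologue,
    MolecularSystem,
    coordinate_derivatives,
    coordinate_gradient,
    evaluate_coordinate,
)

__all__ = ["ModelSpec", "Fixture", "make_fixture", "FIXTURE_NAMES", "dvr_average", "dvr_average_2d"]

FIXTURE_NAMES = (
    "diatomic_morse",
    "xh_heavy",
    "water_like",
    "methane_like",
    "chain_n",
    "hbond_toy",
)


# ----------------------------------------------------------------------
# potential terms


class _Term:
    coords: tuple

    def value_and_derivs(self, c: np.ndarray):
        """Return (V, dV/dc, d2V/dc dc') at internal-coordinate values c."""
        raise NotImplementedError


class MorseTerm(_Term):
    """Morse bond parameterized by harmonic constant k and range a.

    V = D (1 - exp(-a dr))^2 with D = k/(2 a^2); a = 0 degenerates to the
    pure harmonic (1/2) k dr^2 with vanishing cubic constants.
    """

    def __init__(self, coord: InternalCoordinate, k: float, a: float, r0: float):
        self.coords = (coord,)
        self.k, self.a, self.r0 = float(k), float(a), float(r0)

    def value_and_derivs(self, c):
        d = c[0] - self.r0
        if self.a == 0.0:
            return 0.5 * self.k * d * d, np.array([self.k * d]), np.array([[self.k]])
        a, D = self.a, self.k / (2.0 * self.a**2)
        e = np.exp(-a * d)
        v = D * (1.0 - e) ** 2
        g = 2.0 * D * a * e * (1.0 - e)
        h = 2.0 * D * a * a * (2.0 * e * e - e)
        return v, np.array([g]), np.array([[h]])


class PolyTerm(_Term):
    """(1/2) k2 d^2 + (1/6) c3 d^3 + (1/24) c4 d^4 in one coordinate."""

    def __init__(self, coord: InternalCoordinate, k2: float, f0: float, c3: float = 0.0, c4: float = 0.0):
        self.coords = (coord,)
        self.k2, self.f0, self.c3, self.c4 = map(float, (k2, f0, c3, c4))

    def value_and_derivs(self, c):
        d = c[0] - self.f0
        v = 0.5 * self.k2 * d**2 + self.c3 * d**3 / 6.0 + self.c4 * d**4 / 24.0
        g = self.k2 * d + 0.5 * self.c3 * d**2 + self.c4 * d**3 / 6.0
        h = self.k2 + self.c3 * d + 0.5 * self.c4 * d**2
        return v, np.array([g]), np.array([[h]])


class CouplingTerm(_Term):
    """k11 da db + (1/2) c21 da^2 db + (1/2) c12 da db^2 between two coordinates."""

    def __init__(
        self,
        coord_a: InternalCoordinate,
        coord_b: InternalCoordinate,
        f0_a: float,
        f0_b: float,
        k11: float = 0.0,
        c21: float = 0.0,
        c12: float = 0.0,
    ):
        self.coords = (coord_a, coord_b)
        self.f0_a, self.f0_b = float(f0_a), float(f0_b)
        self.k11, self.c21, self.c12 = float(k11), float(c21), float(c12)

    def value_and_derivs(self, c):
        da, db = c[0] - self.f0_a, c[1] - self.f0_b
        v = self.k11 * da * db + 0.5 * self.c21 * da * da * db + 0.5 * self.c12 * da * db * db
        ga = self.k11 * db + self.c21 * da * db + 0.5 * self.c12 * db * db
        gb = self.k11 * da + 0.5 * self.c21 * da * da + self.c12 * da * db
        haa = self.c21 * db
        hbb = self.c12 * da
        hab = self.k11 + self.c21 * da + self.c12 * db
        return v, np.array([ga, gb]), np.array([[haa, hab], [hab, hbb]])


class InternalPES:
    """Potential-energy surface as a sum of internal-coordinate terms.

    Provides ``energy``, ``gradient`` and ``hessian`` evaluator callables
    satisfying the numerical-differentiation contract.  An optional
    Cartesian quadratic form can replace the internal terms entirely
    (useful for exactly harmonic-in-Cartesian tests).
    """

    def __init__(self, terms, n_atoms: int, cartesian_quadratic=None, R_ref=None):
        self.terms = list(terms)
        self.n_atoms = int(n_atoms)
        self.cartesian_quadratic = cartesian_quadratic
        self.R_ref = None if R_ref is None else np.asarray(R_ref, dtype=float)

    def energy(self, geo: np.ndarray) -> float:
        geo = np.asarray(geo, dtype=float)
        v = 0.0
        if self.cartesian_quadratic is not None:
            dx = (geo - self.R_ref).ravel()
            v += 0.5 * dx @ self.cartesian_quadratic @ dx
        for t in self.terms:
            c = np.array([evaluate_coordinate(ci, geo) for ci in t.coords])
            v += t.value_and_derivs(c)[0]
        return float(v)

    def gradient(self, geo: np.ndarray) -> np.ndarray:
        geo = np.asarray(geo, dtype=float)
        g = np.zeros(3 * self.n_atoms)
        if self.cartesian_quadratic is not None:
            g += self.cartesian_quadratic @ (geo - self.R_ref).ravel()
        for t in self.terms:
            c = np.array([evaluate_coordinate(ci, geo) for ci in t.coords])
            _, dv, _ = t.value_and_derivs(c)
            for w, ci in zip(dv, t.coords):
                g += w * coordinate_gradient(ci, geo).ravel()
        return g.reshape(-1, 3)

    def hessian(self, geo: np.ndarray) -> np.ndarray:
        geo = np.asarray(geo, dtype=float)
        n3 = 3 * self.n_atoms
        H = np.zeros((n3, n3))
        if self.cartesian_quadratic is not None:
            H += self.cartesian_quadratic
        for t in self.terms:
            c = np.array([evaluate_coordinate(ci, geo) for ci in t.coords])
            _, dv, d2v = t.value_and_derivs(c)
            grads = []
            for w, ci in zip(dv, t.coords):
                gci, hci = coordinate_derivatives(ci, geo)
                grads.append(gci.ravel())
                H += w * hci
            for p in range(len(t.coords)):
                for q in range(len(t.coords)):
                    if d2v[p, q] != 0.0:
                        H += d2v[p, q] * np.outer(grads[p], grads[q])
        return 0.5 * (H + H.T)


class ShieldingModel:
    """Per-nucleus shielding surface: sigma_n = sigma0 + sum (a1 dc + a2 dc^2).

    Coefficients in ppm per bohr / bohr^2 (or per rad for angles).
    """

    def __init__(self, sigma0: np.ndarray, contributions):
        # contributions: list over nuclei of [(coord, f0, a1, a2), ...]
        self.sigma0 = np.asarray(sigma0, dtype=float)
        self.contributions = contributions

    def __call__(self, geo: np.ndarray) -> np.ndarray:
        out = self.sigma0.copy()
        for n, terms in enumerate(self.contributions):
            for coord, f0, a1, a2 in terms:
                d = evaluate_coordinate(coord, geo) - f0
                out[n] += a1 * d + a2 * d * d
        return out


# ----------------------------------------------------------------------
# fixtures


@dataclass(frozen=True)
class ModelSpec:
    """Declarative record of a synthetic model system."""

    name: str
    params: dict
    seed: int


@dataclass
class Fixture:
    """A model system bundled with its evaluators and bookkeeping.

    ``substitution`` is (atom_index, heavy_mass_amu) of the default
    isotopic substitution; ``coords`` are the reporting internal
    coordinates (the substituted bond first).
    """

    spec: ModelSpec
    system: MolecularSystem
    iso_light: Isotopologue
    substitution: tuple
    pes: InternalPES
    sigma: ShieldingModel
    coords: tuple = ()
    reference_coord: InternalCoordinate = None
    nuclei: tuple = ()

    @property
    def iso_heavy(self) -> Isotopologue:
        idx, mass = self.substitution
        return self.iso_light.substitute(idx, mass, label=self.iso_light.label + "*")


def _bond(i, j, label=""):
    return InternalCoordinate("bond", (i, j), label=label or f"r({i},{j})")


def _angle(i, apex, j, label=""):
    return InternalCoordinate("angle", (i, apex, j), label=label or f"a({i},{apex},{j})")


def _validate_minimum(fix: Fixture) -> None:
    from .harmonic import normal_modes  # deferred: avoids import cycle at module load

    g = fix.pes.gradient(fix.system.coords_e)
    if np.abs(g).max() > 1e-8:
        raise ValueError("fixture geometry is not stationary")
    normal_modes(fix.system, fix.iso_light, fix.pes.hessian(fix.system.coords_e))


def _jitter(rng: np.random.Generator, scale: float = 0.1) -> float:
    return 1.0 + scale * (2.0 * rng.random() - 1.0)


def make_fixture(name: str, params: dict = None, seed: int = 0) -> Fixture:
    """Build one of the named synthetic fixtures.

    Force constants are in hartree/bohr^2 (stretches) or hartree/rad^2
    (bends); the defaults give stretch fundamentals around 3000 cm^-1 and
    bends around 1300-1600 cm^-1, the regime of the C-H/O-H substitutions
    the method targets.  ``seed`` jitters the force field within +-10% for
    randomized variants (seed 0 keeps the defaults).
    """
    if name not in FIXTURE_NAMES:
        raise ValueError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")
    params = dict(params or {})
    rng = np.random.default_rng(seed)
    jit = (lambda: _jitter(rng)) if seed != 0 else (lambda: 1.0)
    builder = globals()[f"_make_{name}"]
    fix = builder(params, jit)
    fix.spec = ModelSpec(name=name, params=params, seed=seed)
    _validate_minimum(fix)
    return fix


def _make_diatomic_morse(params, jit):
    r0 = params.get("r0", 2.05)
    k = params.get("k", 0.31) * jit()
    a = params.get("a", 1.0)
    m_x = params.get("m_x", MASS_C12)
    system = MolecularSystem(("X", "H"), [[0.0, 0.0, 0.0], [0.0, 0.0, r0]], bonds=((0, 1),))
    bond = _bond(0, 1, "r(XH)")
    pes = InternalPES([MorseTerm(bond, k, a, r0)], 2)
    sigma = ShieldingModel(
        [180.0, 30.0],
        [[(bond, r0, -21.0, 5.0)], [(bond, r0, -10.6, 1.4)]],
    )
    return Fixture(
        spec=None,
        system=system,
        iso_light=Isotopologue([m_x, MASS_H1], label="XH"),
        substitution=(1, MASS_H2),
        pes=pes,
        sigma=sigma,
        coords=(bond,),
        reference_coord=bond,
        nuclei=(0, 1),
    )


def _make_xh_heavy(params, jit):
    params = {"m_x": params.get("m_x", 1e6), **params}
    fix = _make_diatomic_morse(params, jit)
    return fix


def _make_water_like(params, jit):
    r0 = params.get("r0", 1.81)
    theta0 = params.get("theta0", np.deg2rad(104.5))
    k_r = params.get("k_r", 0.49) * jit()
    a = params.get("a", 1.1)
    k_th = params.get("k_theta", 0.16) * jit()
    c3_th = params.get("c3_theta", -0.10)
    k_rr = params.get("k_rr", -0.01) * jit()
    c_rth = params.get("c_r_theta", 0.02)

    s, c = np.sin(theta0 / 2), np.cos(theta0 / 2)
    coords_e = [[0.0, 0.0, 0.0], [r0 * s, 0.0, r0 * c], [-r0 * s, 0.0, r0 * c]]
    system = MolecularSystem(("O", "H", "H"), coords_e, bonds=((0, 1), (0, 2)))
    b1, b2 = _bond(0, 1, "r(OH1)"), _bond(0, 2, "r(OH2)")
    ang = _angle(1, 0, 2, "a(HOH)")
    terms = [
        MorseTerm(b1, k_r, a, r0),
        MorseTerm(b2, k_r, a, r0),
        PolyTerm(ang, k_th, theta0, c3=c3_th),
        CouplingTerm(b1, b2, r0, r0, k11=k_rr),
        CouplingTerm(b1, ang, r0, theta0, c21=c_rth),
        CouplingTerm(b2, ang, r0, theta0, c21=c_rth),
    ]
    pes = InternalPES(terms, 3)
    sigma = ShieldingModel(
        [320.0, 30.0, 30.0],
        [
            [(b1, r0, -25.0, 6.0), (b2, r0, -25.0, 6.0), (ang, theta0, 2.0, 1.0)],
            [(b1, r0, -11.0, 1.5), (b2, r0, -1.2, 0.2), (ang, theta0, 0.8, 0.3)],
            [(b2, r0, -11.0, 1.5), (b1, r0, -1.2, 0.2), (ang, theta0, 0.8, 0.3)],
        ],
    )
    return Fixture(
        spec=None,
        system=system,
        iso_light=Isotopologue([MASS_O16, MASS_H1, MASS_H1], label="H2O"),
        substitution=(1, MASS_H2),
        pes=pes,
        sigma=sigma,
        coords=(b1, b2, ang),
        reference_coord=b1,
        nuclei=(0, 1, 2),
    )


def _make_methane_like(params, jit):
    r0 = params.get("r0", 2.05)
    k_r = params.get("k_r", 0.30) * jit()
    a = params.get("a", 1.0)
    k_th = params.get("k_theta", 0.05) * jit()
    c3_th = params.get("c3_theta", -0.03)
    k_rr = params.get("k_rr", 0.005)
    c_rth = params.get("c_r_theta", 0.015)
    m_c = params.get("m_c", MASS_C12)

    t = 1.0 / np.sqrt(3.0)
    dirs = np.array([[t, t, t], [t, -t, -t], [-t, t, -t], [-t, -t, t]])
    coords_e = np.vstack([[0.0, 0.0, 0.0], r0 * dirs])
    bonds = tuple((0, i) for i in range(1, 5))
    system = MolecularSystem(("C", "H", "H", "H", "H"), coords_e, bonds=bonds)
    bvec = [_bond(0, i, f"r(CH{i})") for i in range(1, 5)]
    theta0 = np.arccos(-1.0 / 3.0)
    angs = [
        _angle(i, 0, j, f"a(H{i}CH{j})") for i in range(1, 5) for j in range(i + 1, 5)
    ]
    terms = [MorseTerm(b, k_r, a, r0) for b in bvec]
    terms += [PolyTerm(ag, k_th, theta0, c3=c3_th) for ag in angs]
    terms += [
        CouplingTerm(bvec[i], bvec[j], r0, r0, k11=k_rr)
        for i in range(4)
        for j in range(i + 1, 4)
    ]
    for ag in angs:
        i, _, j = ag.atom_indices
        terms.append(CouplingTerm(bvec[i - 1], ag, r0, theta0, c21=c_rth))
        terms.append(CouplingTerm(bvec[j - 1], ag, r0, theta0, c21=c_rth))
    pes = InternalPES(terms, 5)

    contrib_c = [(b, r0, -13.0, 2.2) for b in bvec]
    contribs = [contrib_c]
    for i in range(1, 5):
        own = [(bvec[i - 1], r0, -12.0, 2.0)]
        other = [(bvec[j - 1], r0, -1.0, 0.15) for j in range(1, 5) if j != i]
        contribs.append(own + other)
    sigma = ShieldingModel([195.0, 31.0, 31.0, 31.0, 31.0], contribs)

    # azimuth/altitude of the substituted C-H1 bond about C, frame = H2, H3
    az = InternalCoordinate("azimuth", (0, 1), reference_frame=(2, 3), label="phi_az(H1)")
    alt = InternalCoordinate("altitude", (0, 1), reference_frame=(2, 3), label="phi_alt(H1)")
    return Fixture(
        spec=None,
        system=system,
        iso_light=Isotopologue([m_c] + [MASS_H1] * 4, label="CH4"),
        substitution=(1, MASS_H2),
        pes=pes,
        sigma=sigma,
        coords=tuple(bvec) + (az, alt),
        reference_coord=bvec[0],
        nuclei=(0, 1, 2, 3, 4),
    )


def _make_chain_n(params, jit):
    n = int(params.get("n", 6))
    if n < 3:
        raise ValueError("chain_n needs n >= 3 heavy atoms")
    r_cc = params.get("r_cc", 2.9)
    r_ch = params.get("r_ch", 2.06)
    theta0 = params.get("theta0", np.deg2rad(113.0))
    k_cc = params.get("k_cc", 0.28) * jit()
    k_ch = params.get("k_ch", 0.30) * jit()
    a_cc, a_ch = params.get("a_cc", 0.8), params.get("a_ch", 1.0)
    k_th = params.get("k_theta", 0.08) * jit()
    c3_th = params.get("c3_theta", -0.02)

    # zigzag carbon backbone in the xz plane, H on atom index n (bonded to C_0)
    pos = [np.zeros(3)]
    direction = 1.0
    half = (np.pi - theta0) / 2.0
    for _ in range(1, n):
        pos.append(pos[-1] + r_cc * np.array([np.cos(half), 0.0, np.sin(half) * direction]))
        direction *= -1.0
    pos = np.array(pos)
    # hydrogen on C_0, continuing the zigzag backwards
    h_dir = np.array([-np.cos(half), 0.0, np.sin(half)])
    pos_h = pos[0] + r_ch * h_dir
    coords_e = np.vstack([pos, pos_h])
    h_idx = n
    symbols = tuple(["C"] * n + ["H"])
    bonds = tuple((i, i + 1) for i in range(n - 1)) + ((0, h_idx),)
    system = MolecularSystem(symbols, coords_e, bonds=bonds)

    bond_coords = [_bond(0, h_idx, "r(C0H)")] + [
        _bond(i, i + 1, f"r(C{i}C{i+1})") for i in range(n - 1)
    ]
    r0s = [r_ch] + [r_cc] * (n - 1)
    terms = [MorseTerm(bond_coords[0], k_ch, a_ch, r_ch)]
    terms += [MorseTerm(b, k_cc, a_cc, r_cc) for b in bond_coords[1:]]
    angles = [_angle(h_idx, 0, 1, "a(HC0C1)")] + [
        _angle(i - 1, i, i + 1, f"a(C{i-1}C{i}C{i+1})") for i in range(1, n - 1)
    ]
    terms += [PolyTerm(ag, k_th, theta0, c3=c3_th) for ag in angles]
    # light stretch-bend coupling at the substituted end
    terms.append(CouplingTerm(bond_coords[0], angles[0], r_ch, theta0, c21=0.015))
    # out-of-plane restraints (the planar zigzag leaves n-2 soft modes
    # uncovered by bonds and in-plane angles): one altitude per atom
    # outside the reference plane of C0, C1, C2
    k_oop = params.get("k_oop", 0.02)
    oop = [
        InternalCoordinate("altitude", (0, h_idx), reference_frame=(1, 2), label="oop(H)")
    ]
    oop += [
        InternalCoordinate(
            "altitude", (k - 1, k), reference_frame=(k - 2, k - 3), label=f"oop(C{k})"
        )
        for k in range(3, n)
    ]
    terms += [PolyTerm(c, k_oop, 0.0) for c in oop]
    pes = InternalPES(terms, n + 1)

    sigma0 = [160.0] * n + [30.0]
    contribs = []
    for i in range(n):
        lst = []
        for b, r0 in zip(bond_coords, r0s):
            if i in b.atom_indices:
                lst.append((b, r0, -14.0, 2.0))
        contribs.append(lst)
    contribs.append([(bond_coords[0], r_ch, -12.0, 2.0)])
    sigma = ShieldingModel(sigma0, contribs)

    return Fixture(
        spec=None,
        system=system,
        iso_light=Isotopologue([MASS_C12] * n + [MASS_H1], label=f"C{n}H"),
        substitution=(h_idx, MASS_H2),
        pes=pes,
        sigma=sigma,
        coords=tuple(bond_coords),
        reference_coord=bond_coords[0],
        nuclei=tuple(range(n + 1)),
    )


def _make_hbond_toy(params, jit):
    r_oh = params.get("r_oh", 1.85)
    r_oo = params.get("r_oo", 5.2)
    r_co = params.get("r_co", 2.65)
    k_oh = params.get("k_oh", 0.42) * jit()
    a_oh = params.get("a_oh", 1.25)
    k_oo = params.get("k_oo", 0.035) * jit()
    k_co = params.get("k_co", 0.35)
    k_th = params.get("k_theta", 0.07) * jit()
    c3_th = params.get("c3_theta", -0.02)
    coupling = params.get("coupling", 0.05)
    coupling_sign = params.get("coupling_sign", +1.0)

    # C - O1 - H ... O2, hydrogen bond along +x, C off-axis
    theta_coh = np.deg2rad(108.0)
    o1 = np.zeros(3)
    h = np.array([r_oh, 0.0, 0.0])
    o2 = np.array([r_oo, 0.0, 0.0])
    c = r_co * np.array([np.cos(theta_coh), 0.0, np.sin(theta_coh)])
    system = MolecularSystem(
        ("C", "O", "H", "O"),
        np.vstack([c, o1, h, o2]),
        bonds=((0, 1), (1, 2)),
    )
    b_co = _bond(0, 1, "r(CO)")
    b_oh = _bond(1, 2, "r(OH)")
    d_oo = InternalCoordinate("interatomic_distance", (1, 3), label="r(O,O)")
    ang = _angle(0, 1, 2, "a(COH)")
    ang_coo = _angle(0, 1, 3, "a(COO)")
    alt_h = InternalCoordinate("altitude", (1, 2), reference_frame=(0, 3), label="oop(H)")
    alt_o2 = InternalCoordinate("altitude", (1, 3), reference_frame=(0, 2), label="oop(O2)")
    terms = [
        MorseTerm(b_co, k_co, 0.9, r_co),
        MorseTerm(b_oh, k_oh, a_oh, r_oh),
        PolyTerm(d_oo, k_oo, r_oo, c3=-0.01),
        PolyTerm(ang, k_th, theta_coh, c3=c3_th),
        # the planar 4-atom frame needs the acceptor direction and the two
        # out-of-plane motions restrained as well
        PolyTerm(ang_coo, 0.03, theta_coh),
        PolyTerm(alt_h, 0.05, 0.0),
        PolyTerm(alt_o2, 0.02, 0.0),
        # anharmonic three-center coupling: the O-H amplitude couples to
        # the donor-acceptor distance; the sign switches the hole between
        # bond-localized and delocalized morphologies
        CouplingTerm(b_oh, d_oo, r_oh, r_oo, k11=-0.02, c21=coupling_sign * coupling),
        CouplingTerm(b_oh, ang, r_oh, theta_coh, c21=0.02),
    ]
    pes = InternalPES(terms, 4)
    sigma = ShieldingModel(
        [120.0, 300.0, 25.0, 300.0],
        [
            [(d_oo, r_oo, -16.0, 2.0), (b_oh, r_oh, -26.0, 4.0)],
            [(b_oh, r_oh, -20.0, 3.0)],
            [(b_oh, r_oh, -14.0, 2.0), (d_oo, r_oo, -6.0, 1.0)],
            [(d_oo, r_oo, -10.0, 1.5)],
        ],
    )
    return Fixture(
        spec=None,
        system=system,
        iso_light=Isotopologue([MASS_C12, MASS_O16, MASS_H1, MASS_O16], label="COHO"),
        substitution=(2, MASS_H2),
        pes=pes,
        sigma=sigma,
        coords=(b_oh, d_oo, b_co, ang),
        reference_coord=b_oh,
        nuclei=(0, 1, 2, 3),
    )


# ----------------------------------------------------------------------
# DVR oracle


def _sinc_dvr_kinetic(n: int, dx: float, mass_me: float) -> np.ndarray:
    i = np.arange(n)
    diff = i[:, None] - i[None, :]
    safe = np.where(diff == 0, 1, diff)
    T = np.where(diff == 0, np.pi**2 / 3.0, 2.0 * (-1.0) ** diff / safe.astype(float) ** 2)
    return T / (2.0 * mass_me * dx * dx)


def dvr_average(
    potential,
    mass_amu: float,
    observable=None,
    center: float = 0.0,
    halfwidth: float = None,
    n: int = 128,
    tol: float = 1e-8,
    max_doublings: int = 6,
):
    """Exact 1D ground state by sinc-DVR with automatic convergence.

    Parameters
    ----------
    potential : callable x -> V (hartree), x in bohr relative coordinate
    mass_amu : reduced mass in amu
    observable : callable x -> value; defaults to x itself
    center, halfwidth : grid placement; halfwidth defaults to an estimate
        from the harmonic length scale at the minimum
    Returns (E0, <observable>).
    """
    m = mass_amu * AMU_TO_ME
    obs = observable if observable is not None else (lambda x: x)
    if halfwidth is None:
        h = 1e-3
        k = (potential(center + h) - 2 * potential(center) + potential(center - h)) / h**2
        if k <= 0:
            raise ValueError("potential not confining at the requested center")
        halfwidth = 12.0 / (m * np.sqrt(k / m)) ** 0.5

    prev = None
    for it in range(max_doublings + 1):
        x = np.linspace(center - halfwidth, center + halfwidth, n)
        dx = x[1] - x[0]
        V = np.array([potential(xi) for xi in x])
        H = _sinc_dvr_kinetic(n, dx, m)
        H[np.diag_indices(n)] += V
        evals, evecs = np.linalg.eigh(H)
        e0 = evals[0]
        psi = evecs[:, 0]
        edge = max(psi[0] ** 2, psi[-1] ** 2)
        o = float(np.sum(psi**2 * np.array([obs(xi) for xi in x])))
        if edge > 1e-12:
            halfwidth *= 1.5
            prev = None
            continue
        if prev is not None and abs(e0 - prev[0]) < tol and abs(o - prev[1]) < tol:
            return float(e0), o
        prev = (e0, o)
        n *= 2
    if prev is None:
        raise ValueError("potential not confining on any attempted grid")
    return float(prev[0]), prev[1]


def dvr_average_2d(
    potential,
    masses_amu,
    observable,
    centers=(0.0, 0.0),
    halfwidths=(1.5, 1.5),
    n: int = 48,
    tol: float = 1e-7,
    max_doublings: int = 3,
):
    """Exact 2D (Cartesian) ground state on a tensor sinc-DVR grid.

    potential / observable take (x, y) arrays broadcast on the grid.
    Returns (E0, <observable>).
    """
    m1, m2 = (m * AMU_TO_ME for m in masses_amu)
    prev = None
    e0 = o = None
    for _ in range(max_doublings + 1):
        x = np.linspace(centers[0] - halfwidths[0], centers[0] + halfwidths[0], n)
        y = np.linspace(centers[1] - halfwidths[1], centers[1] + halfwidths[1], n)
        dx, dy = x[1] - x[0], y[1] - y[0]
        X, Y = np.meshgrid(x, y, indexing="ij")
        V = potential(X, Y).ravel()
        Tx = sp.csr_matrix(_sinc_dvr_kinetic(n, dx, m1))
        Ty = sp.csr_matrix(_sinc_dvr_kinetic(n, dy, m2))
        H = sp.kron(Tx, sp.identity(n)) + sp.kron(sp.identity(n), Ty) + sp.diags(V)
        evals, evecs = spla.eigsh(H.tocsc(), k=1, which="SA", maxiter=10000)
        psi = evecs[:, 0]
        o = float(psi**2 @ observable(X, Y).ravel())
        e0 = float(evals[0])
        if prev is not None and abs(e0 - prev[0]) < tol and abs(o - prev[1]) < tol:
            break
        prev = (e0, o)
        n = int(n * 1.5)
    return e0, o
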