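"""A-priori local comparator methods: loc-VPT2 and LMZL (+centrifugal).

loc-VPT2 treats only the nucleus at the substitution site as mobile: the
3x3 block of the full Cartesian Hessian at that atom is mass-weighted and
diagonalized (no translation/rotation projection; the frozen environment
fixes the frame) and the standard VPT2 machinery is applied to the three
local modes.  Harmonic stretch/bend couplings of the mobile atom are thus
retained.

LMZL treats the three polar coordinates of the mobile atom about its
bonded partner -- the bond length r and the two bending angles phi_az
(azimuth) and phi_alt (altitude) -- as independent 1D problems, each
solved perturbatively at the zero-point level (cubic-only shift, harmonic
amplitude).  This discards all couplings, in particular the centrifugal
stretching of the bond by the angular zero-point motion.  The optional
centrifugal correction restores it by augmenting the radial potential
with V_cent(r) = <L^2>/(2 m r^2), <L^2> being the sum of the two angular
zero-point values <p_phi^2> = m_phi omega_phi / 2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import AMU_TO_ME, PPM_TO_PPB
from .fields import cubic_semidiagonal, property_derivatives
from .harmonic import NormalModeSet, SaddlePointError
from .system import Isotopologue, MolecularSystem, topological_distances
from .vpt2 import IsotopeShiftReport, vib_correction

__all__ = ["LocalModeSet", "local_modes", "loc_vpt2_shift", "lmzl_shift", "LmzlResult"]


@dataclass(frozen=True)
class LocalModeSet:
    """Three local vibration modes of the mobile atom (all other nuclei fixed)."""

    mobile_atom: int
    local_hessian: np.ndarray  # 3x3, hartree/bohr^2
    modes: NormalModeSet  # 3 'v' modes embedded in full Cartesian space


def local_modes(
    system: MolecularSystem, iso: Isotopologue, hessian: np.ndarray, mobile_atom: int
) -> LocalModeSet:
    """Diagonalize the restricted (3x3) mass-weighted force-constant block."""
    n = system.n_atoms
    H = np.asarray(hessian, dtype=float)
    if H.shape != (3 * n, 3 * n):
        raise ValueError("hessian has wrong shape")
    a = int(mobile_atom)
    blk = H[3 * a : 3 * a + 3, 3 * a : 3 * a + 3]
    blk = 0.5 * (blk + blk.T)
    m = iso.masses[a] * AMU_TO_ME
    w2, e = np.linalg.eigh(blk / m)
    tol = 1e-12 * max(np.abs(w2).max(), 1.0)
    if np.any(w2 < -tol):
        raise SaddlePointError("restricted force-constant block has a negative eigenvalue")
    # zero eigenvalues occur when the environment cannot restrain a
    # direction (e.g. the perpendicular motions of a diatomic); those
    # directions carry no local vibration and are dropped
    keep = np.flatnonzero(w2 > tol)
    e = e[:, keep]
    for j in range(e.shape[1]):
        i = np.argmax(np.abs(e[:, j]))
        if e[i, j] < 0:
            e[:, j] = -e[:, j]
    omega = np.sqrt(w2[keep])
    l_local = np.zeros((len(keep), n, 3))
    for j in range(len(keep)):
        l_local[j, a, :] = e[:, j] / np.sqrt(m * omega[j])
    modes = NormalModeSet(
        omega=omega,
        l_modes=l_local,
        kind_flags=np.array(["v"] * len(keep)),
        masses_me=iso.masses * AMU_TO_ME,
    )
    return LocalModeSet(mobile_atom=a, local_hessian=blk, modes=modes)


def loc_vpt2_shift(
    system: MolecularSystem,
    isoA: Isotopologue,
    isoB: Isotopologue,
    hessian_evaluator,
    sigma_evaluator,
    mobile_atom: int,
    h_ff: float = 0.005,
    h_nmr: float = 0.05,
) -> IsotopeShiftReport:
    """Isotope shift with only the substitution-site nucleus mobile.

    The standard VPT2 code path is reused verbatim on the 3-mode local
    systems of the two isotopologues.
    """
    a = int(mobile_atom)
    diff = [i for i, (ma, mb) in enumerate(zip(isoA.masses, isoB.masses)) if ma != mb]
    if diff and diff != [a]:
        raise ValueError(f"substitution at atoms {diff} but mobile atom is {a}")
    R = system.coords_e
    H0 = hessian_evaluator(R)
    corr = {}
    for key, iso in (("A", isoA), ("B", isoB)):
        lm = local_modes(system, iso, H0, a)
        cubic = cubic_semidiagonal(hessian_evaluator, lm.modes, R, h_ff=h_ff)
        prop = property_derivatives(sigma_evaluator, lm.modes, R, h_nmr=h_nmr)
        corr[key] = vib_correction(lm.modes, cubic, prop, label=iso.label)
    from .vpt2 import standard_isotope_shift

    rep = standard_isotope_shift(corr["A"], corr["B"], system, substitution_atoms=[a])
    return IsotopeShiftReport(
        nuclei=rep.nuclei,
        n_bonds=rep.n_bonds,
        shift_harm=rep.shift_harm,
        shift_anh=rep.shift_anh,
        dR=rep.dR,
        method="loc-vpt2",
        label=rep.label,
    )


# ----------------------------------------------------------------------
# LMZL


@dataclass(frozen=True)
class LmzlResult:
    """Per-coordinate zero-point data of one LMZL calculation.

    mean_shift : <c> - c_e per coordinate (bohr / rad)
    amplitude : <(c - c_e)^2> per coordinate (bohr^2 / rad^2)
    Coordinates are ordered (r, phi_az, phi_alt); angular entries are
    absent for a diatomic without an angular frame.
    """

    labels: tuple
    omega: np.ndarray
    mean_shift: np.ndarray
    amplitude: np.ndarray
    centrifugal: bool


def _polar_frame(system: MolecularSystem, mobile: int, partner: int):
    """Orthonormal (radial, azimuth-tangent, altitude-tangent) triad for the
    mobile atom about its partner, or (u, None, None) without a frame."""
    R = system.coords_e
    u = R[mobile] - R[partner]
    r_e = np.linalg.norm(u)
    u = u / r_e
    nbrs = sorted(b for bond in system.bonds for b in bond if partner in bond and b != partner)
    nbrs = [b for b in nbrs if b != mobile]
    if len(nbrs) == 0:
        return r_e, u, None, None, None
    if len(nbrs) == 1:
        # single adjacent bond: one in-plane bending coordinate, no altitude
        b1 = R[nbrs[0]] - R[partner]
        b1 /= np.linalg.norm(b1)
        t_az = b1 - u * (u @ b1)
        nt = np.linalg.norm(t_az)
        if nt < 1e-10:
            return r_e, u, None, None, None
        return r_e, u, t_az / nt, None, (nbrs[0],)
    p1, p2 = nbrs[0], nbrs[1]
    b1 = R[p1] - R[partner]
    b1 /= np.linalg.norm(b1)
    b2 = R[p2] - R[partner]
    b2 /= np.linalg.norm(b2)
    n = np.cross(b1, b2)
    n /= np.linalg.norm(n)  # frame-plane normal -> altitude direction
    m = b1 - b2
    m /= np.linalg.norm(m)  # bisecting-plane normal -> azimuth direction
    # tangents orthogonal to the bond direction
    t_az = m - u * (u @ m)
    t_az /= np.linalg.norm(t_az)
    t_alt = n - u * (u @ n)
    t_alt -= t_az * (t_az @ t_alt)
    t_alt /= np.linalg.norm(t_alt)
    return r_e, u, t_az, t_alt, (p1, p2)


def _fd_derivs_1d(f, h: float):
    """Value-free central 5-point first/second/third derivatives of f at 0."""
    fm2, fm1, f0, fp1, fp2 = (f(x) for x in (-2 * h, -h, 0.0, h, 2 * h))
    d1 = (fm2 - 8 * fm1 + 8 * fp1 - fp2) / (12 * h)
    d2 = (-fm2 + 16 * fm1 - 30 * f0 + 16 * fp1 - fp2) / (12 * h * h)
    d3 = (-fm2 + 2 * fm1 - 2 * fp1 + fp2) / (2 * h**3)
    return d1, d2, d3


def _zero_point_1d(k: float, c3: float, g1: float, mass_me: float):
    """Perturbative zero-point data of a 1D oscillator V = g1 x + k x^2/2 + c3 x^3/6.

    Returns (omega, <x>, <x^2>): the linear term shifts the minimum by
    -g1/k, the cubic term gives the usual VPT2 mean shift -c3/(4 m^2 w^3).
    """
    if k <= 0:
        raise SaddlePointError("negative 1D force constant")
    omega = np.sqrt(k / mass_me)
    shift = -g1 / k - c3 / (4.0 * mass_me**2 * omega**3)
    amp = 1.0 / (2.0 * mass_me * omega)
    return omega, shift, amp


def _lmzl_one_isotopologue(
    system,
    pes_energy,
    sigma_evaluator,
    mobile: int,
    partner: int,
    mass_amu: float,
    centrifugal: bool,
    use_reduced_mass: bool,
    partner_mass_amu: float,
    h_r: float = 0.02,
    h_phi: float = 0.02,
):
    R = system.coords_e
    r_e, u, t_az, t_alt, _ = _polar_frame(system, mobile, partner)
    m_r = mass_amu * AMU_TO_ME
    if use_reduced_mass:
        mp = partner_mass_amu * AMU_TO_ME
        m_r = m_r * mp / (m_r + mp)
    m_h = mass_amu * AMU_TO_ME

    def radial_geo(dr):
        g = R.copy()
        g[mobile] = R[partner] + (r_e + dr) * u
        return g

    def arc_geo(t_hat, phi):
        g = R.copy()
        g[mobile] = R[partner] + r_e * (u * np.cos(phi) + t_hat * np.sin(phi))
        return g

    labels, omegas, shifts, amps = [], [], [], []
    sig_lin = []  # d sigma / dc per nucleus, per coordinate
    sig_curv = []

    # angular coordinates first (their zero point feeds the centrifugal term)
    ang_data = []
    for lab, t_hat in (("phi_az", t_az), ("phi_alt", t_alt)):
        if t_hat is None:
            continue
        _, k_phi, c3_phi = _fd_derivs_1d(lambda p, th=t_hat: pes_energy(arc_geo(th, p)), h_phi)
        m_phi = m_h * r_e**2
        om, sh, am = _zero_point_1d(k_phi, c3_phi, 0.0, m_phi)
        ang_data.append((lab, t_hat, om, sh, am, m_phi))

    # radial coordinate, optionally with the centrifugal potential
    g1_r, k_r, c3_r = _fd_derivs_1d(lambda d: pes_energy(radial_geo(d)), h_r)
    # the equilibrium geometry is stationary; keep any residual as a linear term
    if centrifugal and ang_data:
        L2 = sum(0.5 * m_phi * om for (_, _, om, _, _, m_phi) in ang_data)  # <p_az^2>+<p_alt^2>
        C = L2 / (2.0 * m_r)
        # V_cent = C / r^2 expanded about r_e
        g1_r += -2.0 * C / r_e**3
        k_r += 6.0 * C / r_e**4
        c3_r += -24.0 * C / r_e**5
    om_r, sh_r, am_r = _zero_point_1d(k_r, c3_r, g1_r, m_r)

    labels.append("r")
    omegas.append(om_r)
    shifts.append(sh_r)
    amps.append(am_r)
    d1, d2, _ = _sigma_derivs(sigma_evaluator, radial_geo, h_r)
    sig_lin.append(d1)
    sig_curv.append(d2)
    for lab, t_hat, om, sh, am, _ in ang_data:
        labels.append(lab)
        omegas.append(om)
        shifts.append(sh)
        amps.append(am)
        d1, d2, _ = _sigma_derivs(sigma_evaluator, lambda p, th=t_hat: arc_geo(th, p), h_phi)
        sig_lin.append(d1)
        sig_curv.append(d2)

    res = LmzlResult(
        labels=tuple(labels),
        omega=np.array(omegas),
        mean_shift=np.array(shifts),
        amplitude=np.array(amps),
        centrifugal=centrifugal,
    )
    # vibrational correction to delta per nucleus:
    #   -sum_c [ sigma'_c <c> + (1/2) sigma''_c <dc^2> ]
    sig_lin = np.array(sig_lin)  # (n_coord, n_nuclei)
    sig_curv = np.array(sig_curv)
    d_anh = -np.einsum("c,cn->n", res.mean_shift, sig_lin)
    d_harm = -0.5 * np.einsum("c,cn->n", res.amplitude, sig_curv)
    return res, d_harm, d_anh


def _sigma_derivs(sigma_evaluator, geo_of, h):
    fm2, fm1, f0, fp1, fp2 = (
        np.asarray(sigma_evaluator(geo_of(x)), dtype=float)
        for x in (-2 * h, -h, 0.0, h, 2 * h)
    )
    d1 = (fm2 - 8 * fm1 + 8 * fp1 - fp2) / (12 * h)
    d2 = (-fm2 + 16 * fm1 - 30 * f0 + 16 * fp1 - fp2) / (12 * h * h)
    return d1, d2, f0


def lmzl_shift(
    system: MolecularSystem,
    isoA: Isotopologue,
    isoB: Isotopologue,
    energy_evaluator,
    sigma_evaluator,
    mobile_atom: int,
    centrifugal: bool = False,
    use_reduced_mass: bool = False,
):
    """LMZL isotope shift and per-coordinate zero-point data.

    The mobile atom must be bonded to exactly one partner (the approach is
    undefined for multiply bonded substitution sites).  Returns
    (IsotopeShiftReport, {"A": LmzlResult, "B": LmzlResult}).
    """
    a = int(mobile_atom)
    partners = [b for bond in system.bonds for b in bond if a in bond and b != a]
    if len(partners) != 1:
        raise ValueError(
            f"LMZL needs a singly-bonded mobile atom; atom {a} has {len(partners)} bonds"
        )
    partner = partners[0]

    out = {}
    harm = {}
    anh = {}
    for key, iso in (("A", isoA), ("B", isoB)):
        res, d_harm, d_anh = _lmzl_one_isotopologue(
            system,
            energy_evaluator,
            sigma_evaluator,
            a,
            partner,
            iso.masses[a],
            centrifugal,
            use_reduced_mass,
            iso.masses[partner],
        )
        out[key] = res
        harm[key] = d_harm
        anh[key] = d_anh

    # mobile-atom displacement vector for the r_z-style report
    r_e, u, t_az, t_alt, _ = _polar_frame(system, a, partner)
    dR = np.zeros_like(system.coords_e)
    dA, dB = out["A"], out["B"]
    for lab, vec in (("r", u), ("phi_az", t_az), ("phi_alt", t_alt)):
        if vec is None or lab not in dA.labels:
            continue
        i = dA.labels.index(lab)
        scale = 1.0 if lab == "r" else r_e
        dR[a] += (dB.mean_shift[i] - dA.mean_shift[i]) * scale * vec

    dist = topological_distances(system, [a])
    nuclei = np.arange(system.n_atoms)
    n_bonds = np.array([int(dist[q]) if np.isfinite(dist[q]) else -1 for q in nuclei])
    rep = IsotopeShiftReport(
        nuclei=nuclei,
        n_bonds=n_bonds,
        shift_harm=(harm["B"] - harm["A"]) * PPM_TO_PPB,
        shift_anh=(anh["B"] - anh["A"]) * PPM_TO_PPB,
        dR=dR,
        method="lmzl+cent" if centrifugal else "lmzl",
    )
    return rep, out
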