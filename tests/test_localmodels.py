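"""loc-VPT2 and LMZL (+centrifugal) comparator methods."""

import numpy as np
import pytest

from vibhole.constants import AMU_TO_ME, MASS_C13
from vibhole.localmodels import lmzl_shift, loc_vpt2_shift, local_modes
from vibhole.modelsystems import InternalPES, dvr_average_2d, make_fixture

def test_loc_vpt2_equals_full_vpt2_in_infinite_mass_limit(fixtures, vpt2_runs):
    """With m_X = 1e6 amu the frozen-partner assumption is exact."""
    fix = fixtures("xh_heavy")
    rv = vpt2_runs("xh_heavy")
    rl = loc_vpt2_shift(
        fix.system, fix.iso_light, fix.iso_heavy, fix.pes.hessian, fix.sigma, 1
    )
    assert np.abs(rv.report.shift - rl.shift).max() < 0.1  # ppb


def test_loc_vpt2_harmonic_pes_no_anharmonic_part(fixtures):
    fix = fixtures("methane_like")
    R = fix.system.coords_e
    quad = InternalPES([], 5, cartesian_quadratic=fix.pes.hessian(R), R_ref=R)
    rep = loc_vpt2_shift(fix.system, fix.iso_light, fix.iso_heavy, quad.hessian, fix.sigma, 1)
    assert np.abs(rep.shift_anh).max() < 1e-6


def test_loc_vpt2_vs_dd_same_sign_same_order(fixtures, dd_runs):
    """Localization is approximate: same sign and order of magnitude as
    DD-VPT2, but not equal."""
    fix = fixtures("methane_like")
    rd = dd_runs("methane_like", cutoff=1e-3).report
    rl = loc_vpt2_shift(fix.system, fix.iso_light, fix.iso_heavy, fix.pes.hessian, fix.sigma, 1)
    # compare at the substituted H and the central atom (largest shifts)
    for q in (0, 1):
        assert np.sign(rl.shift[q]) == np.sign(rd.shift[q])
        ratio = rl.shift[q] / rd.shift[q]
        assert 0.2 < ratio < 5.0
        assert rl.shift[q] != pytest.approx(rd.shift[q], abs=1e-6)


def test_loc_vpt2_wrong_mobile_atom_rejected(fixtures):
    fix = fixtures("methane_like")
    with pytest.raises(ValueError):
        loc_vpt2_shift(fix.system, fix.iso_light, fix.iso_heavy, fix.pes.hessian, fix.sigma, 2)


def test_lmzl_multiply_bonded_site_rejected(fixtures):
    fix = fixtures("methane_like")
    A = fix.iso_light
    B = A.substitute(0, MASS_C13)
    with pytest.raises(ValueError):
        lmzl_shift(fix.system, A, B, fix.pes.energy, fix.sigma, 0)


class SeparablePolarPES:
    """Quadratic potential in the displacement of one mobile atom, built
    on the (radial, azimuth-tangent, altitude-tangent) triad LMZL itself
    uses, with three independent force constants: exactly separable."""

    def __init__(self, system, mobile, partner, k_triple):
        from vibhole.localmodels import _polar_frame

        self.R = system.coords_e
        self.mobile = mobile
        r_e, u, t_az, t_alt, _ = _polar_frame(system, mobile, partner)
        self.dirs = np.array([u, t_az, t_alt])
        self.k = np.asarray(k_triple)
        self.n = system.n_atoms

    def energy(self, geo):
        d = np.asarray(geo)[self.mobile] - self.R[self.mobile]
        return float(0.5 * np.sum(self.k * (self.dirs @ d) ** 2))

    def hessian(self, geo):
        H = np.zeros((3 * self.n, 3 * self.n))
        blk = sum(k * np.outer(v, v) for k, v in zip(self.k, self.dirs))
        s = slice(3 * self.mobile, 3 * self.mobile + 3)
        H[s, s] = blk
        return H


def test_separable_harmonic_polar_amplitudes_match_loc_vpt2():
    """With a separable harmonic polar potential there is nothing to
    couple: LMZL 1D amplitudes equal the loc-VPT2 local-mode amplitudes."""
    base = make_fixture("methane_like")
    pes = SeparablePolarPES(base.system, 1, 0, (0.30, 0.10, 0.12))
    iso = base.iso_light
    lm = local_modes(base.system, iso, pes.hessian(base.system.coords_e), 1)
    # loc-VPT2 mean-square Cartesian amplitude along each local mode: l^2/2
    loc_amp = sorted(0.5 * np.sum(l[1] ** 2) for l in lm.modes.l_modes)
    _, res = lmzl_shift(base.system, iso, iso.substitute(1, 2.014102), pes.energy,
                        base.sigma, 1, centrifugal=False)
    rA = res["A"]
    r_e = np.linalg.norm(base.system.coords_e[1] - base.system.coords_e[0])
    # convert angular amplitudes (rad^2) to Cartesian arc amplitudes
    conv = {lab: (1.0 if lab == "r" else r_e**2) for lab in rA.labels}
    lmzl_amp = sorted(a * conv[lab] for lab, a in zip(rA.labels, rA.amplitude))
    assert np.allclose(loc_amp, lmzl_amp, rtol=1e-8)


@pytest.mark.parametrize("name", ["methane_like", "water_like"])
def test_centrifugal_ordering_on_bending_coupled_fixtures(name, fixtures):
    """|dr_g(LMZL)| <= |dr_g(LMZL+cent)| <= |dr_g(loc-VPT2)|: the
    centrifugal correction restores most of the stretch-bend coupling the
    plain local-mode treatment discards."""
    from vibhole.fields import cubic_semidiagonal, property_derivatives
    from vibhole.geometry_stats import rg_parameters
    from vibhole.vpt2 import vib_correction

    fix = fixtures(name)
    A, B = fix.iso_light, fix.iso_heavy
    mob = fix.substitution[0]
    R = fix.system.coords_e
    bond = fix.coords[0]
    H0 = fix.pes.hessian(R)
    fg = {}
    for key, iso in (("A", A), ("B", B)):
        lm = local_modes(fix.system, iso, H0, mob)
        corr = vib_correction(
            lm.modes,
            cubic_semidiagonal(fix.pes.hessian, lm.modes, R),
            property_derivatives(fix.sigma, lm.modes, R),
        )
        fg[key] = rg_parameters([bond], R, corr.dR, lm.modes)[0]
    drg_loc = fg["B"] - fg["A"]
    _, l0 = lmzl_shift(fix.system, A, B, fix.pes.energy, fix.sigma, mob, centrifugal=False)
    _, lc = lmzl_shift(fix.system, A, B, fix.pes.energy, fix.sigma, mob, centrifugal=True)
    i = l0["A"].labels.index("r")
    drg0 = l0["B"].mean_shift[i] - l0["A"].mean_shift[i]
    drgc = lc["B"].mean_shift[i] - lc["A"].mean_shift[i]
    assert abs(drg0) <= abs(drgc) <= abs(drg_loc)
    # and the centrifugal variant is the closer one to loc-VPT2
    assert abs(drgc - drg_loc) < abs(drg0 - drg_loc)


def test_lmzl_amplitudes_insensitive_to_centrifugal_correction(fixtures):
    """The correction mainly shifts the radial minimum; amplitudes move
    little (the pattern of the published comparison tables)."""
    fix = fixtures("methane_like")
    A, B = fix.iso_light, fix.iso_heavy
    _, l0 = lmzl_shift(fix.system, A, B, fix.pes.energy, fix.sigma, 1, centrifugal=False)
    _, lc = lmzl_shift(fix.system, A, B, fix.pes.energy, fix.sigma, 1, centrifugal=True)
    i = l0["A"].labels.index("r")
    rel = abs(lc["A"].amplitude[i] - l0["A"].amplitude[i]) / l0["A"].amplitude[i]
    assert rel < 0.02
    for lab in ("phi_az", "phi_alt"):
        j = l0["A"].labels.index(lab)
        assert lc["A"].amplitude[j] == pytest.approx(l0["A"].amplitude[j], rel=1e-12)


def test_lmzl_centrifugal_against_2d_dvr_oracle():
    """2D polar model (r, phi): LMZL+cent reproduces the exact isotope
    effect on <r> within 25%; plain LMZL is biased low."""
    m_h, m_d = 1.007825, 2.014102
    r_e, k_r, a_m, k_phi = 1.85, 0.45, 1.2, 0.12
    D = k_r / (2 * a_m**2)

    def pot_xy(x, y):
        r = np.sqrt(x * x + y * y)
        phi = np.arctan2(y, x)
        return D * (1 - np.exp(-a_m * (r - r_e))) ** 2 + 0.5 * k_phi * phi * phi

    exact = {}
    for m in (m_h, m_d):
        # fixed 48x48 grid: the residual grid error (~1e-5 bohr) cancels
        # in the isotope difference and is far below the 25% band
        _, ravg = dvr_average_2d(
            pot_xy,
            (m, m),
            lambda x, y: np.sqrt(x * x + y * y),
            centers=(r_e, 0.0),
            halfwidths=(0.9, 0.9),
            n=48,
            max_doublings=0,
        )
        exact[m] = ravg - r_e
    d_exact = exact[m_d] - exact[m_h]

    def lmzl_1d(m, centrifugal):
        me = m * AMU_TO_ME
        w_phi = np.sqrt(k_phi / (me * r_e**2))
        # radial force constants of the Morse potential
        c3 = -6 * D * a_m**3
        g1, k, c3r = 0.0, k_r, c3
        if centrifugal:
            L2 = 0.5 * me * r_e**2 * w_phi
            C = L2 / (2 * me)
            g1 += -2 * C / r_e**3
            k += 6 * C / r_e**4
            c3r += -24 * C / r_e**5
        w = np.sqrt(k / me)
        return -g1 / k - c3r / (4 * me**2 * w**3)

    d_plain = lmzl_1d(m_d, False) - lmzl_1d(m_h, False)
    d_cent = lmzl_1d(m_d, True) - lmzl_1d(m_h, True)
    assert abs(d_cent - d_exact) / abs(d_exact) < 0.25
    assert abs(d_plain) < abs(d_exact)  # plain LMZL biased low
    assert abs(d_cent - d_exact) < abs(d_plain - d_exact)


def test_lmzl_report_structure(fixtures):
    fix = fixtures("methane_like")
    rep, res = lmzl_shift(
        fix.system, fix.iso_light, fix.iso_heavy, fix.pes.energy, fix.sigma, 1
    )
    assert rep.method == "lmzl"
    assert res["A"].labels == ("r", "phi_az", "phi_alt")
    assert np.all(res["A"].amplitude > 0)
    # deuteration reduces every amplitude
    assert np.all(res["B"].amplitude < res["A"].amplitude)
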