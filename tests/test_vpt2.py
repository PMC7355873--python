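"""Standard VPT2 corrections and explicit-difference isotope shifts."""

import numpy as np
import pytest

from vibhole.constants import AMU_TO_ME
from vibhole.fields import cubic_semidiagonal, property_derivatives
from vibhole.harmonic import normal_modes
from vibhole.modelsystems import InternalPES, dvr_average, make_fixture
from vibhole.pipeline import run_standard_vpt2
from vibhole.system import evaluate_coordinate
from vibhole.vpt2 import standard_isotope_shift, vib_correction


@pytest.fixture(scope="module")
def morse():
    fix = make_fixture("diatomic_morse")
    nm = normal_modes(fix.system, fix.iso_light, fix.pes.hessian(fix.system.coords_e))
    return fix, nm


def test_harmonic_pes_gives_zero_anharmonic_parts(fixtures):
    fix = fixtures("methane_like")
    R = fix.system.coords_e
    quad = InternalPES([], 5, cartesian_quadratic=fix.pes.hessian(R), R_ref=R)
    nm = normal_modes(fix.system, fix.iso_light, quad.hessian(R))
    corr = vib_correction(
        nm,
        cubic_semidiagonal(quad.hessian, nm, R),
        property_derivatives(fix.sigma, nm, R),
    )
    assert np.abs(corr.dR).max() < 1e-12
    assert np.abs(corr.delta_anh).max() < 1e-9


def test_one_mode_harmonic_curvature_closed_form(morse):
    """sigma = a + b q1^2 gives Ddelta_harm = -b/2 (in ppm -> ppb)."""
    fix, nm = morse
    R = fix.system.coords_e
    b = 1.3
    l1 = nm.l_modes[0].ravel()

    def sigma(geo):
        q = ((geo - R).ravel() @ l1) / (l1 @ l1)
        return np.array([4.0 + b * q * q])

    corr = vib_correction(
        nm,
        cubic_semidiagonal(fix.pes.hessian, nm, R),
        property_derivatives(sigma, nm, R),
    )
    assert corr.delta_harm[0] == pytest.approx(-b / 2 * 1000.0, rel=1e-7)


def test_morse_anharmonic_shift_against_dvr(morse):
    """Ddelta_anh from a linear sigma(r) equals -a1 <r - r_e>; the exact
    average comes from the DVR oracle, agreement within the VPT2
    truncation bound (relative error ~ x_e)."""
    fix, nm = morse
    R = fix.system.coords_e
    a1 = -10.6

    def sigma(geo):
        bond = fix.coords[0]
        return np.array([a1 * (evaluate_coordinate(bond, geo) - 2.05)])

    corr = vib_correction(
        nm,
        cubic_semidiagonal(fix.pes.hessian, nm, R),
        property_derivatives(sigma, nm, R),
    )
    m1, m2 = fix.iso_light.masses
    mu = m1 * m2 / (m1 + m2)
    a, k = 1.0, 0.31
    D = k / (2 * a * a)
    _, xavg = dvr_average(lambda x: D * (1 - np.exp(-a * x)) ** 2, mu)
    exact = -a1 * xavg * 1000.0  # ppb, delta = -sigma
    omega = np.sqrt(k / (mu * AMU_TO_ME))
    xe = a * a / (2 * mu * AMU_TO_ME * omega)
    assert corr.delta_anh[0] == pytest.approx(exact, rel=5 * xe)


def test_identical_isotopologues_give_zero_shift(fixtures):
    fix = fixtures("water_like")
    run = run_standard_vpt2(
        fix.system, fix.iso_light, fix.iso_light, fix.pes.hessian, fix.sigma
    )
    assert np.abs(run.report.shift).max() == 0.0
    assert np.abs(run.report.dR).max() == 0.0


def test_lighter_substitution_flips_sign_one_mode():
    """In the 1D X-H model, substituting a *lighter* isotope flips the sign
    of the harmonic shift contribution."""
    fix = make_fixture("xh_heavy")
    heavy = run_standard_vpt2(
        fix.system, fix.iso_light, fix.iso_light.substitute(1, 2.014102),
        fix.pes.hessian, fix.sigma,
    )
    light = run_standard_vpt2(
        fix.system, fix.iso_light, fix.iso_light.substitute(1, 0.6),
        fix.pes.hessian, fix.sigma,
    )
    assert np.sign(light.report.shift_harm[1]) == -np.sign(heavy.report.shift_harm[1])


def test_1d_closed_form_isotope_shift():
    """X-H -> X-D with heavy X against the hand-assembled 1D VPT2 formulas:
    shift = -(1/4)[D2s(D) - D2s(H)] - [Ds . (DR_D - DR_H)] with
    DR = -phi3 l / (4 w) per isotopologue."""
    fix = make_fixture("xh_heavy")
    R = fix.system.coords_e
    run = run_standard_vpt2(fix.system, fix.iso_light, fix.iso_heavy, fix.pes.hessian, fix.sigma)

    k, a, r0 = 0.31, 1.0, 2.05
    Dm = k / (2 * a * a)
    sig_params = {0: (-21.0, 5.0), 1: (-10.6, 1.4)}
    shift_expected = {}
    for nuc, (a1, a2) in sig_params.items():
        parts = {}
        for mass in (1.007825, 2.014102):
            mu = mass * AMU_TO_ME  # X is effectively infinite
            w = np.sqrt(k / mu)
            l = 1.0 / np.sqrt(mu * w)  # bohr per unit q
            phi3 = -6.0 * Dm * a**3 * l**3
            dr = -phi3 * l / (4.0 * w)
            harm = -0.25 * (2.0 * a2 * l * l)  # D2 sigma[l] = 2 a2 l^2
            anh = -a1 * dr
            parts[mass] = harm + anh
        shift_expected[nuc] = (parts[2.014102] - parts[1.007825]) * 1000.0
    # X has mass 1e6, not infinity: allow the reduced-mass truncation
    for nuc in (0, 1):
        assert run.report.shift[nuc] == pytest.approx(shift_expected[nuc], rel=2e-4)


def test_cost_model_call_counts(fixtures):
    fix = fixtures("water_like")
    run = run_standard_vpt2(
        fix.system, fix.iso_light, fix.iso_heavy, fix.pes.hessian, fix.sigma
    )
    n_vib = run.modesA.n_vib
    # 1 equilibrium Hessian + 2 n_vib displaced Hessians per isotopologue
    assert run.hessian_calls == 1 + 2 * (2 * n_vib)
    # (2 n_vib + 1) shielding calls per isotopologue
    assert run.sigma_calls == 2 * (2 * n_vib + 1)


def test_dR_invariant_under_mode_rephasing(morse):
    fix, nm = morse
    R = fix.system.coords_e
    corr = vib_correction(
        nm,
        cubic_semidiagonal(fix.pes.hessian, nm, R),
        property_derivatives(fix.sigma, nm, R),
    )
    from vibhole.harmonic import NormalModeSet

    l2 = nm.l_modes.copy()
    l2[0] = -l2[0]  # flip the phase of the vibrational mode
    nm2 = NormalModeSet(nm.omega, l2, nm.kind_flags, nm.masses_me)
    corr2 = vib_correction(
        nm2,
        cubic_semidiagonal(fix.pes.hessian, nm2, R),
        property_derivatives(fix.sigma, nm2, R),
    )
    assert np.abs(corr.dR - corr2.dR).max() < 1e-12


def test_linearity_in_cubic_and_curvature(morse):
    fix, nm = morse
    R = fix.system.coords_e
    cubic = cubic_semidiagonal(fix.pes.hessian, nm, R)
    prop = property_derivatives(fix.sigma, nm, R)
    corr = vib_correction(nm, cubic, prop)
    from vibhole.fields import CubicField, PropertySurface

    cubic2 = CubicField(2.0 * cubic.third_derivatives, cubic.basis_id, cubic.displaced)
    prop3 = PropertySurface(prop.sigma_e, prop.grad, 3.0 * prop.curv, prop.basis_id, prop.nuclei)
    corr2 = vib_correction(nm, cubic2, prop)
    corr3 = vib_correction(nm, cubic, prop3)
    assert np.allclose(corr2.dR, 2.0 * corr.dR, rtol=1e-12)
    assert np.allclose(corr2.delta_anh, 2.0 * corr.delta_anh, rtol=1e-12)
    assert np.allclose(corr3.delta_harm, 3.0 * corr.delta_harm, rtol=1e-12)


def test_shift_decomposition_and_topology(vpt2_runs):
    run = vpt2_runs("methane_like")
    rep = run.report
    assert np.allclose(rep.shift, rep.shift_harm + rep.shift_anh)
    # substitution at H1: C is 1 bond away, other H two bonds
    assert rep.n_bonds[1] == 0 and rep.n_bonds[0] == 1 and rep.n_bonds[2] == 2


def test_mismatched_nuclei_rejected(morse):
    fix, nm = morse
    R = fix.system.coords_e
    cubic = cubic_semidiagonal(fix.pes.hessian, nm, R)
    prop = property_derivatives(fix.sigma, nm, R)
    corr = vib_correction(nm, cubic, prop)
    prop2 = property_derivatives(fix.sigma, nm, R, nuclei=np.array([1, 0]))
    corr2 = vib_correction(nm, cubic, prop2)
    with pytest.raises(ValueError):
        standard_isotope_shift(corr, corr2)
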