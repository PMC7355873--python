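"""Standard VPT2 vibrational corrections and isotope shifts by explicit
difference.

Zero-point (T = 0) averaging only.  Per isotopologue X:

    ddelta_harm(X) = -(1/4) sum_i^v D^2 sigma[l_i]
    DR(X)          = -(1/4) sum_i^v (1/omega_i) sum_k^v phi_(i,kk) l_i
    ddelta_anh(X)  = -D sigma[DR(X)]

with phi_(i,kk) = D^{1,2}V[l_i, l_k].  The shift at each reporting nucleus
is the difference nDdelta = Ddelta(B) - Ddelta(A), which by the
delta = -sigma convention equals the vibrational part of
sigma(A) - sigma(B).  Shieldings are handled in ppm; shifts reported in
ppb.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import PPM_TO_PPB
from .fields import CubicField, PropertySurface, check_basis
from .harmonic import NormalModeSet
from .system import MolecularSystem, topological_distances

__all__ = ["VibCorrection", "IsotopeShiftReport", "vib_correction", "standard_isotope_shift"]


@dataclass(frozen=True)
class VibCorrection:
    """Per-isotopologue vibrational corrections.

    delta_harm / delta_anh : (n_nuclei,) arrays, ppb (corrections to the
    chemical shift delta).  dR : (N, 3) Cartesian r_z shift, bohr.
    """

    delta_harm: np.ndarray
    delta_anh: np.ndarray
    dR: np.ndarray
    nuclei: np.ndarray
    label: str = ""
    #: expansion coefficients of dR in the vibrational modes (internal)
    mode_coefficients: np.ndarray = field(default=None, repr=False)

    @property
    def delta_total(self) -> np.ndarray:
        return self.delta_harm + self.delta_anh


@dataclass(frozen=True)
class IsotopeShiftReport:
    """Per-nucleus isotope shift nDdelta (ppb) and its decomposition."""

    nuclei: np.ndarray
    n_bonds: np.ndarray
    shift_harm: np.ndarray
    shift_anh: np.ndarray
    dR: np.ndarray  # isotope effect on the r_z geometry, bohr
    method: str = "vpt2"
    label: str = ""

    @property
    def shift(self) -> np.ndarray:
        return self.shift_harm + self.shift_anh

    def __post_init__(self):
        assert np.allclose(self.shift, self.shift_harm + self.shift_anh)


def vib_correction(
    modes: NormalModeSet,
    cubic: CubicField,
    prop: PropertySurface,
    label: str = "",
) -> VibCorrection:
    """Assemble the VPT2 zero-point corrections for one isotopologue.

    ``cubic`` must cover all vibrational modes in its displaced (k) index;
    ``prop`` must hold gradients/curvatures along the vibrational modes.
    """
    check_basis(modes, cubic)
    check_basis(modes, prop)
    vib_idx = np.flatnonzero(modes.kind_flags == "v")

    # map displaced-column index -> mode index
    col_of = {int(k): c for c, k in enumerate(cubic.displaced)}
    try:
        kcols = [col_of[int(i)] for i in vib_idx]
    except KeyError as exc:
        raise ValueError("cubic field is missing vibrational-mode data") from exc
    # PropertySurface columns follow the displace order used at build time;
    # here we require they were built over (at least) the vibrational modes
    if prop.grad.shape[1] == len(vib_idx):
        pcols = np.arange(len(vib_idx))
    elif prop.grad.shape[1] == modes.l_modes.shape[0]:
        pcols = vib_idx
    else:
        raise ValueError("property surface does not cover the vibrational modes")

    curv = prop.curv[:, pcols]  # (n_nuclei, n_vib)
    grad = prop.grad[:, pcols]

    delta_harm = -0.25 * curv.sum(axis=1)  # ppm

    # phi[i, k] for i, k vibrational
    phi = cubic.third_derivatives[np.ix_(vib_idx, kcols)]
    coeff = -0.25 / modes.omega * phi.sum(axis=1)  # <q_i>, dimensionless
    l_vib = modes.vib_modes()  # (n_vib, N, 3)
    dR = np.einsum("i,iax->ax", coeff, l_vib)

    # D sigma[dR] decomposed over the per-mode gradients (no extra calls)
    delta_anh = -(grad @ coeff)  # ppm

    return VibCorrection(
        delta_harm=delta_harm * PPM_TO_PPB,
        delta_anh=delta_anh * PPM_TO_PPB,
        dR=dR,
        nuclei=prop.nuclei.copy(),
        label=label,
        mode_coefficients=coeff,
    )


def standard_isotope_shift(
    corrA: VibCorrection,
    corrB: VibCorrection,
    system: MolecularSystem = None,
    substitution_atoms=None,
    method: str = "vpt2",
) -> IsotopeShiftReport:
    """Isotope shift nDdelta = Ddelta(B) - Ddelta(A) per reporting nucleus.

    ``n`` (the bond count to the substitution site) is assigned from the
    user-supplied topology when a system and substitution atoms are given;
    otherwise it is reported as -1.
    """
    if not np.array_equal(corrA.nuclei, corrB.nuclei):
        raise ValueError("mismatched reporting-nuclei sets")
    nuc = corrA.nuclei
    if system is not None and substitution_atoms:
        dist = topological_distances(system, substitution_atoms)
        n_bonds = np.array([int(dist[int(q)]) if np.isfinite(dist[int(q)]) else -1 for q in nuc])
    else:
        n_bonds = np.full(len(nuc), -1, dtype=int)
    return IsotopeShiftReport(
        nuclei=nuc.copy(),
        n_bonds=n_bonds,
        shift_harm=corrB.delta_harm - corrA.delta_harm,
        shift_anh=corrB.delta_anh - corrA.delta_anh,
        dR=corrB.dR - corrA.dR,
        method=method,
        label=f"{corrA.label}->{corrB.label}",
    )
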