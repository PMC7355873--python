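"""Job-file schema, Molden/XYZ export and tabular reports.

The job schema is a single versioned YAML document: diffable metadata
with (small) numeric arrays inline.  Unknown keys are rejected with their
location so typos never pass silently.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .constants import BOHR_TO_ANGSTROM
from .system import Isotopologue, MolecularSystem

__all__ = [
    "VibJob",
    "SchemaError",
    "read_job",
    "write_job",
    "write_molden",
    "read_molden",
    "write_xyz",
    "shift_table",
]

SCHEMA_VERSION = 1
METHODS = ("vpt2", "ddvpt2", "locvpt2", "lmzl", "lmzl_cent")

_DEFAULT_OPTIONS = {
    "h_ff": 0.005,  # dimensionless-coordinate step for the cubic field
    "h_nmr": 0.05,  # step for the shielding derivatives
    "cutoff": 1e-3,  # |kappa| threshold for retained DD modes
    "lambda_viz": 400.0,  # exaggeration factor for hole visualization
}


class SchemaError(ValueError):
    """Job-file violation, with a pointer to the offending key."""


@dataclass(frozen=True)
class VibJob:
    """A complete vibrational-averaging job."""

    system: MolecularSystem
    isoA: Isotopologue
    isoB: Isotopologue
    method: str = "ddvpt2"
    source: dict = field(default_factory=dict)  # fixture name/params or tabulated
    options: dict = field(default_factory=lambda: dict(_DEFAULT_OPTIONS))
    nuclei: tuple = ()
    outputs: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.method not in METHODS:
            raise SchemaError(f"/method: {self.method!r} not one of {METHODS}")
        opts = dict(_DEFAULT_OPTIONS)
        opts.update(self.options)
        object.__setattr__(self, "options", opts)


def _require(mapping: dict, key: str, where: str):
    if key not in mapping:
        raise SchemaError(f"{where}/{key}: missing required key")
    return mapping[key]


def _no_unknown(mapping: dict, allowed, where: str):
    for k in mapping:
        if k not in allowed:
            raise SchemaError(f"{where}/{k}: unknown key")


def job_to_dict(job: VibJob) -> dict:
    sy = job.system
    return {
        "schema_version": SCHEMA_VERSION,
        "system": {
            "atom_symbols": list(sy.atom_symbols),
            "coords_e_bohr": [[float(x) for x in row] for row in sy.coords_e],
            "bonds": [list(b) for b in sy.bonds],
        },
        "isotopologues": {
            "A": {"label": job.isoA.label, "masses_amu": [float(m) for m in job.isoA.masses]},
            "B": {"label": job.isoB.label, "masses_amu": [float(m) for m in job.isoB.masses]},
        },
        "method": job.method,
        "source": dict(job.source),
        "options": {k: float(v) for k, v in job.options.items()},
        "reporting_nuclei": [int(i) for i in job.nuclei],
        "outputs": dict(job.outputs),
    }


def job_from_dict(doc: dict) -> VibJob:
    if not isinstance(doc, dict):
        raise SchemaError("/: job document must be a mapping")
    _no_unknown(
        doc,
        {
            "schema_version",
            "system",
            "isotopologues",
            "method",
            "source",
            "options",
            "reporting_nuclei",
            "outputs",
        },
        "",
    )
    ver = _require(doc, "schema_version", "")
    if ver != SCHEMA_VERSION:
        raise SchemaError(f"/schema_version: unsupported version {ver}")
    sdoc = _require(doc, "system", "")
    _no_unknown(sdoc, {"atom_symbols", "coords_e_bohr", "bonds"}, "/system")
    system = MolecularSystem(
        tuple(_require(sdoc, "atom_symbols", "/system")),
        np.array(_require(sdoc, "coords_e_bohr", "/system"), dtype=float),
        bonds=tuple(tuple(b) for b in sdoc.get("bonds", [])),
    )
    idoc = _require(doc, "isotopologues", "")
    _no_unknown(idoc, {"A", "B"}, "/isotopologues")
    isos = {}
    for key in ("A", "B"):
        entry = _require(idoc, key, "/isotopologues")
        _no_unknown(entry, {"label", "masses_amu"}, f"/isotopologues/{key}")
        masses = np.array(_require(entry, "masses_amu", f"/isotopologues/{key}"), dtype=float)
        if len(masses) != system.n_atoms:
            raise SchemaError(f"/isotopologues/{key}/masses_amu: wrong length")
        if np.any(masses <= 0):
            raise SchemaError(f"/isotopologues/{key}/masses_amu: masses must be positive")
        isos[key] = Isotopologue(masses, label=entry.get("label", key))
    opts = doc.get("options", {})
    _no_unknown(opts, set(_DEFAULT_OPTIONS), "/options")
    return VibJob(
        system=system,
        isoA=isos["A"],
        isoB=isos["B"],
        method=doc.get("method", "ddvpt2"),
        source=doc.get("source", {}),
        options={k: float(v) for k, v in opts.items()},
        nuclei=tuple(int(i) for i in doc.get("reporting_nuclei", [])),
        outputs=doc.get("outputs", {}),
    )


def write_job(job: VibJob, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(job_to_dict(job), fh, sort_keys=False, default_flow_style=None)


def read_job(path) -> VibJob:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return job_from_dict(doc)


# ----------------------------------------------------------------------
# Molden / XYZ


def write_molden(modes_or_dd, system: MolecularSystem, path, kappa: np.ndarray = None) -> None:
    """Standard Molden frequency block.

    For a DD basis, pass kappa to annotate each mode; the pseudo-frequency
    column then numbers the modes (DD modes carry no frequency of their
    own) and kappa is written into comment lines.
    """
    obj = modes_or_dd
    if hasattr(obj, "kappa") and kappa is None:
        kappa = obj.kappa[obj.retained]
        l = obj.l_modes[obj.retained]
        freqs = np.arange(1.0, len(l) + 1.0)
    elif hasattr(obj, "omega"):
        keep = obj.kind_flags == "v"
        l = obj.l_modes[keep]
        freqs = obj.frequencies_invcm
    else:
        raise TypeError("expected a NormalModeSet or DDBasis")

    lines = ["[Molden Format]"]
    if kappa is not None:
        lines.append("; difference-dedicated modes; kappa per mode:")
        for i, k in enumerate(kappa):
            lines.append(f"; mode {i + 1}  kappa = {k: .8e}")
    lines.append("[FREQ]")
    lines += [f"{f:12.4f}" for f in freqs]
    lines.append("[FR-COORD]")
    for sym, xyz in zip(system.atom_symbols, system.coords_e):
        lines.append(f" {sym:4s} {xyz[0]:16.8f} {xyz[1]:16.8f} {xyz[2]:16.8f}")
    lines.append("[FR-NORM-COORD]")
    for i, mode in enumerate(l):
        lines.append(f"vibration {i + 1}")
        for xyz in mode:
            lines.append(f" {xyz[0]:16.8f} {xyz[1]:16.8f} {xyz[2]:16.8f}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_molden(path):
    """Re-parse a Molden frequency file written by write_molden.

    Returns (freqs, coords, modes) with coordinates/displacements in bohr.
    """
    freqs, coords, modes = [], [], []
    section = None
    current = None
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith(";"):
                continue
            up = line.upper()
            if up.startswith("["):
                section = up.strip("[]")
                continue
            if section == "FREQ":
                freqs.append(float(line))
            elif section == "FR-COORD":
                parts = line.split()
                coords.append([float(x) for x in parts[1:4]])
            elif section == "FR-NORM-COORD":
                if line.lower().startswith("vibration"):
                    current = []
                    modes.append(current)
                else:
                    current.append([float(x) for x in line.split()[:3]])
    return np.array(freqs), np.array(coords), np.array(modes)


def write_xyz(system: MolecularSystem, geometry, path, comment: str = "") -> None:
    """XYZ file (Angstrom) for visualization geometries such as R_e + lambda nDR."""
    geo = np.asarray(geometry, dtype=float) * BOHR_TO_ANGSTROM
    lines = [str(system.n_atoms), comment]
    for sym, xyz in zip(system.atom_symbols, geo):
        lines.append(f"{sym:4s} {xyz[0]:14.8f} {xyz[1]:14.8f} {xyz[2]:14.8f}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# ----------------------------------------------------------------------
# reports


def shift_table(reports, symbols=None) -> pd.DataFrame:
    """Method-by-nucleus shift matrix (ppb) from IsotopeShiftReports,
    with mean-signed and RMS deviation columns against the first report
    as the reference method."""
    reports = list(reports)
    ref = reports[0]
    rows = []
    for rep in reports:
        row = {"method": rep.method}
        for q, n, s in zip(rep.nuclei, rep.n_bonds, rep.shift):
            name = symbols[int(q)] if symbols is not None else str(int(q))
            row[f"{n}d({name}{int(q)})"] = s
        dev = rep.shift - ref.shift
        row["MSgD"] = dev.mean()
        row["RMS"] = np.sqrt((dev**2).mean())
        rows.append(row)
    return pd.DataFrame(rows)
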