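"""File formats: PLUMED-dialect COLVAR/HILLS tables, XYZ and PDB frames.

Unit conventions at the file boundary follow the PLUMED ecosystem: hill
heights and bias energies are written in kJ/mol and squared path distances
(z, sigma_z, z walls) in nm^2; everything is converted back to the internal
kcal/mol / A^2 system on read.  Round trips are loss-free to 1e-6.
"""

from __future__ import annotations

import math
from typing import Optional, Sequence

import numpy as np

from .units import A2_TO_NM2, KCAL_TO_KJ, KJ_TO_KCAL, NM2_TO_A2
from .wtmetad import ColvarSeries, HillRecord


class ParseError(ValueError):
    """Malformed input file; the message carries the offending line number."""


# ---------------------------------------------------------------------------
# generic PLUMED-style tables
# ---------------------------------------------------------------------------

def read_table(path) -> tuple:
    """Read a whitespace table with a ``#! FIELDS ...`` header.

    Returns ``(fields, columns)`` where ``columns`` maps each lower-cased
    field name to a float array; the original field spelling is preserved in
    ``fields``.  Additional ``#!`` metadata lines and comments are skipped.
    """
    fields = None
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if stripped.startswith("#!"):
                toks = stripped[2:].split()
                if toks and toks[0].upper() == "FIELDS":
                    fields = toks[1:]
                continue
            if stripped.startswith("#"):
                continue
            if fields is None:
                raise ParseError(
                    f"{path}: line {ln}: data before a '#! FIELDS' header"
                )
            vals = stripped.split()
            if len(vals) != len(fields):
                raise ParseError(
                    f"{path}: line {ln}: expected {len(fields)} columns, "
                    f"got {len(vals)}"
                )
            try:
                rows.append([float(v) for v in vals])
            except ValueError as exc:
                raise ParseError(f"{path}: line {ln}: {exc}") from None
    if fields is None:
        raise ParseError(f"{path}: missing '#! FIELDS' header")
    data = np.array(rows) if rows else np.empty((0, len(fields)))
    columns = {f.lower(): data[:, i] for i, f in enumerate(fields)}
    return fields, columns


def write_table(path, fields: Sequence[str], columns: Sequence[np.ndarray],
                fmt: str = "%.9g"):
    with open(path, "w") as fh:
        fh.write("#! FIELDS " + " ".join(fields) + "\n")
        for row in zip(*columns):
            fh.write(" ".join(fmt % v for v in row) + "\n")


# ---------------------------------------------------------------------------
# HILLS / COLVAR
# ---------------------------------------------------------------------------

def write_hills(path, hills: Sequence[HillRecord], bias_factor: float):
    """Write hills as ``time s z sigma_s sigma_z height biasf`` (height in
    kJ/mol, z and sigma_z in nm^2)."""
    write_table(
        path,
        ["time", "s", "z", "sigma_s", "sigma_z", "height", "biasf"],
        [
            np.array([h.time for h in hills]),
            np.array([h.center[0] for h in hills]),
            np.array([h.center[1] * A2_TO_NM2 for h in hills]),
            np.array([h.widths[0] for h in hills]),
            np.array([h.widths[1] * A2_TO_NM2 for h in hills]),
            np.array([h.height * KCAL_TO_KJ for h in hills]),
            np.full(len(hills), bias_factor),
        ],
    )


def read_hills(path) -> tuple:
    """Read a HILLS file; returns ``(hills, bias_factor)`` in internal units.
    Field names are matched case-insensitively."""
    fields, cols = read_table(path)
    required = ["time", "s", "z", "sigma_s", "sigma_z", "height"]
    for r in required:
        if r not in cols:
            raise ParseError(f"{path}: missing required field '{r}'")
    n = len(cols["time"])
    hills = [
        HillRecord(
            time=float(cols["time"][i]),
            center=(float(cols["s"][i]), float(cols["z"][i]) * NM2_TO_A2),
            widths=(float(cols["sigma_s"][i]),
                    float(cols["sigma_z"][i]) * NM2_TO_A2),
            height=float(cols["height"][i]) * KJ_TO_KCAL,
        )
        for i in range(n)
    ]
    biasf = float(cols["biasf"][0]) if "biasf" in cols and n else math.nan
    return hills, biasf


def write_colvar(path, colvar: ColvarSeries):
    """Write a CV series as ``time s z bias`` (z in nm^2, bias in kJ/mol)."""
    write_table(
        path,
        ["time", "s", "z", "bias"],
        [colvar.times, colvar.s, colvar.z * A2_TO_NM2,
         colvar.bias * KCAL_TO_KJ],
    )


def read_colvar(path) -> ColvarSeries:
    fields, cols = read_table(path)
    for r in ("time", "s", "z"):
        if r not in cols:
            raise ParseError(f"{path}: missing required field '{r}'")
    bias = cols.get("bias", np.zeros_like(cols["time"]))
    return ColvarSeries(
        times=cols["time"], s=cols["s"],
        z=cols["z"] * NM2_TO_A2, bias=bias * KJ_TO_KCAL,
    )


def write_work_profile(path, profile):
    """Write an SMD replica record as ``time cv center force work``
    (kcal/mol-based units, force in kcal/mol/A)."""
    write_table(
        path,
        ["time", "cv", "center", "force", "work"],
        [profile.times, profile.cv_values, profile.restraint_center,
         profile.pulling_force, profile.work],
    )


def read_work_profile(path):
    from .smd import WorkProfile

    fields, cols = read_table(path)
    for r in ("time", "cv", "center", "force", "work"):
        if r not in cols:
            raise ParseError(f"{path}: missing required field '{r}'")
    return WorkProfile(
        times=cols["time"], restraint_center=cols["center"],
        cv_values=cols["cv"], pulling_force=cols["force"], work=cols["work"],
    )


# ---------------------------------------------------------------------------
# frames: XYZ and PDB
# ---------------------------------------------------------------------------

#: map from bead role to an element symbol used in XYZ/PDB records
ROLE_ELEMENTS = {"host": "C", "gate": "N", "guest": "O"}


def write_xyz(path, frames: Sequence[np.ndarray], names: Sequence[str],
              comment: str = ""):
    """Write multi-frame XYZ; coordinates in A, full float precision."""
    frames = [np.asarray(f, dtype=float) for f in frames]
    with open(path, "w") as fh:
        for k, f in enumerate(frames):
            fh.write(f"{len(f)}\n{comment} frame {k}\n")
            for name, (x, y, z) in zip(names, f):
                fh.write(f"{name} {x:.10g} {y:.10g} {z:.10g}\n")


def read_xyz(path) -> tuple:
    """Read multi-frame XYZ; returns ``(frames, names)``."""
    frames, names = [], None
    with open(path) as fh:
        lines = fh.readlines()
    i, ln = 0, 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError:
            raise ParseError(f"{path}: line {i + 1}: expected atom count") from None
        if i + 1 + n >= len(lines) + 1:
            raise ParseError(f"{path}: line {i + 1}: truncated frame")
        block = lines[i + 2: i + 2 + n]
        coords, nms = [], []
        for j, row in enumerate(block):
            toks = row.split()
            if len(toks) < 4:
                raise ParseError(
                    f"{path}: line {i + 3 + j}: expected 'name x y z'"
                )
            nms.append(toks[0])
            try:
                coords.append([float(t) for t in toks[1:4]])
            except ValueError as exc:
                raise ParseError(f"{path}: line {i + 3 + j}: {exc}") from None
        frames.append(np.array(coords))
        names = nms
        i += 2 + n
    if not frames:
        raise ParseError(f"{path}: no frames found")
    return frames, names


def _bead_topology(names: Sequence[str]):
    import mdtraj as md
    from mdtraj.core import element as elem

    top = md.Topology()
    chain = top.add_chain()
    for i, name in enumerate(names):
        res = top.add_residue("BEA", chain)
        symbol = name[0].upper() if name[0].isalpha() else "C"
        try:
            el = elem.get_by_symbol(symbol)
        except KeyError:
            el = elem.carbon
        top.add_atom(f"{symbol}{i}", el, res)
    return top


def write_pdb(path, frames: Sequence[np.ndarray], names: Sequence[str]):
    """Write multi-frame PDB via mdtraj (coordinates to 1e-3 A)."""
    import mdtraj as md

    xyz = np.stack([np.asarray(f, dtype=float) for f in frames]) * 0.1  # A -> nm
    md.Trajectory(xyz, _bead_topology(names)).save_pdb(str(path))


def read_pdb(path) -> tuple:
    """Read a (multi-frame) PDB; returns ``(frames, names)`` in A."""
    import mdtraj as md

    tr = md.load_pdb(str(path))
    frames = [np.array(f, dtype=float) * 10.0 for f in tr.xyz]
    names = [a.name for a in tr.topology.atoms]
    return frames, names


def frame_names_for_system(system) -> list:
    """Atom names for a bead system's frames, element chosen by bead role."""
    return [ROLE_ELEMENTS.get(r, "C") for r in system.bead_roles()]
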