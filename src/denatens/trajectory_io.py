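"""Read and write protein structures, coordinate frames and report tables.

Supported structure dialects:

* PDB — single or multi-``MODEL``; coordinates converted from Å to nm on
  read. Element taken from columns 77–78 when present, otherwise inferred
  from the atom name.
* GRO — single block for topologies; concatenated blocks ("gro_sequence")
  for trajectories. A ``t=`` field on the title line is read as picoseconds
  (the GROMACS convention) and converted to ns.
* XTC — read-only, through mdtraj's low-level reader; requires an existing
  topology for atom metadata.

Reports are pandas DataFrames (or objects exposing ``to_dataframe``) written
as CSV/TSV/JSON with a deterministic column order and fixed float precision.
"""

from __future__ import annotations

import json
import re
import warnings
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .model import KNOWN_ELEMENTS, AtomRecord, Frame, Topology, Trajectory

STANDARD_RESIDUES = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL".split()
)

class ParseError(ValueError):
    """Malformed structure file; message carries the offending line number."""


def infer_element(atom_name: str, pdb_columns: str = "") -> str:
    """Infer the element class of an atom.

    Explicit PDB element columns win. Otherwise the leading letter of the
    stripped atom name decides, with digits skipped (``1HB`` is hydrogen).
    Only protein atom names are expected, so no two-character metal
    disambiguation is attempted (``CA`` is always Cα carbon, not calcium).
    Elements outside {C, N, O, S, H} collapse to ``"X"``; the surface-area
    partition only distinguishes {C, S} from {N, O}.
    """
    explicit = pdb_columns.strip().upper()
    if explicit:
        return explicit if explicit in KNOWN_ELEMENTS else "X"
    stripped = atom_name.strip().lstrip("0123456789")
    if not stripped:
        raise ValueError(f"cannot infer element from atom name {atom_name!r}")
    first = stripped[0].upper()
    return first if first in KNOWN_ELEMENTS else "X"


def _warn_unknown_residues(names: Iterable[str]) -> None:
    unknown = sorted({n for n in names if n not in STANDARD_RESIDUES})
    if unknown:
        warnings.warn(f"unknown residue name(s): {', '.join(unknown)}; atoms kept")


# ---------------------------------------------------------------------------
# PDB


def _parse_pdb_models(lines: list[str]):
    """Yield (atom_records, coords_nm) per model; single lists if no MODEL."""
    models: list[tuple[list, list]] = []
    atoms: list = []
    coords: list = []
    in_model = False
    seen_model_card = False
    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip("\r\n")
        rec = line[:6].strip()
        if rec == "MODEL":
            if atoms and not seen_model_card:
                # atoms before the first MODEL card: treat as model 0
                models.append((atoms, coords))
                atoms, coords = [], []
            seen_model_card = True
            in_model = True
            atoms, coords = [], []
        elif rec == "ENDMDL":
            in_model = False
            models.append((atoms, coords))
            atoms, coords = [], []
        elif rec in ("ATOM", "HETATM"):
            if len(line) < 54:
                raise ParseError(f"line {lineno}: truncated {rec} record")
            altloc = line[16]
            if altloc not in (" ", "A"):
                continue
            try:
                serial = int(line[6:11])
                x = float(line[30:38])
                y = float(line[38:46])
                z = float(line[46:54])
            except ValueError as exc:
                raise ParseError(f"line {lineno}: malformed {rec} record: {exc}") from exc
            name = line[12:16].strip()
            resname = line[17:20].strip()
            chain = line[21]
            resseq = line[22:27]  # includes insertion code
            element = infer_element(name, line[76:78] if len(line) >= 78 else "")
            atoms.append((serial, name, resname, chain, resseq, element))
            coords.append((x / 10.0, y / 10.0, z / 10.0))  # Å → nm
    if atoms:
        models.append((atoms, coords))
    if not models or not models[0][0]:
        raise ParseError("no ATOM records found (empty or non-PDB file)")
    return models


def _topology_from_pdb_atoms(atom_tuples) -> Topology:
    records: list[AtomRecord] = []
    residues: list[tuple[str, int, int]] = []
    prev_key = None
    start = 0
    chain_id = atom_tuples[0][3].strip() or "A"
    for i, (serial, name, resname, chain, resseq, element) in enumerate(atom_tuples):
        key = (chain, resseq)
        if key != prev_key:
            if prev_key is not None:
                residues.append((records[start].residue_name, start, i))
                start = i
            prev_key = key
        records.append(
            AtomRecord(
                atom_name=name,
                element=element,
                residue_index=len(residues),
                residue_name=resname,
                serial=serial,
            )
        )
    residues.append((records[start].residue_name, start, len(records)))
    _warn_unknown_residues(name for name, _, _ in residues)
    return Topology(atoms=records, residues=residues, chain_id=chain_id)


# ---------------------------------------------------------------------------
# GRO

_GRO_TIME_RE = re.compile(r"\bt=\s*([0-9.eE+-]+)")


def _parse_gro_blocks(lines: list[str]):
    """Yield (title, atom_tuples, coords_nm) per concatenated GRO block."""
    i = 0
    n_lines = len(lines)
    blocks = []
    while i < n_lines:
        if not lines[i].strip():
            i += 1
            continue
        title = lines[i].rstrip("\r\n")
        if i + 1 >= n_lines:
            raise ParseError(f"line {i + 1}: GRO block truncated (missing atom count)")
        try:
            n_atoms = int(lines[i + 1].strip())
        except ValueError as exc:
            raise ParseError(f"line {i + 2}: expected atom count, got {lines[i + 1]!r}") from exc
        if i + 2 + n_atoms + 1 > n_lines:
            raise ParseError(f"line {i + 1}: GRO block truncated (expected {n_atoms} atoms)")
        atoms = []
        coords = []
        for k in range(n_atoms):
            lineno = i + 3 + k
            line = lines[i + 2 + k].rstrip("\r\n")
            if len(line) < 44:
                raise ParseError(f"line {lineno}: truncated GRO atom line")
            try:
                resnum = int(line[0:5])
                resname = line[5:10].strip()
                name = line[10:15].strip()
                serial = int(line[15:20])
                x = float(line[20:28])
                y = float(line[28:36])
                z = float(line[36:44])
            except ValueError as exc:
                raise ParseError(f"line {lineno}: malformed GRO atom line: {exc}") from exc
            atoms.append((serial, name, resname, resnum))
            coords.append((x, y, z))
        i = i + 2 + n_atoms + 1  # skip box vector line
        blocks.append((title, atoms, coords))
    if not blocks:
        raise ParseError("empty GRO file")
    return blocks


def _topology_from_gro_atoms(atom_tuples) -> Topology:
    records: list[AtomRecord] = []
    residues: list[tuple[str, int, int]] = []
    prev_key = None
    start = 0
    for i, (serial, name, resname, resnum) in enumerate(atom_tuples):
        if resnum != prev_key:
            if prev_key is not None:
                residues.append((records[start].residue_name, start, i))
                start = i
            prev_key = resnum
        records.append(
            AtomRecord(
                atom_name=name,
                element=infer_element(name),
                residue_index=len(residues),
                residue_name=resname,
                serial=serial,
            )
        )
    residues.append((records[start].residue_name, start, len(records)))
    _warn_unknown_residues(name for name, _, _ in residues)
    return Topology(atoms=records, residues=residues, chain_id="A")


# ---------------------------------------------------------------------------
# Public API


def read_topology(path, format: str = "pdb") -> Topology:
    """Parse atom/residue metadata from the first model of a PDB or GRO file."""
    lines = Path(path).read_text().splitlines()
    if format == "pdb":
        models = _parse_pdb_models(lines)
        return _topology_from_pdb_atoms(models[0][0])
    if format == "gro":
        blocks = _parse_gro_blocks(lines)
        return _topology_from_gro_atoms(blocks[0][1])
    raise ValueError(f"unknown topology format {format!r}")


def read_trajectory(
    topology: Topology,
    path,
    format: str = "multi_model_pdb",
    stride_ns: float = 0.4,
    t0_ns: float = 0.0,
) -> Trajectory:
    """Read coordinate frames against a fixed topology.

    Frame times come from file metadata when present (GRO ``t=`` fields,
    XTC timestamps); otherwise they are synthesized as ``t0 + k*stride``.
    An atom-count mismatch against the topology is a hard error.
    """
    n = topology.n_atoms
    frames: list[Frame] = []
    if format == "multi_model_pdb":
        models = _parse_pdb_models(Path(path).read_text().splitlines())
        for k, (atoms, coords) in enumerate(models):
            if len(atoms) != n:
                raise ValueError(
                    f"model {k + 1} has {len(atoms)} atoms, topology has {n}"
                )
            frames.append(Frame(time_ns=t0_ns + k * stride_ns, coords=np.array(coords)))
    elif format == "gro_sequence":
        blocks = _parse_gro_blocks(Path(path).read_text().splitlines())
        times = []
        for title, atoms, _ in blocks:
            m = _GRO_TIME_RE.search(title)
            times.append(float(m.group(1)) / 1000.0 if m else None)  # ps → ns
        use_meta = all(t is not None for t in times)
        for k, (title, atoms, coords) in enumerate(blocks):
            if len(atoms) != n:
                raise ValueError(
                    f"GRO block {k + 1} has {len(atoms)} atoms, topology has {n}"
                )
            t = times[k] if use_meta else t0_ns + k * stride_ns
            frames.append(Frame(time_ns=t, coords=np.array(coords)))
    elif format == "xtc":
        from mdtraj.formats import XTCTrajectoryFile

        with XTCTrajectoryFile(str(path)) as fh:
            xyz, times_ps, _, _ = fh.read()
        if xyz.shape[1] != n:
            raise ValueError(f"XTC has {xyz.shape[1]} atoms, topology has {n}")
        for k in range(xyz.shape[0]):
            frames.append(Frame(time_ns=float(times_ps[k]) / 1000.0, coords=xyz[k].astype(np.float64)))
    else:
        raise ValueError(f"unknown trajectory format {format!r}")
    return Trajectory(topology=topology, frames=frames)


def write_trajectory(traj: Trajectory, path, format: str = "multi_model_pdb") -> None:
    """Write frames as a multi-MODEL PDB or a concatenated GRO sequence."""
    top = traj.topology
    out = []
    if format == "multi_model_pdb":
        for k, fr in enumerate(traj.frames, start=1):
            out.append(f"MODEL     {k:4d}")
            for i, atom in enumerate(top.atoms):
                x, y, z = fr.coords[i] * 10.0  # nm → Å
                name = atom.atom_name
                # PDB convention: 1-letter elements start in column 14
                field = name.ljust(4) if len(name) >= 4 or name[:1].isdigit() else f" {name}".ljust(4)
                elem = atom.element if atom.element != "X" else "  "
                out.append(
                    f"ATOM  {i + 1:5d} {field} {atom.residue_name:<3s} {top.chain_id[:1] or 'A'}"
                    f"{atom.residue_index + 1:4d}    {x:8.3f}{y:8.3f}{z:8.3f}"
                    f"  1.00  0.00          {elem:>2s}"
                )
            out.append("ENDMDL")
        out.append("END")
    elif format == "gro_sequence":
        for fr in traj.frames:
            out.append(f"frame t= {fr.time_ns * 1000.0:.4f}")
            out.append(f"{top.n_atoms:5d}")
            for i, atom in enumerate(top.atoms):
                x, y, z = fr.coords[i]
                out.append(
                    f"{atom.residue_index + 1:5d}{atom.residue_name:<5s}"
                    f"{atom.atom_name:>5s}{(i + 1) % 100000:5d}"
                    f"{x:8.3f}{y:8.3f}{z:8.3f}"
                )
            out.append("   0.00000   0.00000   0.00000")
    else:
        raise ValueError(f"unknown trajectory format {format!r}")
    Path(path).write_text("\n".join(out) + "\n")


def _as_dataframe(report) -> pd.DataFrame:
    if isinstance(report, pd.DataFrame):
        return report
    if hasattr(report, "to_dataframe"):
        return report.to_dataframe()
    raise TypeError(f"cannot tabulate object of type {type(report).__name__}")


def write_table(report, path, format: str = "csv", float_precision: int = 4) -> None:
    """Write a tabular report as CSV, TSV or JSON records.

    Column order follows the DataFrame; floats are rounded to a fixed
    precision so repeated runs produce byte-identical files.
    """
    df = _as_dataframe(report)
    if df.empty:
        raise ValueError("refusing to write an empty report")
    df = df.round(float_precision)
    path = Path(path)
    if format == "csv":
        df.to_csv(path, index=False, float_format=f"%.{float_precision}f")
    elif format == "tsv":
        df.to_csv(path, index=False, sep="\t", float_format=f"%.{float_precision}f")
    elif format == "json":
        records = json.loads(df.to_json(orient="records"))
        path.write_text(json.dumps(records, indent=1, sort_keys=False) + "\n")
    else:
        raise ValueError(f"unknown table format {format!r}")


def read_table(path, format: str = "csv") -> pd.DataFrame:
    path = Path(path)
    if format == "csv":
        return pd.read_csv(path)
    if format == "tsv":
        return pd.read_csv(path, sep="\t")
    if format == "json":
        return pd.DataFrame(json.loads(path.read_text()))
    raise ValueError(f"unknown table format {format!r}")
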