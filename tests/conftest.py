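import numpy as np
import pytest

from denatens.model import AtomRecord, Frame, Topology, Trajectory

# A 3-residue Ala-Glu-Lys peptide in PDB form: enough to exercise residue
# grouping, element inference and the salt-bridge criterion atoms (Glu CD,
# Lys CE). Coordinates are arbitrary but fixed.
TOY_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       2.000   1.400   0.000  1.00  0.00           C
ATOM      4  O   ALA A   1       1.300   2.400   0.000  1.00  0.00           O
ATOM      5  CB  ALA A   1       2.000  -1.000   1.000  1.00  0.00           C
ATOM      6  N   GLU A   2       3.300   1.500   0.000  1.00  0.00           N
ATOM      7  CA  GLU A   2       4.100   2.700   0.000  1.00  0.00           C
ATOM      8  C   GLU A   2       5.600   2.500   0.000  1.00  0.00           C
ATOM      9  O   GLU A   2       6.100   1.400   0.000  1.00  0.00           O
ATOM     10  CB  GLU A   2       3.700   3.600   1.200  1.00  0.00           C
ATOM     11  CG  GLU A   2       4.300   5.000   1.300  1.00  0.00           C
ATOM     12  CD  GLU A   2       3.900   5.800   2.500  1.00  0.00           C
ATOM     13  N   LYS A   3       6.300   3.600   0.100  1.00  0.00           N
ATOM     14  CA  LYS A   3       7.800   3.600   0.100  1.00  0.00           C
ATOM     15  C   LYS A   3       8.300   5.000   0.200  1.00  0.00           C
ATOM     16  O   LYS A   3       7.500   5.900   0.300  1.00  0.00           O
ATOM     17  CB  LYS A   3       8.400   2.800   1.300  1.00  0.00           C
ATOM     18  CG  LYS A   3       8.000   1.300   1.300  1.00  0.00           C
ATOM     19  CD  LYS A   3       8.600   0.500   2.500  1.00  0.00           C
ATOM     20  CE  LYS A   3       8.200  -1.000   2.500  1.00  0.00           C
END
"""


def toy_gro_text() -> str:
    """The same toy peptide as a GRO block (coordinates in nm)."""
    lines = ["toy peptide", "   20"]
    names = [
        (1, "ALA", ["N", "CA", "C", "O", "CB"]),
        (2, "GLU", ["N", "CA", "C", "O", "CB", "CG", "CD"]),
        (3, "LYS", ["N", "CA", "C", "O", "CB", "CG", "CD", "CE"]),
    ]
    coords_a = [
        l.split()[6:9] for l in TOY_PDB.splitlines() if l.startswith("ATOM")
    ]
    serial = 0
    flat = []
    for resnum, resname, atom_names in names:
        for nm in atom_names:
            x, y, z = (float(v) / 10.0 for v in coords_a[serial])
            serial += 1
            flat.append(f"{resnum:5d}{resname:<5s}{nm:>5s}{serial:5d}{x:8.3f}{y:8.3f}{z:8.3f}")
    lines.extend(flat)
    lines.append("   0.00000   0.00000   0.00000")
    return "\n".join(lines) + "\n"


@pytest.fixture
def toy_pdb(tmp_path):
    p = tmp_path / "toy.pdb"
    p.write_text(TOY_PDB)
    return p


@pytest.fixture
def toy_gro(tmp_path):
    p = tmp_path / "toy.gro"
    p.write_text(toy_gro_text())
    return p


def single_atom_topology(element: str = "C", atom_name: str = "CA") -> Topology:
    return Topology(
        atoms=[AtomRecord(atom_name=atom_name, element=element, residue_index=0,
                          residue_name="ALA", serial=1)],
        residues=[("ALA", 0, 1)],
    )


def point_topology(elements: list[str], residue_name: str = "ALA") -> Topology:
    """One residue holding one atom per element; for geometric fixtures."""
    atoms = [
        AtomRecord(atom_name=f"{el}{i}" if el != "H" else "H", element=el,
                   residue_index=i, residue_name=residue_name, serial=i + 1)
        for i, el in enumerate(elements)
    ]
    residues = [(residue_name, i, i + 1) for i in range(len(elements))]
    return Topology(atoms=atoms, residues=residues)


def calpha_topology(n: int) -> Topology:
    """n residues of one CA atom each."""
    atoms = [
        AtomRecord(atom_name="CA", element="C", residue_index=i,
                   residue_name="ALA", serial=i + 1)
        for i in range(n)
    ]
    return Topology(atoms=atoms, residues=[("ALA", i, i + 1) for i in range(n)])


def make_trajectory(topology: Topology, coord_list, dt_ns: float = 0.4) -> Trajectory:
    frames = [
        Frame(time_ns=k * dt_ns, coords=np.asarray(c, dtype=float))
        for k, c in enumerate(coord_list)
    ]
    return Trajectory(topology=topology, frames=frames)
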