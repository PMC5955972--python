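"""Internal data model shared by all analysis stages.

Coordinates are stored in nanometres and times in nanoseconds throughout.
Residue indices are 0-based internally; user-facing reports convert to
1-based numbering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Elements the analyses distinguish. Anything else maps to "X" (other).
KNOWN_ELEMENTS = frozenset({"C", "N", "O", "S", "H"})

#: Standard atomic masses (u) used for mass-weighted observables.
ATOMIC_MASSES = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "S": 32.06,
    "X": 0.0,
}


@dataclass(frozen=True)
class AtomRecord:
    """A single atom: name, inferred element and residue membership."""

    atom_name: str
    element: str
    residue_index: int
    residue_name: str
    serial: int

    def __post_init__(self) -> None:
        if self.element not in KNOWN_ELEMENTS and self.element != "X":
            raise ValueError(f"unknown element {self.element!r} for atom {self.atom_name!r}")

    @property
    def is_hydrogen(self) -> bool:
        return self.element == "H"


@dataclass
class Topology:
    """Static atom/residue metadata shared by all frames of a trajectory."""

    atoms: list[AtomRecord]
    residues: list[tuple[str, int, int]]  # (residue_name, first atom index, one-past-last)
    chain_id: str = "A"

    def __post_init__(self) -> None:
        # residue atom ranges must partition the atom list
        cursor = 0
        for name, start, stop in self.residues:
            if start != cursor or stop <= start:
                raise ValueError("residue atom ranges do not partition the atom list")
            cursor = stop
        if cursor != len(self.atoms):
            raise ValueError("residue atom ranges do not cover all atoms")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_residues(self) -> int:
        return len(self.residues)

    @property
    def elements(self) -> np.ndarray:
        return np.array([a.element for a in self.atoms], dtype="U1")

    @property
    def masses(self) -> np.ndarray:
        return np.array([ATOMIC_MASSES[a.element] for a in self.atoms])

    @property
    def heavy_mask(self) -> np.ndarray:
        return np.array([not a.is_hydrogen for a in self.atoms])

    def residue_name(self, residue_index: int) -> str:
        return self.residues[residue_index][0]

    def residue_atom_indices(self, residue_index: int) -> range:
        _, start, stop = self.residues[residue_index]
        return range(start, stop)

    def atom_index(self, residue_index: int, atom_name: str) -> int:
        """Index of the named atom within the given residue.

        Raises KeyError naming both residue and atom when absent.
        """
        for i in self.residue_atom_indices(residue_index):
            if self.atoms[i].atom_name == atom_name:
                return i
        name = self.residue_name(residue_index)
        raise KeyError(
            f"residue {name}{residue_index + 1} has no atom {atom_name!r}"
        )

    def has_atom(self, residue_index: int, atom_name: str) -> bool:
        try:
            self.atom_index(residue_index, atom_name)
            return True
        except KeyError:
            return False

    def select(self, which: str = "calpha") -> np.ndarray:
        """Atom indices for a named selection: 'calpha', 'heavy' or 'all'."""
        if which == "calpha":
            idx = [i for i, a in enumerate(self.atoms) if a.atom_name == "CA"]
        elif which == "heavy":
            idx = [i for i, a in enumerate(self.atoms) if not a.is_hydrogen]
        elif which == "all":
            idx = list(range(self.n_atoms))
        else:
            raise ValueError(f"unknown selection {which!r}")
        if not idx:
            raise ValueError(f"selection {which!r} matches no atoms")
        return np.asarray(idx, dtype=np.intp)


@dataclass
class Frame:
    """One snapshot: a timestamp (ns) and per-atom coordinates (nm)."""

    time_ns: float
    coords: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.float64)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must have shape (n_atoms, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        if self.time_ns < 0:
            raise ValueError("time_ns must be non-negative")


@dataclass
class Trajectory:
    """A topology plus a strictly time-ordered sequence of frames."""

    topology: Topology
    frames: list[Frame] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("trajectory must contain at least one frame")
        n = self.topology.n_atoms
        for k, fr in enumerate(self.frames):
            if fr.coords.shape[0] != n:
                raise ValueError(
                    f"frame {k} has {fr.coords.shape[0]} atoms, topology has {n}"
                )
        times = self.times
        if np.any(np.diff(times) <= 0):
            raise ValueError("frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def times(self) -> np.ndarray:
        return np.array([fr.time_ns for fr in self.frames])

    @property
    def coords(self) -> np.ndarray:
        """Stacked coordinates, shape (n_frames, n_atoms, 3)."""
        return np.stack([fr.coords for fr in self.frames])

    def window_indices(self, t0_ns: float, t1_ns: float) -> np.ndarray:
        """Frame indices with t0 <= t < t1 (half-open window)."""
        times = self.times
        mask = (times >= t0_ns) & (times < t1_ns)
        return np.nonzero(mask)[0]
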