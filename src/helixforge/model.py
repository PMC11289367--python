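"""Core domain types: atomic models and density maps.

An :class:`AtomicModel` is a flat, ordered table of atoms backed by parallel
numpy arrays; all geometric analyses in this package operate on it.  A
:class:`DensityMap` is a 3D scalar grid in canonical (x, y, z) axis order with
a physical voxel size and a world-space origin.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np

__all__ = ["AtomicModel", "DensityMap", "ATOMIC_NUMBERS"]

#: Atomic numbers for the elements that occur in the models this package
#: handles (proteins, nucleotides, common ions/waters).
ATOMIC_NUMBERS = {
    "H": 1, "BE": 4, "C": 6, "N": 7, "O": 8, "F": 9, "NA": 11, "MG": 12,
    "P": 15, "S": 16, "CL": 17, "K": 19, "CA": 20, "MN": 25, "FE": 26,
    "ZN": 30, "SE": 34,
}


@dataclass
class AtomicModel:
    """Ordered table of atoms.

    All per-atom annotations are parallel numpy arrays of equal length.
    ``coords`` is an (n, 3) float array in Å.  Order is meaningful and
    preserved through I/O round-trips.
    """

    chain_id: np.ndarray
    residue_number: np.ndarray
    residue_name: np.ndarray
    atom_name: np.ndarray
    element: np.ndarray
    coords: np.ndarray
    b_factor: np.ndarray
    occupancy: np.ndarray
    hetero: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        n = len(self.coords)
        self.chain_id = np.asarray(self.chain_id, dtype="U4")
        self.residue_number = np.asarray(self.residue_number, dtype=np.int64)
        self.residue_name = np.asarray(self.residue_name, dtype="U5")
        self.atom_name = np.asarray(self.atom_name, dtype="U6")
        self.element = np.char.upper(np.asarray(self.element, dtype="U2"))
        self.coords = np.asarray(self.coords, dtype=np.float64).reshape(n, 3)
        self.b_factor = np.asarray(self.b_factor, dtype=np.float64)
        self.occupancy = np.asarray(self.occupancy, dtype=np.float64)
        if self.hetero is None:
            self.hetero = np.zeros(n, dtype=bool)
        self.hetero = np.asarray(self.hetero, dtype=bool)
        for arr in (self.chain_id, self.residue_number, self.residue_name,
                    self.atom_name, self.element, self.b_factor,
                    self.occupancy, self.hetero):
            if len(arr) != n:
                raise ValueError("annotation arrays must have equal length")

    # -- container protocol ------------------------------------------------

    def __len__(self) -> int:
        return len(self.coords)

    def __getitem__(self, index) -> "AtomicModel":
        if np.isscalar(index) or isinstance(index, (int, np.integer)):
            index = [index]
        return AtomicModel(
            self.chain_id[index], self.residue_number[index],
            self.residue_name[index], self.atom_name[index],
            self.element[index], self.coords[index],
            self.b_factor[index], self.occupancy[index], self.hetero[index],
        )

    # -- validation --------------------------------------------------------

    def validate(self) -> None:
        """Raise ``ValueError`` if any type invariant is violated."""
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")
        if np.any(self.b_factor < 0):
            raise ValueError("negative b_factor")
        if np.any((self.occupancy < 0) | (self.occupancy > 1)):
            raise ValueError("occupancy outside [0, 1]")
        keys = list(zip(self.chain_id, self.residue_number, self.atom_name))
        if len(set(keys)) != len(keys):
            raise ValueError("(chain, residue, atom name) triples not unique")

    # -- selection helpers -------------------------------------------------

    @property
    def chains(self) -> list[str]:
        """Chain identifiers in first-appearance order."""
        seen: dict[str, None] = {}
        for c in self.chain_id:
            seen.setdefault(str(c))
        return list(seen)

    def select(self, *, chain: str | None = None,
               residue: int | None = None,
               atom: str | Sequence[str] | None = None,
               element: str | Sequence[str] | None = None) -> "AtomicModel":
        mask = np.ones(len(self), dtype=bool)
        if chain is not None:
            mask &= self.chain_id == chain
        if residue is not None:
            mask &= self.residue_number == residue
        if atom is not None:
            names = [atom] if isinstance(atom, str) else list(atom)
            mask &= np.isin(self.atom_name, names)
        if element is not None:
            elems = [element] if isinstance(element, str) else list(element)
            mask &= np.isin(self.element, [e.upper() for e in elems])
        return self[mask]

    def atom_position(self, chain: str, residue: int, atom: str) -> np.ndarray:
        """Coordinates of a single named atom; raises ``KeyError`` if absent."""
        sub = self.select(chain=chain, residue=residue, atom=atom)
        if len(sub) == 0:
            raise KeyError(f"atom {chain}/{residue}/{atom} not found")
        return sub.coords[0]

    def ca_coords(self, chain: str | None = None) -> np.ndarray:
        sub = self.select(chain=chain, atom="CA")
        return sub.coords

    def residues(self) -> Iterator[tuple[str, int, "AtomicModel"]]:
        """Iterate over (chain_id, residue_number, residue atoms) in order."""
        if len(self) == 0:
            return
        keys = np.array([f"{c}|{r}" for c, r in
                         zip(self.chain_id, self.residue_number)])
        change = np.concatenate(([True], keys[1:] != keys[:-1]))
        starts = np.flatnonzero(change)
        bounds = np.append(starts, len(self))
        for s, e in zip(bounds[:-1], bounds[1:]):
            yield (str(self.chain_id[s]), int(self.residue_number[s]),
                   self[np.arange(s, e)])

    # -- transforms --------------------------------------------------------

    def transformed(self, rotation: np.ndarray,
                    translation: np.ndarray) -> "AtomicModel":
        """Return a copy with coordinates mapped to ``R x + t``."""
        out = self.copy()
        out.coords = self.coords @ np.asarray(rotation).T + np.asarray(translation)
        return out

    def translated(self, shift: np.ndarray) -> "AtomicModel":
        return self.transformed(np.eye(3), shift)

    def copy(self) -> "AtomicModel":
        return AtomicModel(*(a.copy() for a in (
            self.chain_id, self.residue_number, self.residue_name,
            self.atom_name, self.element, self.coords, self.b_factor,
            self.occupancy, self.hetero)))

    def with_chain_id(self, chain: str) -> "AtomicModel":
        out = self.copy()
        out.chain_id = np.full(len(out), chain, dtype="U4")
        return out

    @staticmethod
    def concatenate(models: Iterable["AtomicModel"]) -> "AtomicModel":
        models = list(models)
        if not models:
            raise ValueError("nothing to concatenate")
        return AtomicModel(*(np.concatenate([getattr(m, f) for m in models])
                             for f in ("chain_id", "residue_number",
                                       "residue_name", "atom_name", "element",
                                       "coords", "b_factor", "occupancy",
                                       "hetero")))

    def atomic_numbers(self) -> np.ndarray:
        return np.array([ATOMIC_NUMBERS.get(str(e), 6) for e in self.element],
                        dtype=np.float64)


@dataclass
class DensityMap:
    """3D scalar density grid.

    ``grid`` is indexed ``[ix, iy, iz]`` (canonical x, y, z order); the world
    coordinate of index (i, j, k) is ``origin + (i, j, k) * voxel_size``.
    """

    grid: np.ndarray
    voxel_size: np.ndarray
    origin: np.ndarray

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=np.float64)
        if self.grid.ndim != 3:
            raise ValueError("grid must be 3-dimensional")
        vs = np.asarray(self.voxel_size, dtype=np.float64)
        self.voxel_size = np.full(3, vs) if vs.ndim == 0 else vs.reshape(3)
        if np.any(self.voxel_size <= 0):
            raise ValueError("voxel sizes must be positive")
        self.origin = np.asarray(self.origin, dtype=np.float64).reshape(3)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.grid.shape  # type: ignore[return-value]

    def copy_with(self, grid: np.ndarray) -> "DensityMap":
        return DensityMap(grid, self.voxel_size.copy(), self.origin.copy())

    def index_to_world(self, ijk: np.ndarray) -> np.ndarray:
        return self.origin + np.asarray(ijk, dtype=np.float64) * self.voxel_size

    def world_to_index(self, xyz: np.ndarray) -> np.ndarray:
        """Fractional grid index of a world-space point."""
        return (np.asarray(xyz, dtype=np.float64) - self.origin) / self.voxel_size

    def voxel_volume(self) -> float:
        return float(np.prod(self.voxel_size))

    def integral(self) -> float:
        """Integral of the density over the grid (sum × voxel volume)."""
        return float(self.grid.sum() * self.voxel_volume())
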