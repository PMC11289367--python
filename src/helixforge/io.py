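"""Model and map input/output plus map sampling and synthesis.

PDB / mmCIF parsing is delegated to :mod:`biotite`; MRC2014 maps go through
:mod:`mrcfile`.  Grids are normalized to canonical (x, y, z) axis order on
read regardless of the file's mapc/mapr/maps permutation.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np

from .model import AtomicModel, DensityMap

__all__ = [
    "read_model", "write_model", "read_map", "write_map",
    "interpolate_map", "model_to_map", "EmptyModelError", "OutOfBoundsError",
]


class EmptyModelError(ValueError):
    """Raised when a structure file yields no atoms."""


class OutOfBoundsError(ValueError):
    """Raised when a sample point falls outside the map bounding box."""


# ---------------------------------------------------------------------------
# Atomic models
# ---------------------------------------------------------------------------

def _detect_format(path: str | Path) -> str:
    suffix = Path(path).suffix.lower()
    if suffix in (".cif", ".mmcif", ".pdbx"):
        return "mmcif"
    return "pdb"


def _from_atom_array(arr) -> AtomicModel:
    return AtomicModel(
        chain_id=arr.chain_id,
        residue_number=arr.res_id,
        residue_name=arr.res_name,
        atom_name=arr.atom_name,
        element=arr.element,
        coords=np.asarray(arr.coord, dtype=np.float64),
        b_factor=arr.b_factor if "b_factor" in arr.get_annotation_categories()
        else np.zeros(arr.array_length()),
        occupancy=arr.occupancy if "occupancy" in arr.get_annotation_categories()
        else np.ones(arr.array_length()),
        hetero=arr.hetero,
    )


def _to_atom_array(model: AtomicModel):
    import biotite.structure as struc

    arr = struc.AtomArray(len(model))
    arr.chain_id = model.chain_id.astype("U4")
    arr.res_id = model.residue_number
    arr.res_name = model.residue_name.astype("U5")
    arr.atom_name = model.atom_name.astype("U6")
    # biotite capitalizes written elements itself; store canonical upper-case
    arr.element = model.element
    arr.coord = model.coords.astype(np.float32)
    arr.hetero = model.hetero
    arr.set_annotation("b_factor", model.b_factor)
    arr.set_annotation("occupancy", model.occupancy)
    return arr


def read_model(path: str | Path, format: str = "auto") -> AtomicModel:
    """Read an atomic model from a PDB or mmCIF file.

    HETATM records (ions, waters, ligands) are retained with their element
    field populated; chain and residue order is preserved.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if format == "auto":
        format = _detect_format(path)
    if format == "pdb":
        from biotite.structure.io.pdb import PDBFile
        f = PDBFile.read(str(path))
        arr = f.get_structure(model=1, extra_fields=["b_factor", "occupancy"])
    elif format == "mmcif":
        from biotite.structure.io.pdbx import CIFFile, get_structure
        f = CIFFile.read(str(path))
        arr = get_structure(f, model=1, extra_fields=["b_factor", "occupancy"])
    else:
        raise ValueError(f"unknown model format: {format!r}")
    if arr.array_length() == 0:
        raise EmptyModelError(f"no atoms parsed from {path}")
    return _from_atom_array(arr)


def write_model(model: AtomicModel, path: str | Path,
                format: str = "auto") -> None:
    """Write an atomic model as PDB (fixed-column v3.3) or mmCIF.

    PDB format cannot represent residue numbers above 9999 or more than
    99999 atoms; such models must be written as mmCIF.
    """
    if len(model) == 0:
        raise EmptyModelError("refusing to write an empty model")
    if format == "auto":
        format = _detect_format(path)
    if format == "pdb":
        if np.any(model.residue_number > 9999) or len(model) > 99999:
            raise ValueError(
                "model exceeds fixed-column PDB limits; write mmCIF instead")
        from biotite.structure.io.pdb import PDBFile
        f = PDBFile()
        f.set_structure(_to_atom_array(model))
        f.write(str(path))
    elif format == "mmcif":
        from biotite.structure.io.pdbx import CIFFile, set_structure
        f = CIFFile()
        set_structure(f, _to_atom_array(model))
        f.write(str(path))
    else:
        raise ValueError(f"unknown model format: {format!r}")


# ---------------------------------------------------------------------------
# Density maps
# ---------------------------------------------------------------------------

def read_map(path: str | Path, origin_mode: str = "auto") -> DensityMap:
    """Read an MRC2014 / CCP4 map into canonical x, y, z axis order.

    ``origin_mode`` controls how the world origin is derived:

    - ``"auto"`` (default): use the ORIGIN header record if any component is
      nonzero, otherwise fall back to nstart × voxel size.  Both dialects
      occur in public depositions.
    - ``"origin"`` / ``"nstart"``: force one convention.
    """
    import mrcfile

    with mrcfile.open(str(path), permissive=False) as mrc:
        header = mrc.header
        data = np.asarray(mrc.data, dtype=np.float64)
        vs = mrc.voxel_size
        voxel = np.array([vs.x, vs.y, vs.z], dtype=np.float64)
        mapc, mapr, maps = (int(header.mapc), int(header.mapr),
                            int(header.maps))
        # data axes are (sections, rows, columns) -> crystal axes
        # (maps-1, mapr-1, mapc-1); transpose into x, y, z order
        perm = np.empty(3, dtype=int)
        perm[[maps - 1, mapr - 1, mapc - 1]] = [0, 1, 2]
        grid = np.transpose(data, axes=perm)
        nstart_axis = np.empty(3, dtype=np.float64)
        nstart_axis[[mapc - 1, mapr - 1, maps - 1]] = [
            float(header.nxstart), float(header.nystart), float(header.nzstart)]
        origin_rec = np.array([float(header.origin.x),
                               float(header.origin.y),
                               float(header.origin.z)])
        if origin_mode == "origin":
            origin = origin_rec
        elif origin_mode == "nstart":
            origin = nstart_axis * voxel
        elif origin_mode == "auto":
            origin = origin_rec if np.any(origin_rec != 0) \
                else nstart_axis * voxel
        else:
            raise ValueError(f"unknown origin_mode: {origin_mode!r}")
    return DensityMap(grid, voxel, origin)


def write_map(density: DensityMap, path: str | Path) -> None:
    """Write an MRC2014 map (canonical axis order, origin record set)."""
    import mrcfile

    with mrcfile.new(str(path), overwrite=True) as mrc:
        mrc.set_data(np.ascontiguousarray(
            np.transpose(density.grid, (2, 1, 0)).astype(np.float32)))
        mrc.voxel_size = tuple(density.voxel_size)
        mrc.header.origin = tuple(density.origin)
        mrc.update_header_stats()


# ---------------------------------------------------------------------------
# Map sampling and synthesis
# ---------------------------------------------------------------------------

def interpolate_map(density: DensityMap, points: np.ndarray,
                    outside: str = "raise") -> np.ndarray | float:
    """Trilinear interpolation of the map at one or more world-space points.

    ``outside`` selects the out-of-bounds behaviour: ``"raise"`` (default)
    raises :class:`OutOfBoundsError`, ``"nan"`` yields NaN for offending
    points.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
    frac = density.world_to_index(pts)
    shape = np.array(density.shape)
    oob = np.any((frac < 0) | (frac > shape - 1), axis=1)
    if np.any(oob):
        if outside == "raise":
            raise OutOfBoundsError(
                f"{int(oob.sum())} point(s) outside map bounding box")
        if outside != "nan":
            raise ValueError(f"unknown outside mode: {outside!r}")
    frac_c = np.clip(frac, 0, shape - 1)
    i0 = np.minimum(np.floor(frac_c).astype(int), shape - 2)
    i0 = np.maximum(i0, 0)
    f = frac_c - i0
    g = density.grid
    out = np.zeros(len(pts))
    for dx in (0, 1):
        for dy in (0, 1):
            for dz in (0, 1):
                w = (np.where(dx, f[:, 0], 1 - f[:, 0])
                     * np.where(dy, f[:, 1], 1 - f[:, 1])
                     * np.where(dz, f[:, 2], 1 - f[:, 2]))
                out += w * g[i0[:, 0] + dx, i0[:, 1] + dy, i0[:, 2] + dz]
    out[oob] = np.nan
    if np.asarray(points).ndim == 1:
        return float(out[0])
    return out


def model_to_map(model: AtomicModel, voxel_size: float = 1.0,
                 padding: float = 5.0, b_offset: float = 30.0,
                 grid_like: DensityMap | None = None) -> DensityMap:
    """Render a model as a sum of isotropic atomic Gaussians.

    Each atom contributes a 3D Gaussian with variance
    ``(b_factor + b_offset) / (8 π²)`` per axis and total integral equal to
    its atomic number, so the map integral equals the sum of atomic numbers
    (electron counting, not a full scattering-factor model).

    If ``grid_like`` is given, the density is rendered onto that map's exact
    grid geometry; otherwise a grid covering the model plus ``padding`` is
    allocated.
    """
    if len(model) == 0:
        raise EmptyModelError("cannot render an empty model")
    if grid_like is not None:
        voxel = grid_like.voxel_size.copy()
        origin = grid_like.origin.copy()
        shape = np.array(grid_like.shape)
    else:
        if voxel_size <= 0:
            raise ValueError("voxel_size must be positive")
        voxel = np.full(3, float(voxel_size))
        lo = model.coords.min(axis=0) - padding
        hi = model.coords.max(axis=0) + padding
        origin = lo
        shape = np.maximum(np.ceil((hi - lo) / voxel).astype(int) + 1, 3)
    grid = np.zeros(shape)
    b_total = model.b_factor + b_offset
    if np.any(b_total <= 0):
        raise ValueError("b_factor + b_offset must be positive for all atoms")
    sigma = np.sqrt(b_total / (8.0 * np.pi ** 2))
    amps = model.atomic_numbers()
    cutoff_sigmas = 4.5
    for pos, sig, amp in zip(model.coords, sigma, amps):
        half = cutoff_sigmas * sig
        lo_i = np.floor((pos - half - origin) / voxel).astype(int)
        hi_i = np.ceil((pos + half - origin) / voxel).astype(int)
        lo_i = np.clip(lo_i, 0, shape - 1)
        hi_i = np.clip(hi_i, 0, shape - 1)
        if np.any(hi_i < lo_i):
            continue
        ax = [origin[d] + voxel[d] * np.arange(lo_i[d], hi_i[d] + 1) - pos[d]
              for d in range(3)]
        q = [np.exp(-0.5 * (a / sig) ** 2) for a in ax]
        norm = amp / ((2.0 * np.pi) ** 1.5 * sig ** 3)
        grid[lo_i[0]:hi_i[0] + 1, lo_i[1]:hi_i[1] + 1, lo_i[2]:hi_i[2] + 1] \
            += norm * q[0][:, None, None] * q[1][None, :, None] * q[2][None, None, :]
    return DensityMap(grid, voxel, origin)
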