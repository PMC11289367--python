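"""Seeded synthetic-fixture generators.

Every input class the toolkit consumes can be produced here without
external data: toy monomers with idealized covalent geometry, helical
filaments with known rise/twist, model-derived density maps with controlled
blur and noise, idealized/perturbed metal coordination sites, peptide-flip
variants, and arc-bent filaments.  All generators are pure functions of
their parameters and seed.
"""

from __future__ import annotations

import numpy as np

from .geometry import place_atom, rotation_about_axis
from .helical import HelicalSymmetry, build_filament
from .io import model_to_map
from .metal import IDEAL_GEOMETRIES
from .model import AtomicModel, DensityMap

__all__ = [
    "make_toy_monomer", "make_helical_filament", "make_metal_site",
    "make_noisy_model_map", "make_flipped_variant", "make_bent_filament",
]

# idealized backbone internal coordinates (trans peptide)
_B_N_CA, _B_CA_C, _B_C_N, _B_C_O = 1.458, 1.525, 1.329, 1.231
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA, _A_CA_C_O = 111.0, 116.6, 121.7, 120.8

_SIDECHAIN_CYCLE = ("LYS", "GLU", "LEU")


def _append(rows, chain, resnum, resname, name, element, pos, b=20.0,
            occ=1.0, het=False):
    rows.append((chain, resnum, resname, name, element, pos, b, occ, het))


def _rows_to_model(rows) -> AtomicModel:
    return AtomicModel(
        chain_id=[r[0] for r in rows],
        residue_number=[r[1] for r in rows],
        residue_name=[r[2] for r in rows],
        atom_name=[r[3] for r in rows],
        element=[r[4] for r in rows],
        coords=np.array([r[5] for r in rows]),
        b_factor=[r[6] for r in rows],
        occupancy=[r[7] for r in rows],
        hetero=[r[8] for r in rows],
    )


def _build_sidechain(rows, chain, resnum, resname, n, ca, cb, chi1):
    """Extend CB into a Lys/Glu/Leu side chain at the requested χ1."""
    cg = place_atom(n, ca, cb, 1.52, 113.8, chi1)
    _append(rows, chain, resnum, resname, "CG", "C", cg)
    if resname == "LYS":
        cd = place_atom(ca, cb, cg, 1.52, 111.0, 180.0)
        ce = place_atom(cb, cg, cd, 1.52, 111.0, 180.0)
        nz = place_atom(cg, cd, ce, 1.47, 111.0, 180.0)
        _append(rows, chain, resnum, resname, "CD", "C", cd)
        _append(rows, chain, resnum, resname, "CE", "C", ce)
        _append(rows, chain, resnum, resname, "NZ", "N", nz)
    elif resname == "GLU":
        cd = place_atom(ca, cb, cg, 1.52, 111.0, 180.0)
        oe1 = place_atom(cb, cg, cd, 1.25, 118.0, 0.0)
        oe2 = place_atom(cb, cg, cd, 1.25, 118.0, 180.0)
        _append(rows, chain, resnum, resname, "CD", "C", cd)
        _append(rows, chain, resnum, resname, "OE1", "O", oe1)
        _append(rows, chain, resnum, resname, "OE2", "O", oe2)
    elif resname == "LEU":
        cd1 = place_atom(ca, cb, cg, 1.52, 111.0, 60.0)
        cd2 = place_atom(ca, cb, cg, 1.52, 111.0, 180.0)
        _append(rows, chain, resnum, resname, "CD1", "C", cd1)
        _append(rows, chain, resnum, resname, "CD2", "C", cd2)


def make_toy_monomer(n_residues: int = 20, with_sidechains: bool = False,
                     seed: int = 0, chi1: float = 180.0,
                     chain_id: str = "A") -> AtomicModel:
    """Chemically plausible toy peptide with idealized covalent geometry.

    The backbone uses ideal bond lengths/angles with trans peptides and
    seeded helix-like (φ, ψ) variation, so consecutive Cα–Cα distances sit
    at the canonical ~3.8 Å.  With ``with_sidechains`` every residue cycles
    through Lys/Glu/Leu with the γ branch placed at the requested ``chi1``
    (measured as the N–Cα–Cβ–γ dihedral).
    """
    if n_residues < 3:
        raise ValueError("need at least 3 residues")
    rng = np.random.default_rng(seed)
    phis = rng.uniform(-80.0, -50.0, size=n_residues)
    psis = rng.uniform(-60.0, -20.0, size=n_residues)
    rows: list = []
    # seed the first residue explicitly
    n_pos = np.array([0.0, 0.0, 0.0])
    ca_pos = np.array([_B_N_CA, 0.0, 0.0])
    c_pos = ca_pos + _B_CA_C * np.array(
        [np.cos(np.deg2rad(180 - _A_N_CA_C)),
         np.sin(np.deg2rad(180 - _A_N_CA_C)), 0.0])
    for i in range(n_residues):
        resnum = i + 1
        resname = (_SIDECHAIN_CYCLE[i % 3] if with_sidechains else "ALA")
        _append(rows, chain_id, resnum, resname, "N", "N", n_pos)
        _append(rows, chain_id, resnum, resname, "CA", "C", ca_pos)
        _append(rows, chain_id, resnum, resname, "C", "C", c_pos)
        o_pos = place_atom(n_pos, ca_pos, c_pos, _B_C_O, _A_CA_C_O,
                           psis[i] + 180.0)
        _append(rows, chain_id, resnum, resname, "O", "O", o_pos)
        cb = place_atom(c_pos, n_pos, ca_pos, 1.53, 110.5, 123.0)
        _append(rows, chain_id, resnum, resname, "CB", "C", cb)
        if with_sidechains:
            _build_sidechain(rows, chain_id, resnum, resname,
                             n_pos, ca_pos, cb, chi1)
        if i == n_residues - 1:
            break
        next_n = place_atom(n_pos, ca_pos, c_pos, _B_C_N, _A_CA_C_N, psis[i])
        next_ca = place_atom(ca_pos, c_pos, next_n, _B_N_CA, _A_C_N_CA, 180.0)
        next_c = place_atom(c_pos, next_n, next_ca, _B_CA_C, _A_N_CA_C,
                            phis[i + 1])
        n_pos, ca_pos, c_pos = next_n, next_ca, next_c
    model = _rows_to_model(rows)
    # center on the origin so filament builders control placement explicitly
    return model.translated(-model.coords.mean(axis=0))


def make_helical_filament(sym: HelicalSymmetry | tuple[float, float],
                          n_subunits: int = 5, n_residues: int = 20,
                          seed: int = 0, with_sidechains: bool = False,
                          radius: float = 10.0,
                          jitter_sigma: float = 0.0) -> AtomicModel:
    """Helical filament of toy monomers with known rise/twist.

    The monomer is displaced ``radius`` Å off the helix (z) axis before
    replication; optional per-atom Gaussian jitter of ``jitter_sigma`` Å is
    applied after construction.
    """
    if not isinstance(sym, HelicalSymmetry):
        sym = HelicalSymmetry(*sym)
    monomer = make_toy_monomer(n_residues, with_sidechains=with_sidechains,
                               seed=seed)
    monomer = monomer.translated(np.array([radius, 0.0, 0.0]))
    filament = build_filament(monomer, sym, n_subunits)
    if jitter_sigma > 0:
        rng = np.random.default_rng(seed + 1)
        filament = filament.copy()
        filament.coords = filament.coords + rng.normal(
            0.0, jitter_sigma, size=filament.coords.shape)
    return filament


def make_metal_site(geometry: str = "octahedral", mean_distance: float = 2.1,
                    perturbation_sigma: float = 0.0, seed: int = 0,
                    metal_element: str = "MG",
                    center: np.ndarray | None = None) -> AtomicModel:
    """Metal HETATM plus O ligands (as waters) at perturbed ideal vertices."""
    if geometry not in IDEAL_GEOMETRIES:
        raise ValueError(f"unsupported geometry: {geometry!r}")
    rng = np.random.default_rng(seed)
    c = np.zeros(3) if center is None else np.asarray(center, dtype=float)
    vertices = IDEAL_GEOMETRIES[geometry] * mean_distance
    if perturbation_sigma > 0:
        vertices = vertices + rng.normal(0.0, perturbation_sigma,
                                         size=vertices.shape)
    rows: list = []
    _append(rows, "M", 1, metal_element.upper(), metal_element.upper(),
            metal_element.upper(), c, het=True)
    for i, v in enumerate(vertices):
        _append(rows, "W", i + 2, "HOH", "O", "O", c + v, het=True)
    return _rows_to_model(rows)


def make_noisy_model_map(model: AtomicModel, voxel_size: float = 1.0,
                         b_offset: float = 30.0, noise_sigma: float = 0.0,
                         seed: int = 0, padding: float = 5.0) -> DensityMap:
    """Model-derived Gaussian-atom map with controlled blur and i.i.d.
    Gaussian voxel noise (``noise_sigma`` in absolute map units)."""
    density = model_to_map(model, voxel_size=voxel_size, padding=padding,
                           b_offset=b_offset)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        density = density.copy_with(
            density.grid + rng.normal(0.0, noise_sigma, size=density.shape))
    return density


def make_flipped_variant(model: AtomicModel,
                         residues: list[tuple[str, int]],
                         angle: float = 180.0) -> AtomicModel:
    """Rotate the peptide plane after each listed residue about its
    Cα(i)–Cα(i+1) axis, moving C(i), O(i) and N(i+1) while preserving the
    Cα trace — the geometric signature of a peptide flip."""
    out = model.copy()
    for chain, resnum in residues:
        ca_i = model.atom_position(chain, resnum, "CA")
        ca_j = model.atom_position(chain, resnum + 1, "CA")
        rot = rotation_about_axis(ca_j - ca_i, angle)
        for res, name in ((resnum, "C"), (resnum, "O"), (resnum + 1, "N")):
            mask = ((out.chain_id == chain) & (out.residue_number == res)
                    & (out.atom_name == name))
            if not mask.any():
                continue
            p = out.coords[mask][0]
            out.coords[mask] = ca_i + rot @ (p - ca_i)
    return out


def make_bent_filament(filament: AtomicModel, arc_radius: float | None,
                       seed: int = 0) -> AtomicModel:
    """Bend a z-axis filament by transporting each subunit rigidly onto a
    circular arc in the xz-plane (curvature center on +x).

    Subunits on the −x side travel the longer (outer) path.  ``arc_radius``
    of ``None`` or infinity returns an unchanged copy.  The radius must be
    large enough that the bend stays under a half turn and well clear of
    the filament's own lateral extent (self-intersection guard).
    """
    del seed  # deterministic; kept for a uniform generator signature
    if arc_radius is None or np.isinf(arc_radius):
        return filament.copy()
    z = filament.coords[:, 2]
    z_extent = float(z.max() - z.min())
    lateral = float(np.abs(filament.coords[:, :2]).max())
    if arc_radius <= max(z_extent / np.pi, 2.0 * lateral):
        raise ValueError("arc_radius too small: filament would self-intersect")
    out = filament.copy()
    center = np.array([arc_radius, 0.0, 0.0])
    for chain in filament.chains:
        mask = filament.chain_id == chain
        z_c = float(filament.coords[mask, 2].mean())
        theta = np.degrees(z_c / arc_radius)
        rot = rotation_about_axis(np.array([0.0, 1.0, 0.0]), theta)
        shifted = filament.coords[mask] - np.array([0.0, 0.0, z_c]) - center
        out.coords[mask] = center + shifted @ rot.T
    return out
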