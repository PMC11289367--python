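"""Helical symmetry: filament construction, screw-parameter estimation,
cross-over distances, and twist comparison.

Sign convention: the screw axis is oriented so the rise is positive; the
twist is then the signed right-handed rotation about that axis, so a
left-handed 1-start helix has negative twist.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .geometry import kabsch, rotation_about_axis, rotation_angle_axis
from .model import AtomicModel

__all__ = [
    "HelicalSymmetry", "SymmetryEstimate", "build_filament",
    "estimate_symmetry", "crossover_distance", "compare_twist",
]

_CHAIN_LABELS = [chr(c) for c in range(ord("A"), ord("Z") + 1)] + \
    [chr(a) + chr(b) for a in range(ord("A"), ord("Z") + 1)
     for b in range(ord("A"), ord("Z") + 1)]


@dataclass(frozen=True)
class HelicalSymmetry:
    """Rise (Å, > 0) and signed twist (degrees) per subunit."""

    rise: float
    twist: float

    def __post_init__(self) -> None:
        if self.rise <= 0:
            raise ValueError("rise must be positive")
        if not -360.0 < self.twist < 360.0:
            raise ValueError("twist must lie in (-360, 360)")


@dataclass
class SymmetryEstimate:
    """Per-interface screw parameters of a filament plus their mean."""

    mean_symmetry: HelicalSymmetry
    per_interface: list[tuple[float, float]]
    axis: np.ndarray
    axis_point: np.ndarray

    @property
    def rises(self) -> np.ndarray:
        return np.array([r for r, _ in self.per_interface])

    @property
    def twists(self) -> np.ndarray:
        return np.array([t for _, t in self.per_interface])


def build_filament(monomer: AtomicModel, sym: HelicalSymmetry,
                   n_subunits: int, axis: np.ndarray | None = None
                   ) -> AtomicModel:
    """Replicate a monomer into an ``n_subunits`` helical filament.

    Subunit k is the monomer rotated by ``k * twist`` about the axis
    (through the origin, +z by default) and translated by ``k * rise``
    along it; chains are relabeled A, B, C, ... in subunit order.
    """
    if n_subunits < 2:
        raise ValueError("a filament needs at least 2 subunits")
    u = np.array([0.0, 0.0, 1.0]) if axis is None \
        else np.asarray(axis, dtype=np.float64)
    u = u / np.linalg.norm(u)
    subunits = []
    for k in range(n_subunits):
        rot = rotation_about_axis(u, k * sym.twist)
        sub = monomer.transformed(rot, k * sym.rise * u)
        subunits.append(sub.with_chain_id(_CHAIN_LABELS[k]))
    return AtomicModel.concatenate(subunits)


def _screw_parameters(rot: np.ndarray, trans: np.ndarray
                      ) -> tuple[float, float, np.ndarray, np.ndarray]:
    """Decompose a rigid transform into (rise, twist, axis, axis_point).

    The axis is flipped if needed so the translation along it (the rise) is
    positive; the twist sign follows the right-hand rule about that axis.
    """
    angle, axis = rotation_angle_axis(rot)
    d = float(np.dot(trans, axis))
    if d < 0:
        axis = -axis
        angle = -angle
        d = -d
    # point on the screw axis: solve (I - R) p = t_perp for p ⟂ axis
    t_perp = trans - np.dot(trans, axis) * axis
    a_mat = np.eye(3) - rot
    # the system is rank 2; regularize along the axis direction
    a_aug = np.vstack([a_mat, axis[None, :]])
    b_aug = np.concatenate([t_perp, [0.0]])
    point, *_ = np.linalg.lstsq(a_aug, b_aug, rcond=None)
    return d, float(angle), axis, point


def estimate_symmetry(filament: AtomicModel,
                      chain_order: list[str] | None = None
                      ) -> SymmetryEstimate:
    """Estimate helical parameters from consecutive-chain superpositions.

    For every consecutive chain pair the optimal rigid transform between
    their Cα sets is decomposed into screw parameters; the estimate is the
    arithmetic mean over interfaces.
    """
    chains = chain_order if chain_order is not None else filament.chains
    if len(chains) < 2:
        raise ValueError("need at least 2 chains")
    ca_sets = []
    for ch in chains:
        sub = filament.select(chain=ch, atom="CA")
        if len(sub) < 3:
            raise ValueError(f"chain {ch} has fewer than 3 CA atoms")
        ca_sets.append((sub.residue_number, sub.coords))
    per_interface = []
    axes, points = [], []
    for (res_a, xyz_a), (res_b, xyz_b) in zip(ca_sets[:-1], ca_sets[1:]):
        shared = np.intersect1d(res_a, res_b)
        if len(shared) < 3:
            raise ValueError("fewer than 3 shared CA residues at an interface")
        a = xyz_a[np.isin(res_a, shared)]
        b = xyz_b[np.isin(res_b, shared)]
        rot, trans, _ = kabsch(a, b)
        rise, twist, axis, point = _screw_parameters(rot, trans)
        per_interface.append((rise, twist))
        axes.append(axis)
        points.append(point)
    axes_arr = np.array(axes)
    # average axes with consistent orientation relative to the first
    signs = np.sign(axes_arr @ axes_arr[0])
    mean_axis = (axes_arr * signs[:, None]).mean(axis=0)
    mean_axis = mean_axis / np.linalg.norm(mean_axis)
    mean = HelicalSymmetry(
        rise=float(np.mean([r for r, _ in per_interface])),
        twist=float(np.mean([t for _, t in per_interface])),
    )
    return SymmetryEstimate(mean, per_interface, mean_axis,
                            np.mean(points, axis=0))


def crossover_distance(sym: HelicalSymmetry) -> float:
    """Axial distance over which the two long-pitch strands cross.

    For a 1-start helix with per-subunit rise and twist this is
    ``rise * 180 / (180 - |twist|)``.
    """
    gap = 180.0 - abs(sym.twist)
    if abs(gap) < 1e-12:
        raise ValueError("cross-over undefined for |twist| = 180")
    return sym.rise * 180.0 / gap


def compare_twist(a: SymmetryEstimate, b: SymmetryEstimate
                  ) -> tuple[float, float]:
    """Welch two-sample t-test on per-interface twist values.

    Returns (signed mean difference a − b in degrees, two-sided p-value).
    """
    ta, tb = a.twists, b.twists
    if len(ta) < 2 or len(tb) < 2:
        raise ValueError("need >= 2 per-interface samples on both sides")
    diff = float(ta.mean() - tb.mean())
    se = np.sqrt(ta.var(ddof=1) / len(ta) + tb.var(ddof=1) / len(tb))
    if se == 0:
        return diff, 1.0 if diff == 0 else 0.0
    _, p = stats.ttest_ind(ta, tb, equal_var=False)
    return diff, float(p)
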