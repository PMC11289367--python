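"""Structure superposition and comparison.

Covers per-residue Cα deviation maps (global or locally windowed
alignment), peptide-flip detection, salt-bridge search, named interface
distances, and straight-vs-bent filament distance bookkeeping.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .geometry import angle_between, kabsch
from .model import AtomicModel

__all__ = [
    "ComparisonReport", "ContactSpec", "superpose", "per_residue_deviation",
    "detect_peptide_flips", "detect_salt_bridges", "interface_distance",
    "bending_distance_change",
]

ACIDIC_SIDECHAIN = {"ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2")}
BASIC_SIDECHAIN = {"LYS": ("NZ",), "ARG": ("NH1", "NH2", "NE"),
                   "HIS": ("ND1", "NE2")}


@dataclass
class ComparisonReport:
    global_rmsd: float
    per_residue_ca_deviation: list[tuple[str, int, float]]
    flips: list[tuple[str, int, float]] = field(default_factory=list)
    aligned_pairs: list[tuple[str, int]] = field(default_factory=list)

    @property
    def max_deviation(self) -> tuple[str, int, float]:
        return max(self.per_residue_ca_deviation, key=lambda x: x[2])


@dataclass
class ContactSpec:
    """One inter-atom distance query.

    Each side names (chain, residue number, atom names); with
    ``mode="min-over-equivalents"`` the minimum over all name combinations
    is taken (e.g. both Glu carboxylate oxygens).
    """

    chain_a: str
    residue_a: int
    atoms_a: tuple[str, ...]
    chain_b: str
    residue_b: int
    atoms_b: tuple[str, ...]
    mode: str = "min-over-equivalents"


def _shared_ca(a: AtomicModel, b: AtomicModel
               ) -> tuple[list[tuple[str, int]], np.ndarray, np.ndarray]:
    ca_a = a.select(atom="CA")
    ca_b = b.select(atom="CA")
    keys_a = {(str(c), int(r)): i for i, (c, r) in
              enumerate(zip(ca_a.chain_id, ca_a.residue_number))}
    pairs, xa, xb = [], [], []
    for i, (c, r) in enumerate(zip(ca_b.chain_id, ca_b.residue_number)):
        key = (str(c), int(r))
        if key in keys_a:
            pairs.append(key)
            xa.append(ca_a.coords[keys_a[key]])
            xb.append(ca_b.coords[i])
    return pairs, np.array(xa), np.array(xb)


def superpose(mobile: AtomicModel, reference: AtomicModel,
              selection: Sequence[tuple[str, int]] | None = None
              ) -> tuple[tuple[np.ndarray, np.ndarray], float]:
    """Optimal proper rigid superposition of ``mobile`` onto ``reference``
    over shared Cα atoms (optionally restricted to ``selection`` pairs of
    (chain, residue number)).

    Returns ``((R, t), rmsd)`` with the post-fit Cα RMSD.
    """
    pairs, xb, xa = _shared_ca(reference, mobile)
    if selection is not None:
        keep = [i for i, p in enumerate(pairs) if p in set(selection)]
        pairs = [pairs[i] for i in keep]
        xa, xb = xa[keep], xb[keep]
    if len(pairs) < 3:
        raise ValueError("fewer than 3 paired CA atoms for superposition")
    rot, trans, rmsd = kabsch(xa, xb)
    return (rot, trans), rmsd


def per_residue_deviation(a: AtomicModel, b: AtomicModel,
                          alignment: str = "global",
                          window: int = 10) -> ComparisonReport:
    """Per-residue Cα deviations between two models.

    ``alignment="global"``: one superposition over all shared Cα, then
    per-residue distances.  ``alignment="local"``: each residue is measured
    after superposing only its ±``window``-residue neighborhood, isolating
    local differences from domain motion.
    """
    pairs, xa, xb = _shared_ca(a, b)
    if not pairs:
        raise ValueError("no shared residues")
    if alignment == "global":
        rot, trans, rmsd = kabsch(xb, xa)
        moved = xb @ rot.T + trans
        devs = np.linalg.norm(moved - xa, axis=1)
        global_rmsd = rmsd
    elif alignment == "local":
        devs = np.zeros(len(pairs))
        for i, (chain, resnum) in enumerate(pairs):
            idx = [j for j, (c, r) in enumerate(pairs)
                   if c == chain and abs(r - resnum) <= window]
            if len(idx) < 3:
                idx = list(range(max(0, i - window),
                                 min(len(pairs), i + window + 1)))
            rot, trans, _ = kabsch(xb[idx], xa[idx])
            devs[i] = np.linalg.norm(xb[i] @ rot.T + trans - xa[i])
        global_rmsd = float(np.sqrt(np.mean(devs ** 2)))
    else:
        raise ValueError(f"unknown alignment mode: {alignment!r}")
    report = ComparisonReport(
        global_rmsd=float(global_rmsd),
        per_residue_ca_deviation=[(c, r, float(d))
                                  for (c, r), d in zip(pairs, devs)],
        aligned_pairs=pairs,
    )
    return report


def detect_peptide_flips(a: AtomicModel, b: AtomicModel,
                         angle_threshold: float = 90.0,
                         ca_gate: float = 3.0,
                         window: int = 5) -> list[tuple[str, int, float]]:
    """Find residues whose carbonyl direction rotates by more than
    ``angle_threshold`` while the local backbone trace is preserved.

    For each shared residue the models are superposed on the surrounding
    ±``window`` Cα neighborhood; the residue is flagged when the angle
    between its C→O vectors exceeds the threshold and both its own and the
    next residue's Cα deviations stay below ``ca_gate`` (plane rotated,
    trace kept).  Residues missing backbone C/O atoms are skipped.
    """
    pairs, xa, xb = _shared_ca(a, b)
    if not pairs:
        raise ValueError("no shared residues")
    index = {p: i for i, p in enumerate(pairs)}
    flips = []
    for chain, resnum in pairs:
        try:
            c_a = a.atom_position(chain, resnum, "C")
            o_a = a.atom_position(chain, resnum, "O")
            c_b = b.atom_position(chain, resnum, "C")
            o_b = b.atom_position(chain, resnum, "O")
        except KeyError:
            continue
        idx = [i for (ch, r), i in index.items()
               if ch == chain and abs(r - resnum) <= window]
        if len(idx) < 3:
            continue
        rot, trans, _ = kabsch(xb[idx], xa[idx])
        i = index[(chain, resnum)]
        dev_here = np.linalg.norm(xb[i] @ rot.T + trans - xa[i])
        nxt = index.get((chain, resnum + 1))
        dev_next = (np.linalg.norm(xb[nxt] @ rot.T + trans - xa[nxt])
                    if nxt is not None else dev_here)
        if dev_here >= ca_gate or dev_next >= ca_gate:
            continue
        v_a = o_a - c_a
        v_b = rot @ (o_b - c_b)
        angle = angle_between(v_a, v_b)
        if angle > angle_threshold:
            flips.append((chain, resnum, float(angle)))
    return flips


def detect_salt_bridges(model: AtomicModel, cutoff: float = 5.0,
                        inter_chain_only: bool = False
                        ) -> list[tuple[tuple[str, int, str],
                                        tuple[str, int, str], float]]:
    """Acidic-O / basic-N residue pairs with minimum side-chain distance
    strictly below ``cutoff``; one (closest) atom pair per residue pair."""
    acid_mask = np.zeros(len(model), dtype=bool)
    base_mask = np.zeros(len(model), dtype=bool)
    for res, names in ACIDIC_SIDECHAIN.items():
        acid_mask |= (model.residue_name == res) & np.isin(model.atom_name,
                                                           names)
    for res, names in BASIC_SIDECHAIN.items():
        base_mask |= (model.residue_name == res) & np.isin(model.atom_name,
                                                           names)
    acids = model[acid_mask]
    bases = model[base_mask]
    if len(acids) == 0 or len(bases) == 0:
        return []
    d = np.linalg.norm(acids.coords[:, None, :] - bases.coords[None, :, :],
                       axis=2)
    best: dict[tuple, tuple] = {}
    for i in range(len(acids)):
        for j in range(len(bases)):
            if d[i, j] >= cutoff:
                continue
            if inter_chain_only and acids.chain_id[i] == bases.chain_id[j]:
                continue
            key = (str(acids.chain_id[i]), int(acids.residue_number[i]),
                   str(bases.chain_id[j]), int(bases.residue_number[j]))
            if key not in best or d[i, j] < best[key][2]:
                best[key] = (
                    (key[0], key[1], str(acids.atom_name[i])),
                    (key[2], key[3], str(bases.atom_name[j])),
                    float(d[i, j]))
    return sorted(best.values(), key=lambda x: x[2])


def interface_distance(model: AtomicModel, spec: ContactSpec) -> float:
    """Distance for one :class:`ContactSpec` query.

    In ``min-over-equivalents`` mode the minimum over all listed atom-name
    combinations is returned; ``specific`` mode requires exactly one name
    per side.
    """
    if spec.mode == "specific" and (len(spec.atoms_a) != 1
                                    or len(spec.atoms_b) != 1):
        raise ValueError("specific mode takes exactly one atom name per side")
    pos_a = [model.atom_position(spec.chain_a, spec.residue_a, n)
             for n in spec.atoms_a]
    pos_b = [model.atom_position(spec.chain_b, spec.residue_b, n)
             for n in spec.atoms_b]
    dists = [np.linalg.norm(pa - pb) for pa in pos_a for pb in pos_b]
    return float(min(dists))


def bending_distance_change(straight: AtomicModel, bent: AtomicModel,
                            specs: dict[str, ContactSpec],
                            labels: dict[str, str]
                            ) -> dict[str, list[tuple[str, float, float,
                                                      float]]]:
    """Tabulate an interface distance in straight vs bent filaments.

    ``specs`` maps an interface name to the :class:`ContactSpec` measured at
    that interface; ``labels`` maps each interface name to a group label
    (typically ``"inner"`` / ``"outer"``, supplied by the caller — the
    classification of interfaces relative to the bending plane is not
    inferred).  Returns, per group, (interface, straight Å, bent Å, delta).
    """
    missing = set(specs) - set(labels)
    if missing:
        raise ValueError(f"interfaces without a group label: {sorted(missing)}")
    out: dict[str, list[tuple[str, float, float, float]]] = {}
    for name, spec in specs.items():
        d_straight = interface_distance(straight, spec)
        d_bent = interface_distance(bent, spec)
        out.setdefault(labels[name], []).append(
            (name, d_straight, d_bent, d_bent - d_straight))
    return out
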