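"""Cyclic (Cn) symmetry detection and construction for ring assemblies.

A Cn assembly maps onto itself under rotation by 360/n about one axis,
which permutes its chains cyclically. Detection therefore tests, for
each candidate order compatible with the chain count, the superposition
of the assembly onto its one-step chain permutation and scores it by the
Cα mapping RMSD. Construction is the inverse: replicate one protomer by
rotations of 360/n about a given axis.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .structure_io import Assembly, Atom, Residue, select_atoms
from .superposition import kabsch_superpose

__all__ = [
    "SymmetryEstimate",
    "estimate_axis",
    "detect_symmetry_order",
    "apply_cyclic_symmetry",
    "chain_letters",
]

#: chain id sequence used for constructed assemblies
_ALPHABET = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"


def chain_letters(n: int) -> list[str]:
    if n <= len(_ALPHABET):
        return list(_ALPHABET[:n])
    return [_ALPHABET[i % 26] + str(i // 26) for i in range(n)]


@dataclasses.dataclass
class SymmetryEstimate:
    order: int
    axis_point: np.ndarray
    axis_dir: np.ndarray
    mapping_rmsd: float

    def __post_init__(self) -> None:
        self.axis_point = np.asarray(self.axis_point, dtype=float)
        self.axis_dir = np.asarray(self.axis_dir, dtype=float)
        norm = np.linalg.norm(self.axis_dir)
        if abs(norm - 1.0) > 1e-9:
            raise ValueError("axis_dir must be a unit vector")
        if self.order < 1 or self.mapping_rmsd < 0:
            raise ValueError("order must be ≥1 and mapping_rmsd ≥ 0")

    @property
    def per_step_angle(self) -> float:
        return 360.0 / self.order


def _chain_centroids(assembly: Assembly, chains: Sequence[str]) -> np.ndarray:
    cents = []
    for c in chains:
        sel = select_atoms(assembly, chain=c)
        if len(sel) == 0:
            raise ValueError(f"chain {c!r} has no protein atoms")
        cents.append(sel.coords.mean(axis=0))
    return np.array(cents)


def estimate_axis(
    assembly: Assembly, chains: Sequence[str] | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Symmetry-axis estimate from the ring of chain centroids.

    The axis passes through the centroid of chain centroids and points
    along the least-squares normal of the centroid plane, oriented so
    that the chain sequence advances counterclockwise around it.
    """
    chains = list(chains) if chains is not None else list(assembly.chains)
    if len(chains) < 3:
        raise ValueError(f"axis underdetermined with {len(chains)} chains (need ≥3)")
    cents = _chain_centroids(assembly, chains)
    center = cents.mean(axis=0)
    _, _, vt = np.linalg.svd(cents - center)
    normal = vt[2]
    # orient: consecutive centroids should wind counterclockwise about the axis
    winding = np.zeros(3)
    rel = cents - center
    for k in range(len(chains)):
        winding += np.cross(rel[k], rel[(k + 1) % len(chains)])
    if np.dot(winding, normal) < 0:
        normal = -normal
    return center, normal / np.linalg.norm(normal)


def detect_symmetry_order(
    assembly: Assembly,
    candidates: Iterable[int] = range(2, 13),
    rmsd_accept: float = 3.0,
) -> SymmetryEstimate:
    """Detect the cyclic order of an assembly by self-superposition.

    For each candidate order ``n`` that divides the chain count, the
    assembly is superposed onto itself under the chain permutation
    shifting every chain by ``m/n`` positions (Kabsch on Cα pairs by
    residue number). Orders whose mapping RMSD is below ``rmsd_accept``
    are acceptable; among acceptable orders within a small band of the
    best RMSD the highest order wins (a true Cn match also matches every
    divisor of n with near-identical RMSD, so a pure minimum would be
    decided by noise). Returns order 1 when nothing is acceptable.
    """
    m = len(assembly.chains)
    cand = sorted({int(n) for n in candidates if 2 <= int(n) <= m and m % int(n) == 0})
    point, direction = (
        estimate_axis(assembly) if m >= 3 else (np.zeros(3), np.array([0.0, 0.0, 1.0]))
    )
    results: list[tuple[int, float]] = []
    for n in cand:
        shift = m // n
        mapping = {
            assembly.chains[k]: assembly.chains[(k + shift) % m] for k in range(m)
        }
        pa, pb = [], []
        for ca, cb in mapping.items():
            res_b = {(r.number, r.icode): r for r in assembly.chain_residues(cb)}
            for r in assembly.chain_residues(ca):
                other = res_b.get((r.number, r.icode))
                if other is None:
                    continue
                try:
                    pa.append(r.atom("CA").pos)
                    pb.append(other.atom("CA").pos)
                except KeyError:
                    continue
        if len(pa) < 3:
            raise ValueError(f"chains not alignable under order {n} (too few shared Cα)")
        res = kabsch_superpose(np.array(pa), np.array(pb))
        results.append((n, res.rmsd_all))
    acceptable = [(n, r) for n, r in results if r <= rmsd_accept]
    if not acceptable:
        return SymmetryEstimate(order=1, axis_point=point, axis_dir=direction, mapping_rmsd=0.0)
    best_rmsd = min(r for _, r in acceptable)
    band = best_rmsd * 1.10 + 0.05
    order, rmsd = max((n, r) for n, r in acceptable if r <= band)
    return SymmetryEstimate(order=order, axis_point=point, axis_dir=direction, mapping_rmsd=rmsd)


def rotation_about_axis(
    angle_deg: float, axis_point: np.ndarray, axis_dir: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """(R, t) rotating by ``angle_deg`` about the line (axis_point, axis_dir)."""
    axis_dir = np.asarray(axis_dir, dtype=float)
    axis_dir = axis_dir / np.linalg.norm(axis_dir)
    R = Rotation.from_rotvec(np.radians(angle_deg) * axis_dir).as_matrix()
    p = np.asarray(axis_point, dtype=float)
    t = p - R @ p
    return R, t


def apply_cyclic_symmetry(
    protomer: Assembly,
    n: int,
    axis_point: np.ndarray = (0.0, 0.0, 0.0),
    axis_dir: np.ndarray = (0.0, 0.0, 1.0),
) -> Assembly:
    """Replicate a single-chain protomer into an ideal Cn assembly.

    Chain k is the protomer rotated by k·360/n about the axis; chain ids
    are assigned A, B, C, ...
    """
    if n < 2:
        raise ValueError("n must be ≥ 2")
    if len(protomer.chains) != 1:
        raise ValueError("protomer must have exactly one chain")
    ids = chain_letters(n)
    residues: list[Residue] = []
    for k in range(n):
        R, t = rotation_about_axis(k * 360.0 / n, axis_point, axis_dir)
        for r in protomer.residues:
            atoms = [
                Atom(a.name, a.element, R @ a.pos + t, a.occupancy, a.altloc, a.bfactor)
                for a in r.atoms
            ]
            residues.append(Residue(ids[k], r.number, r.icode, r.name, atoms, r.het))
    return Assembly(id=f"{protomer.id}_C{n}", chains=ids, residues=residues)
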