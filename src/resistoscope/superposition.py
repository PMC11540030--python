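"""Rigid superposition and conformational-change decomposition.

The workhorse is the Kabsch least-squares fit (SVD with reflection
excluded). On top of it sit:

* ``pruned_match_align`` — iterative superposition that discards atom
  pairs beyond a distance cutoff each round, the procedure behind the
  "pruned RMSD" commonly reported when comparing predicted models with
  experimental structures;
* ``pair_chains_cyclically`` — finds the chain correspondence between
  two equal-stoichiometry ring assemblies among cyclic shifts (and the
  reversed orientation);
* ``module_rotation_angle`` — decomposes a protomer conformational
  change into the rigid rotation of a mobile domain module measured in
  the frame of an anchor module, the standard way to quantify the large
  NB-ARC rearrangement between resting and activated NLR states.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from .structure_io import Assembly, DomainMap, select_atoms

__all__ = [
    "RigidTransform",
    "AlignmentResult",
    "kabsch_superpose",
    "pair_chains_cyclically",
    "pruned_match_align",
    "module_rotation_angle",
    "centroid_angle",
]


@dataclasses.dataclass
class RigidTransform:
    """Proper rotation + translation, with derived angle and screw axis."""

    rotation: np.ndarray  # (3, 3), det = +1
    translation: np.ndarray  # (3,)

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        if not np.allclose(self.rotation.T @ self.rotation, np.eye(3), atol=1e-9):
            raise ValueError("rotation matrix is not orthonormal")
        if np.linalg.det(self.rotation) < 0:
            raise ValueError("improper rotation (reflection)")

    @property
    def angle(self) -> float:
        """Rotation angle in degrees, in [0, 180]."""
        c = (np.trace(self.rotation) - 1.0) / 2.0
        return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))

    @property
    def screw_axis(self) -> np.ndarray:
        """Unit eigenvector of the rotation for eigenvalue 1."""
        w, v = np.linalg.eigh((self.rotation + self.rotation.T) / 2.0)
        axis = v[:, np.argmax(w)]
        # orient along the antisymmetric part when the angle is not 0/180
        skew = np.array(
            [
                self.rotation[2, 1] - self.rotation[1, 2],
                self.rotation[0, 2] - self.rotation[2, 0],
                self.rotation[1, 0] - self.rotation[0, 1],
            ]
        )
        if np.linalg.norm(skew) > 1e-12 and np.dot(axis, skew) < 0:
            axis = -axis
        return axis / np.linalg.norm(axis)

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation

    @staticmethod
    def identity() -> "RigidTransform":
        return RigidTransform(np.eye(3), np.zeros(3))


@dataclasses.dataclass
class AlignmentResult:
    transform: RigidTransform
    rmsd_all: float
    rmsd_pruned: float
    n_matched: int
    n_retained: int
    pair_table: list[tuple[object, object, float]] = dataclasses.field(default_factory=list)


def _rmsd(a: np.ndarray, b: np.ndarray, w: np.ndarray | None = None) -> float:
    d2 = np.sum((a - b) ** 2, axis=1)
    if w is None:
        return float(np.sqrt(np.mean(d2)))
    return float(np.sqrt(np.sum(w * d2) / np.sum(w)))


def kabsch_superpose(
    moving: np.ndarray,
    fixed: np.ndarray,
    weights: np.ndarray | None = None,
) -> AlignmentResult:
    """Least-squares rigid fit of ``moving`` onto ``fixed`` (paired points).

    Reflections are excluded (det = +1). Raises on mismatched lengths,
    fewer than 3 points, or collinear/degenerate configurations for
    which the rotation is underdetermined.
    """
    moving = np.asarray(moving, dtype=float)
    fixed = np.asarray(fixed, dtype=float)
    if moving.shape != fixed.shape:
        raise ValueError(f"length mismatch: moving {moving.shape} vs fixed {fixed.shape}")
    n = moving.shape[0]
    if n < 3:
        raise ValueError(f"need at least 3 paired points, got {n}")
    if weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n,) or np.any(w < 0) or w.sum() == 0:
            raise ValueError("weights must be non-negative with positive sum")
    wn = w / w.sum()
    cm = wn @ moving
    cf = wn @ fixed
    P = (moving - cm) * wn[:, None]
    Q = fixed - cf
    H = P.T @ Q
    U, S, Vt = np.linalg.svd(H)
    # collinear points: rank < 2 leaves the rotation free about the line
    if S[1] < 1e-10 * max(S[0], 1e-30):
        raise ValueError("points are collinear; rotation underdetermined")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cf - R @ cm
    tr = RigidTransform(R, t)
    rmsd = _rmsd(tr.apply(moving), fixed, w)
    return AlignmentResult(
        transform=tr, rmsd_all=rmsd, rmsd_pruned=rmsd, n_matched=n, n_retained=n
    )


def _paired_ca(a: Assembly, b: Assembly, chain_map: dict[str, str]):
    """CA coordinate pairs for residues shared (by number+icode) between mapped chains."""
    pa, pb, labels = [], [], []
    for ca_id, cb_id in chain_map.items():
        res_b = {
            (r.number, r.icode): r for r in b.chain_residues(cb_id)
        }
        for r in a.chain_residues(ca_id):
            other = res_b.get((r.number, r.icode))
            if other is None:
                continue
            try:
                x, y = r.atom("CA"), other.atom("CA")
            except KeyError:
                continue
            pa.append(x.pos)
            pb.append(y.pos)
            labels.append(((ca_id, r.number, r.icode), (cb_id, other.number, other.icode)))
    return np.array(pa), np.array(pb), labels


def pair_chains_cyclically(
    a: Assembly, b: Assembly
) -> tuple[dict[str, str], AlignmentResult]:
    """Best chain correspondence between two equal-count ring assemblies.

    All ``n`` cyclic shifts of the chain order, in both ring orientations,
    are scored by whole-assembly Cα RMSD after a Kabsch fit; the minimum
    wins. Returns the mapping (chain of ``a`` → chain of ``b``) and the
    winning alignment.
    """
    if len(a.chains) != len(b.chains):
        raise ValueError(
            f"chain count mismatch: {len(a.chains)} vs {len(b.chains)}"
        )
    n = len(a.chains)
    best: tuple[float, dict[str, str], AlignmentResult] | None = None
    orders = [list(b.chains)]
    if n > 2:
        orders.append(list(reversed(b.chains)))
    for order in orders:
        for shift in range(n):
            mapping = {
                a.chains[k]: order[(k + shift) % n] for k in range(n)
            }
            pa, pb, _ = _paired_ca(a, b, mapping)
            if len(pa) < 3:
                continue
            res = kabsch_superpose(pa, pb)
            if best is None or res.rmsd_all < best[0]:
                best = (res.rmsd_all, mapping, res)
    if best is None:
        raise ValueError("no cyclic correspondence yields enough paired residues")
    return best[1], best[2]


def pruned_match_align(
    moving: Assembly,
    fixed: Assembly,
    chain_map: dict[str, str] | None = None,
    prune_cutoff: float = 2.0,
    max_iter: int = 100,
) -> AlignmentResult:
    """Iteratively pruned Cα superposition of ``moving`` onto ``fixed``.

    Residues are paired by author number within corresponding chains
    (identical-sequence assumption). Each iteration superposes on the
    retained pairs, then drops in one batch every pair farther than
    ``prune_cutoff``; iteration stops when nothing is dropped. The
    result carries both the unpruned RMSD of all matched pairs under the
    final transform (``rmsd_all``) and the pruned RMSD (``rmsd_pruned``).
    """
    if chain_map is None:
        if set(moving.chains) == set(fixed.chains):
            chain_map = {c: c for c in moving.chains}
        elif len(moving.chains) == len(fixed.chains):
            chain_map = dict(zip(moving.chains, fixed.chains))
        else:
            raise ValueError("chain counts differ; supply an explicit chain_map")
    pm, pf, labels = _paired_ca(moving, fixed, chain_map)
    if len(pm) < 3:
        raise ValueError(f"only {len(pm)} shared Cα pairs; need at least 3")
    retained = np.ones(len(pm), dtype=bool)
    result: AlignmentResult | None = None
    for _ in range(max_iter):
        if retained.sum() < 3:
            raise ValueError(
                f"pruning left {int(retained.sum())} pairs (<3); cutoff too strict"
            )
        result = kabsch_superpose(pm[retained], pf[retained])
        dists = np.linalg.norm(result.transform.apply(pm) - pf, axis=1)
        drop = retained & (dists > prune_cutoff)
        if not drop.any():
            break
        retained &= ~drop
    assert result is not None
    moved = result.transform.apply(pm)
    all_d = np.linalg.norm(moved - pf, axis=1)
    return AlignmentResult(
        transform=result.transform,
        rmsd_all=float(np.sqrt(np.mean(all_d**2))),
        rmsd_pruned=float(np.sqrt(np.mean(all_d[retained] ** 2))),
        n_matched=len(pm),
        n_retained=int(retained.sum()),
        pair_table=[(la, lb, float(d)) for (la, lb), d in zip(labels, all_d)],
    )


def _module_ca(
    assembly: Assembly,
    chain: str,
    domain_map: DomainMap,
    labels: Sequence[str],
) -> dict[int, np.ndarray]:
    numbers: set[int] = set()
    for lab in labels:
        numbers.update(domain_map.residue_numbers(lab))
    sel = select_atoms(
        assembly, chain=chain, residue_numbers=numbers, atom_names=["CA"]
    )
    return {res.number: atom.pos for res, atom in sel.refs}


def module_rotation_angle(
    protomer1: Assembly,
    protomer2: Assembly,
    domain_map: DomainMap,
    anchor_labels: Sequence[str],
    mobile_labels: Sequence[str],
    chain1: str | None = None,
    chain2: str | None = None,
) -> tuple[RigidTransform, dict[str, float]]:
    """Rotation of a mobile domain module between two protomer states.

    The second protomer is superposed onto the first on the anchor
    module's shared Cα, then the Kabsch transform taking the mobile
    module of the superposed state onto the first state's mobile module
    is computed; its rotation angle is the module rotation. The returned
    diagnostics include each module's internal RMSD after its own best
    fit (a rigidity check) and the anchor/mobile pair counts.
    """
    chain1 = chain1 or protomer1.chains[0]
    chain2 = chain2 or protomer2.chains[0]

    def shared(labels: Sequence[str]):
        m1 = _module_ca(protomer1, chain1, domain_map, labels)
        m2 = _module_ca(protomer2, chain2, domain_map, labels)
        common = sorted(m1.keys() & m2.keys())
        return (
            np.array([m1[n] for n in common]),
            np.array([m2[n] for n in common]),
            len(common),
        )

    a1, a2, n_anchor = shared(anchor_labels)
    b1, b2, n_mobile = shared(mobile_labels)
    if n_anchor < 10 or n_mobile < 10:
        raise ValueError(
            f"insufficient shared Cα: anchor {n_anchor}, mobile {n_mobile} (need ≥10 each)"
        )
    anchor_fit = kabsch_superpose(a2, a1)
    mobile_in_frame = anchor_fit.transform.apply(b2)
    mobile_fit = kabsch_superpose(mobile_in_frame, b1)
    diagnostics = {
        "anchor_rmsd": anchor_fit.rmsd_all,
        "mobile_internal_rmsd": mobile_fit.rmsd_all,
        "n_anchor": float(n_anchor),
        "n_mobile": float(n_mobile),
    }
    return mobile_fit.transform, diagnostics


def centroid_angle(
    assembly: Assembly,
    domain_map: DomainMap,
    labels: tuple[str, str, str],
    chain: str | None = None,
) -> float:
    """Angle (degrees) at the middle label's Cα centroid between the outer two.

    A generic three-centroid interdomain angle; which domains to use is
    left to the caller, since published interdomain angles rarely state
    their vector definitions.
    """
    chain = chain or assembly.chains[0]
    cents = []
    for lab in labels:
        sel = select_atoms(
            assembly,
            chain=chain,
            residue_numbers=domain_map.residue_numbers(lab),
            atom_names=["CA"],
        )
        if len(sel) == 0:
            raise ValueError(f"no Cα in domain {lab!r} on chain {chain}")
        cents.append(sel.coords.mean(axis=0))
    v1 = cents[0] - cents[1]
    v2 = cents[2] - cents[1]
    c = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))
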