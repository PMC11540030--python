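"""Pore geometry of cyclic assemblies along their symmetry axis.

Activated CC-NLR resistosomes are rings with a channel down the
symmetry axis; the funnel mouth (CC side) and the nucleotide-binding
(NB) side differ in width and chemistry between pentameric and
hexameric assemblies, so this module provides:

* Cα ring diameters at named residues, either between opposite chains
  (even orders only) or as twice the mean distance to the axis (any
  order — the definition that puts pentamers and hexamers on one scale);
* an axial radius profile: at each station along the axis, the minimal
  (distance to axis − vdW radius) over atoms in the slab — a slab-minimum
  approximation of the channel radius, not a Monte-Carlo probe fit;
* pore-lining chemistry classes from residue type.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from .interfaces import VDW_RADII
from .structure_io import Assembly, DomainMap
from .symmetry import estimate_axis

__all__ = [
    "PoreProfile",
    "ring_diameter",
    "pore_radius_profile",
    "classify_pore_chemistry",
    "RESIDUE_CLASS",
]

#: residue-type chemistry classes (three-letter codes)
RESIDUE_CLASS = {
    **{r: "acidic" for r in ("ASP", "GLU")},
    **{r: "basic" for r in ("LYS", "ARG", "HIS")},
    **{r: "polar" for r in ("SER", "THR", "ASN", "GLN", "TYR", "TRP")},
    **{
        r: "hydrophobic"
        for r in ("ALA", "VAL", "LEU", "ILE", "MET", "PHE", "CYS", "GLY", "PRO")
    },
}


@dataclasses.dataclass
class PoreStation:
    z: float
    radius: float
    residue: tuple[str, int, str, str] | None  # chain, number, icode, name


@dataclasses.dataclass
class PoreProfile:
    axis_point: np.ndarray
    axis_dir: np.ndarray
    stations: list[PoreStation]

    @property
    def constriction(self) -> PoreStation:
        return min(self.stations, key=lambda s: s.radius)

    def constriction_in(self, z_lo: float, z_hi: float) -> PoreStation:
        inside = [s for s in self.stations if z_lo <= s.z <= z_hi]
        if not inside:
            raise ValueError(f"no stations in axial range [{z_lo}, {z_hi}]")
        return min(inside, key=lambda s: s.radius)


def _axis(assembly: Assembly, axis):
    if axis is None:
        return estimate_axis(assembly)
    point, direction = axis
    direction = np.asarray(direction, dtype=float)
    return np.asarray(point, dtype=float), direction / np.linalg.norm(direction)


def ring_diameter(
    assembly: Assembly,
    residue_number: int,
    atom: str = "CA",
    method: str = "opposite",
    axis=None,
    icode: str = "",
) -> float:
    """Diameter (Å) of the ring formed by one atom of one residue per chain.

    ``method="opposite"`` (even chain counts): mean distance between the
    atoms of diametrically opposite chains — the convention used when
    ring widths are quoted as Cα–Cα distances across the pore.
    ``method="axis"`` (any count): twice the mean distance to the
    symmetry axis, the general definition valid for odd rings.
    """
    atoms = []
    for c in assembly.chains:
        res = assembly.residue(c, residue_number, icode)
        atoms.append(res.atom(atom).pos)
    coords = np.array(atoms)
    n = len(coords)
    if method == "opposite":
        if n % 2:
            raise ValueError(
                f"method='opposite' undefined for odd chain count {n}; use method='axis'"
            )
        half = n // 2
        d = [np.linalg.norm(coords[k] - coords[(k + half) % n]) for k in range(n)]
        return float(np.mean(d))
    if method == "axis":
        point, direction = _axis(assembly, axis)
        rel = coords - point
        radial = rel - np.outer(rel @ direction, direction)
        return float(2.0 * np.mean(np.linalg.norm(radial, axis=1)))
    raise ValueError(f"unknown method {method!r}; use 'opposite' or 'axis'")


def pore_radius_profile(
    assembly: Assembly,
    axis=None,
    z_range: tuple[float, float] | None = None,
    step: float = 1.0,
    domain_map: DomainMap | None = None,
) -> PoreProfile:
    """Axial pore-radius profile from heavy-atom distances to the axis.

    At each station z the radius is the minimum over atoms whose axial
    coordinate lies within ±step/2 of z of (distance to axis − vdW
    radius), floored at zero. Stations with an empty slab are skipped.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    point, direction = _axis(assembly, axis)
    coords, owners, radii = [], [], []
    for r in assembly.residues:
        if r.het:
            continue
        for a in r.heavy_atoms():
            coords.append(a.pos)
            owners.append(r)
            radii.append(VDW_RADII.get(a.element.upper(), 1.7))
    coords = np.array(coords)
    radii = np.array(radii)
    rel = coords - point
    z = rel @ direction
    radial = np.linalg.norm(rel - np.outer(z, direction), axis=1)
    if z_range is None:
        z_range = (float(z.min()), float(z.max()))
    stations = []
    for zk in np.arange(z_range[0], z_range[1] + step / 2, step):
        # small margin keeps slab membership stable for atoms exactly on a
        # slab boundary when the assembly has been rigidly moved
        mask = np.abs(z - zk) <= step / 2 + 1e-9
        if not mask.any():
            continue
        clearance = radial[mask] - radii[mask]
        idx = np.flatnonzero(mask)[np.argmin(clearance)]
        res = owners[idx]
        stations.append(
            PoreStation(
                z=float(zk),
                radius=float(max(clearance.min(), 0.0)),
                residue=(res.chain_id, res.number, res.icode, res.name),
            )
        )
    if not stations:
        raise ValueError("no atoms in the requested axial range")
    return PoreProfile(axis_point=point, axis_dir=direction, stations=stations)


def classify_pore_chemistry(
    assembly: Assembly, residue_numbers: Sequence[int]
) -> tuple[str, dict[int, str]]:
    """Chemistry of pore-lining residue rings.

    Each listed residue number is classified by residue type (over all
    chains); the ring class is the unanimous per-residue class, or
    "mixed" when the listed rings disagree (e.g. a basic ring plus a
    polar ring).
    """
    per_residue: dict[int, str] = {}
    for num in residue_numbers:
        names = {
            r.name for r in assembly.residues if r.number == num and not r.het
        }
        if not names:
            raise ValueError(f"residue number {num} not present in any chain")
        classes = {RESIDUE_CLASS.get(n, "polar") for n in names}
        per_residue[num] = classes.pop() if len(classes) == 1 else "mixed"
    overall = set(per_residue.values())
    return (overall.pop() if len(overall) == 1 else "mixed"), per_residue
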