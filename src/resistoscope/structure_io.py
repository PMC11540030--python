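"""Coordinate file I/O, atom selection, and domain annotation.

The in-memory model is deliberately small: an :class:`Assembly` is an
ordered list of :class:`Residue` objects (each holding its chain id and
an ordered list of :class:`Atom`), plus the ordered list of chain ids.
Parsing and serialisation of mmCIF/PDB is delegated to :mod:`gemmi`;
this module owns altloc resolution, water/heteroatom policy and the
author-numbering conventions used throughout the package.

Domain annotation is range-based (author residue numbers).  The shipped
default for the NbNRC2 helper NLR assigns the N-terminal α1 helix,
coiled-coil (CC), nucleotide-binding (NB), helical domain 1 (HD1),
winged-helix (WHD) and leucine-rich-repeat (LRR) regions; residues
falling between ranges (e.g. the NB–CC linker) are "unassigned".
"""

from __future__ import annotations

import dataclasses
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gemmi
import numpy as np
import pandas as pd
import yaml

__all__ = [
    "Atom",
    "Residue",
    "Assembly",
    "DomainMap",
    "Selection",
    "UNASSIGNED",
    "read_structure",
    "write_structure",
    "select_atoms",
    "annotate_domains",
    "default_domain_map",
    "load_domain_maps",
]

UNASSIGNED = "unassigned"

#: Residue names treated as solvent and dropped on read.
_WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}

_HYDROGEN = {"H", "D"}

_BACKBONE = {"N", "CA", "C", "O", "OXT"}


@dataclasses.dataclass
class Atom:
    """One atom: name, element symbol, position in Å, occupancy, altloc, B."""

    name: str
    element: str
    pos: np.ndarray
    occupancy: float = 1.0
    altloc: str = ""
    bfactor: float = 0.0

    def __post_init__(self) -> None:
        self.pos = np.asarray(self.pos, dtype=float)
        if self.pos.shape != (3,) or not np.all(np.isfinite(self.pos)):
            raise ValueError(f"atom {self.name}: position must be a finite 3-vector")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"atom {self.name}: occupancy {self.occupancy} outside [0, 1]")

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in _HYDROGEN


@dataclasses.dataclass
class Residue:
    """One residue in author numbering; ``het`` marks non-polymer groups."""

    chain_id: str
    number: int
    icode: str
    name: str
    atoms: list[Atom]
    het: bool = False

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.number, self.icode)

    def atom(self, name: str) -> Atom:
        for a in self.atoms:
            if a.name == name:
                return a
        raise KeyError(f"residue {self.chain_id}{self.number}{self.icode} has no atom {name!r}")

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if not a.is_hydrogen]


@dataclasses.dataclass
class Assembly:
    """An ordered set of chains of residues with Å coordinates."""

    id: str
    chains: list[str]
    residues: list[Residue]
    source: dict | None = None

    def __post_init__(self) -> None:
        known = set(self.chains)
        seen: set[tuple[str, int, str]] = set()
        for r in self.residues:
            if r.chain_id not in known:
                raise ValueError(f"residue {r.key} references unknown chain {r.chain_id!r}")
            if r.key in seen:
                raise ValueError(f"duplicate residue identifier {r.key}")
            seen.add(r.key)
            if not r.atoms:
                raise ValueError(f"residue {r.key} has no atoms")

    def chain_residues(self, chain_id: str, het: bool = False) -> list[Residue]:
        if chain_id not in self.chains:
            raise KeyError(f"unknown chain {chain_id!r}; available: {self.chains}")
        return [r for r in self.residues if r.chain_id == chain_id and (het or not r.het)]

    def residue(self, chain_id: str, number: int, icode: str = "") -> Residue:
        for r in self.residues:
            if r.key == (chain_id, number, icode):
                return r
        raise KeyError(f"residue {(chain_id, number, icode)} not present (unmodeled or absent)")

    def subset_chains(self, chain_ids: Sequence[str]) -> "Assembly":
        keep = [r for r in self.residues if r.chain_id in set(chain_ids)]
        return Assembly(self.id, list(chain_ids), keep, source=self.source)

    @property
    def n_atoms(self) -> int:
        return sum(len(r.atoms) for r in self.residues)


class DomainMap:
    """Mapping from domain label to inclusive author-number ranges.

    Overlapping boundaries between successive labels are resolved with
    earlier-label precedence: the first label declared keeps a residue
    number also claimed by a later label, so the ranges always form a
    deterministic partition.
    """

    def __init__(self, labels: Mapping[str, Sequence[tuple[int, int]]]):
        self.labels: dict[str, list[tuple[int, int]]] = {}
        claimed: dict[int, str] = {}
        for label, ranges in labels.items():
            resolved: list[tuple[int, int]] = []
            covered: set[int] = set()
            for lo, hi in ranges:
                if hi < lo:
                    raise ValueError(f"label {label!r}: range {lo}-{hi} is inverted")
                span = set(range(lo, hi + 1))
                if span & covered:
                    raise ValueError(f"label {label!r}: overlapping ranges within the label")
                covered |= span
                resolved.append((int(lo), int(hi)))
            self.labels[label] = resolved
            for n in covered:
                claimed.setdefault(n, label)  # earlier label wins
        self._claimed = claimed

    def label_of(self, number: int) -> str:
        return self._claimed.get(number, UNASSIGNED)

    def residue_numbers(self, label: str) -> list[int]:
        if label not in self.labels:
            raise KeyError(f"unknown domain label {label!r}; known: {sorted(self.labels)}")
        return sorted(n for n, lab in self._claimed.items() if lab == label)

    def __iter__(self):
        return iter(self.labels)


def load_domain_maps(path: str | Path | None = None) -> dict[str, DomainMap]:
    """Load named domain maps from a YAML config (``protein -> label -> ranges``)."""
    if path is None:
        text = resources.files("resistoscope").joinpath("data/domain_maps.yaml").read_text()
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    maps = {}
    for protein, labels in raw.items():
        maps[protein] = DomainMap(
            {lab: [tuple(r) for r in ranges] for lab, ranges in labels.items()}
        )
    return maps


def default_domain_map(protein: str = "NbNRC2") -> DomainMap:
    """The shipped range annotation for a protein (default: NbNRC2)."""
    maps = load_domain_maps()
    if protein not in maps:
        raise KeyError(f"no shipped domain map for {protein!r}; known: {sorted(maps)}")
    return maps[protein]


# ---------------------------------------------------------------------------
# reading / writing


def _resolve_altlocs(atoms: list[Atom]) -> list[Atom]:
    """Keep one location per atom name: highest occupancy, ties → first altloc id."""
    by_name: dict[str, list[Atom]] = {}
    order: list[str] = []
    for a in atoms:
        if a.name not in by_name:
            order.append(a.name)
        by_name.setdefault(a.name, []).append(a)
    out = []
    for name in order:
        group = by_name[name]
        best = min(group, key=lambda a: (-a.occupancy, a.altloc))
        out.append(best)
    return out


def read_structure(
    path: str | Path,
    format: str = "auto",
    model: int | None = None,
) -> Assembly:
    """Read one model from an mmCIF or PDB file (gzip accepted) into an Assembly.

    Waters are dropped; other heteroatoms (ATP, lipids, ...) are kept and
    flagged ``het``. Alternate locations are collapsed to the
    highest-occupancy atom (ties broken alphabetically by altloc id).

    Parameters
    ----------
    path : file path
    format : ``"mmcif"``, ``"pdb"`` or ``"auto"`` (detect from contents/suffix)
    model : model number to read; ``None`` takes the first model
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    fmt = {"auto": gemmi.CoorFormat.Detect, "mmcif": gemmi.CoorFormat.Mmcif, "pdb": gemmi.CoorFormat.Pdb}
    if format not in fmt:
        raise ValueError(f"unknown format {format!r}; use mmcif, pdb or auto")
    try:
        st = gemmi.read_structure(str(path), format=fmt[format])
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"could not parse {path}: {exc}") from exc
    st.setup_entities()
    if len(st) == 0:
        raise ValueError(f"{path}: no models found")
    if model is None:
        gm = st[0]
    else:
        names = [m.num for m in st]
        matches = [m for m in st if m.num == model]
        if not matches:
            raise ValueError(f"{path}: model {model} absent; available models: {names}")
        gm = matches[0]

    chains: list[str] = []
    residues: list[Residue] = []
    for ch in gm:
        if ch.name not in chains:
            chains.append(ch.name)
        for res in ch:
            if res.name in _WATER_NAMES:
                continue
            het = res.het_flag == "H"
            atoms = [
                Atom(
                    name=a.name,
                    element=a.element.name,
                    pos=np.array([a.pos.x, a.pos.y, a.pos.z]),
                    occupancy=min(max(a.occ, 0.0), 1.0),
                    altloc=a.altloc if a.altloc != "\x00" else "",
                    bfactor=a.b_iso,
                )
                for a in res
            ]
            atoms = _resolve_altlocs(atoms)
            residues.append(
                Residue(
                    chain_id=ch.name,
                    number=res.seqid.num,
                    icode=res.seqid.icode.strip(),
                    name=res.name,
                    atoms=atoms,
                    het=het,
                )
            )
    return Assembly(
        id=st.name or path.stem,
        chains=chains,
        residues=residues,
        source={"path": str(path), "format": format, "model": gm.num},
    )


def write_structure(assembly: Assembly, path: str | Path, format: str | None = None) -> None:
    """Write an Assembly as mmCIF or PDB (format from suffix when not given)."""
    path = Path(path)
    if format is None:
        suffix = path.name.lower()
        format = "pdb" if suffix.endswith((".pdb", ".ent")) else "mmcif"
    if format not in ("mmcif", "pdb"):
        raise ValueError(f"unknown format {format!r}")

    st = gemmi.Structure()
    st.name = assembly.id
    gm = gemmi.Model(1)
    gchains: dict[str, gemmi.Chain] = {}
    for cid in assembly.chains:
        gchains[cid] = gemmi.Chain(cid)
    for r in assembly.residues:
        gr = gemmi.Residue()
        gr.name = r.name
        gr.seqid = gemmi.SeqId(r.number, r.icode or " ")
        gr.het_flag = "H" if r.het else "A"
        for a in r.atoms:
            ga = gemmi.Atom()
            ga.name = a.name
            ga.element = gemmi.Element(a.element)
            ga.pos = gemmi.Position(*a.pos)
            ga.occ = a.occupancy
            ga.altloc = a.altloc or "\x00"
            ga.b_iso = a.bfactor
            gr.add_atom(ga)
        gchains[r.chain_id].add_residue(gr)
    for cid in assembly.chains:
        gm.add_chain(gchains[cid])
    st.add_model(gm)
    st.setup_entities()
    try:
        if format == "pdb":
            st.write_pdb(str(path))
        else:
            st.make_mmcif_document().write_file(str(path))
    except (RuntimeError, OSError) as exc:
        raise OSError(f"could not write {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# selection


@dataclasses.dataclass
class Selection:
    """Ordered coordinates with back-references to (residue, atom)."""

    coords: np.ndarray  # (n, 3)
    refs: list[tuple[Residue, Atom]]

    def __len__(self) -> int:
        return len(self.refs)


def select_atoms(
    assembly: Assembly,
    chain: str | None = None,
    domain_label: str | None = None,
    domain_map: DomainMap | None = None,
    residue_numbers: Iterable[int] | None = None,
    atom_names: Sequence[str] | None = None,
    include_het: bool = False,
    include_hydrogen: bool = False,
) -> Selection:
    """Select atoms by chain / domain label / residue numbers / atom names.

    Order is deterministic: residues in assembly order (chain, number,
    icode), atoms in the order of ``atom_names`` when given, otherwise in
    residue order. Hydrogens and het groups are excluded by default.
    """
    if chain is not None and chain not in assembly.chains:
        raise KeyError(f"unknown chain {chain!r}; available: {assembly.chains}")
    allowed_numbers: set[int] | None = None
    if domain_label is not None:
        if domain_map is None:
            raise ValueError("domain_label given without a DomainMap")
        allowed_numbers = set(domain_map.residue_numbers(domain_label))
    if residue_numbers is not None:
        wanted = set(residue_numbers)
        allowed_numbers = wanted if allowed_numbers is None else (allowed_numbers & wanted)

    coords: list[np.ndarray] = []
    refs: list[tuple[Residue, Atom]] = []
    for r in assembly.residues:
        if chain is not None and r.chain_id != chain:
            continue
        if r.het and not include_het:
            continue
        if allowed_numbers is not None and r.number not in allowed_numbers:
            continue
        if atom_names is None:
            pool = r.atoms
        else:
            by_name = {a.name: a for a in r.atoms}
            pool = [by_name[n] for n in atom_names if n in by_name]
        for a in pool:
            if a.is_hydrogen and not include_hydrogen:
                continue
            coords.append(a.pos)
            refs.append((r, a))
    arr = np.array(coords, dtype=float) if coords else np.empty((0, 3))
    return Selection(coords=arr, refs=refs)


def annotate_domains(assembly: Assembly, domain_map: DomainMap) -> pd.DataFrame:
    """Per-residue domain labels; every residue gets exactly one label or "unassigned"."""
    rows = [
        {
            "chain": r.chain_id,
            "number": r.number,
            "icode": r.icode,
            "name": r.name,
            "label": UNASSIGNED if r.het else domain_map.label_of(r.number),
        }
        for r in assembly.residues
    ]
    return pd.DataFrame(rows, columns=["chain", "number", "icode", "name", "label"])
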