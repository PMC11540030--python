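"""Seeded synthetic fixtures for every analysis the package performs.

The generators build what the real inputs look like structurally while
staying fully deterministic and closed-form:

* a toy multi-domain protomer — five stacked ideal α-helical segments
  (1.5 Å rise, 100° twist per residue) standing in for the CC, NB, HD1,
  WHD and LRR domains of a CC-NLR protomer;
* ideal Cn ring assemblies with a known symmetry order, ring radius and
  optionally planted interface contacts at exact target distances;
* two-state protomer pairs whose mobile domain module is rotated by a
  known angle about a known hinge — the ground truth for conformational
  decomposition;
* grids of model-confidence metadata files across stoichiometries and
  seeds with a controlled score structure (one stoichiometry shifted up
  by a known effect, ligand chains included as in lipid-containing
  prediction runs).

Every generator consumes a single :class:`FixtureSpec` seed through
numpy's PCG64 generator, so outputs are byte-identical across runs and
platforms. Ground truths are returned as plain dictionaries and, when
fixtures are written to disk, stored as JSON sidecars next to the
coordinate files so tests never re-derive them.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np

from .structure_io import Assembly, Atom, DomainMap, Residue, write_structure
from .symmetry import apply_cyclic_symmetry, rotation_about_axis

__all__ = [
    "FixtureSpec",
    "DOMAIN_LABELS",
    "make_toy_protomer",
    "make_cyclic_fixture",
    "make_two_state_fixture",
    "make_confidence_records",
    "make_confidence_fixture",
    "write_cyclic_fixture",
    "write_two_state_fixture",
]

DOMAIN_LABELS = ("CC", "NB", "HD1", "WHD", "LRR")

_HELIX_RISE = 1.5  # Å per residue
_HELIX_TWIST = 100.0  # degrees per residue
_HELIX_RADIUS = 2.3  # Å, Cα radius of an ideal α-helix


@dataclasses.dataclass
class FixtureSpec:
    """Parameters shared by all fixture generators (seed-deterministic)."""

    seed: int = 0
    n_chains: int = 6
    ring_radius: float = 9.5
    segment_length: int = 20
    noise_sigma: float = 0.0
    #: (residue_a, residue_b, target distance Å) planted between adjacent chains
    planted_contacts: list[tuple[int, int, float]] = dataclasses.field(default_factory=list)
    mobile_rotation: float = 180.0
    #: residue whose Cα sits exactly on the protomer's local axis (ring marker)
    ring_residue: int = 50
    residue_names: dict[int, str] = dataclasses.field(default_factory=dict)
    # confidence-grid parameters
    stoichiometries: tuple[int, ...] = (4, 5, 6, 7, 8)
    seeds_per_stoichiometry: int = 10
    best_stoichiometry: int = 6
    confidence_effect: float = 0.1
    confidence_spread: float = 0.02
    confidence_base: float = 0.65
    n_ligand_chains: int = 50

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be ≥ 0")
        if self.segment_length < 4:
            raise ValueError("segment lengths must be ≥ 4 residues")


def _helix_frame(i: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    theta = np.radians(_HELIX_TWIST * i)
    r_hat = np.array([np.cos(theta), np.sin(theta), 0.0])
    t_hat = np.array([-np.sin(theta), np.cos(theta), 0.0])
    ca = _HELIX_RADIUS * r_hat + np.array([0.0, 0.0, _HELIX_RISE * i])
    return ca, r_hat, t_hat


def make_toy_protomer(spec: FixtureSpec) -> tuple[Assembly, DomainMap]:
    """Single-chain poly-alanine-like protomer with five pseudo-domains.

    Residues are numbered contiguously from 1; each of the five domain
    segments is ``segment_length`` residues of ideal helix. The residue
    ``spec.ring_residue`` (when within range) has its Cα placed exactly
    on the protomer's local axis so that ring radii of assemblies built
    from this protomer are known in closed form.
    """
    z_hat = np.array([0.0, 0.0, 1.0])
    residues: list[Residue] = []
    n_total = spec.segment_length * len(DOMAIN_LABELS)
    for i in range(n_total):
        number = i + 1
        ca, r_hat, t_hat = _helix_frame(i)
        if number == spec.ring_residue:
            ca = np.array([0.0, 0.0, _HELIX_RISE * i])
        name = spec.residue_names.get(number, "ALA")
        atoms = [
            Atom("N", "N", ca - 0.8 * r_hat + 0.6 * t_hat - 0.5 * z_hat),
            Atom("CA", "C", ca),
            Atom("C", "C", ca + 0.7 * r_hat - 0.6 * t_hat + 0.6 * z_hat),
            Atom("O", "O", ca + 1.3 * r_hat - 0.6 * t_hat + 1.2 * z_hat),
            Atom("CB", "C", ca + 1.5 * r_hat),
        ]
        residues.append(Residue("A", number, "", name, atoms))
    labels = {
        lab: [(k * spec.segment_length + 1, (k + 1) * spec.segment_length)]
        for k, lab in enumerate(DOMAIN_LABELS)
    }
    return Assembly(id=f"toy_protomer_s{spec.seed}", chains=["A"], residues=residues), DomainMap(labels)


def _plant_contacts(protomer: Assembly, spec: FixtureSpec) -> None:
    """Append marker atoms so adjacent-chain residue pairs hit target distances.

    The planted atom of residue ``a`` sits at the mid-angle between
    chain A and chain B at ring radius; the atom of residue ``b`` is
    placed so that its one-step rotated image lies exactly ``d`` below
    it, making every adjacent-chain (a, b) pair distance exactly d.
    """
    n = spec.n_chains
    half_angle = 180.0 / n
    z_values = [a.pos[2] for r in protomer.residues for a in r.atoms]
    z_mid = float(np.mean(z_values))
    R_back, t_back = rotation_about_axis(-360.0 / n, np.zeros(3), np.array([0, 0, 1.0]))
    for res_a, res_b, dist in spec.planted_contacts:
        if dist <= 0:
            raise ValueError(f"planted distance must be positive, got {dist}")
        theta = np.radians(half_angle)
        m = np.array(
            [spec.ring_radius * np.cos(theta), spec.ring_radius * np.sin(theta), z_mid]
        )
        up = np.array([0.0, 0.0, dist / 2.0])
        pos_a = m + up
        pos_b_protomer = R_back @ (m - up) + t_back
        protomer.residue("A", res_a).atoms.append(Atom("CG", "C", pos_a))
        protomer.residue("A", res_b).atoms.append(Atom("CG", "C", pos_b_protomer))


def make_cyclic_fixture(spec: FixtureSpec) -> tuple[Assembly, DomainMap, dict]:
    """Ideal Cn assembly with known order, ring radius and planted contacts.

    The toy protomer is translated so its local axis sits at
    ``ring_radius`` from the global z axis, contacts are planted, the
    protomer is replicated by rotations of 360/n, and Gaussian
    coordinate noise (if any) is added last. Raises when a planted
    distance is geometrically infeasible, i.e. some other atom pair of
    the planted residues comes closer than the target.
    """
    if spec.n_chains < 2:
        raise ValueError("n_chains must be ≥ 2")
    protomer, domain_map = make_toy_protomer(spec)
    for r in protomer.residues:
        for a in r.atoms:
            a.pos = a.pos + np.array([spec.ring_radius, 0.0, 0.0])
    _plant_contacts(protomer, spec)
    assembly = apply_cyclic_symmetry(protomer, spec.n_chains)
    assembly.id = f"c{spec.n_chains}_ring_s{spec.seed}"

    for res_a, res_b, dist in spec.planted_contacts:
        ra = assembly.residue(assembly.chains[0], res_a)
        rb = assembly.residue(assembly.chains[1], res_b)
        dmin = min(
            float(np.linalg.norm(x.pos - y.pos)) for x in ra.atoms for y in rb.atoms
        )
        if abs(dmin - dist) > 0.01:
            raise ValueError(
                f"planted contact ({res_a}, {res_b}, {dist} Å) infeasible: "
                f"another atom pair of the residues is at {dmin:.2f} Å"
            )
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        for r in assembly.residues:
            for a in r.atoms:
                a.pos = a.pos + rng.normal(0.0, spec.noise_sigma, size=3)
    truth = {
        "seed": spec.seed,
        "order": spec.n_chains,
        "ring_radius": spec.ring_radius,
        "ring_residue": spec.ring_residue,
        "planted_contacts": [list(c) for c in spec.planted_contacts],
        "noise_sigma": spec.noise_sigma,
        "axis_point": [0.0, 0.0, 0.0],
        "axis_dir": [0.0, 0.0, 1.0],
    }
    return assembly, domain_map, truth


def make_two_state_fixture(
    spec: FixtureSpec,
    mobile_labels: Sequence[str] = ("NB", "HD1"),
) -> tuple[Assembly, Assembly, DomainMap, dict]:
    """Two protomer states related by a known rigid rotation of one module.

    State 2 equals state 1 with the residues of ``mobile_labels`` rotated
    by ``spec.mobile_rotation`` degrees about a hinge axis (the x axis
    through the mobile module's boundary midpoint); the anchor module is
    untouched. Independent Gaussian noise is added to both states when
    ``noise_sigma > 0``.
    """
    if not 0 < spec.mobile_rotation <= 180:
        raise ValueError("mobile_rotation must be in (0, 180] degrees")
    state1, domain_map = make_toy_protomer(spec)
    state2, _ = make_toy_protomer(spec)
    state2.id = f"{state2.id}_rotated"
    mobile_numbers: set[int] = set()
    for lab in mobile_labels:
        mobile_numbers.update(domain_map.residue_numbers(lab))
    mobile_cas = [
        r.atom("CA").pos for r in state1.residues if r.number in mobile_numbers
    ]
    hinge_point = np.array(mobile_cas)[[0, -1]].mean(axis=0)
    R, t = rotation_about_axis(spec.mobile_rotation, hinge_point, np.array([1.0, 0.0, 0.0]))
    for r in state2.residues:
        if r.number in mobile_numbers:
            for a in r.atoms:
                a.pos = R @ a.pos + t
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        for state in (state1, state2):
            for r in state.residues:
                for a in r.atoms:
                    a.pos = a.pos + rng.normal(0.0, spec.noise_sigma, size=3)
    truth = {
        "seed": spec.seed,
        "mobile_rotation": spec.mobile_rotation,
        "mobile_labels": list(mobile_labels),
        "anchor_labels": [l for l in DOMAIN_LABELS if l not in mobile_labels],
        "noise_sigma": spec.noise_sigma,
    }
    return state1, state2, domain_map, truth


# ---------------------------------------------------------------------------
# confidence metadata


def make_confidence_records(spec: FixtureSpec) -> tuple[list[dict], dict]:
    """Metadata dictionaries across stoichiometries × seeds with a planted effect.

    Scores are drawn from normal distributions (clipped to [0, 1]) at
    ``confidence_base``, with ``best_stoichiometry`` shifted up by
    ``confidence_effect``. Each model includes ``n_ligand_chains``
    ligand chains (lower, noisier per-chain scores), mirroring
    prediction runs that include lipid copies; chain types are recorded
    so protein-only stoichiometry can be inferred downstream.
    """
    rng = np.random.default_rng(spec.seed)
    clip = lambda x: float(np.clip(x, 0.0, 1.0))
    records = []
    for stoich in spec.stoichiometries:
        level = spec.confidence_base + (
            spec.confidence_effect if stoich == spec.best_stoichiometry else 0.0
        )
        for seed in range(1, spec.seeds_per_stoichiometry + 1):
            n_chains = stoich + spec.n_ligand_chains
            chain_types = ["protein"] * stoich + ["ligand"] * spec.n_ligand_chains
            chain_ptm = [
                clip(rng.normal(level, spec.confidence_spread)) for _ in range(stoich)
            ] + [clip(rng.normal(0.45, 0.05)) for _ in range(spec.n_ligand_chains)]
            pair = rng.normal(0.5, 0.05, size=(n_chains, n_chains))
            pair[:stoich, :stoich] = rng.normal(
                level, spec.confidence_spread, size=(stoich, stoich)
            )
            pair = np.clip((pair + pair.T) / 2.0, 0.0, 1.0)
            records.append(
                {
                    "model_id": f"oligomer_{stoich}mer_seed{seed}_model_0",
                    "seed": seed,
                    "ptm": clip(rng.normal(level, spec.confidence_spread)),
                    "iptm": clip(rng.normal(level, spec.confidence_spread)),
                    "chain_ptm": chain_ptm,
                    "chain_pair_iptm": pair.tolist(),
                    "chain_types": chain_types,
                }
            )
    truth = {
        "seed": spec.seed,
        "best_stoichiometry": spec.best_stoichiometry,
        "effect": spec.confidence_effect,
        "stoichiometries": list(spec.stoichiometries),
        "seeds_per_stoichiometry": spec.seeds_per_stoichiometry,
    }
    return records, truth


def make_confidence_fixture(spec: FixtureSpec, out_dir: str | Path) -> dict:
    """Write the confidence grid as one JSON metadata file per model."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records, truth = make_confidence_records(spec)
    for rec in records:
        (out_dir / f"{rec['model_id']}.json").write_text(json.dumps(rec))
    (out_dir / "truth.json").write_text(json.dumps(truth, indent=2))
    return truth


# ---------------------------------------------------------------------------
# on-disk fixtures (mmCIF + truth sidecar)


def write_cyclic_fixture(spec: FixtureSpec, out_dir: str | Path) -> dict[str, Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    assembly, domain_map, truth = make_cyclic_fixture(spec)
    cif = out_dir / f"{assembly.id}.cif"
    write_structure(assembly, cif, format="mmcif")
    truth_path = out_dir / f"{assembly.id}.truth.json"
    truth_path.write_text(json.dumps(truth, indent=2))
    return {"structure": cif, "truth": truth_path}


def write_two_state_fixture(spec: FixtureSpec, out_dir: str | Path) -> dict[str, Path]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    s1, s2, domain_map, truth = make_two_state_fixture(spec)
    p1 = out_dir / f"{s1.id}.cif"
    p2 = out_dir / f"{s2.id}.cif"
    write_structure(s1, p1, format="mmcif")
    write_structure(s2, p2, format="mmcif")
    truth_path = out_dir / f"two_state_s{spec.seed}.truth.json"
    truth_path.write_text(json.dumps(truth, indent=2))
    return {"state1": p1, "state2": p2, "truth": truth_path}
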