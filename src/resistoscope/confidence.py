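"""Predicted-model confidence metadata: parsing, ranking, tiers, reports.

Structure predictors emit a JSON metadata file per model carrying global
and per-chain confidence metrics: pTM (predicted TM-score of the whole
model), ipTM (interface pTM, sensitive to inter-chain packing), per-chain
pTM and the chain-pair ipTM matrix. When the same complex is modelled at
several stoichiometries with several seeds each, the per-stoichiometry
medians of these metrics rank the candidate oligomeric states — the
procedure used to ask whether a hexamer or a pentamer is the better
supported resistosome assembly.

Confidence tiers follow the common 0.6 / 0.7 conventions: models with
pTM or ipTM below 0.6 are low confidence; models with pTM, ipTM and the
minimum per-chain pTM all at 0.7 or higher are confident; the rest are
moderate.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ConfidenceRecord",
    "StoichiometryRanking",
    "parse_model_metadata",
    "record_from_mapping",
    "min_chain_ptm",
    "aggregate_by_stoichiometry",
    "classify_model_confidence",
    "load_metadata_directory",
    "prediction_report",
]

# accepted key aliases, canonical first
_ALIASES = {
    "ptm": ("ptm", "pTM"),
    "iptm": ("iptm", "ipTM"),
    "chain_ptm": ("chain_ptm", "per_chain_ptm", "chain_ptms"),
    "chain_pair_iptm": ("chain_pair_iptm", "pair_iptm", "chain_pair_iptms"),
}


@dataclasses.dataclass
class ConfidenceRecord:
    model_id: str
    stoichiometry: int
    seed: int
    ptm: float
    iptm: float
    chain_ptm: list[float]
    chain_pair_iptm: np.ndarray
    chain_types: list[str] | None = None  # "protein" / "ligand" per chain
    mean_plddt: float | None = None

    def __post_init__(self) -> None:
        for field, lo, hi in (("ptm", 0, 1), ("iptm", 0, 1)):
            v = getattr(self, field)
            if not lo <= v <= hi:
                raise ValueError(f"{field}={v} outside [{lo}, {hi}]")
        if any(not 0 <= v <= 1 for v in self.chain_ptm):
            raise ValueError("chain_ptm values outside [0, 1]")
        self.chain_pair_iptm = np.asarray(self.chain_pair_iptm, dtype=float)
        m = self.chain_pair_iptm
        if m.ndim != 2 or m.shape[0] != m.shape[1] or m.shape[0] != len(self.chain_ptm):
            raise ValueError("chain_pair_iptm must be square and match chain_ptm length")
        if self.chain_types is not None and len(self.chain_types) != len(self.chain_ptm):
            raise ValueError("chain_types length must match chain_ptm length")
        if self.mean_plddt is not None and not 0 <= self.mean_plddt <= 100:
            raise ValueError(f"mean_plddt={self.mean_plddt} outside [0, 100]")

    def to_json(self) -> dict:
        out = {
            "model_id": self.model_id,
            "stoichiometry": self.stoichiometry,
            "seed": self.seed,
            "ptm": self.ptm,
            "iptm": self.iptm,
            "chain_ptm": list(self.chain_ptm),
            "chain_pair_iptm": self.chain_pair_iptm.tolist(),
        }
        if self.chain_types is not None:
            out["chain_types"] = list(self.chain_types)
        if self.mean_plddt is not None:
            out["mean_plddt"] = self.mean_plddt
        return out


def _lookup(data: dict, canonical: str):
    for key in _ALIASES[canonical]:
        if key in data:
            return data[key]
    return None


def record_from_mapping(data: dict, default_id: str = "record") -> ConfidenceRecord:
    """Build a ConfidenceRecord from an already-parsed metadata mapping.

    Flat and aliased key layouts are accepted; unknown extra keys are
    ignored. Protein stoichiometry is the count of protein chains when a
    ``chain_types`` list is present (ligand copies excluded), otherwise
    an explicit ``stoichiometry`` field, otherwise the chain count.
    """
    missing = [k for k in ("ptm", "iptm", "chain_ptm", "chain_pair_iptm") if _lookup(data, k) is None]
    if missing:
        raise ValueError(f"{default_id}: missing required field(s): {missing}")
    chain_ptm = list(_lookup(data, "chain_ptm"))
    chain_types = data.get("chain_types")
    if chain_types is not None:
        stoich = sum(1 for t in chain_types if t == "protein")
    elif "stoichiometry" in data:
        stoich = int(data["stoichiometry"])
    else:
        stoich = len(chain_ptm)
    return ConfidenceRecord(
        model_id=str(data.get("model_id", default_id)),
        stoichiometry=stoich,
        seed=int(data.get("seed", 0)),
        ptm=float(_lookup(data, "ptm")),
        iptm=float(_lookup(data, "iptm")),
        chain_ptm=[float(v) for v in chain_ptm],
        chain_pair_iptm=np.asarray(_lookup(data, "chain_pair_iptm"), dtype=float),
        chain_types=chain_types,
        mean_plddt=data.get("mean_plddt"),
    )


def parse_model_metadata(path: str | Path) -> ConfidenceRecord:
    """Parse one model-confidence JSON file into a ConfidenceRecord."""
    path = Path(path)
    return record_from_mapping(json.loads(path.read_text()), default_id=path.stem)


def load_metadata_directory(directory: str | Path) -> list[ConfidenceRecord]:
    """Parse all ``*.json`` metadata files in a directory.

    When files follow a ``..._model_<k>.json`` ranked-sibling naming
    scheme, only the top-ranked sibling (``model_0``) of each group is
    retained.
    """
    paths = [
        p for p in sorted(Path(directory).glob("*.json")) if p.name != "truth.json"
    ]  # truth.json is the generator's ground-truth sidecar, not model metadata
    import re

    ranked = re.compile(r"^(?P<stem>.*)_model_(?P<rank>\d+)$")
    keep = []
    groups: dict[str, list[tuple[int, Path]]] = {}
    for p in paths:
        m = ranked.match(p.stem)
        if m:
            groups.setdefault(m.group("stem"), []).append((int(m.group("rank")), p))
        else:
            keep.append(p)
    for stem, members in groups.items():
        keep.append(min(members)[1])
    return [parse_model_metadata(p) for p in sorted(keep)]


def min_chain_ptm(record: ConfidenceRecord, protein_chains_only: bool = True) -> float:
    """Minimum per-chain pTM over the selected chains."""
    values = record.chain_ptm
    if protein_chains_only and record.chain_types is not None:
        values = [
            v for v, t in zip(record.chain_ptm, record.chain_types) if t == "protein"
        ]
    if not values:
        raise ValueError("chain selection is empty")
    return float(min(values))


def classify_model_confidence(record: ConfidenceRecord) -> str:
    """Tier: low (<0.6 on pTM or ipTM), confident (≥0.7 on all), else moderate."""
    if record.ptm < 0.6 or record.iptm < 0.6:
        return "low"
    if (
        record.ptm >= 0.7
        and record.iptm >= 0.7
        and min_chain_ptm(record) >= 0.7
    ):
        return "confident"
    return "moderate"


@dataclasses.dataclass
class StoichiometryRanking:
    summaries: pd.DataFrame  # indexed by stoichiometry
    best: int


def aggregate_by_stoichiometry(records: Sequence[ConfidenceRecord]) -> StoichiometryRanking:
    """Median and interquartile spread per stoichiometry, and the best one.

    Ranking order: median ipTM, ties broken by median pTM, then median
    minimum chain pTM (a repository convention — the metrics are
    reported side by side and rarely combined into one score).
    """
    if not records:
        raise ValueError("no records to aggregate")
    rows = [
        {
            "stoichiometry": r.stoichiometry,
            "seed": r.seed,
            "ptm": r.ptm,
            "iptm": r.iptm,
            "min_chain_ptm": min_chain_ptm(r),
        }
        for r in records
    ]
    df = pd.DataFrame(rows)
    g = df.groupby("stoichiometry")
    summaries = pd.DataFrame(
        {
            "n_models": g.size(),
            "ptm_median": g["ptm"].median(),
            "ptm_iqr": g["ptm"].quantile(0.75) - g["ptm"].quantile(0.25),
            "iptm_median": g["iptm"].median(),
            "iptm_iqr": g["iptm"].quantile(0.75) - g["iptm"].quantile(0.25),
            "min_chain_ptm_median": g["min_chain_ptm"].median(),
        }
    )
    order = summaries.sort_values(
        ["iptm_median", "ptm_median", "min_chain_ptm_median"],
        ascending=False,
        kind="mergesort",
    )
    return StoichiometryRanking(summaries=summaries, best=int(order.index[0]))


def prediction_report(
    model_assembly,
    reference_assembly,
    record: ConfidenceRecord | None = None,
    contact_cutoff: float = 4.5,
    prune_cutoff: float = 2.0,
) -> dict:
    """Predicted-vs-experimental comparison for one oligomer model.

    Combines the cyclically-paired pruned-RMSD alignment, the per
    adjacent-chain-pair contact overlap at ``contact_cutoff``, and the
    model's confidence tier into one report dictionary.
    """
    from .interfaces import find_contacts
    from .superposition import pair_chains_cyclically, pruned_match_align

    chain_map, _ = pair_chains_cyclically(model_assembly, reference_assembly)
    align = pruned_match_align(
        model_assembly,
        reference_assembly,
        chain_map=chain_map,
        prune_cutoff=prune_cutoff,
    )

    def adjacent_summaries(assembly):
        out = {}
        n = len(assembly.chains)
        for k in range(n):
            a, b = assembly.chains[k], assembly.chains[(k + 1) % n]
            out[k] = find_contacts(assembly, a, b, cutoff=contact_cutoff)
        return out

    model_ifaces = adjacent_summaries(model_assembly)
    # reference interfaces expressed in the model's chain frame via the map
    ref_order = [chain_map[c] for c in model_assembly.chains]
    ref_ifaces = {}
    for k in range(len(ref_order)):
        a, b = ref_order[k], ref_order[(k + 1) % len(ref_order)]
        ref_ifaces[k] = find_contacts(reference_assembly, a, b, cutoff=contact_cutoff)

    # recovered fraction: share of reference contacts also present in the model
    inverse = {v: k for k, v in chain_map.items()}

    def remap(keys):
        return {((inverse[p[0]], p[1]), (inverse[q[0]], q[1])) for p, q in keys}

    per_interface = {}
    pooled_model: set = set()
    pooled_ref: set = set()
    for k in model_ifaces:
        mk = model_ifaces[k].pair_keys()
        rk = remap(ref_ifaces[k].pair_keys())
        per_interface[k] = (len(rk & mk) / len(rk)) if rk else float("nan")
        pooled_model |= mk
        pooled_ref |= rk
    report = {
        "rmsd_all": align.rmsd_all,
        "rmsd_pruned": align.rmsd_pruned,
        "n_matched": align.n_matched,
        "n_retained": align.n_retained,
        "recovered_fraction": (
            len(pooled_ref & pooled_model) / len(pooled_ref) if pooled_ref else float("nan")
        ),
        "per_interface_recovered": per_interface,
    }
    if record is not None:
        report["tier"] = classify_model_confidence(record)
        report["ptm"] = record.ptm
        report["iptm"] = record.iptm
    return report
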