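import json

import numpy as np
import pytest

from resistoscope.structure_io import Assembly, Atom, Residue, read_structure
from resistoscope.synthetic_data import (
    FixtureSpec,
    make_cyclic_fixture,
    make_two_state_fixture,
    write_cyclic_fixture,
)


@pytest.fixture(scope="session")
def c6_spec():
    return FixtureSpec(seed=11, planted_contacts=[(10, 12, 3.3)])


@pytest.fixture(scope="session")
def c6_assembly(c6_spec):
    """In-memory ideal C6 ring with one planted 3.3 Å contact."""
    assembly, domain_map, truth = make_cyclic_fixture(c6_spec)
    return assembly, domain_map, truth


@pytest.fixture(scope="session")
def c6_from_file(c6_spec, tmp_path_factory):
    """Same C6 ring, but written to mmCIF and read back (exercises structure_io)."""
    paths = write_cyclic_fixture(c6_spec, tmp_path_factory.mktemp("c6"))
    assembly = read_structure(paths["structure"])
    truth = json.loads(paths["truth"].read_text())
    return assembly, truth


@pytest.fixture(scope="session")
def two_state_90():
    spec = FixtureSpec(seed=7, mobile_rotation=90.0)
    return make_two_state_fixture(spec)


def _random_chain(rng, chain_id, n_res, center):
    residues = []
    for i in range(n_res):
        base = center + rng.uniform(-8, 8, size=3)
        atoms = [
            Atom(name, "C" if k else "N", base + rng.normal(0, 1.2, size=3))
            for k, name in enumerate(["N", "CA", "CB"])
        ]
        residues.append(Residue(chain_id, i + 1, "", "ALA", atoms))
    return residues


def make_random_dimer(seed: int, n_res: int = 15, separation: float = 6.0) -> Assembly:
    """Random two-chain atom cloud for exact-search oracle comparisons."""
    rng = np.random.default_rng(seed)
    res = _random_chain(rng, "A", n_res, np.zeros(3))
    res += _random_chain(rng, "B", n_res, np.array([separation, 0.0, 0.0]))
    return Assembly(f"random_dimer_{seed}", ["A", "B"], res)


def brute_force_contacts(assembly, chain_a, chain_b, cutoff):
    """Independent all-pairs contact oracle (heavy atoms)."""
    out = {}
    for ra in assembly.chain_residues(chain_a):
        for rb in assembly.chain_residues(chain_b):
            best = None
            for a in ra.atoms:
                if a.element.upper() in ("H", "D"):
                    continue
                for b in rb.atoms:
                    if b.element.upper() in ("H", "D"):
                        continue
                    d = float(np.linalg.norm(a.pos - b.pos))
                    if best is None or d < best:
                        best = d
            if best is not None and best <= cutoff:
                out[(ra.key, rb.key)] = best
    return out
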