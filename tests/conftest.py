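import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from abfekit.structio import Atom, Structure
from abfekit.toysampler import default_toy_zone, make_toy_complex

settings.register_profile(
    "repro",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def toy_complex():
    """Deterministic 3-residue peptide + branched ligand fixture."""
    return make_toy_complex(seed=0)


@pytest.fixture(scope="session")
def toy_zone(toy_complex):
    return default_toy_zone(toy_complex)


def build_structure(positions, names=None, roles=None, bonds=(), elements=None,
                    resname="LIG", chain="B"):
    """Ad-hoc structure builder for geometric unit tests (1-based serials)."""
    positions = np.asarray(positions, dtype=float)
    n = positions.shape[0]
    names = names or [f"C{i + 1}" for i in range(n)]
    elements = elements or ["C"] * n
    atoms = [
        Atom(serial=i + 1, name=names[i], element=elements[i], residue_name=resname,
             residue_number=1, chain_id=chain, position=positions[i],
             is_hydrogen=elements[i].upper() == "H")
        for i in range(n)
    ]
    s = Structure(atoms=atoms, bonds=set(tuple(sorted(b)) for b in bonds))
    role_list = roles or ["ligand"] * n
    for atom, role in zip(atoms, role_list):
        s.roles[atom.serial] = role
    return s
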