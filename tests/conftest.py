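import itertools

import pytest

from facegest.meaning import Literal, Meaning, Ontology
from facegest.systems import attested_inventory, builtin_system, default_ontology


@pytest.fixture(scope="session")
def ontology():
    return default_ontology()

@pytest.fixture(scope="session")
def attested():
    return attested_inventory()

@pytest.fixture(scope="session")
def system1():
    return builtin_system("system1")

@pytest.fixture(scope="session")
def system2():
    return builtin_system("system2")

@pytest.fixture(scope="session")
def system3():
    return builtin_system("system3")


def all_meanings(atoms):
    """Every meaning over the given atoms: each atom absent, positive or negated."""
    out = []
    for signs in itertools.product((None, True, False), repeat=len(atoms)):
        lits = [
            Literal(a, s) for a, s in zip(atoms, signs) if s is not None
        ]
        out.append(Meaning(lits))
    return out


# ---------------------------------------------------------------------------
# Independent brute-force oracles (naive repeated scanning, no graph library)
# ---------------------------------------------------------------------------

def oracle_close(m: Meaning, o: Ontology) -> Meaning:
    pos = set(a for a in m.positives())
    changed = True
    while changed:
        changed = False
        for a, b in o.entailment_edges:
            if a in pos and b not in pos:
                pos.add(b)
                changed = True
        for defined, body in o.definitions.items():
            if defined in pos:
                for part in body:
                    if part not in pos:
                        pos.add(part)
                        changed = True
    return Meaning([Literal(a, True) for a in pos] + [Literal(a, False) for a in m.negatives()])


def oracle_entails(m1: Meaning, m2: Meaning, o: Ontology) -> bool:
    return oracle_close(m2, o).literals <= oracle_close(m1, o).literals


def oracle_consistent(m: Meaning, o: Ontology) -> bool:
    c = oracle_close(m, o)
    pos, neg = c.positives(), c.negatives()
    if pos & neg:
        return False
    for ex in o.exclusions:
        if {ex.first, ex.second} <= pos:
            return False
    for inc in o.incompatibilities:
        if inc.literal in c.literals and inc.atom in pos:
            return False
    return True


def oracle_residual(specific: Meaning, general: Meaning, o: Ontology) -> Meaning:
    return Meaning(oracle_close(specific, o).literals - oracle_close(general, o).literals)
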