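"""Meanings as conjunctions of signed atoms over an entailment ontology.

A :class:`Meaning` is a flat conjunction of signed atomic commitments
("approach", "not help", ...). An :class:`Ontology` supplies the background
axioms: entailment edges between atoms, definitional equivalences (a defined
atom abbreviates a conjunction, e.g. submission = fear directed at the
addressee), mutually exclusive atom pairs, and incompatibilities between a
signed literal and an atom. On top of these the module provides conjunction,
forward-chaining closure, entailment, consistency checking, and the residual
(the surplus content of a more specific meaning over a more general one) that
pragmatic strengthening negates.

The algebra is deliberately minimal: no disjunction, no quantification, one
level of negation. Negated literals do not propagate along entailment edges
(no contrapositive closure); negative information only interacts with the
axioms through the consistency check.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import networkx as nx

__all__ = [
    "Atom",
    "Literal",
    "Meaning",
    "Exclusion",
    "Incompatibility",
    "Ontology",
    "OntologyError",
    "ContractError",
    "conjoin",
    "close",
    "entails",
    "consistent",
    "residual",
]


class OntologyError(ValueError):
    """Raised for ill-formed ontologies (cycles, undefined atoms, ...)."""


class ContractError(ValueError):
    """Raised when an operation's precondition is violated."""


@dataclass(frozen=True)
class Atom:
    """An atomic meaning component, e.g. APPROACH or FEAR."""

    id: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id or not self.id.isidentifier():
            raise OntologyError(f"atom id must be a bare token, got {self.id!r}")


@dataclass(frozen=True, order=True)
class Literal:
    """A signed atom: ``Literal("HELP", positive=False)`` is "not help"."""

    atom: str
    positive: bool = True

    def negate(self) -> "Literal":
        return Literal(self.atom, not self.positive)

    def __str__(self) -> str:
        return self.atom if self.positive else f"~{self.atom}"

    @classmethod
    def parse(cls, token: str) -> "Literal":
        token = token.strip()
        if token.startswith("~") or token.startswith("¬"):
            return cls(token[1:], False)
        return cls(token, True)


class Meaning:
    """An immutable conjunction of literals (set semantics, order-free).

    The empty meaning is permitted and plays the role of a contentless
    signal (a neutral face contributes nothing to a combination).
    """

    __slots__ = ("literals",)

    def __init__(self, literals: Iterable[Literal | str] = ()) -> None:
        lits = frozenset(
            lit if isinstance(lit, Literal) else Literal.parse(lit) for lit in literals
        )
        object.__setattr__(self, "literals", lits)

    @classmethod
    def of(cls, *tokens: str) -> "Meaning":
        """Convenience constructor: ``Meaning.of("APPROACH", "~HELP")``."""
        return cls(tokens)

    # -- set-like views -------------------------------------------------
    def positives(self) -> frozenset[str]:
        return frozenset(l.atom for l in self.literals if l.positive)

    def negatives(self) -> frozenset[str]:
        return frozenset(l.atom for l in self.literals if not l.positive)

    def atoms(self) -> frozenset[str]:
        return frozenset(l.atom for l in self.literals)

    def __contains__(self, lit: Literal) -> bool:
        return lit in self.literals

    def __iter__(self) -> Iterator[Literal]:
        return iter(sorted(self.literals))

    def __len__(self) -> int:
        return len(self.literals)

    def __bool__(self) -> bool:
        return bool(self.literals)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, Meaning) and self.literals == other.literals

    def __hash__(self) -> int:
        return hash(self.literals)

    def __or__(self, other: "Meaning") -> "Meaning":
        return conjoin(self, other)

    def __repr__(self) -> str:
        inner = " ∧ ".join(str(l) for l in sorted(self.literals)) or "⊤"
        return f"Meaning({inner})"


EMPTY = Meaning()


@dataclass(frozen=True)
class Exclusion:
    """A mutually exclusive atom pair, optionally governed by an atom.

    A governing atom turns the exclusion into a disjunctive axiom: whenever
    the governor holds, exactly one of the two members should hold (fear is
    either fear of the addressee or fear of an external threat). Ungoverned
    exclusions only forbid co-occurrence.
    """

    first: str
    second: str
    governed_by: str | None = None

    @property
    def pair(self) -> frozenset[str]:
        return frozenset((self.first, self.second))


@dataclass(frozen=True)
class Incompatibility:
    """A signed literal that cannot co-occur with an atom.

    E.g. "not a request for help" is incompatible with "external threat":
    were the threat external, help would be welcome.
    """

    literal: Literal
    atom: str


@dataclass(frozen=True)
class Ontology:
    """Atoms plus the axioms that govern closure and consistency."""

    atoms: tuple[Atom, ...]
    entailment_edges: tuple[tuple[str, str], ...] = ()
    definitions: Mapping[str, frozenset[str]] = field(default_factory=dict)
    exclusions: tuple[Exclusion, ...] = ()
    incompatibilities: tuple[Incompatibility, ...] = ()

    def __post_init__(self) -> None:
        ids = [a.id for a in self.atoms]
        if len(set(ids)) != len(ids):
            raise OntologyError("duplicate atom ids in ontology")
        known = set(ids)

        def check(atom: str, where: str) -> None:
            if atom not in known:
                raise OntologyError(f"undefined atom {atom!r} in {where}")

        for a, b in self.entailment_edges:
            check(a, "entailment edge")
            check(b, "entailment edge")
        object.__setattr__(
            self,
            "definitions",
            {d: frozenset(body) for d, body in dict(self.definitions).items()},
        )
        for defined, body in self.definitions.items():
            check(defined, "definition")
            for b in body:
                check(b, f"definition of {defined}")
            if not body:
                raise OntologyError(f"definition of {defined} is empty")
        for ex in self.exclusions:
            check(ex.first, "exclusion")
            check(ex.second, "exclusion")
            if ex.first == ex.second:
                raise OntologyError("exclusion pair must contain two distinct atoms")
            if ex.governed_by is not None:
                check(ex.governed_by, "exclusion governor")
        for inc in self.incompatibilities:
            check(inc.literal.atom, "incompatibility")
            check(inc.atom, "incompatibility")
        # The expansion graph (entailment edges plus defined -> part edges)
        # must be acyclic for forward chaining to terminate at a fixpoint.
        g = nx.DiGraph()
        g.add_nodes_from(known)
        g.add_edges_from(self.entailment_edges)
        for defined, body in self.definitions.items():
            for part in body:
                g.add_edge(defined, part)
        if not nx.is_directed_acyclic_graph(g):
            cyc = nx.find_cycle(g)
            raise OntologyError(f"entailment/definition graph has a cycle: {cyc}")
        object.__setattr__(self, "_expansion", g)

    @property
    def atom_ids(self) -> frozenset[str]:
        return frozenset(a.id for a in self.atoms)

    def check_meaning(self, m: Meaning) -> None:
        unknown = m.atoms() - self.atom_ids
        if unknown:
            raise OntologyError(f"meaning uses atoms outside the ontology: {sorted(unknown)}")

    def governed_exclusions(self) -> tuple[Exclusion, ...]:
        return tuple(ex for ex in self.exclusions if ex.governed_by is not None)


def conjoin(m1: Meaning, m2: Meaning) -> Meaning:
    """Conjunction of two meanings: the union of their literal sets.

    Commutative, associative and idempotent; the empty meaning is the
    identity. Consistency of the result is a separate question, checked by
    :func:`consistent`.
    """
    return Meaning(m1.literals | m2.literals)


def close(m: Meaning, o: Ontology) -> Meaning:
    """Entailment closure: forward-chain positive commitments to a fixpoint.

    Every atom reachable from a positive literal via an entailment edge or a
    definitional expansion (defined atom -> its parts) is added positively.
    Negative literals are carried through unchanged.
    """
    o.check_meaning(m)
    g: nx.DiGraph = o._expansion  # type: ignore[attr-defined]
    pos: set[str] = set()
    for seed in m.positives():
        pos.add(seed)
        pos.update(nx.descendants(g, seed))
    lits = {Literal(a, True) for a in pos} | {Literal(a, False) for a in m.negatives()}
    return Meaning(lits)


def entails(m1: Meaning, m2: Meaning, o: Ontology) -> bool:
    """True iff every commitment of ``m2`` follows from ``m1``.

    Checked as literal-set containment after closure; reflexive and
    transitive, hence a preorder on meanings.
    """
    return close(m2, o).literals <= close(m1, o).literals


def consistent(m: Meaning, o: Ontology) -> bool:
    """True unless closure triggers a sign clash, exclusion or incompatibility."""
    c = close(m, o)
    pos, neg = c.positives(), c.negatives()
    if pos & neg:
        return False
    for ex in o.exclusions:
        if ex.first in pos and ex.second in pos:
            return False
    for inc in o.incompatibilities:
        if inc.literal in c.literals and inc.atom in pos:
            return False
    return True


def residual(specific: Meaning, general: Meaning, o: Ontology) -> Meaning:
    """The surplus of a more specific meaning over a more general one.

    Precondition: ``specific`` entails ``general``. The residual is the set
    difference of the closures, so ``residual ⊕ general`` entails
    ``specific``. Pragmatic strengthening negates exactly this surplus.
    """
    if not entails(specific, general, o):
        raise ContractError(
            f"residual requires the first meaning to entail the second; "
            f"{specific!r} does not entail {general!r}"
        )
    return Meaning(close(specific, o).literals - close(general, o).literals)
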