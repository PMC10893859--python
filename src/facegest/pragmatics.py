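"""Informativity-based pragmatic strengthening and contextual resolution.

The Informativity Principle: a signal in competition with a strictly more
specific alternative is interpreted as excluding the alternative's surplus
content. Concretely, if a competitor's literal meaning strictly entails the
target's, the target's pragmatic meaning conjoins the negation of the
competitor's surplus (its residual over the target), provided the result
stays consistent.

``resolve`` then applies disjunctive background knowledge: when a governed
exclusion's governor holds (fear is either of the addressee or of an
external threat) and exactly one disjunct is consistent with the meaning,
that disjunct is added. A meaning whose positive content satisfies a
definition is re-labelled with the defined atom (fear-of-you reported as
submission) in the trace.

Every step is recorded in a :class:`DerivationTrace` so a derivation can be
audited end to end: literal conjunction, competitor comparison,
strengthening, and resolution.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from .meaning import Meaning, Literal, Ontology, conjoin, close, consistent, entails, residual
from .systems import SemanticSystem, Signal, _signal_sort_key, interpret_literal

__all__ = [
    "AlternativeSet",
    "DerivationStep",
    "DerivationTrace",
    "alternatives",
    "strengthen",
    "resolve",
]

POLICIES = ("same-face-gesture-swap", "uniform")


@dataclass(frozen=True)
class DerivationStep:
    rule: str
    inputs: tuple[Meaning, ...]
    output: Meaning
    note: str = ""


@dataclass(frozen=True)
class DerivationTrace:
    """Ordered, replayable record of a derivation."""

    steps: tuple[DerivationStep, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "steps", tuple(self.steps))

    @property
    def final(self) -> Meaning:
        if not self.steps:
            raise ValueError("empty trace has no final meaning")
        return self.steps[-1].output

    def altered(self) -> bool:
        """True iff some step changed the running meaning."""
        outs = [s.output for s in self.steps]
        return any(a != b for a, b in zip(outs, outs[1:])) if len(outs) > 1 else False

    def to_text(self) -> str:
        lines = []
        for i, s in enumerate(self.steps, 1):
            lines.append(f"{i}. [{s.rule}] -> {s.output!r}")
            if s.note:
                lines.append(f"   {s.note}")
        return "\n".join(lines)

    def to_rows(self) -> list[dict]:
        return [
            {
                "step": i,
                "rule": s.rule,
                "inputs": " | ".join(repr(m) for m in s.inputs),
                "output": repr(s.output),
                "note": s.note,
            }
            for i, s in enumerate(self.steps, 1)
        ]


@dataclass(frozen=True)
class AlternativeSet:
    target: Signal
    competitors: frozenset[Signal]


def alternatives(
    target: Signal, attested: Iterable[Signal], policy: str = "same-face-gesture-swap"
) -> AlternativeSet:
    """Attested competitors of a signal under a substitution policy.

    ``same-face-gesture-swap``: attested signals sharing the target's face
    and differing in gesture (the competition the fear derivation uses).
    ``uniform``: attested signals differing from the target in exactly one
    component (gesture xor face).
    """
    attested = set(attested)
    if target not in attested:
        raise ValueError(f"target {target} is not in the attested inventory")
    others = attested - {target}
    if policy == "same-face-gesture-swap":
        comp = {s for s in others if s.face == target.face and s.gesture != target.gesture}
    elif policy == "uniform":
        comp = {
            s
            for s in others
            if (s.face == target.face) != (s.gesture == target.gesture)
        }
    else:
        raise ValueError(f"unknown alternative policy {policy!r}; choose from {POLICIES}")
    return AlternativeSet(target, frozenset(comp))


def strengthen(
    target: Signal, sys: SemanticSystem, attested: Iterable[Signal]
) -> tuple[Meaning, DerivationTrace]:
    """Apply the Informativity Principle to one signal.

    For each competitor whose literal meaning *strictly* entails the
    target's, conjoin the negation of the competitor's surplus content.
    Negations are applied in deterministic (sorted) competitor order; one
    that would make the meaning inconsistent is skipped, and the skip is
    logged in the trace. Strengthening never weakens: the result always
    entails the literal meaning.
    """
    if sys.enrichment != "informativity":
        raise ValueError(f"system {sys.id!r} has enrichment={sys.enrichment!r}")
    o = sys.ontology
    literal = interpret_literal(target, sys)
    steps = [
        DerivationStep(
            "literal",
            tuple(sys.lexicon.components.get(c, Meaning()) for c in target.components())
            if sys.composition == "trivial"
            else (literal,),
            literal,
            f"literal meaning of {target}",
        )
    ]
    alt = alternatives(target, attested, sys.alternative_policy)
    stronger = []
    for comp in sorted(alt.competitors, key=_signal_sort_key):
        cm = interpret_literal(comp, sys)
        if entails(cm, literal, o) and not entails(literal, cm, o):
            stronger.append((comp, cm))
    steps.append(
        DerivationStep(
            "competition",
            (literal,),
            literal,
            "competitors: "
            + (", ".join(str(s) for s in sorted(alt.competitors, key=_signal_sort_key)) or "none")
            + "; strictly stronger: "
            + (", ".join(str(s) for s, _ in stronger) or "none"),
        )
    )
    current = literal
    for comp, cm in stronger:
        surplus = residual(cm, literal, o)
        negation = Meaning(lit.negate() for lit in surplus)
        candidate = conjoin(current, negation)
        if consistent(candidate, o):
            current = candidate
            steps.append(
                DerivationStep(
                    "strengthen",
                    (current, cm),
                    current,
                    f"negate surplus of {comp}: not({surplus!r})",
                )
            )
        else:
            steps.append(
                DerivationStep(
                    "strengthen-skipped",
                    (current, cm),
                    current,
                    f"negating surplus of {comp} would be inconsistent; skipped",
                )
            )
    return current, DerivationTrace(tuple(steps))


def resolve(m: Meaning, o: Ontology) -> tuple[Meaning, DerivationTrace]:
    """Resolve governed disjunctions and re-label defined conjunctions.

    For each governed exclusion whose governor is (positively) entailed and
    neither member present: add the single member consistent with the
    meaning, or log an ambiguity if both are. Never removes literals and
    never produces an inconsistent meaning.
    """
    steps: list[DerivationStep] = []
    current = m
    for ex in o.governed_exclusions():
        c = close(current, o)
        pos = c.positives()
        if ex.governed_by not in pos or ex.first in pos or ex.second in pos:
            continue
        options = [
            opt
            for opt in (ex.first, ex.second)
            if consistent(conjoin(current, Meaning.of(opt)), o)
        ]
        if len(options) == 1:
            current = conjoin(current, Meaning.of(options[0]))
            other = ex.second if options[0] == ex.first else ex.first
            steps.append(
                DerivationStep(
                    "resolve",
                    (m,),
                    current,
                    f"{ex.governed_by} is {ex.first} or {ex.second}; "
                    f"{other} is inconsistent here, so {options[0]} holds",
                )
            )
        elif len(options) == 2:
            steps.append(
                DerivationStep(
                    "ambiguous",
                    (m,),
                    current,
                    f"{ex.governed_by} is {ex.first} or {ex.second}; both are "
                    "consistent, disambiguation left to context",
                )
            )
        else:
            steps.append(
                DerivationStep(
                    "unresolvable",
                    (m,),
                    current,
                    f"neither {ex.first} nor {ex.second} is consistent with the meaning",
                )
            )
    # re-label: report defined atoms whose definition is fully satisfied
    pos = close(current, o).positives()
    for defined, body in sorted(o.definitions.items()):
        if defined not in pos and body <= pos:
            steps.append(
                DerivationStep(
                    "relabel",
                    (current,),
                    current,
                    f"{' ∧ '.join(sorted(body))} reported as {defined.lower()}",
                )
            )
    if not steps:
        steps.append(DerivationStep("resolve", (m,), m, "no disjunctive axiom triggered"))
    return current, DerivationTrace(tuple(steps))
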