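"""Signals, lexicons and semantic systems for face-gesture combinations.

The signal inventory follows the field study this package models: two
one-armed gestures (BENT, STRETCHED), two marked facial expressions (HOOT,
BARED) plus a neutral face, and their combinations. A semantic system maps
signals to meanings either *holistically* (every signal form, simple or
complex, carries an independently stipulated meaning) or by *trivial
compositionality* (a combination means the conjunction of its components'
meanings), optionally followed by informativity-based pragmatic enrichment
(see :mod:`facegest.pragmatics`).

Three packaged presets reproduce the systems compared in the study:

* ``system1`` — holistic: six stipulated entries, no composition rule;
* ``system2`` — trivial compositionality with Bared = submission;
* ``system3`` — trivial compositionality with Bared = fear plus the
  Informativity Principle.

``degrees_of_freedom`` counts the independent lexical stipulations each
system needs for an attested inventory, the parsimony currency on which the
systems are compared.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .meaning import (
    Atom,
    Exclusion,
    Incompatibility,
    Literal,
    Meaning,
    Ontology,
    OntologyError,
    conjoin,
)

__all__ = [
    "GESTURES",
    "FACES",
    "NEUTRAL_FACE",
    "SignalComponent",
    "Signal",
    "Lexicon",
    "SemanticSystem",
    "UnstipulatedSignalError",
    "ConfigurationError",
    "interpret_literal",
    "degrees_of_freedom",
    "interpretation_table",
    "InterpretationRow",
    "gloss",
    "default_ontology",
    "builtin_system",
    "attested_inventory",
    "save_system",
    "load_system",
]

GESTURES = ("BENT", "STRETCHED")
FACES = ("NEUTRAL", "HOOT", "BARED")
NEUTRAL_FACE = "NEUTRAL"


class UnstipulatedSignalError(KeyError):
    """A holistic system was asked about a signal it has no entry for.

    Holism has no fallback: meanings of unlisted forms are simply undefined.
    """


class ConfigurationError(ValueError):
    """An ill-formed system, lexicon or config file."""


@dataclass(frozen=True, order=True)
class SignalComponent:
    """One articulator's contribution: a gesture or a facial expression."""

    modality: str  # "gesture" | "face"
    label: str

    def __post_init__(self) -> None:
        if self.modality not in ("gesture", "face"):
            raise ConfigurationError(f"unknown modality {self.modality!r}")

    def __str__(self) -> str:
        return f"{self.modality}:{self.label}"


def _signal_sort_key(s: "Signal") -> tuple:
    return (s.gesture is None, s.gesture or "", s.face or "")


@dataclass(frozen=True)
class Signal:
    """A (possibly multimodal) signal: at most one gesture plus one face.

    An isolated gesture carries the neutral face explicitly — the neutral
    face is a real component with empty meaning, not an absence — so signal
    identity is unambiguous. A face-only signal has ``gesture=None``.
    """

    gesture: str | None
    face: str = NEUTRAL_FACE

    def __post_init__(self) -> None:
        if self.gesture is None and self.face is None:
            raise ConfigurationError("a signal needs at least one component")

    def components(self) -> tuple[SignalComponent, ...]:
        out = []
        if self.gesture is not None:
            out.append(SignalComponent("gesture", self.gesture))
        if self.face is not None:
            out.append(SignalComponent("face", self.face))
        return tuple(out)

    def __str__(self) -> str:
        if self.gesture is None:
            return self.face
        if self.face in (None, NEUTRAL_FACE):
            return str(self.gesture)
        return f"{self.gesture}+{self.face}"


@dataclass(frozen=True)
class Lexicon:
    """Meanings for components and (in holistic systems) whole signal forms."""

    components: Mapping[SignalComponent, Meaning] = field(default_factory=dict)
    signals: Mapping[Signal, Meaning] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "components", dict(self.components))
        object.__setattr__(self, "signals", dict(self.signals))
        neutral = SignalComponent("face", NEUTRAL_FACE)
        if neutral in self.components and self.components[neutral]:
            raise ConfigurationError("the neutral face must have the empty meaning")


@dataclass(frozen=True)
class SemanticSystem:
    """A lexicon plus a composition mode, enrichment mode and ontology."""

    id: str
    lexicon: Lexicon
    composition: str  # "holistic" | "trivial"
    enrichment: str = "none"  # "none" | "informativity"
    ontology: Ontology = None  # type: ignore[assignment]
    alternative_policy: str = "same-face-gesture-swap"

    def __post_init__(self) -> None:
        if self.composition not in ("holistic", "trivial"):
            raise ConfigurationError(f"unknown composition mode {self.composition!r}")
        if self.enrichment not in ("none", "informativity"):
            raise ConfigurationError(f"unknown enrichment mode {self.enrichment!r}")
        if self.composition == "holistic" and self.enrichment != "none":
            raise ConfigurationError(
                "holistic systems have no component meanings to strengthen; "
                "enrichment must be 'none'"
            )
        if self.ontology is None:
            raise ConfigurationError("a semantic system requires an ontology")
        for meaning in list(self.lexicon.components.values()) + list(
            self.lexicon.signals.values()
        ):
            self.ontology.check_meaning(meaning)


def interpret_literal(s: Signal, sys: SemanticSystem) -> Meaning:
    """Literal (pre-enrichment) interpretation of a signal.

    Holistic: exact lookup of the signal form. Trivial compositionality:
    conjunction of the component meanings, with the neutral face
    contributing the empty meaning.
    """
    if sys.composition == "holistic":
        try:
            return sys.lexicon.signals[s]
        except KeyError:
            raise UnstipulatedSignalError(
                f"holistic system {sys.id!r} stipulates no meaning for signal {s}"
            ) from None
    m = Meaning()
    for comp in s.components():
        if comp.label == NEUTRAL_FACE and comp.modality == "face":
            continue  # empty meaning by convention
        try:
            m = conjoin(m, sys.lexicon.components[comp])
        except KeyError:
            raise ConfigurationError(
                f"trivial system {sys.id!r} lacks a lexicon entry for component {comp}"
            ) from None
    return m


def degrees_of_freedom(sys: SemanticSystem, attested: Iterable[Signal]) -> int:
    """Number of independent lexical stipulations needed for the inventory.

    Holistic systems need one stipulation per attested signal *form*
    (isolated components attested on their own, and each attested
    combination). Trivially compositional systems need one per distinct
    component occurring in any attested signal; the neutral face is not
    counted, as its empty meaning is a convention rather than a stipulation.
    """
    attested = sorted(set(attested), key=_signal_sort_key)
    if not attested:
        raise ConfigurationError("attested inventory must be nonempty")
    gaps = []
    for s in attested:
        try:
            interpret_literal(s, sys)
        except (UnstipulatedSignalError, ConfigurationError):
            gaps.append(str(s))
    if gaps:
        raise ConfigurationError(
            f"system {sys.id!r} cannot interpret attested signals: {gaps}"
        )
    if sys.composition == "holistic":
        return len(set(attested))
    comps = {
        comp
        for s in attested
        for comp in s.components()
        if not (comp.modality == "face" and comp.label == NEUTRAL_FACE)
    }
    return len(comps)


# ---------------------------------------------------------------------------
# Interpretation tables (one row per attested signal, enrichment included)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class InterpretationRow:
    signal: Signal
    literal: Meaning
    final: Meaning
    trace: "DerivationTrace"  # noqa: F821 - forward ref to pragmatics
    gloss: str


def interpretation_table(
    sys: SemanticSystem, attested: Iterable[Signal]
) -> list[InterpretationRow]:
    """Interpret every attested signal, applying enrichment when enabled.

    Rows are ordered deterministically: gestures alphabetically, then faces
    alphabetically (face-only signals last).
    """
    from .pragmatics import DerivationStep, DerivationTrace, resolve, strengthen

    attested = set(attested)
    rows = []
    for s in sorted(attested, key=_signal_sort_key):
        literal = interpret_literal(s, sys)
        if sys.enrichment == "informativity":
            strengthened, trace = strengthen(s, sys, attested)
            resolved, rtrace = resolve(strengthened, sys.ontology)
            trace = DerivationTrace(trace.steps + rtrace.steps)
            final = resolved
        else:
            step = DerivationStep("literal", (literal,), literal, "literal interpretation")
            trace = DerivationTrace((step,))
            final = literal
        rows.append(InterpretationRow(s, literal, final, trace, gloss(final, sys.ontology)))
    return rows


def table_to_dataframe(rows: Sequence[InterpretationRow]):
    import pandas as pd

    return pd.DataFrame(
        {
            "signal": [str(r.signal) for r in rows],
            "literal": [" & ".join(str(l) for l in r.literal) for r in rows],
            "final": [" & ".join(str(l) for l in r.final) for r in rows],
            "gloss": [r.gloss for r in rows],
        }
    )


def table_to_text(rows: Sequence[InterpretationRow]) -> str:
    df = table_to_dataframe(rows)
    widths = {c: max(len(c), *(len(str(v)) for v in df[c])) for c in df.columns}
    lines = ["  ".join(c.ljust(widths[c]) for c in df.columns)]
    lines.append("  ".join("-" * widths[c] for c in df.columns))
    for _, row in df.iterrows():
        lines.append("  ".join(str(row[c]).ljust(widths[c]) for c in df.columns))
    return "\n".join(lines)


# Named bundles used only for human-readable glosses. "Begging" is not an
# atom: it abbreviates the conjunction approach-request ∧ help-request, so
# its decomposability is a closure fact rather than a special case.
GLOSS_BUNDLES: tuple[tuple[str, frozenset[str]], ...] = (
    ("submission", frozenset({"FEAR", "AT_ADDRESSEE"})),
    ("begging", frozenset({"APPROACH", "HELP"})),
)

_ATOM_GLOSS = {
    "APPROACH": "approach",
    "HELP": "help",
    "ANTAGONISM": "antagonism",
    "FEAR": "fear",
    "SUBMISSION": "submission",
    "AT_ADDRESSEE": "directed-at-you",
    "AT_EXTERNAL": "external-threat",
}


def gloss(m: Meaning, o: Ontology, include_negative: bool = False) -> str:
    """Render a meaning's positive commitments as a compact label.

    Defined atoms and named bundles are substituted for their parts
    (FEAR ∧ AT_ADDRESSEE reads "submission"). Negative commitments are part
    of the meaning and the derivation trace but are omitted from the short
    gloss by default, following the summary-table convention.
    """
    pos = set(m.positives())
    parts: list[str] = []
    bundles = [(name, o.definitions.get(name.upper(), body)) for name, body in GLOSS_BUNDLES]
    for name, body in bundles:
        if name.upper() in pos:
            pos.discard(name.upper())
            pos.difference_update(body)
            parts.append(name)
        elif body <= pos:
            pos.difference_update(body)
            parts.append(name)
    parts.extend(_ATOM_GLOSS.get(a, a.lower()) for a in sorted(pos))
    order = {"begging": 0, "approach": 0}  # gesture content leads, as in summaries
    parts.sort(key=lambda p: (order.get(p, 1), p))
    out = "+".join(parts) if parts else "(empty)"
    if include_negative and m.negatives():
        out += "".join(f", not {_ATOM_GLOSS.get(a, a.lower())}" for a in sorted(m.negatives()))
    return out


# ---------------------------------------------------------------------------
# Packaged ontology, presets and the attested inventory
# ---------------------------------------------------------------------------


def default_ontology() -> Ontology:
    """The shared background ontology of the three packaged systems.

    Submission is a defined atom (fear directed at the addressee), fear is
    governed by an addressee/external-threat disjunction, and "not a request
    for help" is incompatible with an external threat (were the threat
    external, help would be welcome).
    """
    return Ontology(
        atoms=(
            Atom("APPROACH", "request for the receiver to approach"),
            Atom("HELP", "request for help/assistance"),
            Atom("ANTAGONISM", "display of antagonism"),
            Atom("FEAR", "expression of fear"),
            Atom("AT_ADDRESSEE", "directed at the interaction partner"),
            Atom("AT_EXTERNAL", "directed at an external threat"),
            Atom("SUBMISSION", "submission = fear of the addressee"),
        ),
        definitions={"SUBMISSION": frozenset({"FEAR", "AT_ADDRESSEE"})},
        exclusions=(Exclusion("AT_ADDRESSEE", "AT_EXTERNAL", governed_by="FEAR"),),
        incompatibilities=(Incompatibility(Literal("HELP", False), "AT_EXTERNAL"),),
    )


def attested_inventory() -> frozenset[Signal]:
    """The observed signal inventory: 2 isolated gestures + 4 combinations.

    Faces were never recorded in isolation, so they do not appear as
    stand-alone signals here.
    """
    signals = {Signal(g) for g in GESTURES}
    signals |= {Signal(g, f) for g in GESTURES for f in ("HOOT", "BARED")}
    return frozenset(signals)


_BEGGING = Meaning.of("APPROACH", "HELP")
_APPROACH = Meaning.of("APPROACH")
_ANTAG = Meaning.of("ANTAGONISM")


def _shared_components(bared: Meaning) -> dict[SignalComponent, Meaning]:
    return {
        SignalComponent("gesture", "BENT"): _BEGGING,
        SignalComponent("gesture", "STRETCHED"): _APPROACH,
        SignalComponent("face", "HOOT"): _ANTAG,
        SignalComponent("face", "BARED"): bared,
        SignalComponent("face", NEUTRAL_FACE): Meaning(),
    }


def builtin_system(name: str) -> SemanticSystem:
    """Return one of the packaged presets ``system1``/``system2``/``system3``.

    ``system1`` is holistic; its combination entries are stipulations. The
    study leaves those stipulations arbitrary, so the preset sets them to
    the observed-outcome glosses (the same meanings system 2 derives) — they
    are placeholders, not derived content.
    """
    o = default_ontology()
    name = name.lower()
    if name == "system1":
        subm = Meaning.of("SUBMISSION")
        return SemanticSystem(
            id="system1",
            composition="holistic",
            enrichment="none",
            ontology=o,
            lexicon=Lexicon(
                components=_shared_components(subm),
                signals={
                    Signal("BENT"): _BEGGING,
                    Signal("STRETCHED"): _APPROACH,
                    Signal("BENT", "HOOT"): conjoin(_BEGGING, _ANTAG),
                    Signal("BENT", "BARED"): conjoin(_BEGGING, subm),
                    Signal("STRETCHED", "HOOT"): conjoin(_APPROACH, _ANTAG),
                    Signal("STRETCHED", "BARED"): conjoin(_APPROACH, subm),
                },
            ),
        )
    if name == "system2":
        return SemanticSystem(
            id="system2",
            composition="trivial",
            enrichment="none",
            ontology=o,
            lexicon=Lexicon(components=_shared_components(Meaning.of("SUBMISSION"))),
        )
    if name == "system3":
        return SemanticSystem(
            id="system3",
            composition="trivial",
            enrichment="informativity",
            ontology=o,
            lexicon=Lexicon(components=_shared_components(Meaning.of("FEAR"))),
        )
    raise ConfigurationError(f"unknown builtin system {name!r}")


# ---------------------------------------------------------------------------
# JSON (de)serialization of system specs
# ---------------------------------------------------------------------------


def _ontology_to_dict(o: Ontology) -> dict:
    return {
        "atoms": [{"id": a.id, "description": a.description} for a in o.atoms],
        "entailment_edges": [list(e) for e in o.entailment_edges],
        "definitions": {d: sorted(body) for d, body in o.definitions.items()},
        "exclusions": [
            {"pair": [ex.first, ex.second], "governed_by": ex.governed_by}
            for ex in o.exclusions
        ],
        "incompatibilities": [
            {"literal": str(inc.literal), "atom": inc.atom} for inc in o.incompatibilities
        ],
    }


def _require(mapping: Mapping, key: str, where: str):
    if key not in mapping:
        raise ConfigurationError(f"missing field {key!r} in {where}")
    return mapping[key]


def _ontology_from_dict(d: Mapping) -> Ontology:
    try:
        return Ontology(
            atoms=tuple(
                Atom(_require(a, "id", "atom"), a.get("description", ""))
                for a in _require(d, "atoms", "ontology")
            ),
            entailment_edges=tuple(tuple(e) for e in d.get("entailment_edges", [])),
            definitions={k: frozenset(v) for k, v in d.get("definitions", {}).items()},
            exclusions=tuple(
                Exclusion(*_require(ex, "pair", "exclusion"), ex.get("governed_by"))
                for ex in d.get("exclusions", [])
            ),
            incompatibilities=tuple(
                Incompatibility(
                    Literal.parse(_require(inc, "literal", "incompatibility")),
                    _require(inc, "atom", "incompatibility"),
                )
                for inc in d.get("incompatibilities", [])
            ),
        )
    except (TypeError, OntologyError) as exc:
        raise ConfigurationError(f"invalid ontology: {exc}") from exc


def _signal_from_dict(d: Mapping) -> Signal:
    return Signal(d.get("gesture"), d.get("face", NEUTRAL_FACE))


def system_to_dict(sys: SemanticSystem) -> dict:
    return {
        "id": sys.id,
        "composition": sys.composition,
        "enrichment": sys.enrichment,
        "alternative_policy": sys.alternative_policy,
        "ontology": _ontology_to_dict(sys.ontology),
        "lexicon": {
            "components": {
                str(c): sorted(str(l) for l in m)
                for c, m in sorted(sys.lexicon.components.items())
            },
            "signals": [
                {
                    "gesture": s.gesture,
                    "face": s.face,
                    "meaning": sorted(str(l) for l in m),
                }
                for s, m in sorted(
                    sys.lexicon.signals.items(), key=lambda kv: _signal_sort_key(kv[0])
                )
            ],
        },
    }


def system_from_dict(d: Mapping) -> SemanticSystem:
    if not isinstance(d, Mapping):
        raise ConfigurationError("system spec must be a JSON object")
    lex = d.get("lexicon", {})
    components = {}
    for key, tokens in lex.get("components", {}).items():
        try:
            modality, label = key.split(":", 1)
        except ValueError:
            raise ConfigurationError(
                f"component key {key!r} must look like 'gesture:BENT'"
            ) from None
        components[SignalComponent(modality, label)] = Meaning(tokens)
    signals = {
        _signal_from_dict(entry): Meaning(_require(entry, "meaning", "signal entry"))
        for entry in lex.get("signals", [])
    }
    return SemanticSystem(
        id=str(_require(d, "id", "system spec")),
        composition=str(_require(d, "composition", "system spec")),
        enrichment=str(d.get("enrichment", "none")),
        alternative_policy=str(d.get("alternative_policy", "same-face-gesture-swap")),
        ontology=_ontology_from_dict(_require(d, "ontology", "system spec")),
        lexicon=Lexicon(components=components, signals=signals),
    )


def save_system(sys: SemanticSystem, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(system_to_dict(sys), fh, indent=2, sort_keys=True)
        fh.write("\n")


def load_system(path_or_name) -> SemanticSystem:
    """Load a system spec from JSON, or a builtin by name (``system1``...)."""
    name = str(path_or_name).lower()
    if name in ("system1", "system2", "system3"):
        return builtin_system(name)
    with open(path_or_name, "r", encoding="utf-8") as fh:
        try:
            d = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ConfigurationError(f"invalid JSON in {path_or_name}: {exc}") from exc
    return system_from_dict(d)
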