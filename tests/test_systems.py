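"""Semantic systems: interpretation, degrees of freedom, tables, JSON specs."""

import itertools

import pytest

from facegest.meaning import Atom, Meaning, Ontology
from facegest.systems import (
    ConfigurationError,
    Lexicon,
    SemanticSystem,
    Signal,
    SignalComponent,
    UnstipulatedSignalError,
    builtin_system,
    degrees_of_freedom,
    gloss,
    interpret_literal,
    interpretation_table,
    load_system,
    save_system,
)

# the published summary-table meanings for the four combinations
SYSTEM2_CELLS = {
    Signal("BENT", "HOOT"): Meaning.of("APPROACH", "HELP", "ANTAGONISM"),
    Signal("BENT", "BARED"): Meaning.of("APPROACH", "HELP", "SUBMISSION"),
    Signal("STRETCHED", "HOOT"): Meaning.of("APPROACH", "ANTAGONISM"),
    Signal("STRETCHED", "BARED"): Meaning.of("APPROACH", "SUBMISSION"),
}


class TestInterpretLiteral:
    def test_trivial_combination_is_conjunction(self, system2):
        for sig, expected in SYSTEM2_CELLS.items():
            assert interpret_literal(sig, system2) == expected

    def test_neutral_face_is_identity(self, system3):
        assert interpret_literal(Signal("STRETCHED"), system3) == Meaning.of("APPROACH")
        assert interpret_literal(Signal("STRETCHED", "NEUTRAL"), system3) == Meaning.of(
            "APPROACH"
        )

    def test_component_signals_reproduce_lexicon(self, system2, system3):
        for sys_ in (system2, system3):
            for comp, meaning in sys_.lexicon.components.items():
                if comp.modality != "gesture":
                    continue
                assert interpret_literal(Signal(comp.label), sys_) == meaning

    def test_holistic_lookup_and_miss(self, system1):
        assert interpret_literal(Signal("BENT"), system1) == Meaning.of("APPROACH", "HELP")
        with pytest.raises(UnstipulatedSignalError, match="no meaning"):
            interpret_literal(Signal(None, "BARED"), system1)

    def test_trivial_missing_component(self, ontology):
        sys_ = SemanticSystem(
            id="partial",
            composition="trivial",
            ontology=ontology,
            lexicon=Lexicon(components={SignalComponent("gesture", "BENT"): Meaning.of("HELP")}),
        )
        with pytest.raises(ConfigurationError, match="face:HOOT"):
            interpret_literal(Signal("BENT", "HOOT"), sys_)

    def test_trivial_invariant_under_component_order(self, system2):
        # signal identity is order-free by construction; meanings agree with
        # conjoining the components in either order
        for sig, expected in SYSTEM2_CELLS.items():
            g = system2.lexicon.components[SignalComponent("gesture", sig.gesture)]
            f = system2.lexicon.components[SignalComponent("face", sig.face)]
            assert (g | f) == (f | g) == expected


class TestDegreesOfFreedom:
    def test_packaged_systems(self, system1, system2, system3, attested):
        assert degrees_of_freedom(system1, attested) == 6
        assert degrees_of_freedom(system2, attested) == 4
        assert degrees_of_freedom(system3, attested) == 4

    def test_single_signal(self, system1, system2):
        only_bent = {Signal("BENT")}
        assert degrees_of_freedom(system1, only_bent) == 1
        assert degrees_of_freedom(system2, only_bent) == 1

    @pytest.mark.parametrize("g,f", [(g, f) for g in (1, 2, 3, 4) for f in (1, 2, 3, 4)])
    def test_full_inventory_scaling(self, g, f):
        """With every gesture-face combination attested: holistic g+g*f, trivial g+f."""
        atoms = tuple(Atom(f"A{i}") for i in range(g + f))
        o = Ontology(atoms=atoms)
        gestures = [f"G{i}" for i in range(g)]
        faces = [f"F{i}" for i in range(f)]
        comp_meanings = {
            SignalComponent("gesture", gl): Meaning.of(f"A{i}") for i, gl in enumerate(gestures)
        }
        comp_meanings.update(
            {SignalComponent("face", fl): Meaning.of(f"A{g + i}") for i, fl in enumerate(faces)}
        )
        attested = {Signal(gl) for gl in gestures} | {
            Signal(gl, fl) for gl, fl in itertools.product(gestures, faces)
        }
        trivial = SemanticSystem(
            id="t", composition="trivial", ontology=o, lexicon=Lexicon(components=comp_meanings)
        )
        holistic = SemanticSystem(
            id="h",
            composition="holistic",
            ontology=o,
            lexicon=Lexicon(signals={s: Meaning.of("A0") for s in attested}),
        )
        assert degrees_of_freedom(trivial, attested) == g + f
        assert degrees_of_freedom(holistic, attested) == g + g * f
        assert degrees_of_freedom(trivial, attested) <= degrees_of_freedom(holistic, attested)

    def test_empty_inventory_rejected(self, system2):
        with pytest.raises(ConfigurationError, match="nonempty"):
            degrees_of_freedom(system2, [])

    def test_uninterpretable_inventory_names_gap(self, system1):
        with pytest.raises(ConfigurationError, match="BARED"):
            degrees_of_freedom(system1, {Signal(None, "BARED")})


class TestInterpretationTable:
    def test_system2_matches_summary_row(self, system2, attested):
        rows = {r.signal: r for r in interpretation_table(system2, attested)}
        for sig, expected in SYSTEM2_CELLS.items():
            assert rows[sig].final == expected  # no enrichment: literal == final
            assert rows[sig].literal == expected
        glosses = {str(s): rows[s].gloss for s in SYSTEM2_CELLS}
        assert glosses == {
            "BENT+HOOT": "begging+antagonism",
            "BENT+BARED": "begging+submission",
            "STRETCHED+HOOT": "approach+antagonism",
            "STRETCHED+BARED": "approach+submission",
        }

    def test_deterministic_ordering(self, system2, attested):
        rows = interpretation_table(system2, attested)
        keys = [(r.signal.gesture, r.signal.face) for r in rows]
        assert keys == sorted(keys)  # gestures alphabetical, then faces
        assert keys == [
            (r.signal.gesture, r.signal.face) for r in interpretation_table(system2, attested)
        ]

    def test_holistic_stipulations_returned_verbatim(self, ontology):
        """A randomized holistic lexicon comes back row-for-row unchanged."""
        import random

        rng = random.Random(7)
        atoms = sorted(ontology.atom_ids - {"SUBMISSION"})
        attested = {Signal("BENT"), Signal("BENT", "HOOT"), Signal("STRETCHED", "BARED")}
        stip = {
            s: Meaning.of(*rng.sample(atoms, k=rng.randint(1, 3))) for s in attested
        }
        sys_ = SemanticSystem(
            id="rand-holistic",
            composition="holistic",
            ontology=ontology,
            lexicon=Lexicon(signals=stip),
        )
        for row in interpretation_table(sys_, attested):
            assert row.final == stip[row.signal]


class TestSystemSpecs:
    def test_json_round_trip_preserves_interpretations(self, system3, attested, tmp_path):
        path = tmp_path / "system3.json"
        save_system(system3, path)
        loaded = load_system(path)
        assert loaded.composition == "trivial" and loaded.enrichment == "informativity"
        t1 = interpretation_table(system3, attested)
        t2 = interpretation_table(loaded, attested)
        assert [(r.signal, r.final) for r in t1] == [(r.signal, r.final) for r in t2]

    def test_invalid_spec_diagnostics(self, tmp_path):
        bad = tmp_path / "bad.json"
        bad.write_text('{"id": "x", "composition": "trivial"}')
        with pytest.raises(ConfigurationError, match="ontology"):
            load_system(bad)
        bad.write_text("{not json")
        with pytest.raises(ConfigurationError, match="invalid JSON"):
            load_system(bad)

    def test_holistic_cannot_enrich(self, ontology):
        with pytest.raises(ConfigurationError, match="enrichment"):
            SemanticSystem(
                id="x",
                composition="holistic",
                enrichment="informativity",
                ontology=ontology,
                lexicon=Lexicon(),
            )

    def test_unknown_builtin(self):
        with pytest.raises(ConfigurationError, match="unknown builtin"):
            builtin_system("system9")
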