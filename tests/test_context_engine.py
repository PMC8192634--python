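"""Modifier trigger matching and directional scope assignment."""

import random

import pytest

from pulmostage.annotation_model import (
    CharSpan,
    ConceptCategory,
    ConceptMention,
    Direction,
    ModifierCategory,
    ModifierMention,
)
from pulmostage.context_engine import (
    assign_modifier_scopes,
    load_modifiers,
    match_modifiers,
)
from pulmostage.lexicon_matcher import match_concepts


def _concepts(sentence, lexicon):
    return match_concepts(sentence, lexicon)


def _flags_for(sentence, lexicon, modifiers):
    concepts = match_concepts(sentence, lexicon)
    mods = match_modifiers(sentence, modifiers)
    assign_modifier_scopes(CharSpan(start=0, end=len(sentence)), mods, concepts)
    return {c.concept_id: c.flags for c in concepts}


class TestMatchModifiers:
    def test_every_default_trigger_fires_in_carrier(self, modifiers):
        for entry in modifiers.entries:
            for pattern in entry.patterns:
                literal = pattern.replace("s?", "s")
                carrier = f"lorem {literal} ipsum"
                hits = match_modifiers(carrier, modifiers)
                assert len(hits) == 1, f"{pattern!r}: {hits}"
                assert hits[0].category is entry.category
                assert hits[0].direction is entry.direction

    def test_abutting_is_an_uncertainty_trigger(self, modifiers):
        hits = match_modifiers("mass abutting the mediastinum", modifiers)
        assert len(hits) == 1
        assert hits[0].category is ModifierCategory.UNCERTAINTY

    def test_no_triggers_no_hits(self, modifiers):
        assert match_modifiers("The airways are patent", modifiers) == []

    def test_longest_match_wins_over_contained_trigger(self, modifiers):
        hits = match_modifiers("there is no evidence of invasion", modifiers)
        assert len(hits) == 1
        spanned = "there is no evidence of invasion"[hits[0].span.start:hits[0].span.end]
        assert spanned == "no evidence of"

    def test_pseudo_trigger_suppresses_contained_negation(self, modifiers):
        hits = match_modifiers("no change in the mass", modifiers)
        assert len(hits) == 1
        assert hits[0].category is ModifierCategory.PSEUDO


class TestScopes:
    def test_scope_trace_table(self, lexicon, modifiers):
        cases = [
            ("no invasion of the chest wall",
             {"chest_wall": ("negated", True)}),
            ("mass abutting the mediastinum",
             {"mediastinum": ("uncertain", True), "mass": ("uncertain", False)}),
            ("no invasion of the mediastinum but there is invasion of the chest wall",
             {"mediastinum": ("negated", True), "chest_wall": ("negated", False)}),
            ("invasion of the chest wall was ruled out",
             {"chest_wall": ("negated", True)}),
            ("prior resection of a nodule",
             {"nodule": ("historical", True)}),
        ]
        for sentence, expected in cases:
            flags = _flags_for(sentence, lexicon, modifiers)
            for cid, (attr, value) in expected.items():
                assert getattr(flags[cid], attr) is value, (sentence, cid, attr)

    def test_concepts_without_modifiers_stay_unflagged(self, lexicon, modifiers):
        flags = _flags_for("There is a mass invading the chest wall.",
                           lexicon, modifiers)
        for f in flags.values():
            assert not (f.negated or f.uncertain or f.historical)

    def test_pseudo_assigns_nothing(self, lexicon, modifiers):
        flags = _flags_for("no change in the mass", lexicon, modifiers)
        assert flags["mass"].negated is False

    def test_blacklist_terms_never_flagged(self, lexicon, modifiers):
        flags = _flags_for("no cyst in the kidney", lexicon, modifiers)
        assert flags["cyst"].negated is False
        assert flags["kidney"].negated is False


def _pairwise_oracle(sent_span, mods, concepts):
    """Independent pairwise formulation: a concept is flagged by a modifier
    iff it lies on the acting side and no other flag-bearing or termination
    trigger sits between them (inclusive of the concept's start position)."""
    bearing = {ModifierCategory.NEGATION: "negated",
               ModifierCategory.UNCERTAINTY: "uncertain",
               ModifierCategory.HISTORICAL: "historical"}
    expected = {id(c): {"negated": False, "uncertain": False, "historical": False}
                for c in concepts}
    blockers = [m for m in mods
                if m.category in bearing or m.category is ModifierCategory.TERMINATION]
    for m in mods:
        attr = bearing.get(m.category)
        if attr is None:
            continue
        for c in concepts:
            if c.category is ConceptCategory.BLACKLIST_TERM:
                continue
            fwd = (m.direction in (Direction.FORWARD, Direction.BIDIRECTIONAL)
                   and c.span.start >= m.span.end
                   and not any(b is not m and m.span.end <= b.span.start <= c.span.start
                               for b in blockers))
            bwd = (m.direction in (Direction.BACKWARD, Direction.BIDIRECTIONAL)
                   and c.span.end <= m.span.start
                   and not any(b is not m and c.span.start < b.span.end <= m.span.start
                               for b in blockers))
            if fwd or bwd:
                expected[id(c)][attr] = True
    return expected


def test_scope_assignment_equals_pairwise_oracle():
    rng = random.Random(20)
    mod_kinds = [
        (ModifierCategory.NEGATION, Direction.FORWARD),
        (ModifierCategory.NEGATION, Direction.BACKWARD),
        (ModifierCategory.UNCERTAINTY, Direction.FORWARD),
        (ModifierCategory.UNCERTAINTY, Direction.BIDIRECTIONAL),
        (ModifierCategory.HISTORICAL, Direction.FORWARD),
        (ModifierCategory.TERMINATION, Direction.BIDIRECTIONAL),
        (ModifierCategory.PSEUDO, Direction.FORWARD),
    ]
    for _ in range(300):
        n_spans = rng.randint(1, 8)
        starts = sorted(rng.sample(range(0, 95), n_spans))
        spans = [CharSpan(start=s, end=s + rng.randint(1, 4)) for s in starts]
        mods, concepts = [], []
        for span in spans:
            if rng.random() < 0.5:
                cat, direction = rng.choice(mod_kinds)
                mods.append(ModifierMention(category=cat, direction=direction,
                                            span=span, sentence_ref=0))
            else:
                concepts.append(ConceptMention(
                    concept_id="c", snomed_code="0",
                    category=rng.choice([ConceptCategory.TUMOR_MASS,
                                         ConceptCategory.INVOLVEMENT_TARGET]),
                    span=span, sentence_ref=0))
        sent = CharSpan(start=0, end=100)
        expected = _pairwise_oracle(sent, mods, concepts)
        assign_modifier_scopes(sent, mods, concepts)
        for c in concepts:
            got = {"negated": c.flags.negated, "uncertain": c.flags.uncertain,
                   "historical": c.flags.historical}
            assert got == expected[id(c)]
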