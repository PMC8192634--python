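"""Context validation: negation / uncertainty / historical trigger matching
and directional scope assignment within a sentence.

This follows the classic trigger-term design (NegEx/ConText lineage): a
modifier flags concepts lying in its direction of action until the sentence
boundary, a termination term, or the next flag-bearing modifier.  There is
no dependency parsing; scope is purely positional, which is a deliberate,
documented property of the approach.
"""

from __future__ import annotations

import csv
import re
from functools import lru_cache
from importlib import resources
from typing import Optional

from pydantic import BaseModel, Field, PrivateAttr

from .annotation_model import (
    CharSpan,
    ConceptCategory,
    ConceptMention,
    Direction,
    ModifierCategory,
    ModifierMention,
)
from .lexicon_matcher import LexiconError, _compile

_FLAG_BY_CATEGORY = {
    ModifierCategory.NEGATION: "negated",
    ModifierCategory.UNCERTAINTY: "uncertain",
    ModifierCategory.HISTORICAL: "historical",
}


class ModifierEntry(BaseModel):
    category: ModifierCategory
    direction: Direction
    patterns: list[str] = Field(min_length=1)

    _compiled: Optional[list[re.Pattern]] = PrivateAttr(default=None)

    def compiled(self) -> list[re.Pattern]:
        if self._compiled is None:
            self._compiled = [_compile(p) for p in self.patterns]
        return self._compiled


class ModifierLexicon(BaseModel):
    entries: list[ModifierEntry]
    version: str = "default"


def load_modifiers(path: Optional[str] = None) -> ModifierLexicon:
    """Load the modifier inventory from TSV: category, direction, pattern."""
    if path is None:
        text = resources.files("pulmostage.resources").joinpath("modifiers.tsv").read_text("utf-8")
        version = "builtin"
    else:
        with open(path, "r", encoding="utf-8") as fh:
            text = fh.read()
        version = str(path)
    rows = list(csv.DictReader(text.splitlines(), delimiter="\t"))
    if not rows:
        raise LexiconError("modifier resource is empty")
    for col in ("category", "direction", "pattern"):
        if col not in rows[0]:
            raise LexiconError(f"modifier resource missing column {col!r}")
    entries = []
    for i, row in enumerate(rows, start=2):
        try:
            entry = ModifierEntry(
                category=ModifierCategory(row["category"].strip()),
                direction=Direction(row["direction"].strip()),
                patterns=[row["pattern"].strip()],
            )
        except ValueError as exc:
            raise LexiconError(f"row {i}: {exc}") from exc
        entry.compiled()
        entries.append(entry)
    return ModifierLexicon(entries=entries, version=version)


@lru_cache(maxsize=1)
def default_modifiers() -> ModifierLexicon:
    return load_modifiers()


def match_modifiers(sentence_text: str, lexicon: ModifierLexicon,
                    base_offset: int = 0, sentence_ref: int = 0) -> list[ModifierMention]:
    """Find modifier triggers in one sentence.

    Longest match wins across *all* modifier categories, which is also how
    pseudo triggers work: "no change" outranks and thereby suppresses the
    contained negation "no".
    """
    raw: list[tuple[int, int, ModifierEntry]] = []
    for entry in lexicon.entries:
        for pat in entry.compiled():
            for m in pat.finditer(sentence_text):
                raw.append((m.start(), m.end(), entry))
    kept: list[tuple[int, int, ModifierEntry]] = []
    for start, end, entry in sorted(raw, key=lambda h: (-(h[1] - h[0]), h[0])):
        if any(start < k_end and k_start < end for k_start, k_end, _ in kept):
            continue
        kept.append((start, end, entry))
    return [
        ModifierMention(
            category=e.category, direction=e.direction,
            span=CharSpan(start=base_offset + s, end=base_offset + t),
            sentence_ref=sentence_ref,
        )
        for s, t, e in sorted(kept, key=lambda h: h[0])
    ]


def assign_modifier_scopes(sentence_span: CharSpan,
                           modifiers: list[ModifierMention],
                           concepts: list[ConceptMention]) -> list[ConceptMention]:
    """Set negated/uncertain/historical flags on concepts (in place).

    Forward modifiers act on concepts after them up to the sentence end;
    backward modifiers act on concepts before them down to the sentence
    start; bidirectional act both ways.  A scope is truncated at the
    nearest termination trigger and at the next flag-bearing modifier.
    Pseudo modifiers assign nothing; blacklist terms never carry flags.
    Flags are only ever set, never cleared.
    """
    bearers = [m for m in modifiers if m.category in _FLAG_BY_CATEGORY]
    terminators = [m for m in modifiers if m.category is ModifierCategory.TERMINATION]

    for mod in bearers:
        attr = _FLAG_BY_CATEGORY[mod.category]
        if mod.direction in (Direction.FORWARD, Direction.BIDIRECTIONAL):
            limit = sentence_span.end
            for t in terminators:
                if t.span.start >= mod.span.end:
                    limit = min(limit, t.span.start)
            for other in bearers:
                if other is not mod and other.span.start >= mod.span.end:
                    limit = min(limit, other.span.start)
            for c in concepts:
                if c.category is ConceptCategory.BLACKLIST_TERM:
                    continue
                if mod.span.end <= c.span.start < limit:
                    setattr(c.flags, attr, True)
        if mod.direction in (Direction.BACKWARD, Direction.BIDIRECTIONAL):
            limit = sentence_span.start
            for t in terminators:
                if t.span.end <= mod.span.start:
                    limit = max(limit, t.span.end)
            for other in bearers:
                if other is not mod and other.span.end <= mod.span.start:
                    limit = max(limit, other.span.end)
            for c in concepts:
                if c.category is ConceptCategory.BLACKLIST_TERM:
                    continue
                if limit <= c.span.start and c.span.end <= mod.span.start:
                    setattr(c.flags, attr, True)
    return concepts
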