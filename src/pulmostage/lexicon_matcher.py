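"""Concept matching against a SNOMED-CT-coded lexicon, plus the sentence
blacklist that keeps extrathoracic masses (renal cysts, hepatic lesions)
from being mistaken for the primary lung tumor.

Patterns are case-insensitive regexes anchored at word boundaries; a single
lexicon entry may list synonyms as alternation.  Matching is deterministic:
longest match wins among overlapping hits of the same category.
"""

from __future__ import annotations

import csv
import re
from functools import lru_cache
from importlib import resources
from typing import Iterable, Optional

from pydantic import BaseModel, Field, PrivateAttr

from .annotation_model import (
    CharSpan,
    ConceptCategory,
    ConceptMention,
    Laterality,
    Lobe,
    Measurement,
)


class LexiconError(ValueError):
    """Malformed lexicon resource."""


_REQUIRED_COLUMNS = ("concept_id", "snomed_code", "category", "pattern")


def _compile(pattern: str) -> re.Pattern:
    """Compile a lexicon pattern: case-insensitive, word-boundary anchored,
    literal single spaces tolerant of any whitespace run."""
    body = pattern.replace(" ", r"\s+")
    prefix = r"\b" if re.match(r"[\w(]", pattern) else ""
    suffix = r"\b" if re.search(r"[\w)?]$", pattern) else ""
    try:
        return re.compile(f"{prefix}(?:{body}){suffix}", re.IGNORECASE)
    except re.error as exc:
        raise LexiconError(f"pattern {pattern!r} does not compile: {exc}") from exc


class LexiconEntry(BaseModel):
    concept_id: str
    snomed_code: str
    category: ConceptCategory
    patterns: list[str] = Field(min_length=1)
    notes: str = ""

    _compiled: Optional[list[re.Pattern]] = PrivateAttr(default=None)

    def compiled(self) -> list[re.Pattern]:
        if self._compiled is None:
            self._compiled = [_compile(p) for p in self.patterns]
        return self._compiled


class Lexicon(BaseModel):
    entries: list[LexiconEntry]
    version: str = "default"

    def by_category(self, category: ConceptCategory) -> list[LexiconEntry]:
        return [e for e in self.entries if e.category is category]


def load_lexicon(path: Optional[str] = None) -> Lexicon:
    """Load a concept lexicon from TSV (the shipped default when no path).

    Columns: concept_id, snomed_code, category, pattern, notes.  One row
    per concept; synonym variants are written as regex alternation.
    Duplicate concept_ids and non-compiling patterns are load errors.
    """
    if path is None:
        text = resources.files("pulmostage.resources").joinpath("lexicon.tsv").read_text("utf-8")
        version = "builtin"
    else:
        with open(path, "r", encoding="utf-8") as fh:
            text = fh.read()
        version = str(path)
    rows = list(csv.DictReader(text.splitlines(), delimiter="\t"))
    if not rows:
        raise LexiconError("lexicon resource is empty")
    missing = [c for c in _REQUIRED_COLUMNS if c not in rows[0]]
    if missing:
        raise LexiconError(f"lexicon resource missing columns: {missing}")
    entries: list[LexiconEntry] = []
    seen: set[str] = set()
    for i, row in enumerate(rows, start=2):
        cid = (row["concept_id"] or "").strip()
        if not cid:
            raise LexiconError(f"row {i}: empty concept_id")
        if cid in seen:
            raise LexiconError(f"row {i}: duplicate concept_id {cid!r}")
        seen.add(cid)
        try:
            entry = LexiconEntry(
                concept_id=cid,
                snomed_code=(row["snomed_code"] or "").strip(),
                category=ConceptCategory(row["category"].strip()),
                patterns=[row["pattern"].strip()],
                notes=(row.get("notes") or "").strip(),
            )
        except ValueError as exc:
            raise LexiconError(f"row {i}: {exc}") from exc
        try:
            entry.compiled()  # force pattern compilation now
        except LexiconError as exc:
            raise LexiconError(f"row {i}: {exc}") from exc
        entries.append(entry)
    return Lexicon(entries=entries, version=version)


@lru_cache(maxsize=1)
def default_lexicon() -> Lexicon:
    return load_lexicon()


# ---------------------------------------------------------------------------
# Concept matching
# ---------------------------------------------------------------------------

# Explicit nodal lexemes used to re-categorize a mass hit as a lymph node:
# "a (lymphnodal) subcarinal mass" is a node, not the primary tumor.  A
# nodal-station word alone ("hilar mass") does NOT re-categorize; that
# residual ambiguity is a documented limitation of the rule-based approach.
_LYMPH_CONTEXT_RE = re.compile(r"\b(lymph|lymphnodal|lymph-?adenopathy|nodal|nodes?)\b", re.I)

# Adjectives marking gravity-dependent (non-obstructive) atelectasis, which
# must never count as the post-obstructive presence criterion.
_GRAVITY_ADJECTIVE_RE = re.compile(
    r"\b(basal|bibasilar|bibasal|basilar|bilateral|subsegmental|dependent|"
    r"gravity(-dependent)?|plate-?like|discoid|linear)\b", re.I)


def sentence_has_gravity_adjective(sentence_text: str) -> bool:
    return _GRAVITY_ADJECTIVE_RE.search(sentence_text) is not None


def match_concepts(sentence_text: str, lexicon: Lexicon,
                   base_offset: int = 0, sentence_ref: int = 0) -> list[ConceptMention]:
    """Find all concept mentions in one sentence.

    Rules applied, in order:

    * longest-match-wins among overlapping hits of the same category;
    * a tumor-mass hit strictly contained in a longer hit of another
      category (e.g. "nodule" inside "satellite nodule") is dropped;
    * atelectasis presence hits are dropped when the sentence carries a
      gravity-type adjective (basal, bilateral, subsegmental, ...);
    * tumor-mass hits are re-categorized to lymph_node when the sentence
      contains an explicit nodal lexeme.
    """
    raw_hits: list[tuple[int, int, LexiconEntry]] = []
    for entry in lexicon.entries:
        for pat in entry.compiled():
            for m in pat.finditer(sentence_text):
                raw_hits.append((m.start(), m.end(), entry))

    # longest-match-wins per category
    kept: list[tuple[int, int, LexiconEntry]] = []
    for start, end, entry in sorted(raw_hits, key=lambda h: (-(h[1] - h[0]), h[0])):
        clash = any(
            e2.category is entry.category and start < k_end and k_start < end
            for k_start, k_end, e2 in kept
        )
        if not clash:
            kept.append((start, end, entry))

    # cross-category containment: drop tumor lexemes swallowed by a longer hit
    pruned: list[tuple[int, int, LexiconEntry]] = []
    for start, end, entry in kept:
        if entry.category is ConceptCategory.TUMOR_MASS:
            contained = any(
                e2.category is not ConceptCategory.TUMOR_MASS
                and k_start <= start and end <= k_end and (k_end - k_start) > (end - start)
                for k_start, k_end, e2 in kept
            )
            if contained:
                continue
        pruned.append((start, end, entry))

    gravity = sentence_has_gravity_adjective(sentence_text)
    nodal_context = _LYMPH_CONTEXT_RE.search(sentence_text) is not None

    mentions: list[ConceptMention] = []
    for start, end, entry in sorted(pruned, key=lambda h: h[0]):
        category = entry.category
        if (category is ConceptCategory.PRESENCE_FINDING
                and entry.concept_id == "post_obstructive_atelectasis" and gravity):
            continue
        if category is ConceptCategory.TUMOR_MASS and nodal_context:
            category = ConceptCategory.LYMPH_NODE
        mentions.append(ConceptMention(
            concept_id=entry.concept_id,
            snomed_code=entry.snomed_code,
            category=category,
            span=CharSpan(start=base_offset + start, end=base_offset + end),
            sentence_ref=sentence_ref,
        ))
    return mentions


def apply_blacklist(mentions: list[ConceptMention],
                    measurements: list[Measurement],
                    ) -> tuple[list[ConceptMention], list[Measurement], bool]:
    """Suppress tumor candidates in a sentence naming a blacklisted organ.

    If the sentence holds any blacklist_term mention (kidney, liver, cyst,
    ...), every tumor_mass mention and every measurement in that sentence
    is removed; involvement targets and other categories survive.  Returns
    the filtered lists and whether the blacklist fired.
    """
    fired = any(m.category is ConceptCategory.BLACKLIST_TERM for m in mentions)
    if not fired:
        return mentions, measurements, False
    kept = [m for m in mentions if m.category is not ConceptCategory.TUMOR_MASS]
    return kept, [], True


# ---------------------------------------------------------------------------
# Anatomic location lookup
# ---------------------------------------------------------------------------

LOBE_BY_CONCEPT: dict[str, tuple[Laterality, Lobe]] = {
    "lobe_rul": (Laterality.RIGHT, Lobe.RUL),
    "lobe_rml": (Laterality.RIGHT, Lobe.RML),
    "lobe_rll": (Laterality.RIGHT, Lobe.RLL),
    "lobe_lul": (Laterality.LEFT, Lobe.LUL),
    "lobe_lll": (Laterality.LEFT, Lobe.LLL),
}


def site_of(concept_id: str) -> tuple[Laterality, Lobe]:
    return LOBE_BY_CONCEPT.get(concept_id, (Laterality.UNKNOWN, Lobe.UNKNOWN))
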