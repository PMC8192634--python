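"""Report preprocessing: cleaning, sectionizing, sentence segmentation, tokenization.

The cleaning step normalizes whitespace but never rewrites coordinates:
it returns an offset map from every processed index back to an original
index, so that all downstream annotations can be expressed as spans into
the untouched report text (which is what a reviewing front end highlights).
"""

from __future__ import annotations

import re
from importlib import resources
from typing import Optional

import yaml
from pydantic import BaseModel, Field

from .annotation_model import CharSpan, Section, SectionCategory, Sentence, Token


class EmptyReportError(ValueError):
    """Raised when a report is empty or whitespace-only."""


# Horizontal whitespace subject to run-collapsing; newlines are preserved.
_HSPACE = set(" \t\xa0\u2007\u2009\u202f")


def clean_text(raw: str) -> tuple[str, list[int]]:
    """Normalize line endings, non-breaking spaces and whitespace runs.

    Returns ``(processed, offset_map)`` where ``offset_map[i]`` is an index
    into ``raw`` for processed character ``i``.  No letter, digit or
    punctuation character is ever deleted; for a collapsed whitespace run
    the map points at a plain-space character of the run when one exists,
    otherwise at the run's first character.
    """
    if not raw or not raw.strip():
        raise EmptyReportError("report text is empty or whitespace-only")
    out: list[str] = []
    omap: list[int] = []
    i, n = 0, len(raw)
    while i < n:
        c = raw[i]
        if c == "\r":
            if i + 1 < n and raw[i + 1] == "\n":
                out.append("\n")
                omap.append(i + 1)
                i += 2
            else:
                out.append("\n")
                omap.append(i)
                i += 1
        elif c in _HSPACE:
            j = i
            while j < n and raw[j] in _HSPACE:
                j += 1
            k = next((p for p in range(i, j) if raw[p] == " "), i)
            out.append(" ")
            omap.append(k)
            i = j
        else:
            out.append(c)
            omap.append(i)
            i += 1
    return "".join(out), omap


def map_span(start: int, end: int, offset_map: list[int]) -> CharSpan:
    """Translate a processed-text span into original-text coordinates."""
    return CharSpan(start=offset_map[start], end=offset_map[end - 1] + 1)


# ---------------------------------------------------------------------------
# Section detection
# ---------------------------------------------------------------------------

class SectionPolicy(BaseModel):
    """Which subheadings open which section, and which sections are in scope
    for tumor/size candidate extraction."""

    heading_patterns: dict[SectionCategory, list[str]]
    scope_map: dict[SectionCategory, bool]
    default_in_scope: bool = True

    def compiled(self) -> list[tuple[SectionCategory, re.Pattern]]:
        pats = []
        for cat, patterns in self.heading_patterns.items():
            for p in patterns:
                pats.append((cat, re.compile(rf"(?i)^{p}(\s*\([^)\n]*\))?$")))
        return pats


def load_section_policy(path: Optional[str] = None) -> SectionPolicy:
    """Load a section policy from YAML (the shipped default when no path)."""
    if path is None:
        data = yaml.safe_load(
            resources.files("pulmostage.resources").joinpath("sections.yaml").read_text("utf-8")
        )
    else:
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh)
    heading_patterns: dict[SectionCategory, list[str]] = {}
    scope_map: dict[SectionCategory, bool] = {}
    for name, entry in data["categories"].items():
        cat = SectionCategory(name)
        heading_patterns[cat] = list(entry.get("patterns", []))
        scope_map[cat] = bool(entry["in_scope"])
    for cat in SectionCategory:
        scope_map.setdefault(cat, bool(data.get("default_in_scope", True)))
    return SectionPolicy(
        heading_patterns=heading_patterns,
        scope_map=scope_map,
        default_in_scope=bool(data.get("default_in_scope", True)),
    )


def detect_sections(processed: str, policy: SectionPolicy) -> list[Section]:
    """Split the processed text into headed sections.

    A heading is recognized only at line start, as ``Heading:`` or as a bare
    line equal to a known heading.  Sections partition the text; text before
    the first heading (or a report with no headings at all) is an ``other``
    section which is in scope.
    """
    compiled = policy.compiled()
    hits: list[tuple[int, int, SectionCategory, str]] = []  # (line_start, body_start, cat, raw)
    for m in re.finditer(r"^[^\n]*$", processed, flags=re.M):
        line = m.group(0)
        stripped = line.strip()
        if not stripped:
            continue
        head, colon, _rest = stripped.partition(":")
        candidate = head.strip() if colon else stripped
        cat = None
        for c, pat in compiled:
            if pat.match(candidate):
                cat = c
                break
        if cat is None:
            continue
        if not colon and len(stripped) > 40:
            continue
        body_start = min(m.end() + 1, len(processed))  # first char after heading line
        hits.append((m.start(), body_start, cat, stripped))

    sections: list[Section] = []
    if not hits:
        return [Section(
            heading_raw="", category=SectionCategory.OTHER,
            span=CharSpan(start=0, end=len(processed)), body_start=0,
            in_scope=policy.scope_map.get(SectionCategory.OTHER, True),
        )]
    if hits[0][0] > 0:
        if processed[:hits[0][0]].strip():
            sections.append(Section(
                heading_raw="", category=SectionCategory.OTHER,
                span=CharSpan(start=0, end=hits[0][0]), body_start=0,
                in_scope=policy.scope_map.get(SectionCategory.OTHER, True),
            ))
        else:
            # leading pure-whitespace prefix: fold into the first section
            hits[0] = (0, hits[0][1], hits[0][2], hits[0][3])
    for idx, (start, body_start, cat, raw) in enumerate(hits):
        end = hits[idx + 1][0] if idx + 1 < len(hits) else len(processed)
        sections.append(Section(
            heading_raw=raw, category=cat,
            span=CharSpan(start=start, end=end),
            body_start=min(body_start, end),
            in_scope=policy.scope_map.get(cat, policy.default_in_scope),
        ))
    return sections


# ---------------------------------------------------------------------------
# Sentence segmentation
# ---------------------------------------------------------------------------

_ABBREVIATIONS = {"dr", "mr", "mrs", "e.g", "i.e", "vs", "approx", "pt"}


def _is_boundary(text: str, i: int) -> bool:
    """Is the terminator character at index ``i`` a sentence boundary?"""
    c = text[i]
    if c in "!?":
        return True
    if c != ".":
        return False
    nxt = text[i + 1] if i + 1 < len(text) else ""
    if nxt and not nxt.isspace():
        return False  # decimal point or mid-token period
    # abbreviation guard: word immediately before the period
    m = re.search(r"([A-Za-z.]+)$", text[:i])
    if m and m.group(1).lower().rstrip(".") in _ABBREVIATIONS:
        return False
    return True


def segment_sentences(processed: str, sections: list[Section]) -> list[Sentence]:
    """Segment each section body into sentences (processed coordinates).

    Sentences never cross section boundaries; a section heading line is its
    own sentence.  Every character belongs to exactly one sentence or to
    inter-sentence whitespace.  ``token_range`` is filled by the caller
    after tokenization.
    """
    sentences: list[Sentence] = []
    for sec_idx, sec in enumerate(sections):
        lo, hi = sec.span.start, sec.span.end
        start = None
        for i in range(lo, hi):
            c = processed[i]
            if start is None:
                if not c.isspace():
                    start = i
                continue
            if c == "\n":
                # newline terminates the running sentence
                end = i
                while end > start and processed[end - 1].isspace():
                    end -= 1
                if end > start:
                    sentences.append(Sentence(
                        span=CharSpan(start=start, end=end),
                        token_range=(0, 0), section_ref=sec_idx))
                start = None
            elif c in ".!?" and _is_boundary(processed, i):
                sentences.append(Sentence(
                    span=CharSpan(start=start, end=i + 1),
                    token_range=(0, 0), section_ref=sec_idx))
                start = None
        if start is not None:
            end = hi
            while end > start and processed[end - 1].isspace():
                end -= 1
            if end > start:
                sentences.append(Sentence(
                    span=CharSpan(start=start, end=end),
                    token_range=(0, 0), section_ref=sec_idx))
    return sentences


# ---------------------------------------------------------------------------
# Tokenization
# ---------------------------------------------------------------------------

# numbers with decimal comma or point stay single tokens; words; any other
# non-space character is its own token (so "x"/"×" separators stand alone).
_TOKEN_RE = re.compile(r"\d+[.,]\d+|\d+|[^\W\d_]+|\S", re.UNICODE)


def tokenize(text: str, base_offset: int = 0, index_offset: int = 0) -> list[Token]:
    """Tokenize a sentence string; spans are offset by ``base_offset``."""
    tokens: list[Token] = []
    for k, m in enumerate(_TOKEN_RE.finditer(text)):
        tokens.append(Token(
            index=index_offset + k,
            text=m.group(0),
            span=CharSpan(start=base_offset + m.start(), end=base_offset + m.end()),
        ))
    return tokens


# ---------------------------------------------------------------------------
# Assembled preprocessing pass (original-text coordinates)
# ---------------------------------------------------------------------------

def preprocess_report(raw: str, policy: Optional[SectionPolicy] = None,
                      ) -> tuple[list[Section], list[Sentence], list[Token]]:
    """Full preprocessing pass over one report.

    Cleans the text, detects sections, segments sentences and tokenizes,
    then maps every span back into original-text coordinates through the
    offset map so the records can live in an :class:`AnnotationDocument`.
    """
    if policy is None:
        policy = load_section_policy()
    processed, omap = clean_text(raw)
    sections_p = detect_sections(processed, policy)
    sentences_p = segment_sentences(processed, sections_p)

    sections = [
        Section(
            heading_raw=s.heading_raw, category=s.category,
            span=map_span(s.span.start, s.span.end, omap),
            body_start=(omap[s.body_start] if s.body_start < len(omap)
                        else omap[-1] + 1),
            in_scope=s.in_scope,
        )
        for s in sections_p
    ]
    sentences: list[Sentence] = []
    tokens: list[Token] = []
    for s in sentences_p:
        stext = processed[s.span.start:s.span.end]
        toks_p = tokenize(stext)
        lo = len(tokens)
        for t in toks_p:
            tokens.append(Token(
                index=len(tokens), text=t.text,
                span=map_span(s.span.start + t.span.start,
                              s.span.start + t.span.end, omap),
            ))
        sentences.append(Sentence(
            span=map_span(s.span.start, s.span.end, omap),
            token_range=(lo, len(tokens)),
            section_ref=s.section_ref,
        ))
    return sections, sentences, tokens
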