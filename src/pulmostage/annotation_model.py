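"""Core data types and the token-level standoff interchange format.

Every pipeline stage consumes and produces an :class:`AnnotationDocument`,
a self-contained standoff record whose spans are 0-based half-open
character intervals into the *original* report text.  Keeping annotations
at token/character level (rather than sentence level) lets a front end
highlight exactly the evidence each staging decision rests on, and lets
heterogeneous pipeline components exchange state through plain JSON.
"""

from __future__ import annotations

import json
from enum import Enum
from typing import Optional

from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator


class DocumentValidationError(ValueError):
    """A record in an annotation document violates a structural invariant."""


# ---------------------------------------------------------------------------
# Enumerations
# ---------------------------------------------------------------------------

class FormatTag(str, Enum):
    CT = "CT"
    PET = "PET"
    PET_CT = "PET-CT"
    UNKNOWN = "unknown"


class SectionCategory(str, Enum):
    HISTORY = "history"
    COMPARISON = "comparison"
    TECHNIQUE = "technique"
    FINDINGS = "findings"
    HEAD = "head"
    NECK = "neck"
    CHEST = "chest"
    MEDIASTINUM = "mediastinum"
    ABDOMEN = "abdomen"
    PELVIS = "pelvis"
    BONES = "bones"
    MUSCULOSKELETAL = "musculoskeletal"
    OTHER = "other"


class ConceptCategory(str, Enum):
    TUMOR_MASS = "tumor_mass"
    LYMPH_NODE = "lymph_node"
    INVOLVEMENT_TARGET = "involvement_target"
    PRESENCE_FINDING = "presence_finding"
    ANATOMIC_LOCATION = "anatomic_location"
    BLACKLIST_TERM = "blacklist_term"


class ModifierCategory(str, Enum):
    NEGATION = "negation"
    UNCERTAINTY = "uncertainty"
    HISTORICAL = "historical"
    TERMINATION = "termination"
    PSEUDO = "pseudo"


class Direction(str, Enum):
    FORWARD = "forward"
    BACKWARD = "backward"
    BIDIRECTIONAL = "bidirectional"


class Unit(str, Enum):
    MM = "mm"
    CM = "cm"


class Laterality(str, Enum):
    LEFT = "left"
    RIGHT = "right"
    UNKNOWN = "unknown"


class Lobe(str, Enum):
    RUL = "RUL"
    RML = "RML"
    RLL = "RLL"
    LUL = "LUL"
    LLL = "LLL"
    UNKNOWN = "unknown"


LOBE_LATERALITY = {
    Lobe.RUL: Laterality.RIGHT,
    Lobe.RML: Laterality.RIGHT,
    Lobe.RLL: Laterality.RIGHT,
    Lobe.LUL: Laterality.LEFT,
    Lobe.LLL: Laterality.LEFT,
    Lobe.UNKNOWN: Laterality.UNKNOWN,
}


class FindingRole(str, Enum):
    PRIMARY = "primary"
    SATELLITE_SAME_LOBE = "satellite_same_lobe"
    NODULE_IPSILATERAL_OTHER_LOBE = "nodule_ipsilateral_other_lobe"
    OTHER = "other"


class PresenceKind(str, Enum):
    POST_OBSTRUCTIVE_ATELECTASIS = "post_obstructive_atelectasis"
    MAIN_BRONCHUS = "main_bronchus"
    SATELLITE_SAME_LOBE = "satellite_same_lobe"
    NODULE_IPSILATERAL_OTHER_LOBE = "nodule_ipsilateral_other_lobe"


class TLabel(str, Enum):
    TX = "Tx"
    T1A = "T1a"
    T1B = "T1b"
    T1C = "T1c"
    T2 = "T2"
    T2A = "T2a"
    T2B = "T2b"
    T3 = "T3"
    T4 = "T4"


#: Total order over T labels; ``Tx`` ranks below every substage and the bare
#: tier ``T2`` ranks just below ``T2a`` (a sized T2 is more informative).
T_ORDER: list[str] = ["Tx", "T1a", "T1b", "T1c", "T2", "T2a", "T2b", "T3", "T4"]
_T_RANK = {label: i for i, label in enumerate(T_ORDER)}


def t_rank(label: TLabel | str) -> int:
    return _T_RANK[str(label.value if isinstance(label, TLabel) else label)]


def t_max(*labels: TLabel | str | None) -> Optional[str]:
    """Maximum of the given labels under the T order; ``None`` entries ignored."""
    present = [str(l.value if isinstance(l, TLabel) else l) for l in labels if l is not None]
    if not present:
        return None
    return max(present, key=t_rank)


# ---------------------------------------------------------------------------
# Structural records
# ---------------------------------------------------------------------------

class CharSpan(BaseModel):
    """0-based half-open character interval into the original report text."""

    model_config = ConfigDict(frozen=True)

    start: int = Field(ge=0)
    end: int

    @model_validator(mode="after")
    def _ordered(self) -> "CharSpan":
        if self.end <= self.start:
            raise ValueError(f"empty or inverted span [{self.start}, {self.end})")
        return self

    def __len__(self) -> int:
        return self.end - self.start


class RawReport(BaseModel):
    report_id: str
    text: str
    format_tag: FormatTag = FormatTag.UNKNOWN

    @field_validator("text")
    @classmethod
    def _non_blank(cls, v: str) -> str:
        if not v.strip():
            raise ValueError("report text is empty or whitespace-only")
        return v


class Token(BaseModel):
    index: int = Field(ge=0)
    text: str
    span: CharSpan


class Sentence(BaseModel):
    span: CharSpan
    token_range: tuple[int, int]
    section_ref: int = Field(ge=0)


class Section(BaseModel):
    heading_raw: str = ""
    category: SectionCategory = SectionCategory.OTHER
    span: CharSpan
    #: offset of the first character after the heading line (== span.start
    #: when the section has no recognized heading)
    body_start: int = 0
    in_scope: bool = True


class ContextFlags(BaseModel):
    negated: bool = False
    uncertain: bool = False
    historical: bool = False


class ConceptMention(BaseModel):
    concept_id: str
    snomed_code: str
    category: ConceptCategory
    span: CharSpan
    sentence_ref: int = Field(ge=0)
    flags: ContextFlags = Field(default_factory=ContextFlags)


class ModifierMention(BaseModel):
    category: ModifierCategory
    direction: Direction
    span: CharSpan
    sentence_ref: int = Field(ge=0)


class Measurement(BaseModel):
    magnitudes: list[float] = Field(min_length=1, max_length=3)
    unit: Unit
    max_dim_mm: float = Field(gt=0)
    span: CharSpan
    sentence_ref: int = Field(ge=0)

    @model_validator(mode="after")
    def _max_consistent(self) -> "Measurement":
        factor = 10.0 if self.unit is Unit.CM else 1.0
        expect = max(self.magnitudes) * factor
        if abs(self.max_dim_mm - expect) > 1e-9:
            raise ValueError(
                f"max_dim_mm {self.max_dim_mm} inconsistent with magnitudes "
                f"{self.magnitudes} {self.unit.value}"
            )
        if any(m <= 0 for m in self.magnitudes):
            raise ValueError("measurement magnitudes must be positive")
        return self


class TumorSite(BaseModel):
    laterality: Laterality = Laterality.UNKNOWN
    lobe: Lobe = Lobe.UNKNOWN
    descriptor: str = ""


class InvolvementItem(BaseModel):
    model_config = ConfigDict(frozen=True)

    structure: str
    snomed_code: str = ""
    tier: TLabel

    @field_validator("tier")
    @classmethod
    def _tier_domain(cls, v: TLabel) -> TLabel:
        if v not in (TLabel.T2, TLabel.T3, TLabel.T4):
            raise ValueError(f"involvement tier must be T2/T3/T4, got {v.value}")
        return v


class PresenceItem(BaseModel):
    model_config = ConfigDict(frozen=True)

    kind: PresenceKind
    qualifier_size_mm: Optional[float] = None


class TumorFinding(BaseModel):
    role: FindingRole
    site: TumorSite = Field(default_factory=TumorSite)
    size_mm: Optional[float] = Field(default=None, gt=0)
    involvement: list[InvolvementItem] = Field(default_factory=list)
    presence: list[PresenceItem] = Field(default_factory=list)


class TStageResult(BaseModel):
    label: TLabel
    size_component: Optional[TLabel] = None
    involvement_component: Optional[TLabel] = None
    presence_component: Optional[TLabel] = None
    rationale: list[str] = Field(default_factory=list)

    @model_validator(mode="after")
    def _label_dominates(self) -> "TStageResult":
        comps = [self.size_component, self.involvement_component, self.presence_component]
        present = [c for c in comps if c is not None]
        if not present and self.label is not TLabel.TX:
            raise ValueError("label must be Tx when all components are absent")
        for c in present:
            if t_rank(self.label) < t_rank(c):
                raise ValueError(
                    f"label {self.label.value} below component {c.value}"
                )
        return self


class AnnotationDocument(BaseModel):
    report: RawReport
    tokens: list[Token] = Field(default_factory=list)
    sentences: list[Sentence] = Field(default_factory=list)
    sections: list[Section] = Field(default_factory=list)
    concepts: list[ConceptMention] = Field(default_factory=list)
    modifiers: list[ModifierMention] = Field(default_factory=list)
    measurements: list[Measurement] = Field(default_factory=list)
    findings: list[TumorFinding] = Field(default_factory=list)
    result: Optional[TStageResult] = None
    warnings: list[str] = Field(default_factory=list)


# ---------------------------------------------------------------------------
# Validation and interchange
# ---------------------------------------------------------------------------

def _check_span(span: CharSpan, n: int, record: str) -> None:
    if span.end > n:
        raise DocumentValidationError(
            f"{record}: span [{span.start}, {span.end}) outside text of length {n}"
        )


def validate_document(doc: AnnotationDocument) -> AnnotationDocument:
    """Re-validate all cross-record invariants of a document.

    Raises :class:`DocumentValidationError` naming the offending record.
    """
    text = doc.report.text
    n = len(text)

    prev_end = -1
    for tok in doc.tokens:
        _check_span(tok.span, n, f"token {tok.index}")
        if tok.span.start < prev_end:
            raise DocumentValidationError(f"token {tok.index}: overlapping span")
        prev_end = tok.span.end
        if text[tok.span.start:tok.span.end] != tok.text:
            raise DocumentValidationError(
                f"token {tok.index}: text {tok.text!r} does not match source substring"
            )

    for i, sent in enumerate(doc.sentences):
        _check_span(sent.span, n, f"sentence {i}")
        lo, hi = sent.token_range
        if not (0 <= lo <= hi <= len(doc.tokens)):
            raise DocumentValidationError(f"sentence {i}: token_range out of bounds")
        if sent.section_ref >= len(doc.sections):
            raise DocumentValidationError(f"sentence {i}: dangling section_ref")
    for i, sec in enumerate(doc.sections):
        _check_span(sec.span, n, f"section {i}")
    for kind, records in (("concept", doc.concepts), ("modifier", doc.modifiers),
                          ("measurement", doc.measurements)):
        for i, rec in enumerate(records):
            _check_span(rec.span, n, f"{kind} {i}")
            if rec.sentence_ref >= len(doc.sentences):
                raise DocumentValidationError(f"{kind} {i}: dangling sentence_ref")
    for i, c in enumerate(doc.concepts):
        if c.category is ConceptCategory.BLACKLIST_TERM and (
            c.flags.negated or c.flags.uncertain or c.flags.historical
        ):
            raise DocumentValidationError(f"concept {i}: blacklist term carries flags")
    primaries = [f for f in doc.findings if f.role is FindingRole.PRIMARY]
    if len(primaries) > 1:
        raise DocumentValidationError("more than one primary tumor finding")
    return doc


def serialize_document(doc: AnnotationDocument) -> bytes:
    """Serialize a document to its UTF-8 JSON interchange form.

    Field order is the declaration order of the models, so serialization is
    byte-stable: ``serialize(deserialize(s)) == s`` for any stream ``s``
    produced here.
    """
    validate_document(doc)
    return doc.model_dump_json().encode("utf-8")


def deserialize_document(stream: bytes | str) -> AnnotationDocument:
    """Parse and fully re-validate an interchange stream."""
    if isinstance(stream, bytes):
        stream = stream.decode("utf-8")
    try:
        doc = AnnotationDocument.model_validate_json(stream)
    except ValueError as exc:
        raise DocumentValidationError(str(exc)) from exc
    return validate_document(doc)


def serialize_batch(docs: list[AnnotationDocument]) -> bytes:
    """JSON-lines batch form: one document per line."""
    return b"\n".join(serialize_document(d) for d in docs)


def deserialize_batch(stream: bytes | str) -> list[AnnotationDocument]:
    if isinstance(stream, bytes):
        stream = stream.decode("utf-8")
    return [deserialize_document(line) for line in stream.splitlines() if line.strip()]
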