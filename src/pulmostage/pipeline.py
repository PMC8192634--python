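"""Pipeline orchestration: the five processing stages chained through the
annotation document.

Canonical stage order::

    preprocess -> concepts -> context -> measurements -> classify

Each stage recomputes its layer of the document deterministically from the
layers before it, so stages are idempotent and running them one by one is
exactly equivalent to the fused run.
"""

from __future__ import annotations

import logging
from typing import Callable, Optional, Sequence

from .annotation_model import (
    AnnotationDocument,
    ConceptCategory,
    FormatTag,
    RawReport,
    validate_document,
)
from .context_engine import (
    ModifierLexicon,
    assign_modifier_scopes,
    default_modifiers,
    match_modifiers,
)
from .lexicon_matcher import (
    Lexicon,
    apply_blacklist,
    default_lexicon,
    match_concepts,
)
from .measurement_extractor import (
    ConsolidationInput,
    consolidate_findings,
    extract_measurements,
    link_measurements,
)
from .preprocessing import SectionPolicy, load_section_policy, preprocess_report
from .tstage_classifier import TnmDecisionTable, classify_t, default_decision_table

logger = logging.getLogger(__name__)

STAGE_ORDER = ("preprocess", "concepts", "context", "measurements", "classify")


class StageOrderError(ValueError):
    """Requested stages are not a prefix of the canonical order."""


class Pipeline:
    """A configured processing pipeline.

    Parameters
    ----------
    lexicon, modifiers, section_policy, decision_table:
        Resource objects; the shipped defaults are used when omitted.
    count_uncertain:
        When true, uncertain involvement mentions *do* contribute to
        staging (the stricter certain-only reading is the default).
    """

    def __init__(self,
                 lexicon: Optional[Lexicon] = None,
                 modifiers: Optional[ModifierLexicon] = None,
                 section_policy: Optional[SectionPolicy] = None,
                 decision_table: Optional[TnmDecisionTable] = None,
                 count_uncertain: bool = False):
        self.lexicon = lexicon or default_lexicon()
        self.modifiers = modifiers or default_modifiers()
        self.section_policy = section_policy or load_section_policy()
        self.decision_table = decision_table or default_decision_table()
        self.count_uncertain = count_uncertain

    # -- stages ---------------------------------------------------------

    def stage_preprocess(self, doc: AnnotationDocument) -> AnnotationDocument:
        sections, sentences, tokens = preprocess_report(
            doc.report.text, self.section_policy)
        doc.sections = sections
        doc.sentences = sentences
        doc.tokens = tokens
        return doc

    def _heading_sentence(self, doc: AnnotationDocument, sent) -> bool:
        sec = doc.sections[sent.section_ref]
        return bool(sec.heading_raw) and sent.span.end <= sec.body_start

    def stage_concepts(self, doc: AnnotationDocument) -> AnnotationDocument:
        text = doc.report.text
        concepts = []
        for i, sent in enumerate(doc.sentences):
            if self._heading_sentence(doc, sent):
                continue  # a heading like "Mediastinum:" is not a finding
            stext = text[sent.span.start:sent.span.end]
            concepts.extend(match_concepts(
                stext, self.lexicon, base_offset=sent.span.start, sentence_ref=i))
        doc.concepts = concepts
        return doc

    def stage_context(self, doc: AnnotationDocument) -> AnnotationDocument:
        text = doc.report.text
        modifiers = []
        for i, sent in enumerate(doc.sentences):
            stext = text[sent.span.start:sent.span.end]
            mods = match_modifiers(
                stext, self.modifiers, base_offset=sent.span.start, sentence_ref=i)
            modifiers.extend(mods)
            sent_concepts = [c for c in doc.concepts if c.sentence_ref == i]
            assign_modifier_scopes(sent.span, mods, sent_concepts)
        doc.modifiers = modifiers
        return doc

    def stage_measurements(self, doc: AnnotationDocument) -> AnnotationDocument:
        text = doc.report.text
        evidence = ConsolidationInput()
        doc.measurements = []
        for i, sent in enumerate(doc.sentences):
            section = doc.sections[sent.section_ref]
            concepts = [c for c in doc.concepts if c.sentence_ref == i]
            for c in concepts:
                if c.category is ConceptCategory.INVOLVEMENT_TARGET:
                    if c.flags.uncertain and self.count_uncertain and not c.flags.negated:
                        evidence.involvement_mentions.append(
                            c.model_copy(update={"flags": c.flags.model_copy(
                                update={"uncertain": False})}))
                    else:
                        evidence.involvement_mentions.append(c)
                elif c.category is ConceptCategory.PRESENCE_FINDING:
                    evidence.presence_mentions.append(c)
                    if c.concept_id == "satellite_nodule" and not (
                            c.flags.negated or c.flags.uncertain):
                        evidence.satellite_sentences.add(i)
            if not section.in_scope:
                continue  # no tumor/size candidates outside thoracic sections
            stext = text[sent.span.start:sent.span.end]
            meas = extract_measurements(
                stext, base_offset=sent.span.start, sentence_ref=i)
            mentions, meas, fired = apply_blacklist(concepts, meas)
            if fired:
                logger.debug("%s: blacklist fired in sentence %d",
                             doc.report.report_id, i)
            doc.measurements.extend(meas)
            links = link_measurements(meas, mentions, sentence_ref=i)
            evidence.tumor_links.extend(
                l for l in links if l.concept is not None
                and l.concept.category is ConceptCategory.TUMOR_MASS)
        findings, warnings = consolidate_findings(evidence, self.decision_table)
        doc.findings = findings
        doc.warnings = warnings
        return doc

    def stage_classify(self, doc: AnnotationDocument) -> AnnotationDocument:
        doc.result = classify_t(doc.findings, self.decision_table)
        return doc

    # -- orchestration --------------------------------------------------

    def _stage_fn(self, name: str) -> Callable[[AnnotationDocument], AnnotationDocument]:
        return getattr(self, f"stage_{name}")

    def run_stages(self, doc: AnnotationDocument,
                   stages: Sequence[str]) -> AnnotationDocument:
        """Run a prefix of the canonical stage order on a document."""
        stages = tuple(stages)
        if stages != STAGE_ORDER[:len(stages)]:
            raise StageOrderError(
                f"stages {stages} are not a prefix of {STAGE_ORDER}")
        for name in stages:
            doc = self._stage_fn(name)(doc)
        return doc

    def process(self, report: RawReport | str,
                report_id: str = "report") -> AnnotationDocument:
        """Run the full pipeline on one report."""
        if isinstance(report, str):
            report = RawReport(report_id=report_id, text=report,
                               format_tag=FormatTag.UNKNOWN)
        doc = AnnotationDocument(report=report)
        doc = self.run_stages(doc, STAGE_ORDER)
        return validate_document(doc)

    def process_batch(self, reports: Sequence[RawReport]) -> list[AnnotationDocument]:
        ids = [r.report_id for r in reports]
        if len(set(ids)) != len(ids):
            raise ValueError("report_ids are not unique within the batch")
        return [self.process(r) for r in reports]
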