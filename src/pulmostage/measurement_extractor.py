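"""Size extraction and tumor-finding consolidation.

A size is only a size when it carries a unit: unitless numbers never
become measurements, which mirrors how staging-grade reports are read (a
bare "14" could be a slice number or an SUV).  Recognized forms:

* single values: ``3 cm``, ``14 mm``
* decimal comma or point: ``8,6 cm``, ``3.1 cm``
* 2-3 dimension tuples sharing one trailing unit: ``3.1 x 2.4 x 1.8 cm``
* axis-labelled tuples: ``2.1 (AP) × 3.0 (TVR) × 1.8 (SI) cm``

Ranges (``1-2 cm``) are deliberately not parsed as sizes.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Optional

from .annotation_model import (
    CharSpan,
    ConceptCategory,
    ConceptMention,
    FindingRole,
    Laterality,
    Lobe,
    LOBE_LATERALITY,
    Measurement,
    PresenceItem,
    PresenceKind,
    TumorFinding,
    TumorSite,
    Unit,
)
from .lexicon_matcher import site_of
from .tstage_classifier import TnmDecisionTable

logger = logging.getLogger(__name__)

_NUM = r"\d+(?:[.,]\d+)?"
_AXIS = r"(?:\s*\([A-Za-z]{1,4}\))?"
_MEAS_RE = re.compile(
    rf"(?<![\w.,-])({_NUM}){_AXIS}"
    rf"(?:\s*[x×]\s*({_NUM}){_AXIS})?"
    rf"(?:\s*[x×]\s*({_NUM}){_AXIS})?"
    rf"\s*(mm|cm)\b",
    re.IGNORECASE,
)
_RANGE_RE = re.compile(rf"\b{_NUM}\s*[-–]\s*{_NUM}\s*(?:mm|cm)\b", re.IGNORECASE)


def _to_float(token: str) -> float:
    return float(token.replace(",", "."))


def extract_measurements(sentence_text: str, base_offset: int = 0,
                         sentence_ref: int = 0) -> list[Measurement]:
    """Extract all unit-bearing size expressions from one sentence."""
    ranges = [m.span() for m in _RANGE_RE.finditer(sentence_text)]
    out: list[Measurement] = []
    for m in _MEAS_RE.finditer(sentence_text):
        if any(m.start() < r_end and r_start < m.end() for r_start, r_end in ranges):
            logger.debug("skipping range expression %r", m.group(0))
            continue
        magnitudes = [_to_float(g) for g in m.groups()[:3] if g]
        if any(v <= 0 for v in magnitudes):
            logger.debug("skipping non-positive size %r", m.group(0))
            continue
        unit = Unit(m.group(4).lower())
        factor = 10.0 if unit is Unit.CM else 1.0
        out.append(Measurement(
            magnitudes=magnitudes,
            unit=unit,
            max_dim_mm=max(magnitudes) * factor,
            span=CharSpan(start=base_offset + m.start(), end=base_offset + m.end()),
            sentence_ref=sentence_ref,
        ))
    return out


# ---------------------------------------------------------------------------
# Linking sizes to concepts
# ---------------------------------------------------------------------------

_LINKABLE = (
    ConceptCategory.TUMOR_MASS,
    ConceptCategory.LYMPH_NODE,
    ConceptCategory.INVOLVEMENT_TARGET,
)


@dataclass
class MeasurementLink:
    """One size expression tied to its nearest concept and anatomic site."""
    measurement: Measurement
    concept: Optional[ConceptMention]
    laterality: Laterality = Laterality.UNKNOWN
    lobe: Lobe = Lobe.UNKNOWN
    sentence_ref: int = 0


def link_measurements(measurements: list[Measurement],
                      concepts: list[ConceptMention],
                      sentence_ref: int = 0) -> list[MeasurementLink]:
    """Link each measurement to the nearest non-flagged linkable concept.

    Preceding mentions win over following ones; among preceding mentions
    the closest (largest end offset) wins.  Sizes linked to lymph nodes or
    involvement targets never become tumor sizes downstream.  The lobe and
    laterality come from the nearest anatomic-location mention.
    """
    linkable = [
        c for c in concepts
        if c.category in _LINKABLE and not c.flags.negated and not c.flags.uncertain
    ]
    anatomic = [c for c in concepts if c.category is ConceptCategory.ANATOMIC_LOCATION]
    links: list[MeasurementLink] = []
    for meas in measurements:
        preceding = [c for c in linkable if c.span.end <= meas.span.start]
        following = [c for c in linkable if c.span.start >= meas.span.end]
        if preceding:
            concept = max(preceding, key=lambda c: c.span.end)
        elif following:
            concept = min(following, key=lambda c: c.span.start)
        else:
            concept = None
            logger.info("measurement %s has no linkable concept in sentence %d",
                        meas.magnitudes, sentence_ref)
        lat, lobe = Laterality.UNKNOWN, Lobe.UNKNOWN
        lobar = [c for c in anatomic if c.concept_id.startswith("lobe_")]
        if lobar:
            mid = (meas.span.start + meas.span.end) / 2
            nearest = min(lobar, key=lambda c: abs((c.span.start + c.span.end) / 2 - mid))
            lat, lobe = site_of(nearest.concept_id)
        links.append(MeasurementLink(
            measurement=meas, concept=concept,
            laterality=lat, lobe=lobe, sentence_ref=sentence_ref,
        ))
    return links


# ---------------------------------------------------------------------------
# Document-level consolidation
# ---------------------------------------------------------------------------

@dataclass
class ConsolidationInput:
    """Per-document staging evidence gathered from in-scope sentences."""
    tumor_links: list[MeasurementLink] = field(default_factory=list)
    involvement_mentions: list[ConceptMention] = field(default_factory=list)
    presence_mentions: list[ConceptMention] = field(default_factory=list)
    #: sentence_refs that contain a satellite-nodule presence mention
    satellite_sentences: set[int] = field(default_factory=set)


def consolidate_findings(evidence: ConsolidationInput,
                         table: TnmDecisionTable) -> tuple[list[TumorFinding], list[str]]:
    """Merge sentence-level evidence into a list of tumor findings.

    The largest linked lung-tumor size becomes the primary tumor.  A second
    sized tumor in a different ipsilateral lobe becomes a separate finding
    and a T4-relevant presence item; contralateral nodules are ignored for
    T (they belong to the M domain).  Two different sizes for what reads
    as the same tumor resolve to the larger size with a warning.
    Involvement and presence items attach to the primary and only ever
    come from non-negated, non-uncertain mentions.
    """
    warnings: list[str] = []
    findings: list[TumorFinding] = []

    involvement = []
    seen_structures: set[str] = set()
    for m in evidence.involvement_mentions:
        if m.flags.negated or m.flags.uncertain:
            continue
        if m.concept_id in seen_structures:
            continue
        seen_structures.add(m.concept_id)
        involvement.append(table.involvement_item(m.concept_id, m.snomed_code))
    involvement.sort(key=lambda item: item.structure)

    presence: list[PresenceItem] = []
    presence_kinds: set[PresenceKind] = set()
    for m in evidence.presence_mentions:
        if m.flags.negated or m.flags.uncertain:
            continue
        kind = (PresenceKind.SATELLITE_SAME_LOBE if m.concept_id == "satellite_nodule"
                else PresenceKind.POST_OBSTRUCTIVE_ATELECTASIS)
        if kind not in presence_kinds:
            presence_kinds.add(kind)
            presence.append(PresenceItem(kind=kind))

    sized = [l for l in evidence.tumor_links
             if l.concept is not None
             and l.concept.category is ConceptCategory.TUMOR_MASS]

    if not sized:
        if involvement or presence:
            findings.append(TumorFinding(
                role=FindingRole.PRIMARY, site=TumorSite(),
                size_mm=None, involvement=involvement, presence=presence,
            ))
        return findings, warnings

    primary_link = max(sized, key=lambda l: (l.measurement.max_dim_mm, -l.sentence_ref))
    primary_size = primary_link.measurement.max_dim_mm
    p_lat, p_lobe = primary_link.laterality, primary_link.lobe

    secondary: list[TumorFinding] = []
    for link in sized:
        if link is primary_link:
            continue
        size = link.measurement.max_dim_mm
        same_lobe = (link.lobe is p_lobe) or link.lobe is Lobe.UNKNOWN or p_lobe is Lobe.UNKNOWN
        if same_lobe:
            if link.sentence_ref in evidence.satellite_sentences:
                continue  # the satellite presence item already covers it
            if abs(size - primary_size) > 1e-9:
                warnings.append(
                    f"same tumor reported with different sizes "
                    f"({size:g} mm vs {primary_size:g} mm); using the larger")
            continue
        if link.laterality is p_lat and p_lat is not Laterality.UNKNOWN:
            secondary.append(TumorFinding(
                role=FindingRole.NODULE_IPSILATERAL_OTHER_LOBE,
                site=TumorSite(laterality=link.laterality, lobe=link.lobe),
                size_mm=size,
            ))
            if PresenceKind.NODULE_IPSILATERAL_OTHER_LOBE not in presence_kinds:
                presence_kinds.add(PresenceKind.NODULE_IPSILATERAL_OTHER_LOBE)
                presence.append(PresenceItem(
                    kind=PresenceKind.NODULE_IPSILATERAL_OTHER_LOBE,
                    qualifier_size_mm=size,
                ))
        else:
            warnings.append(
                f"contralateral nodule ({size:g} mm, {link.lobe.value}) ignored for T staging")

    findings.append(TumorFinding(
        role=FindingRole.PRIMARY,
        site=TumorSite(laterality=p_lat, lobe=p_lobe),
        size_mm=primary_size,
        involvement=involvement,
        presence=presence,
    ))
    findings.extend(secondary)
    return findings, warnings
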