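"""T-descriptor classification (AJCC/UICC TNM 8th edition, lung).

The classifier maps three independent components — maximum tumor dimension,
invaded structures, and presence findings — each to a T label, and returns
their maximum under the total order

    Tx < T1a < T1b < T1c < T2 < T2a < T2b < T3 < T4.

Size classes are inclusive on their upper bound (">x but <=y cm").  The
bare label ``T2`` is a real output class: it is emitted when a T2
criterion (main-bronchus or visceral-pleura involvement, post-obstructive
atelectasis) fires and no size is available to pick T2a or T2b.  ``Tx``
means no staging evidence of any kind was extracted.

Two thresholds are not fixed by the TNM booklet and are set here as
explicit decision-table values: an ipsilateral different-lobe nodule needs
to exceed 10 mm to raise T4, and a same-lobe satellite nodule has no
minimum size.
"""

from __future__ import annotations

import logging
from functools import lru_cache
from importlib import resources
from typing import Iterable, Optional

import yaml
from pydantic import BaseModel, Field, PrivateAttr, model_validator

from .annotation_model import (
    FindingRole,
    InvolvementItem,
    PresenceItem,
    PresenceKind,
    TLabel,
    TStageResult,
    TumorFinding,
    t_max,
    t_rank,
)

logger = logging.getLogger(__name__)


class StagingConfigError(ValueError):
    """Unknown structure or malformed decision table."""


class TnmDecisionTable(BaseModel):
    """Versioned size breakpoints and involvement/presence tier maps."""

    version: str = "AJCC8"
    #: ordered (label, upper bound in mm) pairs; inclusive upper bounds
    size_breakpoints_mm: list[tuple[TLabel, float]]
    size_above_last: TLabel = TLabel.T4
    involvement_tiers: dict[TLabel, list[str]]
    presence_map: dict[PresenceKind, TLabel]
    nodule_min_size_mm: float = 10.0
    #: SNOMED codes per structure, filled from the lexicon when available
    structure_codes: dict[str, str] = Field(default_factory=dict)

    _tier_cache: Optional[dict] = PrivateAttr(default=None)
    _presence_cache: Optional[dict] = PrivateAttr(default=None)

    @model_validator(mode="after")
    def _check(self) -> "TnmDecisionTable":
        bounds = [b for _, b in self.size_breakpoints_mm]
        if bounds != sorted(bounds) or len(set(bounds)) != len(bounds):
            raise StagingConfigError("size breakpoints must be strictly increasing")
        seen: set[str] = set()
        for tier, structures in self.involvement_tiers.items():
            if tier not in (TLabel.T2, TLabel.T3, TLabel.T4):
                raise StagingConfigError(f"invalid involvement tier {tier}")
            for s in structures:
                if s in seen:
                    raise StagingConfigError(f"structure {s!r} appears in two tiers")
                seen.add(s)
        return self

    @property
    def structure_tier(self) -> dict[str, TLabel]:
        if self._tier_cache is None:
            object.__setattr__(self, "_tier_cache",
                               {s: tier for tier, ss in self.involvement_tiers.items()
                                for s in ss})
        return self._tier_cache

    @property
    def presence_label(self) -> dict[str, str]:
        """Presence map keyed/valued by plain strings (hot-path lookup)."""
        if self._presence_cache is None:
            object.__setattr__(self, "_presence_cache",
                               {k.value: v.value for k, v in self.presence_map.items()})
        return self._presence_cache

    def involvement_item(self, structure: str, snomed_code: str = "") -> InvolvementItem:
        tier = self.structure_tier.get(structure)
        if tier is None:
            raise StagingConfigError(f"structure {structure!r} not in decision table")
        return InvolvementItem(structure=structure, snomed_code=snomed_code, tier=tier)


def load_decision_table(path: Optional[str] = None) -> TnmDecisionTable:
    if path is None:
        data = yaml.safe_load(
            resources.files("pulmostage.resources").joinpath("tnm_ajcc8.yaml").read_text("utf-8")
        )
    else:
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh)
    return TnmDecisionTable(
        version=data.get("version", "AJCC8"),
        size_breakpoints_mm=[(TLabel(l), float(b)) for l, b in data["size_breakpoints_mm"]],
        size_above_last=TLabel(data.get("size_above_last", "T4")),
        involvement_tiers={TLabel(k): list(v) for k, v in data["involvement_tiers"].items()},
        presence_map={PresenceKind(k): TLabel(v) for k, v in data["presence_map"].items()},
        nodule_min_size_mm=float(data.get("nodule_min_size_mm", 10.0)),
    )


@lru_cache(maxsize=1)
def default_decision_table() -> TnmDecisionTable:
    return load_decision_table()


# ---------------------------------------------------------------------------
# Component classifiers
# ---------------------------------------------------------------------------

def size_to_t(size_mm: Optional[float], table: TnmDecisionTable) -> Optional[TLabel]:
    """Size component; inclusive on each class upper bound; absent -> absent."""
    if size_mm is None:
        return None
    if size_mm <= 0:
        raise ValueError(f"tumor size must be positive, got {size_mm}")
    for label, bound in table.size_breakpoints_mm:
        if size_mm <= bound:
            return label
    return table.size_above_last


def involvement_to_t(involvement: Iterable[InvolvementItem | str],
                     table: TnmDecisionTable) -> Optional[TLabel]:
    """Highest tier among invaded structures; tiers come from the table."""
    tiers = []
    for item in involvement:
        structure = item if isinstance(item, str) else item.structure
        tier = table.structure_tier.get(structure)
        if tier is None:
            raise StagingConfigError(f"structure {structure!r} not in decision table")
        tiers.append(tier)
    if not tiers:
        return None
    return TLabel(t_max(*tiers))


def presence_to_t(presence: Iterable[PresenceItem],
                  table: TnmDecisionTable) -> Optional[TLabel]:
    """Highest contribution among presence findings.

    A different-lobe ipsilateral nodule contributes T4 only above the
    table's minimum size; at or below it (or with no size recorded) it
    contributes nothing.
    """
    labels = []
    for item in presence:
        if item.kind is PresenceKind.NODULE_IPSILATERAL_OTHER_LOBE:
            if item.qualifier_size_mm is None or item.qualifier_size_mm <= table.nodule_min_size_mm:
                logger.info("different-lobe nodule at/below %g mm: no T4 contribution",
                            table.nodule_min_size_mm)
                continue
        labels.append(table.presence_map[item.kind])
    if not labels:
        return None
    return TLabel(t_max(*labels))


# ---------------------------------------------------------------------------
# Final classification
# ---------------------------------------------------------------------------

def classify_components(size_mm: Optional[float],
                        structures: Iterable[str],
                        presence: Iterable[tuple[str, Optional[float]]],
                        table: TnmDecisionTable,
                        ) -> tuple[str, Optional[str], Optional[str], Optional[str]]:
    """Rule engine over raw components; returns (label, size, involvement,
    presence) component labels as strings.

    ``presence`` is an iterable of (kind value, qualifier size or None).
    This is the hot path used both by :func:`classify_t` and by bulk
    exhaustive checks, so it works on plain strings and cached maps.
    """
    size_c: Optional[str] = None
    if size_mm is not None:
        if size_mm <= 0:
            raise ValueError(f"tumor size must be positive, got {size_mm}")
        for label_, bound in table.size_breakpoints_mm:
            if size_mm <= bound:
                size_c = label_.value
                break
        else:
            size_c = table.size_above_last.value

    tier_of = table.structure_tier
    inv_c: Optional[str] = None
    for s in structures:
        tier = tier_of.get(s)
        if tier is None:
            raise StagingConfigError(f"structure {s!r} not in decision table")
        if inv_c is None or t_rank(tier.value) > t_rank(inv_c):
            inv_c = tier.value

    pres_label = table.presence_label
    pres_c: Optional[str] = None
    for kind, qualifier in presence:
        if kind == "nodule_ipsilateral_other_lobe" and (
                qualifier is None or qualifier <= table.nodule_min_size_mm):
            continue
        lab = pres_label[kind]
        if pres_c is None or t_rank(lab) > t_rank(pres_c):
            pres_c = lab

    label = t_max(size_c, inv_c, pres_c)
    if label is None:
        return ("Tx", None, None, None)
    # bare-tier refinement: a winning bare T2 with a known size resolves to
    # the sized substage (a size above 50 mm cannot reach here because the
    # size component itself would then exceed T2).
    if label == "T2" and size_mm is not None:
        label = "T2a" if size_mm <= 40 else "T2b"
    return (label, size_c, inv_c, pres_c)


def classify_t(findings: list[TumorFinding],
               table: Optional[TnmDecisionTable] = None) -> TStageResult:
    """Classify the consolidated findings of one document."""
    if table is None:
        table = default_decision_table()
    primary = next((f for f in findings if f.role is FindingRole.PRIMARY), None)
    if primary is None:
        return TStageResult(label=TLabel.TX,
                            rationale=["no tumor evidence extracted"])
    label, size_c, inv_c, pres_c = classify_components(
        primary.size_mm,
        [item.structure for item in primary.involvement],
        [(item.kind.value, item.qualifier_size_mm) for item in primary.presence],
        table,
    )
    rationale = []
    if size_c is not None:
        rationale.append(f"size {primary.size_mm:g} mm -> {size_c}")
    for item in primary.involvement:
        rationale.append(
            f"involvement of {item.structure} -> {table.structure_tier[item.structure].value}")
    for item in primary.presence:
        if item.kind is PresenceKind.NODULE_IPSILATERAL_OTHER_LOBE:
            if item.qualifier_size_mm is not None and item.qualifier_size_mm > table.nodule_min_size_mm:
                rationale.append(
                    f"ipsilateral different-lobe nodule {item.qualifier_size_mm:g} mm -> T4")
            else:
                rationale.append(
                    "ipsilateral different-lobe nodule at/below threshold: ignored")
        else:
            rationale.append(
                f"presence of {item.kind.value} -> {table.presence_map[item.kind].value}")
    if not rationale:
        rationale.append("no staging evidence extracted")
    return TStageResult(
        label=TLabel(label),
        size_component=None if size_c is None else TLabel(size_c),
        involvement_component=None if inv_c is None else TLabel(inv_c),
        presence_component=None if pres_c is None else TLabel(pres_c),
        rationale=rationale,
    )
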