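"""Seeded generator of English chest CT / PET-CT staging reports with gold
T-substage labels.

Real staging corpora are clinical data and cannot be redistributed, so
every stage of the pipeline is exercised against generated reports instead.
The generator emulates three report layouts seen in practice — a strictly
radiological CT report, a PET-CT report with the nuclear information
blended into the findings, and a more structured whole-body PET-CT with
per-region subheadings — and plants a primary tumor (size, lobe), optional
involvement/presence criteria, and configurable distractor constructs that
target known failure modes of rule-based staging: benign cysts with sizes,
gravity-dependent atelectasis, negated or merely suspected involvement,
sized nodal-station lymph nodes, and unitless sizes.

Reports are built from a template grammar whose lexical choices are drawn
from the same synonym inventory the matcher uses, which guarantees that a
gold label is computable for every report; robustness to out-of-grammar
phrasing is therefore *not* measured here.
"""

from __future__ import annotations

import random
from typing import Optional

from pydantic import BaseModel, Field, model_validator

from .annotation_model import (
    FindingRole,
    FormatTag,
    Laterality,
    Lobe,
    LOBE_LATERALITY,
    PresenceItem,
    PresenceKind,
    RawReport,
    TLabel,
    TumorFinding,
    TumorSite,
)
from .tstage_classifier import TnmDecisionTable, classify_t, default_decision_table


class PlanError(ValueError):
    """A gold plan is internally inconsistent with its intended label."""


DISTRACTOR_KINDS = (
    "benign_cyst",
    "gravity_atelectasis",
    "negated_involvement",
    "uncertain_involvement",
    "lymph_node_station",
    "unitless_size",
)

#: Default distractor frequencies for the adversarial corpus: high enough
#: that each construct appears in a large share of reports.
DEFAULT_DISTRACTOR_RATES: dict[str, float] = {
    "benign_cyst": 0.5,
    "gravity_atelectasis": 0.5,
    "negated_involvement": 0.4,
    "uncertain_involvement": 0.4,
    "lymph_node_station": 0.5,
    "unitless_size": 0.3,
}

CLEAN_DISTRACTOR_RATES: dict[str, float] = {k: 0.0 for k in DISTRACTOR_KINDS}

#: Substage weights follow the pooled cohort composition of a real staging
#: population: T1b/T1c/T2a/T2b/T3/T4 common, T1a and unsized T2 rare.
DEFAULT_SUBSTAGE_WEIGHTS: dict[str, float] = {
    "T1a": 10, "T1b": 58, "T1c": 84, "T2": 9,
    "T2a": 76, "T2b": 50, "T3": 74, "T4": 64,
}

DEFAULT_FORMAT_MIX: dict[str, float] = {"CT": 0.53, "PET": 0.39, "PET-CT": 0.08}

DEFAULT_DIALECT_RATES: dict[str, float] = {
    "decimal_comma": 0.2,
    "triple_dimension": 0.3,
    "axis_labels": 0.1,
}


class SynthSpec(BaseModel):
    """Specification of a synthetic corpus."""

    n: int = Field(ge=0)
    seed: int = 0
    format_mix: dict[str, float] = Field(default_factory=lambda: dict(DEFAULT_FORMAT_MIX))
    substage_distribution: dict[str, float] = Field(
        default_factory=lambda: dict(DEFAULT_SUBSTAGE_WEIGHTS))
    distractor_rates: dict[str, float] = Field(
        default_factory=lambda: dict(DEFAULT_DISTRACTOR_RATES))
    dialect_rates: dict[str, float] = Field(
        default_factory=lambda: dict(DEFAULT_DIALECT_RATES))

    @model_validator(mode="after")
    def _valid(self) -> "SynthSpec":
        for name, p in {**self.distractor_rates, **self.dialect_rates,
                        **self.format_mix}.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability for {name!r} outside [0, 1]: {p}")
        weights = list(self.substage_distribution.values())
        if any(w < 0 for w in weights) or not any(w > 0 for w in weights):
            raise ValueError("substage weights must be nonnegative and not all zero")
        return self


class Distractor(BaseModel):
    kind: str
    sentence_index: int
    text: str


class GoldRecord(BaseModel):
    report_id: str
    label: TLabel
    planted: list[TumorFinding]
    distractors: list[Distractor] = Field(default_factory=list)


# ---------------------------------------------------------------------------
# Gold plans
# ---------------------------------------------------------------------------

_LOBES = [Lobe.RUL, Lobe.RML, Lobe.RLL, Lobe.LUL, Lobe.LLL]

_T2_STRUCTURES = ["main_bronchus", "visceral_pleura"]
_T3_STRUCTURES = ["chest_wall", "parietal_pericardium", "phrenic_nerve"]
_T4_STRUCTURES = ["mediastinum", "diaphragm", "heart", "great_vessels",
                  "trachea", "carina", "esophagus", "vertebral_body"]


class GoldPlan(BaseModel):
    label: TLabel
    lobe: Lobe
    size_mm: Optional[int] = None
    involvement: list[str] = Field(default_factory=list)
    post_obstructive_atelectasis: bool = False
    satellite_same_lobe: bool = False
    other_lobe_nodule_mm: Optional[int] = None
    other_lobe: Optional[Lobe] = None


def sample_plan(label: TLabel | str, rng: random.Random,
                table: Optional[TnmDecisionTable] = None) -> GoldPlan:
    """Draw a finding plan whose classification equals ``label``."""
    label = TLabel(label)
    lobe = rng.choice(_LOBES)
    plan = GoldPlan(label=label, lobe=lobe)
    if label is TLabel.T1A:
        plan.size_mm = rng.randint(5, 10)
    elif label is TLabel.T1B:
        plan.size_mm = rng.randint(11, 20)
    elif label is TLabel.T1C:
        plan.size_mm = rng.randint(21, 30)
    elif label is TLabel.T2:
        # unsized tumor with a T2 criterion
        variant = rng.randrange(3)
        if variant == 0:
            plan.post_obstructive_atelectasis = True
        else:
            plan.involvement = [rng.choice(_T2_STRUCTURES)]
    elif label is TLabel.T2A:
        if rng.random() < 0.6:
            plan.size_mm = rng.randint(31, 40)
        else:
            plan.size_mm = rng.randint(15, 30)
            plan.involvement = [rng.choice(_T2_STRUCTURES)]
    elif label is TLabel.T2B:
        plan.size_mm = rng.randint(41, 50)
        if rng.random() < 0.3:
            plan.involvement = [rng.choice(_T2_STRUCTURES)]
    elif label is TLabel.T3:
        variant = rng.randrange(3)
        if variant == 0:
            plan.size_mm = rng.randint(51, 70)
        elif variant == 1:
            plan.size_mm = rng.randint(15, 50)
            plan.involvement = [rng.choice(_T3_STRUCTURES)]
        else:
            plan.size_mm = rng.randint(15, 70)
            plan.satellite_same_lobe = True
    elif label is TLabel.T4:
        variant = rng.randrange(3)
        if variant == 0:
            plan.size_mm = rng.randint(71, 110)
        elif variant == 1:
            plan.size_mm = rng.randint(15, 70)
            plan.involvement = [rng.choice(_T4_STRUCTURES)]
        else:
            plan.size_mm = rng.randint(15, 70)
            plan.other_lobe_nodule_mm = rng.randint(12, 25)
            same_side = [l for l in _LOBES
                         if LOBE_LATERALITY[l] is LOBE_LATERALITY[lobe] and l is not lobe]
            plan.other_lobe = rng.choice(same_side)
    else:
        raise PlanError(f"cannot plan label {label.value}")
    return plan


def plan_to_findings(plan: GoldPlan,
                     table: Optional[TnmDecisionTable] = None) -> list[TumorFinding]:
    """Materialize a plan into the findings it should produce."""
    if table is None:
        table = default_decision_table()
    presence: list[PresenceItem] = []
    if plan.post_obstructive_atelectasis:
        presence.append(PresenceItem(kind=PresenceKind.POST_OBSTRUCTIVE_ATELECTASIS))
    if plan.satellite_same_lobe:
        presence.append(PresenceItem(kind=PresenceKind.SATELLITE_SAME_LOBE))
    findings: list[TumorFinding] = []
    if plan.other_lobe_nodule_mm is not None:
        presence.append(PresenceItem(
            kind=PresenceKind.NODULE_IPSILATERAL_OTHER_LOBE,
            qualifier_size_mm=float(plan.other_lobe_nodule_mm)))
    findings.append(TumorFinding(
        role=FindingRole.PRIMARY,
        site=TumorSite(laterality=LOBE_LATERALITY[plan.lobe], lobe=plan.lobe),
        size_mm=None if plan.size_mm is None else float(plan.size_mm),
        involvement=sorted(
            (table.involvement_item(s) for s in plan.involvement),
            key=lambda i: i.structure),
        presence=presence,
    ))
    if plan.other_lobe_nodule_mm is not None:
        findings.append(TumorFinding(
            role=FindingRole.NODULE_IPSILATERAL_OTHER_LOBE,
            site=TumorSite(laterality=LOBE_LATERALITY[plan.other_lobe],
                           lobe=plan.other_lobe),
            size_mm=float(plan.other_lobe_nodule_mm),
        ))
    result = classify_t(findings, table)
    if result.label is not plan.label:
        raise PlanError(
            f"plan for {plan.label.value} classifies as {result.label.value}")
    return findings


# ---------------------------------------------------------------------------
# Text rendering
# ---------------------------------------------------------------------------

_LOBE_TEXT = {
    Lobe.RUL: "right upper lobe", Lobe.RML: "right middle lobe",
    Lobe.RLL: "right lower lobe", Lobe.LUL: "left upper lobe",
    Lobe.LLL: "left lower lobe",
}

_STRUCTURE_TEXT = {
    "main_bronchus": ["main bronchus", "mainstem bronchus"],
    "visceral_pleura": ["visceral pleura"],
    "chest_wall": ["chest wall", "thoracic wall"],
    "parietal_pericardium": ["pericardium", "parietal pericardium"],
    "phrenic_nerve": ["phrenic nerve"],
    "mediastinum": ["mediastinum"],
    "diaphragm": ["diaphragm"],
    "heart": ["heart"],
    "great_vessels": ["aorta", "pulmonary artery"],
    "trachea": ["trachea"],
    "carina": ["carina"],
    "esophagus": ["esophagus"],
    "recurrent_laryngeal_nerve": ["recurrent laryngeal nerve"],
    "vertebral_body": ["vertebral body"],
}

_TUMOR_SYNONYMS = ["mass", "tumor", "lesion", "nodule", "opacity"]
_TUMOR_ADJECTIVES = ["spiculated", "irregular", "lobulated", "ill-defined", "solid"]
_GRAVITY_ADJ = ["bibasilar", "bilateral", "subsegmental", "dependent", "basal"]
_CYST_ORGANS = ["right kidney", "left kidney", "liver", "spleen"]
_NODAL_STATIONS = ["subcarinal", "paratracheal", "hilar", "supraclavicular"]


def _fmt_cm(value_mm: int, comma: bool) -> str:
    s = f"{value_mm / 10:.1f}"
    return s.replace(".", ",") if comma else s


def render_size(size_mm: int, rng: random.Random, dialects: dict[str, float]) -> str:
    """Render a size expression whose maximum dimension is ``size_mm``."""
    roll = rng.random()
    axis = roll < dialects.get("axis_labels", 0.0)
    triple = axis or roll < dialects.get("axis_labels", 0.0) + dialects.get(
        "triple_dimension", 0.0)
    use_cm = size_mm >= 10 and rng.random() < 0.7
    comma = use_cm and rng.random() < dialects.get("decimal_comma", 0.0)
    if not triple:
        return f"{_fmt_cm(size_mm, comma)} cm" if use_cm else f"{size_mm} mm"
    dims = [size_mm]
    d = size_mm
    for _ in range(2):
        d = max(2, d - rng.randint(1, max(2, size_mm // 4)))
        dims.append(d)
    rng.shuffle(dims)
    sep = rng.choice([" x ", " × "])
    if use_cm:
        parts = [_fmt_cm(v, comma) for v in dims]
    else:
        parts = [str(v) for v in dims]
    if axis:
        labels = ["AP", "TVR", "SI"]
        parts = [f"{p} ({l})" for p, l in zip(parts, labels)]
    unit = "cm" if use_cm else "mm"
    return sep.join(parts) + f" {unit}"


def _tumor_sentences(plan: GoldPlan, rng: random.Random,
                     dialects: dict[str, float], pet: bool) -> list[str]:
    adj = rng.choice(_TUMOR_ADJECTIVES)
    syn = rng.choice(_TUMOR_SYNONYMS)
    lobe = _LOBE_TEXT[plan.lobe]
    out = []
    if plan.size_mm is not None:
        size = render_size(plan.size_mm, rng, dialects)
        template = rng.choice([
            f"There is a {adj} {syn} in the {lobe} measuring {size}.",
            f"A {adj} {syn} measuring {size} is seen in the {lobe}.",
            f"Within the {lobe} there is a {adj} {syn} measuring {size}.",
        ])
    else:
        template = f"There is a {adj} {syn} in the {lobe}."
    out.append(template)
    if pet:
        suv = f"{rng.uniform(4.0, 18.0):.1f}"
        out.append(f"The {syn} demonstrates intense FDG uptake with SUVmax of {suv}.")
    for structure in plan.involvement:
        stext = rng.choice(_STRUCTURE_TEXT[structure])
        out.append(rng.choice([
            f"The {syn} invades the {stext}.",
            f"There is invasion of the {stext}.",
            f"The {syn} involves the {stext}.",
        ]))
    if plan.post_obstructive_atelectasis:
        out.append(rng.choice([
            "There is associated post-obstructive atelectasis.",
            f"Post-obstructive atelectasis is seen distal to the {syn}.",
        ]))
    if plan.satellite_same_lobe:
        out.append(rng.choice([
            "A satellite nodule is seen in the same lobe.",
            f"There are satellite nodules adjacent to the {syn}.",
        ]))
    if plan.other_lobe_nodule_mm is not None:
        size2 = render_size(plan.other_lobe_nodule_mm, rng, dialects)
        other = _LOBE_TEXT[plan.other_lobe]
        syn2 = rng.choice(["nodule", "lesion"])
        out.append(rng.choice([
            f"A separate {syn2} measuring {size2} is seen in the {other}.",
            f"An additional {syn2} in the {other} measures {size2}.",
        ]))
    return out


def _distractor_sentence(kind: str, plan: GoldPlan, rng: random.Random,
                         dialects: dict[str, float]) -> str:
    if kind == "benign_cyst":
        organ = rng.choice(_CYST_ORGANS)
        comma = rng.random() < dialects.get("decimal_comma", 0.0)
        size = _fmt_cm(rng.randint(12, 38), comma)
        return f"There is a simple cyst in the {organ} measuring {size} cm."
    if kind == "gravity_atelectasis":
        adj = rng.choice(_GRAVITY_ADJ)
        return f"There is {adj} atelectasis at the lung bases."
    if kind == "negated_involvement":
        pool = [s for s in _T3_STRUCTURES + _T4_STRUCTURES if s not in plan.involvement]
        stext = rng.choice(_STRUCTURE_TEXT[rng.choice(pool)])
        return rng.choice([
            f"No invasion of the {stext} is identified.",
            f"There is no evidence of invasion of the {stext}.",
        ])
    if kind == "uncertain_involvement":
        pool = [s for s in _T4_STRUCTURES if s not in plan.involvement]
        stext = rng.choice(_STRUCTURE_TEXT[rng.choice(pool)])
        syn = rng.choice(["mass", "tumor"])
        return rng.choice([
            f"The {syn} is abutting the {stext}.",
            f"The {syn} is in close relation to the {stext}.",
            f"Possible invasion of the {stext}.",
        ])
    if kind == "lymph_node_station":
        station = rng.choice(_NODAL_STATIONS)
        comma = rng.random() < dialects.get("decimal_comma", 0.0)
        size = _fmt_cm(rng.randint(11, 24), comma)
        return f"Enlarged {station} lymph nodes are noted, measuring {size} cm."
    if kind == "unitless_size":
        syn = rng.choice(["opacity", "lesion"])
        return f"A further small {syn} measures {rng.randint(11, 30)}."
    raise ValueError(f"unknown distractor kind {kind!r}")


_CHEST_FILLER = [
    "The airways are patent.",
    "No pleural effusion.",
    "The lungs are otherwise clear.",
]
_MEDIASTINUM_FILLER = [
    "No pathologically enlarged lymph nodes.",
    "Normal cardiomediastinal contours without focal abnormality.",
]
_ABDOMEN_FILLER = [
    "The liver and adrenal glands are unremarkable.",
    "No focal abnormality in the upper abdomen.",
]


def generate_report(spec: SynthSpec, plan: GoldPlan, rng: random.Random,
                    report_id: str = "R0001",
                    table: Optional[TnmDecisionTable] = None,
                    ) -> tuple[RawReport, GoldRecord]:
    """Render one report for a gold plan and return it with its gold record."""
    if table is None:
        table = default_decision_table()
    planted = plan_to_findings(plan, table)  # raises PlanError when infeasible

    fmt_names = list(spec.format_mix.keys())
    fmt_weights = list(spec.format_mix.values())
    fmt = FormatTag(rng.choices(fmt_names, weights=fmt_weights, k=1)[0]) \
        if sum(fmt_weights) > 0 else FormatTag.CT
    pet = fmt is not FormatTag.CT

    draws = {kind: rng.random() < spec.distractor_rates.get(kind, 0.0)
             for kind in DISTRACTOR_KINDS}

    chest = _tumor_sentences(plan, rng, spec.dialect_rates, pet)
    chest.append(rng.choice(_CHEST_FILLER))
    mediastinum = [rng.choice(_MEDIASTINUM_FILLER)]
    abdomen = [rng.choice(_ABDOMEN_FILLER)]

    distractor_texts: dict[str, str] = {}
    for kind in DISTRACTOR_KINDS:
        if not draws[kind]:
            continue
        sentence = _distractor_sentence(kind, plan, rng, spec.dialect_rates)
        distractor_texts[kind] = sentence
        if kind == "benign_cyst":
            abdomen.insert(0, sentence)
        elif kind == "lymph_node_station":
            mediastinum.insert(0, sentence)
        else:
            chest.append(sentence)

    technique = ("Contrast-enhanced CT of the chest was performed."
                 if fmt is FormatTag.CT else
                 "Whole-body FDG PET-CT from skull base to mid-thigh.")
    if fmt is FormatTag.PET_CT:
        sections = [
            ("History", ["Staging evaluation of known lung carcinoma."]),
            ("Technique", [technique]),
            ("Head", ["No acute intracranial abnormality."]),
            ("Neck", ["No cervical lymphadenopathy."]),
            ("Chest", chest),
            ("Mediastinum", mediastinum),
            ("Abdomen", abdomen),
            ("Pelvis", ["No suspicious pelvic abnormality."]),
            ("Bones", ["No aggressive osseous changes."]),
        ]
    elif fmt is FormatTag.PET:
        sections = [
            ("History", ["Staging evaluation of known lung carcinoma."]),
            ("Technique", [technique]),
            ("Findings", chest + mediastinum + abdomen),
        ]
    else:
        sections = [
            ("History", ["Staging evaluation of known lung carcinoma."]),
            ("Comparison", ["No prior imaging available for comparison."]),
            ("Technique", [technique]),
            ("Findings", chest + mediastinum),
            ("Abdomen", abdomen),
        ]

    lines: list[str] = []
    sentence_index = 0
    distractors: list[Distractor] = []
    emitted: dict[str, int] = {}
    for heading, sentences in sections:
        lines.append(f"{heading}:")
        for s in sentences:
            lines.append(s)
            for kind, text in distractor_texts.items():
                if text == s and kind not in emitted:
                    emitted[kind] = sentence_index
            sentence_index += 1
        lines.append("")
    for kind, idx in sorted(emitted.items(), key=lambda kv: kv[1]):
        distractors.append(Distractor(
            kind=kind, sentence_index=idx, text=distractor_texts[kind]))

    text = "\n".join(lines).rstrip() + "\n"
    report = RawReport(report_id=report_id, text=text, format_tag=fmt)
    gold = GoldRecord(report_id=report_id, label=plan.label,
                      planted=planted, distractors=distractors)
    return report, gold


def generate_corpus(spec: SynthSpec,
                    table: Optional[TnmDecisionTable] = None,
                    ) -> tuple[list[RawReport], list[GoldRecord]]:
    """Generate ``spec.n`` reports; deterministic under ``spec.seed``."""
    if table is None:
        table = default_decision_table()
    rng = random.Random(spec.seed)
    labels = list(spec.substage_distribution.keys())
    weights = list(spec.substage_distribution.values())
    reports: list[RawReport] = []
    golds: list[GoldRecord] = []
    for k in range(spec.n):
        label = rng.choices(labels, weights=weights, k=1)[0]
        plan = sample_plan(label, rng, table)
        report_id = f"R{k + 1:04d}"
        report, gold = generate_report(spec, plan, rng, report_id=report_id, table=table)
        reports.append(report)
        golds.append(gold)
    return reports, golds
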