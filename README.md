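# pulmostage

Rule-based extraction of the primary-tumor **T descriptor** (AJCC/UICC TNM,
8th edition) from free-text English chest CT and PET-CT staging reports.

Radiology reports describe lung tumors in prose — "a spiculated mass in the
right upper lobe measuring 3.1 x 2.4 cm, abutting the mediastinum" — while
tumor boards, registries and restaging studies need the structured stage.
`pulmostage` reads the free text and derives the T-substage from three
extracted items:

* **size** — the maximum tumor dimension, which must carry a unit
  (`mm`/`cm`; decimal commas, 2–3-dimension tuples and axis-labelled tuples
  like `2.1 (AP) × 3.0 (TVR) × 1.8 (SI) cm` are all recognized);
* **involvement** — invasion of named structures, each mapped to a minimum
  tier (T2: main bronchus, visceral pleura; T3: chest wall, parietal
  pericardium, phrenic nerve; T4: mediastinum, diaphragm, heart, great
  vessels, trachea, carina, esophagus, recurrent laryngeal nerve,
  vertebral body);
* **presence** — non-size criteria: post-obstructive atelectasis (T2),
  satellite nodule in the same lobe (T3), a >10 mm nodule in a different
  ipsilateral lobe (T4).

The final label is the maximum of the three component labels under the
total order `Tx < T1a < T1b < T1c < T2 < T2a < T2b < T3 < T4`; size classes
use the standard breakpoints (≤10, ≤20, ≤30, ≤40, ≤50, ≤70 mm, else T4),
inclusive on their upper bound.

The pipeline runs five chained stages — preprocessing (sectionizing,
sentence segmentation, tokenization), concept matching against a
SNOMED-CT-coded lexicon, ConText/NegEx-style negation/uncertainty scoping,
measurement extraction and linking, and the T-stage classifier — and every
stage exchanges a token-level standoff JSON document whose character spans
point into the original report text, so a front end can highlight exactly
the evidence behind each decision.

Because real staging corpora are restricted clinical data, the package
includes a seeded synthetic-report generator (three report layouts, gold
labels, and distractor constructs such as sized benign kidney cysts,
gravity-dependent atelectasis, negated or merely "abutting" involvement,
sized nodal-station lymph nodes, and unitless sizes) plus an evaluation
module with substage/stage/size-only accuracy, per-class precision/recall/
F1 and confusion matrices.

## Worked example

```bash
printf 'Findings:\nThere is a mass in the left upper lobe measuring 4,2 cm invading the chest wall.\n' > report.txt
pulmostage stage report.txt | python -m json.tool | grep -A7 '"result"'
```

```
"result": {
    "label": "T3",
    "size_component": "T2b",
    "involvement_component": "T3",
    "presence_component": null,
    "rationale": [
        "size 42 mm -> T2b",
        "involvement of chest_wall -> T3"
    ],
```

The decimal-comma size `4,2 cm` normalizes to 42 mm (component T2b, i.e.
>40 but ≤50 mm); chest-wall invasion is a T3 criterion; the final label is
the maximum of the components, **T3**. The full JSON document also carries
the tokens, sentences, sections, concept/modifier mentions and measurement
spans that support the verdict.

Batch processing, corpus generation and scoring:

```bash
pulmostage synth --n 200 --seed 7 --out corpus/
pulmostage batch corpus/reports.csv --out docs.jsonl --predictions preds.csv
pulmostage eval preds.csv corpus/gold.csv --out eval.json
```

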