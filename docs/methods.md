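# Methods

## The staging model

`pulmostage` implements rule-based T-staging of pulmonary tumors from
free-text radiology reports. The T descriptor of TNM (8th edition) is a
function of three observable items, and the pipeline extracts exactly
those: the maximum tumor dimension, invasion ("involvement") of named
thoracic structures, and presence findings that raise the stage without
being either a size or an invasion. Each item maps to a component label
and the result is their maximum under the total order

```
Tx < T1a < T1b < T1c < T2 < T2a < T2b < T3 < T4
```

Size classes are inclusive on the upper bound (e.g. exactly 30 mm is T1c,
exactly 40 mm is T2a), following the ">x but ≤y cm" wording of the
descriptor tables. Two conventions deserve note:

* **Bare T2** is a real output class, emitted when a T2 criterion fires
  (main-bronchus or visceral-pleura involvement, post-obstructive
  atelectasis) and no size is available to choose between T2a and T2b.
  When a size *is* known and a bare T2 criterion wins, the label resolves
  to T2a (size ≤40 mm) or T2b (≤50 mm); a size above 50 mm cannot reach
  this branch because its own size component already exceeds T2.
* **Tx** is emitted when no staging evidence of any kind is extracted.
  This is our convention for the no-finding case, chosen so that the
  pipeline always produces a label; it is not part of the descriptor
  table itself.

Two thresholds are not fixed by the TNM booklet and are explicit,
versioned decision-table values (`resources/tnm_ajcc8.yaml`): a nodule in
a different ipsilateral lobe must exceed **10 mm** (>1 cm) to raise T4,
and a same-lobe satellite nodule has **no minimum size**. Contralateral
nodules are ignored for T (they belong to the M domain) and logged.

## Pipeline design

The pipeline is five chained stages; each consumes and produces the same
token-level standoff JSON document, and each stage recomputes its layer
deterministically, so stages are idempotent and chaining them one at a
time is bit-identical to the fused run.

**Preprocessing.** Cleaning normalizes line endings, non-breaking spaces
and whitespace runs but never deletes content characters; it returns an
offset map so that *all* downstream spans are expressed in original-text
coordinates (a reviewing GUI highlights the untouched report). Sections
are detected from subheadings at line starts (`Findings:`, `Chest`,
`Mediastinum`, `Abdomen`, ...); a report without headings is a single
in-scope section. Tumor/size candidates are restricted to the sections
{findings, chest, mediastinum, other}; head, neck, abdomen, pelvis, bones
and musculoskeletal sections are out of scope because whole-body PET-CT
reports describe sized masses in organs that cannot hold the primary lung
tumor. Sentences never cross section boundaries and splitting is
measurement-safe (the period in `3.1 cm` never splits). Tokenization
keeps decimal-comma/point numbers as single tokens and treats dimension
separators (`x`, `×`) as their own tokens.

**Concept matching.** Concepts are case-insensitive, word-boundary-safe
regexes, one lexicon row per concept with synonyms as alternation, each
carrying a SNOMED-CT code (codes are carried as labels; no ontology
traversal). Longest match wins within a category; a tumor lexeme strictly
contained in a longer hit of another category ("nodule" inside "satellite
nodule") is dropped. Two disambiguation rules address the classic
node-versus-mass problem: a tumor lexeme in a sentence with an explicit
nodal lexeme (lymph, lymphnodal, nodal, node(s)) is re-categorized as a
lymph node, while a nodal-station word alone ("hilar mass") does *not*
re-categorize — that residual ambiguity is a documented property of the
rule-based approach, not something we attempt to solve. A sentence-level
blacklist (kidney, liver, adrenal, thyroid, spleen, pancreas, breast,
cyst) suppresses every tumor mention and measurement in a sentence naming
an extrathoracic organ; involvement targets survive. The blacklist is
deliberately blunt: a "cystic" lung tumor is suppressed by the cyst rule,
a known and accepted failure mode of this design. Atelectasis counts as
the post-obstructive presence criterion only when the sentence carries no
gravity-type adjective (basal, bibasilar, bilateral, subsegmental,
dependent, plate-like, discoid, linear).

**Context validation.** Negation, uncertainty and historical status are
assigned by directional trigger terms in the NegEx/ConText style: forward
triggers flag concepts from the trigger to the sentence end, backward
triggers to the sentence start, and any scope is truncated at the nearest
termination term (but, however, although, whereas, ";") or at the next
flag-bearing trigger. Pseudo triggers ("no change") outrank and thereby
suppress contained true triggers. There is no dependency parsing; scope
is purely positional. The uncertainty inventory includes hedged-invasion
phrasing ("abutting", "extending towards", "in close relation to",
"possible", "cannot exclude"), because reports frequently describe
possible invasion without asserting it. A concept flagged negated or
uncertain never contributes to staging; the certain-only policy matches
how staging gold standards are annotated. The switch
`Pipeline(count_uncertain=True)` lets uncertain involvement count, for
sites that prefer sensitivity over specificity.

**Measurement extraction and linking.** A size requires a unit; unitless
numbers are never measurements. Decimal commas normalize to points before
parsing; cm converts to mm by an exact ×10; the maximum dimension of a
tuple is invariant under permutation; ranges (`1-2 cm`) are skipped as
ambiguous. Each measurement links to the nearest non-flagged tumor,
lymph-node or involvement mention in its sentence — preceding mentions
preferred — and takes its lobe/laterality from the nearest
anatomic-location mention. Sizes linked to lymph nodes or involvement
targets (e.g. "pleural thickening of 8,6 cm") never become tumor sizes.
At document level, the largest linked tumor size becomes the primary; a
second sized tumor in a different ipsilateral lobe becomes a separate
finding and a T4-relevant presence item; a same-lobe duplicate with a
different size resolves to the larger size with a warning (reports do
state two sizes for one tumor); involvement and presence attach to the
primary. A document with involvement/presence but no sized tumor still
yields a sizeless primary, which is how bare T2 arises.

## The synthetic corpus

The staging corpora this tool targets are restricted clinical data,
so the generator produces the study material: English staging reports in
three layouts (strict CT; PET-CT with nuclear findings blended into one
findings section; structured whole-body PET-CT with per-region
subheadings), with a planted primary tumor and a gold label that is
*computed* from the planted findings at generation time (a plan whose
classification differs from its intended label is rejected), so gold
labels are self-consistent by construction.

Defaults, chosen once as the study conditions:

* substage weights follow a pooled real staging cohort (T1a 10, T1b 58,
  T1c 84, T2 9, T2a 76, T2b 50, T3 74, T4 64) — T1a and unsized T2 rare,
  the middle classes common;
* format mix CT 0.53 / blended PET 0.39 / structured PET-CT 0.08;
* notation dialects: decimal comma 0.2, 2–3-dimension tuples 0.3,
  axis-labelled tuples 0.1;
* distractor rates (adversarial corpus): benign sized cyst 0.5,
  gravity-dependent atelectasis 0.5, negated involvement 0.4, uncertain
  involvement 0.4, sized nodal-station lymph nodes 0.5, unitless size
  0.3. The clean corpus sets all six to zero.

Each distractor targets one defense: the cyst exercises the organ
blacklist and section scoping, gravity atelectasis the adjective
exclusion, negated/uncertain involvement the context scoping, nodal
stations the node-versus-mass rule, and unitless sizes the unit
requirement. Distractor sentences are recorded in the gold record (kind,
sentence index, text) so that error triage and the flagged-upgrade
measurement can re-process a report with specific sentences removed.

The generator is a template grammar drawing its lexical choices from the
same synonym inventory the matcher uses. That guarantees gold-label
computability but also bounds what passing tests demonstrate: recovery on
this corpus shows the pipeline's rules compose correctly and its defenses
hold against the planted constructs; it says nothing about recall on
out-of-grammar phrasing, speech-recognition artifacts, institution-
specific headings outside the policy file, or genuinely ambiguous prose,
which in real corpora are the dominant error source.

## Evaluation

Three accuracy views: substage (exact label, bare T2 its own class),
stage (labels collapsed T1a/b/c→T1, T2/T2a/T2b→T2), and size-only (the
label the size component alone would give, Tx when sizeless; compared at
substage level against the gold substage). Per-class precision/recall/F1
come from one-vs-rest counts on the confusion matrix; a metric with a
zero denominator is reported as null, not zero. Collapsing can only merge
errors away, so substage accuracy never exceeds stage accuracy; micro
recall equals substage accuracy (single-label classification).

## Numerical and scale choices

Corpus-level checks use n = 200 reports per condition and the exhaustive
classifier grid covers all sizes 1–100 mm plus absent × 1024 involvement
subsets (ten structures spanning all tiers) × 12 presence combinations
(~1.2 M cases); both complete in seconds. Size comparisons use exact
decimal arithmetic on mm values (cm ×10); tie-breaks are deterministic
(first-seen wins at equal size; alternatives in a lexicon row are tried
left to right, so longer synonyms are listed first). Degenerate inputs:
empty or whitespace-only reports are rejected with a dedicated error (CLI
exit code 2); a report with no recognized heading is one in-scope
section; a sentence with a measurement but no linkable mention logs an
unlinked measurement and contributes nothing.

## Known limitations

* Positional context scoping, no dependency parsing: a modifier can
  attach to the wrong concept in convoluted sentences.
* The cyst blacklist suppresses cystic *lung* tumors (documented above).
* "Hilar mass" versus hilar node remains ambiguous without an explicit
  nodal lexeme.
* The same-tumor-versus-satellite decision for two sized masses in one
  lobe relies on an explicit satellite phrase; without one, two sizes in
  the same lobe are merged to the larger.
* The generator's grammar cannot measure robustness to free phrasing;
  accuracies on it are upper bounds for real-report performance.
* N and M staging are out of scope; the interchange format reserves no
  more than optional slots for them.
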