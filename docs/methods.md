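# Methods

## Problem and model

The package determines, from the free text of a nuclear cardiac stress test
report, whether the report documents myocardial ischemia. The observable
contract is binary: ischemia in *any* myocardial territory makes the
document positive, however many territories are read as normal, fixed
(scar), or artifactual. The system is rules-based by design — the rule
files are JSON a clinician can audit, and every classification carries an
evidence excerpt naming the decisive targets and modifiers.

The document decision decomposes into mention-level decisions:

* **Targets.** Three concept categories. `ISCHEMIA_TERM` ("ischemia",
  "reversible ischemia") and `REVERSIBILITY_TERM` ("reversibility",
  "reversible defect") are intrinsically positive evidence.
  `PERFUSION_FINDING` ("perfusion defect", "reduced counts", bare
  "defect") is a neutral observation: a bare finding is not ischemia and
  only becomes positive when a reversibility cue attaches to it.
* **Modifiers.** `NEGATED_EXISTENCE`, `FIXED` and `ARTIFACT` refute;
  `REVERSIBLE` promotes a perfusion finding; `UNCERTAIN` hedges without
  refuting ("Likely ischemia" is positive); `TERMINATE` ("and", "but")
  cuts modifier scopes at clause boundaries, which is what lets "small,
  primarily fixed defect **and** a mild, reversible defect" come out
  positive.
* **Polarity.** A mention is positive iff it is intrinsically positive or
  carries the reversible flag, and no refuting flag is set. Attributes
  accumulate independently; precedence (refutation dominates positivity)
  is applied only here. When both a reversible and a refuting cue govern
  one mention ("no reversible perfusion abnormality") the mention is
  refuted, and the conflict is logged.
* **Aggregation.** Strict any-positive disjunction over mentions. A
  document with no target mentions at all ("Negative myocardial perfusion
  study") is a negative screen. We deliberately use the disjunction rather
  than numeric token weights: the binary contract is the only observable
  behavior, and the disjunction reproduces every phrase in the reference
  suite, including the mixed fixed-plus-reversible sentence.

## Scope semantics

Scopes are directional and strictly intra-sentence (no cross-sentence
anaphora, matching standard ConText behavior). A FORWARD scope runs from
the cue to the earliest of: sentence end, the nearest following TERMINATE
cue, or `max_scope_tokens` tokens (default 10 — bounds runaway scopes in
run-on impressions; a rule can override or remove the cap). BACKWARD is
symmetric toward the sentence start. BIDIRECTIONAL is represented as the
contiguous token window spanning both reaches, cue included; since targets
and modifiers rarely share tokens this is equivalent to the two-sided
union in practice and keeps scopes representable as single spans. A
FORWARD cue in sentence-final position has an empty (None) scope.

Governance is span intersection between target and scope, with one
addition: a REVERSIBLE cue binds to a perfusion finding it is immediately
adjacent to (≤ 1 character gap) or overlaps, so "partially reversible
defect" keeps its head noun even under aggressive termination settings.

Cue directions were chosen from how the phrases read clinically: negation,
fixed and hedge cues precede their findings (FORWARD); artifact
attributions ("favored to be artifactual", "consistent with attenuation
artifact", "resolves on prone imaging") trail them (BACKWARD), as does
"which is reversible".

## Text processing

Impressions are short, telegraphic and list-structured, so segmentation is
deterministic rather than statistical: boundaries at newline runs and at
`.?!` followed by whitespace and an uppercase letter or digit; enumerated
list markers ("1.", "2.") never end a sentence; a period followed by a
lowercase continuation does not split. Tokenization splits on whitespace
and detaches `,.;:()/` as separate tokens; matching operates on
lower-cased token sequences (with `*` single-token wildcards), never raw
characters, so "ischemia" cannot fire inside a longer word. When candidate
matches overlap, the longest wins, then leftmost, then the earlier-listed
rule — this prevents "ischemia" from shadowing "reversible ischemia",
which matters because modifiers attach to whole mentions.

Section headers match at line start, case-insensitively, tolerant of a
trailing colon/dash or a bare header line; bare prose that merely begins
with a header word ("History of prior MI…") does not count. The default
text policy is impression-first with fallback to the IMPRESSION section of
the full report (flagged in provenance); `IMPRESSION_ONLY` reproduces the
impressions-only operating mode exactly.

## Evaluation metrics

Confusion cells follow the clinical convention a/b/c/d = TP/FP/FN/TN.
F1 is computed from *unrounded* precision and recall and only then
rounded — the numerically principled order, and the one that reproduces
all five published model columns from their printed integer cells.
Rounding is half-up to one decimal (`Decimal`, not banker's rounding);
integral values print without decimals ("100%"). A zero denominator yields
an explicit NA marker, never a silent zero. scikit-learn serves as an
independent cross-check in the tests only.

## Synthetic corpus generator

The generator defines the study conditions for all pipeline tests. It
emulates: per-site boilerplate and layout dialects (numbered lists,
running prose, one-finding-per-line) across `site_count` synthetic sites;
multi-territory impressions (positive documents carry one or two positive
sentences plus 0–3 negative/neutral distractors); slot-filled findings
over seven territories and four sizes; and optional full reports wrapping
the impression in INDICATION/TECHNIQUE/FINDINGS/IMPRESSION sections.
Positive counts are exact — round-half-up of n × prevalence — and corpora
are pure functions of their spec (seeded `random.Random`, per-document
child seeds).

The benchmark split mirrors the annotated study sample: 440 training
documents at 17% prevalence and a 214-document enriched set at 43% split
into 115 validation + 99 test (654 total; 440/654 rounds to a 67% training
share). Prevalences are inputs, not simulations of the enrichment string
search that produced them.

`noise_fraction` swaps decisive sentences for paraphrases deliberately
outside default-rulebook coverage, in both directions (missed positives
such as "inducible hypoperfusion", spurious positives such as "ischemia
cannot be completely excluded"), to exercise error-analysis tooling; its
default is 0, under which classifier accuracy is exactly 100% by
construction. That 100% therefore validates the engine's mechanics —
scoping, termination, aggregation, determinism — not performance on real
clinical language, whose synonym drift, typos and cross-sentence
references the generator does not model.

## Numerical and design choices

* Character offsets are 0-based half-open throughout; spans always equal
  the source substring they index.
* Multi-token mention/scope spans render inter-token gaps as single
  spaces in their `text`; inputs with tabs inside a mention would differ
  from the raw slice in whitespace only.
* Rulebook JSON round-trips losslessly; unknown fields are warned about
  and ignored so richer rule files stay loadable; category/direction
  closed sets are enforced at load with the offending rule named.
* The default rulebook is authored to be behavior-complete on the
  13-phrase reference suite (5 positive, 8 negative) rather than to match
  any particular rule count; `validate-rules` re-runs that suite as a
  smoke test against any user rulebook.
* Per-document errors (no usable text) are aggregated into the corpus
  summary rather than aborting a batch; the CLI's `--strict` flag turns
  them fatal. Logs carry report ids and counts, never report text.

## Problem sizes

The test suite runs the context-engine oracle equivalence on 10,000
randomized sentences of ≤ 12 tokens (plus 3,000 for the matcher), label
faithfulness on a 1,000-document corpus, and the full benchmark split; the
acceptance script uses the same sizes. The whole suite completes in well
under a minute on one CPU.

## Known limitations

* No territory-level sub-labels, severity grading, or ejection-fraction
  extraction; no fuzzy matching or UMLS normalization.
* Single-sentence scope: "This defect is reversible" referring to a prior
  sentence is missed.
* The default lexicon covers the reference suite and common variants; site
  lexicons beyond it require rule additions (the supported workflow — see
  `examples/custom_rulebook.py`).
* Published headline metrics from the original multisite deployment are
  arithmetic-reproducible here (from their confusion matrices) but not
  re-measurable: the underlying clinical reports are private.
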