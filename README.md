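# ischemia-nlp

Rules-based classification of **myocardial ischemia** from nuclear cardiac
stress test reports, for clinical-informatics teams who need a discrete
ischemia indicator from free-text imaging documentation — for example to
audit the appropriateness of invasive coronary angiography at population
scale — without shipping report text to an opaque model.

Nuclear stress test reports describe the distribution of a radiotracer in
heart muscle at rest and under stress. The textual hallmark of ischemia is a
*reversible* perfusion defect (present at stress, resolving at rest); a
*fixed* defect is scar, and apparent defects can be *attenuation artifacts*.
A single report may be positive in one myocardial territory and negative in
another, and any positive territory makes the document positive.

## How it works

The pipeline is an interpretable target/context rule system:

1. **Text selection** — classify the impression section (`IMPRESSION_ONLY`
   or fallback to the IMPRESSION section of the full report), located by
   line-initial section-header rules.
2. **Sentences and tokens** — deterministic rule-based segmentation and
   whitespace/punctuation tokenization with character offsets.
3. **Target matching** — case-insensitive token-sequence rules find concept
   mentions in three categories: `ISCHEMIA_TERM`, `REVERSIBILITY_TERM`,
   `PERFUSION_FINDING`. Longest match wins.
4. **Context scoping** — ConText-style cues (`NEGATED_EXISTENCE`, `FIXED`,
   `ARTIFACT`, `REVERSIBLE`, `UNCERTAIN`) govern a directional, in-sentence
   scope that is cut by `TERMINATE` conjunctions ("and", "but") and capped
   at 10 tokens; targets inside a scope acquire the cue's attribute flag.
5. **Polarity and aggregation** — a mention is positive iff

   ```
   (category ∈ {ISCHEMIA_TERM, REVERSIBILITY_TERM} ∨ has_reversible_modifier)
   ∧ ¬(is_negated ∨ is_fixed ∨ is_artifact)
   ```

   (hedges never change the outcome), and the document indicator is the
   any-positive disjunction over mentions. Every decision is reported as a
   text excerpt of the targets and modifiers used.

Evaluation uses the clinical 2×2 convention (a=TP, b=FP, c=FN, d=TN) with
sensitivity/recall a/(a+c), specificity d/(b+d), precision/PPV a/(a+b),
NPV d/(c+d), and F1 = 2PR/(P+R) from unrounded P and R, rounded half-up to
one decimal. A synthetic corpus generator produces gold-labeled multi-site
report impressions so the whole pipeline is testable without clinical data.

## Worked example

```python
from ischemia_nlp import ReportDocument, classify_document

doc = ReportDocument(report_id="demo",
                     impression_text="There is a small area of fixed ischemia")
result = classify_document(doc)
print(result.ischemia)   # 0
print(result.evidence)   # ischemia [ISCHEMIA_TERM; modifiers: fixed]
```

The mention "ischemia" is found, but the forward `FIXED` cue governs it —
fixed defects are scar, not ischemia — so the report is negative, and the
evidence excerpt shows exactly why. Running
`python examples/generate_and_evaluate.py` prints, for a noise-free
synthetic corpus of 200 documents:

```
Evaluation: noise_fraction=0.0
  True positives  (a): 86
  False positives (b): 0
  False negatives (c): 0
  True negatives  (d): 114
  ...
  F1                  : 100%
```

and the same corpus at `noise_fraction=0.15` (out-of-coverage paraphrases)
drops to F1 82.8% — the mechanism for exercising error-analysis tooling.
The other scripts in `examples/` demonstrate classification with evidence,
the benchmark split structure, and authoring a site-specific rulebook.

## Command line

```bash
ischemia-nlp generate --benchmark --seed 7 --output-dir bench
ischemia-nlp classify bench/test.jsonl -o preds.jsonl
ischemia-nlp evaluate preds.jsonl bench/test.jsonl
ischemia-nlp validate-rules builtin
```

Corpora are JSONL or CSV with columns `report_id`, `impression_text`,
`full_report_text`, `site_id`, `gold_label`; rulebooks are single JSON
files with `targets`/`contexts`/`sections` lists (see
`src/ischemia_nlp/data/ischemia_rules.json`).

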