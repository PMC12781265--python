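"""Classify a handful of stress test impressions and show the evidence.

Each report is reduced to a binary ischemia indicator (1 = ischemia
documented) plus an excerpt of the target mentions and the context
modifiers that decided the call — the auditable core of the system.
"""

from ischemia_nlp import ReportDocument, classify_document, default_ischemia_rulebook

impressions = [
    "Likely ischemia",
    "There is a small area of fixed ischemia",
    "1. Moderate reversible defect in the inferior wall.\n2. Normal function.",
    "Large perfusion defect without evidence of reversibility",
]

rulebook = default_ischemia_rulebook()
for i, text in enumerate(impressions):
    doc = ReportDocument(report_id=f"demo{i}", impression_text=text)
    result = classify_document(doc, rulebook)
    print(f"[{result.ischemia}] {text.splitlines()[0]}")
    print(f"    evidence: {result.evidence or '(no target mentions)'}")

# ischemia=1 lines carry positive evidence (an unrefuted ischemia or
# reversibility mention); ischemia=0 lines show the refuting modifiers
# (fixed, negation, artifact) that blocked the mention.
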