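"""Author a minimal rulebook in code, save it as JSON, reload it, and
classify with it — the workflow for adapting the system to a new site
lexicon without touching the engine."""

import tempfile
from pathlib import Path

from ischemia_nlp import (
    ContextRule,
    ReportDocument,
    Rulebook,
    TargetRule,
    classify_document,
    load_rulebook,
    save_rulebook,
)
from ischemia_nlp.core import Direction, ModifierCategory, TargetCategory

rulebook = Rulebook(
    name="site-demo",
    version="1",
    targets=(
        TargetRule(rule_id="t-isch", pattern="ischemia",
                   category=TargetCategory.ISCHEMIA_TERM),
        TargetRule(rule_id="t-hypoperf", pattern="inducible hypoperfusion",
                   category=TargetCategory.ISCHEMIA_TERM),
    ),
    contexts=(
        ContextRule(rule_id="c-no-evid", pattern="no evidence of",
                    category=ModifierCategory.NEGATED_EXISTENCE,
                    direction=Direction.FORWARD, max_scope_tokens=10),
    ),
)

with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "site_rules.json"
    save_rulebook(rulebook, path)
    reloaded = load_rulebook(path)
    assert reloaded == rulebook
    print(f"round-tripped {path.name}: {len(reloaded.targets)} target rules, "
          f"{len(reloaded.contexts)} context rules")

for text in ("Inducible hypoperfusion in the lateral wall",
             "No evidence of inducible hypoperfusion"):
    doc = ReportDocument(report_id="x", impression_text=text)
    print(classify_document(doc, reloaded).ischemia, "<-", text)

# The site-specific synonym is caught as positive, and the negation cue's
# forward scope correctly refutes it in the second impression.
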