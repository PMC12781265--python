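{
  "name": "ischemia-default",
  "version": "1",
  "targets": [
    {"rule_id": "t-ischemia", "pattern": "ischemia", "category": "ISCHEMIA_TERM"},
    {"rule_id": "t-reversible-ischemia", "pattern": "reversible ischemia", "category": "ISCHEMIA_TERM"},
    {"rule_id": "t-ischemic-changes", "pattern": "ischemic changes", "category": "ISCHEMIA_TERM"},
    {"rule_id": "t-reversibility", "pattern": "reversibility", "category": "REVERSIBILITY_TERM"},
    {"rule_id": "t-reversible-defect", "pattern": "reversible defect", "category": "REVERSIBILITY_TERM"},
    {"rule_id": "t-reversible-defects", "pattern": "reversible defects", "category": "REVERSIBILITY_TERM"},
    {"rule_id": "t-perf-defect", "pattern": "perfusion defect", "category": "PERFUSION_FINDING"},
    {"rule_id": "t-perf-defects", "pattern": "perfusion defects", "category": "PERFUSION_FINDING"},
    {"rule_id": "t-perf-abnormality", "pattern": "perfusion abnormality", "category": "PERFUSION_FINDING"},
    {"rule_id": "t-perf-abnormalities", "pattern": "perfusion abnormalities", "category": "PERFUSION_FINDING"},
    {"rule_id": "t-reduced-counts", "pattern": "reduced counts", "category": "PERFUSION_FINDING"},
    {"rule_id": "t-defect", "pattern": "defect", "category": "PERFUSION_FINDING"},
    {"rule_id": "t-defects", "pattern": "defects", "category": "PERFUSION_FINDING"}
  ],
  "contexts": [
    {"rule_id": "c-negative-for", "pattern": "negative for", "category": "NEGATED_EXISTENCE", "direction": "FORWARD", "max_scope_tokens": 10},
    {"rule_id": "c-no-evidence-of", "pattern": "no evidence of", "category": "NEGATED_EXISTENCE", "direction": "FORWARD", "max_scope_tokens": 10},
    {"rule_id": "c-without-evidence-of", "pattern": "without evidence of", "category": "NEGATED_EXISTENCE", "direction": "FORWARD", "max_scope_tokens": 10},
    {"rule_id": "c-without", "pattern": "without", "category": "NEGATED_EXISTENCE", "direction": "FORWARD", "max_scope_tokens": 10},
    {"rule_id": "c-no", "pattern": "no", "category": "NEGATED_EXISTENCE", "direction": "FORWARD", "max_scope_tokens": 10},
    {"rule_id": "c-negative", "pattern": "negative", "category": "NEGATED_EXISTENCE", "direction": "FORWARD", "max_scope_tokens": 10},
    {"rule_id": "c-rules-out", "pattern": "rules out", "category": "NEGATED_EXISTENCE", "direction": "FORWARD", "max_scope_tokens": 10},
    {"rule_id": "c-fixed", "pattern": "fixed", "category": "FIXED", "direction": "FORWARD", "max_scope_tokens": 10},
    {"rule_id": "c-primarily-fixed", "pattern": "primarily fixed", "category": "FIXED", "direction": "FORWARD", "max_scope_tokens": 10},
    {"rule_id": "c-scar", "pattern": "consistent with scar", "category": "FIXED", "direction": "BACKWARD", "max_scope_tokens": 10},
    {"rule_id": "c-artifact", "pattern": "artifact", "category": "ARTIFACT", "direction": "BACKWARD", "max_scope_tokens": 10},
    {"rule_id": "c-artifactual", "pattern": "artifactual", "category": "ARTIFACT", "direction": "BACKWARD", "max_scope_tokens": 10},
    {"rule_id": "c-attenuation-artifact", "pattern": "attenuation artifact", "category": "ARTIFACT", "direction": "BACKWARD", "max_scope_tokens": 10},
    {"rule_id": "c-prone-resolves", "pattern": "resolves on prone imaging", "category": "ARTIFACT", "direction": "BACKWARD", "max_scope_tokens": 10},
    {"rule_id": "c-reversible", "pattern": "reversible", "category": "REVERSIBLE", "direction": "FORWARD", "max_scope_tokens": 10},
    {"rule_id": "c-partially-reversible", "pattern": "partially reversible", "category": "REVERSIBLE", "direction": "FORWARD", "max_scope_tokens": 10},
    {"rule_id": "c-which-is-reversible", "pattern": "which is reversible", "category": "REVERSIBLE", "direction": "BACKWARD", "max_scope_tokens": 10},
    {"rule_id": "c-likely", "pattern": "likely", "category": "UNCERTAIN", "direction": "FORWARD", "max_scope_tokens": 10},
    {"rule_id": "c-favored-to-be", "pattern": "favored to be", "category": "UNCERTAIN", "direction": "FORWARD", "max_scope_tokens": 10},
    {"rule_id": "c-possible", "pattern": "possible", "category": "UNCERTAIN", "direction": "FORWARD", "max_scope_tokens": 10},
    {"rule_id": "c-suggestive-of", "pattern": "suggestive of", "category": "UNCERTAIN", "direction": "FORWARD", "max_scope_tokens": 10},
    {"rule_id": "c-term-and", "pattern": "and", "category": "TERMINATE"},
    {"rule_id": "c-term-but", "pattern": "but", "category": "TERMINATE"}
  ],
  "sections": [
    {"rule_id": "s-impression", "header_pattern": "IMPRESSION", "section_category": "IMPRESSION"},
    {"rule_id": "s-conclusion", "header_pattern": "CONCLUSION", "section_category": "IMPRESSION"},
    {"rule_id": "s-findings", "header_pattern": "FINDINGS", "section_category": "FINDINGS"},
    {"rule_id": "s-indication", "header_pattern": "INDICATION", "section_category": "INDICATION"},
    {"rule_id": "s-technique", "header_pattern": "TECHNIQUE", "section_category": "TECHNIQUE"},
    {"rule_id": "s-procedure", "header_pattern": "PROCEDURE", "section_category": "TECHNIQUE"},
    {"rule_id": "s-history", "header_pattern": "HISTORY", "section_category": "HISTORY"},
    {"rule_id": "s-comparison", "header_pattern": "COMPARISON", "section_category": "COMPARISON"}
  ]
}
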