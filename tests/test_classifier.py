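import pytest

from ischemia_nlp import (
    Polarity,
    ReportDocument,
    Span,
    TextPolicy,
    UnclassifiableDocumentError,
    classify_corpus,
    classify_document,
    mention_polarity,
)
from ischemia_nlp.core import MentionAttributes, TargetCategory, TargetMention
from ischemia_nlp.synthetic import CorpusSpec, generate_corpus


def _mention(category, **flags):
    return TargetMention(
        span=Span(0, 4, "stub"),
        category=category,
        rule_id="t",
        sentence_index=0,
        attributes=MentionAttributes(**flags),
    )


@pytest.mark.parametrize(
    "category,flags,expected",
    [
        (TargetCategory.ISCHEMIA_TERM, {}, Polarity.POSITIVE),
        (TargetCategory.ISCHEMIA_TERM, {"is_uncertain": True}, Polarity.POSITIVE),
        (TargetCategory.ISCHEMIA_TERM, {"is_fixed": True}, Polarity.NOT_POSITIVE),
        (TargetCategory.ISCHEMIA_TERM, {"is_negated": True}, Polarity.NOT_POSITIVE),
        (TargetCategory.ISCHEMIA_TERM, {"is_artifact": True}, Polarity.NOT_POSITIVE),
        (TargetCategory.REVERSIBILITY_TERM, {}, Polarity.POSITIVE),
        (TargetCategory.PERFUSION_FINDING, {}, Polarity.NOT_POSITIVE),
        (TargetCategory.PERFUSION_FINDING, {"has_reversible_modifier": True},
         Polarity.POSITIVE),
        (TargetCategory.PERFUSION_FINDING,
         {"has_reversible_modifier": True, "is_fixed": True}, Polarity.NOT_POSITIVE),
        (TargetCategory.PERFUSION_FINDING,
         {"has_reversible_modifier": True, "is_uncertain": True}, Polarity.POSITIVE),
    ],
)
def test_mention_polarity_decision_table(category, flags, expected):
    assert mention_polarity(_mention(category, **flags)) is expected


def test_gold_phrase_suite(rulebook, gold_phrases):
    """End-to-end behavioral contract: every reference phrase classifies to
    its printed label (5 positive, 8 negative)."""
    for i, (phrase, label) in enumerate(gold_phrases):
        doc = ReportDocument(report_id=f"g{i:02d}", impression_text=phrase)
        result = classify_document(doc, rulebook)
        assert result.ischemia == label, phrase
        if result.mentions:
            assert result.evidence != ""


def test_gold_phrase_corpus_tally(rulebook, gold_phrases):
    docs = [
        ReportDocument(report_id=f"g{i:02d}", impression_text=p)
        for i, (p, _) in enumerate(gold_phrases)
    ]
    results, summary = classify_corpus(docs, rulebook)
    assert summary.n_classified == 13
    assert summary.n_positive == 5
    assert sum(1 - r.ischemia for r in results) == 8
    assert [r.report_id for r in results] == [d.report_id for d in docs]


def test_any_positive_monotonicity(rulebook, gold_phrases):
    """Appending a positive sentence forces 1; appending a negative screen
    sentence never flips a positive document to 0."""
    for i, (phrase, _) in enumerate(gold_phrases):
        doc = ReportDocument(
            report_id=f"m{i}",
            impression_text=phrase + "\nModerate area of reversibility",
        )
        assert classify_document(doc, rulebook).ischemia == 1

    for i, (phrase, label) in enumerate(gold_phrases):
        if label != 1:
            continue
        doc = ReportDocument(
            report_id=f"n{i}",
            impression_text=phrase + "\nNegative myocardial perfusion study",
        )
        assert classify_document(doc, rulebook).ischemia == 1


def test_multi_territory_aggregation(rulebook):
    """One positive territory outweighs any number of negative ones."""
    negatives = [
        "No evidence of ischemia in the inferior wall",
        "Fixed perfusion defect in the septal wall",
        "Large perfusion defect without evidence of reversibility",
    ]
    text = "\n".join(negatives[:2] + ["Stress induced ischemia in the lateral wall"]
                     + negatives[2:])
    doc = ReportDocument(report_id="mt", impression_text=text)
    result = classify_document(doc, rulebook)
    assert result.ischemia == 1
    assert "ischemia" in result.evidence


def test_negative_evidence_lists_refuting_modifiers(rulebook):
    doc = ReportDocument(report_id="e1",
                         impression_text="There is a small area of fixed ischemia")
    result = classify_document(doc, rulebook)
    assert result.ischemia == 0
    assert "fixed" in result.evidence
    assert "ischemia" in result.evidence


def test_no_mentions_means_negative_with_empty_evidence(rulebook):
    doc = ReportDocument(report_id="e2", impression_text="Normal study")
    result = classify_document(doc, rulebook)
    assert (result.ischemia, result.evidence, result.mentions) == (0, "", ())


def test_unclassifiable_document_raises_with_id(rulebook):
    with pytest.raises(UnclassifiableDocumentError, match="bad-doc"):
        classify_document(ReportDocument(report_id="bad-doc"), rulebook)


def test_classify_is_deterministic(rulebook):
    docs = generate_corpus(CorpusSpec(n=40, prevalence=0.4, seed=5))
    first = [classify_document(d, rulebook) for d in docs]
    second = [classify_document(d, rulebook) for d in docs]
    assert first == second


def test_corpus_summary_aggregates_errors(rulebook):
    docs = [
        ReportDocument(report_id="ok", impression_text="Likely ischemia"),
        ReportDocument(report_id="empty"),
    ]
    results, summary = classify_corpus(docs, rulebook)
    assert (summary.n_total, summary.n_classified, summary.n_errored) == (2, 1, 1)
    assert summary.errors[0][0] == "empty"
    assert [r.report_id for r in results] == ["ok"]
    assert summary.prevalence == 1.0


def test_empty_corpus(rulebook):
    results, summary = classify_corpus([], rulebook)
    assert results == []
    assert summary.prevalence is None


def test_conflicting_modifiers_resolve_as_refuted(rulebook):
    doc = ReportDocument(report_id="cf",
                         impression_text="No reversible perfusion abnormality identified")
    result = classify_document(doc, rulebook)
    assert result.ischemia == 0
    (mention,) = result.mentions
    assert mention.attributes.has_reversible_modifier
    assert mention.attributes.is_negated


def test_full_report_fallback_policy(rulebook):
    doc = ReportDocument(
        report_id="fb",
        full_report_text="INDICATION: pain.\nIMPRESSION:\nModerate area of reversibility\n",
    )
    result = classify_document(
        doc, rulebook, TextPolicy.IMPRESSION_THEN_FULL_IMPRESSION_SECTION
    )
    assert result.ischemia == 1
    assert result.source_text_provenance == "full_report_impression_section"
    with pytest.raises(UnclassifiableDocumentError):
        classify_document(doc, rulebook, TextPolicy.IMPRESSION_ONLY)
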