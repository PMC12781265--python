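"""Synthetic nuclear stress test report generator with gold labels.

Emulates short free-text impressions the way they appear in a multisite
clinical data warehouse: perfusion findings with reversibility or fixed
qualifiers, artifact attributions, negations, hedges, multi-territory
sentences, per-site boilerplate and formatting dialects (numbered lists,
prose, one-finding-per-line), and optional sectioned full reports wrapping
the impression. Positive counts are exact (round-half-up of n x prevalence,
not per-document coin flips) so split prevalences are testable as
equalities, and corpora are a pure function of their spec.

The reference phrase suite — the printed example impressions that indicate
or refute ischemia, 5 positive and 8 negative — ships verbatim as fixed
templates and doubles as the integration fixture for the classifier.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

from .core import ReportDocument
from .metrics import round_half_up

#: The 13 reference example phrases with their printed ischemia labels
#: (1 = indicates ischemia). The default rulebook is behavior-complete on
#: this suite.
GOLD_PHRASES: tuple[tuple[str, int], ...] = (
    ("Defect resolves on prone imaging, consistent with attenuation artifact", 0),
    ("Fixed area of mildly reduced counts", 0),
    ("Fixed perfusion defects are seen", 0),
    ("Large perfusion defect without evidence of reversibility", 0),
    ("Likely ischemia", 1),
    ("Moderate area of reversibility", 1),
    ("Moderate size, mildly reduced counts in anterior wall which is reversible", 1),
    ("Negative for reversible ischemia", 0),
    ("Negative myocardial perfusion study", 0),
    ("Small perfusion abnormality is favored to be artifactual", 0),
    ("Small, primarily fixed defect and a mild, reversible defect", 1),
    ("There is a medium size, partially reversible defect", 1),
    ("There is a small area of fixed ischemia", 0),
)


@dataclass(frozen=True)
class PhraseTemplate:
    """An impression-sentence template with ``{territory}``/``{size}``/``{ef}``
    slots. ``label_contribution`` states what the sentence does to the gold
    label; ``in_rulebook_coverage`` whether the default rulebook is
    guaranteed to read it the same way."""

    text: str
    label_contribution: str  # POSITIVE | NEGATIVE | NEUTRAL
    in_rulebook_coverage: bool = True


TERRITORIES = (
    "anterior",
    "inferior",
    "lateral",
    "septal",
    "apical",
    "anterolateral",
    "inferolateral",
)
SIZES = ("Small", "Mild", "Moderate", "Large")

POSITIVE_TEMPLATES = tuple(
    [PhraseTemplate(t, "POSITIVE") for t, lab in GOLD_PHRASES if lab == 1]
    + [
        PhraseTemplate("{size} reversible defect in the {territory} wall", "POSITIVE"),
        PhraseTemplate(
            "{size} area of reversibility involving the {territory} wall", "POSITIVE"
        ),
        PhraseTemplate(
            "Partially reversible perfusion defect in the {territory} territory",
            "POSITIVE",
        ),
        PhraseTemplate("Stress induced ischemia in the {territory} wall", "POSITIVE"),
        PhraseTemplate(
            "{size} perfusion defect in the {territory} wall which is reversible",
            "POSITIVE",
        ),
        PhraseTemplate(
            "Findings consistent with ischemia in the {territory} territory",
            "POSITIVE",
        ),
    ]
)

NEGATIVE_TEMPLATES = tuple(
    [PhraseTemplate(t, "NEGATIVE") for t, lab in GOLD_PHRASES if lab == 0]
    + [
        PhraseTemplate("No evidence of ischemia", "NEGATIVE"),
        PhraseTemplate("Negative for ischemia", "NEGATIVE"),
        PhraseTemplate(
            "{size} fixed perfusion defect in the {territory} wall", "NEGATIVE"
        ),
        PhraseTemplate(
            "Fixed defect in the {territory} wall consistent with scar", "NEGATIVE"
        ),
        PhraseTemplate(
            "{size} perfusion defect attributed to attenuation artifact", "NEGATIVE"
        ),
        PhraseTemplate("No reversible perfusion abnormality identified", "NEGATIVE"),
    ]
)

NEUTRAL_TEMPLATES = (
    PhraseTemplate("Normal myocardial perfusion study", "NEUTRAL"),
    PhraseTemplate("Normal left ventricular size and systolic function", "NEUTRAL"),
    PhraseTemplate("Left ventricular ejection fraction is {ef}%", "NEUTRAL"),
    PhraseTemplate("No significant ECG changes with stress", "NEUTRAL"),
    PhraseTemplate("Normal perfusion throughout the myocardium", "NEUTRAL"),
)

#: Paraphrases deliberately outside default-rulebook coverage; selected by
#: ``noise_fraction`` to emulate the sub-100% accuracy a deployed system
#: shows on real language variation.
NOISE_POSITIVE_TEMPLATES = (
    PhraseTemplate(
        "Stress-induced perfusion change suggestive of flow limitation",
        "POSITIVE",
        in_rulebook_coverage=False,
    ),
    PhraseTemplate(
        "Scintigraphic evidence of inducible hypoperfusion in the {territory} wall",
        "POSITIVE",
        in_rulebook_coverage=False,
    ),
)
NOISE_NEGATIVE_TEMPLATES = (
    PhraseTemplate(
        "Ischemia cannot be completely excluded", "NEGATIVE", in_rulebook_coverage=False
    ),
    PhraseTemplate(
        "Prior study demonstrated ischemia, now resolved",
        "NEGATIVE",
        in_rulebook_coverage=False,
    ),
)

#: Per-site opening boilerplate; sites also differ in list formatting.
SITE_BOILERPLATE = (
    "Myocardial perfusion SPECT imaging performed at rest and stress.",
    "Nuclear stress test with pharmacologic agent.",
    "Gated SPECT myocardial perfusion study",
    "Exercise myocardial perfusion imaging report.",
)


@dataclass(frozen=True)
class CorpusSpec:
    """Everything that determines a generated corpus.

    ``noise_fraction`` is the fraction of documents whose decisive sentence
    comes from out-of-coverage paraphrase templates; 0 (the default) makes
    classifier accuracy on the corpus exactly 100%.
    """

    n: int
    prevalence: float
    seed: int
    site_count: int = 3
    noise_fraction: float = 0.0
    full_report_fraction: float = 0.25
    id_prefix: str = "r"

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError("n must be >= 0")
        for name in ("prevalence", "noise_fraction", "full_report_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.site_count < 1:
            raise ValueError("site_count must be >= 1")


def _instantiate(template: PhraseTemplate, rng: random.Random) -> str:
    return template.text.format(
        territory=rng.choice(TERRITORIES),
        size=rng.choice(SIZES),
        ef=rng.randrange(45, 75, 5),
    )


def _join_impression(sentences: list[str], site_index: int) -> str:
    style = site_index % 3
    if style == 0:  # numbered list
        return "\n".join(f"{i + 1}. {s.rstrip('.')}." for i, s in enumerate(sentences))
    if style == 1:  # running prose
        return " ".join(f"{s.rstrip('.')}." for s in sentences)
    return "\n".join(sentences)  # one finding per line


def _wrap_full_report(impression: str, boilerplate: str, rng: random.Random) -> str:
    indication = rng.choice(
        ("Chest pain evaluation", "Dyspnea on exertion", "Preoperative risk assessment")
    )
    return (
        f"INDICATION: {indication}.\n"
        f"TECHNIQUE: {boilerplate}\n"
        "FINDINGS: Gated images reviewed in standard axes.\n"
        f"IMPRESSION:\n{impression}\n"
    )


def generate_report(
    label: int,
    rng: random.Random,
    spec: CorpusSpec,
    report_id: str = "r00000",
    noisy: bool = False,
) -> ReportDocument:
    """Generate one gold-labeled report.

    A positive document carries at least one positive-template sentence and
    0-3 negative/neutral distractors (exercising multi-territory
    aggregation); a negative document carries only negative/neutral
    sentences. ``noisy`` swaps the decisive sentence for an out-of-coverage
    paraphrase.
    """
    site_index = rng.randrange(spec.site_count)
    boilerplate = SITE_BOILERPLATE[site_index % len(SITE_BOILERPLATE)]
    distractor_bank = NEGATIVE_TEMPLATES + NEUTRAL_TEMPLATES

    sentences: list[str] = []
    if label == 1:
        bank = NOISE_POSITIVE_TEMPLATES if noisy else POSITIVE_TEMPLATES
        for _ in range(rng.choice((1, 1, 2))):
            sentences.append(_instantiate(rng.choice(bank), rng))
        for _ in range(rng.randrange(4)):  # 0-3 distractors
            sentences.append(_instantiate(rng.choice(distractor_bank), rng))
    else:
        if noisy:
            sentences.append(_instantiate(rng.choice(NOISE_NEGATIVE_TEMPLATES), rng))
            extra = rng.randrange(3)
        else:
            extra = 1 + rng.randrange(3)
        for _ in range(extra):
            sentences.append(_instantiate(rng.choice(distractor_bank), rng))
    rng.shuffle(sentences)
    sentences.insert(0, boilerplate)

    impression = _join_impression(sentences, site_index)
    full_report = ""
    if rng.random() < spec.full_report_fraction:
        full_report = _wrap_full_report(impression, boilerplate, rng)
    return ReportDocument(
        report_id=report_id,
        impression_text=impression,
        full_report_text=full_report,
        site_id=f"site{site_index:02d}",
        gold_label=label,
    )


def positive_count(n: int, prevalence: float) -> int:
    """Exact number of positives: round-half-up of n x prevalence."""
    return int(round_half_up(n * prevalence, 0))


def generate_corpus(spec: CorpusSpec) -> list[ReportDocument]:
    """Generate a shuffled corpus with exactly ``positive_count`` positive
    gold labels; byte-identical for identical specs."""
    rng = random.Random(spec.seed)
    n_pos = positive_count(spec.n, spec.prevalence)
    labels = [1] * n_pos + [0] * (spec.n - n_pos)
    rng.shuffle(labels)
    n_noisy = positive_count(spec.n, spec.noise_fraction)
    noisy_indices = set(rng.sample(range(spec.n), n_noisy)) if spec.n else set()
    docs = [
        generate_report(
            label,
            random.Random(rng.randrange(2**31)),
            spec,
            report_id=f"{spec.id_prefix}{i:05d}",
            noisy=i in noisy_indices,
        )
        for i, label in enumerate(labels)
    ]
    return docs


def generate_benchmark_splits(seed: int) -> dict[str, list[ReportDocument]]:
    """The annotated-sample split structure: 440 training documents at 17%
    prevalence plus a 214-document set at 43% prevalence broken into 115
    validation and 99 test documents (654 total, a 67/18/15 split).
    Report ids are globally unique across the three corpora."""
    specs = {
        "train": CorpusSpec(n=440, prevalence=0.17, seed=seed * 4 + 1, id_prefix="train-"),
        "validation": CorpusSpec(
            n=115, prevalence=0.43, seed=seed * 4 + 2, id_prefix="val-"
        ),
        "test": CorpusSpec(n=99, prevalence=0.43, seed=seed * 4 + 3, id_prefix="test-"),
    }
    return {name: generate_corpus(s) for name, s in specs.items()}
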