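import random

import pytest

from ischemia_nlp import default_ischemia_rulebook
from ischemia_nlp.synthetic import GOLD_PHRASES


@pytest.fixture(scope="session")
def rulebook():
    return default_ischemia_rulebook()


@pytest.fixture(scope="session")
def gold_phrases():
    return GOLD_PHRASES


@pytest.fixture()
def rng():
    return random.Random(20240917)


def random_context_setup(rng: random.Random):
    """A random small sentence plus random target/context rules over a
    shared vocabulary, for matcher/context oracle-equivalence tests."""
    from ischemia_nlp.core import Direction, ModifierCategory, TargetCategory
    from ischemia_nlp.rules import ContextRule, TargetRule

    vocab = [f"w{i}" for i in range(6)]
    n = rng.randint(1, 12)
    words = [rng.choice(vocab) for _ in range(n)]
    text = " ".join(words)

    def pattern():
        return " ".join(
            rng.choice(vocab + ["*"]) for _ in range(rng.choice((1, 1, 2)))
        )

    targets = [
        TargetRule(
            rule_id=f"t{i}",
            pattern=pattern(),
            category=rng.choice(list(TargetCategory)),
        )
        for i in range(rng.randint(1, 3))
    ]
    contexts = [
        ContextRule(
            rule_id=f"c{i}",
            pattern=pattern(),
            category=rng.choice(
                [c for c in ModifierCategory if c is not ModifierCategory.TERMINATE]
            ),
            direction=rng.choice(list(Direction)),
            max_scope_tokens=rng.choice((1, 2, 3, 10, None)),
        )
        for i in range(rng.randint(0, 3))
    ]
    contexts.append(
        ContextRule(
            rule_id="cterm",
            pattern=rng.choice(vocab),
            category=ModifierCategory.TERMINATE,
        )
    )
    return text, targets, contexts
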