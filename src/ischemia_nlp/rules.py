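"""Rule definitions: target, context and section rules, loadable from JSON.

A rulebook is a single JSON object with keys ``targets``, ``contexts`` and
``sections``. Patterns are case-insensitive literal token sequences with
optional single-token wildcards (``*``) rather than regular expressions, so
rule files stay auditable by clinicians. Unknown JSON fields are warned
about and ignored so rule files from richer ecosystems remain loadable.
"""

from __future__ import annotations

import json
import logging
from importlib import resources
from pathlib import Path
from typing import Iterator, Optional, Union

from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

from .core import Direction, ModifierCategory, TargetCategory

logger = logging.getLogger(__name__)

#: Default token reach of a directional context cue when a rule does not
#: override it; sentence boundaries and TERMINATE cues always cap scope.
DEFAULT_MAX_SCOPE_TOKENS = 10

_KNOWN_FIELDS = {
    "TargetRule": {"rule_id", "pattern", "category"},
    "ContextRule": {"rule_id", "pattern", "category", "direction", "max_scope_tokens"},
    "SectionRule": {"rule_id", "header_pattern", "section_category"},
}


class RulebookError(ValueError):
    """Schema violation, duplicate id, or other rule-file defect."""


class _Rule(BaseModel):
    model_config = ConfigDict(frozen=True, extra="allow")

    rule_id: str = Field(min_length=1)

    @model_validator(mode="after")
    def _warn_unknown_fields(self):
        known = _KNOWN_FIELDS[type(self).__name__]
        for name in self.model_extra or {}:
            logger.warning(
                "rule %s: ignoring unknown field %r", self.rule_id, name
            )
        return self


class TargetRule(_Rule):
    """A clinical concept pattern, e.g. ``"perfusion defect"``."""

    pattern: str = Field(min_length=1)
    category: TargetCategory


class ContextRule(_Rule):
    """A directional context cue, e.g. ``"negative for"`` (FORWARD).

    TERMINATE rules cut scopes and need no direction; all other
    categories require one. ``max_scope_tokens`` of ``None`` means
    unlimited within the sentence.
    """

    pattern: str = Field(min_length=1)
    category: ModifierCategory
    direction: Optional[Direction] = None
    max_scope_tokens: Optional[int] = DEFAULT_MAX_SCOPE_TOKENS

    @field_validator("max_scope_tokens")
    @classmethod
    def _positive(cls, v):
        if v is not None and v < 1:
            raise ValueError("max_scope_tokens must be positive or null")
        return v

    @model_validator(mode="after")
    def _direction_required(self):
        if self.category is not ModifierCategory.TERMINATE and self.direction is None:
            raise ValueError(
                f"rule {self.rule_id!r}: direction is required for "
                f"category {self.category.value}"
            )
        return self


class SectionRule(_Rule):
    """A line-initial report header, matched case-insensitively and
    tolerant of a trailing colon or dash."""

    header_pattern: str = Field(min_length=1)
    section_category: str = Field(min_length=1)


class Rulebook(BaseModel):
    model_config = ConfigDict(frozen=True)

    name: str = "unnamed"
    version: str = "0"
    targets: tuple[TargetRule, ...] = ()
    contexts: tuple[ContextRule, ...] = ()
    sections: tuple[SectionRule, ...] = ()

    @model_validator(mode="after")
    def _unique_ids(self):
        seen: set[str] = set()
        for rule in self.iter_rules():
            if rule.rule_id in seen:
                raise ValueError(f"duplicate rule_id {rule.rule_id!r}")
            seen.add(rule.rule_id)
        return self

    def iter_rules(self) -> Iterator[_Rule]:
        yield from self.targets
        yield from self.contexts
        yield from self.sections


def _dump(rb: Rulebook) -> dict:
    def rule_dict(rule: _Rule) -> dict:
        d = rule.model_dump(mode="json", exclude_none=False)
        for extra in rule.model_extra or {}:
            d.pop(extra, None)
        return d

    return {
        "name": rb.name,
        "version": rb.version,
        "targets": [rule_dict(r) for r in rb.targets],
        "contexts": [rule_dict(r) for r in rb.contexts],
        "sections": [rule_dict(r) for r in rb.sections],
    }


def rulebook_from_dict(data: dict) -> Rulebook:
    if not isinstance(data, dict):
        raise RulebookError("rulebook JSON must be a single object")
    for key in data:
        if key not in {"name", "version", "targets", "contexts", "sections"}:
            logger.warning("rulebook: ignoring unknown top-level key %r", key)
    try:
        return Rulebook(
            name=data.get("name", "unnamed"),
            version=str(data.get("version", "0")),
            targets=tuple(TargetRule(**r) for r in data.get("targets", [])),
            contexts=tuple(ContextRule(**r) for r in data.get("contexts", [])),
            sections=tuple(SectionRule(**r) for r in data.get("sections", [])),
        )
    except (TypeError, ValueError) as exc:
        raise RulebookError(f"invalid rulebook: {exc}") from exc


def load_rulebook(path: Union[str, Path]) -> Rulebook:
    """Load and validate a rulebook JSON file.

    Raises :class:`RulebookError` naming the offending rule on any
    closed-set violation or duplicate rule id.
    """
    path = Path(path)
    try:
        data = json.loads(path.read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise RulebookError(f"{path}: not valid JSON: {exc}") from exc
    return rulebook_from_dict(data)


def save_rulebook(rb: Rulebook, path: Union[str, Path]) -> None:
    """Write ``rb`` as JSON such that :func:`load_rulebook` round-trips it."""
    Path(path).write_text(
        json.dumps(_dump(rb), indent=2, ensure_ascii=False) + "\n", encoding="utf-8"
    )


def default_ischemia_rulebook() -> Rulebook:
    """The built-in ischemia rulebook shipped with the package.

    Authored to be behavior-complete on the reference phrase suite of
    indicative and refuting impressions (see :mod:`ischemia_nlp.synthetic`):
    targets for ischemia / reversibility / perfusion-finding terms, refuting
    cues (negation, fixed, artifact), the reversibility promoter, hedges,
    and clause terminators, plus the common report section headers.
    """
    with resources.files("ischemia_nlp.data").joinpath(
        "ischemia_rules.json"
    ).open("r", encoding="utf-8") as fh:
        return rulebook_from_dict(json.load(fh))
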