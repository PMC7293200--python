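"""Hierarchical reaction-class labels.

Reaction classes are organised in a four-level taxonomy from broad bond
chemistry (level 1, e.g. "C-C Bond Formation") down to transformation
type, substrate and functionality (e.g. "C-C Bond Formation (Coupling)
(Suzuki) (Iodo)").  Truncating a label to a shallower level merges
specific classes into more generic ones, which is how recommendations
made at one level are generalised to another.

Textual form: ``Level1 (Level2) (Level3) (Level4)``.  En-dashes are
normalised to plain hyphens and whitespace is collapsed on parse.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, List, Sequence, Tuple

__all__ = [
    "ReactionClassLabel",
    "LabelVocabulary",
    "parse_label",
    "truncate_label",
    "matches_at_level",
]

MAX_LEVELS = 4


@dataclass(frozen=True, order=True)
class ReactionClassLabel:
    levels: Tuple[str, ...]

    def __post_init__(self) -> None:
        if not 1 <= len(self.levels) <= MAX_LEVELS:
            raise ValueError("a label has between 1 and 4 levels")
        if any(not lv for lv in self.levels):
            raise ValueError("label components must be non-empty")

    @property
    def depth(self) -> int:
        return len(self.levels)

    def truncate(self, level: int) -> "ReactionClassLabel":
        return truncate_label(self, level)

    def __str__(self) -> str:
        head, *rest = self.levels
        return " ".join([head] + [f"({lv})" for lv in rest])


def _normalise(text: str) -> str:
    text = text.replace("–", "-").replace("—", "-")
    return re.sub(r"\s+", " ", text).strip()


def parse_label(text: str) -> ReactionClassLabel:
    """Parse the parenthesised textual form into a hierarchical label."""
    text = _normalise(text)
    if not text:
        raise ValueError("empty label")
    if text.count("(") != text.count(")"):
        raise ValueError(f"unbalanced parentheses in label: {text!r}")
    first = text.find("(")
    if first == -1:
        return ReactionClassLabel((text,))
    head = text[:first].strip()
    if not head:
        raise ValueError(f"label has no level-1 component: {text!r}")
    rest = re.findall(r"\(([^()]*)\)", text[first:])
    tail = text[first:]
    if re.sub(r"\(([^()]*)\)", "", tail).strip():
        raise ValueError(f"trailing text outside parentheses: {text!r}")
    levels = [head] + [part.strip() for part in rest]
    return ReactionClassLabel(tuple(levels))


def truncate_label(label: ReactionClassLabel, level: int) -> ReactionClassLabel:
    if level < 1:
        raise ValueError("level must be >= 1")
    return ReactionClassLabel(label.levels[: min(level, label.depth)])


def matches_at_level(
    a: ReactionClassLabel, b: ReactionClassLabel, level: int
) -> bool:
    """True iff a and b agree once truncated to the given level."""
    return truncate_label(a, level) == truncate_label(b, level)


@dataclass(frozen=True)
class LabelVocabulary:
    """Ordered, duplicate-free list of labels, all truncated to one level."""

    level: int
    labels: Tuple[ReactionClassLabel, ...]

    def __post_init__(self) -> None:
        if not 1 <= self.level <= MAX_LEVELS:
            raise ValueError("vocabulary level must be 1-4")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("vocabulary labels must be unique")
        for lab in self.labels:
            if lab.depth > self.level:
                raise ValueError(f"label {lab} deeper than vocabulary level")

    @classmethod
    def from_labels(
        cls, labels: Iterable[ReactionClassLabel], level: int
    ) -> "LabelVocabulary":
        uniq = sorted({truncate_label(l, level) for l in labels})
        return cls(level=level, labels=tuple(uniq))

    def __len__(self) -> int:
        return len(self.labels)

    def __iter__(self):
        return iter(self.labels)

    def index(self, label: ReactionClassLabel) -> int:
        return self.labels.index(label)
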