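"""Interval-rule semantics: antecedent evaluation, confusion counts,
accuracy fitness, and the textual rule form.

A rule is a conjunction of inclusive per-channel bounds with a class
consequent, e.g. ``if((266 ≤ MQ3 ≤ 637) and (516 ≤ NH3 ≤ 847)) Then L``.
Rules are stored and reported in raw sensor units.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np

from .datamodel import FeatureTable

__all__ = [
    "Condition",
    "IntervalRule",
    "ConfusionCounts",
    "UndefinedFitnessError",
    "RuleParseError",
    "antecedent_fires",
    "fires_vector",
    "confusion",
    "accuracy",
    "format_rule",
    "parse_rule",
    "rule_to_dict",
    "rule_from_dict",
]


class UndefinedFitnessError(ValueError):
    """Accuracy requested for an all-zero confusion count."""


class RuleParseError(ValueError):
    """Rule text does not match the grammar; carries the failure position."""

    def __init__(self, message: str, position: int = 0):
        super().__init__(f"{message} (at position {position})")
        self.position = position


@dataclass(frozen=True)
class Condition:
    channel: str
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not self.lower <= self.upper:
            raise ValueError(
                f"condition on {self.channel!r}: lower {self.lower} > upper {self.upper}"
            )


@dataclass(frozen=True)
class IntervalRule:
    """Conjunction of inclusive interval conditions implying a class."""

    consequent: str
    conditions: tuple[Condition, ...]

    def __post_init__(self) -> None:
        if len(self.conditions) == 0:
            raise ValueError("a rule needs at least one condition")
        names = [c.channel for c in self.conditions]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate channels in rule: {names}")

    @staticmethod
    def make(consequent: str, conditions: Iterable[tuple[str, float, float]]) -> "IntervalRule":
        return IntervalRule(
            consequent,
            tuple(Condition(ch, float(lo), float(hi)) for ch, lo, hi in conditions),
        )

    @property
    def channels(self) -> list[str]:
        return [c.channel for c in self.conditions]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def antecedent_fires(rule: IntervalRule, row: Mapping[str, float]) -> bool:
    """True iff every condition holds with inclusive bounds."""
    for cond in rule.conditions:
        try:
            v = row[cond.channel]
        except KeyError:
            raise KeyError(f"row has no channel {cond.channel!r}") from None
        if not (cond.lower <= v <= cond.upper):
            return False
    return True


def fires_vector(rule: IntervalRule, table: FeatureTable) -> np.ndarray:
    """Boolean antecedent outcome for every row of ``table`` (vectorized)."""
    fired = np.ones(table.n, dtype=bool)
    for cond in rule.conditions:
        col = table.column(cond.channel)
        fired &= (col >= cond.lower) & (col <= cond.upper)
    return fired


def confusion(rule: IntervalRule, table: FeatureTable) -> ConfusionCounts:
    """Count TP/TN/FP/FN of ``rule`` over all rows of ``table``.

    A row is positive when its label equals the rule's consequent; the
    antecedent outcome is the prediction.  Fires & positive -> TP; fires &
    negative -> FP; silent & positive -> FN; silent & negative -> TN.
    """
    fired = fires_vector(rule, table)
    positive = table.labels == rule.consequent
    tp = int(np.sum(fired & positive))
    fp = int(np.sum(fired & ~positive))
    fn = int(np.sum(~fired & positive))
    tn = int(np.sum(~fired & ~positive))
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def accuracy(counts: ConfusionCounts) -> float:
    """(TP + TN) / (TP + TN + FP + FN)."""
    if counts.total == 0:
        raise UndefinedFitnessError("accuracy undefined for zero evaluated rows")
    return (counts.tp + counts.tn) / counts.total


def _fmt_num(x: float) -> str:
    # shortest text that round-trips through float()
    if float(x) == int(x) and abs(x) < 1e16:
        return str(int(x))
    return repr(float(x))


def format_rule(rule: IntervalRule) -> str:
    parts = [
        f"({_fmt_num(c.lower)} ≤ {c.channel} ≤ {_fmt_num(c.upper)})"
        for c in rule.conditions
    ]
    return f"if({' and '.join(parts)}) Then {rule.consequent}"


_COND_RE = re.compile(
    r"\(\s*([0-9.eE+-]+)\s*(?:≤|<=)\s*(\w+)\s*(?:≤|<=)\s*([0-9.eE+-]+)\s*\)"
)
_RULE_RE = re.compile(r"^\s*if\s*\((?P<body>.*)\)\s*Then\s+(?P<cls>\S+)\s*$", re.DOTALL)


def parse_rule(text: str) -> IntervalRule:
    """Parse ``if((lo ≤ CH ≤ hi)[ and (...)]*) Then CLASS`` (ASCII ``<=`` ok)."""
    m = _RULE_RE.match(text)
    if not m:
        raise RuleParseError("text does not match 'if(...) Then CLASS'", 0)
    body = m.group("body")
    conds: list[Condition] = []
    pos = 0
    for piece in re.split(r"\s+and\s+", body.strip()):
        cm = _COND_RE.match(piece.strip())
        if not cm:
            raise RuleParseError(f"bad condition {piece.strip()!r}", m.start("body") + pos)
        lo, ch, hi = float(cm.group(1)), cm.group(2), float(cm.group(3))
        if lo > hi:
            raise RuleParseError(
                f"lower {lo} > upper {hi} for channel {ch!r}", m.start("body") + pos
            )
        conds.append(Condition(ch, lo, hi))
        pos += len(piece)
    return IntervalRule(m.group("cls"), tuple(conds))


def rule_to_dict(rule: IntervalRule) -> dict:
    return {
        "consequent": rule.consequent,
        "conditions": [
            {"channel": c.channel, "lower": c.lower, "upper": c.upper}
            for c in rule.conditions
        ],
    }


def rule_from_dict(d: Mapping) -> IntervalRule:
    return IntervalRule.make(
        d["consequent"],
        [(c["channel"], c["lower"], c["upper"]) for c in d["conditions"]],
    )
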