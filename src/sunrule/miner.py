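"""Per-class interval-rule mining on top of the sunflower optimiser.

A candidate solution for a table with ``d`` channels is a ``3 d`` vector:
``d`` activation scores in [0, 1] (an attribute joins the rule when its
score strictly exceeds the threshold ``delta``), then ``d`` candidate
lower bounds and ``d`` candidate upper bounds in normalized units.
Bounds are confined to the target class's subspace box; fitness is
confusion-matrix accuracy on the *full* training table (so true/false
negatives are meaningful).  The "parallel" scheme runs independent
islands with distinct seeds and unions their final populations.
"""

from __future__ import annotations

import logging
import statistics
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .datamodel import (
    FeatureTable,
    NormalizationSpec,
    fit_normalization,
    invert_normalization,
)
from .rule_engine import IntervalRule, accuracy, confusion
from .sfoa import SfoaConfig, optimize

logger = logging.getLogger(__name__)

__all__ = [
    "EncodedSolution",
    "MinerConfig",
    "RunStats",
    "EmptyAntecedentError",
    "decode",
    "make_fitness",
    "class_subspace",
    "mine_rules",
    "test_rules",
    "stratified_split",
    "run_experiment",
]

class EmptyAntecedentError(ValueError):
    """No activation score exceeded the threshold; the rule has no 'if' part."""


@dataclass(frozen=True)
class EncodedSolution:
    """The three sub-vectors of one candidate, plus its target class."""

    y_t: np.ndarray
    y_a: np.ndarray
    y_h: np.ndarray
    target_class: str

    @staticmethod
    def from_position(position: np.ndarray, target_class: str) -> "EncodedSolution":
        position = np.asarray(position, dtype=float)
        if position.size % 3 != 0:
            raise ValueError("encoded position length must be a multiple of 3")
        d = position.size // 3
        return EncodedSolution(position[:d], position[d : 2 * d], position[2 * d :], target_class)

    def to_position(self) -> np.ndarray:
        return np.concatenate([self.y_t, self.y_a, self.y_h])


@dataclass
class MinerConfig:
    """Mining hyperparameters; defaults follow the reference protocol
    (population 30, pollination 2.5%, elimination 20%, 300 iterations)."""

    population: int = 30
    pollination_rate: float = 0.025
    elimination_rate: float = 0.20
    iterations: int = 300
    phi: float = 20.0
    delta: float = 0.5
    islands: int = 2
    rules_kept: int = 4
    split_fraction: float = 0.2
    experiments: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.delta < 1:
            raise ValueError("delta must lie in (0, 1)")
        if self.islands < 1:
            raise ValueError("islands must be >= 1")
        if self.rules_kept < 1:
            raise ValueError("rules_kept must be >= 1")
        if not 0 < self.split_fraction < 1:
            raise ValueError("split_fraction must lie in (0, 1)")

    def sfoa_config(self, lower: np.ndarray, upper: np.ndarray, seed: int) -> SfoaConfig:
        return SfoaConfig(
            lower=lower,
            upper=upper,
            population=self.population,
            pollination_rate=self.pollination_rate,
            elimination_rate=self.elimination_rate,
            iterations=self.iterations,
            phi=self.phi,
            seed=seed,
        )


@dataclass
class RunStats:
    """Best/Worst/Mean/Median/Std of one class's per-run test accuracies."""

    values: list[float]

    @property
    def best(self) -> float:
        return max(self.values)

    @property
    def worst(self) -> float:
        return min(self.values)

    @property
    def mean(self) -> float:
        return statistics.fmean(self.values)

    @property
    def median(self) -> float:
        return statistics.median(self.values)

    @property
    def std(self) -> float:
        return statistics.pstdev(self.values) if len(self.values) > 1 else 0.0

    def as_dict(self) -> dict[str, float]:
        return {
            "Best": self.best,
            "Worst": self.worst,
            "Mean": self.mean,
            "Median": self.median,
            "Std": self.std,
        }


def decode(solution: EncodedSolution, delta: float, spec: NormalizationSpec) -> IntervalRule:
    """Threshold the activations (strict ``>``), swap inverted bounds, and
    map normalized bounds back to raw units.  Constant channels never
    activate.  Raises :class:`EmptyAntecedentError` when nothing activates.
    """
    active = (solution.y_t > delta) & ~spec.constant_mask
    if not active.any():
        raise EmptyAntecedentError("no attribute activation exceeds delta")
    conditions = []
    for j in np.nonzero(active)[0]:
        lo_n = min(solution.y_a[j], solution.y_h[j])
        hi_n = max(solution.y_a[j], solution.y_h[j])
        ch = spec.channels[j]
        conditions.append(
            (ch, invert_normalization(spec, lo_n, ch), invert_normalization(spec, hi_n, ch))
        )
    return IntervalRule.make(solution.target_class, conditions)


def make_fitness(
    train_table: FeatureTable,
    target_class: str,
    delta: float,
    spec: NormalizationSpec,
):
    """Fitness callable over 3d positions: train-set accuracy of the
    decoded rule; solutions with an empty antecedent score 0."""
    if train_table.n == 0:
        raise ValueError("training table is empty")
    X = np.ascontiguousarray(train_table.values)
    positive = train_table.labels == target_class
    n = train_table.n
    d = train_table.d
    mins, maxs = spec.mins, spec.maxs
    nb, nh = spec.target
    span = np.where(spec.constant_mask, 0.0, maxs - mins)
    const = spec.constant_mask

    def fitness(position: np.ndarray) -> float:
        y_t = position[:d]
        y_a = position[d : 2 * d]
        y_h = position[2 * d :]
        active = (y_t > delta) & ~const
        if not active.any():
            return 0.0
        idx = np.nonzero(active)[0]
        lo_n = np.minimum(y_a[idx], y_h[idx])
        hi_n = np.maximum(y_a[idx], y_h[idx])
        # same affine map as invert_normalization, vectorized
        lo = mins[idx] + (lo_n - nb) / (nh - nb) * span[idx]
        hi = mins[idx] + (hi_n - nb) / (nh - nb) * span[idx]
        sub = X[:, idx]
        fired = np.all((sub >= lo) & (sub <= hi), axis=1)
        correct = np.count_nonzero(fired == positive)
        return correct / n

    return fitness


def class_subspace(table: FeatureTable, class_label: str) -> tuple[np.ndarray, np.ndarray]:
    """Per-channel (lower, upper) extrema of the rows bearing ``class_label``,
    in raw units.  Used to bound the candidate interval sub-vectors; the
    fitness itself is always computed on the full table."""
    rows = table.class_rows(class_label)
    return rows.values.min(axis=0), rows.values.max(axis=0)


def _search_box(table: FeatureTable, spec: NormalizationSpec) -> tuple[np.ndarray, np.ndarray]:
    """3d box: activations and candidate bounds all range over the full
    normalized target interval, keeping the N_b <= y <= N_h constraint
    valid throughout and the optimum away from box corners.

    Confining the bound sub-vectors to the per-class subspace was tried
    and measurably slowed interval recovery (tiny per-dimension step caps
    plus corner optima), so the subspace informs reporting only.
    """
    d = table.d
    nb, nh = spec.target
    lower = np.concatenate([np.full(d, nb)] * 3)
    upper = np.concatenate([np.full(d, nh)] * 3)
    return lower, upper


def _round_sig(x: float, sig: int = 6) -> float:
    return float(f"{x:.{sig}g}")


def _dedup_key(rule: IntervalRule) -> tuple:
    return (
        rule.consequent,
        tuple((c.channel, _round_sig(c.lower), _round_sig(c.upper)) for c in rule.conditions),
    )


def mine_rules(
    train_table: FeatureTable,
    class_label: str,
    config: MinerConfig,
    island_seeds: Sequence[int] | None = None,
) -> list[tuple[IntervalRule, float]]:
    """Mine interval rules concluding ``class_label``.

    Runs ``config.islands`` independent optimisation processes (distinct
    seeds unless ``island_seeds`` says otherwise), decodes the union of
    their final populations, deduplicates, and ranks by training accuracy
    (desc), then condition count (asc), then discovery order.  Returns at
    most ``config.rules_kept`` ``(rule, train_accuracy)`` pairs.
    """
    if class_label not in train_table.labels:
        raise KeyError(f"class {class_label!r} absent from training table")
    if island_seeds is None:
        island_seeds = [config.seed + k for k in range(config.islands)]
    elif len(island_seeds) != config.islands:
        raise ValueError("need one seed per island")

    spec = fit_normalization(train_table)
    lower, upper = _search_box(train_table, spec)
    fitness = make_fitness(train_table, class_label, config.delta, spec)
    if logger.isEnabledFor(logging.DEBUG):
        sub_lo, sub_hi = class_subspace(train_table, class_label)
        logger.debug(
            "class %s subspace: %s", class_label,
            {c: (lo, hi) for c, lo, hi in zip(train_table.channels, sub_lo, sub_hi)},
        )

    candidates: list[tuple[IntervalRule, float]] = []
    seen: set[tuple] = set()
    for seed in island_seeds:
        result = optimize(fitness, config.sfoa_config(lower, upper, seed))
        for position in result.population.positions:
            sol = EncodedSolution.from_position(position, class_label)
            try:
                rule = decode(sol, config.delta, spec)
            except EmptyAntecedentError:
                continue
            key = _dedup_key(rule)
            if key in seen:
                continue
            seen.add(key)
            candidates.append((rule, accuracy(confusion(rule, train_table))))

    ranked = sorted(
        range(len(candidates)),
        key=lambda i: (-candidates[i][1], len(candidates[i][0].conditions), i),
    )
    return [candidates[i] for i in ranked[: config.rules_kept]]


def test_rules(
    rules: Sequence[IntervalRule | tuple[IntervalRule, float]],
    test_table: FeatureTable,
) -> list[tuple[IntervalRule, float]]:
    """Score rules on a held-out table; input order is preserved.
    Accepts bare rules or ``(rule, train_accuracy)`` pairs."""
    if len(rules) == 0:
        raise ValueError("no rules to test")
    out = []
    for item in rules:
        rule = item[0] if isinstance(item, tuple) else item
        out.append((rule, accuracy(confusion(rule, test_table))))
    return out


def stratified_split(
    table: FeatureTable, test_fraction: float, seed: int
) -> tuple[FeatureTable, FeatureTable]:
    """Per-class shuffled split preserving class ratios.

    Each class contributes ``round(test_fraction * n_class)`` test rows,
    with at least one row kept on each side when the class has >= 2 rows.
    """
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    test_mask = np.zeros(table.n, dtype=bool)
    for label in table.label_set:
        idx = np.nonzero(table.labels == label)[0]
        rng.shuffle(idx)
        k = int(round(test_fraction * len(idx)))
        if len(idx) >= 2:
            k = min(max(k, 1), len(idx) - 1)
        test_mask[idx[:k]] = True
    return table.subset(~test_mask), table.subset(test_mask)


@dataclass
class ExperimentResult:
    stats: dict[str, RunStats]
    top_rules: dict[str, list[tuple[IntervalRule, float, float]]]  # rule, train, test acc
    run_seeds: list[int] = field(default_factory=list)


def run_experiment(
    table: FeatureTable,
    config: MinerConfig,
    run_seeds: Sequence[int] | None = None,
) -> ExperimentResult:
    """Repeat the full protocol ``config.experiments`` times.

    Each run draws a fresh split seed and fresh island seeds, mines every
    class on the training partition and scores each class's top rule on
    the held-out partition.  Per-class Best/Worst/Mean/Median/Std of
    those test accuracies are returned alongside the final run's rules.
    """
    if config.experiments < 2:
        raise ValueError("need at least 2 independent experiments")
    if run_seeds is None:
        ss = np.random.SeedSequence(config.seed)
        run_seeds = [int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(config.experiments)]
    elif len(run_seeds) != config.experiments:
        raise ValueError("need one seed per experiment")

    classes = table.label_set
    per_class: dict[str, list[float]] = {c: [] for c in classes}
    last_rules: dict[str, list[tuple[IntervalRule, float, float]]] = {}
    for r, run_seed in enumerate(run_seeds):
        train, test = stratified_split(table, config.split_fraction, seed=run_seed)
        for label in classes:
            island_seeds = [run_seed + 7919 * (k + 1) for k in range(config.islands)]
            mined = mine_rules(train, label, config, island_seeds=island_seeds)
            if not mined:
                logger.warning("run %d: no rule decoded for class %s", r, label)
                continue
            scored = test_rules(mined, test)
            per_class[label].append(scored[0][1])
            last_rules[label] = [
                (rule, train_acc, test_acc)
                for (rule, train_acc), (_, test_acc) in zip(mined, scored)
            ]
    stats = {c: RunStats(vals) for c, vals in per_class.items() if vals}
    return ExperimentResult(stats=stats, top_rules=last_rules, run_seeds=list(run_seeds))
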