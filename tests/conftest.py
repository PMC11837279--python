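import numpy as np
import pytest

from sunrule.datamodel import FeatureTable, load_fixture_rules, load_fixture_table
from sunrule.rule_engine import IntervalRule, rule_from_dict


@pytest.fixture(scope="session")
def follicle_table() -> FeatureTable:
    return load_fixture_table("follicle", canonical_labels=True)


@pytest.fixture(scope="session")
def cl_table() -> FeatureTable:
    return load_fixture_table("cl", canonical_labels=True)


@pytest.fixture(scope="session")
def follicle_rules() -> list[IntervalRule]:
    return [rule_from_dict(d) for d in load_fixture_rules("follicle")]


@pytest.fixture(scope="session")
def cl_rules() -> list[IntervalRule]:
    return [rule_from_dict(d) for d in load_fixture_rules("cl")]


def naive_confusion(rule: IntervalRule, table: FeatureTable) -> tuple[int, int, int, int]:
    """Independent per-row oracle for confusion counting (no vectorization,
    no shared code with the package's implementation)."""
    tp = tn = fp = fn = 0
    for i in range(table.n):
        row = dict(zip(table.channels, table.values[i]))
        fires = all(c.lower <= row[c.channel] <= c.upper for c in rule.conditions)
        positive = table.labels[i] == rule.consequent
        if fires and positive:
            tp += 1
        elif fires and not positive:
            fp += 1
        elif not fires and positive:
            fn += 1
        else:
            tn += 1
    return tp, tn, fp, fn


def random_rule_and_table(
    rng: np.random.Generator, max_n: int = 200, max_d: int = 10
) -> tuple[IntervalRule, FeatureTable]:
    """A random table plus a random (possibly non-covering) rule on it."""
    n = int(rng.integers(1, max_n + 1))
    d = int(rng.integers(1, max_d + 1))
    channels = [f"C{j}" for j in range(d)]
    values = rng.uniform(-50, 50, size=(n, d))
    labels = rng.choice(np.array(["P", "N"], dtype=object), size=n)
    table = FeatureTable(values, channels, labels)
    k = int(rng.integers(1, d + 1))
    chosen = rng.choice(d, size=k, replace=False)
    conds = []
    for j in chosen:
        a, b = sorted(rng.uniform(-60, 60, size=2))
        conds.append((channels[j], a, b))
    rule = IntervalRule.make(str(rng.choice(["P", "N"])), conds)
    return rule, table
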