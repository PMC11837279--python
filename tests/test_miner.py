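import numpy as np
import pytest

from sunrule.datamodel import FeatureTable, apply_normalization, fit_normalization
from sunrule.miner import (
    EmptyAntecedentError,
    EncodedSolution,
    MinerConfig,
    RunStats,
    class_subspace,
    decode,
    make_fitness,
    mine_rules,
    run_experiment,
    stratified_split,
)
from sunrule.miner import test_rules as score_rules
from sunrule.rule_engine import IntervalRule, accuracy, confusion
from sunrule.synth import GeneratorSpec, generate


def small_table(seed=0, n=40, d=3, labels=("P", "N"), p=0.5):
    rng = np.random.default_rng(seed)
    values = rng.uniform(0, 100, size=(n, d))
    labs = rng.choice(np.array(labels, dtype=object), size=n, p=[p, 1 - p])
    return FeatureTable(values, [f"C{j}" for j in range(d)], labs)


def jaccard(a, b):
    inter = max(0.0, min(a[1], b[1]) - max(a[0], b[0]))
    union = max(a[1], b[1]) - min(a[0], b[0])
    return inter / union if union > 0 else 1.0


class TestDecode:
    def setup_method(self):
        self.table = FeatureTable(
            np.array([[0.0, 10.0, 100.0], [1.0, 20.0, 200.0]]),
            ["a", "b", "c"],
            np.array(["P", "N"], dtype=object),
        )
        self.spec = fit_normalization(self.table)

    def test_strict_threshold_selects_active_set(self):
        sol = EncodedSolution(
            np.array([0.7, 0.3, 0.51]), np.array([0.1, 0.1, 0.1]), np.array([0.9, 0.9, 0.9]), "P"
        )
        rule = decode(sol, 0.5, self.spec)
        assert rule.channels == ["a", "c"]

    def test_score_equal_to_delta_is_inactive(self):
        sol = EncodedSolution(
            np.array([0.5, 0.5, 0.8]), np.zeros(3), np.ones(3), "P"
        )
        rule = decode(sol, 0.5, self.spec)
        assert rule.channels == ["c"]

    def test_swap_on_decode(self):
        sol = EncodedSolution(
            np.array([0.9, 0.0, 0.0]), np.array([0.8, 0.0, 0.0]), np.array([0.2, 0.0, 0.0]), "P"
        )
        rule = decode(sol, 0.5, self.spec)
        # normalized (0.2, 0.8) on channel a spanning [0, 1] raw
        assert rule.conditions[0].lower == pytest.approx(0.2)
        assert rule.conditions[0].upper == pytest.approx(0.8)

    def test_no_active_attribute_raises(self):
        sol = EncodedSolution(np.array([0.1, 0.2, 0.3]), np.zeros(3), np.ones(3), "P")
        with pytest.raises(EmptyAntecedentError):
            decode(sol, 0.5, self.spec)

    def test_constant_channel_never_activates(self):
        t = FeatureTable(
            np.array([[5.0, 1.0], [5.0, 2.0]]), ["k", "x"], np.array(["P", "N"], dtype=object)
        )
        spec = fit_normalization(t)
        sol = EncodedSolution(np.array([0.9, 0.9]), np.zeros(2), np.ones(2), "P")
        rule = decode(sol, 0.5, spec)
        assert rule.channels == ["x"]

    def test_decoded_rules_always_valid(self):
        rng = np.random.default_rng(21)
        spec = fit_normalization(small_table())
        for _ in range(200):
            sol = EncodedSolution(rng.uniform(size=3), rng.uniform(size=3), rng.uniform(size=3), "P")
            try:
                rule = decode(sol, 0.5, spec)
            except EmptyAntecedentError:
                continue
            for c in rule.conditions:
                assert c.lower <= c.upper


class TestFitness:
    def test_empty_antecedent_scores_zero(self):
        table = small_table()
        fitness = make_fitness(table, "P", 0.5, fit_normalization(table))
        pos = np.concatenate([np.zeros(3), np.zeros(3), np.ones(3)])
        assert fitness(pos) == 0.0

    def test_full_range_solution_matches_majority_frequency(self):
        table = small_table(seed=5, n=100, p=0.6)
        spec = fit_normalization(table)
        fitness = make_fitness(table, "P", 0.5, spec)
        pos = np.concatenate([np.ones(3), np.zeros(3), np.ones(3)])
        freq = np.mean(table.labels == "P")
        assert fitness(pos) == pytest.approx(freq)

    def test_planted_rule_scores_one_on_noiseless_data(self):
        table, truth = generate(GeneratorSpec(n=200, d=4, planted={0: (0.2, 0.7)}, seed=3))
        assert accuracy(confusion(truth, table)) == 1.0

    def test_fast_path_equals_decode_confusion_route(self):
        # dual route: the vectorized fitness must agree with the object path
        table = small_table(seed=9, n=60, d=4)
        spec = fit_normalization(table)
        fitness = make_fitness(table, "P", 0.5, spec)
        rng = np.random.default_rng(17)
        for _ in range(100):
            pos = rng.uniform(size=12)
            sol = EncodedSolution.from_position(pos, "P")
            try:
                rule = decode(sol, 0.5, spec)
            except EmptyAntecedentError:
                assert fitness(pos) == 0.0
                continue
            assert fitness(pos) == pytest.approx(accuracy(confusion(rule, table)), abs=1e-12)

    def test_fixture_rule_accuracy_via_encoding(self, cl_table):
        # encode the printed one-condition rule and score it through fitness
        spec = fit_normalization(cl_table)
        d = cl_table.d
        j = cl_table.channels.index("T2620")
        y_t = np.zeros(d)
        y_t[j] = 0.9
        y_a, y_h = np.zeros(d), np.zeros(d)
        y_a[j] = apply_normalization(spec, 739.0, "T2620")
        y_h[j] = apply_normalization(spec, 963.0, "T2620")
        fitness = make_fitness(cl_table, "P", 0.5, spec)
        pos = np.concatenate([y_t, y_a, y_h])
        assert fitness(pos) == pytest.approx(11 / 19)


class TestClassSubspace:
    def test_extrema_of_class_rows(self):
        t = FeatureTable(
            np.array([[2.0], [7.0], [5.0], [100.0]]),
            ["X"],
            np.array(["C", "C", "C", "D"], dtype=object),
        )
        lo, hi = class_subspace(t, "C")
        assert (lo[0], hi[0]) == (2.0, 7.0)

    def test_single_row_degenerate_box(self):
        t = FeatureTable(np.array([[4.0], [9.0]]), ["X"], np.array(["C", "D"], dtype=object))
        lo, hi = class_subspace(t, "C")
        assert lo[0] == hi[0] == 4.0

    def test_cl_fixture_class_p_temp1(self, cl_table):
        # frozen by scanning the twelve printed class-P rows: min 31, max 41
        lo, hi = class_subspace(cl_table, "P")
        j = cl_table.channels.index("TEMP1")
        assert (lo[j], hi[j]) == (31.0, 41.0)

    def test_absent_class_key_error(self, cl_table):
        with pytest.raises(KeyError):
            class_subspace(cl_table, "Z")


class TestMineRules:
    def test_planted_recovery_smoke(self):
        table, truth = generate(GeneratorSpec(n=200, d=4, planted={0: (0.2, 0.6), 2: (0.3, 0.8)}, seed=1))
        cfg = MinerConfig(iterations=80, islands=1, seed=1)
        mined = mine_rules(table, "P", cfg)
        assert mined[0][1] >= 0.9

    def test_rules_kept_truncates(self):
        table = small_table(seed=2, n=60)
        mined = mine_rules(table, "P", MinerConfig(iterations=30, islands=2, rules_kept=4, seed=2))
        assert 1 <= len(mined) <= 4

    def test_ranked_by_train_accuracy_descending(self):
        table = small_table(seed=3, n=60)
        mined = mine_rules(table, "P", MinerConfig(iterations=40, rules_kept=8, seed=3))
        accs = [a for _, a in mined]
        assert accs == sorted(accs, reverse=True)

    def test_island_independence_same_seed_same_rules(self):
        table = small_table(seed=4, n=60)
        cfg2 = MinerConfig(iterations=30, islands=2, seed=4)
        cfg1 = MinerConfig(iterations=30, islands=1, seed=4)
        two = mine_rules(table, "P", cfg2, island_seeds=[5, 5])
        one = mine_rules(table, "P", cfg1, island_seeds=[5])
        assert two == one

    def test_monotone_consistency_vs_full_range_rule(self):
        table = small_table(seed=6, n=80, p=0.55)
        mined = mine_rules(table, "P", MinerConfig(iterations=60, seed=6))
        full = IntervalRule.make(
            "P", [(ch, table.column(ch).min(), table.column(ch).max()) for ch in table.channels]
        )
        assert mined[0][1] >= accuracy(confusion(full, table))

    def test_absent_class_key_error(self):
        with pytest.raises(KeyError):
            mine_rules(small_table(), "Q", MinerConfig(iterations=5))


class TestTestRules:
    def test_perfect_planted_rule_scores_one(self):
        table, truth = generate(GeneratorSpec(n=100, d=3, planted={1: (0.2, 0.8)}, seed=8))
        scored = score_rules([truth], table)
        assert scored[0][1] == 1.0

    def test_uncovering_rule_on_all_negative_table_scores_one(self):
        t = FeatureTable(np.array([[1.0], [2.0]]), ["X"], np.array(["N", "N"], dtype=object))
        rule = IntervalRule.make("P", [("X", 50, 60)])
        assert score_rules([rule], t)[0][1] == 1.0  # both rows are true negatives

    def test_order_preserved(self, cl_rules, cl_table):
        scored = score_rules(cl_rules[:3], cl_table)
        assert [r for r, _ in scored] == cl_rules[:3]

    def test_empty_rules_rejected(self, cl_table):
        with pytest.raises(ValueError):
            score_rules([], cl_table)


class TestStratifiedSplit:
    def test_partition_is_disjoint_and_complete(self):
        table = small_table(seed=10, n=100)
        train, test = stratified_split(table, 0.2, seed=0)
        assert train.n + test.n == 100

    def test_class_ratios_preserved(self):
        table = small_table(seed=11, n=200, p=0.7)
        train, test = stratified_split(table, 0.2, seed=1)
        p_all = np.mean(table.labels == "P")
        assert np.mean(train.labels == "P") == pytest.approx(p_all, abs=0.05)
        assert np.mean(test.labels == "P") == pytest.approx(p_all, abs=0.08)

    def test_deterministic(self):
        table = small_table(seed=12, n=50)
        a = stratified_split(table, 0.2, seed=3)
        b = stratified_split(table, 0.2, seed=3)
        np.testing.assert_array_equal(a[0].values, b[0].values)

    def test_every_class_on_both_sides(self):
        rng = np.random.default_rng(13)
        labels = np.array(["P"] * 6 + ["N"] * 24, dtype=object)
        table = FeatureTable(rng.uniform(0, 1, size=(30, 3)), ["a", "b", "c"], labels)
        train, test = stratified_split(table, 0.2, seed=5)
        assert set(train.labels) == set(test.labels) == {"P", "N"}

    def test_bad_fraction(self):
        with pytest.raises(ValueError):
            stratified_split(small_table(), 1.5, seed=0)


class TestRunExperiment:
    def test_identical_run_seeds_give_zero_std(self):
        table, _ = generate(GeneratorSpec(n=120, d=3, planted={0: (0.2, 0.8)}, seed=20))
        cfg = MinerConfig(iterations=20, islands=1, experiments=3, seed=20)
        res = run_experiment(table, cfg, run_seeds=[7, 7, 7])
        for stats in res.stats.values():
            assert stats.std == 0.0

    def test_order_statistics(self):
        table, _ = generate(GeneratorSpec(n=120, d=3, planted={0: (0.2, 0.8)}, seed=21))
        cfg = MinerConfig(iterations=20, islands=1, experiments=4, seed=21)
        res = run_experiment(table, cfg)
        for stats in res.stats.values():
            assert stats.best >= stats.median >= stats.worst
            assert stats.best >= stats.mean >= stats.worst

    def test_noise_floor(self):
        # 10% label flips: mean test accuracy of the recovered rule stays
        # within [1 - noise - margin, 1]
        table, _ = generate(
            GeneratorSpec(n=300, d=4, planted={0: (0.25, 0.75), 2: (0.2, 0.8)}, label_noise=0.1, seed=22)
        )
        cfg = MinerConfig(iterations=100, islands=1, experiments=4, seed=22)
        res = run_experiment(table, cfg)
        assert 0.80 <= res.stats["P"].mean <= 1.0

    def test_needs_two_experiments(self):
        with pytest.raises(ValueError):
            run_experiment(small_table(), MinerConfig(experiments=1))


class TestRunStats:
    def test_stats_of_known_values(self):
        s = RunStats([0.5, 0.7, 0.9])
        assert s.best == 0.9 and s.worst == 0.5
        assert s.mean == pytest.approx(0.7)
        assert s.median == 0.7
        assert s.std == pytest.approx(np.std([0.5, 0.7, 0.9]))
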