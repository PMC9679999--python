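"""Rule proposal, evaluation, filtering and the iterative level procedure."""

import numpy as np
import pandas as pd
import pytest

import glymotif as gm
from glymotif.rules import Rule, RuleCondition


def _planted(n=200, seed=0, noise=0.0, two_stage=False):
    """Features with one (or two) informative binary columns plus distractors.

    Binders are a minority of the library, as on a real array; in the
    two-stage design the predominant motif is clearly rarer than the blocker so the
    level order is determined (the motif-A rule has the higher precision).
    """
    rng = np.random.default_rng(seed)
    X = pd.DataFrame({
        "motifA": (rng.random(n) < (0.35 if two_stage else 0.25)).astype(int),
        "motifB": (rng.random(n) < 0.3).astype(int),
        "noise1": rng.integers(0, 4, n),
        "noise2": rng.integers(0, 2, n),
        "constant": np.zeros(n, dtype=int),
    }, index=[f"G{i}" for i in range(n)])
    if two_stage:
        y = ((X["motifA"] == 1) & (X["motifB"] == 0)).astype(int)
    else:
        y = (X["motifA"] == 1).astype(int)
    if noise:
        flip = rng.random(n) < noise
        y = y ^ flip.astype(int)
    return X, y


def _rule(*conds):
    return Rule(conditions=tuple(RuleCondition(f, op, t) for f, op, t in conds))


class TestEvaluateRule:
    def test_counting_example(self):
        # 10 satisfiers of which 8 bound; 40 bound in total
        X = pd.DataFrame({"f": [1] * 10 + [0] * 90})
        y = pd.Series([1] * 8 + [0] * 2 + [1] * 32 + [0] * 58)
        p, r = gm.evaluate_rule(_rule(("f", ">=", 0.5)), X, y)
        assert (p, r) == (0.8, 0.2)

    def test_trivial_true_rule(self):
        X = pd.DataFrame({"f": [1] * 50})
        y = pd.Series([1] * 20 + [0] * 30)
        p, r = gm.evaluate_rule(_rule(("f", ">=", 0.5)), X, y)
        assert p == pytest.approx(0.4)  # base rate
        assert r == 1.0

    def test_unsatisfied_rule_discarded(self):
        X = pd.DataFrame({"f": [0] * 10})
        y = pd.Series([1] * 5 + [0] * 5)
        assert gm.evaluate_rule(_rule(("f", ">=", 0.5)), X, y) is None

    def test_matches_brute_force_on_random_fixtures(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            n = int(rng.integers(5, 51))
            X = pd.DataFrame({
                "a": rng.integers(0, 3, n),
                "b": rng.integers(0, 2, n),
            })
            y = pd.Series(rng.integers(0, 2, n))
            rule = _rule(("a", ">=", 1.5), ("b", "<", 0.5))
            res = gm.evaluate_rule(rule, X, y)
            sat = [(X["a"][i] >= 1.5) and (X["b"][i] < 0.5) for i in range(n)]
            hits = sum(1 for i in range(n) if sat[i] and y[i] == 1)
            nb = int((y == 1).sum())
            if sum(sat) == 0:
                assert res is None
            else:
                p, r = res
                assert p == hits / sum(sat)
                assert r == (hits / nb if nb else 0.0)


class TestFilterValid:
    def test_inclusive_boundaries(self):
        cfg = gm.MiningConfig()
        keep = Rule(conditions=(RuleCondition("f", ">=", 0.5),),
                    precision=0.30, recall=0.10, estimator_support=0.15)
        assert gm.filter_valid([keep], cfg) == [keep]

    @pytest.mark.parametrize("p,r,s", [(0.29, 0.5, 0.5), (0.5, 0.09, 0.5),
                                       (0.5, 0.5, 0.14)])
    def test_below_any_threshold_dropped(self, p, r, s):
        cfg = gm.MiningConfig()
        rule = Rule(conditions=(RuleCondition("f", ">=", 0.5),),
                    precision=p, recall=r, estimator_support=s)
        assert gm.filter_valid([rule], cfg) == []


class TestProposeRules:
    def test_perfect_feature_has_high_support(self):
        hits = 0
        for seed in range(10):
            X, y = _planted(seed=seed)
            cands = gm.propose_rules(X, y, gm.MiningConfig(seed=seed))
            by_feat = {c.conditions[0].feature: c for c in cands
                       if len(c.conditions) == 1}
            if "motifA" in by_feat and by_feat["motifA"].estimator_support >= 0.9:
                hits += 1
        assert hits >= 9

    def test_permuted_labels_yield_no_valid_rule(self):
        null_ok = 0
        for seed in range(10):
            X, y = _planted(seed=seed)
            rng = np.random.default_rng(seed + 100)
            y_perm = pd.Series(rng.permutation(y.values), index=y.index)
            rs = gm.mine_ruleset(X, y_perm, gm.MiningConfig(seed=seed))
            if not rs.levels:
                null_ok += 1
        assert null_ok >= 9

    def test_constant_feature_never_used(self):
        for seed in range(3):
            X, y = _planted(seed=seed)
            cands = gm.propose_rules(X, y, gm.MiningConfig(seed=seed))
            assert all(c.feature != "constant"
                       for r in cands for c in r.conditions)

    def test_class_balance_required(self):
        X, y = _planted(n=50, seed=0)
        y[:] = 1
        y.iloc[:3] = 0
        with pytest.raises(ValueError, match="class balance"):
            gm.propose_rules(X, y, gm.MiningConfig(seed=0))


class TestMineRuleset:
    def test_two_stage_lectin_two_levels_stop(self):
        for seed in range(5):
            X, y = _planted(seed=seed, two_stage=True)
            rs = gm.mine_ruleset(X, y, gm.MiningConfig(seed=seed,
                                                       min_split_size=10**6))
            assert len(rs.levels) == 2, rs.stop_reason
            lvl1, lvl2 = rs.primary_rules
            assert lvl1.conditions[0].feature == "motifA"
            assert lvl2.conditions[0].feature == "motifB"
            assert lvl2.precision == 1.0
            assert rs.stop_reason == "reached precision 1.0"

    def test_single_perfect_rule_stops_at_level_one(self):
        X, y = _planted(seed=1)
        rs = gm.mine_ruleset(X, y, gm.MiningConfig(seed=1))
        assert len(rs.levels) == 1
        assert rs.stop_reason == "reached precision 1.0"

    def test_empty_ruleset_logs_stop_reason(self):
        X, y = _planted(seed=2)
        rng = np.random.default_rng(0)
        y_perm = pd.Series(rng.permutation(y.values), index=y.index)
        rs = gm.mine_ruleset(X, y_perm, gm.MiningConfig(seed=2))
        assert rs.levels == [] and rs.stop_reason

    def test_deterministic_given_seed(self):
        X, y = _planted(seed=3, two_stage=True, noise=0.05)
        a = gm.mine_ruleset(X, y, gm.MiningConfig(seed=3)).to_json()
        b = gm.mine_ruleset(X, y, gm.MiningConfig(seed=3)).to_json()
        assert a == b

    def test_level_precision_strictly_increases(self):
        for seed in range(5):
            X, y = _planted(seed=seed, two_stage=True, noise=0.03)
            rs = gm.mine_ruleset(X, y, gm.MiningConfig(seed=seed))
            precs = [r.precision for r in rs.primary_rules]
            assert all(b > a for a, b in zip(precs, precs[1:]))

    def test_small_fixture_full_set_fallback_noted(self):
        X, y = _planted(n=20, seed=4)
        rs = gm.mine_ruleset(X, y, gm.MiningConfig(seed=4))
        assert any("full set" in n for n in rs.notes)

    def test_planted_motif_recovery_with_label_noise(self):
        hits = 0
        for seed in range(10):
            X, y = _planted(seed=seed, noise=0.05)
            rs = gm.mine_ruleset(X, y, gm.MiningConfig(seed=seed))
            if rs.levels and rs.primary_rules[0].conditions[0].feature == "motifA":
                hits += 1
        assert hits >= 9
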