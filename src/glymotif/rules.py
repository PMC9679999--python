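"""Interpretable binding-rule extraction from shallow tree ensembles.

For each lectin, an ensemble of 50 depth-one decision trees is bagged on a
stratified 80% training split of the glycan feature matrix; every
root-to-"bound"-leaf path becomes a candidate conjunction. Candidates are kept
when, on the held-out 20%, precision ≥ 0.3 and recall ≥ 0.1, and when at least
15% of the estimators proposed the (canonicalized) conjunction. If no depth-one
rule qualifies, depth-two trees are tried. Rule levels are mined iteratively:
each subsequent level is mined on the subset of glycans satisfying the previous
level's rule and is accepted only if it strictly improves precision; mining
stops at precision 1.0, after five levels, or when no valid rule remains. When
two rules qualify at a level they are reported as alternatives (1a/1b).

Precision = bound ∧ satisfies / satisfies; recall = bound ∧ satisfies / bound.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split
from sklearn.tree import DecisionTreeClassifier

from .features import FeatureMatrix

__all__ = [
    "RuleCondition",
    "Rule",
    "RuleSet",
    "MiningConfig",
    "propose_rules",
    "evaluate_rule",
    "filter_valid",
    "mine_ruleset",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class RuleCondition:
    """One feature-threshold test; comparator is ">=" or "<"."""

    feature: str
    comparator: str
    threshold: float

    def __post_init__(self):
        if self.comparator not in (">=", "<"):
            raise ValueError(f"bad comparator {self.comparator!r}")

    def evaluate(self, features: pd.DataFrame) -> pd.Series:
        col = features[self.feature]
        return col >= self.threshold if self.comparator == ">=" else col < self.threshold

    def __str__(self) -> str:
        return f"{self.feature} {self.comparator} {self.threshold:g}"


@dataclass
class Rule:
    """Conjunction of 1-2 conditions with its quality metrics."""

    conditions: tuple[RuleCondition, ...]
    precision: float = float("nan")
    recall: float = float("nan")
    estimator_support: float = 0.0
    level: int = 0
    alternative_tag: str | None = None

    def satisfies(self, features: pd.DataFrame) -> pd.Series:
        mask = pd.Series(True, index=features.index)
        for cond in self.conditions:
            mask &= cond.evaluate(features)
        return mask

    def canonical(self) -> tuple:
        return tuple(sorted((c.feature, c.comparator, c.threshold)
                            for c in self.conditions))

    def describe(self) -> str:
        return " AND ".join(str(c) for c in self.conditions)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["conditions"] = [asdict(c) for c in self.conditions]
        return d


@dataclass
class RuleSet:
    """Ordered rule levels for one lectin, with alternatives and stop reason."""

    lectin_id: str
    levels: list[list[Rule]] = field(default_factory=list)  # alternatives per level
    stop_reason: str = ""
    notes: list[str] = field(default_factory=list)

    @property
    def primary_rules(self) -> list[Rule]:
        return [alts[0] for alts in self.levels]

    def cumulative_mask(self, features: pd.DataFrame, upto: int | None = None) -> pd.Series:
        """Glycans satisfying the primary rule of every level (up to ``upto``)."""
        mask = pd.Series(True, index=features.index)
        for alts in (self.levels if upto is None else self.levels[:upto]):
            mask &= alts[0].satisfies(features)
        return mask

    def to_dict(self) -> dict:
        return {
            "lectin_id": self.lectin_id,
            "levels": [[r.to_dict() for r in alts] for alts in self.levels],
            "stop_reason": self.stop_reason,
            "notes": self.notes,
        }

    def to_json(self, path: str | None = None) -> str:
        blob = json.dumps(self.to_dict(), indent=2)
        if path:
            with open(path, "w") as fh:
                fh.write(blob)
        return blob


@dataclass
class MiningConfig:
    n_estimators: int = 50
    max_depth_first: int = 1
    max_depth_fallback: int = 2
    train_fraction: float = 0.8
    min_precision: float = 0.3
    min_recall: float = 0.1
    min_estimator_support: float = 0.15
    max_levels: int = 5
    stop_precision: float = 1.0
    min_split_size: int = 25   # below this, evaluate on the full set
    seed: int = 0


def _snap(threshold: float) -> float:
    """Snap tree split thresholds to half-integers for readable count rules."""
    return round(threshold * 2.0) / 2.0


def _paths_to_bound(tree: DecisionTreeClassifier, feature_names: list[str]) -> list[tuple]:
    """Canonical conjunctions for every root-to-leaf path predicting 'bound'."""
    t = tree.tree_
    out = []

    def walk(node: int, conds: list[tuple[str, str, float]]):
        if t.children_left[node] == -1:  # leaf
            counts = t.value[node][0]
            if len(counts) > 1 and counts[1] > counts[0]:
                out.append(tuple(sorted(conds)))
            return
        feat = feature_names[t.feature[node]]
        thr = _snap(float(t.threshold[node]))
        walk(t.children_left[node], conds + [(feat, "<", thr)])
        walk(t.children_right[node], conds + [(feat, ">=", thr)])

    walk(0, [])
    return out


def propose_rules(
    features: pd.DataFrame,
    labels: pd.Series,
    config: MiningConfig,
    max_depth: int | None = None,
    rng: np.random.Generator | None = None,
) -> list[Rule]:
    """Fit a bagged ensemble of depth-limited trees and harvest candidate
    conjunctions with their estimator support (fraction of trees proposing
    the canonical conjunction)."""
    n_bound = int((labels == 1).sum())
    n_unbound = int((labels == 0).sum())
    if n_bound < 5 or n_unbound < 5:
        raise ValueError(
            f"insufficient class balance: {n_bound} bound / {n_unbound} unbound "
            "(need >=5 of each)")
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    depth = max_depth if max_depth is not None else config.max_depth_first
    X = features.to_numpy(dtype=float)
    y = labels.to_numpy(dtype=int)
    names = list(features.columns)
    counts: dict[tuple, int] = {}
    n = len(labels)
    for _ in range(config.n_estimators):
        idx = rng.integers(0, n, size=n)  # bootstrap (bagging)
        clf = DecisionTreeClassifier(
            max_depth=depth, criterion="gini",
            random_state=int(rng.integers(0, 2**31 - 1)))
        clf.fit(X[idx], y[idx])
        for conj in set(_paths_to_bound(clf, names)):
            counts[conj] = counts.get(conj, 0) + 1
    rules = []
    for conj, cnt in counts.items():
        conds = tuple(RuleCondition(f, op, thr) for f, op, thr in conj)
        rules.append(Rule(conditions=conds,
                          estimator_support=cnt / config.n_estimators))
    return rules


def evaluate_rule(
    rule: Rule, features: pd.DataFrame, labels: pd.Series
) -> tuple[float, float] | None:
    """(precision, recall) on the given evaluation set; None when no glycan
    satisfies the rule (undefined precision; the rule is discarded)."""
    sat = rule.satisfies(features)
    n_sat = int(sat.sum())
    if n_sat == 0:
        log.info("rule %s discarded: satisfied by no glycan", rule.describe())
        return None
    bound = labels == 1
    hits = int((sat & bound).sum())
    n_bound = int(bound.sum())
    precision = hits / n_sat
    recall = hits / n_bound if n_bound else 0.0
    return precision, recall


def filter_valid(candidates: list[Rule], config: MiningConfig) -> list[Rule]:
    """Keep rules meeting the precision/recall/support thresholds (inclusive)."""
    return [r for r in candidates
            if r.precision >= config.min_precision
            and r.recall >= config.min_recall
            and r.estimator_support >= config.min_estimator_support]


def _rank_key(rule: Rule) -> tuple:
    return (-rule.precision, -rule.recall, -rule.estimator_support,
            rule.canonical())


def _mine_level(train_X, train_y, eval_X, eval_y, config, rng) -> list[Rule]:
    """Candidates at one level: depth-1 ensemble, depth-2 fallback."""
    for depth in (config.max_depth_first, config.max_depth_fallback):
        cands = propose_rules(train_X, train_y, config, max_depth=depth, rng=rng)
        evaluated = []
        for rule in cands:
            pr = evaluate_rule(rule, eval_X, eval_y)
            if pr is None:
                continue
            rule.precision, rule.recall = pr
            evaluated.append(rule)
        valid = filter_valid(evaluated, config)
        if valid:
            return sorted(valid, key=_rank_key)
    return []


def mine_ruleset(
    features: FeatureMatrix | pd.DataFrame,
    labels: pd.Series,
    config: MiningConfig | None = None,
    lectin_id: str = "lectin",
) -> RuleSet:
    """Iterative multi-level rule mining for one lectin.

    The ensemble trains on a stratified 80% split and rules are scored on the
    held-out 20% (full set, with a note, below ``min_split_size`` glycans).
    Levels after the first are mined on the subset satisfying the previous
    level and must strictly improve precision.
    """
    config = config or MiningConfig()
    X = features.values if isinstance(features, FeatureMatrix) else features
    labels = labels.reindex(X.index)
    rng = np.random.default_rng(config.seed)
    rs = RuleSet(lectin_id=lectin_id)

    if len(X) < config.min_split_size:
        train_X = eval_X = X
        train_y = eval_y = labels
        rs.notes.append(
            f"fewer than {config.min_split_size} glycans: evaluated on the full set")
    else:
        tr_idx, te_idx = train_test_split(
            X.index, train_size=config.train_fraction,
            stratify=labels, random_state=config.seed)
        train_X, eval_X = X.loc[tr_idx], X.loc[te_idx]
        train_y, eval_y = labels.loc[tr_idx], labels.loc[te_idx]

    prev_precision = -np.inf
    for level in range(1, config.max_levels + 1):
        try:
            ranked = _mine_level(train_X, train_y, eval_X, eval_y, config, rng)
        except ValueError as exc:
            rs.stop_reason = f"no further rule: {exc}"
            break
        if not ranked:
            rs.stop_reason = "no valid rule at depths 1-2"
            break
        best = ranked[0]
        if level > 1 and best.precision <= prev_precision:
            rs.stop_reason = "no rule improved precision"
            break
        alts = ranked[:2]
        for i, rule in enumerate(alts):
            rule.level = level
            rule.alternative_tag = ("ab"[i] if len(alts) > 1 else None)
        rs.levels.append(alts)
        prev_precision = best.precision
        if best.precision >= config.stop_precision:
            rs.stop_reason = "reached precision 1.0"
            break
        sat_train = best.satisfies(train_X)
        sat_eval = best.satisfies(eval_X)
        train_X, train_y = train_X[sat_train], train_y[sat_train]
        eval_X, eval_y = eval_X[sat_eval], eval_y[sat_eval]
    else:
        rs.stop_reason = f"reached {config.max_levels} levels"
    if not rs.stop_reason:
        rs.stop_reason = f"reached {config.max_levels} levels"
    return rs
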