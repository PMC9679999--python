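"""Self-validation experiments: ground-truth recovery on planted designs.

Each function runs a complete simulated study — library generation, scan
simulation, Z-score processing, featurization, mining/contrast/clustering —
and measures how well the pipeline recovers what was planted. They are used
by the test suite and the reproduction script; all randomness is seeded.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .arrays import binding_threshold, process_arrays, stouffer_combine
from .cluster import cluster_profiles
from .features import build_feature_matrix, default_catalog
from .glycans import parse_condensed, to_canonical
from .report import contrast_features
from .rules import MiningConfig, Rule, RuleCondition, evaluate_rule, mine_ruleset
from .simulate import (
    PLANTED_RULE_FEATURES,
    SimulationConfig,
    generate_library,
    lectin_family_panels,
    planted_inhibitor_panel,
    planted_rule_panel,
    simulate_dataset,
)

__all__ = [
    "threshold_check",
    "stouffer_max_deviation",
    "rule_metric_mismatches",
    "planted_rule_recovery",
    "inhibitor_recovery",
    "two_level_stop_check",
    "cluster_separation",
    "library_roundtrip_fraction",
]

INHIBITOR_FEATURES = ("bisecting GlcNAc",)


def threshold_check(p: float = 0.05) -> float:
    """The binding cutoff from the package's inverse-normal utility."""
    return round(binding_threshold(p), 3)


def stouffer_max_deviation(n_profiles: int = 1000, seed: int = 0) -> float:
    """Max |vectorized − scalar-loop| Stouffer score over random profiles with
    2-6 concentrations each."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_profiles):
        n_conc = int(rng.integers(2, 7))
        n_gly = int(rng.integers(3, 25))
        zs = [pd.Series(rng.normal(size=n_gly)) for _ in range(n_conc)]
        combined = stouffer_combine(zs)
        for g in range(n_gly):
            oracle = sum(z.iloc[g] for z in zs) / np.sqrt(n_conc)
            worst = max(worst, abs(combined.iloc[g] - oracle))
    return worst


def rule_metric_mismatches(n_fixtures: int = 100, seed: int = 0) -> int:
    """Number of random ≤50-glycan fixtures where evaluate_rule disagrees with
    exhaustive counting (expected 0)."""
    rng = np.random.default_rng(seed)
    mismatches = 0
    for _ in range(n_fixtures):
        n = int(rng.integers(5, 51))
        X = pd.DataFrame({"a": rng.integers(0, 3, n), "b": rng.integers(0, 2, n)})
        y = pd.Series(rng.integers(0, 2, n))
        rule = Rule(conditions=(RuleCondition("a", ">=", 1.5),
                                RuleCondition("b", "<", 0.5)))
        res = evaluate_rule(rule, X, y)
        sat = [(X["a"][i] >= 1.5) and (X["b"][i] < 0.5) for i in range(n)]
        hits = sum(1 for i in range(n) if sat[i] and y[i] == 1)
        n_bound = int((y == 1).sum())
        if sum(sat) == 0:
            ok = res is None
        else:
            ok = res == (hits / sum(sat), (hits / n_bound if n_bound else 0.0))
        mismatches += not ok
    return mismatches


def _mine_planted(panel, seed, n_glycans, spot_noise_cv, mining_config):
    cfg = SimulationConfig(n_glycans=n_glycans, seed=seed,
                           spot_noise_cv=spot_noise_cv)
    scans, library, _ = simulate_dataset(panel, cfg)
    matrix, _ = process_arrays(scans)
    gids = [gid for gid, _ in library if gid in matrix.labels.index]
    graphs = {gid: parse_condensed(s) for gid, s in library}
    features = build_feature_matrix([graphs[g] for g in gids],
                                    default_catalog(), gids)
    ruleset = mine_ruleset(features, matrix.labels["TGT"], mining_config, "TGT")
    return ruleset, features, matrix


def planted_rule_recovery(seeds=range(10), n_glycans: int = 200) -> dict:
    """Fraction of seeds where the mined level-1 rule names the planted
    disaccharide with held-out precision and recall ≥ 0.9 (4 concentrations,
    15% spot CV, 5% per-array label noise)."""
    successes, details = 0, []
    for seed in seeds:
        rs, _, _ = _mine_planted(planted_rule_panel(label_noise=0.05), seed,
                                 n_glycans, 0.15, MiningConfig(seed=seed))
        ok, feat, prec, rec = False, None, float("nan"), float("nan")
        if rs.levels:
            rule = rs.primary_rules[0]
            feat = rule.conditions[0].feature
            prec, rec = rule.precision, rule.recall
            ok = (feat in PLANTED_RULE_FEATURES and prec >= 0.9 and rec >= 0.9)
        successes += ok
        details.append({"seed": int(seed), "feature": feat,
                        "precision": prec, "recall": rec, "ok": bool(ok)})
    return {"n_success": successes, "n_seeds": len(details), "details": details}


def inhibitor_recovery(seeds=range(10), n_glycans: int = 300) -> dict:
    """Fraction of seeds where the bound-vs-unbound contrast within the
    level-1 rule subset ranks the planted hard inhibitor first with negative
    direction. Rules are scored on the full analyzed set here so the level-1
    subset is the predominant-motif stratum on every seed."""
    successes, details = 0, []
    for seed in seeds:
        config = MiningConfig(seed=seed, min_split_size=10**9)
        rs, features, matrix = _mine_planted(
            planted_inhibitor_panel(label_noise=0.05), seed, n_glycans, 0.15,
            config)
        contrasts = contrast_features(rs, features, matrix.labels["TGT"])
        ok, top = False, None
        if contrasts:
            c = contrasts[0]
            top = c.feature
            ok = (c.feature in INHIBITOR_FEATURES and c.direction == -1
                  and c.q_value <= 0.05)
        successes += ok
        details.append({"seed": int(seed), "top_feature": top, "ok": bool(ok)})
    return {"n_success": successes, "n_seeds": len(details), "details": details}


def two_level_stop_check(seeds=range(10), n_glycans: int = 300) -> dict:
    """Fraction of seeds where the noiseless two-stage lectin (predominant
    motif AND inhibitor absent) yields exactly two rule levels terminating at
    precision 1.0."""
    successes, details = 0, []
    for seed in seeds:
        config = MiningConfig(seed=seed, min_split_size=10**9)
        rs, _, _ = _mine_planted(planted_inhibitor_panel(label_noise=0.0),
                                 seed, n_glycans, 0.0, config)
        ok = (len(rs.levels) == 2
              and rs.stop_reason == "reached precision 1.0"
              and rs.primary_rules[-1].precision == 1.0)
        successes += ok
        details.append({"seed": int(seed), "n_levels": len(rs.levels),
                        "stop": rs.stop_reason, "ok": bool(ok)})
    return {"n_success": successes, "n_seeds": len(details), "details": details}


def cluster_separation(seeds=range(10), n_glycans: int = 200) -> dict:
    """Fraction of seeds where a k=2 cut of the average-linkage Pearson tree
    separates the two planted five-lectin families exactly (15% spot CV)."""
    successes, details = 0, []
    for seed in seeds:
        cfg = SimulationConfig(n_glycans=n_glycans, seed=seed,
                               spot_noise_cv=0.15)
        scans, _, _ = simulate_dataset(lectin_family_panels(), cfg)
        matrix, _ = process_arrays(scans)
        result = cluster_profiles(matrix.processed, axis="lectins")
        flat = result.flat_clusters(2)
        a = {flat[l] for l in flat if l.startswith("FamA")}
        b = {flat[l] for l in flat if l.startswith("FamB")}
        ok = len(a) == 1 and len(b) == 1 and a != b
        successes += ok
        details.append({"seed": int(seed), "ok": bool(ok)})
    return {"n_success": successes, "n_seeds": len(details), "details": details}


def library_roundtrip_fraction(n_structures: int = 1000, per_library: int = 200,
                               seed: int = 0) -> float:
    """Fraction of generated structures whose canonical string reparses to an
    isomorphic graph, over several independent libraries."""
    n_libraries = int(np.ceil(n_structures / per_library))
    total, ok = 0, 0
    for i in range(n_libraries):
        lib = generate_library(SimulationConfig(n_glycans=per_library,
                                                seed=seed + i))
        for _, s in lib:
            total += 1
            g = parse_condensed(s)
            canon = to_canonical(g)
            ok += to_canonical(parse_condensed(canon)) == canon
        if total >= n_structures:
            break
    return ok / total
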