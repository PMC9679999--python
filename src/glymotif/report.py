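"""Per-lectin annotation reports: Prefers / Tolerates / Inhibited-by candidates.

After rule mining, glycans satisfying the level-1 rule are contrasted feature
by feature between binders and non-binders (exact 2×2 test, two-sided, with
Benjamini-Hochberg adjustment across features). Features enriched among
binders are enhancer candidates; features enriched among non-binders are
inhibitor candidates. Bound glycans not covered by any rule are grouped by
their shared curated features as additional-motif candidates. The statistical
contrast automates what is otherwise a manual comparison step and is labelled
as such in the output.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import pandas as pd
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

from .features import FeatureMatrix
from .rules import RuleSet

__all__ = [
    "FeatureContrast",
    "LectinReport",
    "contrast_features",
    "uncovered_binders",
    "tolerated_features",
    "build_report",
    "render_report",
]

log = logging.getLogger(__name__)

REPORT_SCHEMA_VERSION = "1.0"


@dataclass
class FeatureContrast:
    """2×2 association of one feature with binding in the rule-satisfying set."""

    feature: str
    present_bound: int
    present_unbound: int
    absent_bound: int
    absent_unbound: int
    direction: int       # +1 enriched in binders, -1 enriched in non-binders
    p_value: float
    q_value: float = 1.0


@dataclass
class LectinReport:
    lectin_id: str
    ruleset: RuleSet
    predominant: str
    enhancers: list[FeatureContrast] = field(default_factory=list)
    inhibitors: list[FeatureContrast] = field(default_factory=list)
    tolerates: list[str] = field(default_factory=list)
    additional_binders: list[dict] = field(default_factory=list)
    notes: list[str] = field(default_factory=list)


def _presence(features: pd.DataFrame) -> pd.DataFrame:
    return (features > 0).astype(int)


def contrast_features(
    ruleset: RuleSet,
    features: FeatureMatrix | pd.DataFrame,
    labels: pd.Series,
    q_threshold: float = 0.05,
) -> list[FeatureContrast]:
    """Within glycans satisfying the level-1 rule, test each feature's presence
    against binding (Fisher exact, two-sided; BH-adjusted q-values). Features
    constant within the subset are excluded. Sorted by p-value ascending."""
    X = features.values if isinstance(features, FeatureMatrix) else features
    labels = labels.reindex(X.index)
    if not ruleset.levels:
        log.info("no rules for %s: empty contrast", ruleset.lectin_id)
        return []
    subset = ruleset.levels[0][0].satisfies(X)
    Xs, ys = X[subset], labels[subset]
    if ys.nunique() < 2:
        log.info("rule-satisfying subset of %s has a single class; empty contrast",
                 ruleset.lectin_id)
        return []
    pres = _presence(Xs)
    bound = ys == 1
    contrasts: list[FeatureContrast] = []
    for feat in pres.columns:
        col = pres[feat]
        if col.nunique() < 2:
            continue
        pb = int((col.astype(bool) & bound).sum())
        pu = int((col.astype(bool) & ~bound).sum())
        ab = int((~col.astype(bool) & bound).sum())
        au = int((~col.astype(bool) & ~bound).sum())
        _, p = fisher_exact([[pb, pu], [ab, au]], alternative="two-sided")
        # direction: is presence more frequent among binders than non-binders?
        rate_bound = pb / max(pb + ab, 1)
        rate_unbound = pu / max(pu + au, 1)
        direction = 1 if rate_bound >= rate_unbound else -1
        contrasts.append(FeatureContrast(
            feature=feat, present_bound=pb, present_unbound=pu,
            absent_bound=ab, absent_unbound=au,
            direction=direction, p_value=float(p)))
    if not contrasts:
        return []
    _, qvals, _, _ = multipletests([c.p_value for c in contrasts], method="fdr_bh")
    for c, q in zip(contrasts, qvals):
        c.q_value = float(max(q, c.p_value))
    contrasts.sort(key=lambda c: (c.p_value, c.feature))
    return contrasts


def tolerated_features(
    features: FeatureMatrix | pd.DataFrame,
    labels: pd.Series,
    contrasts: list[FeatureContrast],
    prevalence: float = 0.2,
    q_threshold: float = 0.05,
) -> list[str]:
    """Features common (≥ ``prevalence``) among binders whose association with
    binding is not significant — the report's "Tolerates" column."""
    X = features.values if isinstance(features, FeatureMatrix) else features
    labels = labels.reindex(X.index)
    binders = X[labels == 1]
    if binders.empty:
        return []
    rates = _presence(binders).mean()
    significant = {c.feature for c in contrasts if c.q_value <= q_threshold}
    return sorted(f for f in rates.index[rates >= prevalence]
                  if f not in significant and not f.startswith("linker:"))


def uncovered_binders(
    ruleset: RuleSet,
    labels: pd.Series,
    features: FeatureMatrix | pd.DataFrame,
    share_frac: float = 0.5,
) -> list[dict]:
    """Bound glycans failing every rule level, with the curated features shared
    by ≥ ``share_frac`` of the group (additional-motif candidates)."""
    X = features.values if isinstance(features, FeatureMatrix) else features
    curated = (features.curated_names
               if isinstance(features, FeatureMatrix) else list(X.columns))
    labels = labels.reindex(X.index)
    bound = labels == 1
    if ruleset.levels:
        covered = pd.Series(False, index=X.index)
        for alts in ruleset.levels:
            for rule in alts:
                covered |= rule.satisfies(X)
        uncovered = bound & ~covered
    else:
        uncovered = bound
    ids = list(X.index[uncovered])
    if not ids:
        return []
    sub = _presence(X.loc[ids, [c for c in curated if c in X.columns]] if curated
                    else X.loc[ids])
    shared = sorted(sub.columns[sub.mean() >= share_frac])
    return [{"glycan_ids": ids, "shared_features": shared,
             "n_uncovered": len(ids)}]


def build_report(
    lectin_id: str,
    ruleset: RuleSet,
    features: FeatureMatrix | pd.DataFrame,
    labels: pd.Series,
    q_threshold: float = 0.05,
) -> LectinReport:
    contrasts = contrast_features(ruleset, features, labels, q_threshold)
    enhancers = [c for c in contrasts if c.direction > 0 and c.q_value <= q_threshold]
    inhibitors = [c for c in contrasts if c.direction < 0 and c.q_value <= q_threshold]
    predominant = (ruleset.primary_rules[0].describe()
                   if ruleset.levels else "no rule found")
    report = LectinReport(
        lectin_id=lectin_id,
        ruleset=ruleset,
        predominant=predominant,
        enhancers=enhancers,
        inhibitors=inhibitors,
        tolerates=tolerated_features(features, labels, contrasts,
                                     q_threshold=q_threshold),
        additional_binders=uncovered_binders(ruleset, labels, features),
    )
    report.notes.append(
        "enhancer/inhibitor candidates from an automated exact-test contrast "
        "(Fisher 2x2, two-sided, BH-adjusted), not expert annotation")
    return report


def render_report(report: LectinReport) -> tuple[str, str]:
    """Deterministic JSON and human-readable text (Prefers / Tolerates /
    Inhibited-by layout)."""
    payload = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "lectin_id": report.lectin_id,
        "predominant": report.predominant,
        "rules": report.ruleset.to_dict(),
        "enhancers": [vars(c) for c in report.enhancers],
        "inhibitors": [vars(c) for c in report.inhibitors],
        "tolerates": report.tolerates,
        "additional_binders": report.additional_binders,
        "notes": report.notes,
    }
    js = json.dumps(payload, indent=2)

    lines = [f"Lectin: {report.lectin_id}",
             f"Prefers: {report.predominant}"]
    for alts in report.ruleset.levels:
        for rule in alts:
            tag = rule.alternative_tag or ""
            lines.append(
                f"  rule {rule.level}{tag}: {rule.describe()} "
                f"(precision {rule.precision:.2f}, recall {rule.recall:.2f}, "
                f"support {rule.estimator_support:.2f})")
    if not report.ruleset.levels:
        lines.append("  no rule found")
    lines.append(f"  stop reason: {report.ruleset.stop_reason}")
    lines.append("Tolerates: " + (", ".join(report.tolerates) or "-"))
    lines.append("Inhibited by: " +
                 (", ".join(c.feature for c in report.inhibitors) or "-"))
    if report.enhancers:
        lines.append("Enhanced by: " + ", ".join(c.feature for c in report.enhancers))
    for grp in report.additional_binders:
        lines.append(
            f"Additional binders ({grp['n_uncovered']}): shared features "
            + (", ".join(grp["shared_features"]) or "-"))
    for note in report.notes:
        lines.append(f"Note: {note}")
    return js, "\n".join(lines) + "\n"
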