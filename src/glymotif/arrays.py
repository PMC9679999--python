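"""Raw array fluorescence → combined Z-scores (Zs), QC flags and binder labels.

The processing chain is fixed and runs in this order:

1. trimmed spot average (drop one min and one max of ≥4 replicate spots);
2. per-array Z-score over glycans (raw RFU, sample SD) — valid because most
   glycans on an array are not bound, so the array mean approximates the
   no-binding baseline;
3. array/lectin exclusion: arrays whose highest signal is <1000 RFU are
   dropped; lectins with no glycan ≥4000 RFU at any concentration, or with
   fewer than two surviving arrays, are excluded;
4. Stouffer combination across concentrations: Zs = ΣZ_c / √(n_conc);
5. non-varying/nonspecific flagging (σ² < 10% of the lectin's max
   across-concentration variance; <10% of max signal at top concentration);
6. background subtraction: per glycan, subtract the mean Zs across lectins;
7. binder call at Zs ≥ 1.645 (one-tailed p = 0.05), nonspecific cells forced
   to unbound;
8. glycans bound by no lectin are dropped.

Every exclusion is recorded in a QC log with the rule that triggered it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "Z_THRESHOLD",
    "binding_threshold",
    "ProcessingConfig",
    "QCLog",
    "CombinedZMatrix",
    "robust_spot_average",
    "zscore_array",
    "exclude_low_signal",
    "stouffer_combine",
    "flag_nonvarying",
    "subtract_background",
    "call_binders",
    "drop_never_bound_glycans",
    "process_arrays",
    "account_exclusions",
]


def binding_threshold(p: float = 0.05) -> float:
    """One-sided normal quantile used as the binding cutoff; 1.645 at p=0.05."""
    return float(stats.norm.ppf(1.0 - p))


Z_THRESHOLD = 1.645  # binding_threshold(0.05) to 3 decimals


@dataclass
class ProcessingConfig:
    z_threshold: float = Z_THRESHOLD
    lectin_min_rfu: float = 4000.0   # lectin kept only if some glycan reaches this
    array_min_rfu: float = 1000.0    # array kept only if its max signal reaches this
    variance_frac: float = 0.10      # "non-varying" σ² cut, fraction of lectin max
    signal_frac: float = 0.10        # nonspecific cut, fraction of top-array max RFU
    min_spots: int = 4


@dataclass
class QCLog:
    """Accumulates every exclusion with the rule that triggered it."""

    events: list[dict] = field(default_factory=list)
    summary: dict = field(default_factory=dict)

    def record(self, kind: str, subject: str, rule: str, **detail) -> None:
        self.events.append({"kind": kind, "subject": subject, "rule": rule, **detail})

    def to_json(self, path: str | None = None) -> str:
        blob = json.dumps({"summary": self.summary, "events": self.events}, indent=2)
        if path:
            with open(path, "w") as fh:
                fh.write(blob)
        return blob


@dataclass
class CombinedZMatrix:
    """Glycans × lectins combined scores plus labels and per-cell QC flags."""

    zs: pd.DataFrame          # Stouffer-combined Zs (after non-varying adjustment)
    processed: pd.DataFrame   # zs after background subtraction
    labels: pd.DataFrame      # 1 = bound
    flags: pd.DataFrame       # "", "nonvarying", "nonvarying+nonspecific"


# ---------------------------------------------------------------------------
# Elementary operations
# ---------------------------------------------------------------------------

def robust_spot_average(spots) -> float:
    """Mean of replicate spots after removing exactly one max and one min."""
    arr = np.asarray(spots, dtype=float)
    if arr.size < 4 or not np.all(np.isfinite(arr)):
        raise ValueError(f"need >=4 finite replicate spots, got {spots!r}")
    order = np.argsort(arr, kind="stable")
    keep = order[1:-1]  # drop one instance of the min and one of the max
    return float(arr[keep].mean())


def zscore_array(rfu: pd.Series) -> pd.Series:
    """Per-glycan Z over one array: (RFU − mean) / sample SD across glycans."""
    if len(rfu) < 3:
        raise ValueError("array must carry at least 3 glycans")
    sd = rfu.std(ddof=1)
    if not np.isfinite(sd) or sd == 0:
        raise ValueError("degenerate array: zero spread across glycans")
    return (rfu - rfu.mean()) / sd


def exclude_low_signal(
    scans: dict[str, dict[float, pd.Series]],
    config: ProcessingConfig = ProcessingConfig(),
    qc: QCLog | None = None,
) -> dict[str, dict[float, pd.Series]]:
    """Apply the array-level (<1000 RFU) and lectin-level (≥4000 RFU, ≥2
    surviving arrays) exclusion rules.

    ``scans`` maps lectin_id → {concentration → averaged-RFU Series}.
    """
    qc = qc if qc is not None else QCLog()
    kept: dict[str, dict[float, pd.Series]] = {}
    for lectin_id, by_conc in scans.items():
        peak = max(float(rfu.max()) for rfu in by_conc.values())
        if peak < config.lectin_min_rfu:
            qc.record("lectin_excluded", lectin_id, "no_glycan_ge_4000_rfu",
                      peak_rfu=peak)
            continue
        surviving = {}
        for conc, rfu in by_conc.items():
            if float(rfu.max()) < config.array_min_rfu:
                qc.record("array_dropped", f"{lectin_id}@{conc}",
                          "max_signal_lt_1000_rfu", max_rfu=float(rfu.max()))
            else:
                surviving[conc] = rfu
        if len(surviving) <= 1:
            qc.record("lectin_excluded", lectin_id, "single_surviving_array",
                      n_arrays=len(surviving))
            continue
        kept[lectin_id] = surviving
    return kept


def stouffer_combine(z_by_concentration: list[pd.Series]) -> pd.Series:
    """Stouffer's method: Zs = Σ_c Z_c / √(number of concentrations)."""
    if not z_by_concentration:
        raise ValueError("no arrays to combine")
    index = z_by_concentration[0].index
    for z in z_by_concentration[1:]:
        if not z.index.equals(index):
            raise ValueError("mismatched glycan sets across concentration arrays")
    stacked = pd.concat(z_by_concentration, axis=1)
    return stacked.sum(axis=1) / np.sqrt(len(z_by_concentration))


def flag_nonvarying(
    z_table: pd.DataFrame,
    rfu_table: pd.DataFrame,
    zs: pd.Series,
    config: ProcessingConfig = ProcessingConfig(),
) -> tuple[pd.Series, pd.Series]:
    """Flag above-threshold glycans whose signal does not vary with concentration.

    ``z_table`` and ``rfu_table`` are concentrations × glycans for one lectin.
    A glycan above the Zs threshold whose raw-signal variance across
    concentrations is strictly below ``variance_frac`` of the lectin's maximum
    such variance over glycans is flagged non-varying and its Zs replaced by
    the plain across-concentration Z average (the concentration series lends
    it no independent support). The variance is assessed on averaged RFU, not
    Z, because per-array Z-scores are invariant to the overall array scale: a
    genuine titrating binder has a near-constant Z profile but a strongly
    varying signal. Flagged glycans additionally below ``signal_frac`` of the
    top-concentration array's maximum signal are nonspecific binders (label
    forced 0).

    Returns (adjusted Zs, flag Series of "", "nonvarying",
    "nonvarying+nonspecific").
    """
    if len(z_table) < 2:
        raise ValueError("need >=2 concentrations to assess variance")
    var_by_glycan = rfu_table.var(axis=0, ddof=1)
    max_var = float(var_by_glycan.max())
    adjusted = zs.copy()
    flags = pd.Series("", index=zs.index, dtype=object)
    if max_var <= 0:
        return adjusted, flags
    rfu_top = rfu_table.iloc[-1]  # rows sorted by concentration ascending
    top_max = float(rfu_top.max())
    for gid in zs.index:
        if zs[gid] >= config.z_threshold and var_by_glycan[gid] < config.variance_frac * max_var:
            adjusted[gid] = float(z_table[gid].mean())
            if rfu_top[gid] < config.signal_frac * top_max:
                flags[gid] = "nonvarying+nonspecific"
            else:
                flags[gid] = "nonvarying"
    return adjusted, flags


def subtract_background(zs: pd.DataFrame) -> pd.DataFrame:
    """Per glycan, subtract the mean Zs across lectins (rows then sum to 0)."""
    if zs.shape[1] < 2:
        raise ValueError("background subtraction needs >=2 lectins")
    return zs.sub(zs.mean(axis=1), axis=0)


def call_binders(
    processed: pd.DataFrame,
    flags: pd.DataFrame | None = None,
    threshold: float = Z_THRESHOLD,
) -> pd.DataFrame:
    """Label 1 where processed Zs ≥ threshold and the cell is not nonspecific."""
    labels = (processed >= threshold).astype(int)
    if flags is not None:
        labels = labels.where(~flags.apply(lambda c: c.str.contains("nonspecific")), 0)
    return labels


def drop_never_bound_glycans(
    labels: pd.DataFrame, qc: QCLog | None = None
) -> pd.Index:
    """Glycan ids bound by at least one lectin; all-zero rows are removed."""
    bound_any = labels.sum(axis=1) > 0
    if qc is not None:
        for gid in labels.index[~bound_any]:
            qc.record("glycan_dropped", str(gid), "bound_by_no_lectin")
    return labels.index[bound_any]


# ---------------------------------------------------------------------------
# End-to-end processing of long-format scan tables
# ---------------------------------------------------------------------------

def _spot_columns(df: pd.DataFrame) -> list[str]:
    cols = [c for c in df.columns if c.startswith("spot")]
    if not cols:
        raise ValueError("no spot columns (spot1..spotN) in scan table")
    return cols


def process_arrays(
    scans_df: pd.DataFrame,
    metadata: pd.DataFrame | None = None,
    config: ProcessingConfig = ProcessingConfig(),
) -> tuple[CombinedZMatrix, QCLog]:
    """Run the full chain on a long-format scan table.

    ``scans_df`` columns: glycan_id, lectin_id, concentration, spot1..spotN.
    ``metadata`` (optional) columns: lectin_id, duplicate_of, exclude_reason;
    duplicates and a-priori excluded preparations are removed before scoring.
    """
    qc = QCLog()
    df = scans_df.copy()
    required = {"glycan_id", "lectin_id", "concentration"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"scan table missing columns: {sorted(missing)}")

    if metadata is not None:
        drop = set()
        meta = metadata.set_index("lectin_id")
        for lectin_id, row in meta.iterrows():
            if isinstance(row.get("duplicate_of"), str) and row["duplicate_of"]:
                qc.record("lectin_excluded", str(lectin_id), "duplicate_preparation",
                          duplicate_of=row["duplicate_of"])
                drop.add(lectin_id)
            elif isinstance(row.get("exclude_reason"), str) and row["exclude_reason"]:
                qc.record("lectin_excluded", str(lectin_id), row["exclude_reason"])
                drop.add(lectin_id)
        df = df[~df["lectin_id"].isin(drop)]

    spot_cols = _spot_columns(df)
    df = df.assign(rfu=[robust_spot_average(row) for row in df[spot_cols].to_numpy()])

    # lectin -> conc -> per-glycan averaged RFU
    scans: dict[str, dict[float, pd.Series]] = {}
    for (lectin_id, conc), grp in df.groupby(["lectin_id", "concentration"], sort=True):
        series = grp.set_index("glycan_id")["rfu"].sort_index()
        scans.setdefault(str(lectin_id), {})[float(conc)] = series

    scans = exclude_low_signal(scans, config, qc)
    if not scans:
        raise ValueError("all lectins excluded by signal filters")

    zs_cols, flag_cols = {}, {}
    for lectin_id in sorted(scans):
        by_conc = dict(sorted(scans[lectin_id].items()))
        z_list = [zscore_array(rfu) for rfu in by_conc.values()]
        zs = stouffer_combine(z_list)
        z_table = pd.DataFrame({c: z for c, z in zip(by_conc, z_list)}).T
        rfu_table = pd.DataFrame(by_conc).T
        adjusted, flags = flag_nonvarying(z_table, rfu_table, zs, config)
        zs_cols[lectin_id] = adjusted
        flag_cols[lectin_id] = flags

    zs_matrix = pd.DataFrame(zs_cols).sort_index()
    flags = pd.DataFrame(flag_cols).reindex(zs_matrix.index).fillna("")
    processed = subtract_background(zs_matrix)
    labels = call_binders(processed, flags, config.z_threshold)
    kept_glycans = drop_never_bound_glycans(labels, qc)

    result = CombinedZMatrix(
        zs=zs_matrix.loc[kept_glycans],
        processed=processed.loc[kept_glycans],
        labels=labels.loc[kept_glycans],
        flags=flags.loc[kept_glycans],
    )
    qc.summary.update(
        n_lectins=int(result.zs.shape[1]),
        n_glycans=int(result.zs.shape[0]),
        n_glycans_dropped=int(labels.shape[0] - len(kept_glycans)),
    )
    return result, qc


def account_exclusions(metadata: pd.DataFrame, qc: QCLog | None = None) -> dict:
    """Preparation-level accounting: duplicates, a-priori exclusions, and the
    resulting number of unique annotated lectins. Returns the summary dict and
    records it on the QC log."""
    qc = qc if qc is not None else QCLog()
    n_prep = len(metadata)
    dup = metadata["duplicate_of"].fillna("").astype(str).str.len() > 0
    reasons = metadata["exclude_reason"].fillna("").astype(str)
    excluded_reasons = reasons[(~dup) & (reasons.str.len() > 0)]
    summary = {
        "preparations": int(n_prep),
        "duplicates": int(dup.sum()),
        "unique_annotated_lectins": int(n_prep - dup.sum() - len(excluded_reasons)),
    }
    for reason, count in excluded_reasons.value_counts().items():
        summary[f"excluded:{reason}"] = int(count)
    qc.summary.update(summary)
    return summary
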