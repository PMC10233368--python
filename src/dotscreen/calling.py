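"""Replicate normalization, QC exclusion rules, and preference calling.

Each dot's biotinylation signal is normalized by its loading control
(SA/LC ratio); the nine replicates of a (bait, prey) set — three
biological x three technical — are aggregated by the median; sets are
excluded when the prey strain was missing before lysis (pre-lysis OD below
a floor) or when the aggregate sits more than ``z_threshold`` standard
deviations BELOW the rest of the membrane stack (a one-sided rule: strong
interactors are the signal of interest and are never excluded for being
high). A prey is then called as preferring one bait over the other when
its normalized signal differs by more than a twofold change; both signals
under the detection floor means no detectable interaction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

EXCLUSION_PRIORITY = ("no_od", "missing_strain", "too_few_replicates", "low_signal_z")


@dataclass
class AggregateResult:
    aggregate: float
    replicate_sd: float
    n_used: int
    ok: bool
    reason: str | None = None


def normalize_dot(
    signal_corrected: float, control_corrected: float, control_floor: float = 0.0
) -> tuple[float, bool]:
    """SA/LC ratio of one dot: signal over loading control.

    Returns ``(ratio, valid)``. A loading control at or below
    ``control_floor`` marks the dot invalid (ratio NaN) instead of
    producing an unbounded ratio.
    """
    if signal_corrected < 0 or control_corrected < 0:
        raise ValueError("corrected intensities must be >= 0")
    if control_corrected <= control_floor:
        return float("nan"), False
    return signal_corrected / control_corrected, True


def aggregate_replicates(
    ratios: Sequence[float], min_replicates: int = 3
) -> AggregateResult:
    """Aggregate up to nine replicate SA/LC ratios of one (bait, prey) set.

    The aggregate is the median (robust to a single bad dot); the spread is
    the sample standard deviation. Fewer than ``min_replicates`` finite
    ratios refuses aggregation rather than reporting an unstable value.
    """
    arr = np.asarray(ratios, dtype=float)
    arr = arr[np.isfinite(arr)]
    if np.any(arr < 0):
        raise ValueError("replicate ratios must be >= 0")
    n = len(arr)
    if n < max(min_replicates, 1):
        return AggregateResult(
            float("nan"), float("nan"), n, False, "too_few_replicates"
        )
    sd = float(np.std(arr, ddof=1)) if n > 1 else 0.0
    return AggregateResult(float(np.median(arr)), sd, n, True, None)


def build_normalized_sets(
    dots: pd.DataFrame,
    plate_map: pd.DataFrame,
    control_floor_frac: float = 0.1,
    min_replicates: int = 3,
) -> pd.DataFrame:
    """Join per-dot measurements to the plate map and aggregate per set.

    ``control_floor`` is taken per membrane as ``control_floor_frac`` times
    the median corrected loading control over that membrane's mapped dots,
    so a missing strain (near-zero load) yields invalid dots rather than
    wild ratios. Returns one row per (bait_id, prey_id) with the aggregate
    SA/LC ratio, replicate SD, and replicate accounting.
    """
    merged = plate_map.merge(
        dots, on=["membrane_id", "row", "col"], how="left", validate="1:1"
    )
    if merged["signal_corrected"].isna().any():
        missing = merged[merged["signal_corrected"].isna()]
        pos = missing.iloc[0]
        raise ValueError(
            "plate map references unmeasured position "
            f"{pos['membrane_id']} r{pos['row']} c{pos['col']} "
            f"({len(missing)} positions total)"
        )
    floors = (
        merged.groupby("membrane_id")["control_corrected"]
        .median()
        .mul(control_floor_frac)
    )
    floor_per_dot = merged["membrane_id"].map(floors)
    valid = merged["control_corrected"] > floor_per_dot
    ratio = np.where(
        valid,
        merged["signal_corrected"] / merged["control_corrected"].where(valid, 1.0),
        np.nan,
    )
    merged = merged.assign(ratio=ratio, ratio_valid=valid)

    rows = []
    for (bait, prey), grp in merged.groupby(["bait_id", "prey_id"], sort=True):
        agg = aggregate_replicates(
            grp["ratio"].to_numpy(), min_replicates=min_replicates
        )
        rows.append(
            {
                "bait_id": bait,
                "prey_id": prey,
                "aggregate": agg.aggregate,
                "replicate_sd": agg.replicate_sd,
                "n_used": agg.n_used,
                "n_total": len(grp),
                "agg_ok": agg.ok,
                "agg_reason": agg.reason or "",
            }
        )
    return pd.DataFrame(rows)


def leave_one_out_z(values: np.ndarray) -> np.ndarray:
    """Z-score of each value against the mean/SD of all the others."""
    values = np.asarray(values, dtype=float)
    n = len(values)
    if n < 3:
        return np.full(n, np.nan)
    total = values.sum()
    totalsq = (values**2).sum()
    out = np.empty(n)
    for i, v in enumerate(values):
        mean = (total - v) / (n - 1)
        var = (totalsq - v * v) / (n - 1) - mean * mean
        var = max(var, 0.0) * (n - 1) / (n - 2)  # ddof=1 on the n-1 others
        sd = np.sqrt(var)
        if sd > 0:
            out[i] = (v - mean) / sd
        elif v == mean:
            out[i] = 0.0
        else:
            out[i] = np.inf if v > mean else -np.inf
    return out


def apply_exclusions(
    sets: pd.DataFrame,
    od_table: pd.DataFrame,
    z_threshold: float = 10.0,
    sd_flag_threshold: float = 3.0,
    od_floor: float = 0.05,
) -> pd.DataFrame:
    """Apply the screen's exclusion rules to aggregated sets.

    A set is excluded when (in priority order) its strain has no pre-lysis
    OD record, its OD is below ``od_floor`` (the strain was missing to
    begin with), too few replicates survived, or its aggregate lies more
    than ``z_threshold`` SDs below the rest of its bait's membrane stack
    (leave-one-out Z; one-sided low tail only). Sets whose replicate SD
    exceeds ``sd_flag_threshold`` are flagged for the reproducibility
    report but NOT excluded.
    """
    if len(sets) < 10:
        raise ValueError(
            "need at least 10 sets per run to compute membrane statistics"
        )
    od = od_table.set_index("strain_id")["od600"]
    out = sets.copy()
    strain = out["bait_id"] + ":" + out["prey_id"]
    out["od600"] = strain.map(od)

    out["membrane_z"] = np.nan
    for bait, grp in out.groupby("bait_id"):
        ok = grp["agg_ok"].to_numpy()
        vals = grp["aggregate"].to_numpy()[ok]
        z = np.full(len(grp), np.nan)
        z[ok] = leave_one_out_z(vals)
        out.loc[grp.index, "membrane_z"] = z

    reasons = []
    for rec in out.itertuples():
        if pd.isna(rec.od600):
            reasons.append("no_od")
        elif rec.od600 < od_floor:
            reasons.append("missing_strain")
        elif not rec.agg_ok:
            reasons.append("too_few_replicates")
        elif np.isfinite(rec.membrane_z) and rec.membrane_z < -z_threshold:
            reasons.append("low_signal_z")
        else:
            reasons.append("")
    out["exclusion_reason"] = reasons
    out["excluded"] = out["exclusion_reason"] != ""
    out["sd_flagged"] = (
        out["replicate_sd"].to_numpy() > sd_flag_threshold
    ) & np.isfinite(out["replicate_sd"].to_numpy())
    return out


def call_preference(
    signal_A: float,
    signal_B: float,
    preference_threshold: float = 2.0,
    detection_floor: float = 0.0,
) -> tuple[str, float]:
    """Classify one prey from its two aggregated SA/LC signals.

    Both signals below the detection floor: no detectable interaction.
    Exactly one above: preference for that bait, fold change reported
    against the floor. Both above: preference for the larger when the
    max/min fold change STRICTLY exceeds ``preference_threshold`` (a
    twofold signal difference by default), otherwise interaction with
    both. Returns ``(category, fold_change)``; fold change is NaN for
    no_interaction.
    """
    if signal_A < 0 or signal_B < 0:
        raise ValueError("aggregated signals must be >= 0")
    a_up = signal_A >= detection_floor and signal_A > 0
    b_up = signal_B >= detection_floor and signal_B > 0
    if not a_up and not b_up:
        return "no_interaction", float("nan")
    if a_up and not b_up:
        ref = max(detection_floor, 1e-300)
        return "prefers_A", signal_A / ref
    if b_up and not a_up:
        ref = max(detection_floor, 1e-300)
        return "prefers_B", signal_B / ref
    hi, lo = max(signal_A, signal_B), min(signal_A, signal_B)
    fc = hi / lo if lo > 0 else float("inf")
    if fc > preference_threshold:
        return ("prefers_A" if signal_A > signal_B else "prefers_B"), fc
    return "both", fc


def detection_floors(
    dots_by_membrane: Mapping[str, pd.DataFrame],
    plate_map: pd.DataFrame,
    mode: str = "empty_quantile",
    quantile: float = 0.95,
    fixed: float = 0.1,
) -> dict[str, float]:
    """Detection floor per membrane, on the SA/LC ratio scale.

    ``empty_quantile`` mode: the floor is the ``quantile`` of
    pseudo-ratios of the membrane's EMPTY grid positions — each empty
    position's corrected signal divided by the median corrected loading
    control of the occupied dots (empty positions have no loading control
    of their own). A membrane with no empty positions (fully packed grid)
    falls back to the ``fixed`` floor, as does ``mode="fixed"``.
    """
    if mode not in ("empty_quantile", "fixed"):
        raise ValueError(f"unknown detection floor mode {mode!r}")
    floors: dict[str, float] = {}
    occupied = plate_map.set_index(["membrane_id", "row", "col"]).index
    for mem_id, dots in dots_by_membrane.items():
        if mode == "fixed":
            floors[mem_id] = fixed
            continue
        key = pd.MultiIndex.from_arrays(
            [np.repeat(mem_id, len(dots)), dots["row"], dots["col"]]
        )
        is_occ = key.isin(occupied)
        if is_occ.all():
            floors[mem_id] = fixed
            continue
        ctl_med = float(np.median(dots.loc[is_occ, "control_corrected"]))
        if ctl_med <= 0:
            floors[mem_id] = fixed
            continue
        pseudo = dots.loc[~is_occ, "signal_corrected"].to_numpy() / ctl_med
        floors[mem_id] = float(np.quantile(pseudo, quantile))
    return floors


def call_pairs(
    sets: pd.DataFrame,
    baits: tuple[str, str],
    preference_threshold: float = 2.0,
    detection_floor: float | Mapping[str, float] = 0.0,
) -> pd.DataFrame:
    """Pair each prey's two bait sets and classify it.

    ``sets`` is the output of :func:`apply_exclusions`. A prey whose set is
    excluded for either bait is categorized ``excluded`` with the reason
    recorded. ``detection_floor`` may be a single ratio or a per-bait
    mapping.
    """
    bait_a, bait_b = baits
    if isinstance(detection_floor, Mapping):
        floor_a = detection_floor.get(bait_a, 0.0)
        floor_b = detection_floor.get(bait_b, 0.0)
    else:
        floor_a = floor_b = float(detection_floor)
    floor = max(floor_a, floor_b)

    wide = sets.set_index(["bait_id", "prey_id"])
    preys = sets["prey_id"].unique()
    rows = []
    for prey in preys:
        rec = {}
        for suffix, bait in (("A", bait_a), ("B", bait_b)):
            s = wide.loc[(bait, prey)]
            rec[f"signal_{suffix}"] = s["aggregate"]
            rec[f"replicate_sd_{suffix}"] = s["replicate_sd"]
            rec[f"excluded_{suffix}"] = bool(s["excluded"])
            rec[f"reason_{suffix}"] = s["exclusion_reason"]
        if rec["excluded_A"] or rec["excluded_B"]:
            category, fc = "excluded", float("nan")
            reason = ";".join(
                sorted({r for r in (rec["reason_A"], rec["reason_B"]) if r})
            )
        else:
            category, fc = call_preference(
                rec["signal_A"], rec["signal_B"],
                preference_threshold=preference_threshold,
                detection_floor=floor,
            )
            reason = ""
        rows.append(
            {
                "prey_id": prey,
                "signal_A": rec["signal_A"],
                "signal_B": rec["signal_B"],
                "fold_change": fc,
                "category": category,
                "exclusion_reason": reason,
                "replicate_sd_A": rec["replicate_sd_A"],
                "replicate_sd_B": rec["replicate_sd_B"],
            }
        )
    return pd.DataFrame(rows)


SUMMARY_CATEGORIES = ("no_interaction", "both", "prefers_A", "prefers_B", "excluded")


def summarize_screen(pairs: pd.DataFrame) -> pd.DataFrame:
    """Category counts over all preys (the pie-chart accounting).

    Counts are exhaustive over the five categories and sum to the number
    of preys; a duplicated prey is an error.
    """
    dup = pairs["prey_id"][pairs["prey_id"].duplicated()].unique().tolist()
    if dup:
        raise ValueError(f"duplicate preys in preference table: {dup}")
    unknown = set(pairs["category"]) - set(SUMMARY_CATEGORIES)
    if unknown:
        raise ValueError(f"unknown categories: {sorted(unknown)}")
    counts = pairs["category"].value_counts()
    return pd.DataFrame(
        {
            "category": SUMMARY_CATEGORIES,
            "count": [int(counts.get(c, 0)) for c in SUMMARY_CATEGORIES],
        }
    )
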