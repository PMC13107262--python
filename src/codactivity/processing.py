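"""Detection filtering and preparation.

Implements the standard cleaning chain for accelerometer/depth telemetry
from fixed receiver arrays, in the order the clock-corrected data are
analysed:

1. linear receiver clock correction (initiation/download time stamps);
2. removal of dead fish (no vertical movement for more than a day);
3. deduplication of the same transmission logged by several receivers
   within the minimum tag delay;
4. removal of dubious lone detections (a single daily detection);
5. pairing of each accelerometer transmission with the nearest-in-time
   depth transmission of the same fish (within 1800 s);
6. scope restriction (fish depth <= 60 m, tagging year only, exclusion
   windows);
7. thinning of high-rate (2024-protocol) tags to every fifth value;
8. season and depth-category labelling.

All functions take and return pandas DataFrames in the detection-record
schema (``receiver_id, timestamp, fish_id, sensor, value`` with
timestamps as float epoch seconds UTC); extra columns pass through
untouched, so simulator truth columns survive the pipeline for
oracle-based testing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .simulate import (
    SHALLOW_DEEP_BOUNDARY_M,
    ReceiverSpec,
    month_to_season,
)
from .tags import TAG_SPECS, TagSpec

__all__ = [
    "ProcessingConfig",
    "RemovalLedger",
    "correct_clock",
    "filter_dead_fish",
    "dedup_multireceiver",
    "filter_single_daily",
    "pair_depth",
    "restrict_scope",
    "trim_high_rate",
    "assign_season",
    "assign_depth_category",
    "process_detections",
]


@dataclass(frozen=True)
class ProcessingConfig:
    """Thresholds of the cleaning chain (all exposed, defaults standard)."""

    pair_max_gap: float = 1800.0  # s
    max_depth: float = 60.0  # m, inclusive
    depth_boundary: float = SHALLOW_DEEP_BOUNDARY_M  # shallow/deep split, m
    stillness_window: float = 86400.0  # s, "no vertical movement" horizon
    depth_epsilon: float = 0.5  # m, depth range counted as no movement
    trim_factor: int = 5  # thinning of high-rate tags
    timezone: str = "Europe/Oslo"  # calendar days for the lone-detection rule
    high_activity_threshold: float = 2.0  # m/s^2, used downstream


class RemovalLedger:
    """Per-stage record-count reconciliation (input = output + removed)."""

    def __init__(self) -> None:
        self.rows: list[dict] = []

    def log(self, stage: str, n_in: int, n_out: int, **extra) -> None:
        if n_in - n_out < 0:
            raise ValueError(f"stage {stage} increased the record count")
        self.rows.append(
            {"stage": stage, "n_in": n_in, "n_out": n_out, "n_removed": n_in - n_out, **extra}
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)


# ---------------------------------------------------------------------------
# 1. clock correction


def correct_clock(
    records: pd.DataFrame,
    receivers: ReceiverSpec | Sequence[ReceiverSpec],
) -> pd.DataFrame:
    """Undo linear receiver clock drift.

    Each recorded timestamp ``t`` is mapped to
    ``t - drift_total * (t - deploy_start) / (deploy_end - deploy_start)``,
    the linear correction anchored at the receiver's initiation and
    download satellite time stamps.  Records outside the deployment
    interval pass through unchanged with a warning.
    """
    if isinstance(receivers, ReceiverSpec):
        receivers = [receivers]
    out = records.copy()
    t = out["timestamp"].to_numpy(dtype=float)
    corrected = t.copy()
    n_outside = 0
    for rec in receivers:
        sel = (out["receiver_id"] == rec.receiver_id).to_numpy()
        if not sel.any():
            continue
        inside = sel & (t >= rec.deploy_start) & (t <= rec.deploy_end)
        n_outside += int(sel.sum() - inside.sum())
        span = rec.deploy_end - rec.deploy_start
        corrected[inside] = t[inside] - rec.drift_total * (t[inside] - rec.deploy_start) / span
    if n_outside:
        warnings.warn(
            f"{n_outside} records outside their receiver's deployment interval "
            "were left uncorrected",
            stacklevel=2,
        )
    out["timestamp"] = corrected
    order = np.argsort(corrected, kind="stable")
    return out.iloc[order].reset_index(drop=True)


# ---------------------------------------------------------------------------
# 2. dead-fish removal


def _dead_cutoff(
    times: np.ndarray,
    depths: np.ndarray,
    stillness_window: float,
    depth_epsilon: float,
) -> float | None:
    """Earliest depth-record time from which the fish shows no vertical
    movement (suffix depth range <= epsilon) for longer than the
    stillness window, through the end of the record.  None if the fish
    keeps moving (or its terminal flat stretch is shorter than the
    window)."""
    if times.size == 0:
        return -np.inf  # no depth data at all: treat as never moving
    # suffix running min/max
    smax = np.maximum.accumulate(depths[::-1])[::-1]
    smin = np.minimum.accumulate(depths[::-1])[::-1]
    flat = (smax - smin) <= depth_epsilon
    long_enough = (times[-1] - times) > stillness_window
    eligible = flat & long_enough
    if flat[0]:
        # never displayed any vertical movement: drop the fish entirely
        return -np.inf
    if eligible.any():
        return float(times[np.argmax(eligible)])
    return None


def filter_dead_fish(
    records: pd.DataFrame,
    stillness_window: float = 86400.0,
    depth_epsilon: float = 0.5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove detections of fish presumed dead.

    A fish that never displays vertical movement (total depth range at
    most ``depth_epsilon``, or no depth records at all) is removed
    entirely; for a fish whose vertical movement ceases, only the period
    from the cessation instant onward is removed, provided the flat
    terminal stretch exceeds ``stillness_window``.

    Returns the surviving records and a removal log with one row per
    affected fish (``fish_id, reason, cutoff, n_removed``).
    """
    keep = np.ones(len(records), dtype=bool)
    log_rows = []
    t_all = records["timestamp"].to_numpy(dtype=float)
    fish_codes, fish_index = pd.factorize(records["fish_id"])
    is_depth = (records["sensor"] == "depth").to_numpy()
    values = records["value"].to_numpy(dtype=float)
    for fc, fish_id in enumerate(fish_index):
        sel = fish_codes == fc
        pos = np.flatnonzero(sel)
        dpos = pos[is_depth[pos]]
        order = np.argsort(t_all[dpos], kind="stable")
        dpos = dpos[order]
        cutoff = _dead_cutoff(
            t_all[dpos], values[dpos], stillness_window, depth_epsilon
        )
        if cutoff is None:
            continue
        if np.isneginf(cutoff):
            keep[pos] = False
            reason = "no_vertical_movement" if dpos.size else "no_depth_records"
            log_rows.append(
                {"fish_id": fish_id, "reason": reason, "cutoff": np.nan, "n_removed": pos.size}
            )
        else:
            drop = pos[t_all[pos] >= cutoff]
            keep[drop] = False
            log_rows.append(
                {
                    "fish_id": fish_id,
                    "reason": "movement_ceased",
                    "cutoff": cutoff,
                    "n_removed": int(drop.size),
                }
            )
    removal_log = pd.DataFrame(
        log_rows, columns=["fish_id", "reason", "cutoff", "n_removed"]
    )
    return records.loc[keep].reset_index(drop=True), removal_log


# ---------------------------------------------------------------------------
# 3. multi-receiver deduplication


def _tag_delay_by_fish(
    records: pd.DataFrame,
    tag: TagSpec | None,
    fish_meta: pd.DataFrame | None,
) -> pd.Series:
    """Per-record minimum tag delay (s)."""
    if fish_meta is not None and "tag_spec_name" in fish_meta:
        lut = {
            r.fish_id: TAG_SPECS[r.tag_spec_name].delay_min
            for r in fish_meta.itertuples()
        }
        default = (tag or next(iter(TAG_SPECS.values()))).delay_min
        codes, index = pd.factorize(records["fish_id"])
        per_fish = np.array([lut.get(f, default) for f in index], dtype=float)
        return pd.Series(per_fish[codes], index=records.index)
    if tag is None:
        raise ValueError("need a TagSpec or fish metadata with tag_spec_name")
    return pd.Series(tag.delay_min, index=records.index)


def dedup_multireceiver(
    records: pd.DataFrame,
    tag: TagSpec | None = None,
    fish_meta: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Collapse the same transmission logged at several receivers.

    Within any group of records sharing (fish id, sensor, sensor value)
    whose members lie within the minimum tag delay of the group's first
    member, only the earliest record is kept.  Groups are built greedily
    in time order: the earliest not-yet-grouped record anchors a group
    that absorbs every later matching record within ``delay_min`` of it.
    """
    if len(records) == 0:
        return records.copy()
    delay = _tag_delay_by_fish(records, tag, fish_meta).to_numpy(dtype=float)
    fish_codes, _ = pd.factorize(records["fish_id"])
    sensor_codes, _ = pd.factorize(records["sensor"])
    t_raw = records["timestamp"].to_numpy(dtype=float)
    val_raw = records["value"].to_numpy(dtype=float)
    pos = np.lexsort((t_raw, val_raw, sensor_codes, fish_codes))
    t = t_raw[pos]
    dly = delay[pos]
    key = fish_codes[pos].astype(np.int64) * (sensor_codes.max() + 1) + sensor_codes[pos]
    val = val_raw[pos]
    n = len(pos)
    new_key = np.ones(n, dtype=bool)
    new_key[1:] = (key[1:] != key[:-1]) | (val[1:] != val[:-1])
    # fast path: a gap larger than delay_min always starts a new greedy
    # group, so greedy groups never straddle these session boundaries
    gap_break = np.ones(n, dtype=bool)
    gap_break[1:] = (t[1:] - t[:-1]) > dly[1:]
    session = np.cumsum(new_key | gap_break)
    keep_sorted = np.zeros(n, dtype=bool)
    sess_starts = np.flatnonzero(np.diff(session, prepend=session[0] - 1))
    sess_ends = np.append(sess_starts[1:], n)
    for s, e in zip(sess_starts, sess_ends):
        if t[e - 1] - t[s] <= dly[s]:
            keep_sorted[s] = True  # whole session within delay of its anchor
        else:
            anchor = t[s]
            keep_sorted[s] = True
            for j in range(s + 1, e):
                if t[j] - anchor > dly[j]:
                    keep_sorted[j] = True
                    anchor = t[j]
    keep = np.zeros(len(records), dtype=bool)
    keep[pos[keep_sorted]] = True
    out = records.loc[keep]
    order = np.argsort(out["timestamp"].to_numpy(dtype=float), kind="stable")
    return out.iloc[order].reset_index(drop=True)


# ---------------------------------------------------------------------------
# 4. lone daily detections


def filter_single_daily(
    records: pd.DataFrame, timezone: str = "Europe/Oslo"
) -> pd.DataFrame:
    """Drop dubious detections: a single daily detection of a fish.

    Days are calendar days in the given (local) timezone.
    """
    if len(records) == 0:
        return records.copy()
    idx = pd.DatetimeIndex(
        pd.to_datetime(records["timestamp"].to_numpy(dtype=float), unit="s", utc=True)
    )
    local_day = idx.tz_convert(timezone).tz_localize(None).values.astype("datetime64[D]")
    day_codes = pd.factorize(local_day)[0]
    fish_codes, _ = pd.factorize(records["fish_id"])
    combo = fish_codes.astype(np.int64) * (day_codes.max() + 1) + day_codes
    counts = np.bincount(combo)[combo]
    return records.loc[counts > 1].reset_index(drop=True)


# ---------------------------------------------------------------------------
# 5. depth pairing


def pair_depth(
    records: pd.DataFrame, max_gap: float = 1800.0
) -> tuple[pd.DataFrame, dict]:
    """Assign each accelerometer transmission its nearest depth record.

    For every accel record the same-fish depth record minimising the
    absolute time difference is chosen; ties are broken toward the
    earlier depth record.  Accel records with no depth candidate within
    ``max_gap`` seconds before or after are dropped and counted.

    Returns the paired table (``fish_id, timestamp, accel, depth,
    pair_gap`` with ``pair_gap = depth_time - accel_time``, plus any
    pass-through columns of the accel records) and a stats dict with the
    pairing fraction.
    """
    acc = (
        records[records["sensor"] == "accel"]
        .sort_values("timestamp", kind="stable")
        .reset_index(drop=True)
    )
    dep = (
        records[records["sensor"] == "depth"]
        .sort_values("timestamp", kind="stable")
        .reset_index(drop=True)
    )
    n_accel = len(acc)
    if n_accel == 0 or len(dep) == 0:
        stats = {"n_accel": n_accel, "n_paired": 0, "pairing_fraction": np.nan}
        cols = ["fish_id", "timestamp", "accel", "depth", "pair_gap"]
        return pd.DataFrame(columns=cols), stats
    dep_small = dep[["fish_id", "timestamp", "value"]].rename(
        columns={"timestamp": "depth_time", "value": "depth"}
    )
    acc2 = acc.rename(columns={"value": "accel"})
    back = pd.merge_asof(
        acc2,
        dep_small,
        left_on="timestamp",
        right_on="depth_time",
        by="fish_id",
        direction="backward",
        tolerance=max_gap,
    )
    fwd = pd.merge_asof(
        acc2,
        dep_small,
        left_on="timestamp",
        right_on="depth_time",
        by="fish_id",
        direction="forward",
        tolerance=max_gap,
    )
    gap_b = back["timestamp"] - back["depth_time"]  # >= 0
    gap_f = fwd["depth_time"] - fwd["timestamp"]  # >= 0
    use_back = gap_b.notna() & (gap_f.isna() | (gap_b <= gap_f))
    depth = np.where(use_back, back["depth"], fwd["depth"])
    depth_time = np.where(use_back, back["depth_time"], fwd["depth_time"])
    paired = acc2.copy()
    paired["depth"] = depth
    paired["pair_gap"] = depth_time - paired["timestamp"].to_numpy()
    ok = ~np.isnan(depth)
    dropped_fish = paired.loc[~ok, "fish_id"].value_counts().to_dict()
    paired = paired.loc[ok].reset_index(drop=True)
    stats = {
        "n_accel": n_accel,
        "n_paired": len(paired),
        "pairing_fraction": len(paired) / n_accel,
        "dropped_by_fish": dropped_fish,
    }
    return paired, stats


# ---------------------------------------------------------------------------
# 6. scope restriction


def restrict_scope(
    pairs: pd.DataFrame,
    fish_meta: pd.DataFrame,
    exclusion_windows: pd.DataFrame | None = None,
    max_depth: float = 60.0,
) -> pd.DataFrame:
    """Restrict pairs to analysable scope.

    Drops pairs with fish depth above ``max_depth`` (<= 60 m kept,
    boundary inclusive), pairs outside the fish's tagging calendar year
    (UTC), and pairs inside any exclusion window (noise-exposure
    periods; ``start``/``end`` epoch seconds, both inclusive).
    """
    if len(pairs) == 0:
        return pairs.copy()
    out = pairs.copy()
    keep = out["depth"].to_numpy(dtype=float) <= max_depth
    year_lut = fish_meta.set_index("fish_id")["year"].to_dict()
    yr = pd.DatetimeIndex(
        pd.to_datetime(out["timestamp"].to_numpy(dtype=float), unit="s", utc=True)
    ).year
    codes, index = pd.factorize(out["fish_id"])
    tag_year = np.array([year_lut.get(f, -1) for f in index])[codes]
    keep &= yr.to_numpy() == tag_year
    if exclusion_windows is not None and len(exclusion_windows):
        t = out["timestamp"].to_numpy(dtype=float)
        excluded = np.zeros(len(out), dtype=bool)
        for w in exclusion_windows.itertuples():
            excluded |= (t >= w.start) & (t <= w.end)
        keep &= ~excluded
    return out.loc[keep].reset_index(drop=True)


# ---------------------------------------------------------------------------
# 7. high-rate trimming


def trim_high_rate(
    pairs: pd.DataFrame, fish_meta: pd.DataFrame, factor: int = 5
) -> pd.DataFrame:
    """Thin pairs of high-rate tags to every ``factor``-th measurement.

    Fish whose tag spec is flagged high-rate (the 2024 protocol, ~5x the
    standard transmission rate) keep indices 0, factor, 2*factor, ... of
    their time-ordered pairs; all other fish pass through untouched.
    """
    if len(pairs) == 0:
        return pairs.copy()
    high = {
        r.fish_id
        for r in fish_meta.itertuples()
        if TAG_SPECS[r.tag_spec_name].high_rate
    }
    if not high:
        return pairs.copy()
    out = pairs.sort_values(["fish_id", "timestamp"], kind="stable")
    rank = out.groupby("fish_id", sort=False).cumcount()
    keep = (~out["fish_id"].isin(high)) | (rank % factor == 0)
    return out.loc[keep].sort_values("timestamp", kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# 8. labelling


def assign_season(pairs: pd.DataFrame) -> pd.DataFrame:
    """Label each pair with its season.

    February-March -> spawning, May-December -> feeding, January and
    April -> ``omitted`` (transitional months, excluded from models).
    """
    out = pairs.copy()
    if len(out) == 0:
        out["season"] = pd.Series(dtype=object)
        return out
    months = pd.DatetimeIndex(
        pd.to_datetime(out["timestamp"].to_numpy(dtype=float), unit="s", utc=True)
    ).month.to_numpy()
    out["season"] = month_to_season(months)
    return out


def assign_depth_category(
    pairs: pd.DataFrame, boundary: float = SHALLOW_DEEP_BOUNDARY_M
) -> pd.DataFrame:
    """Label pairs shallow/deep by fish depth (half-open split at 20 m:
    [0, 20) shallow, [20, 60] deep)."""
    out = pairs.copy()
    if len(out) == 0:
        out["depth_category"] = pd.Series(dtype=object)
        return out
    out["depth_category"] = np.where(
        out["depth"].to_numpy(dtype=float) >= boundary, "deep", "shallow"
    )
    return out


# ---------------------------------------------------------------------------
# full chain


def process_detections(
    detections: pd.DataFrame,
    fish_meta: pd.DataFrame,
    receivers: Iterable[ReceiverSpec],
    config: ProcessingConfig = ProcessingConfig(),
    exclusion_windows: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Run the whole cleaning chain; returns (pairs, ledger, stats).

    Stages run in the order the time-corrected data are analysed: clock
    correction, dead-fish removal, deduplication, lone-detection
    removal, depth pairing, scope restriction, high-rate trimming, then
    season/depth-category labelling.  The ledger reconciles record
    counts per stage; the pairing fraction is reported before scope
    restriction.
    """
    ledger = RemovalLedger()
    recs = correct_clock(detections, list(receivers))
    ledger.log("clock_correction", len(detections), len(recs))
    recs, dead_log = filter_dead_fish(
        recs, config.stillness_window, config.depth_epsilon
    )
    ledger.log("dead_fish", ledger.rows[-1]["n_out"], len(recs))
    recs = dedup_multireceiver(recs, fish_meta=fish_meta)
    ledger.log("dedup_multireceiver", ledger.rows[-1]["n_out"], len(recs))
    recs = filter_single_daily(recs, config.timezone)
    ledger.log("single_daily", ledger.rows[-1]["n_out"], len(recs))
    pairs, pair_stats = pair_depth(recs, config.pair_max_gap)
    ledger.log("pair_depth", pair_stats["n_accel"], len(pairs))
    pairs = restrict_scope(pairs, fish_meta, exclusion_windows, config.max_depth)
    ledger.log("restrict_scope", ledger.rows[-1]["n_out"], len(pairs))
    pairs = trim_high_rate(pairs, fish_meta, config.trim_factor)
    ledger.log("trim_high_rate", ledger.rows[-1]["n_out"], len(pairs))
    pairs = assign_depth_category(assign_season(pairs), config.depth_boundary)
    stats = {"pairing": pair_stats, "dead_fish_log": dead_log}
    return pairs, ledger.to_frame(), stats
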