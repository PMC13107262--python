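"""Independent brute-force implementations of the cleaning rules.

Deliberately naive (plain Python loops, dictionary scans) so they share
no code or vectorisation tricks with the package; used to cross-check
the production filters on random instances.
"""

import numpy as np
import pandas as pd

from codactivity import (
    STANDARD_TAG,
    dedup_multireceiver,
    filter_dead_fish,
    filter_single_daily,
    pair_depth,
)


def _kept_keys(df: pd.DataFrame) -> set:
    return set(
        zip(df["receiver_id"], df["timestamp"], df["fish_id"], df["sensor"], df["value"])
    )


def assert_filters_match_bruteforce(records: pd.DataFrame) -> None:
    """Run all four production filters against their naive counterparts."""
    got = dedup_multireceiver(records, STANDARD_TAG)
    want_idx = bf_dedup(records, STANDARD_TAG.delay_min)
    want = records.reset_index(drop=True).iloc[sorted(want_idx)]
    assert _kept_keys(got) == _kept_keys(want)

    got2, _ = filter_dead_fish(records, 86400.0, 0.5)
    want2 = records.reset_index(drop=True).iloc[
        sorted(bf_dead_fish(records, 86400.0, 0.5))
    ]
    assert _kept_keys(got2) == _kept_keys(want2)

    got3 = filter_single_daily(records, "Europe/Oslo")
    want3 = records.reset_index(drop=True).iloc[
        sorted(bf_single_daily(records, "Europe/Oslo"))
    ]
    assert _kept_keys(got3) == _kept_keys(want3)

    pairs, _ = pair_depth(records, 1800.0)
    df = records.reset_index(drop=True)
    want_pairs = {
        (df["fish_id"][i], df["timestamp"][i], df["value"][best[0]], best[1])
        for i, best in bf_pair(records, 1800.0)
        if best is not None
    }
    got_pairs = set(
        zip(pairs["fish_id"], pairs["timestamp"], pairs["depth"], pairs["pair_gap"])
    )
    assert got_pairs == want_pairs


def bf_dedup(records: pd.DataFrame, delay_min: float) -> set:
    """Kept positional indices under the greedy first-anchored rule."""
    keep = set()
    df = records.reset_index(drop=True)
    groups = {}
    for i in range(len(df)):
        key = (df["fish_id"][i], df["sensor"][i], df["value"][i])
        groups.setdefault(key, []).append(i)
    for idxs in groups.values():
        idxs = sorted(idxs, key=lambda i: df["timestamp"][i])
        anchor = None
        for i in idxs:
            t = df["timestamp"][i]
            if anchor is None or t - anchor > delay_min:
                keep.add(i)
                anchor = t
    return keep


def bf_dead_fish(records: pd.DataFrame, window: float, eps: float) -> set:
    """Kept positional indices under the dead-fish rule."""
    df = records.reset_index(drop=True)
    keep = set(range(len(df)))
    for fish in df["fish_id"].unique():
        rows = [i for i in range(len(df)) if df["fish_id"][i] == fish]
        depth_rows = sorted(
            (i for i in rows if df["sensor"][i] == "depth"),
            key=lambda i: df["timestamp"][i],
        )
        if not depth_rows:
            keep -= set(rows)
            continue
        depths = [df["value"][i] for i in depth_rows]
        times = [df["timestamp"][i] for i in depth_rows]
        if max(depths) - min(depths) <= eps:
            keep -= set(rows)
            continue
        cutoff = None
        for j in range(len(depth_rows)):
            suffix = depths[j:]
            if max(suffix) - min(suffix) <= eps and times[-1] - times[j] > window:
                cutoff = times[j]
                break
        if cutoff is not None:
            keep -= {i for i in rows if df["timestamp"][i] >= cutoff}
    return keep


def bf_single_daily(records: pd.DataFrame, timezone: str) -> set:
    """Kept positional indices under the lone-daily-detection rule."""
    df = records.reset_index(drop=True)
    counts = {}
    days = []
    for i in range(len(df)):
        day = (
            pd.Timestamp(df["timestamp"][i], unit="s", tz="UTC")
            .tz_convert(timezone)
            .date()
        )
        key = (df["fish_id"][i], day)
        days.append(key)
        counts[key] = counts.get(key, 0) + 1
    return {i for i in range(len(df)) if counts[days[i]] > 1}


def bf_pair(records: pd.DataFrame, max_gap: float) -> list:
    """(accel positional index, (depth positional index, gap) or None)."""
    df = records.reset_index(drop=True)
    fish_ids = list(df["fish_id"])
    sensors = list(df["sensor"])
    times = list(df["timestamp"])
    depths_by_fish = {}
    for j in range(len(df)):
        if sensors[j] == "depth":
            depths_by_fish.setdefault(fish_ids[j], []).append(j)
    out = []
    for i in range(len(df)):
        if sensors[i] != "accel":
            continue
        best = None
        for j in depths_by_fish.get(fish_ids[i], ()):  # every candidate scanned
            gap = times[j] - times[i]
            if abs(gap) > max_gap:
                continue
            if (
                best is None
                or abs(gap) < abs(best[1])
                or (abs(gap) == abs(best[1]) and gap < best[1])
            ):
                best = (j, gap)
        out.append((i, best))
    return out


def random_instance(seed: int, n: int = 1000) -> pd.DataFrame:
    """A messy random detection table: echoes, value collisions, lone
    daily hits, and sometimes a fish that stops moving vertically."""
    rng = np.random.default_rng(seed)
    n_base = int(n * 0.8)
    fish = rng.choice(["f1", "f2", "f3"], size=n_base)
    t = np.sort(rng.uniform(0.0, 4 * 86400.0, size=n_base)) + 1.6121376e9
    sensor = rng.choice(["accel", "depth"], size=n_base)
    value = np.where(
        sensor == "accel",
        np.round(rng.uniform(0, 3.43, n_base), 1),  # coarse: forces collisions
        np.round(rng.uniform(1, 70, n_base), 1),
    )
    rows = pd.DataFrame(
        {
            "receiver_id": rng.choice(["A", "B"], size=n_base),
            "timestamp": t,
            "fish_id": fish,
            "sensor": sensor,
            "value": value,
        }
    )
    if rng.uniform() < 0.5:
        # one fish goes flat at depth for the rest of the record
        sel = (rows["fish_id"] == "f3") & (rows["sensor"] == "depth")
        cut = rows.loc[sel, "timestamp"].quantile(rng.uniform(0.2, 0.6))
        late = sel & (rows["timestamp"] >= cut)
        rows.loc[late, "value"] = 33.3
    # echoes: copies at the other receiver within or beyond the min delay
    n_echo = n - n_base
    src = rows.sample(n=n_echo, random_state=int(rng.integers(1 << 30)))
    echo = src.copy()
    echo["receiver_id"] = np.where(src["receiver_id"] == "A", "B", "A")
    echo["timestamp"] = src["timestamp"] + rng.uniform(1.0, 400.0, size=n_echo)
    out = pd.concat([rows, echo], ignore_index=True)
    return out.sort_values("timestamp", kind="stable", ignore_index=True)
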