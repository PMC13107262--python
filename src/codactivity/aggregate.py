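"""Per-fish aggregation of activity data.

Model datasets use one value per fish (or per fish x depth category):
the mean of all imputed acceleration values in scope, weighted by the
log of the number of detections, plus the proportion of high-activity
values P_HV (> 2 m/s^2) squeezed into (0,1) for beta regression.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "aggregate_fish",
    "compute_phv",
    "squeeze_transform",
    "build_model_table",
]

HIGH_ACTIVITY_THRESHOLD = 2.0  # m/s^2


def _log_weight(n: np.ndarray, floor: bool = True) -> np.ndarray:
    """Weight = ln(n).  With ``floor`` (default) a fish with n = 1 gets
    ln 2 instead of 0, so a detected fish is never silently excluded
    from weighted fits; set ``floor=False`` for strict ln(n)."""
    w = np.log(n.astype(float))
    if floor:
        w = np.maximum(w, np.log(2.0))
    return w


def aggregate_fish(
    pairs: pd.DataFrame,
    fish_meta: pd.DataFrame,
    grouping: str = "overall",
    season: str | None = None,
    value_col: str = "accel_imputed",
    weight_floor: bool = True,
) -> pd.DataFrame:
    """One aggregate row per fish (or fish x depth category).

    Parameters
    ----------
    grouping
        ``"overall"`` for one row per fish, ``"by_depth_category"`` for
        one row per fish and depth stratum (a fish detected both above
        and below 20 m yields two rows).
    season
        Restrict to one season label before aggregating (rows labelled
        ``omitted`` never enter model tables).

    Empty groups emit no row.  Columns: fish metadata, ``mean_activity``
    (m/s^2), ``n_detections``, ``weight`` (log n).
    """
    if grouping not in ("overall", "by_depth_category"):
        raise ValueError("grouping must be 'overall' or 'by_depth_category'")
    df = pairs
    if season is not None:
        df = df[df["season"] == season]
    df = df[df.get("season", pd.Series("", index=df.index)) != "omitted"]
    if len(df) == 0:
        cols = ["fish_id", "depth_category", "mean_activity", "n_detections", "weight"]
        return pd.DataFrame(columns=cols)
    keys = ["fish_id"] + (["depth_category"] if grouping == "by_depth_category" else [])
    agg = (
        df.groupby(keys, sort=True, observed=True)[value_col]
        .agg(mean_activity="mean", n_detections="size")
        .reset_index()
    )
    if grouping == "overall":
        agg.insert(1, "depth_category", "all")
    agg["weight"] = _log_weight(agg["n_detections"].to_numpy(), weight_floor)
    meta_cols = [c for c in ("sex", "length_cm", "ground", "year") if c in fish_meta]
    agg = agg.merge(fish_meta[["fish_id"] + meta_cols], on="fish_id", how="left")
    if season is not None:
        agg["season"] = season
    return agg


def compute_phv(
    pairs: pd.DataFrame,
    fish_meta: pd.DataFrame | None = None,
    threshold: float = HIGH_ACTIVITY_THRESHOLD,
    grouping: str = "by_depth_category",
    season: str | None = None,
    value_col: str = "accel_imputed",
) -> pd.DataFrame:
    """Per-fish proportion of high-activity values (strictly > threshold).

    High activity marks burst behaviour (chases, agonistic
    interactions); the 2 m/s^2 default follows the swimming literature
    on cod burst acceleration.  Imputed values should be used, since
    imputation can only push ceiling values further above the threshold.
    """
    df = pairs
    if season is not None:
        df = df[df["season"] == season]
    if len(df) == 0:
        return pd.DataFrame(columns=["fish_id", "depth_category", "p_hv", "n_detections"])
    keys = ["fish_id"] + (["depth_category"] if grouping == "by_depth_category" else [])
    vals = df[value_col].astype(float) > threshold
    out = (
        vals.groupby([df[k] for k in keys], observed=True)
        .agg(p_hv="mean", n_detections="size")
        .reset_index()
    )
    if grouping == "overall":
        out.insert(1, "depth_category", "all")
    if fish_meta is not None:
        meta_cols = [c for c in ("sex", "length_cm", "ground", "year") if c in fish_meta]
        out = out.merge(fish_meta[["fish_id"] + meta_cols], on="fish_id", how="left")
    return out


def squeeze_transform(p, n):
    """Squeeze proportions from [0,1] into the open interval (0,1).

    The standard compression used before beta regression:
    ``(p * (n - 1) + 0.5) / n`` with ``n`` the sample size.  Monotone in
    p, fixed point at 0.5, and converges to the identity as n grows.
    """
    p_arr = np.asarray(p, dtype=float)
    n_arr = np.asarray(n, dtype=float)
    if np.any(n_arr < 1):
        raise ValueError("sample size must be >= 1")
    if np.any((p_arr < 0) | (p_arr > 1)):
        raise ValueError("proportions must lie in [0, 1]")
    out = (p_arr * (n_arr - 1.0) + 0.5) / n_arr
    if np.ndim(p) == 0 and np.ndim(n) == 0:
        return float(out)
    return out


def build_model_table(
    pairs: pd.DataFrame,
    fish_meta: pd.DataFrame,
    season: str = "spawning",
    grouping: str = "by_depth_category",
    threshold: float = HIGH_ACTIVITY_THRESHOLD,
    weight_floor: bool = True,
) -> pd.DataFrame:
    """Analysis table: mean activity and squeezed P_HV per fish(-stratum).

    The squeeze uses the number of rows in the resulting table as the
    sample size (the convention of the transform used before beta
    regression), so every transformed value lies strictly inside (0,1).
    """
    agg = aggregate_fish(
        pairs, fish_meta, grouping=grouping, season=season, weight_floor=weight_floor
    )
    phv = compute_phv(
        pairs, threshold=threshold, grouping=grouping, season=season
    )
    keys = ["fish_id"] + (
        ["depth_category"] if grouping == "by_depth_category" else []
    )
    out = agg.merge(phv[keys + ["p_hv"]], on=keys, how="left")
    if len(out):
        out["p_hv_transformed"] = squeeze_transform(
            out["p_hv"].to_numpy(), len(out)
        )
    else:
        out["p_hv"] = pd.Series(dtype=float)
        out["p_hv_transformed"] = pd.Series(dtype=float)
    return out
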