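"""End-to-end orchestration: simulate -> process -> impute -> aggregate -> fit.

One YAML config describes a run (scenario, thresholds, model set, master
seed); :func:`run_pipeline` executes the stages, writes every
intermediate as CSV into the run directory together with a removal
ledger and a provenance file (config hash, package version, seed), and
never mutates its inputs.  Stage failures raise :class:`PipelineError`
carrying the stage name and the ledger accumulated so far.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .aggregate import build_model_table
from .censoring import impute_pairs
from .inference import ModelSpec, ModelResult, fit_model, select_aicc, summarize_result
from .processing import ProcessingConfig, process_detections
from .simulate import (
    BehaviorSpec,
    ScenarioConfig,
    SimulatedStudy,
    netpen_scenario,
    null_field_scenario,
    simulate_study,
    spawning_field_scenario,
)

__all__ = [
    "PipelineError",
    "RunConfig",
    "ModelRunSpec",
    "load_config",
    "scenario_from_dict",
    "run_pipeline",
    "write_detections",
    "read_detections",
    "write_fish",
    "read_fish",
]


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and the ledger so far."""

    def __init__(self, stage: str, message: str, ledger: pd.DataFrame | None = None):
        super().__init__(f"pipeline aborted at stage '{stage}': {message}")
        self.stage = stage
        self.ledger = ledger


# ---------------------------------------------------------------------------
# CSV interchange (ISO-8601 UTC timestamps)


def _to_iso(seconds: pd.Series) -> pd.Series:
    return pd.to_datetime(seconds, unit="s", utc=True).dt.strftime(
        "%Y-%m-%dT%H:%M:%S.%f"
    ) + "Z"


def _from_iso(col: pd.Series) -> pd.Series:
    ts = pd.to_datetime(col, utc=True, format="ISO8601")
    return ts.astype("int64") / 1e9


def write_detections(df: pd.DataFrame, path) -> None:
    out = df[["receiver_id", "timestamp", "fish_id", "sensor", "value"]].copy()
    out["timestamp"] = _to_iso(out["timestamp"])
    out.to_csv(path, index=False)


def read_detections(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"receiver_id": str, "fish_id": str, "sensor": str})
    df["timestamp"] = _from_iso(df["timestamp"])
    return df


def write_fish(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out["release_time"] = _to_iso(out["release_time"])
    out.to_csv(path, index=False)


def read_fish(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"fish_id": str, "sex": str, "ground": str})
    df["release_time"] = _from_iso(df["release_time"])
    return df


# ---------------------------------------------------------------------------
# configuration


_SCENARIO_KINDS = {
    "spawning_field": spawning_field_scenario,
    "null_field": null_field_scenario,
    "netpen": netpen_scenario,
}


def scenario_from_dict(d: dict) -> ScenarioConfig:
    """Build a scenario from a config mapping.

    ``kind`` selects a stock scenario factory; remaining keys are passed
    through as factory arguments.  An optional ``behavior`` mapping
    overrides :class:`BehaviorSpec` fields; its ``burst_rate`` and
    ``baseline_mean`` entries use space-separated keys such as
    ``"M spawning deep"``.
    """
    d = dict(d)
    kind = d.pop("kind", "spawning_field")
    if kind not in _SCENARIO_KINDS:
        raise ValueError(f"unknown scenario kind: {kind}")
    behav_cfg = d.pop("behavior", None)
    if behav_cfg is not None:
        kwargs = dict(behav_cfg)
        for key in ("burst_rate", "baseline_mean"):
            if key in kwargs:
                kwargs[key] = {
                    tuple(k.split()): float(v) for k, v in kwargs[key].items()
                }
        d["behavior"] = BehaviorSpec(**kwargs)
    return _SCENARIO_KINDS[kind](**d)


@dataclass(frozen=True)
class ModelRunSpec:
    """One model to fit in a run: which table, which model, selection?"""

    name: str
    season: str
    grouping: str  # "overall" | "by_depth_category"
    model: ModelSpec
    select: bool = True


def default_model_set(multi_year: bool = False) -> tuple[ModelRunSpec, ...]:
    """The study's model set for one ground.

    The general (overall) spawning model is a weighted LM, or an LMM
    with a year intercept when several tagging years are pooled; the
    depth-dependent spawning models are the gamma and beta GLMMs with a
    fish intercept (plus year when pooled).
    """
    general_family = "gaussian_lmm" if multi_year else "gaussian_lm"
    general_random = ("year",) if multi_year else ()
    glmm_random = ("fish_id", "year") if multi_year else ("fish_id",)
    return (
        ModelRunSpec(
            "general_spawning",
            "spawning",
            "overall",
            ModelSpec("mean_activity", general_family, ("sex", "length", "sex:length"), general_random),
        ),
        ModelRunSpec(
            "general_feeding",
            "feeding",
            "overall",
            ModelSpec("mean_activity", general_family, ("sex", "length", "sex:length"), general_random),
        ),
        ModelRunSpec(
            "activity_by_depth",
            "spawning",
            "by_depth_category",
            ModelSpec(
                "mean_activity",
                "gamma_log_glmm",
                ("sex", "depth_category", "sex:depth_category"),
                glmm_random,
            ),
        ),
        ModelRunSpec(
            "phv_by_depth",
            "spawning",
            "by_depth_category",
            ModelSpec(
                "p_hv_transformed",
                "beta_logit_glmm",
                ("sex", "depth_category", "sex:depth_category"),
                glmm_random,
            ),
        ),
    )


@dataclass(frozen=True)
class RunConfig:
    """Everything one pipeline run needs besides the master seed."""

    scenario: dict
    processing: ProcessingConfig = ProcessingConfig()
    models: tuple[ModelRunSpec, ...] | None = None  # None -> default set
    exclusion_windows: tuple[tuple[float, float], ...] = ()
    weight_floor: bool = True

    def config_hash(self) -> str:
        blob = json.dumps(_as_jsonable(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _as_jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _as_jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _as_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_as_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def load_config(path) -> RunConfig:
    """Read a YAML run configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    proc = ProcessingConfig(**raw.get("processing", {}))
    models = None
    if "models" in raw:
        models = tuple(
            ModelRunSpec(
                name=m["name"],
                season=m.get("season", "spawning"),
                grouping=m.get("grouping", "overall"),
                model=ModelSpec(
                    response=m["response"],
                    family=m["family"],
                    fixed=tuple(m.get("fixed", ())),
                    random=tuple(m.get("random", ())),
                    weights=m.get("weights", "log_n"),
                ),
                select=m.get("select", True),
            )
            for m in raw["models"]
        )
    excl = tuple(
        (float(w["start"]), float(w["end"]))
        for w in raw.get("exclusion_windows", [])
    )
    return RunConfig(
        scenario=raw.get("scenario", {}),
        processing=proc,
        models=models,
        exclusion_windows=excl,
        weight_floor=raw.get("weight_floor", True),
    )


# ---------------------------------------------------------------------------
# the run


@dataclass
class PipelineResult:
    """In-memory bundle of one pipeline run."""

    study: SimulatedStudy
    pairs: pd.DataFrame
    ledger: pd.DataFrame
    imputation_report: pd.DataFrame
    tables: dict
    models: dict
    selections: dict
    outdir: Path | None = None


def run_pipeline(
    config: RunConfig, seed: int, outdir=None, write: bool = True
) -> PipelineResult:
    """Execute one full run; deterministic given (config, seed).

    Stage order: simulate, process (clock/filters/pairing/scope/trim),
    impute (censored-Gaussian per dataset), aggregate (per-fish tables
    per model), fit (with AICc selection where requested).  All outputs
    are written fresh into ``outdir``; inputs are never mutated.
    """
    out = Path(outdir) if outdir is not None else None
    if write and out is not None:
        out.mkdir(parents=True, exist_ok=True)
    ledger_df = None

    def fail(stage, msg):
        raise PipelineError(stage, msg, ledger_df)

    # --- simulate
    try:
        scenario = scenario_from_dict(config.scenario)
        study = simulate_study(scenario, seed)
    except (ValueError, KeyError, TypeError) as err:
        fail("simulate", str(err))
    if len(study.detections) == 0:
        fail("simulate", "no detections generated")

    # --- process
    excl = pd.DataFrame(config.exclusion_windows, columns=["start", "end"], dtype=float)
    if len(study.exclusion_windows):
        excl = pd.concat([excl, study.exclusion_windows], ignore_index=True)
    pairs, ledger_df, proc_stats = process_detections(
        study.detections,
        study.fish,
        study.receivers,
        config.processing,
        excl if len(excl) else None,
    )
    if len(pairs) == 0:
        _write_common(out, write, study, pairs, ledger_df, None, config, seed, {})
        fail("process", "no paired activity records in scope")

    # --- impute
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xCE]))
    pairs, imp_report = impute_pairs(pairs, study.fish, rng)

    # --- aggregate & fit
    model_specs = config.models
    if model_specs is None:
        model_specs = default_model_set(multi_year=study.fish["year"].nunique() > 1)
    tables: dict[str, pd.DataFrame] = {}
    models: dict[str, ModelResult] = {}
    selections = {}
    for mrs in model_specs:
        key = (mrs.season, mrs.grouping)
        tkey = f"{mrs.season}_{mrs.grouping}"
        if tkey not in tables:
            tables[tkey] = build_model_table(
                pairs,
                study.fish,
                season=mrs.season,
                grouping=mrs.grouping,
                threshold=config.processing.high_activity_threshold,
                weight_floor=config.weight_floor,
            )
        table = tables[tkey]
        if len(table) == 0:
            warnings.warn(
                f"no data for model {mrs.name} ({tkey}): skipped", stacklevel=2
            )
            continue
        try:
            if mrs.select:
                sel = select_aicc(mrs.model, table)
                selections[mrs.name] = sel
                models[mrs.name] = sel.final
            else:
                models[mrs.name] = fit_model(mrs.model, table)
        except ValueError as err:
            _write_common(out, write, study, pairs, ledger_df, imp_report, config, seed, tables)
            fail("fit", f"{mrs.name}: {err}")
    if not models:
        _write_common(out, write, study, pairs, ledger_df, imp_report, config, seed, tables)
        fail("fit", "no model dataset contained any data")

    if write and out is not None:
        _write_common(out, write, study, pairs, ledger_df, imp_report, config, seed, tables)
        for name, res in models.items():
            res.coefficients.to_csv(out / f"model_{name}_coefficients.csv", index=False)
            (out / f"model_{name}_summary.txt").write_text(summarize_result(res))
        for name, sel in selections.items():
            st = sel.model_table.copy()
            st["terms"] = st["terms"].map(lambda t: "+".join(t) if t else "(intercept)")
            st.to_csv(out / f"model_{name}_selection.csv", index=False)
    return PipelineResult(
        study=study,
        pairs=pairs,
        ledger=ledger_df,
        imputation_report=imp_report,
        tables=tables,
        models=models,
        selections=selections,
        outdir=out,
    )


def _write_common(out, write, study, pairs, ledger_df, imp_report, config, seed, tables):
    if not write or out is None:
        return
    out.mkdir(parents=True, exist_ok=True)
    write_detections(study.detections, out / "detections.csv")
    write_fish(study.fish, out / "fish.csv")
    if pairs is not None and len(pairs):
        p = pairs.copy()
        p["timestamp"] = _to_iso(p["timestamp"])
        keep = [
            c
            for c in (
                "fish_id", "timestamp", "accel", "accel_imputed", "depth",
                "pair_gap", "season", "depth_category",
            )
            if c in p
        ]
        p[keep].to_csv(out / "paired_activity.csv", index=False)
    if ledger_df is not None:
        ledger_df.to_csv(out / "ledger.csv", index=False)
    if imp_report is not None:
        imp_report.to_csv(out / "imputation_report.csv", index=False)
    for tkey, table in tables.items():
        table.to_csv(out / f"aggregates_{tkey}.csv", index=False)
    prov = {
        "package": "codactivity",
        "version": __version__,
        "seed": int(seed),
        "config_hash": config.config_hash(),
    }
    (out / "provenance.json").write_text(json.dumps(prov, indent=2, sort_keys=True))
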