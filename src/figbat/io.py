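"""CSV readers/writers, run configuration and the end-to-end pipeline.

All tables are plain CSV.  Writers prepend ``#``-prefixed header lines
carrying the config hash and seed so every output is traceable; readers
skip them.  Timestamps are epoch seconds; an ISO-8601 ingestion path is
provided for fix files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
import pathlib
from typing import Any, Sequence

import numpy as np
import pandas as pd
import yaml

from . import encounters as enc_mod
from . import manipulation as manip_mod
from . import synth, tracks

logger = logging.getLogger(__name__)


class SchemaError(ValueError):
    """An input table is missing a required column."""


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")


_REQUIRED = {
    "fixes": synth.FIX_COLUMNS,
    "trees": synth.TREE_COLUMNS,
    "visits": synth.VISIT_COLUMNS,
    "manifest": synth.MANIFEST_COLUMNS,
    "roster": synth.ROSTER_COLUMNS,
}


def _check_schema(df: pd.DataFrame, kind: str) -> None:
    for col in _REQUIRED[kind]:
        if col not in df.columns:
            raise SchemaError(f"{kind} table missing required column {col!r}")


def _read_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def read_fixes(path) -> pd.DataFrame:
    """Load a fix table: sort by (tag, t), drop NaN coordinates and
    duplicate (tag, t) rows, accept ISO-8601 or epoch-second times."""
    df = pd.read_csv(path, comment="#")
    if "time" in df.columns and "t" not in df.columns:
        df = df.rename(columns={"time": "t"})
    _check_schema(df, "fixes")
    if df["t"].dtype == object:
        df["t"] = pd.to_datetime(df["t"], utc=True).astype(np.int64) / 10**9
    bad = df[["x", "y"]].isna().any(axis=1)
    if bad.any():
        logger.info("dropping %d fixes with NaN coordinates", int(bad.sum()))
        df = df[~bad]
    before = len(df)
    df = df.drop_duplicates(subset=["tag_id", "t"], keep="first")
    if len(df) < before:
        logger.info("dropped %d duplicated (tag, t) fixes", before - len(df))
    return df.sort_values(["tag_id", "t"], ignore_index=True)


def read_trees(path) -> pd.DataFrame:
    df = _read_csv(path)
    _check_schema(df, "trees")
    return df


def read_visits(path) -> pd.DataFrame:
    df = _read_csv(path)
    _check_schema(df, "visits")
    df["tree_id"] = df["tree_id"].astype("Int64")
    return df


def read_manifest(path) -> pd.DataFrame:
    df = _read_csv(path)
    _check_schema(df, "manifest")
    return df


def read_roster(path) -> pd.DataFrame:
    df = _read_csv(path)
    _check_schema(df, "roster")
    return df


def write_table(df: pd.DataFrame, path, meta: dict[str, Any] | None = None) -> None:
    path = pathlib.Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for k, v in (meta or {}).items():
            fh.write(f"# {k}={v}\n")
        df.to_csv(fh, index=False)


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class RunConfig:
    """Everything one pipeline run needs, loadable from YAML."""

    seed: int = 0
    simulate: bool = True
    manipulation_night: int | None = None
    fixes_path: str | None = None
    trees_path: str | None = None
    manifest_path: str | None = None
    roster_path: str | None = None
    sim: synth.SimConfig = dataclasses.field(default_factory=synth.SimConfig)
    segmenter: tracks.SegmenterParams = dataclasses.field(
        default_factory=tracks.SegmenterParams
    )
    windows: Sequence[int] = (1, 2, 3, 4, 5, 6)
    min_cohort: int = 70
    n_iterations: int = 215
    lags: Sequence[int] = (1, 2, 3, 4, 5, 6)
    ficus_only: bool = False
    log_level: str = "INFO"

    def validate(self) -> None:
        if not self.simulate:
            for name in ("fixes_path", "trees_path", "manifest_path", "roster_path"):
                p = getattr(self, name)
                if p is None or not pathlib.Path(p).exists():
                    raise FileNotFoundError(f"{name} missing or does not exist: {p}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sim"] = dataclasses.asdict(self.sim)
        d["segmenter"] = dataclasses.asdict(self.segmenter)
        d["windows"] = list(self.windows)
        d["lags"] = list(self.lags)
        d["sim"]["lag_pmf"] = list(self.sim.lag_pmf)
        return d

    def hash(self) -> str:
        canon = yaml.safe_dump(_plain(self.to_dict()), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:12]


def _plain(obj):
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def load_run_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    sim = synth.SimConfig(**{
        **raw.get("sim", {}),
        **({"lag_pmf": tuple(raw["sim"]["lag_pmf"])} if "lag_pmf" in raw.get("sim", {}) else {}),
    })
    seg = tracks.SegmenterParams(**raw.get("segmenter", {}))
    top = {k: v for k, v in raw.items() if k not in ("sim", "segmenter")}
    cfg = RunConfig(sim=sim, segmenter=seg, **top)
    cfg.validate()
    return cfg


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------


def run_pipeline(config: RunConfig, outdir) -> dict[str, pd.DataFrame]:
    """simulate (optional) -> segment -> manipulation test -> encounters.

    Every output CSV carries the config hash and seed; identical configs
    produce byte-identical outputs.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    config.validate()
    outdir = pathlib.Path(outdir)
    meta = {"config_hash": config.hash(), "seed": config.seed}
    rng = np.random.default_rng(config.seed)
    out: dict[str, pd.DataFrame] = {}

    try:
        if config.simulate:
            cfg = dataclasses.replace(config.sim, seed=config.seed)
            result = synth.simulate_experiment(
                cfg,
                manipulation_night=config.manipulation_night,
                render_fixes=True,
                rng=rng,
            )
            fixes, trees = result.fixes, result.trees
            manifest, roster = result.manifest, result.roster
            write_table(trees, outdir / "trees.csv", meta)
            write_table(fixes, outdir / "fixes.csv", meta)
            write_table(result.truth, outdir / "truth.csv", meta)
            if manifest is not None:
                write_table(manifest, outdir / "manifest.csv", meta)
            write_table(roster, outdir / "roster.csv", meta)
        else:
            fixes = read_fixes(config.fixes_path)
            trees = read_trees(config.trees_path)
            manifest = read_manifest(config.manifest_path)
            roster = read_roster(config.roster_path)
    except Exception as e:  # noqa: BLE001
        raise PipelineError("simulate/load", e) from e

    try:
        visits = tracks.segment_all(fixes, trees, config.segmenter)
        write_table(visits, outdir / "visits.csv", meta)
        out["visits"] = visits
    except Exception as e:  # noqa: BLE001
        raise PipelineError("segment", e) from e

    focal = list(trees.loc[trees["is_focal"].astype(bool), "tree_id"])
    if manifest is not None and focal:
        try:
            report = manip_mod.run_manipulation_test(
                visits,
                manifest,
                roster,
                focal,
                windows=config.windows,
                min_cohort=config.min_cohort,
                n_iterations=config.n_iterations,
                rng=rng,
            )
            write_table(report, outdir / "manipulation_report.csv", meta)
            out["manipulation_report"] = report
        except Exception as e:  # noqa: BLE001
            raise PipelineError("manip-test", e) from e

    try:
        try:
            enc = enc_mod.run_encounter_analysis(
                visits,
                roster,
                trees=trees,
                lags=config.lags,
                ficus_only=config.ficus_only,
                rng=rng,
            )
        except enc_mod.InsufficientControlsError as e:
            logger.warning("encounter models skipped: %s", e)
            empty = pd.DataFrame(columns=enc_mod.RECORD_COLUMNS)
            enc = {
                "encounters": enc_mod.detect_encounters(visits),
                "records": empty,
                "models": enc_mod.fit_lag_models(empty, config.lags),
            }
        write_table(enc["encounters"], outdir / "encounters.csv", meta)
        write_table(enc["records"], outdir / "discovery_records.csv", meta)
        write_table(enc["models"], outdir / "lag_models.csv", meta)
        out.update(enc)
    except Exception as e:  # noqa: BLE001
        raise PipelineError("encounters", e) from e
    return out
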