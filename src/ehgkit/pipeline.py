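"""End-to-end study runner: simulate -> preprocess -> features -> stats
-> train -> report, from a single YAML config with one global seed.

The global seed is fanned out to per-stage seeds by hashing
(seed, stage-name), so any stage can be rerun independently and still
reproduce the full run bit for bit. Every produced file is listed in the
run manifest together with a hash of the resolved configuration.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .evaluate import StudyReport, aggregate_report, report_to_frame
from .features import FeatureConfig, OBSTETRIC_NAMES, SpectralConfig, extract_cohort_features
from .model import INPUT_SETS, ModelConfig, run_study
from .preprocess import preprocess_recording
from .simulate import Cohort, SyntheticCohortConfig, generate_cohort, write_cohort
from .stats import feature_table, table_to_markdown

logger = logging.getLogger(__name__)


def derive_seed(seed: int, stage: str) -> int:
    """Stable per-stage seed below 2^31 from the global seed."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31 - 1)


@dataclass
class RunConfig:
    """Resolved configuration of one full study run."""

    seed: int = 0
    horizons: tuple[int, ...] = (7, 14)
    input_sets: tuple[str, ...] = INPUT_SETS
    class_effect: float = 1.0
    n_per_class: tuple[int, int] | None = None  # None = clinical imbalance
    duration_s: float = 1800.0
    fs_out: float = 20.0
    artifact_fraction: float = 0.0
    band: tuple[float, float] = (0.1, 4.0)
    write_signals: bool = False
    features: FeatureConfig = field(default_factory=FeatureConfig)
    model: ModelConfig = field(default_factory=ModelConfig)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs = dict(raw)
        if "features" in kwargs and isinstance(kwargs["features"], dict):
            fdict = dict(kwargs["features"])
            if "spectral" in fdict and isinstance(fdict["spectral"], dict):
                fdict["spectral"] = SpectralConfig(
                    **{k: tuple(v) for k, v in fdict["spectral"].items()}
                )
            kwargs["features"] = FeatureConfig(**fdict)
        if "model" in kwargs and isinstance(kwargs["model"], dict):
            mdict = dict(kwargs["model"])
            if "hidden_grid" in mdict:
                mdict["hidden_grid"] = tuple(mdict["hidden_grid"])
            kwargs["model"] = ModelConfig(**mdict)
        for key in ("horizons", "input_sets", "n_per_class", "band"):
            if key in kwargs and kwargs[key] is not None:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)

    def config_hash(self) -> str:
        canon = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


@dataclass
class RunManifest:
    """Provenance record of one run (reproducible given config + seed)."""

    config_hash: str
    seed: int
    package_version: str
    stages: dict[str, float] = field(default_factory=dict)  # stage -> seconds
    files: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True))


def build_design_matrix(
    features: pd.DataFrame, obstetric: pd.DataFrame, input_set: str
) -> np.ndarray:
    """Feature matrix for one classifier input set (23 / 6 / 29 columns)."""
    if input_set == "ehg":
        return features.to_numpy(dtype=float)
    if input_set == "obstetric":
        return obstetric[list(OBSTETRIC_NAMES)].to_numpy(dtype=float)
    if input_set == "both":
        return np.hstack(
            [features.to_numpy(dtype=float), obstetric[list(OBSTETRIC_NAMES)].to_numpy(dtype=float)]
        )
    raise ValueError(f"unknown input set {input_set!r}; expected one of {INPUT_SETS}")


@dataclass
class HorizonResults:
    """All artifacts computed for one prediction horizon."""

    cohort: Cohort
    features: pd.DataFrame
    stats_table: pd.DataFrame
    reports: dict[str, StudyReport]  # input set -> report


def run_horizon(config: RunConfig, horizon: int) -> HorizonResults:
    """Simulate, characterize and model one prediction horizon."""
    cohort_cfg = SyntheticCohortConfig(
        n_per_class=config.n_per_class,
        duration_s=config.duration_s,
        fs_out=config.fs_out,
        class_effect=config.class_effect,
        artifact_fraction=config.artifact_fraction,
        seed=derive_seed(config.seed, f"simulate-h{horizon}"),
        horizon=horizon,
    )
    cohort = generate_cohort(cohort_cfg)
    processed = [
        preprocess_recording(rec, fs_out=config.fs_out, band=config.band)
        for rec in cohort.recordings
    ]
    features = extract_cohort_features(processed, config.features)
    labels = cohort.labels[f"label_ttd{horizon}"].to_numpy()
    kept = features.index  # recordings excluded during extraction drop out
    id_to_row = {rec.recording_id: i for i, rec in enumerate(cohort.recordings)}
    rows = [id_to_row[rid] for rid in kept]
    obstetric = cohort.obstetric.iloc[rows].reset_index(drop=True)
    y = labels[rows]
    feats = features.reset_index(drop=True)

    stats_table = feature_table(feats, obstetric, y)

    reports: dict[str, StudyReport] = {}
    for input_set in config.input_sets:
        X = build_design_matrix(feats, obstetric, input_set)
        results = run_study(
            X, y, config.model, seed=derive_seed(config.seed, f"train-h{horizon}-{input_set}")
        )
        reports[input_set] = aggregate_report(results)
    return HorizonResults(cohort=cohort, features=feats, stats_table=stats_table, reports=reports)


def run_all(config: RunConfig | str | Path, out_dir: str | Path) -> RunManifest:
    """Run every stage for every configured horizon and write all outputs."""
    if not isinstance(config, RunConfig):
        config = RunConfig.from_yaml(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config_hash=config.config_hash(), seed=config.seed, package_version=__version__
    )

    def record(path: Path) -> None:
        manifest.files.append(str(path.relative_to(out)))

    resolved = out / "config.resolved.yaml"
    resolved.write_text(yaml.safe_dump(asdict(config), sort_keys=True))
    record(resolved)

    for horizon in config.horizons:
        t0 = time.time()
        logger.info("running horizon %d", horizon)
        res = run_horizon(config, horizon)
        hdir = out / f"horizon_{horizon}"
        hdir.mkdir(exist_ok=True)

        for p in write_cohort(res.cohort, hdir, write_signals=config.write_signals):
            record(p)
        fpath = hdir / "features.csv"
        res.features.to_csv(fpath, index=False, float_format="%.8g")
        record(fpath)
        spath = hdir / "stats.csv"
        res.stats_table.to_csv(spath, index=False, float_format="%.6g")
        record(spath)
        mdpath = hdir / "stats.md"
        mdpath.write_text(table_to_markdown(res.stats_table, horizon))
        record(mdpath)
        for input_set, report in res.reports.items():
            base = hdir / f"report_{input_set}"
            rpath = base.with_suffix(".csv")
            report_to_frame(report).to_csv(rpath, index=False, float_format="%.4f")
            record(rpath)
            roc_path = hdir / f"roc_{input_set}.csv"
            report.mean_roc.to_csv(roc_path, index=False, float_format="%.6f")
            record(roc_path)
            conf_path = hdir / f"confusion_{input_set}.csv"
            report.mean_confusion.to_csv(conf_path, float_format="%.4f")
            record(conf_path)
        manifest.stages[f"horizon_{horizon}"] = round(time.time() - t0, 3)

    mpath = out / "manifest.json"
    manifest.to_json(mpath)
    record(mpath)
    return manifest
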