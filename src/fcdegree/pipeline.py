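"""End-to-end orchestration of the degree-centrality analysis.

The pipeline is a pure function of ``(inputs, config, seed)``: every stage's
outputs land in a dedicated subdirectory of the artifact tree together with
the config hash, and a rerun with an unchanged config reuses cached stage
outputs. Stage order mirrors the analysis: simulate (optional) ->
preprocess + degree -> group statistics -> clinical correlations ->
classification -> demographics report.

Global-signal-regression on/off runs write parallel trees (``gsr-on`` /
``gsr-off``) when requested via the config.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError, DataError
from . import imaging_io as io
from .classify import ClassifyConfig, classify_clusters, extract_features
from .clincorr import (
    DEFAULT_CLINICAL_VARS,
    DEFAULT_COVARIATES,
    cluster_clinical_screen,
)
from .degree import DegreeConfig, DegreeMap, degree_map
from .demographics import demographics_table
from .groupstats import StatsConfig, group_comparison
from .preprocess import PreprocessConfig, preprocess_run
from .synthcohort import SimulationConfig, gray_matter_mask, simulate_cohort

ALL_STAGES = ("simulate", "preprocess", "degree", "stats", "correlate",
              "classify", "report")


def analyze_synthetic_cohort(
    sim_config: SimulationConfig,
    preprocess_config: PreprocessConfig | None = None,
    degree_config: DegreeConfig | None = None,
    stats_config: StatsConfig | None = None,
):
    """Simulate one cohort in memory and run it through preprocessing,
    degree mapping and the GRF-corrected group comparison.

    Avoids disk round-trips, so Monte-Carlo studies (familywise-error
    calibration, parameter recovery) stay fast. Returns a dict with the
    cluster ``table``, ``label_map``, per-subject ``maps``, ``phenotypes``
    (including measured mean FD), the ``mask`` and the run ``info``.
    """
    from .synthcohort import sample_phenotype, simulate_subject

    preprocess_config = preprocess_config or PreprocessConfig()
    degree_config = degree_config or DegreeConfig()
    stats_config = stats_config or StatsConfig()
    mask = gray_matter_mask(sim_config)
    maps, records, fd_means = [], [], []
    sid = 0
    for group, count in (("patient", sim_config.n_patients),
                         ("control", sim_config.n_controls)):
        for _ in range(count):
            sid += 1
            run, motion, nuis = simulate_subject(sim_config, group, sid)
            run, qc = preprocess_run(
                run, motion, nuis["wm"], nuis["csf"], preprocess_config, mask
            )
            maps.append(degree_map(run, mask, degree_config))
            pheno_rng = np.random.default_rng(
                [sim_config.seed, sid, 1000 + (group == "patient")]
            )
            records.append(sample_phenotype(group, f"s{sid:03d}", pheno_rng))
            fd_means.append(qc["fd_mean"])
    phenotypes = io.phenotypes_to_frame(records)
    phenotypes["fd_mean"] = fd_means
    table, label_map, thresholded, info = group_comparison(
        maps, phenotypes, stats_config, mask, mask.affine
    )
    return {
        "table": table,
        "label_map": label_map,
        "thresholded_t": thresholded,
        "maps": maps,
        "phenotypes": phenotypes,
        "mask": mask,
        "info": info,
    }


@dataclass
class RunConfig:
    """Nested stage configurations plus IO paths, seed and stage list."""

    output_dir: str = "fcdegree-run"
    input_dir: str | None = None  # existing cohort; None = simulate
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    degree: DegreeConfig = field(default_factory=DegreeConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)
    classify: ClassifyConfig = field(default_factory=ClassifyConfig)
    clinical_vars: tuple[str, ...] = DEFAULT_CLINICAL_VARS
    clinical_covariates: tuple[str, ...] = DEFAULT_COVARIATES

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ConfigurationError(f"unknown stages {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        for key, sub in (
            ("simulation", SimulationConfig),
            ("preprocess", PreprocessConfig),
            ("degree", DegreeConfig),
            ("stats", StatsConfig),
            ("classify", ClassifyConfig),
        ):
            if key in raw:
                params = dict(raw.pop(key))
                for k, v in params.items():
                    if isinstance(v, list):
                        params[k] = tuple(v)
                kwargs[key] = sub(**params)
        for k, v in raw.items():
            if isinstance(v, list):
                v = tuple(v)
            kwargs[k] = v
        try:
            return cls(**kwargs)
        except TypeError as exc:
            raise ConfigurationError(f"bad run config: {exc}") from exc

    def to_dict(self) -> dict:
        def convert(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: convert(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, tuple):
                return [convert(v) for v in obj]
            return obj

        return {f.name: convert(getattr(self, f.name))
                for f in dataclasses.fields(self)}

    def hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


class _RunLog:
    def __init__(self, path: Path):
        self.path = path
        self.path.parent.mkdir(parents=True, exist_ok=True)

    def write(self, **event) -> None:
        event["time"] = time.strftime("%Y-%m-%dT%H:%M:%S")
        with open(self.path, "a") as fh:
            fh.write(json.dumps(event) + "\n")


def _stage_done(stage_dir: Path, config_hash: str) -> bool:
    marker = stage_dir / ".hash"
    return marker.exists() and marker.read_text().strip() == config_hash


def _mark_done(stage_dir: Path, config_hash: str) -> None:
    (stage_dir / ".hash").write_text(config_hash)


def run_pipeline(config: RunConfig) -> Path:
    """Execute the configured stages; returns the artifact directory.

    Every stage writes into ``<output_dir>/<stage>/`` and records the config
    hash; stages whose hash already matches are skipped on rerun. Any stage
    failure is re-raised annotated with the stage name.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    config_hash = config.hash()
    (out / "config.yaml").write_text(
        yaml.safe_dump({"config_hash": config_hash, **config.to_dict()},
                       sort_keys=False)
    )
    log = _RunLog(out / "run_log.jsonl")
    log.write(event="pipeline_start", config_hash=config_hash, seed=config.seed)

    state: dict = {}
    for stage in ALL_STAGES:
        if stage not in config.stages:
            continue
        stage_dir = out / stage
        try:
            _run_stage(stage, stage_dir, config, config_hash, state, log)
        except Exception as exc:
            log.write(event="stage_failed", stage=stage, error=str(exc))
            raise type(exc)(f"stage {stage!r}: {exc}") from exc
    log.write(event="pipeline_done", config_hash=config_hash)
    return out


def _run_stage(stage, stage_dir, config, config_hash, state, log):
    log.write(event="stage_start", stage=stage)
    if stage == "simulate":
        cohort_dir = Path(config.input_dir) if config.input_dir else stage_dir
        if config.input_dir is None:
            sim = dataclasses.replace(config.simulation, seed=config.seed)
            if not _stage_done(stage_dir, config_hash):
                simulate_cohort(sim, stage_dir)
                _mark_done(stage_dir, config_hash)
            state["sim_config"] = sim
        state["cohort_dir"] = cohort_dir
        return

    cohort_dir = state.get("cohort_dir")
    if cohort_dir is None:
        cohort_dir = Path(config.input_dir) if config.input_dir else (
            Path(config.output_dir) / "simulate"
        )
        state["cohort_dir"] = cohort_dir
    records = state.get("records")
    if records is None:
        records = io.read_phenotypes(cohort_dir / "phenotypes.csv")
        state["records"] = records
        state["mask"] = io.read_mask(cohort_dir / "gm_mask.nii.gz")

    if stage == "preprocess" or stage == "degree":
        # preprocessing and degree mapping run jointly per subject so each
        # run is loaded once
        if "maps" in state:
            return
        stage_dir.mkdir(parents=True, exist_ok=True)
        degree_dir = Path(config.output_dir) / "degree"
        degree_dir.mkdir(parents=True, exist_ok=True)
        mask = state["mask"]
        maps: list[DegreeMap] = []
        qcs = []
        for rec in records:
            run = io.read_bold(rec.bold_path)
            motion = io.read_motion(rec.motion_path)
            nuis = io.read_nuisance(rec.nuisance_path)
            run, qc = preprocess_run(
                run, motion, nuis["wm"].to_numpy(), nuis["csf"].to_numpy(),
                config.preprocess, mask,
            )
            dmap = degree_map(run, mask, config.degree)
            maps.append(dmap)
            qc["fd_mean"] = qc["fd_mean"]
            qcs.append(qc)
            io.write_volume(
                dmap.values, mask.affine,
                degree_dir / f"sub-{rec.subject_id}_degree.nii.gz",
            )
            sidecar = degree_dir / f"sub-{rec.subject_id}_degree.json"
            sidecar.write_text(json.dumps(dataclasses.asdict(dmap.config)))
        qc_frame = pd.DataFrame(
            [{k: v for k, v in qc.items() if k != "retained_indices"}
             for qc in qcs]
        )
        qc_frame.to_csv(stage_dir / "qc.csv", index=False)
        (stage_dir / "qc.json").write_text(json.dumps(qcs, indent=1))
        state["maps"] = maps
        state["qc"] = qc_frame
        _mark_done(stage_dir, config_hash)
        _mark_done(degree_dir, config_hash)
        return

    # later stages need maps + phenotype frame with fd_mean merged in
    pheno = state.get("pheno")
    if pheno is None:
        pheno = io.phenotypes_to_frame(records)
        qc = state.get("qc")
        if qc is None:
            qc_path = Path(config.output_dir) / "preprocess" / "qc.csv"
            if qc_path.exists():
                qc = pd.read_csv(qc_path)
        if qc is not None:
            pheno = pheno.merge(
                qc[["subject_id", "fd_mean"]], on="subject_id", how="left"
            )
        state["pheno"] = pheno
    maps = state.get("maps")
    if maps is None:
        raise DataError("degree maps unavailable; run the degree stage first")
    mask = state["mask"]

    if stage == "stats":
        stage_dir.mkdir(parents=True, exist_ok=True)
        table, label_map, thresholded, info = group_comparison(
            maps, pheno, config.stats, mask, mask.affine
        )
        io.write_cluster_table(table, stage_dir / "cluster_table.tsv")
        io.write_volume(thresholded, mask.affine, stage_dir / "thresholded_t.nii.gz")
        io.write_volume(
            label_map.astype(float), mask.affine, stage_dir / "cluster_labels.nii.gz"
        )
        (stage_dir / "info.json").write_text(json.dumps(info, indent=1))
        state["cluster_table"] = table
        state["label_map"] = label_map
        log.write(event="stats_done", n_clusters=len(table), **{
            k: info[k] for k in ("df", "fwhm_vox")
        })
        _mark_done(stage_dir, config_hash)
        return

    cluster_table = state.get("cluster_table")
    label_map = state.get("label_map")
    if cluster_table is None:
        stats_dir = Path(config.output_dir) / "stats"
        cluster_table = io.read_cluster_table(stats_dir / "cluster_table.tsv")
        label_map = io.read_volume(stats_dir / "cluster_labels.nii.gz")[0].astype(int)
        state["cluster_table"] = cluster_table
        state["label_map"] = label_map

    if stage == "correlate":
        stage_dir.mkdir(parents=True, exist_ok=True)
        assoc = cluster_clinical_screen(
            maps, cluster_table, label_map, pheno,
            config.clinical_vars, config.clinical_covariates,
        )
        assoc.to_csv(stage_dir / "associations.tsv", sep="\t", index=False)
        state["associations"] = assoc
        _mark_done(stage_dir, config_hash)
        return

    if stage == "classify":
        stage_dir.mkdir(parents=True, exist_ok=True)
        if len(cluster_table) == 0:
            (stage_dir / "cv_report.json").write_text(
                json.dumps({"note": "no clusters survived; classification skipped"})
            )
            _mark_done(stage_dir, config_hash)
            return
        features = extract_features(maps, cluster_table, label_map)
        labels = pheno["group"].to_numpy()
        ccfg = dataclasses.replace(config.classify, seed=config.seed)
        report = classify_clusters(features, labels, ccfg)
        (stage_dir / "cv_report.json").write_text(
            json.dumps(report.to_dict(), indent=1)
        )
        state["cv_report"] = report
        log.write(event="classify_done", accuracy=report.accuracy,
                  permutation_p=report.permutation_p)
        _mark_done(stage_dir, config_hash)
        return

    if stage == "report":
        stage_dir.mkdir(parents=True, exist_ok=True)
        table = demographics_table(pheno)
        table.to_csv(stage_dir / "demographics.tsv", sep="\t", index=False)
        _mark_done(stage_dir, config_hash)
        return
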