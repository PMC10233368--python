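"""End-to-end pipeline: simulate -> quantify -> call -> sp-profile.

Ties the stages together behind one configuration object, writes every
intermediate table, a QC report (exclusion counts by reason, replicate-SD
distribution) and a machine-readable manifest sufficient to reproduce the
run. Any stage failure aborts with the stage name and the offending
record.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import __version__
from . import calling, hydropathy, io, quantify, simulate

log = logging.getLogger("dotscreen")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Everything a run needs: inputs, thresholds, outputs.

    The classification constants live here as auditable defaults, never
    hard-coded downstream: exclusion at a Z score of 10 below the rest of
    the membrane (one-sided), an interaction preference at a fold change
    strictly greater than two, and a replicate-SD reproducibility flag at
    3.
    """

    screen: simulate.ScreenConfig = field(default_factory=simulate.ScreenConfig)
    #: optional pre-existing inputs; when images_dir is set the simulate
    #: stage is skipped and images/plate map/OD are read from disk
    images_dir: str | None = None
    plate_map_path: str | None = None
    od_path: str | None = None
    annotations_path: str | None = None
    z_threshold: float = 10.0
    preference_threshold: float = 2.0
    sd_flag_threshold: float = 3.0
    min_replicates: int = 3
    od_floor: float = 0.05
    control_floor_frac: float = 0.1
    detection_floor_mode: str = "empty_quantile"
    detection_floor_quantile: float = 0.95
    detection_floor_fixed: float = 0.1
    profile_max_len: int = 25
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        for name in (
            "z_threshold", "preference_threshold", "sd_flag_threshold",
            "od_floor", "control_floor_frac", "detection_floor_fixed",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["screen"] = self.screen.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "PipelineConfig":
        d = dict(d)
        if "screen" in d and d["screen"] is not None:
            d["screen"] = simulate.ScreenConfig.from_dict(d["screen"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(io.load_yaml(path))

    def to_yaml(self, path) -> None:
        io.dump_yaml(path, self.to_dict())


@dataclass
class PipelineResult:
    preferences: pd.DataFrame
    summary: pd.DataFrame
    sets: pd.DataFrame
    profiles: pd.DataFrame | None
    qc_report: dict
    manifest: dict
    truth: simulate.SyntheticGroundTruth | None = None


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                log.info("stage %s: start", name)
                out = fn(*args, **kwargs)
                log.info("stage %s: done", name)
                return out
            except StageError:
                raise
            except Exception as exc:  # noqa: BLE001 - tag and re-raise
                raise StageError(name, str(exc)) from exc
        return wrapped
    return deco


@_stage("simulate")
def _simulate_stage(config: PipelineConfig, outdir: Path):
    screen_cfg = dataclasses.replace(config.screen, seed=config.seed)
    screen = simulate.generate_screen(screen_cfg)
    mem_dir = outdir / "membranes"
    mem_dir.mkdir(parents=True, exist_ok=True)
    for mem_id, img in screen.images.items():
        io.write_membrane_tiff(mem_dir / f"{mem_id}.tif", img)
    io.write_tsv(outdir / "plate_map.tsv", screen.plate_map)
    io.write_tsv(outdir / "od.tsv", screen.od_table)
    truth_dir = outdir / "truth"
    truth_dir.mkdir(exist_ok=True)
    io.write_tsv(truth_dir / "preys.tsv", screen.truth.preys)
    io.write_tsv(truth_dir / "signals.tsv", screen.truth.signals)
    io.write_tsv(truth_dir / "dots.tsv", screen.truth.dots)
    log.info("simulated %d membranes, %d mapped dots",
             len(screen.images), len(screen.plate_map))
    return screen


@_stage("load-inputs")
def _load_stage(config: PipelineConfig):
    plate_map = io.read_plate_map(config.plate_map_path)
    od_table = io.read_od_table(config.od_path)
    images = {}
    images_dir = Path(config.images_dir)
    for mem_id in plate_map["membrane_id"].unique():
        path = images_dir / f"{mem_id}.tif"
        if not path.exists():
            raise StageError(
                "load-inputs",
                f"plate map references membrane {mem_id!r} but image file "
                f"{path} does not exist",
            )
        images[mem_id] = io.read_membrane_tiff(path)
    return images, plate_map, od_table


@_stage("quantify")
def _quantify_stage(
    images: Mapping[str, np.ndarray], config: PipelineConfig, outdir: Path
) -> dict[str, pd.DataFrame]:
    rows = config.screen.grid_rows
    cols = config.screen.grid_cols
    dots_dir = outdir / "dots"
    dots_dir.mkdir(parents=True, exist_ok=True)
    dots = {}
    for mem_id, img in images.items():
        grid = quantify.fit_grid(img, rows=rows, cols=cols)
        df = quantify.quantify_dots(img, grid, membrane_id=mem_id)
        io.write_tsv(dots_dir / f"{mem_id}.tsv", df)
        dots[mem_id] = df
        log.info("quantified %s: %d dots, grid residual %.2fpx",
                 mem_id, len(df), grid.residual_rms)
    return dots


@_stage("call")
def _call_stage(
    dots: Mapping[str, pd.DataFrame],
    plate_map: pd.DataFrame,
    od_table: pd.DataFrame,
    config: PipelineConfig,
    outdir: Path,
):
    all_dots = pd.concat(dots.values(), ignore_index=True)
    sets = calling.build_normalized_sets(
        all_dots, plate_map,
        control_floor_frac=config.control_floor_frac,
        min_replicates=config.min_replicates,
    )
    sets = calling.apply_exclusions(
        sets, od_table,
        z_threshold=config.z_threshold,
        sd_flag_threshold=config.sd_flag_threshold,
        od_floor=config.od_floor,
    )
    floors = calling.detection_floors(
        dots, plate_map,
        mode=config.detection_floor_mode,
        quantile=config.detection_floor_quantile,
        fixed=config.detection_floor_fixed,
    )
    baits = tuple(config.screen.baits)
    mem_baits = plate_map[["membrane_id", "bait_id"]].drop_duplicates()
    bait_floor = {
        bait: max(
            floors[m] for m in mem_baits.loc[
                mem_baits["bait_id"] == bait, "membrane_id"
            ]
        )
        for bait in baits
    }
    pairs = calling.call_pairs(
        sets, baits,
        preference_threshold=config.preference_threshold,
        detection_floor=bait_floor,
    )
    summary = calling.summarize_screen(pairs)
    io.write_tsv(outdir / "normalized_sets.tsv", sets)
    io.write_tsv(outdir / "preferences.tsv", pairs)
    io.write_tsv(outdir / "summary.tsv", summary)
    log.info("called %d preys: %s", len(pairs),
             dict(zip(summary["category"], summary["count"])))
    return sets, pairs, summary, bait_floor


@_stage("sp-profile")
def _profile_stage(
    pairs: pd.DataFrame,
    annotations: pd.DataFrame,
    config: PipelineConfig,
    outdir: Path,
) -> pd.DataFrame:
    filtered = hydropathy.filter_substrates(pairs, annotations)
    groups = {}
    for cat in ("prefers_A", "prefers_B", "both"):
        seqs = filtered.loc[
            (filtered["category"] == cat)
            & filtered["is_candidate"]
            & (filtered["sp_sequence"].fillna("") != ""),
            "sp_sequence",
        ].tolist()
        if seqs:
            groups[cat] = seqs
    profiles = hydropathy.profiles_by_group(groups, max_len=config.profile_max_len)
    io.write_tsv(outdir / "profiles.tsv", profiles)
    io.write_tsv(outdir / "substrate_candidates.tsv", filtered)
    return profiles


def qc_report(sets: pd.DataFrame, pairs: pd.DataFrame) -> dict:
    """Exclusion accounting and replicate reproducibility distribution."""
    reasons = sets.loc[sets["excluded"], "exclusion_reason"].value_counts()
    sd = sets["replicate_sd"].to_numpy()
    sd = sd[np.isfinite(sd)]
    return {
        "n_sets": int(len(sets)),
        "n_excluded_sets": int(sets["excluded"].sum()),
        "exclusions_by_reason": {k: int(v) for k, v in reasons.items()},
        "n_sd_flagged": int(sets["sd_flagged"].sum()),
        "replicate_sd": {
            "max": float(sd.max()) if len(sd) else None,
            "median": float(np.median(sd)) if len(sd) else None,
            "p95": float(np.quantile(sd, 0.95)) if len(sd) else None,
        },
        "category_counts": {
            c: int(n)
            for c, n in pairs["category"].value_counts().items()
        },
    }


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> PipelineResult:
    """Run the full screen analysis and write all outputs under ``outdir``.

    Deterministic for a fixed config and seed: rerunning writes
    byte-identical tables.
    """
    logging.basicConfig(level=config.log_level)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    truth = None
    if config.images_dir is None:
        screen = _simulate_stage(config, outdir)
        images, plate_map, od_table = (
            screen.images, screen.plate_map, screen.od_table,
        )
        truth = screen.truth
    else:
        images, plate_map, od_table = _load_stage(config)

    dots = _quantify_stage(images, config, outdir)
    sets, pairs, summary, floors = _call_stage(
        dots, plate_map, od_table, config, outdir
    )

    profiles = None
    annotations = None
    if config.annotations_path is not None:
        annotations = io.read_annotations(config.annotations_path)
    elif truth is not None:
        annotations = simulate.synthetic_annotations(
            truth.preys, seed=config.seed
        )
        io.write_tsv(outdir / "annotations.tsv", annotations)
    if annotations is not None:
        profiles = _profile_stage(pairs, annotations, config, outdir)

    report = qc_report(sets, pairs)
    report["detection_floors"] = {k: float(v) for k, v in floors.items()}
    manifest = {
        "tool": "dotscreen",
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "outputs": sorted(
            str(p.relative_to(outdir)) for p in outdir.rglob("*") if p.is_file()
        ),
    }
    with open(outdir / "qc_report.json", "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return PipelineResult(
        preferences=pairs,
        summary=summary,
        sets=sets,
        profiles=profiles,
        qc_report=report,
        manifest=manifest,
        truth=truth,
    )
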