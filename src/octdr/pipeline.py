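"""End-to-end pipeline: simulate -> segment -> features -> train -> evaluate.

Each stage writes its artifacts under the output directory and the run
ends with an output manifest (path -> sha256) plus a provenance block
(config hash, global seed, package version) embedded in every report.
One global seed is fanned out to per-stage seeds by fixed offsets so
stages are reproducible independently of each other.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from PIL import Image

from ._version import __version__ as _pkg_version
from .classifier import AutoencoderSpec, classify, train_stage, pretrain_autoencoders
from .evaluation import plan_folds, run_cv
from .features import DEFAULT_GRIDS, assemble_descriptor
from .geometry import LayerMap
from .io import (
    read_boundaries,
    read_bscan,
    read_manifest,
    load_model,
    save_model,
    write_boundaries,
    write_bscan,
    write_descriptors,
    read_descriptors,
    write_manifest,
    write_report,
)
from .segmentation import MGRFParams, build_shape_atlas, segment_bscan
from .synthetic import PhantomConfig, generate_cohort

logger = logging.getLogger("octdr")

STAGES = ("simulate", "segment", "features", "train", "evaluate")

# fixed offsets fanning the global seed out to stages
_SEED_OFFSETS = {"cohort": 0, "atlas": 101, "classifier": 202,
                 "folds": 303, "bootstrap": 404}


class PipelineError(RuntimeError):
    """A stage failure; the message names the stage and record."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")


@dataclass
class PipelineConfig:
    """Everything a full run needs; round-trips losslessly through YAML."""

    out_dir: str = "octdr_out"
    seed: int = 1
    n_subjects: int = 80
    grade_mix: tuple[float, float, float] = (0.5, 0.25, 0.25)
    n_atlas_subjects: int = 6
    phantom: dict = field(default_factory=dict)      # PhantomConfig overrides
    potts_potential: float = 4.0
    icm_max_iters: int = 12
    icm_tol: float = 1e-4
    classifier: dict = field(default_factory=dict)   # AutoencoderSpec overrides
    eval_scheme: str = "loso"
    eval_k: int = 2
    n_boot: int = 2000
    images_dir: str | None = None  # read an existing cohort instead of simulating

    def __post_init__(self) -> None:
        self.grade_mix = tuple(self.grade_mix)
        _check_keys(self.phantom, PhantomConfig, "phantom")
        _check_keys(self.classifier, AutoencoderSpec, "classifier")

    # -- (de)serialization -------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["grade_mix"] = list(self.grade_mix)
        return d

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    # -- derived objects ---------------------------------------------------
    def phantom_config(self, **extra) -> PhantomConfig:
        return PhantomConfig(**{**self.phantom, **extra})

    def mgrf_params(self) -> MGRFParams:
        return MGRFParams(potts_potential=self.potts_potential,
                          icm_max_iters=self.icm_max_iters,
                          icm_tol=self.icm_tol)

    def autoencoder_spec(self) -> AutoencoderSpec:
        return AutoencoderSpec(**{"seed": self.stage_seed("classifier"),
                                  **self.classifier})

    def stage_seed(self, stage: str) -> int:
        return (self.seed + _SEED_OFFSETS[stage]) % (2**31 - 1)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _check_keys(overrides: dict, cls, name: str) -> None:
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(overrides) - known
    if unknown:
        raise ValueError(f"unknown {name} config keys: {sorted(unknown)}")


def provenance(config: PipelineConfig) -> dict:
    return {"config_hash": config.config_hash(), "seed": config.seed,
            "package_version": _pkg_version}


# ---------------------------------------------------------------------------
# Stage implementations
# ---------------------------------------------------------------------------

def _eye_stem(subject_id: str, eye: str) -> str:
    return f"{subject_id}_{eye}"


def stage_simulate(config: PipelineConfig, out: Path) -> pd.DataFrame:
    """Generate the cohort, write images + truth boundaries + manifest."""
    img_dir = out / "images"
    img_dir.mkdir(parents=True, exist_ok=True)
    records, manifest = generate_cohort(
        config.n_subjects, config.grade_mix, config.phantom_config(),
        seed=config.stage_seed("cohort"))
    rows = []
    for rec in records:
        stem = _eye_stem(rec.truth.subject_id, rec.truth.eye)
        image_path = img_dir / f"{stem}.tiff"
        meta_path = img_dir / f"{stem}.json"
        truth_path = img_dir / f"{stem}_truth.csv"
        write_bscan(rec.scan, image_path, meta_path)
        write_boundaries(rec.truth.boundaries, truth_path)
        rows.append({
            "subject_id": rec.truth.subject_id, "eye": rec.truth.eye,
            "grade": rec.truth.grade, "image_path": str(image_path),
            "meta_path": str(meta_path), "boundary_path": str(truth_path),
        })
    manifest = pd.DataFrame(rows)
    write_manifest(manifest, out / "manifest.csv")
    logger.info("simulate: wrote %d eyes to %s", len(rows), img_dir)
    return manifest


LABELMAP_PALETTE_NOTE = "8-bit PNG; pixel value = label index 0..13"


def stage_segment(config: PipelineConfig, out: Path,
                  manifest: pd.DataFrame) -> pd.DataFrame:
    """Build the normal-template shape atlas, segment every eye."""
    seg_dir = out / "segmentation"
    seg_dir.mkdir(parents=True, exist_ok=True)
    atlas_records, _ = generate_cohort(
        config.n_atlas_subjects, (1.0, 0.0, 0.0), config.phantom_config(),
        seed=config.stage_seed("atlas"))
    atlas = build_shape_atlas([r.truth.layer_map for r in atlas_records])
    mgrf = config.mgrf_params()

    rows = []
    for _, row in manifest.iterrows():
        stem = _eye_stem(row["subject_id"], row["eye"])
        try:
            scan = read_bscan(row["image_path"], row["meta_path"])
            lmap, bset, _ = segment_bscan(scan, atlas, mgrf=mgrf)
        except Exception as exc:  # noqa: BLE001 - annotate and re-raise
            raise PipelineError("segment", f"record {stem}: {exc}") from exc
        bpath = seg_dir / f"{stem}_boundaries.csv"
        lpath = seg_dir / f"{stem}_labels.png"
        write_boundaries(bset, bpath)
        Image.fromarray(lmap.labels.astype(np.uint8)).save(lpath)
        r = dict(row)
        r["seg_boundary_path"] = str(bpath)
        r["labelmap_path"] = str(lpath)
        r["fovea_column_px"] = (lmap.fovea_column_px
                                if lmap.fovea_column_px is not None else -1)
        rows.append(r)
        logger.debug("segment: %s done", stem)
    seg_manifest = pd.DataFrame(rows)
    seg_manifest.to_csv(out / "segmentation_manifest.csv", index=False)
    logger.info("segment: %d eyes segmented", len(rows))
    return seg_manifest


def stage_features(config: PipelineConfig, out: Path,
                   seg_manifest: pd.DataFrame) -> list:
    """Assemble the 36-CDF descriptor for every eye."""
    feat_dir = out / "features"
    feat_dir.mkdir(parents=True, exist_ok=True)
    descriptors = []
    for _, row in seg_manifest.iterrows():
        stem = _eye_stem(row["subject_id"], row["eye"])
        try:
            scan = read_bscan(row["image_path"], row["meta_path"])
            labels = np.asarray(Image.open(row["labelmap_path"]))
            fovea = int(row["fovea_column_px"])
            lmap = LayerMap(labels, fovea_column_px=(fovea if fovea >= 0 else None))
            bset = read_boundaries(row["seg_boundary_path"], scan.width)
            d = assemble_descriptor(
                scan, lmap, bset, subject_id=row["subject_id"], eye=row["eye"],
                grade_label=row.get("grade"))
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("features", f"record {stem}: {exc}") from exc
        descriptors.append(d)
    write_descriptors(descriptors, feat_dir / "descriptors.csv",
                      feat_dir / "grids.json")
    logger.info("features: %d descriptors written", len(descriptors))
    return descriptors


def stage_train(config: PipelineConfig, out: Path, descriptors: list) -> dict:
    """Train final screen + grade fusion networks on the full cohort."""
    model_dir = out / "models"
    model_dir.mkdir(parents=True, exist_ok=True)
    spec = config.autoencoder_spec()
    labels = [d.grade_label for d in descriptors]
    try:
        encoders = pretrain_autoencoders(descriptors, spec)
        screen = train_stage(descriptors, labels, "screen", spec,
                             encoders=encoders)
        dr = [d for d in descriptors
              if d.grade_label in ("subclinical", "mild_moderate")]
        grade = train_stage(dr, [d.grade_label for d in dr], "grade", spec,
                            encoders=encoders)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("train", str(exc)) from exc
    save_model(screen, model_dir / "screen.json")
    save_model(grade, model_dir / "grade.json")
    logger.info("train: models written to %s", model_dir)
    return {"screen": screen, "grade": grade}


def stage_evaluate(config: PipelineConfig, out: Path, descriptors: list) -> dict:
    """Cross-validated evaluation; writes the JSON report."""
    report_dir = out / "reports"
    report_dir.mkdir(parents=True, exist_ok=True)
    manifest = pd.DataFrame(
        [{"subject_id": d.subject_id, "eye": d.eye, "grade": d.grade_label}
         for d in descriptors])
    try:
        plan = plan_folds(manifest, config.eval_scheme,
                          k=config.eval_k, seed=config.stage_seed("folds"))
        reports = run_cv(descriptors, plan, config.autoencoder_spec(),
                         boot_seed=config.stage_seed("bootstrap"),
                         n_boot=config.n_boot)
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("evaluate", str(exc)) from exc
    payload = {
        "provenance": provenance(config),
        "scheme": config.eval_scheme,
        "per_subject": (reports["screen"].records
                        .drop(columns=["true_dr", "pred_dr"])
                        .to_dict(orient="records")),
        **{stage: rep.to_dict() for stage, rep in reports.items()},
    }
    write_report(payload, report_dir / "evaluation.json")
    (reports["screen"].records
     .to_csv(report_dir / "per_subject_predictions.csv", index=False))
    logger.info("evaluate: stage-1 acc %.3f, stage-2 acc %.3f",
                reports["screen"].accuracy, reports["grade"].accuracy)
    return reports


# ---------------------------------------------------------------------------
# Driver
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig, stop_after: str | None = None) -> dict:
    """Run the full chain, writing every intermediate artifact.

    Returns a summary dict; raises :class:`PipelineError` naming the stage
    on any failure.  ``stop_after`` halts the chain after the named stage.
    """
    if stop_after is not None and stop_after not in STAGES:
        raise ValueError(f"stop_after must be one of {STAGES}")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    summary: dict = {"provenance": provenance(config)}

    if config.images_dir is not None:
        mpath = Path(config.images_dir) / "manifest.csv"
        if not mpath.exists():
            raise PipelineError("simulate",
                                f"images_dir has no manifest: {mpath}")
        manifest = read_manifest(mpath)
    else:
        manifest = stage_simulate(config, out)
    summary["n_eyes"] = len(manifest)
    if stop_after == "simulate":
        return _finish(config, out, summary)

    seg_manifest = stage_segment(config, out, manifest)
    if stop_after == "segment":
        return _finish(config, out, summary)

    descriptors = stage_features(config, out, seg_manifest)
    summary["n_descriptors"] = len(descriptors)
    if stop_after == "features":
        return _finish(config, out, summary)

    stage_train(config, out, descriptors)
    if stop_after == "train":
        return _finish(config, out, summary)

    reports = stage_evaluate(config, out, descriptors)
    summary["screen_accuracy"] = reports["screen"].accuracy
    summary["grade_accuracy"] = reports["grade"].accuracy
    return _finish(config, out, summary)


def _finish(config: PipelineConfig, out: Path, summary: dict) -> dict:
    hashes = {str(p.relative_to(out)): _sha256(p)
              for p in sorted(out.rglob("*")) if p.is_file()
              and p.name != "outputs.json"}
    write_report({"provenance": provenance(config), "outputs": hashes},
                 out / "outputs.json")
    summary["n_artifacts"] = len(hashes)
    return summary
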