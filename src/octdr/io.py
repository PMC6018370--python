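"""On-disk artifacts: images, boundary CSVs, manifests, descriptors, models, reports.

Conventions
-----------
* Images are single-channel 8- or 16-bit TIFF/PNG; intensities are scaled
  by the container bit depth (never per image), so the reflectivity
  normalization in :mod:`octdr.features` is the only intensity calibration.
* Coordinates are 0-based; row 0 is the top (vitreous side) of the scan.
* All writers are deterministic byte-for-byte for identical inputs: fixed
  field order, fixed float formatting, sorted JSON keys.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from PIL import Image

from .geometry import N_BOUNDARIES, BoundarySet

MIN_IMAGE_SIZE = 100  # reject degenerate scans

GRADES = ("normal", "subclinical", "mild_moderate")
EYES = ("OD", "OS")

SCHEMA_VERSION = 1


class MetadataError(ValueError):
    """Missing or invalid sidecar metadata."""


@dataclass
class OCTBScan:
    """A single macular OCT B-scan: axial (rows) x lateral (columns).

    ``intensities`` are floats in [0, 1] after load-time bit-depth scaling.
    ``fovea_column_px`` is the column of the foveal pit when known (the
    generator records it; for real scans it can be estimated from the
    thinnest-retina column).
    """

    intensities: np.ndarray
    axial_um_per_px: float
    lateral_um_per_px: float
    fovea_column_px: int | None = None

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 2:
            raise ValueError("B-scan must be a single-channel 2-D image")
        h, w = self.intensities.shape
        if h < MIN_IMAGE_SIZE or w < MIN_IMAGE_SIZE:
            raise ValueError(
                f"degenerate B-scan {h}x{w}: need at least "
                f"{MIN_IMAGE_SIZE}x{MIN_IMAGE_SIZE} px"
            )
        if not (self.axial_um_per_px > 0 and self.lateral_um_per_px > 0):
            raise ValueError("pixel spacings must be strictly positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.intensities.shape

    @property
    def height(self) -> int:
        return self.intensities.shape[0]

    @property
    def width(self) -> int:
        return self.intensities.shape[1]


# ---------------------------------------------------------------------------
# B-scan image + sidecar metadata
# ---------------------------------------------------------------------------

def write_bscan(scan: OCTBScan, path: str | Path, meta_path: str | Path,
                bit_depth: int = 16) -> None:
    """Write a B-scan as a grayscale TIFF/PNG plus a JSON sidecar."""
    path = Path(path)
    if bit_depth == 16:
        arr = np.round(np.clip(scan.intensities, 0.0, 1.0) * 65535).astype(np.uint16)
    elif bit_depth == 8:
        arr = np.round(np.clip(scan.intensities, 0.0, 1.0) * 255).astype(np.uint8)
    else:
        raise ValueError("bit_depth must be 8 or 16")
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        tifffile.imwrite(path, arr)
    elif suffix == ".png":
        Image.fromarray(arr).save(path)
    else:
        raise ValueError(f"unsupported image format: {suffix}")
    meta = {
        "axial_um_per_px": scan.axial_um_per_px,
        "lateral_um_per_px": scan.lateral_um_per_px,
    }
    if scan.fovea_column_px is not None:
        meta["fovea_column_px"] = int(scan.fovea_column_px)
    _write_json(meta, meta_path)


def read_bscan(path: str | Path, meta_path: str | Path) -> OCTBScan:
    """Read a grayscale image and its sidecar metadata.

    Intensities are scaled by the container bit depth (255 or 65535), never
    per image, so identically exposed scans load identically.
    """
    path, meta_path = Path(path), Path(meta_path)
    if not Path(meta_path).exists():
        raise MetadataError(f"metadata required: sidecar JSON not found at {meta_path}")
    meta = json.loads(Path(meta_path).read_text())
    for key in ("axial_um_per_px", "lateral_um_per_px"):
        if key not in meta:
            raise MetadataError(f"metadata required: missing key {key!r} in {meta_path}")
        if not meta[key] > 0:
            raise MetadataError(f"non-positive pixel spacing {key}={meta[key]}")

    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = np.asarray(Image.open(path))
    if arr.ndim != 2:
        raise ValueError(f"expected single-channel image, got shape {arr.shape}")
    if arr.dtype == np.uint8:
        intensities = arr.astype(float) / 255.0
    elif arr.dtype == np.uint16:
        intensities = arr.astype(float) / 65535.0
    else:
        raise ValueError(f"unsupported pixel dtype {arr.dtype}: expected uint8/uint16")
    return OCTBScan(
        intensities=intensities,
        axial_um_per_px=float(meta["axial_um_per_px"]),
        lateral_um_per_px=float(meta["lateral_um_per_px"]),
        fovea_column_px=(int(meta["fovea_column_px"])
                         if meta.get("fovea_column_px") is not None else None),
    )


# ---------------------------------------------------------------------------
# Boundary CSVs
# ---------------------------------------------------------------------------

def write_boundaries(bset: BoundarySet, path: str | Path) -> None:
    """CSV with columns boundary_index (1-based), column_px, row_px (3 dp)."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        fh.write("boundary_index,column_px,row_px\n")
        for k in range(N_BOUNDARIES):
            for c in range(bset.width):
                fh.write(f"{k + 1},{c},{bset.curves[k, c]:.3f}\n")


def read_boundaries(path: str | Path, width_px: int) -> BoundarySet:
    """Load a boundary CSV; validates coverage and the ordering invariant."""
    df = pd.read_csv(path)
    required = {"boundary_index", "column_px", "row_px"}
    if not required.issubset(df.columns):
        raise ValueError(f"boundary file missing columns {required - set(df.columns)}")
    indices = sorted(df["boundary_index"].unique())
    if indices != list(range(1, N_BOUNDARIES + 1)):
        raise ValueError(
            f"boundary file must cover boundaries 1..{N_BOUNDARIES}, got {indices}"
        )
    curves = np.full((N_BOUNDARIES, width_px), np.nan)
    curves[df["boundary_index"] - 1, df["column_px"]] = df["row_px"]
    if np.isnan(curves).any():
        raise ValueError("boundary file does not cover every column for every boundary")
    return BoundarySet(curves)  # ordering validated by the container


# ---------------------------------------------------------------------------
# Manifests
# ---------------------------------------------------------------------------

MANIFEST_COLUMNS = ("subject_id", "eye", "grade", "image_path", "meta_path",
                    "boundary_path")


def validate_manifest(df: pd.DataFrame) -> pd.DataFrame:
    missing = set(("subject_id", "eye")) - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns {missing}")
    dup = df.duplicated(subset=["subject_id", "eye"])
    if dup.any():
        raise ValueError("manifest has duplicate (subject_id, eye) rows")
    counts = df.groupby("subject_id").size()
    if (counts > 2).any():
        raise ValueError("a subject contributes more than two eyes")
    bad_eyes = set(df["eye"].unique()) - set(EYES)
    if bad_eyes:
        raise ValueError(f"unknown eye labels {bad_eyes}; expected {EYES}")
    if "grade" in df.columns:
        bad = set(df["grade"].dropna().unique()) - set(GRADES)
        if bad:
            raise ValueError(f"unknown grades {bad}; expected {GRADES}")
    return df


def write_manifest(df: pd.DataFrame, path: str | Path) -> None:
    validate_manifest(df)
    cols = [c for c in MANIFEST_COLUMNS if c in df.columns]
    out = df[cols].sort_values(["subject_id", "eye"]).reset_index(drop=True)
    out.to_csv(path, index=False)


def read_manifest(path: str | Path) -> pd.DataFrame:
    return validate_manifest(pd.read_csv(path))


# ---------------------------------------------------------------------------
# Descriptor tables (36 CDF vectors per eye, wide CSV + grid sidecar)
# ---------------------------------------------------------------------------

def write_descriptors(descriptors: list, path: str | Path,
                      grids_path: str | Path) -> None:
    """One row per (subject, eye); 36 x G feature columns, fixed order."""
    from .features import FEATURE_FAMILIES  # deferred: avoid import cycle

    rows = []
    grids = None
    for d in descriptors:
        if grids is None:
            grids = {fam: d.cdfs[i].grid for i, fam in enumerate(FEATURE_FAMILIES)}
        row: dict = {"subject_id": d.subject_id, "eye": d.eye,
                     "grade": d.grade_label if d.grade_label is not None else ""}
        for i, cdf in enumerate(d.cdfs):
            layer = i // len(FEATURE_FAMILIES) + 1
            fam = FEATURE_FAMILIES[i % len(FEATURE_FAMILIES)]
            for j, v in enumerate(cdf.values):
                row[f"L{layer:02d}_{fam}_{j:02d}"] = f"{v:.6f}"
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
    _write_json({fam: [float(x) for x in g] for fam, g in (grids or {}).items()},
                grids_path)


def read_descriptors(path: str | Path, grids_path: str | Path) -> list:
    from .features import FEATURE_FAMILIES, FeatureCDF, SubjectDescriptor

    grids = {fam: np.asarray(g) for fam, g in
             json.loads(Path(grids_path).read_text()).items()}
    df = pd.read_csv(path, keep_default_na=False)
    out = []
    for _, row in df.iterrows():
        cdfs = []
        for layer in range(1, 13):
            for fam in FEATURE_FAMILIES:
                cols = sorted(c for c in df.columns if c.startswith(f"L{layer:02d}_{fam}_"))
                values = np.array([float(row[c]) for c in cols])
                cdfs.append(FeatureCDF(grid=grids[fam], values=values))
        out.append(SubjectDescriptor(
            cdfs=cdfs, subject_id=str(row["subject_id"]), eye=str(row["eye"]),
            grade_label=(str(row["grade"]) or None)))
    return out


# ---------------------------------------------------------------------------
# JSON helpers: reports, model files
# ---------------------------------------------------------------------------

def _write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def write_report(report: dict, path: str | Path) -> None:
    """Evaluation / provenance report as sorted-key JSON."""
    _write_json(report, path)


def read_report(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def save_model(model, path: str | Path) -> None:
    """Portable structured serialization (architecture + weights, versioned)."""
    payload = model.to_dict()
    payload["schema_version"] = SCHEMA_VERSION
    _write_json(payload, path)


def load_model(path: str | Path):
    from .classifier import FusionNetwork

    payload = json.loads(Path(path).read_text())
    version = payload.pop("schema_version", None)
    if version != SCHEMA_VERSION:
        raise ValueError(f"unsupported model schema version {version}")
    return FusionNetwork.from_dict(payload)
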