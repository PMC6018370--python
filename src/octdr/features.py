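"""Per-layer reflectivity, curvature and thickness features as CDF descriptors.

Three feature families are measured for each of the 12 segmented layers:

* **reflectivity** — raw intensities normalised to a 0–1000 scale where
  the clear vitreous maps to 0 and the hyperreflective RPE to 1000,
  sampled from two parafoveal windows (the thickest retina on the nasal
  and temporal sides of the foveal peak);
* **curvature** — |y''| / (1 + y'^2)^(3/2) of the layer's upper boundary
  in physical (um) coordinates, after local-polynomial smoothing;
* **thickness** — the axial distance between the layer's lower and upper
  boundaries at the same column, in um.

Each family's per-layer samples are summarised as an empirical CDF
evaluated on a fixed global grid, making descriptors comparable across
eyes: 12 layers x 3 families = 36 CDF vectors per eye.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from .geometry import LABEL_RPE, LABEL_VITREOUS, N_LAYERS, BoundarySet, LayerMap
from .io import OCTBScan

FEATURE_FAMILIES = ("reflectivity", "curvature", "thickness")

REFLECTIVITY_SCALE = 1000.0
REFLECTIVITY_CLIP = (-100.0, 1100.0)  # soft bounds beyond the anchors

#: fixed global evaluation grids, one per feature family
DEFAULT_GRIDS: dict[str, np.ndarray] = {
    "reflectivity": np.linspace(-100.0, 1100.0, 64),
    "curvature": np.linspace(0.0, 0.05, 64),      # 1/um
    "thickness": np.linspace(0.0, 300.0, 64),     # um
}


@dataclass
class FeatureCDF:
    """Empirical CDF of one (layer, family) sample set on a fixed grid."""

    grid: np.ndarray
    values: np.ndarray
    flagged_empty: bool = False

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.grid.shape != self.values.shape:
            raise ValueError("grid and values must have the same length")
        if (np.diff(self.values) < -1e-12).any():
            raise ValueError("CDF values must be nondecreasing")


@dataclass
class SubjectDescriptor:
    """The 36 fixed-grid CDF vectors for one eye, plus metadata.

    Order is layer-major, feature-minor: slot ``3*(layer-1) + f`` holds
    layer ``layer`` (1-based) and family ``FEATURE_FAMILIES[f]``.
    """

    cdfs: list[FeatureCDF]
    subject_id: str = "S0000"
    eye: str = "OD"
    grade_label: str | None = None

    def __post_init__(self) -> None:
        if len(self.cdfs) != 3 * N_LAYERS:
            raise ValueError(f"descriptor must hold exactly {3 * N_LAYERS} CDFs")

    def vector(self) -> np.ndarray:
        """Concatenated 36 x G feature vector (classifier input)."""
        return np.concatenate([c.values for c in self.cdfs])

    def slot(self, layer: int, family: str) -> FeatureCDF:
        return self.cdfs[3 * (layer - 1) + FEATURE_FAMILIES.index(family)]


# ---------------------------------------------------------------------------
# Reflectivity
# ---------------------------------------------------------------------------

def normalize_reflectivity(bscan: OCTBScan, layer_map: LayerMap) -> np.ndarray:
    """Map raw intensities to the 0–1000 reflectivity scale.

    The affine map sends the median vitreous intensity to 0 and the median
    RPE intensity to 1000; the result is clipped to [-100, 1100] so noise
    beyond the calibration anchors survives without dominating.
    """
    img = bscan.intensities
    labels = layer_map.labels
    vit = img[labels == LABEL_VITREOUS]
    rpe = img[labels == LABEL_RPE]
    if vit.size == 0 or rpe.size == 0:
        raise ValueError("vitreous or RPE region empty: cannot calibrate reflectivity")
    v_med, r_med = float(np.median(vit)), float(np.median(rpe))
    if r_med <= v_med:
        raise ValueError(
            f"RPE median ({r_med:.3f}) <= vitreous median ({v_med:.3f}): "
            "segmentation looks failed")
    out = (img - v_med) / (r_med - v_med) * REFLECTIVITY_SCALE
    return np.clip(out, *REFLECTIVITY_CLIP)


def select_reflectivity_regions(layer_map: LayerMap, fovea_column: int,
                                width: int = 60) -> list[tuple[int, int]]:
    """Two column windows over the thickest retina on each side of the fovea.

    Each window is centred on the column of maximal ILM-to-RPE thickness
    on its side of the foveal column, then clipped so it neither crosses
    the fovea nor leaves the image.  If the fovea sits at an image edge a
    one-sided result is returned with a warning.
    """
    labels = layer_map.labels
    w = labels.shape[1]
    if not 0 <= fovea_column < w:
        raise ValueError("fovea column outside the image")
    retina = ((labels >= 1) & (labels <= N_LAYERS)).sum(axis=0).astype(float)

    windows: list[tuple[int, int]] = []
    for side in ("temporal", "nasal"):
        if side == "temporal":
            lo_lim, hi_lim = 0, fovea_column        # columns strictly left
        else:
            lo_lim, hi_lim = fovea_column + 1, w    # columns strictly right
        if hi_lim - lo_lim < max(width // 2, 1):
            warnings.warn(f"fovea at image edge: no {side} window", stacklevel=2)
            continue
        profile = retina[lo_lim:hi_lim]
        ties = np.flatnonzero(profile == profile.max())
        centre = lo_lim + int(ties[ties.size // 2])  # middle of the plateau
        lo = max(lo_lim, centre - width // 2)
        hi = min(hi_lim, lo + width)
        lo = max(lo_lim, hi - width)
        windows.append((lo, hi))
    if not windows:
        raise ValueError("fovea column leaves no usable reflectivity window")
    return windows


# ---------------------------------------------------------------------------
# Curvature and thickness
# ---------------------------------------------------------------------------

def compute_curvature(boundary_curve: np.ndarray, lateral_um_per_px: float,
                      axial_um_per_px: float, smooth_window: int = 7) -> np.ndarray:
    """Per-column curvature of a boundary curve, in 1/um.

    The curve is converted to physical coordinates, smoothed with a local
    quadratic (Savitzky–Golay) filter, differentiated with central
    differences (one-sided at the endpoints), and the plane-curve formula
    kappa = |y''| / (1 + y'^2)^(3/2) is applied.
    """
    curve = np.asarray(boundary_curve, dtype=float)
    if smooth_window < 5:
        raise ValueError("smooth_window must be >= 5")
    if curve.size < smooth_window:
        raise ValueError("curve shorter than the smoothing window")
    y = curve * axial_um_per_px
    y = savgol_filter(y, window_length=smooth_window, polyorder=2, mode="interp")
    d1 = np.gradient(y, lateral_um_per_px)
    d2 = np.gradient(d1, lateral_um_per_px)
    return np.abs(d2) / (1.0 + d1**2) ** 1.5


def compute_thickness(bset: BoundarySet, layer_index: int,
                      axial_um_per_px: float) -> np.ndarray:
    """Per-column thickness of layer ``layer_index`` (1..12), in um.

    Corresponding points are taken at the same column (axial
    correspondence), the customary OCT convention.
    """
    return bset.thickness_px(layer_index) * axial_um_per_px


# ---------------------------------------------------------------------------
# CDF construction and descriptor assembly
# ---------------------------------------------------------------------------

def build_cdf(samples: np.ndarray, grid: np.ndarray) -> FeatureCDF:
    """Empirical CDF of ``samples`` evaluated at the grid points.

    An empty sample set yields an all-zero, flagged vector.
    """
    grid = np.asarray(grid, dtype=float)
    if (np.diff(grid) <= 0).any():
        raise ValueError("grid must be strictly ascending")
    samples = np.asarray(samples, dtype=float).ravel()
    if samples.size == 0:
        return FeatureCDF(grid=grid, values=np.zeros_like(grid), flagged_empty=True)
    s = np.sort(samples)
    values = np.searchsorted(s, grid, side="right") / s.size
    return FeatureCDF(grid=grid, values=values)


def assemble_descriptor(bscan: OCTBScan, layer_map: LayerMap, bset: BoundarySet,
                        grids: dict[str, np.ndarray] | None = None,
                        fovea_column: int | None = None,
                        region_width: int = 60,
                        smooth_window: int = 7,
                        subject_id: str = "S0000", eye: str = "OD",
                        grade_label: str | None = None) -> SubjectDescriptor:
    """All 36 CDFs for one eye, in layer-major / feature-minor order.

    Reflectivity samples come only from the two parafoveal windows;
    curvature (of each layer's upper boundary) and thickness are sampled
    across the full scan width.  A layer missing from the label map gets
    zero-flagged reflectivity CDFs.
    """
    if grids is None:
        grids = DEFAULT_GRIDS
    if fovea_column is None:
        fovea_column = layer_map.fovea_column_px
        if fovea_column is None:
            fovea_column = bscan.fovea_column_px
    if fovea_column is None:
        raise ValueError("fovea column required (not recorded on inputs)")

    norm = normalize_reflectivity(bscan, layer_map)
    windows = select_reflectivity_regions(layer_map, fovea_column,
                                          width=region_width)
    col_mask = np.zeros(layer_map.shape[1], dtype=bool)
    for lo, hi in windows:
        col_mask[lo:hi] = True

    cdfs: list[FeatureCDF] = []
    for layer in range(1, N_LAYERS + 1):
        in_layer = layer_map.labels == layer
        refl_samples = norm[in_layer & col_mask[None, :]]
        curv = compute_curvature(bset.curves[layer - 1], bscan.lateral_um_per_px,
                                 bscan.axial_um_per_px, smooth_window=smooth_window)
        thick = compute_thickness(bset, layer, bscan.axial_um_per_px)
        cdfs.append(build_cdf(refl_samples, grids["reflectivity"]))
        cdfs.append(build_cdf(curv, grids["curvature"]))
        cdfs.append(build_cdf(thick, grids["thickness"]))
    return SubjectDescriptor(cdfs=cdfs, subject_id=subject_id, eye=eye,
                             grade_label=grade_label)


def descriptors_from_cohort(records: list,
                            grids: dict[str, np.ndarray] | None = None,
                            use_truth: bool = True) -> list[SubjectDescriptor]:
    """Descriptors for a generated cohort, from its ground-truth segmentation.

    Convenient for studying the feature and classification stages in
    isolation from segmentation error (the full pipeline in
    :mod:`octdr.pipeline` segments each scan instead).
    """
    if not use_truth:
        raise ValueError("only ground-truth segmentation is supported here; "
                         "use octdr.pipeline for segmented descriptors")
    return [
        assemble_descriptor(
            r.scan, r.truth.layer_map, r.truth.boundaries, grids=grids,
            subject_id=r.truth.subject_id, eye=r.truth.eye,
            grade_label=r.truth.grade)
        for r in records
    ]
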