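"""Synthetic macular OCT B-scan phantoms with known 13-boundary ground truth.

The generator emulates the statistical structure the segmentation and
grading pipeline assumes: a 12-layer laminar retina with a smooth foveal
depression, per-layer mean reflectivities, additive (optionally
multiplicative speckle-like) noise, and grade-dependent perturbations of
layer thickness, reflectivity and boundary undulation.

Disease model
-------------
Three grades are generated: ``normal``, ``subclinical`` and
``mild_moderate``.  Diabetic eyes show thinning of the inner layers
(nerve-fiber and ganglion-cell layers) and thickening of the inner nuclear
and outer plexiform layers, reduced inner-layer reflectivity, and wavier
boundaries.  Subclinical eyes sit between normal and overt disease: by
default they receive 50% of the mild/moderate effect on every axis.

Geometry
--------
Boundaries are smooth functions of the lateral coordinate: a foveal
Gaussian pit (compressing all layers proportionally so the outer retina
stays flat) plus a low-frequency sinusoidal undulation shared by all
boundaries (so it perturbs curvature without perturbing thickness).
The shared undulation keeps layer thickness an exact function of the
configured thicknesses, which gives closed-form oracles for tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .geometry import N_BOUNDARIES, N_LAYERS, BoundarySet, LayerMap
from .io import EYES, GRADES, OCTBScan

# Default per-layer mean intensities (fraction of full scale), inner to
# outer.  Adjacent layers alternate bright/dark as in real spectral-domain
# OCT, with the RPE the brightest band.
DEFAULT_LAYER_INTENSITIES = (
    0.85, 0.45, 0.60, 0.35, 0.55, 0.20, 0.50, 0.30, 0.90, 0.40, 0.70, 0.95,
)
#: base layer thicknesses in um (inner to outer), ~326 um total retina
DEFAULT_LAYER_THICKNESS_UM = (
    20.0, 35.0, 35.0, 35.0, 30.0, 70.0, 12.0, 16.0, 16.0, 16.0, 16.0, 25.0,
)

#: mild/moderate fractional thickness deltas: inner-layer thinning,
#: INL/OPL thickening; subclinical applies half of these by default.
DEFAULT_THICKNESS_DELTA = (
    -0.18, -0.18, 0.0, 0.15, 0.15, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0,
)
#: mild/moderate fractional reflectivity deltas (inner-layer dimming)
DEFAULT_REFLECTIVITY_DELTA = (
    -0.10, -0.10, -0.05, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0,
)

GRADE_SCALE = {"normal": 0.0, "subclinical": 0.5, "mild_moderate": 1.0}


@dataclass(frozen=True)
class GradeEffect:
    """Per-grade multiplicative deltas, specified at mild/moderate strength.

    ``subclinical_fraction`` scales every axis down for subclinical eyes
    (the disease stage is defined only as intermediate between normal and
    overt retinopathy, so the fraction is a free parameter; default 0.5).
    """

    thickness_delta: tuple[float, ...] = DEFAULT_THICKNESS_DELTA
    reflectivity_delta: tuple[float, ...] = DEFAULT_REFLECTIVITY_DELTA
    undulation_gain: float = 1.0  # amplitude multiplier added at full strength
    subclinical_fraction: float = 0.5

    def scale(self, grade: str) -> float:
        s = GRADE_SCALE[grade]
        return s if s != 0.5 else self.subclinical_fraction


@dataclass(frozen=True)
class PhantomConfig:
    """Full description of one phantom B-scan."""

    image_height_px: int = 160
    image_width_px: int = 256
    axial_um_per_px: float = 4.0
    lateral_um_per_px: float = 23.4  # ~6 mm / 256 px
    layer_mean_intensities: tuple[float, ...] = DEFAULT_LAYER_INTENSITIES
    layer_base_thickness_um: tuple[float, ...] = DEFAULT_LAYER_THICKNESS_UM
    vitreous_intensity: float = 0.05
    background_intensity: float = 0.12
    ilm_depth_um: float = 140.0          # vitreous margin above the ILM
    fovea_depth_um: float = 110.0        # pit depth at the ILM
    fovea_width_px: int = 20             # Gaussian sigma of the pit, in columns
    undulation_amp_um: float = 5.0       # shared sinusoidal waviness
    undulation_cycles: float = 1.5       # full periods across the scan width
    noise_sd: float = 0.03               # additive Gaussian, intensity units
    speckle_sd: float = 0.0              # optional multiplicative component
    grade: str = "normal"
    grade_effect: GradeEffect = field(default_factory=GradeEffect)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grade not in GRADES:
            raise ValueError(f"grade must be one of {GRADES}")
        if len(self.layer_mean_intensities) != N_LAYERS:
            raise ValueError(f"need {N_LAYERS} layer intensities")
        if len(self.layer_base_thickness_um) != N_LAYERS:
            raise ValueError(f"need {N_LAYERS} layer thicknesses")
        if not (self.axial_um_per_px > 0 and self.lateral_um_per_px > 0):
            raise ValueError("pixel spacings must be positive")
        if min(self.layer_base_thickness_um) <= 0:
            raise ValueError("base thicknesses must be strictly positive")
        if self.fovea_depth_um < 0 or self.noise_sd < 0:
            raise ValueError("fovea depth and noise sd must be nonnegative")


@dataclass
class PhantomTruth:
    """Ground truth for one generated eye."""

    boundaries: BoundarySet
    layer_map: LayerMap
    grade: str
    subject_id: str = "S0000"
    eye: str = "OD"
    fovea_column_px: int | None = None


def _effective_thicknesses(config: PhantomConfig,
                           jitter: np.ndarray | None = None) -> np.ndarray:
    """Per-layer thickness (um) after grade perturbation and optional jitter."""
    base = np.asarray(config.layer_base_thickness_um, dtype=float)
    s = config.grade_effect.scale(config.grade)
    t = base * (1.0 + s * np.asarray(config.grade_effect.thickness_delta))
    if jitter is not None:
        t = t * jitter
    if t.min() <= 0:
        raise ValueError("layer thicknesses must stay strictly positive "
                         "after grade perturbation")
    return t


def _effective_intensities(config: PhantomConfig,
                           jitter: np.ndarray | None = None) -> np.ndarray:
    base = np.asarray(config.layer_mean_intensities, dtype=float)
    s = config.grade_effect.scale(config.grade)
    m = base * (1.0 + s * np.asarray(config.grade_effect.reflectivity_delta))
    if jitter is not None:
        m = m * jitter
    return np.clip(m, 0.0, 1.0)


def _boundary_curves(config: PhantomConfig, thicknesses_um: np.ndarray,
                     phase: float) -> np.ndarray:
    """Closed-form 13 boundary curves (fractional rows)."""
    w = config.image_width_px
    x = np.arange(w, dtype=float)
    fc = w // 2

    total_um = float(thicknesses_um.sum())
    cum_um = np.concatenate([[0.0], np.cumsum(thicknesses_um)])  # (13,)

    # foveal pit: Gaussian in the lateral coordinate, compressing every
    # layer proportionally so the outermost boundary stays flat
    sigma_px = max(config.fovea_width_px, 1)
    pit_um = config.fovea_depth_um * np.exp(-0.5 * ((x - fc) / sigma_px) ** 2)
    if config.fovea_depth_um >= total_um:
        raise ValueError("foveal pit deeper than the retina")

    # shared low-frequency undulation (same for all boundaries)
    s = config.grade_effect.scale(config.grade)
    amp = config.undulation_amp_um * (1.0 + s * config.grade_effect.undulation_gain)
    und_um = amp * np.sin(2 * np.pi * config.undulation_cycles * x / w + phase)

    ilm_um = config.ilm_depth_um
    # boundary k at column x: ILM base + pit*remaining-fraction + undulation
    frac_remaining = 1.0 - cum_um / total_um  # 1 at ILM, 0 at outer boundary
    rows_um = (ilm_um + cum_um[:, None]
               + pit_um[None, :] * frac_remaining[:, None]
               + und_um[None, :])
    curves = rows_um / config.axial_um_per_px

    h = config.image_height_px
    if curves.min() < 1.0 or curves.max() > h - 2.0:
        raise ValueError(
            "layers do not fit in the image: boundaries span rows "
            f"[{curves.min():.1f}, {curves.max():.1f}] of {h}"
        )
    return curves


def generate_bscan(config: PhantomConfig,
                   subject_id: str = "S0000", eye: str = "OD",
                   thickness_jitter: np.ndarray | None = None,
                   intensity_jitter: np.ndarray | None = None,
                   phase: float | None = None) -> tuple[OCTBScan, PhantomTruth]:
    """Generate one phantom B-scan and its ground truth.

    Deterministic for a fixed config (the seed drives noise and the
    undulation phase).  The jitter arrays are internal hooks used by
    :func:`generate_cohort` to correlate the two eyes of a subject.
    """
    rng = np.random.default_rng(config.seed)
    if phase is None:
        phase = float(rng.uniform(0, 2 * np.pi))
    else:
        rng.uniform(0, 2 * np.pi)  # keep the noise stream aligned

    t_um = _effective_thicknesses(config, thickness_jitter)
    means = _effective_intensities(config, intensity_jitter)
    curves = _boundary_curves(config, t_um, phase)
    bset = BoundarySet(curves)

    h, w = config.image_height_px, config.image_width_px
    fc = w // 2
    lmap = LayerMap.from_boundaries(bset, h, fovea_column_px=fc)

    # label -> intensity lookup over the 14-symbol alphabet
    means_ext = np.concatenate([[config.vitreous_intensity], means,
                                [config.background_intensity]])
    img = means_ext[lmap.labels]
    if config.speckle_sd > 0:
        img = img * (1.0 + config.speckle_sd * rng.standard_normal((h, w)))
    if config.noise_sd > 0:
        img = img + config.noise_sd * rng.standard_normal((h, w))
    img = np.clip(img, 0.0, 1.0)

    scan = OCTBScan(intensities=img, axial_um_per_px=config.axial_um_per_px,
                    lateral_um_per_px=config.lateral_um_per_px,
                    fovea_column_px=fc)
    truth = PhantomTruth(boundaries=bset, layer_map=lmap, grade=config.grade,
                         subject_id=subject_id, eye=eye, fovea_column_px=fc)
    return scan, truth


@dataclass
class CohortRecord:
    scan: OCTBScan
    truth: PhantomTruth


#: subject-level biological variation (multiplicative sd on thickness and
#: reflectivity); per-eye jitter is smaller so the two eyes stay correlated
SUBJECT_THICKNESS_JITTER_SD = 0.04
SUBJECT_INTENSITY_JITTER_SD = 0.03
EYE_THICKNESS_JITTER_SD = 0.015
EYE_INTENSITY_JITTER_SD = 0.01


def _grade_counts(n_subjects: int, grade_mix: tuple[float, float, float]) -> list[int]:
    """Largest-remainder apportionment of subjects to grades."""
    if abs(sum(grade_mix) - 1.0) > 1e-9:
        raise ValueError("grade_mix proportions must sum to 1")
    raw = [p * n_subjects for p in grade_mix]
    counts = [int(np.floor(r)) for r in raw]
    remainders = [r - c for r, c in zip(raw, counts)]
    for i in sorted(range(3), key=lambda i: -remainders[i])[: n_subjects - sum(counts)]:
        counts[i] += 1
    return counts


def generate_cohort(n_subjects: int,
                    grade_mix: tuple[float, float, float] = (0.5, 0.25, 0.25),
                    config_template: PhantomConfig | None = None,
                    seed: int = 0) -> tuple[list[CohortRecord], pd.DataFrame]:
    """Generate a two-eyes-per-subject cohort with subject-correlated eyes.

    Both eyes of a subject share the grade and a subject-level latent
    perturbation of thickness and reflectivity; each eye adds a smaller
    independent jitter plus its own noise realisation.  Returns the records
    and a manifest DataFrame (subject_id, eye, grade).
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    if config_template is None:
        config_template = PhantomConfig()
    rng = np.random.default_rng(seed)

    counts = _grade_counts(n_subjects, grade_mix)
    grades = sum(([g] * c for g, c in zip(GRADES, counts)), [])
    order = rng.permutation(n_subjects)
    grades = [grades[i] for i in order]

    records: list[CohortRecord] = []
    rows = []
    for i, grade in enumerate(grades):
        subject_id = f"S{i + 1:04d}"
        subj_t = np.exp(rng.normal(0, SUBJECT_THICKNESS_JITTER_SD, N_LAYERS))
        subj_m = np.exp(rng.normal(0, SUBJECT_INTENSITY_JITTER_SD, N_LAYERS))
        phase = float(rng.uniform(0, 2 * np.pi))
        for eye in EYES:
            eye_t = subj_t * np.exp(rng.normal(0, EYE_THICKNESS_JITTER_SD, N_LAYERS))
            eye_m = subj_m * np.exp(rng.normal(0, EYE_INTENSITY_JITTER_SD, N_LAYERS))
            eye_phase = phase + float(rng.normal(0, 0.15))
            eye_seed = int(rng.integers(0, 2**31 - 1))
            config = replace(config_template, grade=grade, seed=eye_seed)
            scan, truth = generate_bscan(
                config, subject_id=subject_id, eye=eye,
                thickness_jitter=eye_t, intensity_jitter=eye_m, phase=eye_phase)
            records.append(CohortRecord(scan=scan, truth=truth))
            rows.append({"subject_id": subject_id, "eye": eye, "grade": grade})
    manifest = pd.DataFrame(rows)
    return records, manifest
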