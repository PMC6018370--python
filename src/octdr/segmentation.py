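"""Joint shape / intensity / spatial segmentation of retinal layers.

The labelling model combines three terms over the 14-symbol alphabet
(vitreous, 12 layers, sub-RPE background):

* a **shape prior**: per-pixel label probabilities learned from aligned
  gold-standard label maps (``ShapeAtlas``);
* an **intensity model**: a linear combination of discrete Gaussians
  (LCDG) fitted to the scan's gray-level histogram — a dominant mixture
  with one positive component per class, refined by a small number of
  signed subordinate components (``LCDGModel``);
* a **spatial model**: a second-order (8-neighbour) Markov–Gibbs random
  field with a Potts potential penalising unequal neighbouring labels
  (``MGRFParams``).

The maximum-a-posteriori label map is found by iterated conditional modes
(ICM) seeded at the atlas argmax, swept over a 2x2 block colouring so each
vectorised update is a true coordinate-descent step (energy never
increases).  Ordered boundary curves are then extracted column-wise with
an isotonic repair and lateral median filtering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .geometry import (
    N_BOUNDARIES,
    N_LABELS,
    N_LAYERS,
    BoundarySet,
    LayerMap,
)
from .io import OCTBScan

_EPS = 1e-12


# ---------------------------------------------------------------------------
# Shape atlas
# ---------------------------------------------------------------------------

@dataclass
class ShapeAtlas:
    """Per-pixel label prior on a reference grid.

    ``prior`` has shape (14, H, W) and sums to 1 over labels at each pixel.
    The reference frame is anchored laterally at the foveal column and
    axially at the inner-limiting-membrane (ILM) row, so a new scan only
    needs two 1-D translations to come into register.
    """

    prior: np.ndarray
    reference_fovea_column: int
    reference_ilm_row: float

    def __post_init__(self) -> None:
        self.prior = np.asarray(self.prior, dtype=np.float32)
        if self.prior.ndim != 3 or self.prior.shape[0] != N_LABELS:
            raise ValueError(f"prior must have shape (14, H, W), got {self.prior.shape}")
        sums = self.prior.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-6):
            raise ValueError("atlas prior must sum to 1 at every pixel")

    @property
    def shape(self) -> tuple[int, int]:
        return self.prior.shape[1:]


def _first_row_at_least(labels: np.ndarray, k: int) -> np.ndarray:
    """Per column, first row with label >= k (height where none)."""
    ge = labels >= k
    first = np.argmax(ge, axis=0).astype(float)
    first[~ge.any(axis=0)] = labels.shape[0]
    return first


def _ilm_row_of_map(labels: np.ndarray) -> float:
    return float(np.median(_first_row_at_least(labels, 1)))


def _shift_labels(labels: np.ndarray, d_row: int, d_col: int) -> np.ndarray:
    """Integer-shift a label image; vitreous fills the top, background the
    bottom, columns replicate at the lateral edges."""
    h, w = labels.shape
    out = labels
    if d_col:
        out = np.roll(out, d_col, axis=1)
        if d_col > 0:
            out[:, :d_col] = out[:, [d_col]]
        else:
            out[:, d_col:] = out[:, [d_col - 1]]
    if d_row:
        shifted = np.empty_like(out)
        if d_row > 0:
            shifted[d_row:] = out[: h - d_row]
            shifted[:d_row] = 0  # vitreous
        else:
            shifted[:d_row] = out[-d_row:]
            shifted[d_row:] = N_LABELS - 1  # sub-RPE background
        out = shifted
    return out


def build_shape_atlas(truth_set: list[LayerMap],
                      fovea_columns: list[int] | None = None) -> ShapeAtlas:
    """Build the label prior from gold-standard label maps.

    Maps are aligned to the reference (the median foveal column and ILM
    row) by 1-D lateral + axial integer shifts, then per-pixel label
    frequencies are computed with add-one smoothing.
    """
    if not truth_set:
        raise ValueError("empty training set")
    if len(truth_set) < 2:
        raise ValueError("need at least 2 training maps to build an atlas")
    shape = truth_set[0].shape
    if any(m.shape != shape for m in truth_set):
        raise ValueError("all training maps must share a grid")
    if fovea_columns is None:
        fovea_columns = [m.fovea_column_px for m in truth_set]
        if any(c is None for c in fovea_columns):
            raise ValueError("fovea columns required (not recorded on the maps)")

    ref_fc = int(np.median(fovea_columns))
    ilm_rows = [_ilm_row_of_map(m.labels) for m in truth_set]
    ref_ilm = float(np.median(ilm_rows))

    counts = np.zeros((N_LABELS,) + shape, dtype=np.float64)
    for m, fc, ilm in zip(truth_set, fovea_columns, ilm_rows):
        aligned = _shift_labels(m.labels, int(round(ref_ilm - ilm)),
                                int(ref_fc - fc))
        for lab in range(N_LABELS):
            counts[lab] += aligned == lab

    counts += 1.0  # add-one smoothing over the 14 labels
    prior = counts / counts.sum(axis=0, keepdims=True)
    return ShapeAtlas(prior=prior.astype(np.float32),
                      reference_fovea_column=ref_fc, reference_ilm_row=ref_ilm)


# ---------------------------------------------------------------------------
# LCDG intensity model
# ---------------------------------------------------------------------------

@dataclass
class LCDGModel:
    """Linear combination of discrete Gaussians over the gray-level range.

    ``dominant`` holds one positive (weight, mean, sd) per class, sorted by
    mean; ``subordinate`` holds signed refinement components fitted to the
    residual between the empirical and dominant densities.  The per-class
    discrete densities (``class_density``, one row per class over
    ``levels``) are nonnegative and each sums to 1.
    """

    dominant: list[tuple[float, float, float]]
    subordinate: list[tuple[float, float, float]]
    n_classes: int
    levels: np.ndarray
    class_density: np.ndarray      # (n_classes, L), rows sum to 1
    class_weights: np.ndarray      # (n_classes,), sums to 1
    loglik_trace: list[float] = field(default_factory=list)
    single_class_fallback: bool = False

    def __post_init__(self) -> None:
        self.levels = np.asarray(self.levels, dtype=float)
        self.class_density = np.asarray(self.class_density, dtype=float)
        if self.class_density.min(initial=0.0) < -1e-12:
            raise ValueError("class density negative after combining signed terms")
        sums = self.class_density.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-6):
            raise ValueError("per-class density must sum to 1 over the levels")

    @property
    def class_means(self) -> np.ndarray:
        return np.array([m for _, m, _ in self.dominant])

    def density(self) -> np.ndarray:
        """Combined mixture density over the levels (sums to 1)."""
        d = (self.class_weights[:, None] * self.class_density).sum(axis=0)
        return d / d.sum()

    def class_posterior(self, level_indices: np.ndarray) -> np.ndarray:
        """p(class | level) for an array of level indices -> (n_classes, ...)."""
        joint = (self.class_weights[:, None]
                 * self.class_density)[:, level_indices]
        return joint / np.maximum(joint.sum(axis=0, keepdims=True), _EPS)

    def log_class_likelihood(self, level_indices: np.ndarray) -> np.ndarray:
        return np.log(np.maximum(self.class_density[:, level_indices], _EPS))


def _gauss(levels: np.ndarray, mu: float, sd: float) -> np.ndarray:
    return np.exp(-0.5 * ((levels - mu) / sd) ** 2) / (sd * np.sqrt(2 * np.pi))


def fit_lcdg(intensity_histogram: np.ndarray, n_classes: int,
             max_subordinate: int = 4, levels: np.ndarray | None = None,
             max_iter: int = 300, tol: float = 1e-8) -> LCDGModel:
    """Fit the LCDG intensity model to a gray-level histogram.

    The dominant mixture (one Gaussian per class) is estimated by exact EM
    on the binned data, so the log-likelihood trace is nondecreasing.  Up
    to ``max_subordinate`` signed Gaussians are then fitted greedily to the
    residual between the empirical and dominant densities; the combined
    per-class densities are clipped to be nonnegative and renormalised.
    """
    hist = np.asarray(intensity_histogram, dtype=float)
    if hist.ndim != 1 or hist.size == 0 or hist.sum() <= 0:
        raise ValueError("histogram must be a nonempty 1-D array of counts")
    if n_classes < 2:
        raise ValueError("n_classes must be >= 2")
    if levels is None:
        levels = np.linspace(0.0, 1.0, hist.size)
    levels = np.asarray(levels, dtype=float)
    L = levels.size
    spacing = float(np.median(np.diff(levels))) if L > 1 else 1.0
    # floor well below the level spacing so a single-level cluster keeps
    # its mass on its own level after discretisation
    sd_floor = max(spacing / 4.0, 1e-5)

    occupied = np.flatnonzero(hist > 0)
    if occupied.size == 1:
        # degenerate: a single gray level; flag the single-class fallback
        mu = float(levels[occupied[0]])
        dens = np.zeros(L)
        dens[occupied[0]] = 1.0
        return LCDGModel(
            dominant=[(1.0, mu, sd_floor)], subordinate=[], n_classes=1,
            levels=levels, class_density=dens[None, :],
            class_weights=np.array([1.0]), loglik_trace=[],
            single_class_fallback=True)

    # --- init: deterministic weighted 1-D k-means over occupied levels,
    #     centres seeded at uniform quantiles of the *distinct* occupied
    #     levels so small, well-separated modes each attract a centre
    occ_x = levels[occupied]
    occ_c = hist[occupied]
    k_eff = min(n_classes, occupied.size)
    centres = occ_x[np.linspace(0, occupied.size - 1, k_eff).round().astype(int)]
    for _ in range(60):
        assign = np.argmin(np.abs(occ_x[None, :] - centres[:, None]), axis=0)
        new_centres = centres.copy()
        for k in range(k_eff):
            m = assign == k
            if m.any():
                new_centres[k] = (occ_c[m] * occ_x[m]).sum() / occ_c[m].sum()
        if np.allclose(new_centres, centres):
            break
        centres = new_centres
    w = np.full(n_classes, 1e-6)
    mu = np.empty(n_classes)
    sd = np.full(n_classes, sd_floor)
    mu[:k_eff] = np.sort(centres)
    if k_eff < n_classes:  # duplicate centres for surplus classes
        mu[k_eff:] = mu[k_eff - 1]
    order0 = np.argsort(centres)
    for j, k in enumerate(order0):
        m = assign == k
        tot = occ_c[m].sum()
        if tot > 0:
            w[j] = tot / hist.sum()
            var = (occ_c[m] * (occ_x[m] - mu[j]) ** 2).sum() / tot
            sd[j] = max(np.sqrt(var), sd_floor)
    w /= w.sum()

    # --- EM on the binned data (weights = counts)
    trace: list[float] = []
    prev = -np.inf
    for _ in range(max_iter):
        comp = w[:, None] * np.stack([_gauss(levels, mu[k], sd[k])
                                      for k in range(n_classes)])
        total = np.maximum(comp.sum(axis=0), _EPS)
        ll = float((hist * np.log(total)).sum())
        trace.append(ll)
        resp = comp / total  # (K, L)
        nk = (resp * hist).sum(axis=1)
        nk = np.maximum(nk, _EPS)
        w = nk / nk.sum()
        mu = (resp * hist * levels).sum(axis=1) / nk
        var = (resp * hist * (levels[None] - mu[:, None]) ** 2).sum(axis=1) / nk
        sd = np.maximum(np.sqrt(var), sd_floor)
        if ll - prev < tol * max(abs(ll), 1.0) and ll >= prev:
            break
        prev = ll

    order = np.argsort(mu)
    w, mu, sd = w[order], mu[order], sd[order]
    dominant = [(float(w[k]), float(mu[k]), float(sd[k])) for k in range(n_classes)]

    # --- dominant discrete densities per class
    dom_pdfs = np.stack([_gauss(levels, mu[k], sd[k]) for k in range(n_classes)])
    dom_pdfs /= np.maximum(dom_pdfs.sum(axis=1, keepdims=True), _EPS)

    # --- signed subordinate refinement of the pooled residual
    emp = hist / hist.sum()
    model_density = (w[:, None] * dom_pdfs).sum(axis=0)
    residual = emp - model_density
    subordinate: list[tuple[float, float, float]] = []
    for _ in range(max_subordinate):
        idx = int(np.argmax(np.abs(residual)))
        peak = residual[idx]
        if abs(peak) < 0.01 * emp.max():
            break
        sign = np.sign(peak)
        same = sign * residual > 0
        # contiguous run of same-signed residual around the peak
        lo = idx
        while lo > 0 and same[lo - 1]:
            lo -= 1
        hi = idx
        while hi < L - 1 and same[hi + 1]:
            hi += 1
        r = np.abs(residual[lo:hi + 1])
        x = levels[lo:hi + 1]
        mass = r.sum()
        m = (r * x).sum() / mass
        s = max(np.sqrt((r * (x - m) ** 2).sum() / mass), sd_floor)
        weight = float(sign * mass)
        subordinate.append((weight, float(m), float(s)))
        pdf = _gauss(levels, m, s)
        pdf /= max(pdf.sum(), _EPS)
        residual = residual - weight * pdf

    # --- fold subordinates into the nearest dominant class, keep densities
    #     nonnegative and normalised
    class_density = dom_pdfs.copy()
    for weight, m, s in subordinate:
        k = int(np.argmin(np.abs(mu - m)))
        pdf = _gauss(levels, m, s)
        pdf /= max(pdf.sum(), _EPS)
        class_density[k] = class_density[k] + (weight / max(w[k], _EPS)) * pdf
    class_density = np.maximum(class_density, 0.0)
    class_density /= np.maximum(class_density.sum(axis=1, keepdims=True), _EPS)

    return LCDGModel(dominant=dominant, subordinate=subordinate,
                     n_classes=n_classes, levels=levels,
                     class_density=class_density, class_weights=w,
                     loglik_trace=trace)


def histogram_of(scan: OCTBScan, n_levels: int = 256) -> np.ndarray:
    """Gray-level histogram of a [0,1] B-scan over ``n_levels`` bins."""
    idx = np.clip(np.round(scan.intensities * (n_levels - 1)).astype(int),
                  0, n_levels - 1)
    return np.bincount(idx.ravel(), minlength=n_levels).astype(float)


# ---------------------------------------------------------------------------
# MGRF + ICM labelling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MGRFParams:
    """Second-order (8-neighbour) Potts model and ICM schedule."""

    potts_potential: float = 4.0
    icm_max_iters: int = 12
    icm_tol: float = 1e-4  # stop when fewer than this fraction of pixels change

    def __post_init__(self) -> None:
        if not np.isfinite(self.potts_potential) or self.potts_potential < 0:
            raise ValueError("potts_potential must be finite and >= 0")
        if self.icm_max_iters < 1:
            raise ValueError("icm_max_iters must be >= 1")


_NEIGHBOR_OFFSETS = [(-1, -1), (-1, 0), (-1, 1), (0, -1),
                     (0, 1), (1, -1), (1, 0), (1, 1)]


def _neighbor_label_counts(labels: np.ndarray) -> np.ndarray:
    """(14, H, W) count of 8-neighbours holding each label."""
    h, w = labels.shape
    onehot = (labels[None, :, :] == np.arange(N_LABELS)[:, None, None])
    padded = np.zeros((N_LABELS, h + 2, w + 2), dtype=np.uint8)
    padded[:, 1:-1, 1:-1] = onehot
    counts = np.zeros((N_LABELS, h, w), dtype=np.uint8)
    for dr, dc in _NEIGHBOR_OFFSETS:
        counts += padded[:, 1 + dr:h + 1 + dr, 1 + dc:w + 1 + dc]
    return counts


def mgrf_energy(labels: np.ndarray, unary: np.ndarray, potts: float) -> float:
    """Gibbs energy: sum of unary costs + Potts penalty per unequal pair."""
    h, w = labels.shape
    e = float(unary[labels, np.arange(h)[:, None], np.arange(w)[None, :]].sum())
    unequal = 0
    for dr, dc in [(0, 1), (1, 0), (1, 1), (1, -1)]:  # each pair once
        a = labels[max(0, -dr):h - max(0, dr), max(0, -dc):w - max(0, dc)]
        b = labels[max(0, dr):h + min(0, dr) or h, max(0, dc):w + min(0, dc) or w]
        unequal += int((a != b).sum())
    return e + potts * unequal


def _icm(unary: np.ndarray, init: np.ndarray, params: MGRFParams,
         return_trace: bool = False):
    """Iterated conditional modes over a 2x2 block colouring.

    Pixels of one colour are mutually non-adjacent in the 8-neighbourhood,
    so each vectorised colour update is exact coordinate descent and the
    Gibbs energy is nonincreasing across updates.
    """
    labels = init.copy()
    h, w = labels.shape
    rr, cc = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    color_masks = [((rr % 2 == a) & (cc % 2 == b))
                   for a in (0, 1) for b in (0, 1)]
    potts = params.potts_potential
    energies = []
    if return_trace:
        energies.append(mgrf_energy(labels, unary, potts))
    for _ in range(params.icm_max_iters):
        changed = 0
        for mask in color_masks:
            counts = _neighbor_label_counts(labels)
            # cost of assigning label l = unary + potts * (#neighbours != l)
            nn = counts.sum(axis=0)  # neighbours present (border-aware)
            cost = unary + potts * (nn[None, :, :].astype(np.float32)
                                    - counts.astype(np.float32))
            best = np.argmin(cost, axis=0).astype(np.int8)  # ties: lowest label
            upd = mask & (best != labels)
            changed += int(upd.sum())
            labels[upd] = best[upd]
            if return_trace:
                energies.append(mgrf_energy(labels, unary, potts))
        if changed / labels.size < params.icm_tol:
            break
    if return_trace:
        return labels, energies
    return labels


def estimate_ilm_row(image: np.ndarray) -> float:
    """Median over columns of the first row brighter than the mid threshold."""
    sm = ndimage.uniform_filter(image, size=3)
    thr = 0.5 * (np.percentile(sm, 5) + np.percentile(sm, 95))
    above = sm > thr
    first = np.argmax(above, axis=0).astype(float)
    ok = above.any(axis=0)
    if not ok.any():
        raise ValueError("could not locate the ILM: no bright rows found")
    return float(np.median(first[ok]))


def estimate_fovea_column(scan: OCTBScan, window_fraction: float = 0.5) -> int:
    """Column of minimal retina extent within a central lateral window.

    The retina extent of a column is counted as rows brighter than the
    mid threshold between the dark (vitreous/background) and bright
    (retinal) intensity ranges; the foveal pit makes it minimal at the
    foveal centre.
    """
    img = ndimage.uniform_filter(scan.intensities, size=3)
    thr = 0.5 * (np.percentile(img, 5) + np.percentile(img, 95))
    extent = (img > thr).sum(axis=0).astype(float)
    extent = ndimage.uniform_filter1d(extent, size=9)
    w = scan.width
    half = int(w * window_fraction / 2)
    lo, hi = w // 2 - half, w // 2 + half
    return int(lo + np.argmin(extent[lo:hi]))


def _align_atlas_prior(scan: OCTBScan, atlas: ShapeAtlas,
                       fovea_column: int) -> np.ndarray:
    """Shift the atlas prior into the scan frame (lateral + axial)."""
    if atlas.shape != scan.shape:
        raise ValueError(
            f"atlas/bscan grid mismatch after alignment: {atlas.shape} vs {scan.shape}")
    d_col = int(fovea_column - atlas.reference_fovea_column)
    d_row = int(round(estimate_ilm_row(scan.intensities) - atlas.reference_ilm_row))
    prior = atlas.prior
    if d_col or d_row:
        h = prior.shape[1]
        shifted = np.empty_like(prior)
        for lab in range(N_LABELS):
            arr = prior[lab]
            if d_col:
                arr = np.roll(arr, d_col, axis=1)
                if d_col > 0:
                    arr[:, :d_col] = arr[:, [d_col]]
                else:
                    arr[:, d_col:] = arr[:, [d_col - 1]]
            if d_row:
                moved = np.empty_like(arr)
                if d_row > 0:
                    moved[d_row:] = arr[: h - d_row]
                    moved[:d_row] = arr[[0]]
                else:
                    moved[:d_row] = arr[-d_row:]
                    moved[d_row:] = arr[[-1]]
                arr = moved
            shifted[lab] = arr
        prior = shifted / np.maximum(shifted.sum(axis=0, keepdims=True), _EPS)
    return prior


def joint_map_label(bscan: OCTBScan, atlas: ShapeAtlas, lcdg: LCDGModel,
                    mgrf: MGRFParams, return_trace: bool = False):
    """MAP label field under the joint shape + intensity + spatial model.

    Each anatomical label is tied to the LCDG class whose mean is closest
    to the label's prior-weighted mean intensity in this scan, so several
    labels may share an intensity class and the shape prior disambiguates
    them.  Optimisation is ICM seeded at the atlas argmax.
    """
    fovea_column = (bscan.fovea_column_px if bscan.fovea_column_px is not None
                    else estimate_fovea_column(bscan))
    prior = _align_atlas_prior(bscan, atlas, fovea_column)

    img = bscan.intensities
    L = lcdg.levels.size
    level_idx = np.clip(np.round(img * (L - 1)).astype(int), 0, L - 1)

    # label -> intensity class: median scan intensity over the label's
    # atlas-argmax region.  The median tolerates the one-or-two-row
    # misregistration a translation-only atlas leaves on thin layers
    # (a mean would blend in the neighbouring layer), and the smoothing
    # floor of the prior is irrelevant inside the argmax region.
    class_means = lcdg.class_means
    argmax_prior = np.argmax(prior, axis=0)
    label_class = np.empty(N_LABELS, dtype=int)
    for lab in range(N_LABELS):
        region = argmax_prior == lab
        if region.any():
            m = float(np.median(img[region]))
        else:  # nowhere the argmax: fall back to excess-prior weighting
            excess = np.maximum(prior[lab] - prior[lab].min(), 0.0)
            m = float((excess * img).sum() / max(excess.sum(), _EPS))
        label_class[lab] = int(np.argmin(np.abs(class_means - m)))

    log_like = lcdg.log_class_likelihood(level_idx)  # (K, H, W)
    unary = np.empty((N_LABELS,) + img.shape, dtype=np.float32)
    for lab in range(N_LABELS):
        unary[lab] = -(log_like[label_class[lab]]
                       + np.log(np.maximum(prior[lab], _EPS)))

    init = np.argmax(prior, axis=0).astype(np.int8)
    result = _icm(unary, init, mgrf, return_trace=return_trace)
    if return_trace:
        labels, energies = result
        return LayerMap(labels, fovea_column_px=fovea_column), energies
    return LayerMap(result, fovea_column_px=fovea_column)


# ---------------------------------------------------------------------------
# Boundary extraction
# ---------------------------------------------------------------------------

def extract_boundaries(layer_map: LayerMap, median_window: int = 5) -> BoundarySet:
    """Ordered boundary curves from a label map.

    Per column, boundary ``k`` (0-based) is the transition midpoint before
    the first pixel with label >= k+1; ordering is enforced by an isotonic
    (running-maximum) projection down each column of boundaries and each
    curve is median-filtered laterally.  Columns where a layer vanishes
    (consecutive boundaries coincide) are flagged.
    """
    labels = layer_map.labels
    h, w = labels.shape
    curves = np.empty((N_BOUNDARIES, w))
    for k in range(N_BOUNDARIES):
        curves[k] = _first_row_at_least(labels, k + 1) - 0.5
    curves = np.maximum.accumulate(curves, axis=0)  # isotonic repair
    if median_window > 1:
        curves = np.stack([
            ndimage.median_filter(c, size=median_window, mode="nearest")
            for c in curves
        ])
        curves = np.maximum.accumulate(curves, axis=0)
    flagged = (np.diff(curves, axis=0) <= 0).any(axis=0)
    if flagged.any():
        warnings.warn(f"{int(flagged.sum())} columns have a zero-thickness layer",
                      stacklevel=2)
    return BoundarySet(curves, flagged_columns=flagged)


# ---------------------------------------------------------------------------
# Segmentation metrics
# ---------------------------------------------------------------------------

def dice_coefficient(a: LayerMap | np.ndarray, b: LayerMap | np.ndarray,
                     label: int) -> float:
    """Sørensen–Dice overlap 2|A∩B| / (|A|+|B|) for one label.

    When the label is absent from both maps the score is defined as 1.0
    (and a warning is emitted): two empty sets are identical.
    """
    la = a.labels if isinstance(a, LayerMap) else np.asarray(a)
    lb = b.labels if isinstance(b, LayerMap) else np.asarray(b)
    if la.shape != lb.shape:
        raise ValueError("label maps must share a grid")
    ma, mb = la == label, lb == label
    denom = int(ma.sum()) + int(mb.sum())
    if denom == 0:
        warnings.warn(f"label {label} empty in both maps; Dice defined as 1.0",
                      stacklevel=2)
        return 1.0
    return 2.0 * int((ma & mb).sum()) / denom


def mean_layer_dice(a: LayerMap, b: LayerMap,
                    labels: range = range(1, N_LAYERS + 1)) -> float:
    """Mean Dice over the 12 retinal layers."""
    return float(np.mean([dice_coefficient(a, b, lab) for lab in labels]))


def boundary_error_um(a: BoundarySet, b: BoundarySet,
                      axial_um_per_px: float) -> np.ndarray:
    """Per-boundary mean absolute row difference, in micrometres (13,)."""
    if a.width != b.width:
        raise ValueError("boundary sets must share a width")
    return np.abs(a.curves - b.curves).mean(axis=1) * axial_um_per_px


# ---------------------------------------------------------------------------
# Convenience driver
# ---------------------------------------------------------------------------

def segment_bscan(bscan: OCTBScan, atlas: ShapeAtlas,
                  mgrf: MGRFParams | None = None, n_classes: int = N_LABELS,
                  n_levels: int = 256, max_subordinate: int = 4,
                  ) -> tuple[LayerMap, BoundarySet, LCDGModel]:
    """Histogram -> LCDG fit -> joint MAP labelling -> boundary extraction."""
    if mgrf is None:
        mgrf = MGRFParams()
    hist = histogram_of(bscan, n_levels=n_levels)
    lcdg = fit_lcdg(hist, n_classes=n_classes, max_subordinate=max_subordinate)
    layer_map = joint_map_label(bscan, atlas, lcdg, mgrf)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        bset = extract_boundaries(layer_map)
    return layer_map, bset, lcdg
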