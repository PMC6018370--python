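"""Core geometric containers shared across the pipeline.

A macular B-scan is segmented into 12 retinal layers delimited by 13
boundary curves.  Pixels above the inner limiting membrane (ILM) are
vitreous, pixels below the outermost boundary (the RPE/choroid interface)
are sub-RPE background, giving a 14-symbol label alphabet:

    0          vitreous
    1 .. 12    retinal layers, top (inner) to bottom (outer)
    13         below-RPE background

Boundary ``k`` (0-based, k = 0..12) is the interface between label ``k``
and label ``k+1``; its value at a column is the *fractional* row of the
interface (row 0 is the top / vitreous side).  Fractional rows are what
make sub-pixel boundary errors in micrometres meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

N_LAYERS = 12
N_BOUNDARIES = 13
N_LABELS = 14  # vitreous + 12 layers + sub-RPE background

LABEL_VITREOUS = 0
LABEL_RPE = 12  # outermost retinal layer, the bright calibration anchor
LABEL_BACKGROUND = 13

#: positional layer names (the anatomy is treated positionally; these are
#: conventional inner-to-outer names used for display only)
LAYER_NAMES = (
    "RNFL", "GCL", "IPL", "INL", "OPL", "ONL",
    "ELM", "MZ", "EZ", "OS", "IZ", "RPE",
)

_ORDER_TOL = 1e-6


@dataclass
class BoundarySet:
    """13 ordered boundary curves, one fractional row per column each.

    ``curves`` has shape (13, width); ``curves[k] <= curves[k+1]``
    everywhere (a zero-thickness layer makes consecutive curves coincide).
    """

    curves: np.ndarray
    flagged_columns: np.ndarray | None = None  # bool mask: zero-thickness repairs

    def __post_init__(self) -> None:
        self.curves = np.asarray(self.curves, dtype=float)
        if self.curves.ndim != 2 or self.curves.shape[0] != N_BOUNDARIES:
            raise ValueError(
                f"expected {N_BOUNDARIES} boundary curves, got shape {self.curves.shape}"
            )
        diffs = np.diff(self.curves, axis=0)
        if diffs.min(initial=0.0) < -_ORDER_TOL:
            raise ValueError("boundary ordering violated: curve k > curve k+1 somewhere")

    @property
    def width(self) -> int:
        return self.curves.shape[1]

    def thickness_px(self, layer_index: int) -> np.ndarray:
        """Per-column thickness of layer ``layer_index`` (1..12) in pixels."""
        if not 1 <= layer_index <= N_LAYERS:
            raise ValueError(f"layer_index must be in 1..{N_LAYERS}")
        return self.curves[layer_index] - self.curves[layer_index - 1]

    def retina_thickness_px(self) -> np.ndarray:
        """ILM-to-outermost-boundary distance per column, in pixels."""
        return self.curves[-1] - self.curves[0]


@dataclass
class LayerMap:
    """Per-pixel label image over the 14-symbol alphabet."""

    labels: np.ndarray
    fovea_column_px: int | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("labels must be a 2-D grid")
        if self.labels.min(initial=0) < 0 or self.labels.max(initial=0) >= N_LABELS:
            raise ValueError(f"labels must lie in 0..{N_LABELS - 1}")
        self.labels = self.labels.astype(np.int8)

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def is_laminar(self) -> bool:
        """True when labels are nondecreasing down every column."""
        return bool((np.diff(self.labels.astype(np.int16), axis=0) >= 0).all())

    @classmethod
    def from_boundaries(cls, bset: BoundarySet, height: int,
                        fovea_column_px: int | None = None) -> "LayerMap":
        """Rasterize boundary curves into a label image.

        Pixel centre convention: pixel row ``r`` gets label
        ``#{k : boundary_k <= r}`` so a boundary at fractional row ``y``
        separates rows ``ceil(y)-1`` and ``ceil(y)``.
        """
        rows = np.arange(height, dtype=float)[:, None]  # (H, 1)
        labels = (bset.curves[None, :, :] <= rows[:, :, None]).sum(axis=1)
        return cls(labels.astype(np.int8), fovea_column_px=fovea_column_px)
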