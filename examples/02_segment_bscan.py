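"""Segment a phantom B-scan into 12 layers / 13 boundaries.

The joint model combines a shape atlas (label prior from gold-standard
maps), an LCDG intensity model fitted to the scan's histogram, and an
8-neighbour Potts MGRF optimised by ICM.  Accuracy is measured against
the phantom's known boundaries.
"""

import numpy as np

from octdr import (
    PhantomConfig,
    boundary_error_um,
    build_shape_atlas,
    generate_bscan,
    mean_layer_dice,
    segment_bscan,
)
from octdr.synthetic import generate_cohort

# shape atlas from 12 normal eyes (the "template" population)
atlas_records, _ = generate_cohort(6, (1.0, 0.0, 0.0), PhantomConfig(),
                                   seed=99)
atlas = build_shape_atlas([r.truth.layer_map for r in atlas_records])

cfg = PhantomConfig(noise_sd=0.05, seed=11)
scan, truth = generate_bscan(cfg)
layer_map, boundaries, lcdg = segment_bscan(scan, atlas)

dice = mean_layer_dice(layer_map, truth.layer_map)
err = boundary_error_um(boundaries, truth.boundaries, cfg.axial_um_per_px)
print(f"noise sd {cfg.noise_sd}: mean Dice over 12 layers = {dice:.3f}")
print(f"mean boundary error = {err.mean():.2f} um "
      f"({err.mean() / cfg.axial_um_per_px:.2f} axial px), "
      f"worst boundary = {err.max():.2f} um")
print(f"LCDG fitted {lcdg.n_classes} intensity classes; "
      f"EM took {len(lcdg.loglik_trace)} iterations")

# Dice near 1 and sub-pixel boundary error mean the label field matches
# the ground truth almost everywhere despite the speckle noise.
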