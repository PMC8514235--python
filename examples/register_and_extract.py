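"""Confocal → two-photon registration: landmark fit, ROI transfer, trace pull.

Blood-vessel landmarks visible in both frames pin down a similarity transform
(rotation + scale + translation).  ROIs drawn on the stained confocal image
are then mapped onto the movie's pixel grid and used to extract per-soma
fluorescence traces.
"""

import numpy as np

from retinotype import FieldGeometry
from retinotype.register import (
    ROI,
    SimilarityTransform,
    estimate_similarity_transform,
    extract_traces,
    transfer_rois,
)
from retinotype.synthetic import generate_landmark_fields, generate_roi_movie

# landmarks in two frames related by a known transform, with 1 µm click jitter
true = SimilarityTransform(rotation_deg=30.0, scale=1.1, translation=(12.0, -5.0))
pairs = generate_landmark_fields(40, true, jitter_sd=1.0, seed=0)
est, rms = estimate_similarity_transform(pairs)
print(f"true transform:      rot 30.0°, scale 1.100, t (12.0, -5.0) µm")
print(
    f"estimated transform: rot {est.rotation_deg:.1f}°, scale {est.scale:.3f}, "
    f"t ({est.translation[0]:.1f}, {est.translation[1]:.1f}) µm; "
    f"RMS residual {rms:.2f} µm"
)

# transfer two soma ROIs into a 64×32 µm movie frame and pull their traces
geometry = FieldGeometry(64.0, 32.0, pixel_size=1.0)
rois = [
    ROI("soma_1", polygon=[(5, 5), (15, 5), (15, 15), (5, 15)]),
    ROI("soma_2", polygon=[(40, 10), (55, 10), (55, 25), (40, 25)]),
]
kept, excluded = transfer_rois(rois, SimilarityTransform(), geometry)
known = [2 + np.sin(np.arange(40) / 4.0), 1 + (np.arange(40) >= 20) * 2.0]
movie = generate_roi_movie([r.mask for r in kept], known, noise_sd=0.05, seed=1)
traces = extract_traces(movie, kept, sample_rate=8.0)
for roi, trace, truth in zip(kept, traces, known):
    err = np.abs(trace.values - truth).mean()
    print(f"{roi.id}: {roi.mask.sum()} px, mean |trace − truth| = {err:.3f}")

# The estimate matches the generating transform to well under the landmark
# jitter, and each extracted trace reproduces the trace painted into its ROI.
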