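"""Calcium-response typing: z-score, ON-OFF index, DSI/OSI, QI, grouping.

Simulates three archetypal ganglion cells — an untuned sustained-ON cell, a
direction-selective ON cell, and an ON-OFF cell — and computes the feature
indices used to type them.
"""

import numpy as np

from retinotype.responses import (
    average_trials,
    direction_selectivity,
    epoch_mean,
    on_off_index,
    orientation_selectivity,
    peak_by_direction,
    quality_index,
    zscore_trace,
)
from retinotype.synthetic import CellTuningParams, StimulusProtocol, generate_trial_responses

protocol = StimulusProtocol.moving_bar()  # full-field flash + 8 bar directions
cells = {
    "sustained ON": CellTuningParams(0.0, kappa=0.0, on_amplitude=1.2,
                                     off_amplitude=0.05, noise_sd=0.1),
    "ON direction-selective": CellTuningParams(270.0, kappa=3.0, on_amplitude=1.0,
                                               off_amplitude=0.1, noise_sd=0.1),
    "ON-OFF": CellTuningParams(0.0, kappa=0.5, on_amplitude=0.8,
                               off_amplitude=0.8, noise_sd=0.1),
}

for name, cell in cells.items():
    trials = generate_trial_responses(cell, protocol, n_trials=5, frame_rate=8.0, seed=3)
    z = [zscore_trace(t) for t in trials]
    avg = average_trials(z)
    onoff = on_off_index(epoch_mean(avg, "full_on"), epoch_mean(avg, "full_off"))
    tuning = peak_by_direction(z)
    dsi = direction_selectivity(tuning)
    osi = orientation_selectivity(tuning)
    qi = quality_index(np.stack([t.values for t in z]))
    print(
        f"{name}: ON-OFF {onoff:+.2f}  DSI {dsi.index:.2f} @ {dsi.preferred_angle:.0f}°  "
        f"OSI {osi.index:.2f}  QI {qi:.2f}"
    )

# ON-OFF near +1 marks pure-ON cells and near 0 balanced ON-OFF cells; the
# DS cell's DSI is high with a preferred direction near its ground-truth 270°;
# QI near 1 reflects repeatable trials at this noise level.
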