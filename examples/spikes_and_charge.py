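"""Electrophysiology: spike detection, PSTH, tuning, and charge integration.

Loose-patch spikes are detected by robust peak finding and binned into 50 ms
PSTHs; whole-cell currents are baseline-subtracted and integrated over each
stimulus epoch to give synaptic charge.
"""

import numpy as np

from retinotype.core import TrialResponse
from retinotype.ephys import detect_spikes, integrate_charge, psth, tuning_from_psth
from retinotype.responses import direction_selectivity
from retinotype.synthetic import generate_current_trace, generate_spike_trains

# --- spike detection on a noisy voltage trace with three known spikes
rate = 20_000.0
rng = np.random.default_rng(0)
v = rng.normal(0.0, 1.0, int(rate))
for t_spk in (0.12, 0.45, 0.80):
    v[int(t_spk * rate)] += 40.0
train = detect_spikes(TrialResponse(v, rate), threshold_k=5.0, refractory=0.002)
print(f"detected spikes at {np.round(train.spike_times, 3)} s (injected at 0.12, 0.45, 0.80)")

# --- PSTH + direction tuning from Poisson spiking with a tuned rate
directions = np.arange(0.0, 360, 45)
hists = {}
for theta in directions:
    peak = 40.0 * np.exp(3.0 * (np.cos(np.deg2rad(theta - 90.0)) - 1.0))
    trains = generate_spike_trains(
        lambda t, r=peak: np.where((t >= 0.5) & (t < 1.5), r + 2.0, 2.0),
        2.0, n_trials=20, seed=int(theta),
    )
    hists[theta] = psth(trains, bin_width=0.05)
tuning = tuning_from_psth(hists, {th: (0.5, 1.5) for th in directions})
res = direction_selectivity(tuning)
print(f"spike-rate tuning: DSI {res.index:.2f}, preferred {res.preferred_angle:.0f}° "
      f"(rate peaked at 90°)")

# --- charge transferred by an inward synaptic current
trace = generate_current_trace(
    epochs={"baseline": (0.0, 0.5), "stim": (0.5, 1.0)},
    amplitudes={"stim": -60.0}, baseline=-5.0, noise_sd=2.0, sample_rate=20_000.0, seed=1,
)
result = integrate_charge(trace, "stim")
print(f"stimulus-evoked charge {result.charge_pc:.1f} pC, peak {result.peak_pa:.0f} pA "
      f"(−60 pA × 0.5 s → −30 pC)")
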