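"""Remove ocular artifacts with ICA, then cut fixation-locked epochs.

Each saccade superimposes a large corneo-retinal dipole deflection on the EEG.
An Infomax unmixing matrix is estimated on the 12 EEG channels; components
whose activations correlate with the EOG channels at |r| >= 0.7 are zeroed and
the EEG is back-projected.  Epochs (800 ms from fixation onset) are then
extracted and bandpass filtered 0.5-10 Hz.
"""

import numpy as np

from fixfrp import gaze, preprocess, simulate

cfg = simulate.reference_high_snr_config(seed=7)
rng = np.random.default_rng(cfg.seed)
layout, stream, truth, recording = simulate.simulate_subject(cfg, rng)

cleaned, ica = preprocess.clean_recording(recording, seed=cfg.seed)
print(f"ICA removed component(s): {sorted(ica.removed)} of {ica.unmixing.shape[0]}")

# how much saccade-interval power did cleaning remove from a frontal channel?
fz = recording.channel_names.index("Fz")
before = recording.data[fz].var()
after = cleaned.data[fz].var()
print(f"Fz variance: {before:8.1f} -> {after:8.1f} uV^2 "
      f"({1 - after / before:.0%} reduction)")

fixations = gaze.label_fixations(
    gaze.detect_fixations(stream, px_per_deg=cfg.px_per_deg),
    layout, px_per_deg=cfg.px_per_deg,
)
epochs = preprocess.extract_epochs(cleaned, fixations, subject_id="S00")
epochs = preprocess.bandpass_epochs(epochs, 0.5, 10.0)
print(f"\n{len(epochs)} epochs of shape {epochs[0].data.shape} "
      f"(channels x samples, {preprocess.EPOCH_DURATION_S * 1000:.0f} ms)")

# fixation-related potential: average the Pz channel per class
pz = epochs[0].channel_names.index("Pz")
for cls in ("target", "nontarget", "background"):
    avg = np.mean([e.data[pz] for e in epochs if e.label == cls], axis=0)
    peak = np.argmax(avg)
    print(f"  {cls:<10s} Pz peak {avg[peak]:6.2f} uV at "
          f"{peak / epochs[0].fs * 1000:3.0f} ms post fixation onset")
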