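"""Preprocess a raw multichannel recording with the 128 Hz recipe.

Builds a 30 s, 2-channel recording at 256 Hz containing a 10 Hz alpha
rhythm plus broadband noise, then runs the dimensional-dataset recipe
(band-pass 4-45 Hz, resample to 128 Hz, cut 4-s epochs) and prints the
result.  The epoch count follows from floor(30 s / 4 s) = 7; each epoch is
4 s x 128 Hz = 512 samples.
"""

import numpy as np

from ertnet import EEGRecording, apply_pipeline
from ertnet.io import DEAP_PIPELINE

rng = np.random.default_rng(0)
t = np.arange(30 * 256) / 256.0
signal = np.stack([
    20 * np.sin(2 * np.pi * 10 * t) + rng.normal(0, 5, t.size),
    rng.normal(0, 5, t.size),
])
rec = EEGRecording(signal, 256.0, ["O1", "Cz"], subject_id="S01")

epochs = apply_pipeline(rec, DEAP_PIPELINE)
print(f"input:  {rec.n_channels} channels x {rec.n_samples} samples "
      f"@ {rec.sampling_rate:.0f} Hz")
print(f"output: {len(epochs)} epochs of "
      f"{epochs.epochs.shape[1]} x {epochs.epochs.shape[2]} "
      f"@ {epochs.sampling_rate:.0f} Hz")
print(f"finite: {np.isfinite(epochs.epochs).all()}")
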