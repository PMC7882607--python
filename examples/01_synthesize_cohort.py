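"""Generate a small synthetic EEG cohort and look at its structure.

The generator emulates a two-age-group study: elderly subjects have their
alpha peak shifted 1 Hz down and occipital alpha gains attenuated to 0.7.
"""

import numpy as np
from scipy.signal import periodogram

from eegmarkers import CohortConfig, generate_cohort

cfg = CohortConfig(
    n_young=4, n_elderly=4, n_channels=16, n_trials_per_condition=20,
    conditions=("face", "car"), seed=1,
)
cohort = generate_cohort(cfg)
print(f"{len(cohort.subjects)} subjects × {len(cohort.conditions)} conditions, "
      f"trials of shape {cohort.get('S000', 'face').data.shape} at {cohort.fs:g} Hz")

occ = cfg.occipital_channels[-1]
for subject in cohort.subjects:
    ts = cohort.get(subject, "face")
    f, p = periodogram(ts.data[:, occ, :], fs=cfg.fs, axis=-1)
    p = p.mean(axis=0)
    band = (f >= 6) & (f <= 14)
    peak = f[band][np.argmax(p[band])]
    print(f"  {subject} ({ts.group:7s}): occipital alpha peak {peak:5.2f} Hz")

# Elderly peaks cluster ~1 Hz below young ones — the group effect every
# downstream feature set tries to recover.
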