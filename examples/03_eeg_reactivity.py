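"""Baseline-normalized EEG band-power reactivity for one cohort.

For every session: band-pass filter (0.1-50 Hz) + notch, EOG regression,
2000-ms epochs with artifact rejection, Hamming-tapered spectra at 0.5 Hz
resolution, band x ROI powers, and the task-related reactivity
TR = (P_task - P_baseline) / P_baseline against the eyes-open baseline.
"""

import pandas as pd

from stresslab import CohortSpec, EffectSpec, iter_cohort, session_reactivity

rows = []
for s in iter_cohort(CohortSpec.fast(n_per_group=4, seed=3), EffectSpec()):
    tr = session_reactivity(s.eeg)
    tr["group"] = s.group
    rows.append(tr)
df = pd.concat(rows, ignore_index=True)

print("group-mean reactivity per band (averaged over ROIs and discourses):")
print(df.groupby(["group", "band"])["tr_psd"].mean().unstack().round(3).to_string())

# Negative values = band power suppressed relative to baseline. The dynamic
# group shows alpha/theta/delta suppression and gamma elevation -- the
# injected effect pattern: stronger attentional engagement and cognitive
# involvement under the dynamic committee.
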