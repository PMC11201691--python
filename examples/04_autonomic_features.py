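"""Heart-rate, HRV and electrodermal features per discourse.

ECG: 35 Hz low-pass, R peaks by derivative-energy thresholding, per-phase
HR (bpm), RMSSD and SDNN (ms). EDA: 10 Hz low-pass, tonic level (SCL) by
0.05 Hz low-pass, phasic skin-conductance responses (SCRs) as trough-to-
peak excursions of at least 0.01 uS.
"""

from stresslab import CohortSpec, EffectSpec, ecg_features, eda_features, generate_cohort

cohort = generate_cohort(CohortSpec.fast(n_per_group=2, seed=9), EffectSpec())
s = cohort[0]

ecg = ecg_features(s.ecg, s.markers, s.sfreq)
print(f"{s.participant_id} ({s.group}) ECG features:")
print(ecg.round(2).to_string(index=False))

eda = eda_features(s.eda, s.markers, s.sfreq)
print("\nEDA features:")
print(eda.round(3).to_string(index=False))

truth = s.ground_truth
print(f"\nground truth: mean IBI {truth['ibi_ms'].mean():.0f} ms "
      f"(HR {60000 / truth['ibi_ms'].mean():.1f} bpm), "
      f"{len(truth['scr_events'])} injected SCRs across the whole session")

# HR should recover the injected inter-beat statistics; SCR counts per
# discourse follow the group's injected Poisson rate (higher in Dyn-DSST).
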