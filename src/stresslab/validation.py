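"""Simulation studies: calibration and parameter recovery of the pipeline.

These functions run many seeded synthetic cohorts through the analysis to
measure (i) the type-I error of the group test under a null cohort, (ii)
how often the injected group effect directions are recovered with the
correct sign at the default effect sizes, and (iii) the sensitivity and
false-discovery rate of the phasic electrodermal-response detector. They
back the package's own quality gates and are reusable for power analyses.

All problem sizes are chosen for desk-scale runs: the recovery study uses
the reduced cohort profile (128 Hz, 12-s baselines, 10-s preparation
segments, the eight analysis channels plus EOG) with the full 26
participants per group.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sct

from . import behavioral
from .autonomic import detect_scrs, eda_features
from .cohort import CohortSpec, EffectSpec, iter_cohort, synth_eda
from .constants import GROUP_DYNAMIC, GROUP_STATIC
from .eeg import session_reactivity
from .stats import oneway_anova

__all__ = [
    "type1_error_rate",
    "direction_recovery",
    "scr_detection_performance",
]


def _child_seeds(seed: int, n: int) -> np.ndarray:
    """Independent 31-bit child seeds from one root seed."""
    return np.random.SeedSequence(seed).generate_state(n) & 0x7FFFFFFF


def type1_error_rate(
    n_reps: int = 1000,
    seed: int = 0,
    n_per_group: int = 26,
    alpha: float = 0.05,
) -> float:
    """Rejection rate of the one-way group test on null cohorts.

    Each replicate draws preparation times for both groups from the same
    truncated-normal model (no group effect), scores them, decile-transforms
    the regulation score against the pilot reference, and tests the group
    main effect at ``alpha``. Returns the fraction of replicates rejecting;
    calibration means a value near ``alpha``.
    """
    spec = CohortSpec()
    ref = behavioral.score_prep_times(behavioral.pilot_reference())["reg_raw"].to_numpy()
    a = (0.0 - spec.rt_loc) / spec.rt_scale
    b = (spec.prep_limit - spec.rt_loc) / spec.rt_scale
    labels = np.repeat([GROUP_DYNAMIC, GROUP_STATIC], n_per_group)
    rejections = 0
    for s in _child_seeds(seed, n_reps):
        rng = np.random.default_rng(s)
        t = sct.truncnorm.rvs(a, b, loc=spec.rt_loc, scale=spec.rt_scale,
                              size=(2 * n_per_group, spec.n_discourses),
                              random_state=rng)
        prep = pd.DataFrame(t, columns=[f"d{i+1}" for i in range(spec.n_discourses)])
        prep.insert(0, "group", labels)
        prep.insert(0, "participant_id", [f"p{i:03d}" for i in range(len(prep))])
        scores = behavioral.score_prep_times(prep)
        scores["reg_decile"] = behavioral.decile_transform(scores["reg_raw"], ref)
        res = oneway_anova(
            {g: sub["reg_decile"].to_numpy() for g, sub in scores.groupby("group")}
        )
        rejections += res.p < alpha
    return rejections / n_reps


def _cohort_directions(spec: CohortSpec, effects: EffectSpec) -> dict[str, bool]:
    """Sign checks of the four headline group effects for one cohort."""
    reg, alpha_tr, gamma_tr, scr = {}, {}, {}, {}
    for s in iter_cohort(spec, effects):
        reg.setdefault(s.group, []).append(
            np.mean([behavioral.reg_score_bin(t) for t in s.prep_times]))
        tr = session_reactivity(s.eeg)
        by_band = tr.groupby("band")["tr_psd"].mean()
        alpha_tr.setdefault(s.group, []).append(by_band["alpha"])
        gamma_tr.setdefault(s.group, []).append(by_band["gamma"])
        eda = eda_features(s.eda, s.markers, s.sfreq)
        scr.setdefault(s.group, []).append(eda["scr_amp_mean"].mean())
    dyn, stat = spec.group_labels
    m = {k: {g: float(np.mean(v)) for g, v in d.items()}
         for k, d in [("reg", reg), ("alpha", alpha_tr), ("gamma", gamma_tr), ("scr", scr)]}
    return {
        "reg_stat_gt_dyn": m["reg"][stat] > m["reg"][dyn],
        "alpha_dyn_lt_stat": m["alpha"][dyn] < m["alpha"][stat],
        "gamma_dyn_gt_stat": m["gamma"][dyn] > m["gamma"][stat],
        "scr_dyn_gt_stat": m["scr"][dyn] > m["scr"][stat],
    }


def direction_recovery(
    n_cohorts: int = 200,
    seed: int = 0,
    n_per_group: int = 26,
) -> dict[str, float]:
    """Fraction of simulated cohorts recovering each effect direction.

    At the default injected effect sizes the expected directions are:
    higher regulation score in the static group, lower alpha reactivity and
    higher gamma reactivity in the dynamic group, and a higher mean phasic
    electrodermal amplitude in the dynamic group. Returns the per-effect
    fraction of cohorts whose group means are ordered accordingly.
    """
    effects = EffectSpec()
    counts: dict[str, int] = {}
    for s in _child_seeds(seed, n_cohorts):
        spec = CohortSpec.fast(n_per_group=n_per_group, seed=int(s))
        for k, ok in _cohort_directions(spec, effects).items():
            counts[k] = counts.get(k, 0) + int(ok)
    return {k: v / n_cohorts for k, v in counts.items()}


def scr_detection_performance(
    n_segments: int = 200,
    seed: int = 0,
    duration: float = 60.0,
    fs: float = 128.0,
    scr_rate: float = 4.0,
    scr_amp: float = 0.5,
    match_tol_s: float = 1.0,
) -> dict[str, float]:
    """Sensitivity and false-discovery rate of the SCR detector.

    Synthesizes ``n_segments`` electrodermal segments at the default
    signal-to-noise ratio, detects phasic responses, and matches detections
    to the injected ground-truth onsets within ``match_tol_s`` (greedy,
    one-to-one). Returns pooled sensitivity, false-discovery rate and the
    event count.
    """
    n_true = n_hit = n_det = 0
    for s in _child_seeds(seed, n_segments):
        sig, events = synth_eda(duration, fs, scr_rate, scr_amp, int(s))
        det = detect_scrs(sig, fs)
        truth = [t for t, _ in events]
        n_true += len(truth)
        n_det += len(det)
        used = set()
        for t0 in truth:
            best, best_d = None, match_tol_s
            for i, onset in enumerate(det["onset"]):
                if i in used:
                    continue
                d = abs(onset - t0)
                if d <= best_d:
                    best, best_d = i, d
            if best is not None:
                used.add(best)
                n_hit += 1
    return {
        "sensitivity": n_hit / n_true if n_true else np.nan,
        "fdr": (n_det - n_hit) / n_det if n_det else 0.0,
        "n_events": n_true,
    }
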