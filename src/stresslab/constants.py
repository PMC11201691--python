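"""Design constants of the digital social stress interview paradigm.

The task is a five-discourse simulated interview (a digitally administered
variant of the Trier Social Stress Test). Each discourse has a preparation
phase capped at 120 s; two resting baselines (eyes open / eyes closed) are
recorded before the task. Signals are EEG (10/20 montage, earlobe
reference), two EOG channels, ECG and electrodermal activity, natively
sampled at 1000 Hz.
"""

from __future__ import annotations

# --- study design ---------------------------------------------------------
N_PER_GROUP = 26
N_PARTICIPANTS = 2 * N_PER_GROUP
N_DISCOURSES = 5
PREP_LIMIT_S = 120.0          # hard cap on the preparation phase
SPEECH_LIMIT_S = 60.0         # speech phase cap (not analyzed here)
BASELINE_DURATION_S = 120.0   # each resting baseline, eyes open and closed
NATIVE_SAMPLING_RATE_HZ = 1000.0

GROUP_DYNAMIC = "Dyn-DSST"    # video-recorded, dynamic examining committee
GROUP_STATIC = "Stat-DSST"    # still-image, static examining committee
GROUP_LABELS = (GROUP_DYNAMIC, GROUP_STATIC)

# --- montage ---------------------------------------------------------------
# 16 scalp sites from the 10/20 system plus two periocular EOG electrodes
# (18 recorded electrode channels in total).
SCALP_CHANNELS = (
    "Fp1", "Fp2", "F7", "F3", "F4", "F8",
    "T7", "C3", "Cz", "C4", "T8",
    "P3", "Pz", "P4", "O1", "O2",
)
EOG_CHANNELS = ("EOG1", "EOG2")

# Electrode pairs entering the band-power analysis, grouped into four
# regions of interest: left/right frontal and left/right temporo-parietal.
ROIS = {
    "F1": ("F3", "F7"),
    "F2": ("F4", "F8"),
    "TP1": ("T7", "P3"),
    "TP2": ("T8", "P4"),
}
ANALYSIS_CHANNELS = tuple(ch for pair in ROIS.values() for ch in pair)

# --- spectral analysis ------------------------------------------------------
# Canonical band edges (Hz); gaps between printed bands belong to no band.
BANDS = {
    "delta": (0.5, 3.5),
    "theta": (4.0, 7.5),
    "alpha": (8.0, 12.5),
    "beta": (13.0, 30.0),
    "gamma": (30.5, 50.0),
}
EPOCH_MS = 2000.0             # analysis window length
FREQ_RESOLUTION_HZ = 0.5      # spectral bin width (1 / epoch length)
UPPER_BAND_EDGE_HZ = 50.0

# --- marker labels ----------------------------------------------------------
MARKER_BASELINE_OPEN = "baseline_open"
MARKER_BASELINE_CLOSED = "baseline_closed"


def prep_marker(discourse: int) -> str:
    """Marker label for the preparation phase of discourse ``discourse`` (1-based)."""
    return f"prep_D{discourse}"


def discourse_of(label: str) -> int | None:
    """Inverse of :func:`prep_marker`; ``None`` for non-preparation labels."""
    if label.startswith("prep_D"):
        return int(label[len("prep_D"):])
    return None
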