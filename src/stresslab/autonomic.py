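"""Autonomic features: heart rate / HRV from ECG, tonic and phasic EDA.

ECG is low-pass filtered at 35 Hz; R peaks are located by derivative-energy
thresholding with a refractory period and refined to the local signal
maximum. Per preparation phase the inter-beat intervals (IBIs, ms) give the
heart rate (HR = 60000 / mean IBI, bpm) and two time-domain HRV metrics:
RMSSD (root mean square of successive IBI differences; the headline
short-segment metric) and SDNN (IBI standard deviation).

Electrodermal activity is low-pass filtered at 10 Hz and split into a tonic
skin-conductance level (very slow component, 0.05 Hz low-pass) and a phasic
residual; skin-conductance responses are trough-to-peak excursions of the
phasic component of at least ``amp_threshold`` µS with a 1–5 s rise time.
Per phase the features are the mean SCL, the mean SCR amplitude (0 when no
event occurred) and the SCR count.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps

from .eeg import Marker
from .constants import discourse_of

__all__ = [
    "detect_rpeaks",
    "rmssd",
    "sdnn",
    "ecg_features",
    "tonic_phasic_split",
    "detect_scrs",
    "eda_features",
]

MIN_BEATS = 3
# Conventional bounds on the trough-to-peak rise time of a skin-conductance
# response; the lower edge also resolves closely spaced response pairs.
SCR_MIN_RISE_S = 0.5
SCR_MAX_RISE_S = 5.0
DEFAULT_SCR_THRESHOLD_US = 0.01   # conventional minimum SCR amplitude


from functools import lru_cache


@lru_cache(maxsize=64)
def _lp_sos(order: int, cutoff: float, fs: float):
    return sps.butter(order, cutoff, btype="lowpass", fs=fs, output="sos")


def _lowpass(x: np.ndarray, fs: float, cutoff: float, order: int = 4) -> np.ndarray:
    return sps.sosfiltfilt(_lp_sos(order, cutoff, fs), x)


# ---------------------------------------------------------------------------
# ECG


def detect_rpeaks(signal: np.ndarray, fs: float,
                  refractory_s: float = 0.25) -> np.ndarray:
    """R-peak sample indices by derivative-energy thresholding.

    The 35 Hz low-passed signal is differentiated and squared; a 120-ms
    moving average of that energy is thresholded at 30% of its 99th
    percentile; energy bursts closer than the refractory period are merged.
    Each burst is refined to the maximum of the filtered signal within
    ±100 ms, which on clean recordings recovers the R sample exactly.
    """
    y = _lowpass(np.asarray(signal, float), fs, 35.0)
    energy = np.diff(y, prepend=y[0]) ** 2
    win = max(int(round(0.12 * fs)), 1)
    env = np.convolve(energy, np.ones(win) / win, mode="same")
    thr = 0.3 * np.percentile(env, 99)
    if thr <= 0:
        return np.array([], dtype=int)
    bursts, _ = sps.find_peaks(env, height=thr, distance=max(int(refractory_s * fs), 1))
    half = int(round(0.1 * fs))
    peaks = []
    for b in bursts:
        lo, hi = max(b - half, 0), min(b + half + 1, y.size)
        peaks.append(lo + int(np.argmax(y[lo:hi])))
    peaks = sorted(set(peaks))
    # drop refinements that collapsed onto the same R wave
    out = []
    for p in peaks:
        if not out or p - out[-1] > int(refractory_s * fs):
            out.append(p)
    return np.asarray(out, dtype=int)


def rmssd(ibi_ms: np.ndarray) -> float:
    """Root mean square of successive inter-beat-interval differences (ms)."""
    ibi = np.asarray(ibi_ms, dtype=float)
    if ibi.size < 2:
        return np.nan
    return float(np.sqrt(np.mean(np.diff(ibi) ** 2)))


def sdnn(ibi_ms: np.ndarray) -> float:
    """Standard deviation of the inter-beat intervals (ms, ddof=1)."""
    ibi = np.asarray(ibi_ms, dtype=float)
    if ibi.size < 2:
        return np.nan
    return float(np.std(ibi, ddof=1))


def ecg_features(signal: np.ndarray, markers: Sequence[Marker], fs: float,
                 min_beats: int = MIN_BEATS) -> pd.DataFrame:
    """Per-discourse HR (bpm), RMSSD and SDNN (ms) from one ECG record.

    Phases with fewer than ``min_beats`` detected beats yield NaN features
    and are flagged in the ``valid`` column.
    """
    peaks = detect_rpeaks(signal, fs)
    beat_t = peaks / fs
    rows = []
    for m in markers:
        d = discourse_of(m.label)
        if d is None:
            continue
        sel = beat_t[(beat_t >= m.onset) & (beat_t <= m.onset + m.duration)]
        ibi = np.diff(sel) * 1000.0
        ok = sel.size >= min_beats
        rows.append({
            "discourse": d,
            "n_beats": int(sel.size),
            "hr": 60000.0 / ibi.mean() if ok else np.nan,
            "rmssd": rmssd(ibi) if ok else np.nan,
            "sdnn": sdnn(ibi) if ok else np.nan,
            "valid": bool(ok),
        })
    return pd.DataFrame(rows).sort_values("discourse").reset_index(drop=True)


# ---------------------------------------------------------------------------
# EDA


def tonic_phasic_split(signal: np.ndarray, fs: float,
                       tonic_cutoff: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Split an EDA record into tonic (0.05 Hz low-pass) and phasic residual.

    The tonic filter is first order: its step response is monotone, so
    sparse phasic events do not ring through into the residual.
    """
    clean = _lowpass(np.asarray(signal, float), fs, 10.0)
    tonic = _lowpass(clean, fs, tonic_cutoff, order=1)
    return tonic, clean - tonic


def detect_scrs(signal: np.ndarray, fs: float,
                amp_threshold: float = DEFAULT_SCR_THRESHOLD_US) -> pd.DataFrame:
    """Skin-conductance responses on a full record.

    Candidate peaks are local maxima of a smoothed phasic component; each
    is paired with its onset trough (see inline notes). Kept events have
    trough-to-peak amplitude ≥ ``amp_threshold``, a peak above the phasic
    zero line, and a rise time within [0.5, 5] s. Returns onset (trough)
    time, peak time and amplitude per event.
    """
    _, phasic = tonic_phasic_split(signal, fs)
    # 2 Hz smoothing: phasic events live well below 2 Hz, and close pairs
    # of responses keep distinct local maxima
    det = _lowpass(phasic, fs, 2.0)
    peaks, _ = sps.find_peaks(det, distance=max(int(0.5 * fs), 1),
                              prominence=amp_threshold / 2)
    rows = []
    max_rise = int(SCR_MAX_RISE_S * fs)
    for p in peaks:
        # onset trough: walk back tracking the running minimum until the
        # signal (seen backward) has risen by the threshold — skips noise
        # micro-minima but stops at the dip separating two close responses
        lo = max(p - max_rise, 0)
        trough = p
        i = p
        while i > lo:
            i -= 1
            if det[i] < det[trough]:
                trough = i
            elif det[i] - det[trough] >= amp_threshold:
                break
        amp = float(det[p] - det[trough])
        rise = (p - trough) / fs
        # a genuine response peaks above the phasic zero line; bumps inside
        # the post-response undershoot (recovering toward zero) do not
        if (amp >= amp_threshold and det[p] >= amp_threshold
                and SCR_MIN_RISE_S <= rise <= SCR_MAX_RISE_S):
            rows.append({"onset": trough / fs, "peak": p / fs, "amplitude": amp})
    return pd.DataFrame(rows, columns=["onset", "peak", "amplitude"])


def eda_features(signal: np.ndarray, markers: Sequence[Marker], fs: float,
                 amp_threshold: float = DEFAULT_SCR_THRESHOLD_US,
                 min_duration_s: float = 10.0) -> pd.DataFrame:
    """Per-discourse SCL (µS), mean SCR amplitude and SCR count.

    Phases shorter than ``min_duration_s`` are flagged invalid (NaN
    features): the tonic/phasic split is unreliable on very short segments.
    An event belongs to the phase containing its onset.
    """
    tonic, _ = tonic_phasic_split(signal, fs)
    scrs = detect_scrs(signal, fs, amp_threshold=amp_threshold)
    rows = []
    for m in markers:
        d = discourse_of(m.label)
        if d is None:
            continue
        ok = m.duration >= min_duration_s
        i0, i1 = int(round(m.onset * fs)), int(round((m.onset + m.duration) * fs))
        ev = scrs[(scrs["onset"] >= m.onset) & (scrs["onset"] < m.onset + m.duration)]
        rows.append({
            "discourse": d,
            "scl": float(tonic[i0:i1].mean()) if ok else np.nan,
            "scr_amp_mean": (float(ev["amplitude"].mean()) if len(ev) else 0.0) if ok else np.nan,
            "scr_count": int(len(ev)) if ok else 0,
            "valid": bool(ok),
        })
    return pd.DataFrame(rows).sort_values("discourse").reset_index(drop=True)
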