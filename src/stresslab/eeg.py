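"""EEG processing: filtering, ocular correction, epoching, band power, reactivity.

The chain mirrors a conventional scalp-EEG stress protocol: zero-phase IIR
band-pass (0.1–50 Hz, ~48 dB/octave) with a 50 Hz notch, EOG-based ocular
correction, segmentation into fixed 2000-ms epochs with amplitude/flatline
artifact rejection, Hamming-windowed FFT power spectra at 0.5 Hz resolution,
band averaging over five canonical bands and four two-electrode regions of
interest, and task-related normalization against the eyes-open baseline:

    TR = (P_task - P_baseline) / P_baseline

per (band, ROI, discourse), a dimensionless fractional power change.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps

from .constants import BANDS, EOG_CHANNELS, EPOCH_MS, ROIS, discourse_of

logger = logging.getLogger(__name__)

__all__ = [
    "Marker",
    "EEGRecording",
    "EpochSet",
    "Spectrum",
    "BandPowerTable",
    "preprocess",
    "correct_ocular",
    "epoch_and_reject",
    "periodogram_hamming",
    "phase_psd",
    "band_roi_power",
    "normalize",
    "session_reactivity",
]


@dataclass(frozen=True)
class Marker:
    """One annotated interval: ``label`` starting at ``onset`` s for ``duration`` s."""

    label: str
    onset: float
    duration: float


@dataclass
class EEGRecording:
    """Channel-labeled multichannel signal block (µV) with phase markers."""

    data: np.ndarray          # (n_channels, n_samples)
    ch_names: Sequence[str]
    sfreq: float
    markers: Sequence[Marker] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be (n_channels, n_samples)")
        if self.data.shape[0] != len(self.ch_names):
            raise ValueError(
                f"{self.data.shape[0]} rows but {len(self.ch_names)} channel names"
            )
        dur = self.data.shape[1] / self.sfreq
        for m in self.markers:
            if m.onset < 0 or m.onset + m.duration > dur + 1e-9:
                raise ValueError(f"marker {m.label!r} extends beyond the recording")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def pick(self, names: Iterable[str]) -> np.ndarray:
        idx = [list(self.ch_names).index(n) for n in names]
        return self.data[idx]

    def segment(self, marker: Marker) -> np.ndarray:
        i0 = int(round(marker.onset * self.sfreq))
        i1 = int(round((marker.onset + marker.duration) * self.sfreq))
        return self.data[:, i0:i1]


@dataclass
class EpochSet:
    """Fixed-length epochs per phase with keep/reject bookkeeping."""

    phase: str
    epochs: np.ndarray        # (n_epochs, n_channels, n_samples)
    ch_names: Sequence[str]
    sfreq: float
    keep: np.ndarray          # bool per epoch
    reasons: list[str]        # "" for kept epochs

    @property
    def n_kept(self) -> int:
        return int(self.keep.sum())

    def kept(self) -> np.ndarray:
        return self.epochs[self.keep]


@dataclass
class Spectrum:
    """Per-channel power spectral density (µV²/Hz) on a regular frequency grid."""

    freqs: np.ndarray
    power: np.ndarray         # (n_channels, n_freqs)
    ch_names: Sequence[str]


@dataclass
class BandPowerTable:
    """Mean PSD per (band, channel) and per (band, ROI) for one phase."""

    phase: str
    channel: pd.DataFrame     # index band, columns channel
    roi: pd.DataFrame         # index band, columns ROI


# ---------------------------------------------------------------------------
# filtering


def preprocess(
    rec: EEGRecording,
    l_freq: float = 0.1,
    h_freq: float = 50.0,
    notch: float | None = 50.0,
) -> EEGRecording:
    """Zero-phase band-pass (0.1–50 Hz) plus mains notch on every channel.

    Implemented as a zero-phase cascade: an order-10 Butterworth low-pass
    at the upper edge (steep enough that a tone one-fifth of an octave
    above the edge is attenuated below 5% amplitude) and drift removal at
    the lower edge. A direct IIR high-pass at 0.1 Hz is numerically
    unusable at EEG sampling rates (the normalized cutoff is ~1e-4 and the
    section coefficients degenerate), so the sub-``l_freq`` drift is
    estimated on an anti-aliased decimated copy — where the same filter is
    well conditioned — interpolated back and subtracted.
    """
    if rec.sfreq <= 2 * h_freq:
        raise ValueError(
            f"sampling rate {rec.sfreq} Hz too low for a {h_freq} Hz band edge"
        )
    out = sps.sosfiltfilt(_lp_sos(10, h_freq, rec.sfreq), rec.data, axis=-1)
    out = out - _drift(out, rec.sfreq, l_freq)
    if notch is not None and notch < rec.sfreq / 2:
        b, a = _notch_ba(notch, rec.sfreq)
        out = sps.filtfilt(b, a, out, axis=-1)
    return replace(rec, data=out)


def _drift(data: np.ndarray, fs: float, l_freq: float) -> np.ndarray:
    """Sub-``l_freq`` drift component of each channel (zero-phase)."""
    data = np.atleast_2d(data)
    n = data.shape[-1]
    q = max(int(fs // (40.0 * l_freq)), 1)   # decimated rate ~40x the cutoff
    if q == 1:
        sos = sps.butter(4, l_freq, btype="lowpass", fs=fs, output="sos")
        return sps.sosfiltfilt(sos, data, axis=-1)
    xd = sps.resample_poly(data, up=1, down=q, axis=-1)
    fsd = fs / q
    sos = sps.butter(4, l_freq, btype="lowpass", fs=fsd, output="sos")
    dd = sps.sosfiltfilt(sos, xd, axis=-1,
                         padlen=min(xd.shape[-1] - 1, int(20.0 * fsd / l_freq)))
    t = np.arange(n) / fs
    td = np.arange(xd.shape[-1]) / fsd
    return np.vstack([np.interp(t, td, row) for row in dd])


@lru_cache(maxsize=32)
def _lp_sos(order: int, h_freq: float, fs: float):
    return sps.butter(order, h_freq, btype="lowpass", fs=fs, output="sos")


@lru_cache(maxsize=32)
def _notch_ba(notch: float, fs: float):
    return sps.iirnotch(notch, Q=30.0, fs=fs)


# ---------------------------------------------------------------------------
# ocular correction


def correct_ocular(
    rec: EEGRecording,
    eog_channels: Sequence[str] = EOG_CHANNELS,
    var_tol: float = 1e-12,
) -> EEGRecording:
    """Remove the EOG-predicted component from every scalp channel.

    Least-squares regression of each scalp channel on the (demeaned) EOG
    channels; the fitted contribution is subtracted. Deterministic and
    sufficient for stereotyped blink artifacts; EOG channels themselves are
    passed through unchanged. If the EOG channels are missing or flat the
    recording is returned untouched (with a logged warning in the former
    case: correction cannot run without periocular electrodes).
    """
    names = list(rec.ch_names)
    if not all(c in names for c in eog_channels):
        warnings.warn("EOG channels missing; ocular correction skipped", stacklevel=2)
        return replace(rec, data=rec.data.copy())
    eog_idx = [names.index(c) for c in eog_channels]
    scalp_idx = [i for i in range(len(names)) if i not in eog_idx]
    eog = rec.data[eog_idx]
    eog = eog - eog.mean(axis=1, keepdims=True)
    if float(np.max(eog.var(axis=1), initial=0.0)) < var_tol:
        return replace(rec, data=rec.data.copy())  # flat EOG: identity
    scalp = rec.data[scalp_idx]
    mean = scalp.mean(axis=1, keepdims=True)
    # coefficients (n_scalp, n_eog): solve scalp' ~ eog'
    coef, *_ = np.linalg.lstsq(eog.T, (scalp - mean).T, rcond=None)
    out = rec.data.copy()
    out[scalp_idx] = scalp - coef.T @ eog
    return replace(rec, data=out)


# ---------------------------------------------------------------------------
# epoching and artifact rejection


def epoch_and_reject(
    rec: EEGRecording,
    window_ms: float = EPOCH_MS,
    amp_limit: float = 100.0,
    flat_tol: float = 1e-10,
    exclude: Sequence[str] = EOG_CHANNELS,
) -> dict[str, EpochSet]:
    """Cut each marked phase into consecutive non-overlapping fixed windows.

    An epoch is rejected when any analysis channel exceeds ``amp_limit`` µV
    peak-to-peak, or is flat (peak-to-peak below ``flat_tol``). EOG channels
    are excluded from the criterion: they legitimately carry blinks and are
    not analysis channels. A phase shorter than one window yields zero
    epochs and a warning.
    """
    n_win = int(round(window_ms / 1000.0 * rec.sfreq))
    names = list(rec.ch_names)
    check_idx = [i for i, n in enumerate(names) if n not in exclude]
    out: dict[str, EpochSet] = {}
    for m in rec.markers:
        seg = rec.segment(m)
        n_ep = seg.shape[1] // n_win
        if n_ep == 0:
            warnings.warn(
                f"phase {m.label!r} shorter than one {window_ms:.0f}-ms window",
                stacklevel=2,
            )
        epochs = np.stack(
            [seg[:, i * n_win:(i + 1) * n_win] for i in range(n_ep)]
        ) if n_ep else np.empty((0, seg.shape[0], n_win))
        keep = np.ones(n_ep, dtype=bool)
        reasons = [""] * n_ep
        for i in range(n_ep):
            ptp = np.ptp(epochs[i][check_idx], axis=1)
            if np.any(ptp > amp_limit):
                keep[i] = False
                bad = names[check_idx[int(np.argmax(ptp))]]
                reasons[i] = f"amplitude>{amp_limit:g}uV ({bad})"
            elif np.all(ptp < flat_tol):
                keep[i] = False
                reasons[i] = "flat"
        out[m.label] = EpochSet(m.label, epochs, names, rec.sfreq, keep, reasons)
    return out


# ---------------------------------------------------------------------------
# spectra


def periodogram_hamming(x: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    """One-sided Hamming-tapered periodogram, density scaling (power/Hz).

    Normalized by the taper energy so that, for white noise, the integral of
    the density over frequency is an unbiased estimate of the variance.
    Operates on the last axis.
    """
    freqs, pxx = sps.periodogram(
        x, fs=fs, window="hamming", detrend=False, scaling="density", axis=-1
    )
    return freqs, pxx


def phase_psd(epochset: EpochSet) -> Spectrum:
    """Average Hamming periodogram over the kept epochs of one phase.

    With 2-s epochs the bin width is 0.5 Hz. Raises if no epoch survived
    rejection, naming the phase.
    """
    kept = epochset.kept()
    if kept.shape[0] == 0:
        raise ValueError(f"no artifact-free epochs in phase {epochset.phase!r}")
    freqs, pxx = periodogram_hamming(kept, epochset.sfreq)
    return Spectrum(freqs, pxx.mean(axis=0), list(epochset.ch_names))


# ---------------------------------------------------------------------------
# band and ROI aggregation


def band_roi_power(
    spectrum: Spectrum,
    phase: str = "",
    bands: Mapping[str, tuple[float, float]] = BANDS,
    rois: Mapping[str, Sequence[str]] = ROIS,
) -> BandPowerTable:
    """Average the spectrum into canonical bands, then ROI channel pairs.

    A bin belongs to a band when its center frequency lies inside the band,
    edges inclusive; the narrow gaps between printed band edges belong to no
    band. ROI power is the mean over the ROI's two channels.
    """
    fmax = max(hi for _, hi in bands.values())
    if spectrum.freqs[-1] < fmax:
        raise ValueError(
            f"spectrum reaches {spectrum.freqs[-1]:g} Hz but bands extend to {fmax:g} Hz"
        )
    names = list(spectrum.ch_names)
    band_list = list(bands)
    vals = np.empty((len(band_list), len(names)))
    for i, band in enumerate(band_list):
        lo, hi = bands[band]
        sel = (spectrum.freqs >= lo - 1e-9) & (spectrum.freqs <= hi + 1e-9)
        vals[i] = spectrum.power[:, sel].mean(axis=1)
    chan = pd.DataFrame(vals, index=band_list, columns=names)
    roi_vals = np.empty((len(band_list), len(rois)))
    for j, (roi, chans) in enumerate(rois.items()):
        try:
            idx = [names.index(c) for c in chans]
        except ValueError:
            missing = [c for c in chans if c not in names]
            raise ValueError(f"ROI {roi} channels missing from spectrum: {missing}")
        roi_vals[:, j] = vals[:, idx].mean(axis=1)
    return BandPowerTable(phase, chan,
                          pd.DataFrame(roi_vals, index=band_list, columns=list(rois)))


def normalize(task: BandPowerTable, baseline_open: BandPowerTable) -> pd.DataFrame:
    """Task-related reactivity (P_task − P_baseline) / P_baseline at ROI level.

    Returns a band × ROI frame. Cells with non-positive (or numerically
    negligible) baseline power are set to NaN and logged rather than divided.
    """
    base = baseline_open.roi
    t = task.roi.reindex(index=base.index, columns=base.columns)
    bad = ~(base > np.finfo(float).tiny)
    if bad.to_numpy().any():
        for band, roi in zip(*np.nonzero(bad.to_numpy())):
            logger.warning(
                "baseline power <= 0 for band=%s roi=%s; reactivity undefined",
                base.index[band], base.columns[roi],
            )
    out = (t - base) / base.where(~bad)
    return out


# ---------------------------------------------------------------------------
# per-recording convenience chain


def session_reactivity(
    rec: EEGRecording,
    amp_limit: float = 100.0,
    baseline_label: str = "baseline_open",
) -> pd.DataFrame:
    """Full chain for one recording: filter, EOG-correct, epoch, PSD, normalize.

    Returns a long-format frame (band, roi, discourse, tr_psd) with one row
    per band × ROI × preparation phase, normalized to the eyes-open baseline.
    """
    rec = preprocess(rec)
    rec = correct_ocular(rec)
    epochsets = epoch_and_reject(rec, amp_limit=amp_limit)
    if baseline_label not in epochsets:
        raise ValueError(f"no {baseline_label!r} marker in recording")
    base_tab = band_roi_power(phase_psd(epochsets[baseline_label]), baseline_label)
    rows = []
    for label, es in epochsets.items():
        d = discourse_of(label)
        if d is None:
            continue
        tab = band_roi_power(phase_psd(es), label)
        tr = normalize(tab, base_tab)
        for band in tr.index:
            for roi in tr.columns:
                rows.append(
                    {"band": band, "roi": roi, "discourse": d, "tr_psd": tr.loc[band, roi]}
                )
    return pd.DataFrame(rows).sort_values(["band", "roi", "discourse"]).reset_index(drop=True)
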