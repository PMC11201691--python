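"""Readers and writers for the plain-text signal dialect and event tables.

Signal CSV dialect: one column per channel, header row of labels, first
column ``time`` in seconds. Markers are TSV with columns onset, duration,
label (seconds). Preparation times are CSV with columns participant_id,
group, d1..d5. EDF recordings can be read through mne when it is installed
(``pip install stresslab[edf]``).
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .eeg import EEGRecording, Marker

__all__ = [
    "write_signals_csv", "read_signals_csv",
    "write_markers_tsv", "read_markers_tsv",
    "write_prep_times_csv", "read_prep_times_csv",
    "write_session", "read_session",
    "read_edf",
]


def write_signals_csv(path, data: np.ndarray, ch_names: Sequence[str],
                      sfreq: float) -> None:
    """Write a (n_channels, n_samples) block to the CSV signal dialect."""
    t = np.arange(data.shape[1]) / sfreq
    df = pd.DataFrame(data.T, columns=list(ch_names))
    df.insert(0, "time", t)
    df.to_csv(path, index=False, float_format="%.6f")


def read_signals_csv(path) -> tuple[np.ndarray, list[str], float]:
    """Read the CSV signal dialect; returns (data, ch_names, sfreq)."""
    df = pd.read_csv(path)
    if df.columns[0] != "time":
        raise ValueError(f"{path}: first column must be 'time'")
    t = df["time"].to_numpy()
    if len(t) < 2:
        raise ValueError(f"{path}: need at least two samples")
    sfreq = 1.0 / float(np.median(np.diff(t)))
    ch_names = [c for c in df.columns if c != "time"]
    return df[ch_names].to_numpy().T, ch_names, sfreq


def write_markers_tsv(path, markers: Sequence[Marker]) -> None:
    pd.DataFrame(
        [{"onset": m.onset, "duration": m.duration, "label": m.label} for m in markers]
    ).to_csv(path, sep="\t", index=False)


def read_markers_tsv(path) -> list[Marker]:
    df = pd.read_csv(path, sep="\t")
    return [Marker(str(r.label), float(r.onset), float(r.duration))
            for r in df.itertuples()]


def write_prep_times_csv(path, prep: pd.DataFrame) -> None:
    prep.to_csv(path, index=False, float_format="%.3f")


def read_prep_times_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_session(session, out_dir) -> None:
    """Write one synthetic session: signals CSV (EEG + ECG + EDA) + markers TSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    data = np.vstack([session.eeg.data, session.ecg[None], session.eda[None]])
    names = list(session.eeg.ch_names) + ["ECG", "EDA"]
    write_signals_csv(out / f"{session.participant_id}_signals.csv",
                      data, names, session.sfreq)
    write_markers_tsv(out / f"{session.participant_id}_markers.tsv",
                      session.eeg.markers)


def read_session(signals_path, markers_path) -> tuple[EEGRecording, np.ndarray, np.ndarray]:
    """Read one session back; returns (eeg_recording, ecg, eda)."""
    data, names, sfreq = read_signals_csv(signals_path)
    markers = read_markers_tsv(markers_path)
    aux = {"ECG", "EDA"}
    eeg_idx = [i for i, n in enumerate(names) if n not in aux]
    eeg = EEGRecording(data[eeg_idx], [names[i] for i in eeg_idx], sfreq, markers)
    ecg = data[names.index("ECG")] if "ECG" in names else np.array([])
    eda = data[names.index("EDA")] if "EDA" in names else np.array([])
    return eeg, ecg, eda


def read_edf(path, markers: Sequence[Marker] | None = None) -> EEGRecording:
    """Read an EDF recording into an :class:`EEGRecording` (requires mne).

    Amplitudes are converted to µV for EEG/EOG channels. Annotations are
    used as markers when present and none are passed explicitly.
    """
    try:
        import mne
    except ImportError as exc:  # pragma: no cover
        raise ImportError("reading EDF requires mne (pip install stresslab[edf])") from exc
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data() * 1e6   # V -> µV
    if markers is None:
        markers = [Marker(str(d), float(o), float(du))
                   for o, du, d in zip(raw.annotations.onset,
                                       raw.annotations.duration,
                                       raw.annotations.description)]
    return EEGRecording(data, list(raw.ch_names), float(raw.info["sfreq"]),
                        list(markers))
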