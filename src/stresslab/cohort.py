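"""Seeded synthetic cohorts for the two-group, five-discourse interview design.

Generates, per participant: preparation-phase response times (truncated
normal, capped at the 120-s limit, with a group-level shift), multichannel
EEG (pink 1/f background plus independent band-limited oscillations whose
power is modulated per group/band/ROI/discourse, with optional blink
artifacts on the EOG and frontal channels), ECG (template R-wave train at
Gaussian inter-beat intervals) and electrodermal activity (slow tonic drift
plus sparse phasic responses from a per-segment Poisson process, at a higher
rate and amplitude in the dynamic group).

Every stochastic draw is logged in ``SyntheticSession.ground_truth`` so that
downstream feature extraction can be tested as parameter recovery. A single
cohort seed fans out to per-participant, per-signal streams through
``numpy.random.SeedSequence`` spawning, so identical seeds give bit-identical
cohorts and partial re-runs are reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np
from scipy import stats as sct

from .constants import (
    ANALYSIS_CHANNELS,
    BANDS,
    BASELINE_DURATION_S,
    EOG_CHANNELS,
    GROUP_DYNAMIC,
    GROUP_LABELS,
    GROUP_STATIC,
    MARKER_BASELINE_CLOSED,
    MARKER_BASELINE_OPEN,
    N_DISCOURSES,
    N_PER_GROUP,
    NATIVE_SAMPLING_RATE_HZ,
    PREP_LIMIT_S,
    ROIS,
    SCALP_CHANNELS,
    prep_marker,
)
from .eeg import EEGRecording, Marker

__all__ = [
    "CohortSpec",
    "EffectSpec",
    "SyntheticSession",
    "generate_cohort",
    "iter_cohort",
    "synth_eeg",
    "synth_ecg",
    "synth_eda",
]

# Baseline rms amplitudes (µV) of the band-limited oscillations at gain 1,
# and of the pink background. Chosen to put alpha and the slow bands well
# above the background within their own band, the usual situation in resting
# adult EEG, while gamma stays a small fraction of total power.
BAND_AMPS_UV = {"delta": 4.0, "theta": 3.0, "alpha": 4.0, "beta": 2.0, "gamma": 1.0}
BACKGROUND_AMP_UV = 5.0

# Blink coupling (µV per unit template): strong on the periocular channels,
# attenuated front-to-back on the scalp.
BLINK_WEIGHTS_UV = {
    "EOG1": 150.0, "EOG2": 120.0,
    "Fp1": 45.0, "Fp2": 45.0,
    "F3": 22.0, "F4": 22.0, "F7": 18.0, "F8": 18.0, "Fz": 25.0,
}
BLINK_DEFAULT_UV = 4.0        # residual coupling on all remaining channels

INTER_SEGMENT_GAP_S = 2.0
BASELINE_SCR_RATE_PER_MIN = 1.0
MIN_SCR_SPACING_S = 1.0       # physiological refractory between phasic events

_CH_ROI = {ch: roi for roi, pair in ROIS.items() for ch in pair}


def _as_group_map(value, groups: Sequence[str]) -> dict[str, float]:
    if isinstance(value, Mapping):
        return dict(value)
    return {g: float(value) for g in groups}


@dataclass
class CohortSpec:
    """Cohort-level design parameters.

    The default profile is scaled for desk-size runs (250 Hz, 30-s
    segments); :meth:`native` restores the acquisition-fidelity profile
    (1000 Hz, 120-s baselines and preparation windows), and :meth:`fast`
    is a further-reduced profile for simulation studies that need many
    hundreds of cohorts.
    """

    n_per_group: int = N_PER_GROUP
    group_labels: tuple[str, str] = GROUP_LABELS
    n_discourses: int = N_DISCOURSES
    prep_limit: float = PREP_LIMIT_S
    sampling_rate: float = 250.0
    baseline_duration: float = 30.0
    prep_segment_duration: float = 30.0
    rt_loc: float = 45.0          # location of the truncated-normal RT model (s)
    rt_scale: float = 20.0        # its scale (s); truncation to (0, prep_limit]
    channels: tuple[str, ...] = SCALP_CHANNELS
    seed: int = 0

    @classmethod
    def native(cls, **kw) -> "CohortSpec":
        kw.setdefault("sampling_rate", NATIVE_SAMPLING_RATE_HZ)
        kw.setdefault("baseline_duration", BASELINE_DURATION_S)
        kw.setdefault("prep_segment_duration", PREP_LIMIT_S)
        return cls(**kw)

    @classmethod
    def fast(cls, **kw) -> "CohortSpec":
        kw.setdefault("sampling_rate", 128.0)
        kw.setdefault("baseline_duration", 12.0)
        kw.setdefault("prep_segment_duration", 10.0)
        kw.setdefault("channels", ANALYSIS_CHANNELS)
        return cls(**kw)

    def validate(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        if len(self.group_labels) != 2 or len(set(self.group_labels)) != 2:
            raise ValueError("group_labels must be two distinct condition names")
        for name in ("prep_limit", "sampling_rate", "baseline_duration",
                     "prep_segment_duration", "rt_scale"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_discourses < 1:
            raise ValueError("n_discourses must be >= 1")
        if self.prep_segment_duration < 2.0:
            raise ValueError("prep_segment_duration must allow at least one 2-s epoch")


@dataclass
class EffectSpec:
    """Injected group-level effects.

    ``band_gain`` maps effect keys to multiplicative band-power factors
    applied during preparation phases; keys may be ``(group, band)``,
    ``(group, band, roi)`` or ``(group, band, roi, discourse)``, resolved
    most-specific-first, default 1.0. The defaults encode the reported
    direction of every effect: in the dynamic group the slow bands and
    alpha are suppressed and gamma is elevated, preparation times are
    longer, and phasic electrodermal responses are more frequent and
    larger.
    """

    band_gain: dict = field(default_factory=lambda: {
        (GROUP_DYNAMIC, "delta"): 0.80,
        (GROUP_DYNAMIC, "theta"): 0.75,
        (GROUP_DYNAMIC, "alpha"): 0.60,
        (GROUP_DYNAMIC, "gamma"): 1.50,
    })
    rt_shift: dict = field(default_factory=lambda: {GROUP_DYNAMIC: 10.0, GROUP_STATIC: 0.0})
    scr_rate: dict = field(default_factory=lambda: {GROUP_DYNAMIC: 4.0, GROUP_STATIC: 2.0})
    scr_amp: dict = field(default_factory=lambda: {GROUP_DYNAMIC: 0.5, GROUP_STATIC: 0.3})
    ibi_mean: float = 800.0
    ibi_sd: float = 50.0
    blink_rate: float = 8.0       # blinks per minute

    @classmethod
    def null(cls) -> "EffectSpec":
        """No group differences anywhere; for type-I-error simulations."""
        return cls(band_gain={}, rt_shift={}, scr_rate=_as_group_map(2.0, GROUP_LABELS),
                   scr_amp=_as_group_map(0.3, GROUP_LABELS))

    def validate(self) -> None:
        for key, g in self.band_gain.items():
            if g <= 0:
                raise ValueError(f"band_gain for {key} must be positive")
        for name in ("scr_rate", "scr_amp"):
            for g, v in getattr(self, name).items():
                if v < 0:
                    raise ValueError(f"{name}[{g!r}] must be >= 0")
        if self.ibi_mean <= 0:
            raise ValueError("ibi_mean must be positive")
        if self.ibi_sd < 0:
            raise ValueError("ibi_sd must be >= 0")
        if self.blink_rate < 0:
            raise ValueError("blink_rate must be >= 0")

    def gain(self, group: str, band: str, channel: str, discourse: int) -> float:
        roi = _CH_ROI.get(channel)
        for key in (
            (group, band, roi, discourse),
            (group, band, roi),
            (group, band),
        ):
            if key in self.band_gain:
                return float(self.band_gain[key])
        return 1.0


@dataclass
class SyntheticSession:
    """One participant: signals, markers, response times and injected truth."""

    participant_id: str
    group: str
    eeg: EEGRecording
    ecg: np.ndarray
    eda: np.ndarray
    sfreq: float
    prep_times: np.ndarray     # seconds, one per discourse
    ground_truth: dict

    @property
    def markers(self) -> Sequence[Marker]:
        return self.eeg.markers


# ---------------------------------------------------------------------------
# elementary signal synthesizers


def _shaped_noise(n_ch: int, n: int, shape: np.ndarray,
                  rng: np.random.Generator) -> np.ndarray:
    """Gaussian noise with amplitude spectrum ``shape``, unit rms per row.

    Frequency-domain synthesis: complex white noise multiplied by the target
    amplitude shape and inverse-transformed. Equivalent to filtering white
    noise with a filter of that magnitude response, and much cheaper.
    """
    nz = np.flatnonzero(shape)
    spec = np.zeros((n_ch, shape.size), dtype=complex)
    spec[:, nz] = shape[nz] * (
        rng.standard_normal((n_ch, nz.size)) + 1j * rng.standard_normal((n_ch, nz.size))
    )
    x = np.fft.irfft(spec, n, axis=-1)
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def _pink_shape(n: int, fs: float) -> np.ndarray:
    """1/f amplitude shape (flattened below 0.5 Hz, zero DC)."""
    f = np.fft.rfftfreq(n, 1.0 / fs)
    shape = 1.0 / np.sqrt(np.maximum(f, 0.5))
    shape[0] = 0.0
    return shape


def _band_shape(n: int, fs: float, lo: float, hi: float) -> np.ndarray:
    """Flat in-band amplitude shape (band-limited process)."""
    f = np.fft.rfftfreq(n, 1.0 / fs)
    return ((f >= lo) & (f <= min(hi, fs / 2))).astype(float)


def _blink_template(fs: float) -> np.ndarray:
    """Stereotyped biphasic blink deflection, ~400 ms, unit peak."""
    t = np.arange(0.0, 0.4, 1.0 / fs)
    w = np.exp(-0.5 * ((t - 0.10) / 0.040) ** 2) - 0.3 * np.exp(-0.5 * ((t - 0.25) / 0.060) ** 2)
    return w


def synth_eeg(
    duration: float,
    fs: float,
    band_gains: Mapping[str, float | np.ndarray],
    seed: int | np.random.SeedSequence,
    channels: Sequence[str] = SCALP_CHANNELS,
    background_amp: float = BACKGROUND_AMP_UV,
    band_amps: Mapping[str, float] = BAND_AMPS_UV,
    blink_times: Sequence[float] | None = None,
    blink_weights: Mapping[str, float] | None = None,
) -> tuple[np.ndarray, dict]:
    """Synthesize one EEG block: pink background + gained band oscillations.

    ``band_gains`` maps band name to a multiplicative *power* factor (scalar
    or per-channel array); the oscillation amplitude is scaled by its square
    root so measured band power is proportional to the gain. Returns the
    (n_channels, n_samples) block in µV and a ground-truth dict with the
    injected per-band, per-channel component variances and blink times.
    """
    if duration < 2.0:
        raise ValueError("duration must be >= 2 s (one analysis epoch)")
    rng = np.random.default_rng(seed)
    n = int(round(duration * fs))
    n_ch = len(channels)
    data = np.zeros((n_ch, n))
    comp_power = {band: np.zeros(n_ch) for band in BANDS}
    if background_amp > 0:
        data += background_amp * _shaped_noise(n_ch, n, _pink_shape(n, fs), rng)
    for band, (lo, hi) in BANDS.items():
        gains = np.asarray(band_gains.get(band, 1.0), dtype=float)
        g = np.broadcast_to(gains.ravel() if gains.ndim else gains, (n_ch,))
        amps = band_amps.get(band, 0.0) * np.sqrt(g)
        if np.any(amps > 0):
            data += amps[:, None] * _shaped_noise(n_ch, n, _band_shape(n, fs, lo, hi), rng)
        comp_power[band][:] = amps ** 2
    truth = {"component_power": comp_power, "blink_times": list(blink_times or [])}
    if blink_times:
        tmpl = _blink_template(fs)
        weights = blink_weights or {}
        for t0 in blink_times:
            i0 = int(round(t0 * fs))
            sl = slice(i0, min(i0 + tmpl.size, n))
            seg = tmpl[: sl.stop - sl.start]
            for c, ch in enumerate(channels):
                w = weights.get(ch, BLINK_DEFAULT_UV)
                data[c, sl] += w * seg
    return data, truth


def synth_ecg(
    duration: float,
    fs: float,
    ibi_mean: float,
    ibi_sd: float,
    seed: int | np.random.SeedSequence,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Template ECG (mV): P-QRS-T complexes at Gaussian inter-beat intervals.

    Returns ``(signal, ibi_ms, beat_times_s)`` where ``ibi_ms`` is the true
    inter-beat series actually used. Draws that would be non-positive are
    resampled above a floor of 0.3 × ``ibi_mean`` with a warning.
    """
    if ibi_mean <= 0:
        raise ValueError("ibi_mean must be positive")
    if ibi_sd < 0:
        raise ValueError("ibi_sd must be >= 0")
    rng = np.random.default_rng(seed)
    floor = 0.3 * ibi_mean
    beats = [0.5]
    ibis: list[float] = []
    while True:
        ibi = ibi_mean if ibi_sd == 0 else float(rng.normal(ibi_mean, ibi_sd))
        if ibi < floor:
            warnings.warn("IBI draw below physiological floor; truncated", stacklevel=2)
            ibi = floor
        t_next = beats[-1] + ibi / 1000.0
        if t_next > duration - 0.3:
            break
        beats.append(t_next)
        ibis.append(ibi)
    t = np.arange(int(round(duration * fs))) / fs
    sig = np.zeros_like(t)
    # (amplitude mV, center offset s, width s) for P, Q, R, S, T waves
    waves = [(0.12, -0.18, 0.040), (-0.15, -0.025, 0.010),
             (1.00, 0.0, 0.012), (-0.25, 0.025, 0.010), (0.30, 0.30, 0.070)]
    for tb in beats:
        for amp, off, width in waves:
            lo = np.searchsorted(t, tb + off - 5 * width)
            hi = np.searchsorted(t, tb + off + 5 * width)
            sig[lo:hi] += amp * np.exp(-0.5 * ((t[lo:hi] - tb - off) / width) ** 2)
    return sig, np.asarray(ibis), np.asarray(beats)


def scr_kernel(fs: float, t_rise: float = 0.7, t_decay: float = 3.0,
               length_s: float = 12.0) -> np.ndarray:
    """Bi-exponential phasic kernel, peak-normalized to 1."""
    t = np.arange(0.0, length_s, 1.0 / fs)
    k = np.exp(-t / t_decay) - np.exp(-t / t_rise)
    return k / k.max()


def synth_eda(
    duration: float,
    fs: float,
    scr_rate: float,
    scr_amp: float,
    seed: int | np.random.SeedSequence,
    tonic_level: float = 2.0,
    noise_sd: float = 0.005,
) -> tuple[np.ndarray, list[tuple[float, float]]]:
    """Electrodermal signal (µS): tonic drift + sparse phasic events + noise.

    Event count is Poisson with mean ``scr_rate × duration / 60``; onsets are
    uniform with a 1-s refractory (closer draws are dropped — overlapping
    phasic events are not physiologically separable). Returns the signal and
    the ground-truth ``(onset_s, amplitude_µS)`` list.
    """
    if scr_rate < 0 or scr_amp < 0:
        raise ValueError("scr_rate and scr_amp must be >= 0")
    rng = np.random.default_rng(seed)
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    # slow tonic component: level + gentle sinusoidal wander + linear drift
    sig = (tonic_level
           + 0.2 * np.sin(2 * np.pi * t / (2.0 * max(duration, 60.0)) + rng.uniform(0, 2 * np.pi))
           + 0.1 * (t / 60.0) * rng.uniform(-1, 1))
    events: list[tuple[float, float]] = []
    if scr_rate > 0 and duration > 2.0:
        n_ev = rng.poisson(scr_rate * duration / 60.0)
        onsets = np.sort(rng.uniform(0.0, max(duration - 2.0, 0.1), size=n_ev))
        kern = scr_kernel(fs)
        last = -np.inf
        for t0 in onsets:
            if t0 - last < MIN_SCR_SPACING_S:
                continue
            last = t0
            amp = max(float(rng.normal(scr_amp, 0.15 * scr_amp)), 0.05) if scr_amp > 0 else 0.0
            if amp <= 0:
                continue
            i0 = int(round(t0 * fs))
            sl = slice(i0, min(i0 + kern.size, n))
            sig[sl] += amp * kern[: sl.stop - sl.start]
            events.append((float(t0), amp))
    if noise_sd > 0:
        sig = sig + rng.normal(0.0, noise_sd, size=n)
    return sig, events


# ---------------------------------------------------------------------------
# cohort assembly


def _session_timeline(spec: CohortSpec) -> list[tuple[str, float]]:
    """Ordered (label, duration) segments; '' labels are unmarked gaps."""
    segs = [(MARKER_BASELINE_OPEN, spec.baseline_duration),
            (MARKER_BASELINE_CLOSED, spec.baseline_duration)]
    for d in range(1, spec.n_discourses + 1):
        segs.append(("", INTER_SEGMENT_GAP_S))
        segs.append((prep_marker(d), spec.prep_segment_duration))
    return segs


def _draw_prep_times(spec: CohortSpec, loc: float, rng: np.random.Generator) -> np.ndarray:
    a = (0.0 - loc) / spec.rt_scale
    b = (spec.prep_limit - loc) / spec.rt_scale
    return sct.truncnorm.rvs(a, b, loc=loc, scale=spec.rt_scale,
                             size=spec.n_discourses, random_state=rng)


def expected_prep_time(spec: CohortSpec, group: str, effects: EffectSpec) -> float:
    """Analytic mean of the truncated-normal RT model for one group."""
    loc = spec.rt_loc + float(effects.rt_shift.get(group, 0.0))
    a = (0.0 - loc) / spec.rt_scale
    b = (spec.prep_limit - loc) / spec.rt_scale
    return float(sct.truncnorm.mean(a, b, loc=loc, scale=spec.rt_scale))


def _make_session(
    spec: CohortSpec,
    effects: EffectSpec,
    pid: str,
    group: str,
    ss: np.random.SeedSequence,
) -> SyntheticSession:
    keys = ss.spawn(5)  # rt, eeg, blinks, ecg, eda
    rng_rt = np.random.default_rng(keys[0])
    rng_blk = np.random.default_rng(keys[2])
    channels = tuple(spec.channels) + EOG_CHANNELS
    fs = spec.sampling_rate

    loc = spec.rt_loc + float(effects.rt_shift.get(group, 0.0))
    prep_times = _draw_prep_times(spec, loc, rng_rt)

    segs = _session_timeline(spec)
    total = sum(d for _, d in segs)
    n_blinks = rng_blk.poisson(effects.blink_rate * total / 60.0)
    blink_times = np.sort(rng_blk.uniform(0.0, total - 0.5, size=n_blinks))

    # One stationary process per band for the whole session, amplitude-
    # modulated per segment by the injected gains (cheap, and identical in
    # distribution to per-segment synthesis up to slow modulation edges).
    rng_eeg = np.random.default_rng(keys[1])
    n_total = int(round(total * fs))
    n_ch = len(channels)
    markers = []
    gains_truth = {}
    comp_truth = {}
    bounds = []
    t0 = 0.0
    for label, dur in segs:
        i0, i1 = int(round(t0 * fs)), int(round((t0 + dur) * fs))
        bounds.append((label, i0, min(i1, n_total)))
        if label:
            markers.append(Marker(label, t0, dur))
        t0 += dur
    data = BACKGROUND_AMP_UV * _shaped_noise(n_ch, n_total, _pink_shape(n_total, fs), rng_eeg)
    for band, (lo, hi) in BANDS.items():
        base = BAND_AMPS_UV[band]
        amp = np.full((n_ch, n_total), base)
        for label, i0, i1 in bounds:
            if label.startswith("prep_D"):
                d = int(label[len("prep_D"):])
                g = np.array([effects.gain(group, band, ch, d) for ch in channels])
                amp[:, i0:i1] = base * np.sqrt(g)[:, None]
                gains_truth.setdefault(label, {})[band] = g
                comp_truth.setdefault(label, {})[band] = base ** 2 * g
            elif label:
                comp_truth.setdefault(label, {})[band] = np.full(n_ch, base ** 2)
        data += amp * _shaped_noise(n_ch, n_total, _band_shape(n_total, fs, lo, hi), rng_eeg)
    tmpl = _blink_template(fs)
    weights = np.array([BLINK_WEIGHTS_UV.get(ch, BLINK_DEFAULT_UV) for ch in channels])
    for tb in blink_times:
        i0 = int(round(tb * fs))
        sl = slice(i0, min(i0 + tmpl.size, n_total))
        data[:, sl] += weights[:, None] * tmpl[: sl.stop - sl.start]
    eeg = EEGRecording(data, list(channels), fs, markers)

    ecg, ibis, beat_times = synth_ecg(total, fs, effects.ibi_mean, effects.ibi_sd, keys[3])

    # EDA: one tonic record, per-segment Poisson phasic events
    eda_keys = keys[4].spawn(len(segs) + 1)
    eda, _ = synth_eda(total, fs, 0.0, 0.0, eda_keys[0])
    kern = scr_kernel(fs)
    scr_events: list[tuple[float, float]] = []
    t0 = 0.0
    for (label, dur), k in zip(segs, eda_keys[1:]):
        rate = (effects.scr_rate.get(group, 2.0) if label.startswith("prep_D")
                else BASELINE_SCR_RATE_PER_MIN if label else 0.0)
        if rate > 0:
            rng_e = np.random.default_rng(k)
            n_ev = rng_e.poisson(rate * dur / 60.0)
            onsets = np.sort(rng_e.uniform(0.0, max(dur - 2.0, 0.1), size=n_ev))
            amp_mu = float(effects.scr_amp.get(group, 0.3))
            last = -np.inf
            for rel in onsets:
                if rel - last < MIN_SCR_SPACING_S:
                    continue
                last = rel
                amp = max(float(rng_e.normal(amp_mu, 0.15 * amp_mu)), 0.05)
                i0 = int(round((t0 + rel) * fs))
                sl = slice(i0, min(i0 + kern.size, eda.size))
                eda[sl] += amp * kern[: sl.stop - sl.start]
                scr_events.append((float(t0 + rel), amp))
        t0 += dur

    truth = {
        "prep_times": prep_times.copy(),
        "rt_loc": loc,
        "band_gain": gains_truth,
        "band_component_power": comp_truth,
        "blink_times": blink_times.tolist(),
        "ibi_ms": ibis,
        "beat_times": beat_times,
        "scr_events": scr_events,
    }
    return SyntheticSession(pid, group, eeg, ecg, eda, fs, prep_times, truth)


def iter_cohort(spec: CohortSpec, effects: EffectSpec | None = None) -> Iterator[SyntheticSession]:
    """Lazily generate the cohort one participant at a time (memory-friendly)."""
    effects = effects if effects is not None else EffectSpec()
    spec.validate()
    effects.validate()
    root = np.random.SeedSequence(spec.seed)
    children = root.spawn(2 * spec.n_per_group)
    i = 0
    for group in spec.group_labels:
        for j in range(spec.n_per_group):
            pid = f"{'dyn' if group == spec.group_labels[0] else 'stat'}{j + 1:03d}"
            yield _make_session(spec, effects, pid, group, children[i])
            i += 1


def generate_cohort(spec: CohortSpec, effects: EffectSpec | None = None) -> list[SyntheticSession]:
    """Generate the full cohort (2 × ``n_per_group`` balanced sessions)."""
    return list(iter_cohort(spec, effects))


def cohort_prep_times(spec: CohortSpec, effects: EffectSpec | None = None):
    """Response times only — no signal synthesis. Fast path for behavioral
    simulations; uses the same per-participant seed streams as the full
    generator, so RTs match those of :func:`generate_cohort` for equal specs.
    """
    import pandas as pd

    effects = effects if effects is not None else EffectSpec()
    spec.validate()
    effects.validate()
    root = np.random.SeedSequence(spec.seed)
    children = root.spawn(2 * spec.n_per_group)
    rows = []
    i = 0
    for group in spec.group_labels:
        loc = spec.rt_loc + float(effects.rt_shift.get(group, 0.0))
        for j in range(spec.n_per_group):
            rng = np.random.default_rng(children[i].spawn(5)[0])
            t = _draw_prep_times(spec, loc, rng)
            pid = f"{'dyn' if group == spec.group_labels[0] else 'stat'}{j + 1:03d}"
            rows.append({"participant_id": pid, "group": group,
                         **{f"d{k + 1}": t[k] for k in range(spec.n_discourses)}})
            i += 1
    return pd.DataFrame(rows)
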