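"""Behavioral stress scores from preparation-phase response times.

Two indices are derived from the five preparation response times (RTs,
seconds, capped at 120 s) of the simulated interview:

* **stress regulation** — each discourse's RT is binned 1–5 against fixed
  thresholds calibrated on a pilot normal distribution (faster preparation
  = higher score); the participant score is the mean of the five bins;
* **stress resistance** — the absolute deviation |s| between the mean RT of
  the last two, most acutely stressful discourses (D4, D5) and the overall
  five-discourse mean, binned 1–5 (smaller deviation = higher score).

Both scores are then mapped onto deciles of a reference distribution (a
packaged synthetic pilot sample of 131 RT profiles by default, or the study
sample itself), and the two decile scores are correlated per group.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats as sct

from .constants import N_DISCOURSES, PREP_LIMIT_S

__all__ = [
    "reg_score_bin",
    "res_deviation",
    "res_score_bin",
    "decile_transform",
    "score_prep_times",
    "score_cohort",
    "correlate_scores",
    "pilot_reference",
]

PILOT_N = 131
_PILOT_SEED = 14060608   # fixed; regenerating the packaged fixture reproduces it


def reg_score_bin(t: float) -> int:
    """Regulation bin (1–5) for one preparation RT in seconds.

    Thresholds: ≤20 → 5, (20,40] → 4, (40,60] → 3, (60,80) → 2, ≥80 → 1.
    The extreme rows own their printed boundary (≤20, ≥80); interior
    boundaries resolve to the higher score.
    """
    t = float(t)
    if not (0.0 < t <= PREP_LIMIT_S):
        raise ValueError(f"preparation time {t} s outside (0, {PREP_LIMIT_S:g}]")
    if t <= 20.0:
        return 5
    if t <= 40.0:
        return 4
    if t <= 60.0:
        return 3
    if t < 80.0:
        return 2
    return 1


def res_deviation(t: np.ndarray, d45: str = "mean") -> float:
    """Resistance deviation |s| in seconds for one participant's five RTs.

    ``d45="mean"`` (default): |mean(t4, t5) − mean(t1..t5)| — deviation of
    the acute-stress discourses from overall performance. ``d45="diff"``:
    |t4 − t5|, the alternative reading of the D4–D5 statistic.
    """
    t = np.asarray(t, dtype=float)
    if t.shape != (N_DISCOURSES,):
        raise ValueError(f"expected {N_DISCOURSES} preparation times, got {t.shape}")
    if np.any((t <= 0) | (t > PREP_LIMIT_S)):
        raise ValueError("preparation times must lie in (0, 120] s")
    if d45 == "mean":
        return float(abs(t[3:5].mean() - t.mean()))
    if d45 == "diff":
        return float(abs(t[3] - t[4]))
    raise ValueError(f"unknown d45 reading {d45!r}")


def res_score_bin(dev: float) -> int:
    """Resistance bin (1–5) for a deviation |s| in seconds.

    Thresholds: ≤6 → 5, (6,12] → 4, (12,18] → 3, (18,24) → 2, ≥24 → 1.
    Boundary convention as in :func:`reg_score_bin`.
    """
    dev = float(dev)
    if dev < 0:
        raise ValueError("deviation must be >= 0")
    if dev <= 6.0:
        return 5
    if dev <= 12.0:
        return 4
    if dev <= 18.0:
        return 3
    if dev < 24.0:
        return 2
    return 1


def decile_transform(values, reference=None) -> np.ndarray:
    """Map raw scores onto deciles 1–10 of a reference distribution.

    Decile edges are the 10%,…,90% quantiles of ``reference`` (or of
    ``values`` itself when ``reference`` is None, which requires at least
    10 reference values). The mapping is rank-monotone; tied values share a
    decile; values outside the reference range clamp to 1 / 10.
    """
    values = np.asarray(values, dtype=float)
    ref = values if reference is None else np.asarray(reference, dtype=float)
    if ref.size < 10:
        raise ValueError(
            "need at least 10 reference values for a decile transform; "
            "pass the pilot reference or a larger sample"
        )
    edges = np.quantile(ref, np.arange(1, 10) / 10.0)
    return (1 + np.searchsorted(edges, values, side="left")).astype(int)


def _rt_columns(df: pd.DataFrame) -> list[str]:
    cols = [f"d{i}" for i in range(1, N_DISCOURSES + 1)]
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"prep-times table missing columns {missing}")
    return cols


def score_prep_times(prep: pd.DataFrame, d45: str = "mean") -> pd.DataFrame:
    """Raw scores per participant from a (participant_id, group, d1..d5) table."""
    cols = _rt_columns(prep)
    out = prep[["participant_id", "group"]].copy()
    bins = prep[cols].apply(lambda s: s.map(reg_score_bin))
    for i, c in enumerate(cols, start=1):
        out[f"reg_bin_d{i}"] = bins[c].astype(int)
    out["reg_raw"] = bins.mean(axis=1)
    out["res_dev"] = [res_deviation(r, d45=d45) for r in prep[cols].to_numpy()]
    out["res_bin"] = out["res_dev"].map(res_score_bin).astype(int)
    return out


def pilot_reference() -> pd.DataFrame:
    """The packaged synthetic pilot sample (131 RT profiles) used as the
    default decile calibration reference."""
    with resources.files("stresslab.data").joinpath(
        "pilot_reference_synthetic.csv"
    ).open() as f:
        return pd.read_csv(f)


def make_pilot_reference(n: int = PILOT_N, seed: int = _PILOT_SEED,
                         loc: float = 45.0, scale: float = 20.0) -> pd.DataFrame:
    """Regenerate the synthetic pilot fixture (truncated-normal RT model)."""
    rng = np.random.default_rng(seed)
    a, b = (0.0 - loc) / scale, (PREP_LIMIT_S - loc) / scale
    t = sct.truncnorm.rvs(a, b, loc=loc, scale=scale,
                          size=(n, N_DISCOURSES), random_state=rng)
    df = pd.DataFrame(t.round(3), columns=[f"d{i}" for i in range(1, N_DISCOURSES + 1)])
    df.insert(0, "group", "pilot")
    df.insert(0, "participant_id", [f"pilot{i + 1:03d}" for i in range(n)])
    return df


def score_cohort(prep: pd.DataFrame, reference: str = "pilot",
                 d45: str = "mean") -> pd.DataFrame:
    """Full behavioral table: bins, raw scores and decile scores.

    ``reference="pilot"`` anchors the deciles on the packaged pilot sample;
    ``"self"`` uses the study sample itself (needs ≥ 10 participants).
    """
    scores = score_prep_times(prep, d45=d45)
    if reference == "pilot":
        ref = score_prep_times(pilot_reference(), d45=d45)
        reg_ref, res_ref = ref["reg_raw"].to_numpy(), ref["res_bin"].to_numpy()
    elif reference == "self":
        reg_ref = res_ref = None
    else:
        raise ValueError(f"reference must be 'pilot' or 'self', got {reference!r}")
    scores["reg_decile"] = decile_transform(scores["reg_raw"], reg_ref)
    scores["res_decile"] = decile_transform(scores["res_bin"], res_ref)
    return scores


def correlate_scores(scores: pd.DataFrame, x: str = "reg_decile",
                     y: str = "res_decile", by_group: bool = True) -> pd.DataFrame:
    """Pearson correlation between the two stress scores, per group.

    Returns one record per group (or one overall) with n, r and the
    two-sided p. Zero variance in either score is flagged (``degenerate``
    True, r/p NaN) instead of silently reporting 0.
    """
    frames = scores.groupby("group", sort=True) if by_group else [("all", scores)]
    rows = []
    for g, sub in frames:
        if len(sub) < 3:
            raise ValueError(f"group {g!r} has fewer than 3 participants")
        xv, yv = sub[x].to_numpy(float), sub[y].to_numpy(float)
        if np.std(xv) == 0 or np.std(yv) == 0:
            rows.append({"group": g, "n": len(sub), "r": np.nan, "p": np.nan,
                         "degenerate": True})
            continue
        r, p = sct.pearsonr(xv, yv)
        rows.append({"group": g, "n": len(sub), "r": float(r), "p": float(p),
                     "degenerate": False})
    return pd.DataFrame(rows)
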