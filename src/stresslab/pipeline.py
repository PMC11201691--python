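"""End-to-end orchestration: simulate → score → EEG → autonomic → ANOVA.

A single :class:`RunConfig` (YAML/JSON-serializable, round-trip stable)
drives the whole chain with one seed; re-running the same config reproduces
byte-identical outputs. Sessions are processed one at a time so memory
stays flat in the cohort size.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import yaml

from . import behavioral, autonomic as auto
from .cohort import CohortSpec, EffectSpec, SyntheticSession, iter_cohort
from .constants import BANDS
from .eeg import session_reactivity

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "extract_features", "analyze", "run_all"]

AUTONOMIC_INDICES = ("scr_amp_mean", "scl", "hr", "rmssd")


def _effects_to_dict(e: EffectSpec) -> dict:
    d = dataclasses.asdict(e)
    d["band_gain"] = [
        {"key": list(k), "factor": v} for k, v in e.band_gain.items()
    ]
    return d


def _effects_from_dict(d: dict) -> EffectSpec:
    d = dict(d)
    bg = d.get("band_gain", [])
    if isinstance(bg, list):
        d["band_gain"] = {tuple(item["key"]): float(item["factor"]) for item in bg}
    return EffectSpec(**d)


@dataclass
class RunConfig:
    """Everything one analysis run depends on."""

    cohort: CohortSpec = field(default_factory=CohortSpec)
    effects: EffectSpec = field(default_factory=EffectSpec)
    amp_limit: float = 100.0          # epoch rejection threshold, µV peak-to-peak
    scr_threshold: float = 0.01       # minimum SCR amplitude, µS
    decile_reference: str = "pilot"   # or "self"
    d45: str = "mean"                 # resistance-statistic reading
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        self.cohort.seed = self.seed

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cohort"] = dataclasses.asdict(self.cohort)
        d["cohort"]["group_labels"] = list(self.cohort.group_labels)
        d["cohort"]["channels"] = list(self.cohort.channels)
        d["effects"] = _effects_to_dict(self.effects)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        c = dict(d.get("cohort", {}))
        c["group_labels"] = tuple(c.get("group_labels", ("Dyn-DSST", "Stat-DSST")))
        c["channels"] = tuple(c.get("channels", CohortSpec().channels))
        d["cohort"] = CohortSpec(**c)
        d["effects"] = _effects_from_dict(d.get("effects", {}))
        return cls(**d)

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def extract_features(
    sessions: Iterable[SyntheticSession],
    amp_limit: float = 100.0,
    scr_threshold: float = 0.01,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Per-session feature extraction over a cohort (streaming).

    Returns three long-format frames: preparation times (participant_id,
    group, d1..d5), EEG reactivity (…, band, roi, discourse, tr_psd) and
    autonomic features (…, discourse, hr, rmssd, sdnn, scl, scr_amp_mean,
    scr_count).
    """
    prep_rows, eeg_rows, auto_rows = [], [], []
    for s in sessions:
        ident = {"participant_id": s.participant_id, "group": s.group}
        prep_rows.append({**ident,
                          **{f"d{i+1}": t for i, t in enumerate(s.prep_times)}})
        tr = session_reactivity(s.eeg, amp_limit=amp_limit)
        for r in tr.itertuples():
            eeg_rows.append({**ident, "band": r.band, "roi": r.roi,
                             "discourse": r.discourse, "tr_psd": r.tr_psd})
        ecg = auto.ecg_features(s.ecg, s.markers, s.sfreq)
        eda = auto.eda_features(s.eda, s.markers, s.sfreq,
                                amp_threshold=scr_threshold)
        merged = ecg.merge(eda, on="discourse", suffixes=("_ecg", "_eda"))
        for r in merged.itertuples():
            auto_rows.append({**ident, "discourse": r.discourse, "hr": r.hr,
                              "rmssd": r.rmssd, "sdnn": r.sdnn, "scl": r.scl,
                              "scr_amp_mean": r.scr_amp_mean,
                              "scr_count": r.scr_count})
        logger.info("features extracted for %s", s.participant_id)
    return (pd.DataFrame(prep_rows), pd.DataFrame(eeg_rows),
            pd.DataFrame(auto_rows))


def analyze(
    prep: pd.DataFrame,
    eeg_long: pd.DataFrame,
    auto_long: pd.DataFrame,
    decile_reference: str = "pilot",
    d45: str = "mean",
) -> dict:
    """The inferential layer on extracted feature tables.

    One-way group ANOVAs on the two decile scores, per-group score
    correlations, one 2 × 4 × 5 (group × ROI × discourse) mixed ANOVA per
    band, and one 2 × 5 (group × discourse) mixed ANOVA per autonomic index.
    """
    from .stats import mixed_rm_anova, oneway_anova

    scores = behavioral.score_cohort(prep, reference=decile_reference, d45=d45)
    out: dict = {"scores": scores}
    out["behavioral_anova"] = {
        name: oneway_anova(
            {g: sub[name].to_numpy() for g, sub in scores.groupby("group")}
        )
        for name in ("reg_decile", "res_decile")
    }
    out["correlations"] = behavioral.correlate_scores(scores)
    out["eeg_anova"] = {}
    for band in BANDS:
        sub = eeg_long[eeg_long["band"] == band]
        if sub.empty:
            continue
        out["eeg_anova"][band] = mixed_rm_anova(
            sub, dv="tr_psd", subject="participant_id", between="group",
            within=["roi", "discourse"])
    out["autonomic_anova"] = {}
    for index in AUTONOMIC_INDICES:
        if index not in auto_long.columns or auto_long[index].isna().any():
            logger.warning("autonomic index %s incomplete; ANOVA skipped", index)
            continue
        out["autonomic_anova"][index] = mixed_rm_anova(
            auto_long, dv=index, subject="participant_id", between="group",
            within="discourse")
    return out


def _report(config: RunConfig, results: dict) -> dict:
    is_null = (not config.effects.band_gain
               and not any(config.effects.rt_shift.values())
               and len(set(config.effects.scr_rate.values())) <= 1
               and len(set(config.effects.scr_amp.values())) <= 1)
    rep: dict = {"null_run": bool(is_null), "seed": config.seed, "effects": {}}
    for name, res in results["behavioral_anova"].items():
        rep["effects"][f"behavioral/{name}/group"] = res.to_dict()
    rep["correlations"] = results["correlations"].drop(columns=["degenerate"]) \
        .to_dict(orient="records")
    for band, res in results["eeg_anova"].items():
        for r in res.table.itertuples():
            rep["effects"][f"eeg/{band}/{r.effect}"] = {
                "F": r.F, "df1": r.df1, "df2": r.df2,
                "epsilon": None if np.isnan(r.epsilon) else r.epsilon,
                "df1_gg": r.df1_gg, "df2_gg": r.df2_gg,
                "p": r.p, "p_gg": r.p_gg,
                "eta_sq": r.eta_sq, "eta_p_sq": r.eta_p_sq,
            }
    for index, res in results["autonomic_anova"].items():
        for r in res.table.itertuples():
            rep["effects"][f"autonomic/{index}/{r.effect}"] = {
                "F": r.F, "df1": r.df1, "df2": r.df2,
                "epsilon": None if np.isnan(r.epsilon) else r.epsilon,
                "df1_gg": r.df1_gg, "df2_gg": r.df2_gg,
                "p": r.p, "p_gg": r.p_gg,
                "eta_sq": r.eta_sq, "eta_p_sq": r.eta_p_sq,
            }
    return rep


def run_all(config: RunConfig, out_dir) -> dict:
    """Run the whole pipeline and write the report bundle to ``out_dir``.

    Writes features/, stats/, report.json and the resolved config; returns
    the report dict. Any stage failure propagates with the participant or
    table that caused it named in the exception.
    """
    out = Path(out_dir)
    (out / "features").mkdir(parents=True, exist_ok=True)
    (out / "stats").mkdir(parents=True, exist_ok=True)
    config.save(out / "config_resolved.yaml")

    prep, eeg_long, auto_long = extract_features(
        iter_cohort(config.cohort, config.effects),
        amp_limit=config.amp_limit, scr_threshold=config.scr_threshold)
    prep.to_csv(out / "features" / "prep_times.csv", index=False,
                float_format="%.3f")
    eeg_long.to_csv(out / "features" / "eeg_tr_psd.csv", index=False,
                    float_format="%.6f")
    auto_long.to_csv(out / "features" / "autonomic.csv", index=False,
                     float_format="%.6f")

    results = analyze(prep, eeg_long, auto_long,
                      decile_reference=config.decile_reference, d45=config.d45)
    results["scores"].to_csv(out / "features" / "scores.csv", index=False,
                             float_format="%.4f")
    results["correlations"].to_csv(out / "stats" / "correlations.csv",
                                   index=False, float_format="%.6f")
    for band, res in results["eeg_anova"].items():
        res.table.to_csv(out / "stats" / f"eeg_anova_{band}.csv", index=False,
                         float_format="%.6f")
    for index, res in results["autonomic_anova"].items():
        res.table.to_csv(out / "stats" / f"autonomic_anova_{index}.csv",
                         index=False, float_format="%.6f")

    report = _report(config, results)
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report
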