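"""Inferential layer: one-way and mixed repeated-measures ANOVA.

Covers the designs of the stress-interview analysis: a one-way ANOVA on the
behavioral scores (between factor: group), and mixed repeated-measures
ANOVAs with group as the between-subject factor and one (discourse) or two
(ROI × discourse) within-subject factors, on balanced complete tables.

The sums-of-squares decomposition uses participant-within-group as the
random blocking factor; each within effect (and its interaction with group)
is tested against its own error stratum. Greenhouse–Geisser ε is estimated
per within family from the pooled within-group covariance of orthonormal
contrast scores,

    ε = tr(M Σ Mᵀ)² / (d · tr((M Σ Mᵀ)²)),   d = rank of the effect,

clamped to its analytic bounds [1/d, 1], and applied to every within
effect's degrees of freedom; both the uncorrected and corrected p are
reported, the corrected one being the headline. Effect sizes are classic
η² (SS_effect / SS_total) and partial η² (SS_effect / (SS_effect +
SS_error)). Pairwise simple effects use independent t (between-group
contrasts inside a cell) or paired t (within-subject contrasts), with
Bonferroni adjustment over the family actually tested.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sct
from scipy.linalg import helmert

__all__ = [
    "OneWayResult",
    "MixedAnovaResult",
    "oneway_anova",
    "gg_epsilon",
    "mixed_rm_anova",
    "bonferroni_pairwise",
]


# ---------------------------------------------------------------------------
# one-way ANOVA


@dataclass
class OneWayResult:
    F: float
    df: tuple[int, int]
    p: float
    eta_sq: float
    ss_between: float
    ss_within: float
    group_means: dict[str, float]
    degenerate: bool = False   # zero within-group variance with unequal means

    @property
    def ss_total(self) -> float:
        return self.ss_between + self.ss_within

    def to_dict(self) -> dict:
        return {
            "F": self.F, "df1": self.df[0], "df2": self.df[1], "p": self.p,
            "eta_sq": self.eta_sq, "group_means": self.group_means,
            "degenerate": self.degenerate,
        }


def oneway_anova(groups: Mapping[str, Sequence[float]]) -> OneWayResult:
    """Fixed-effects one-way ANOVA on ``{group label: values}``.

    η² = SS_between / SS_total. With zero within-group variance and unequal
    means, F is reported infinite with p = 0 and the result flagged
    degenerate rather than raising.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = {g: np.asarray(v, dtype=float) for g, v in groups.items()}
    if any(a.size < 2 for a in arrays.values()):
        raise ValueError("each group needs at least 2 observations")
    allv = np.concatenate(list(arrays.values()))
    gm = allv.mean()
    ssb = sum(a.size * (a.mean() - gm) ** 2 for a in arrays.values())
    ssw = sum(((a - a.mean()) ** 2).sum() for a in arrays.values())
    df1, df2 = len(arrays) - 1, allv.size - len(arrays)
    sst = ssb + ssw
    means = {g: float(a.mean()) for g, a in arrays.items()}
    if ssw <= 0:
        if ssb > 0:
            return OneWayResult(np.inf, (df1, df2), 0.0, 1.0, float(ssb), 0.0,
                                means, degenerate=True)
        return OneWayResult(0.0, (df1, df2), 1.0, 0.0, 0.0, 0.0, means,
                            degenerate=True)
    F = (ssb / df1) / (ssw / df2)
    p = float(sct.f.sf(F, df1, df2))
    return OneWayResult(float(F), (df1, df2), p, float(ssb / sst),
                        float(ssb), float(ssw), means)


# ---------------------------------------------------------------------------
# Greenhouse–Geisser epsilon


def gg_epsilon(cov: np.ndarray) -> float:
    """Greenhouse–Geisser ε from a k × k within-level covariance matrix.

    Computed on the double-centered covariance A = C Σ C (C the centering
    projector): ε = tr(A)² / ((k−1) tr(A²)), clamped to [1/(k−1), 1]. A
    singular (numerically zero) double-centered covariance falls back to
    the lower bound with a warning.
    """
    S = np.asarray(cov, dtype=float)
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise ValueError("covariance must be square")
    k = S.shape[0]
    if k < 2:
        raise ValueError("need at least 2 within levels")
    C = np.eye(k) - np.ones((k, k)) / k
    A = C @ S @ C
    denom = (k - 1) * np.trace(A @ A)
    if denom <= np.finfo(float).tiny:
        warnings.warn("singular within-level covariance; ε set to lower bound",
                      stacklevel=2)
        return 1.0 / (k - 1)
    eps = float(np.trace(A) ** 2 / denom)
    return float(np.clip(eps, 1.0 / (k - 1), 1.0))


def _contrast_epsilon(S: np.ndarray, M: np.ndarray) -> float:
    """ε for one within effect from pooled cell covariance S and orthonormal
    contrast rows M (d × k)."""
    d = M.shape[0]
    if d == 0:
        return 1.0
    V = M @ S @ M.T
    denom = d * np.trace(V @ V)
    if denom <= np.finfo(float).tiny:
        warnings.warn("singular contrast covariance; ε set to lower bound",
                      stacklevel=2)
        return 1.0 / d if d > 1 else 1.0
    eps = float(np.trace(V) ** 2 / denom)
    return float(np.clip(eps, 1.0 / d, 1.0))


def _helmert(k: int) -> np.ndarray:
    """(k−1) × k orthonormal contrast rows (orthogonal to the constant)."""
    if k == 1:
        return np.empty((0, 1))
    return helmert(k, full=False)


# ---------------------------------------------------------------------------
# mixed repeated-measures ANOVA


@dataclass
class MixedAnovaResult:
    """Per-effect table of a mixed design with factor metadata."""

    table: pd.DataFrame
    between: str
    within: tuple[str, ...]
    levels: dict[str, list]
    n_per_group: dict[str, int]
    epsilons: dict[str, float] = field(default_factory=dict)

    def effect(self, name: str) -> pd.Series:
        sub = self.table[self.table["effect"] == name]
        if sub.empty:
            raise KeyError(f"no effect {name!r} in table")
        return sub.iloc[0]


def _pivot_balanced(data: pd.DataFrame, dv: str, subject: str, between: str,
                    within: Sequence[str]):
    """Validate balance/completeness and return (Y, groups, subjects, levels).

    Y has shape (n_subjects, k1[, k2]) in sorted level order.
    """
    required = [dv, subject, between, *within]
    missing = [c for c in required if c not in data.columns]
    if missing:
        raise ValueError(f"table missing columns {missing}")
    if data[dv].isna().any():
        raise ValueError(f"missing values in {dv!r}; the design must be complete")
    gmap = data.groupby(subject)[between].nunique()
    if (gmap > 1).any():
        bad = gmap[gmap > 1].index.tolist()
        raise ValueError(f"subjects in more than one group: {bad}")
    counts = data.groupby([subject, *within], sort=True).size()
    if (counts != 1).any():
        bad = counts[counts != 1].index[0]
        raise ValueError(f"cell {bad} not observed exactly once (unbalanced design)")
    levels = {w: sorted(data[w].unique().tolist()) for w in within}
    n_cells_exp = int(np.prod([len(levels[w]) for w in within]))
    per_subj = data.groupby(subject).size()
    if (per_subj != n_cells_exp).any():
        bad = per_subj[per_subj != n_cells_exp].index.tolist()
        raise ValueError(f"subjects with missing within cells: {bad}")
    piv = data.pivot_table(index=subject, columns=list(within), values=dv,
                           sort=True)
    # enforce canonical sorted column order
    if len(within) == 1:
        piv = piv.reindex(columns=levels[within[0]])
        Y = piv.to_numpy()[:, :, None]   # unified (N, k1, k2) with k2=1
        shape = (len(levels[within[0]]), 1)
    else:
        cols = pd.MultiIndex.from_product([levels[within[0]], levels[within[1]]])
        piv = piv.reindex(columns=cols)
        shape = (len(levels[within[0]]), len(levels[within[1]]))
        Y = piv.to_numpy().reshape(len(piv), *shape)
    subjects = piv.index.to_list()
    groups = data.drop_duplicates(subject).set_index(subject)[between].reindex(subjects)
    glevels = sorted(groups.unique().tolist())
    n_per_group = groups.value_counts().to_dict()
    if len(set(n_per_group.values())) > 1:
        raise ValueError(f"unequal group sizes {n_per_group}; design must be balanced")
    return Y, groups.to_numpy(), glevels, subjects, levels, n_per_group


def mixed_rm_anova(
    data: pd.DataFrame,
    dv: str,
    subject: str,
    between: str,
    within: str | Sequence[str],
) -> MixedAnovaResult:
    """Mixed repeated-measures ANOVA: one between factor, 1–2 within factors.

    Requires a balanced complete long-format table (every within cell
    observed exactly once per subject, equal group sizes); anything else
    raises with the offending subject/cell named — no silent imputation.
    """
    within = [within] if isinstance(within, str) else list(within)
    if not 1 <= len(within) <= 2:
        raise ValueError("within must name one or two factors")
    Y, groups, glevels, subjects, levels, n_per_group = _pivot_balanced(
        data, dv, subject, between, within)
    N, b, c = Y.shape
    a = len(glevels)
    n = N // a
    gi = {g: np.flatnonzero(groups == g) for g in glevels}

    GM = Y.mean()
    m_s = Y.mean(axis=(1, 2))                       # per subject
    m_g = np.array([Y[gi[g]].mean() for g in glevels])
    m_b = Y.mean(axis=(0, 2))                       # per level of W1
    m_c = Y.mean(axis=(0, 1))                       # per level of W2
    m_gb = np.stack([Y[gi[g]].mean(axis=(0, 2)) for g in glevels])   # (a, b)
    m_gc = np.stack([Y[gi[g]].mean(axis=(0, 1)) for g in glevels])   # (a, c)
    m_bc = Y.mean(axis=0)                           # (b, c)
    m_gbc = np.stack([Y[gi[g]].mean(axis=0) for g in glevels])       # (a, b, c)
    m_sb = Y.mean(axis=2)                           # (N, b)
    m_sc = Y.mean(axis=1)                           # (N, c)
    g_of = np.array([glevels.index(g) for g in groups])

    ss_total = float(((Y - GM) ** 2).sum())
    ss_subj = b * c * float(((m_s - GM) ** 2).sum())
    ss_A = n * b * c * float(((m_g - GM) ** 2).sum())
    ss_SA = ss_subj - ss_A
    ss_B = N * c * float(((m_b - GM) ** 2).sum())
    ss_AB = n * c * float(((m_gb - m_g[:, None] - m_b[None, :] + GM) ** 2).sum())
    ss_BSA = c * float(((m_sb - m_s[:, None] - m_gb[g_of] + m_g[g_of, None]) ** 2).sum())

    rows = []
    eps: dict[str, float] = {}
    w1 = within[0]

    # pooled within-group covariance of the cell scores, for ε
    X = Y.reshape(N, b * c)
    Xc = X - np.stack([X[gi[g]].mean(axis=0) for g in glevels])[g_of]
    S = (Xc.T @ Xc) / max(N - a, 1)
    Hb = _helmert(b)

    def add(effect, ss, df1, ss_err, df2, err_name, epsilon=None):
        ms = ss / df1 if df1 else np.nan
        ms_e = ss_err / df2 if df2 else np.nan
        F = ms / ms_e if df1 and df2 and ms_e > 0 else (np.inf if ss > 0 else 0.0)
        p = float(sct.f.sf(F, df1, df2)) if np.isfinite(F) else 0.0
        e = 1.0 if epsilon is None else epsilon
        d1c, d2c = df1 * e, df2 * e
        p_gg = float(sct.f.sf(F, d1c, d2c)) if np.isfinite(F) else 0.0
        rows.append({
            "effect": effect, "ss": ss, "df1": df1, "df2": df2, "ms": ms,
            "ms_error": ms_e, "F": float(F), "p": p,
            "epsilon": np.nan if epsilon is None else epsilon,
            "df1_gg": d1c, "df2_gg": d2c, "p_gg": p_gg,
            "eta_sq": ss / ss_total if ss_total > 0 else 0.0,
            "eta_p_sq": ss / (ss + ss_err) if (ss + ss_err) > 0 else 0.0,
            "error_term": err_name,
        })

    add(between, ss_A, a - 1, ss_SA, N - a, "subjects(group)")

    if c == 1:
        eps[w1] = _contrast_epsilon(S, Hb) if b > 1 else 1.0
        df_b, df_e = b - 1, (N - a) * (b - 1)
        add(w1, ss_B, df_b, ss_BSA, df_e, f"{w1}*subjects(group)", eps[w1])
        add(f"{between}*{w1}", ss_AB, (a - 1) * df_b, ss_BSA, df_e,
            f"{w1}*subjects(group)", eps[w1])
    else:
        w2 = within[1]
        Hc = _helmert(c)
        jb = np.full((1, b), 1 / np.sqrt(b))
        jc = np.full((1, c), 1 / np.sqrt(c))
        ss_C = N * b * float(((m_c - GM) ** 2).sum())
        ss_AC = n * b * float(((m_gc - m_g[:, None] - m_c[None, :] + GM) ** 2).sum())
        ss_CSA = b * float(((m_sc - m_s[:, None] - m_gc[g_of] + m_g[g_of, None]) ** 2).sum())
        ss_BC = N * float(((m_bc - m_b[:, None] - m_c[None, :] + GM) ** 2).sum())
        ss_ABC = n * float((
            (m_gbc - m_gb[:, :, None] - m_gc[:, None, :] - m_bc[None]
             + m_g[:, None, None] + m_b[None, :, None] + m_c[None, None, :] - GM) ** 2
        ).sum())
        ss_BCSA = (ss_total - ss_subj - ss_B - ss_AB - ss_BSA
                   - ss_C - ss_AC - ss_CSA - ss_BC - ss_ABC)
        ss_BCSA = max(ss_BCSA, 0.0)

        eps[w1] = _contrast_epsilon(S, np.kron(Hb, jc)) if b > 1 else 1.0
        eps[w2] = _contrast_epsilon(S, np.kron(jb, Hc)) if c > 1 else 1.0
        eps[f"{w1}*{w2}"] = _contrast_epsilon(S, np.kron(Hb, Hc)) if b > 1 and c > 1 else 1.0

        df_b, df_eb = b - 1, (N - a) * (b - 1)
        df_c, df_ec = c - 1, (N - a) * (c - 1)
        df_bc, df_ebc = (b - 1) * (c - 1), (N - a) * (b - 1) * (c - 1)
        add(w1, ss_B, df_b, ss_BSA, df_eb, f"{w1}*subjects(group)", eps[w1])
        add(f"{between}*{w1}", ss_AB, (a - 1) * df_b, ss_BSA, df_eb,
            f"{w1}*subjects(group)", eps[w1])
        add(w2, ss_C, df_c, ss_CSA, df_ec, f"{w2}*subjects(group)", eps[w2])
        add(f"{between}*{w2}", ss_AC, (a - 1) * df_c, ss_CSA, df_ec,
            f"{w2}*subjects(group)", eps[w2])
        add(f"{w1}*{w2}", ss_BC, df_bc, ss_BCSA, df_ebc,
            f"{w1}*{w2}*subjects(group)", eps[f"{w1}*{w2}"])
        add(f"{between}*{w1}*{w2}", ss_ABC, (a - 1) * df_bc, ss_BCSA, df_ebc,
            f"{w1}*{w2}*subjects(group)", eps[f"{w1}*{w2}"])

    return MixedAnovaResult(pd.DataFrame(rows), between, tuple(within),
                            {**levels, between: glevels}, n_per_group, eps)


# ---------------------------------------------------------------------------
# pairwise simple effects


def bonferroni_pairwise(
    data: pd.DataFrame,
    dv: str,
    subject: str,
    contrasts: Sequence[dict],
) -> pd.DataFrame:
    """Pairwise simple-effect comparisons with Bonferroni adjustment.

    Each contrast is a dict: ``{"cell": {factor: level, ...}, "factor": f,
    "levels": (l1, l2), "kind": "between"|"within"}``. ``cell`` fixes the
    remaining factors; ``kind="between"`` compares two independent groups
    inside the cell (independent-samples t), ``kind="within"`` compares two
    within-subject levels (paired t). The family size m is the number of
    contrasts passed; adjusted p = min(1, m·p).
    """
    m = len(contrasts)
    if m == 0:
        raise ValueError("no contrasts given")
    rows = []
    for ctr in contrasts:
        cell, factor = ctr.get("cell", {}), ctr["factor"]
        l1, l2 = ctr["levels"]
        kind = ctr["kind"]
        sub = data
        for col, lev in cell.items():
            sub = sub[sub[col] == lev]
        x1 = sub[sub[factor] == l1]
        x2 = sub[sub[factor] == l2]
        label = ", ".join(f"{k}={v}" for k, v in cell.items())
        name = f"{factor}: {l1} vs {l2}" + (f" | {label}" if label else "")
        if x1.empty or x2.empty:
            raise ValueError(f"empty cell in contrast {name!r}")
        if kind == "between":
            v1 = x1.groupby(subject)[dv].mean().to_numpy()
            v2 = x2.groupby(subject)[dv].mean().to_numpy()
            t, p = sct.ttest_ind(v1, v2)
            diff = float(v1.mean() - v2.mean())
        elif kind == "within":
            piv = pd.concat([
                x1.groupby(subject)[dv].mean().rename("a"),
                x2.groupby(subject)[dv].mean().rename("b"),
            ], axis=1)
            if piv.isna().any().any():
                raise ValueError(f"unpaired subjects in contrast {name!r}")
            d = piv["a"] - piv["b"]
            diff = float(d.mean())
            if np.allclose(d, 0):
                t, p = 0.0, 1.0
            else:
                t, p = sct.ttest_rel(piv["a"], piv["b"])
        else:
            raise ValueError(f"unknown contrast kind {kind!r}")
        rows.append({"contrast": name, "kind": kind, "mean_diff": diff,
                     "t": float(t), "p_raw": float(p),
                     "p_bonf": float(min(1.0, m * float(p)))})
    return pd.DataFrame(rows)
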