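"""Behavioral performance: hit/correct-rejection rates, d-prime, reaction times.

d' is the signal-detection sensitivity z(hit) - z(false alarm).  Reaction
times are normalised to each session's mean before drug x attention ANOVA,
since stimulus geometry (and hence raw RT) varies between sessions.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import norm, ttest_ind

from .attention import factorial_anova


def hit_cr_rates(trials: pd.DataFrame) -> tuple[float, float]:
    """(hit rate, correct-rejection rate) from a behavioral trial table.

    Hit rate = reported target dimmings / target dimmings shown;
    CR rate = unreported distractor dimmings / distractor dimmings shown.
    """
    saw = trials["saw_target"].to_numpy(dtype=bool)
    n_targets = int(saw.sum())
    n_hits = int((trials["outcome"] == "hit").sum())
    n_distractors = int(trials["n_distractor_dims"].sum())
    n_cr = int(trials["n_correct_rejections"].sum())
    if n_targets == 0 or n_distractors == 0:
        raise ValueError("need at least one target and one distractor dimming")
    return n_hits / n_targets, n_cr / n_distractors


def d_prime(hit_rate: float, false_alarm_rate: float,
            n_clip: int | None = None) -> float:
    """z(hit) - z(false alarm).

    Rates of exactly 0 or 1 are clipped by 1/(2N) when ``n_clip`` is given
    (with a warning); otherwise they produce an infinite d'.
    """
    h, f = float(hit_rate), float(false_alarm_rate)
    if n_clip is not None:
        lo, hi = 1.0 / (2 * n_clip), 1.0 - 1.0 / (2 * n_clip)
        if h <= 0 or h >= 1 or f <= 0 or f >= 1:
            warnings.warn("0/1 rate clipped by 1/(2N) before quantile transform")
        h = min(max(h, lo), hi)
        f = min(max(f, lo), hi)
    return float(norm.ppf(h) - norm.ppf(f))


def normalize_rts(trials: pd.DataFrame, rt_col: str = "rt_ms",
                  session_col: str = "session") -> pd.Series:
    """Each RT divided by its session mean (over included trials).

    Rows with missing RT are ignored; sessions with no RT are skipped with
    a warning.  The per-session mean of the output is exactly 1.
    """
    rts = trials[rt_col]
    out = pd.Series(np.nan, index=trials.index, name="rt_norm")
    for sess, grp in trials.groupby(session_col):
        valid = grp[rt_col].notna()
        if not valid.any():
            warnings.warn(f"session {sess!r} has no reaction times; skipped")
            continue
        mean = grp.loc[valid, rt_col].mean()
        out.loc[grp.index[valid]] = grp.loc[valid, rt_col] / mean
    return out


def rt_anova(trials: pd.DataFrame, rt_norm: pd.Series) -> dict:
    """2-factor ANOVA (drug x attention locus) of normalised RTs, with the
    post-hoc two-sided t tests of drug within each attention locus.

    The three cued locations collapse to the locus factor RF vs. away.
    """
    df = trials.copy()
    df["rt_norm"] = rt_norm
    df = df[df["rt_norm"].notna()].copy()
    df["locus"] = np.where(df["attention"] == "RF", "RF", "away")
    f, p = factorial_anova(df["rt_norm"].to_numpy(), df[["drug", "locus"]])
    out = dict(f_values=f, p_values=p)
    for locus, grp in df.groupby("locus"):
        on = grp.loc[grp["drug"] == "on", "rt_norm"]
        off = grp.loc[grp["drug"] == "off", "rt_norm"]
        if len(on) >= 2 and len(off) >= 2:
            t, pv = ttest_ind(on, off)
            out[f"posthoc_{locus}"] = dict(t=float(t), p=float(pv))
    return out


def behavior_summary(trials: pd.DataFrame) -> dict:
    """Hit/CR rates, d', and the normalised-RT drug x attention ANOVA."""
    hit, cr = hit_cr_rates(trials)
    n = int(trials["saw_target"].sum())
    rt_norm = normalize_rts(trials)
    out = dict(
        hit_rate=hit,
        correct_rejection_rate=cr,
        d_prime=d_prime(hit, 1.0 - cr, n_clip=n),
        n_sessions=int(trials["session"].nunique()),
    )
    if trials["drug"].nunique() > 1:
        out["rt_anova"] = rt_anova(trials, rt_norm)
    return out
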