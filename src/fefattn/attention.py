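"""Attentional-modulation statistics: factorial ANOVA screen, AUROC, Cohen's D.

The per-cell screen is a fixed-effects factorial ANOVA of single-trial
predimming rates on attention (3 levels) x direction (2) x drug (2), with
Type-II sums of squares for unbalanced designs.  Attentional modulation is
quantified by the ideal-observer AUROC — the probability that a trial rate
drawn from the attend-RF condition exceeds one drawn from attend-away —
and by Cohen's D.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multitest import multipletests

from . import metrics
from .synth import CellRecording

ALPHA = 0.05


@dataclass
class CellScreen:
    p_values: dict  # effect name -> p
    f_values: dict
    attention_modulated: bool
    drug_modulated: bool


def factorial_anova(
    rates: np.ndarray, factors: pd.DataFrame
) -> tuple[dict, dict]:
    """Fixed-effects factorial ANOVA with all interactions, Type-II SS.

    ``factors`` holds one categorical column per factor.  Factors with a
    single observed level are dropped with a warning.  Returns
    (F by effect, p by effect).
    """
    names = []
    for col in factors.columns:
        if factors[col].nunique() < 2:
            warnings.warn(f"factor {col!r} has a single level; dropped")
        else:
            names.append(col)
    if not names:
        raise ValueError("no factor with >= 2 levels")
    # neutral internal names keep user column names out of the formula
    alias = {col: f"f{i}" for i, col in enumerate(names)}
    df = factors[names].rename(columns=alias).copy()
    df["__y"] = np.asarray(rates, dtype=float)
    rhs = " * ".join(f"C({alias[c]})" for c in names)
    model = smf.ols(f"__y ~ {rhs}", data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    back = {f"C({v})": k for k, v in alias.items()}
    fvals, pvals = {}, {}
    for term in table.index:
        if term == "Residual":
            continue
        clean = ":".join(back[part] for part in term.split(":"))
        fvals[clean] = float(table.loc[term, "F"])
        pvals[clean] = float(table.loc[term, "PR(>F)"])
    return fvals, pvals


def classify_modulation(fvals: dict, pvals: dict, alpha: float = ALPHA) -> CellScreen:
    """Screen flags: a cell is attention (drug) modulated iff the attention
    (drug) main effect or any interaction involving it is significant."""

    def involved(effect: str, factor: str) -> bool:
        return factor in effect.split(":")

    attn = any(
        p < alpha for e, p in pvals.items() if involved(e, "attention")
    )
    drug = any(p < alpha for e, p in pvals.items() if involved(e, "drug"))
    return CellScreen(
        p_values=pvals, f_values=fvals,
        attention_modulated=attn, drug_modulated=drug,
    )


def screen_cell(cell: CellRecording, window_name: str = "dim") -> CellScreen:
    """3-factor screen (attention x direction x drug) on predimming rates."""
    win = metrics.window(window_name)
    rows = [
        dict(
            rate=metrics.epoch_rate(t, win),
            attention=t.attention,
            direction=t.direction,
            drug=t.drug,
        )
        for t in cell.trials
    ]
    df = pd.DataFrame(rows)
    f, p = factorial_anova(df["rate"].to_numpy(), df[["attention", "direction", "drug"]])
    return classify_modulation(f, p)


def auroc(rates_rf: np.ndarray, rates_away: np.ndarray) -> float:
    """Pair-counting AUROC: P(RF sample > away sample), ties counted half.

    Equals the Mann-Whitney U statistic divided by n_RF * n_away.
    """
    a = np.asarray(rates_rf, dtype=float)
    b = np.asarray(rates_away, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    diff = a[:, None] - b[None, :]
    greater = np.count_nonzero(diff > 0)
    ties = np.count_nonzero(diff == 0)
    return float((greater + 0.5 * ties) / (a.size * b.size))


def auroc_folding(value: float) -> float:
    """Sensitivity variant max(AUROC, 1 - AUROC); reported alongside the
    raw value, never replacing it."""
    if not 0.0 <= value <= 1.0:
        raise ValueError("AUROC must be in [0, 1]")
    return max(value, 1.0 - value)


def cohens_d(sample_a: np.ndarray, sample_b: np.ndarray) -> float:
    """(mean_a - mean_b) / pooled SD; NaN when the pooled SD is zero."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs >= 2 values")
    na, nb = a.size, b.size
    pooled = np.sqrt(
        ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    )
    if pooled == 0:
        return float("nan")
    return float((a.mean() - b.mean()) / pooled)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must be in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def attention_result(
    cell: CellRecording,
    window_name: str = "dim",
    pool_away: bool = True,
) -> dict:
    """AUROC and Cohen's D per drug state for one cell.

    With ``pool_away`` both attend-away locations and both motion
    directions are pooled into one away sample (maximises trials).
    """
    win = metrics.window(window_name)
    out: dict = dict(cell_id=cell.cell_id)
    for drug in ("off", "on"):
        rf = metrics.cell_rates(cell, win, attention="RF", drug=drug)
        if pool_away:
            away = np.concatenate(
                [
                    metrics.cell_rates(cell, win, attention=loc, drug=drug)
                    for loc in ("away1", "away2")
                ]
            )
        else:
            away = metrics.cell_rates(cell, win, attention="away1", drug=drug)
        key = "nodrug" if drug == "off" else "drug"
        if rf.size == 0 or away.size == 0:
            out[f"auroc_{key}"] = float("nan")
            out[f"cohens_d_{key}"] = float("nan")
            continue
        out[f"auroc_{key}"] = auroc(rf, away)
        out[f"cohens_d_{key}"] = (
            cohens_d(rf, away) if rf.size >= 2 and away.size >= 2 else float("nan")
        )
        out[f"n_rf_{key}"] = int(rf.size)
        out[f"n_away_{key}"] = int(away.size)
    return out
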