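"""Normalised modulation indices for drug and attention effects.

All indices share the form (a - b) / (a + b), bounded in [-1, 1] for
nonnegative inputs.  Sign conventions: the drug MI is
(no drug - drug), so a drug that raises activity gives negative values;
the attention gain-variance MI is (away - RF), so attention-induced
variability reduction gives positive values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import gainvar, metrics
from .synth import CellRecording


@dataclass
class ModulationIndex:
    value: float
    numerator_kind: str  # rate | gain_variance
    epoch: str | None = None
    valid: bool = True


def _mi(a: float, b: float) -> tuple[float, bool]:
    if a < 0 or b < 0:
        raise ValueError("inputs must be >= 0")
    if a == 0 and b == 0:
        return float("nan"), False
    return (a - b) / (a + b), True


def drug_mi(activity_nodrug: float, activity_drug: float,
            epoch: str | None = None) -> ModulationIndex:
    """(rate_nodrug - rate_drug) / (rate_nodrug + rate_drug)."""
    v, ok = _mi(activity_nodrug, activity_drug)
    return ModulationIndex(v, "rate", epoch, ok)


def drug_gain_mi(gv_nodrug: float, gv_drug: float,
                 epoch: str | None = None) -> ModulationIndex:
    """(gv_nodrug - gv_drug) / (gv_nodrug + gv_drug)."""
    v, ok = _mi(gv_nodrug, gv_drug)
    return ModulationIndex(v, "gain_variance", epoch, ok)


def attention_gain_mi(gv_attend_away: float, gv_attend_rf: float,
                      epoch: str | None = None) -> ModulationIndex:
    """(gv_away - gv_RF) / (gv_away + gv_RF); positive when attention
    stabilises firing."""
    v, ok = _mi(gv_attend_away, gv_attend_rf)
    return ModulationIndex(v, "gain_variance", epoch, ok)


def cell_drug_mi(
    cell: CellRecording,
    window_name: str = "dim",
    order: str = "mean_of_mis",
) -> ModulationIndex:
    """Headline per-cell drug MI in one epoch.

    Default order: an MI of condition-mean rates per stimulus condition
    (attention x direction), then averaged across conditions
    (mean-of-MIs).  ``order='mi_of_means'`` instead averages rates across
    conditions first and takes a single MI.
    """
    win = metrics.window(window_name)
    conds = [(a, d) for a in ("RF", "away1", "away2") for d in ("d1", "d2")]
    pairs = []
    for attention, direction in conds:
        off = metrics.cell_rates(cell, win, attention=attention,
                                 direction=direction, drug="off")
        on = metrics.cell_rates(cell, win, attention=attention,
                                direction=direction, drug="on")
        if off.size and on.size:
            pairs.append((float(off.mean()), float(on.mean())))
    if not pairs:
        return ModulationIndex(float("nan"), "rate", window_name, False)
    if order == "mi_of_means":
        a = float(np.mean([p[0] for p in pairs]))
        b = float(np.mean([p[1] for p in pairs]))
        v, ok = _mi(a, b)
        return ModulationIndex(v, "rate", window_name, ok)
    vals = [drug_mi(a, b).value for a, b in pairs if not (a == 0 and b == 0)]
    if not vals:
        return ModulationIndex(float("nan"), "rate", window_name, False)
    return ModulationIndex(float(np.nanmean(vals)), "rate", window_name, True)


def cell_gain_mis(cell: CellRecording, window_name: str = "dim") -> dict:
    """Drug-gain MI and attention-gain MIs (per drug state) for one cell."""
    rf_off, away_off = gainvar.gain_variance_by_attention(
        cell, window_name, drug_state="off"
    )
    rf_on, away_on = gainvar.gain_variance_by_attention(
        cell, window_name, drug_state="on"
    )
    gv_off = np.nanmean([rf_off, away_off])
    gv_on = np.nanmean([rf_on, away_on])
    return dict(
        cell_id=cell.cell_id,
        drug_gain_mi=drug_gain_mi(gv_off, gv_on).value
        if np.isfinite(gv_off) and np.isfinite(gv_on)
        else float("nan"),
        attention_gain_mi_nodrug=attention_gain_mi(away_off, rf_off).value
        if np.isfinite(away_off) and np.isfinite(rf_off)
        else float("nan"),
        attention_gain_mi_drug=attention_gain_mi(away_on, rf_on).value
        if np.isfinite(away_on) and np.isfinite(rf_on)
        else float("nan"),
        gv_rf_nodrug=rf_off,
        gv_away_nodrug=away_off,
        gv_rf_drug=rf_on,
        gv_away_drug=away_on,
    )
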