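"""Negative-binomial (gamma-gain Poisson) fits of single-trial spike counts.

The count model is N ~ NB with mean lambda and variance
lambda + sigma^2_G * lambda^2, parameterised directly by the gain variance
sigma^2_G = 1/r (r the conventional NB size).  sigma^2_G captures
trial-to-trial excitability fluctuations over and above Poisson noise.
Fitting is by profile likelihood: lambda-hat is the sample mean (the MLE in
this parameterisation), and sigma^2_G is optimised on a log grid refined by
bounded scalar minimisation, with the Poisson boundary sigma^2_G = 0
compared explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import gammaln

from . import metrics
from .synth import CellRecording

MIN_TRIALS = 5


@dataclass
class GainFit:
    mean_count: float
    gain_var: float
    loglik: float
    converged: bool
    n_trials: int

    @property
    def fitted_variance(self) -> float:
        return self.mean_count + self.gain_var * self.mean_count**2


def nb_loglik(counts: np.ndarray, lam: float, gain_var: float) -> float:
    """Log-likelihood of counts under NB(mean lam, var lam + gv*lam^2).

    gain_var = 0 is the Poisson limit.
    """
    k = np.asarray(counts, dtype=float)
    if gain_var <= 0:
        return float(np.sum(k * np.log(lam) - lam - gammaln(k + 1)))
    r = 1.0 / gain_var
    return float(
        np.sum(
            gammaln(k + r)
            - gammaln(r)
            - gammaln(k + 1)
            + r * np.log(r / (r + lam))
            + k * np.log(lam / (r + lam))
        )
    )


def fit_negative_binomial(counts) -> GainFit:
    """Maximum-likelihood gain-variance fit of per-trial spike counts.

    Initialised from the method of moments
    sigma^2_hat = max(0, (v - m) / m^2); under-dispersed data return the
    Poisson boundary sigma^2_G = 0 with converged=True.
    """
    counts = np.asarray(counts)
    if counts.size < MIN_TRIALS:
        raise ValueError(f"need >= {MIN_TRIALS} trials")
    if np.any(counts < 0) or not np.allclose(counts, np.round(counts)):
        raise ValueError("counts must be nonnegative integers")
    counts = np.round(counts).astype(int)
    n = counts.size
    m = counts.mean()
    if m == 0:
        return GainFit(0.0, float("nan"), float("nan"), False, n)
    v = counts.var(ddof=1)
    ll0 = nb_loglik(counts, m, 0.0)
    mom = (v - m) / m**2
    if mom <= 0:
        return GainFit(float(m), 0.0, ll0, True, n)
    # profile likelihood in log(gain_var) around the moment estimate
    lo, hi = np.log(mom) - 6.0, np.log(mom) + 6.0
    res = minimize_scalar(
        lambda lg: -nb_loglik(counts, m, np.exp(lg)),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-8},
    )
    gv, ll = float(np.exp(res.x)), float(-res.fun)
    if ll0 >= ll:  # boundary wins
        return GainFit(float(m), 0.0, ll0, True, n)
    return GainFit(float(m), gv, ll, bool(res.success), n)


def gain_variance_by_attention(
    cell: CellRecording,
    window_name: str = "dim",
    drug_state: str = "off",
    min_trials: int = MIN_TRIALS,
) -> tuple[float, float]:
    """(gv_attendRF, gv_attendAway) for one drug state.

    The two attend-RF conditions (RF x 2 directions) give the attend-RF
    estimate and the four attend-away conditions (2 locations x 2
    directions) the attend-away estimate; per-condition gain variances are
    arithmetically averaged within each side.  A side with no fittable
    condition returns NaN.
    """
    win = metrics.window(window_name)
    sides = {
        "rf": [("RF", d) for d in ("d1", "d2")],
        "away": [(a, d) for a in ("away1", "away2") for d in ("d1", "d2")],
    }
    out = {}
    for side, conds in sides.items():
        gvs = []
        for attention, direction in conds:
            counts = np.array(
                [
                    metrics.epoch_spike_count(t, win)
                    for t in cell.trials
                    if t.attention == attention
                    and t.direction == direction
                    and t.drug == drug_state
                ]
            )
            if counts.size < min_trials or counts.sum() == 0:
                continue
            fit = fit_negative_binomial(counts)
            if fit.converged:
                gvs.append(fit.gain_var)
        out[side] = float(np.mean(gvs)) if gvs else float("nan")
    return out["rf"], out["away"]
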