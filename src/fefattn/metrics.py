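"""Per-cell waveform and spike-train statistics.

Waveform width (trough-to-peak time, P2T) classifies cells as narrow
(P2T <= 250 us) or broad; interspike-interval statistics (CV, CV2, Lv)
quantify firing regularity; epoch rates and Fano factors summarise the
three canonical task windows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline

from .synth import CellRecording, TrialRecord

NARROW_P2T_US = 250.0

#: canonical analysis windows: (anchor, start_ms, end_ms)
EPOCH_WINDOWS = {
    "stim": ("stimulus_onset", 100.0, 400.0),
    "cue": ("cue_onset", 100.0, 400.0),
    "dim": ("first_dimming", -500.0, 0.0),
}


@dataclass(frozen=True)
class EpochWindow:
    anchor: str  # stimulus_onset | cue_onset | first_dimming
    start_ms: float
    end_ms: float

    def __post_init__(self) -> None:
        if self.start_ms >= self.end_ms:
            raise ValueError("start_ms must be < end_ms")

    def anchor_time(self, trial: TrialRecord) -> float:
        if self.anchor == "stimulus_onset":
            return trial.stim_on_ms
        if self.anchor == "cue_onset":
            return trial.cue_on_ms
        if self.anchor == "first_dimming":
            return trial.dim1_ms
        raise ValueError(f"unknown anchor {self.anchor!r}")


def window(name: str) -> EpochWindow:
    anchor, start, end = EPOCH_WINDOWS[name]
    return EpochWindow(anchor, start, end)


def peak_to_trough(waveform: np.ndarray, sampling_khz: float) -> float:
    """Trough-to-peak time in microseconds, on a x10 interpolated waveform.

    The waveform is cubic-spline upsampled tenfold; P2T is the time from the
    global trough to the largest subsequent maximum.  Raises ValueError for
    waveforms with no trough-then-peak shape.
    """
    wf = np.asarray(waveform, dtype=float)
    if wf.size < 4:
        raise ValueError("waveform too short")
    dt_us = 1000.0 / sampling_khz
    x = np.arange(wf.size)
    fine = np.linspace(0, wf.size - 1, (wf.size - 1) * 10 + 1)
    y = CubicSpline(x, wf)(fine)
    i_trough = int(np.argmin(y))
    if i_trough >= y.size - 1:
        raise ValueError("no peak after trough (monotone waveform)")
    after = y[i_trough:]
    i_peak = i_trough + int(np.argmax(after))
    if i_peak == i_trough or y[i_peak] <= y[i_trough]:
        raise ValueError("no peak after trough (monotone waveform)")
    return (fine[i_peak] - fine[i_trough]) * dt_us


def classify_cell_width(p2t_us: float) -> str:
    """'narrow' iff P2T <= 250 us, else 'broad'."""
    if p2t_us <= 0:
        raise ValueError("p2t_us must be > 0")
    return "narrow" if p2t_us <= NARROW_P2T_US else "broad"


def epoch_spike_count(trial: TrialRecord, win: EpochWindow) -> int:
    t0 = win.anchor_time(trial)
    lo, hi = t0 + win.start_ms, t0 + win.end_ms
    s = trial.spikes_ms
    return int(np.count_nonzero((s >= lo) & (s < hi)))


def epoch_rate(trial: TrialRecord, win: EpochWindow) -> float:
    """Spike count in the half-open window [start, end), in spikes/s."""
    n = epoch_spike_count(trial, win)
    return n / ((win.end_ms - win.start_ms) / 1000.0)


def trial_isis(trials: list[TrialRecord]) -> list[np.ndarray]:
    """Within-trial ISIs; never computed across trial boundaries."""
    return [np.diff(t.spikes_ms) for t in trials if t.spikes_ms.size >= 2]


def isi_stats(isis_per_trial: list[np.ndarray]) -> tuple[float, float, float]:
    """(CV, CV2, Lv) from per-trial ISI sequences.

    CV is computed on the pooled ISIs.  CV2 and Lv use adjacent ISI pairs
    within a trial only:

        CV2 = mean_i 2|I_{i+1} - I_i| / (I_{i+1} + I_i)
        Lv  = 3/(n-1) * sum_i ((I_i - I_{i+1}) / (I_i + I_{i+1}))^2

    with n the number of ISIs in a trial; trial-wise sums and pair counts
    are pooled across trials.  Returns NaNs when fewer than 3 ISIs exist.
    """
    pooled = (
        np.concatenate(isis_per_trial) if isis_per_trial else np.empty(0)
    )
    if pooled.size < 3:
        return (float("nan"),) * 3
    cv = float(np.std(pooled, ddof=1) / np.mean(pooled))
    cv2_terms = []
    lv_terms = []
    for isi in isis_per_trial:
        if isi.size < 2:
            continue
        a, b = isi[:-1], isi[1:]
        denom = a + b
        ratio = np.divide(a - b, denom, out=np.zeros_like(denom, dtype=float),
                          where=denom > 0)
        cv2_terms.append(2.0 * np.abs(ratio))
        lv_terms.append(ratio**2)
    if not lv_terms:
        return cv, float("nan"), float("nan")
    cv2_all = np.concatenate(cv2_terms)
    lv_all = np.concatenate(lv_terms)
    cv2 = float(np.mean(cv2_all))
    lv = float(3.0 * np.mean(lv_all))
    return cv, cv2, lv


def fano_factor(counts: np.ndarray) -> float:
    """variance/mean of trial spike counts; NaN when the mean is zero."""
    counts = np.asarray(counts, dtype=float)
    if counts.size < 2:
        raise ValueError("need >= 2 trials")
    m = counts.mean()
    if m == 0:
        return float("nan")
    return float(counts.var(ddof=1) / m)


def cell_rates(
    cell: CellRecording,
    win: EpochWindow,
    attention: str | None = None,
    direction: str | None = None,
    drug: str | None = None,
) -> np.ndarray:
    """Per-trial rates in a window, optionally filtered by condition."""
    out = []
    for t in cell.trials:
        if attention is not None and t.attention != attention:
            continue
        if direction is not None and t.direction != direction:
            continue
        if drug is not None and t.drug != drug:
            continue
        out.append(epoch_rate(t, win))
    return np.asarray(out)


def cell_metrics(
    cell: CellRecording,
    ff_window: str = "dim",
    ff_attention: str = "RF",
) -> dict:
    """Clustering features of one cell.

    ISIs are pooled across all no-drug trials (the features describe the
    cell's intrinsic physiology, not the manipulation).  FR and FF come
    from the predimming window: FR over all no-drug trials, FF from the
    attend-RF no-drug condition.
    """
    p2t = peak_to_trough(cell.waveform, cell.sampling_khz)
    nodrug = [t for t in cell.trials if t.drug == "off"]
    cv, cv2, lv = isi_stats(trial_isis(nodrug))
    win = window(ff_window)
    rates = np.array([epoch_rate(t, win) for t in nodrug])
    fr = float(rates.mean()) if rates.size else float("nan")
    ff_counts = np.array(
        [epoch_spike_count(t, win) for t in nodrug if t.attention == ff_attention]
    )
    ff = fano_factor(ff_counts) if ff_counts.size >= 2 else float("nan")
    return dict(
        cell_id=cell.cell_id,
        p2t_us=p2t,
        cell_class=classify_cell_width(p2t),
        cv=cv,
        cv2=cv2,
        lv=lv,
        fr=fr,
        ff=ff,
    )
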