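"""Synthetic FEF recordings with known ground truth.

Generates populations of simulated cells performing a three-stimulus covert
attention task (attend-RF vs. two attend-away locations, two motion
directions, drug iontophoresis on/off: six stimulus conditions per drug
state).  Spiking is a gamma-renewal process whose rate is scaled by a
per-trial multiplicative gain drawn from a Gamma distribution with mean 1
and variance sigma^2_G, so spike counts follow the gamma-gain (negative
binomial) count law the analysis fits, while interspike-interval regularity
is controlled independently by the renewal shape kappa.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

ATTENTION_LEVELS = ("RF", "away1", "away2")
DIRECTIONS = ("d1", "d2")
DRUG_STATES = ("off", "on")


@dataclass(frozen=True)
class CellArchetype:
    """Generative parameters of one simulated cell class.

    Rates are multiplicative: the condition mean is
    ``base_rate_hz * attention_gain^[attend RF] * drug_gain^[drug on]``,
    with the attention gain applied only after cue onset.  ``gain_var`` is
    the variance sigma^2_G of the per-trial excitability gain;
    ``*_scale`` fields scale it per condition.  ``isi_shape`` is the gamma
    renewal shape kappa (1 = Poisson-like, >1 more regular).
    """

    name: str
    p2t_mean_us: float
    p2t_sd_us: float
    base_rate_hz: float
    attention_gain: float = 1.0
    drug_gain: float = 1.0
    attention_gain_drug_scale: float = 1.0
    gain_var: float = 0.0
    gain_var_attend_scale: float = 1.0
    gain_var_drug_scale: float = 1.0
    isi_shape: float = 1.0

    def __post_init__(self) -> None:
        if self.base_rate_hz <= 0:
            raise ValueError("base_rate_hz must be > 0")
        if self.gain_var < 0:
            raise ValueError("gain_var must be >= 0")
        if self.isi_shape <= 0:
            raise ValueError("isi_shape must be > 0")
        if self.p2t_sd_us < 0:
            raise ValueError("p2t_sd_us must be >= 0")

    def condition_rate(self, attention: str, drug: str) -> float:
        """Post-cue mean rate (Hz) for one condition, gain = 1."""
        attn = self.attention_gain if attention == "RF" else 1.0
        if drug == "on":
            attn = 1.0 + (attn - 1.0) * self.attention_gain_drug_scale
            return self.base_rate_hz * self.drug_gain * attn
        return self.base_rate_hz * attn

    def condition_gain_var(self, attention: str, drug: str) -> float:
        gv = self.gain_var
        if attention == "RF":
            gv *= self.gain_var_attend_scale
        if drug == "on":
            gv *= self.gain_var_drug_scale
        return gv


@dataclass(frozen=True)
class TaskDesign:
    """Event schedule and trial counts of the dimming task.

    Stimulus onset is time 0; the cue appears at a uniform latency in
    ``cue_onset_range_ms`` and the first dimming follows the cue by a
    uniform delay in ``dim_delay_range_ms``, so the three canonical
    analysis windows (stim +100..+400, cue +100..+400, dim -500..0)
    exist on every trial.
    """

    n_trials_per_condition: int
    stim_onset_ms: float = 0.0
    cue_onset_range_ms: tuple[float, float] = (300.0, 1400.0)
    dim_delay_range_ms: tuple[float, float] = (1500.0, 2000.0)
    drug_states: tuple[str, ...] = DRUG_STATES

    def __post_init__(self) -> None:
        if self.n_trials_per_condition < 1:
            raise ValueError("n_trials_per_condition must be >= 1")
        lo, hi = self.cue_onset_range_ms
        if not (lo < hi and lo >= 300.0 and hi <= 1400.0):
            raise ValueError("cue onset range must lie within [300, 1400] ms")
        if self.dim_delay_range_ms[0] < 1500.0:
            raise ValueError("first dimming must be >= 1500 ms after cue")

    @property
    def conditions(self) -> list[tuple[str, str, str]]:
        """All (attention, direction, drug) cells; 6 per drug state."""
        return list(
            itertools.product(ATTENTION_LEVELS, DIRECTIONS, self.drug_states)
        )


@dataclass
class TrialRecord:
    trial_id: int
    attention: str
    direction: str
    drug: str
    drug_name: str
    stim_on_ms: float
    cue_on_ms: float
    dim1_ms: float
    spikes_ms: np.ndarray
    outcome: str = "hit"
    rt_ms: float = float("nan")


@dataclass
class CellRecording:
    cell_id: str
    drug_name: str
    trials: list[TrialRecord]
    waveform: np.ndarray
    sampling_khz: float
    archetype: str | None = None


def simulate_waveform(
    archetype: CellArchetype,
    sampling_khz: float = 40.0,
    seed: int | np.random.Generator = 0,
    max_retries: int = 20,
) -> tuple[np.ndarray, float]:
    """Biphasic trough-then-peak waveform with a drawn trough-to-peak time.

    The target P2T is drawn from N(p2t_mean_us, p2t_sd_us); non-positive
    draws are retried a bounded number of times.  Lobes are Gaussians a
    quarter P2T wide, so the extrema sit at their centres to well under one
    interpolated sample.
    """
    rng = np.random.default_rng(seed)
    p2t_us = float("nan")
    for _ in range(max_retries):
        p2t_us = float(rng.normal(archetype.p2t_mean_us, archetype.p2t_sd_us))
        if p2t_us > 50.0:
            break
    else:
        raise ValueError(
            f"could not draw a positive P2T for archetype {archetype.name!r}"
        )
    if sampling_khz < 30:
        raise ValueError("sampling_khz must be >= 30")
    dt_us = 1000.0 / sampling_khz
    lead_us, tail_us = 500.0, 500.0
    n = int(np.ceil((lead_us + p2t_us + tail_us) / dt_us)) + 1
    t = np.arange(n) * dt_us
    sig = p2t_us / 4.0
    trough_t = lead_us
    peak_t = lead_us + p2t_us
    wf = -np.exp(-0.5 * ((t - trough_t) / sig) ** 2)
    wf += 0.45 * np.exp(-0.5 * ((t - peak_t) / sig) ** 2)
    return wf, sampling_khz


def _renewal_spikes(
    rng: np.random.Generator,
    kappa: float,
    rate1_hz: float,
    rate2_hz: float,
    cue_ms: float,
    end_ms: float,
) -> np.ndarray:
    """Gamma-renewal spikes on [0, end_ms) with a rate step at cue_ms.

    Generated by time rescaling: unit-mean gamma intervals (shape kappa)
    accumulate in operational time, then map through the inverse of the
    piecewise-linear cumulative intensity.
    """
    lam1 = rate1_hz * cue_ms / 1000.0
    lam_total = lam1 + rate2_hz * (end_ms - cue_ms) / 1000.0
    if lam_total <= 0:
        return np.empty(0)
    # draw in blocks until the cumulative operational time passes lam_total
    taus: list[np.ndarray] = []
    total = 0.0
    block = max(16, int(lam_total + 4 * np.sqrt(lam_total) + 10))
    while total <= lam_total:
        draw = rng.gamma(kappa, 1.0 / kappa, size=block)
        taus.append(draw)
        total += draw.sum()
    tau = np.cumsum(np.concatenate(taus))
    tau = tau[tau < lam_total]
    t = np.where(
        tau < lam1,
        tau / max(rate1_hz, 1e-300) * 1000.0,
        cue_ms + (tau - lam1) / max(rate2_hz, 1e-300) * 1000.0,
    )
    return t


def simulate_cell(
    archetype: CellArchetype,
    design: TaskDesign,
    seed: int | np.random.Generator = 0,
    drug_name: str = "ACh",
    cell_id: str = "cell0",
    sampling_khz: float = 40.0,
) -> CellRecording:
    """Simulate all trials of one cell under the full factorial design.

    Per trial a gain G ~ Gamma(mean 1, var sigma^2_G(condition)) multiplies
    the condition rate; before cue onset the attention gain does not apply.
    """
    rng = np.random.default_rng(seed)
    waveform, khz = simulate_waveform(archetype, sampling_khz, rng)
    trials: list[TrialRecord] = []
    trial_id = 0
    for attention, direction, drug in design.conditions:
        gv = archetype.condition_gain_var(attention, drug)
        post_rate = archetype.condition_rate(attention, drug)
        pre_rate = archetype.condition_rate("away1", drug)  # no attention gain pre-cue
        for _ in range(design.n_trials_per_condition):
            cue = rng.uniform(*design.cue_onset_range_ms)
            dim = cue + rng.uniform(*design.dim_delay_range_ms)
            g = 1.0 if gv == 0 else rng.gamma(1.0 / gv, gv)
            spikes = _renewal_spikes(
                rng, archetype.isi_shape, g * pre_rate, g * post_rate, cue, dim
            )
            trials.append(
                TrialRecord(
                    trial_id=trial_id,
                    attention=attention,
                    direction=direction,
                    drug=drug,
                    drug_name=drug_name,
                    stim_on_ms=design.stim_onset_ms,
                    cue_on_ms=cue,
                    dim1_ms=dim,
                    spikes_ms=spikes,
                )
            )
            trial_id += 1
    return CellRecording(
        cell_id=cell_id,
        drug_name=drug_name,
        trials=trials,
        waveform=waveform,
        sampling_khz=khz,
        archetype=archetype.name,
    )


def simulate_population(
    archetypes: list[CellArchetype],
    cells_per_archetype: list[int] | int,
    design: TaskDesign,
    seed: int = 0,
    drug_name: str = "ACh",
) -> tuple[list[CellRecording], list[str]]:
    """Independent cells drawn per archetype, with ground-truth labels."""
    if not archetypes:
        raise ValueError("need at least one archetype")
    if isinstance(cells_per_archetype, int):
        cells_per_archetype = [cells_per_archetype] * len(archetypes)
    if len(cells_per_archetype) != len(archetypes):
        raise ValueError("cells_per_archetype must match archetypes")
    if sum(cells_per_archetype) == 0:
        raise ValueError("population is empty")
    ss = np.random.SeedSequence(seed)
    cells: list[CellRecording] = []
    labels: list[str] = []
    idx = 0
    for arch, n_cells in zip(archetypes, cells_per_archetype):
        for child in ss.spawn(n_cells):
            cells.append(
                simulate_cell(
                    arch,
                    design,
                    seed=np.random.default_rng(child),
                    drug_name=drug_name,
                    cell_id=f"c{idx:04d}",
                )
            )
            labels.append(arch.name)
            idx += 1
    return cells, labels


def simulate_counts(
    n_trials: int,
    mean_count: float,
    gain_var: float,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Trial spike counts from the gamma-gain Poisson (negative binomial) law.

    Count-level shortcut for calibration studies: counts are Poisson with a
    per-trial Gamma(mean 1, var gain_var) rate multiplier, so
    Var[N] = mean_count + gain_var * mean_count^2.
    """
    rng = np.random.default_rng(seed)
    if gain_var == 0:
        return rng.poisson(mean_count, size=n_trials)
    g = rng.gamma(1.0 / gain_var, gain_var, size=n_trials)
    return rng.poisson(g * mean_count)


def simulate_behavior(
    design: TaskDesign,
    hit_p: float,
    false_alarm_p: float,
    rt_mean_ms: float = 400.0,
    rt_sd_ms: float = 60.0,
    seed: int = 0,
    n_trials: int | None = None,
    session_id: str = "s000",
    drug_name: str = "ACh",
    rt_effects: dict[tuple[str, str], float] | None = None,
) -> pd.DataFrame:
    """Behavioral session: outcomes and reaction times per trial.

    The cued stimulus dims first, second or third with equal probability;
    distractor dimmings preceding the target each elicit a false alarm with
    probability ``false_alarm_p``, otherwise they are correctly rejected.
    On reaching the target dimming the animal responds (hit) with
    probability ``hit_p``.  ``rt_effects`` maps (attention, drug) to an RT
    multiplier, for building sessions with planted drug x attention effects.
    """
    if not (0 <= hit_p <= 1 and 0 <= false_alarm_p <= 1):
        raise ValueError("probabilities must be in [0, 1]")
    rng = np.random.default_rng(seed)
    if n_trials is None:
        n_trials = design.n_trials_per_condition * 6 * len(design.drug_states)
    rows = []
    for i in range(n_trials):
        attention = ATTENTION_LEVELS[i % 3]
        drug = design.drug_states[(i // 3) % len(design.drug_states)]
        target_pos = rng.integers(1, 4)  # dims first, second or third
        n_distractors = int(target_pos - 1)
        fa = rng.random(n_distractors) < false_alarm_p if n_distractors else np.array([])
        rt = float("nan")
        if fa.any():
            outcome = "false_alarm"
            n_cr = int(np.argmax(fa))  # distractors correctly rejected before the FA
            saw_target = False
        else:
            n_cr = n_distractors
            saw_target = True
            outcome = "hit" if rng.random() < hit_p else "miss"
        if outcome in ("hit", "false_alarm"):
            mult = 1.0
            if rt_effects:
                mult = rt_effects.get((attention, drug), 1.0)
            rt = max(100.0, rng.normal(rt_mean_ms * mult, rt_sd_ms))
        rows.append(
            dict(
                session=session_id,
                trial_id=i,
                attention=attention,
                drug=drug,
                drug_name=drug_name,
                target_dim_pos=int(target_pos),
                saw_target=saw_target,
                n_distractor_dims=n_distractors if saw_target else int(np.argmax(fa)) + 1,
                n_correct_rejections=n_cr,
                outcome=outcome,
                rt_ms=rt,
            )
        )
    return pd.DataFrame(rows)


def default_design(n_trials_per_condition: int = 20, **kw) -> TaskDesign:
    return TaskDesign(n_trials_per_condition=n_trials_per_condition, **kw)
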