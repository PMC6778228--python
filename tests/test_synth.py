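"""Generator checks: seeded determinism, count law, renewal regularity."""

import numpy as np
import pytest

from fefattn import (
    CellArchetype,
    TaskDesign,
    simulate_behavior,
    simulate_cell,
    simulate_counts,
    simulate_population,
    simulate_waveform,
)
from fefattn.metrics import (
    classify_cell_width,
    epoch_spike_count,
    isi_stats,
    peak_to_trough,
    trial_isis,
    window,
)
from fefattn.synth import _renewal_spikes


def _arch(**kw):
    base = dict(name="a", p2t_mean_us=400.0, p2t_sd_us=0.0, base_rate_hz=20.0)
    base.update(kw)
    return CellArchetype(**base)


class TestWaveform:
    def test_deterministic_template_hits_target_p2t(self):
        wf, khz = simulate_waveform(_arch(p2t_mean_us=400.0), 40.0, seed=0)
        measured = peak_to_trough(wf, khz)
        assert abs(measured - 400.0) <= 2.5  # one interpolated sample

    def test_narrow_template_classified_narrow(self):
        wf, khz = simulate_waveform(_arch(p2t_mean_us=200.0), 40.0, seed=0)
        assert classify_cell_width(peak_to_trough(wf, khz)) == "narrow"

    def test_same_seed_identical(self):
        a, _ = simulate_waveform(_arch(p2t_sd_us=30.0), 40.0, seed=42)
        b, _ = simulate_waveform(_arch(p2t_sd_us=30.0), 40.0, seed=42)
        np.testing.assert_array_equal(a, b)

    def test_low_sampling_rate_rejected(self):
        with pytest.raises(ValueError):
            simulate_waveform(_arch(), 20.0, seed=0)


class TestSimulateCell:
    def test_trial_structure(self, null_cell):
        assert len(null_cell.trials) == 25 * 12
        for t in null_cell.trials[:20]:
            assert 300.0 <= t.cue_on_ms <= 1400.0
            assert t.dim1_ms - t.cue_on_ms >= 1500.0

    def test_null_cell_fano_near_one(self, null_cell):
        win = window("dim")
        counts = np.array(
            [epoch_spike_count(t, win) for t in null_cell.trials]
        )
        ff = counts.var(ddof=1) / counts.mean()
        assert abs(ff - 1.0) < 0.2

    def test_invalid_trial_count_rejected(self):
        with pytest.raises(ValueError):
            TaskDesign(n_trials_per_condition=0)

    @pytest.mark.parametrize("gain_var", [0.0, 0.1, 0.25])
    def test_count_variance_follows_gamma_poisson_law(self, gain_var):
        """Var[N] = mu*T + sigma^2_G (mu*T)^2 for the spike-level generator."""
        arch = _arch(base_rate_hz=40.0, gain_var=gain_var)
        design = TaskDesign(n_trials_per_condition=300, drug_states=("off",))
        cell = simulate_cell(arch, design, seed=3)
        win = window("dim")
        counts = np.array(
            [epoch_spike_count(t, win) for t in cell.trials
             if t.attention != "RF"]
        )
        mu = counts.mean()
        expected = mu + gain_var * mu**2
        observed = counts.var(ddof=1)
        # sampling error of a variance estimate: sd ~ sqrt(2/n)*var
        tol = 4.0 * np.sqrt(2.0 / counts.size) * expected + 2.0
        assert abs(observed - expected) < tol


class TestRenewalRegularity:
    @pytest.mark.parametrize("kappa", [0.5, 1.0, 2.0, 4.0])
    def test_lv_matches_gamma_renewal_expectation(self, kappa):
        """E[Lv] = 3/(2 kappa + 1) for a gamma renewal process."""
        rng = np.random.default_rng(17)
        lvs = []
        for _ in range(20):
            spikes = _renewal_spikes(rng, kappa, 100.0, 100.0, 3000.0, 6000.0)
            _, _, lv = isi_stats([np.diff(spikes)])
            lvs.append(lv)
        lvs = np.asarray(lvs)
        se = lvs.std(ddof=1) / np.sqrt(lvs.size)
        assert abs(lvs.mean() - 3.0 / (2.0 * kappa + 1.0)) < 3.0 * se

    def test_poisson_train_cv_cv2_lv_near_one(self):
        rng = np.random.default_rng(23)
        spikes = _renewal_spikes(rng, 1.0, 200.0, 200.0, 30000.0, 60000.0)
        cv, cv2, lv = isi_stats([np.diff(spikes)])
        n = spikes.size - 1
        assert abs(cv - 1.0) < 3.0 / np.sqrt(n)
        assert abs(cv2 - 1.0) < 4.0 / np.sqrt(n)
        assert abs(lv - 1.0) < 4.0 / np.sqrt(n)


class TestPopulation:
    def test_same_seed_reproduces_spike_times_exactly(self):
        archs = [_arch(name="x", gain_var=0.1), _arch(name="y", isi_shape=2.0)]
        design = TaskDesign(n_trials_per_condition=3)
        a, la = simulate_population(archs, 2, design, seed=9)
        b, lb = simulate_population(archs, 2, design, seed=9)
        assert la == lb
        for ca, cb in zip(a, b):
            for ta, tb in zip(ca.trials, cb.trials):
                np.testing.assert_array_equal(ta.spikes_ms, tb.spikes_ms)

    def test_empty_population_rejected(self):
        design = TaskDesign(n_trials_per_condition=2)
        with pytest.raises(ValueError):
            simulate_population([], 5, design, seed=0)
        with pytest.raises(ValueError):
            simulate_population([_arch()], 0, design, seed=0)


class TestSimulateCounts:
    def test_poisson_limit(self):
        c = simulate_counts(5000, 20.0, 0.0, seed=1)
        assert abs(c.var(ddof=1) / c.mean() - 1.0) < 0.1

    def test_overdispersion(self):
        c = simulate_counts(5000, 20.0, 0.25, seed=1)
        m = c.mean()
        assert abs(c.var(ddof=1) - (m + 0.25 * m**2)) < 15.0


class TestBehaviorGenerator:
    def test_perfect_performance(self):
        design = TaskDesign(n_trials_per_condition=10)
        df = simulate_behavior(design, 1.0, 0.0, seed=0, n_trials=300)
        assert (df.loc[df["saw_target"], "outcome"] == "hit").all()
        assert df["n_correct_rejections"].sum() == df["n_distractor_dims"].sum()

    def test_probability_validation(self):
        design = TaskDesign(n_trials_per_condition=10)
        with pytest.raises(ValueError):
            simulate_behavior(design, 1.2, 0.0, seed=0)
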