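"""Synthetic gait generator: forward consistency, reproducibility, EMG."""

import numpy as np
import pytest

from coordsim.emg import activation_ratio
from coordsim.pipeline import envelopes_on_grid, process_emg
from coordsim.synth import (
    TrialConfig,
    generate_emg,
    generate_trial,
    make_cohort,
    retention_config,
)


class TestTrialGeneration:
    def test_seed_reproducibility(self, model):
        t1, tr1 = generate_trial(model, seed=11)
        t2, tr2 = generate_trial(model, seed=11)
        assert np.array_equal(tr1.activations_true, tr2.activations_true)
        for dof in model.dofs:
            assert np.array_equal(t1.m_id[dof], t2.m_id[dof])

    def test_truth_in_bounds(self, trial_truth):
        _, truth = trial_truth
        a = truth.activations_true
        assert np.all(a >= 0.0) and np.all(a <= 1.0)

    def test_stance_is_contiguous_prefix(self, trial_truth):
        trial, _ = trial_truth
        st = trial.stance_mask
        first_false = int(np.argmin(st))
        assert np.all(st[:first_false]) and not np.any(st[first_false:])

    def test_moments_achievable_without_reserves(self, natural_solution):
        """Forward consistency: the generated moments admit a solution with
        reserve torques at numerical zero."""
        assert np.abs(natural_solution.reserve_torques).max() < 1e-6

    def test_phasing_matches_normative_dominance(self, model, trial_truth):
        """Hamstrings dominate early stance, quadriceps early-mid stance,
        gastrocnemius late stance in the ground truth."""
        trial, truth = trial_truth
        names = truth.muscle_names
        st = np.flatnonzero(trial.stance_mask)
        pct = 100.0 * np.arange(len(st)) / (len(st) - 1)

        def group_mean(members, lo, hi):
            win = st[(pct >= lo) & (pct < hi)]
            idx = [names.index(m) for m in members]
            return truth.activations_true[np.ix_(win, idx)].sum(axis=1).mean()

        ham = ("bflh", "bfsh", "semiten", "semimem")
        quad = ("vasmed", "vaslat", "recfem")
        gas = ("gasmed", "gaslat")
        assert group_mean(ham, 0, 10) > group_mean(gas, 0, 10)
        assert group_mean(quad, 10, 40) > group_mean(gas, 10, 40)
        assert group_mean(gas, 40, 90) > group_mean(quad, 40, 90)
        assert group_mean(gas, 40, 90) > group_mean(ham, 40, 90)

    def test_overdriven_bumps_rejected(self, model):
        cfg = TrialConfig(
            amplitude_jitter={name: 4.0 for name in ("soleus", "gasmed")}
        )
        with pytest.raises(ValueError):
            generate_trial(model, cfg, seed=0)


class TestEMGGeneration:
    def test_envelope_recovers_modulator(self, model, trial_truth, emg_bundle):
        """Processed envelope of generated EMG correlates > 0.95 with the
        ground-truth activation for strongly modulated channels."""
        trial, truth = trial_truth
        raw, mvc, fs = emg_bundle
        delayed = process_emg(raw, mvc, fs)
        grid = envelopes_on_grid(delayed.channels, fs, trial, 1.1)
        names = truth.muscle_names
        for ch in ("gasmed", "soleus", "vasmed"):
            a = truth.activations_true[:, names.index(ch)]
            r = np.corrcoef(grid[ch], a)[0, 1]
            assert r > 0.95

    def test_ratio_recovered_within_tolerance(self, model, trial_truth,
                                              emg_bundle):
        """Activation ratio computed from generated EMG matches the truth
        ratio within 0.03."""
        trial, truth = trial_truth
        raw, mvc, fs = emg_bundle
        delayed = process_emg(raw, mvc, fs)
        grid = envelopes_on_grid(delayed.channels, fs, trial, 1.1)
        names = truth.muscle_names
        r_emg = activation_ratio(grid["gasmed"], grid["soleus"],
                                 trial.stance_mask)
        r_true = activation_ratio(
            truth.activations_true[:, names.index("gasmed")],
            truth.activations_true[:, names.index("soleus")],
            trial.stance_mask,
        )
        assert abs(r_emg - r_true) < 0.03

    def test_zero_activation_channel_at_noise_floor(self, trial_truth):
        """A channel with a silenced modulator carries only sensor noise."""
        import dataclasses

        _, truth = trial_truth
        mods = dict(truth.emg_modulators)
        mods["tibant"] = np.zeros_like(mods["tibant"])
        silenced = dataclasses.replace(truth, emg_modulators=mods)
        raw, _ = generate_emg(silenced, fs=2000.0)
        assert np.std(raw["tibant"]) < 0.1 * np.std(raw["soleus"])
        assert np.std(raw["tibant"]) == pytest.approx(0.008, rel=0.2)

    def test_same_seed_same_noise(self, trial_truth):
        _, truth = trial_truth
        raw1, mvc1 = generate_emg(truth, fs=2000.0)
        raw2, mvc2 = generate_emg(truth, fs=2000.0)
        assert np.array_equal(raw1["gasmed"], raw2["gasmed"])
        assert np.array_equal(mvc1["soleus"], mvc2["soleus"])

    def test_low_rate_rejected(self, trial_truth):
        _, truth = trial_truth
        with pytest.raises(ValueError):
            generate_emg(truth, fs=500.0)


class TestCohort:
    def test_single_subject(self, model):
        pairs = make_cohort(model, 1, seed=2)
        assert len(pairs) == 1

    def test_regeneration_identical(self, model):
        p1 = make_cohort(model, 2, seed=9)
        p2 = make_cohort(model, 2, seed=9)
        for a, b in zip(p1, p2):
            assert np.array_equal(
                a.baseline[1].activations_true, b.baseline[1].activations_true
            )
            assert a.config_baseline.bodyweight == b.config_baseline.bodyweight

    def test_retention_truth_ratio_reduced_exactly(self, model):
        """The retention preset reduces the ground-truth activation ratio
        by exactly the configured fraction (25% by default)."""
        pair = make_cohort(model, 1, seed=4)[0]
        names = pair.baseline[1].muscle_names
        i_g = names.index("gasmed")
        i_s = names.index("soleus")

        def truth_ratio(bundle):
            trial, truth = bundle
            return activation_ratio(
                truth.activations_true[:, i_g],
                truth.activations_true[:, i_s],
                trial.stance_mask,
            )

        r_base = truth_ratio(pair.baseline)
        r_ret = truth_ratio(pair.retention)
        assert r_ret / r_base == pytest.approx(0.75, rel=1e-9)

    def test_invalid_count(self, model):
        with pytest.raises(ValueError):
            make_cohort(model, 0, seed=1)

    def test_retention_config_defaults(self):
        cfg = retention_config()
        assert cfg.gastroc_scale == pytest.approx(0.6)
        assert cfg.ratio_reduction == pytest.approx(0.25)
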