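import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from odorwords import rates, screening, synthetic
from odorwords.screening import benjamini_hochberg, screen_units
from odorwords.screening import test_odor_association as odor_association_test
from odorwords.screening import test_stimulus_responsiveness as responsiveness_test

from helpers import make_null_tensor


def modulated_counts(
    n_trials, baseline_hz, gain, window, odor_mask=None, odor_gain=1.0, seed=0
):
    """Window counts for one unit with a rate bump in one post window."""
    rng = np.random.default_rng(seed)
    ws = rates.WindowSet()
    lam = np.full((1, n_trials, ws.n_windows), float(baseline_hz))
    lam[0, :, window] *= gain
    if odor_mask is not None:
        lam[0, odor_mask, window] *= odor_gain
    return synthetic.poisson_window_counts(lam, ws.durations_s, rng)


class TestStimulusResponsiveness:
    def test_identical_post_and_baseline_not_flagged(self):
        values = np.tile(np.arange(10.0)[:, None], (1, 5))
        res = responsiveness_test(values)
        assert not res.flagged
        assert np.all(res.p == 1.0)  # zero-variance differences guard

    def test_strong_gain_flagged_with_correct_window(self, first_presentation_trials):
        """Gain 3 in [0.5, 1.0) at 4 Hz baseline: flagged, increase, window 2."""
        counts = modulated_counts(200, 4.0, 3.0, window=2, seed=21)
        tensor = rates.tensor_from_counts(
            counts, ["amygdala"], first_presentation_trials
        )
        tensor = rates.zscore_rates(tensor)
        res = responsiveness_test(tensor.z[0])
        assert res.flagged
        assert res.best_window == 1  # post-window index of [0.5, 1.0)
        assert res.direction == "increase"

    def test_decrease_direction(self, first_presentation_trials):
        counts = modulated_counts(200, 6.0, 0.2, window=1, seed=22)
        tensor = rates.zscore_rates(
            rates.tensor_from_counts(counts, ["amygdala"], first_presentation_trials)
        )
        res = responsiveness_test(tensor.z[0])
        assert res.flagged and res.direction == "decrease"

    def test_null_familywise_rate(self, first_presentation_trials):
        """With no modulation, <= ~5% of units are flagged family-wise."""
        tensor = rates.zscore_rates(
            make_null_tensor(1000, first_presentation_trials, seed=100)
        )
        results = screen_units(tensor, "stimulus")
        n_flagged = int(results["flagged"].sum())
        # 97.5th percentile of Binomial(1000, 0.05)
        assert n_flagged <= 64

    def test_raw_and_z_flags_identical(self, first_presentation_trials):
        """The paired contrast is invariant to the per-unit affine z-transform."""
        rng = np.random.default_rng(42)
        ws = rates.WindowSet()
        lam = np.full((50, 200, 5), 4.0)
        lam[:25, :, 2] *= rng.uniform(1.2, 2.0, size=(25, 1))
        counts = synthetic.poisson_window_counts(lam, ws.durations_s, rng)
        tensor = rates.zscore_rates(
            rates.tensor_from_counts(counts, ["amygdala"] * 50, first_presentation_trials)
        )
        flags_z = screen_units(tensor, "stimulus", use_z=True)["flagged"]
        flags_raw = screen_units(tensor, "stimulus", use_z=False)["flagged"]
        keep = [
            str(u) not in tensor.zscore_excluded for u in tensor.unit_ids
        ]
        np.testing.assert_array_equal(flags_z.to_numpy(), flags_raw.to_numpy()[keep])

    def test_too_few_trials_rejected(self):
        with pytest.raises(ValueError):
            responsiveness_test(np.ones((1, 5)))


class TestOdorAssociation:
    def test_injected_odor_gain_flagged(self, first_presentation_trials):
        odor = first_presentation_trials["is_odor"].to_numpy(dtype=bool)
        counts = modulated_counts(
            200, 4.0, 1.0, window=2, odor_mask=odor, odor_gain=2.0, seed=30
        )
        tensor = rates.zscore_rates(
            rates.tensor_from_counts(counts, ["amygdala"], first_presentation_trials)
        )
        res = odor_association_test(tensor.z[0][:, 1:], odor)
        assert res.flagged
        assert res.direction == "increase"
        assert res.best_window == 1

    def test_label_swap_flips_t_keeps_p(self, first_presentation_trials):
        odor = first_presentation_trials["is_odor"].to_numpy(dtype=bool)
        counts = modulated_counts(
            200, 4.0, 1.0, window=1, odor_mask=odor, odor_gain=1.5, seed=31
        )
        tensor = rates.zscore_rates(
            rates.tensor_from_counts(counts, ["amygdala"], first_presentation_trials)
        )
        a = odor_association_test(tensor.z[0][:, 1:], odor)
        b = odor_association_test(tensor.z[0][:, 1:], ~odor)
        np.testing.assert_allclose(a.t, -b.t)
        np.testing.assert_allclose(a.p, b.p)

    def test_permutation_null_calibrated(self, first_presentation_trials):
        """Random condition labels on a null unit flag at most ~5% of repeats."""
        rng = np.random.default_rng(8)
        ws = rates.WindowSet()
        counts = synthetic.poisson_window_counts(
            np.full((1000, 200, 5), 4.0), ws.durations_s, rng
        )
        tensor = rates.zscore_rates(
            rates.tensor_from_counts(
                counts, ["amygdala"] * 1000, first_presentation_trials
            )
        )
        flags = 0
        for i in range(1000):
            labels = np.zeros(200, dtype=bool)
            labels[rng.choice(200, 100, replace=False)] = True
            if str(tensor.unit_ids[i]) in tensor.zscore_excluded:
                continue
            flags += odor_association_test(tensor.z[i][:, 1:], labels).flagged
        assert flags <= 64

    def test_identical_condition_values_guarded(self):
        post = np.ones((10, 4))
        labels = np.arange(10) < 5
        res = odor_association_test(post, labels)
        assert np.all(res.p == 1.0) and not res.flagged

    def test_single_trial_condition_rejected(self):
        post = np.random.default_rng(0).normal(size=(5, 4))
        with pytest.raises(ValueError):
            odor_association_test(post, np.array([True, False, False, False, False]))


class TestBenjaminiHochberg:
    def test_step_up_example(self):
        """Thresholds k/m*q = 0.0125/0.025/0.0375/0.05 reject all four."""
        flags = benjamini_hochberg([0.01, 0.02, 0.03, 0.04], q=0.05)
        assert flags.all()

    def test_none_rejected(self):
        assert not benjamini_hochberg([0.9, 0.9, 0.9, 0.9]).any()

    def test_empty_input(self):
        assert benjamini_hochberg([]).size == 0

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=16),
        st.floats(min_value=0.01, max_value=0.2),
    )
    def test_dominates_bonferroni(self, pvals, q):
        p = np.asarray(pvals)
        bh = benjamini_hochberg(p, q)
        bonf = p < q / len(p)
        assert np.all(bh[bonf])

    def test_bh_flags_superset_in_screening(self, first_presentation_trials):
        tensor = rates.zscore_rates(
            make_null_tensor(300, first_presentation_trials, seed=17)
        )
        bonf = screen_units(tensor, "stimulus", correction="bonferroni")
        bh = screen_units(tensor, "stimulus", correction="bh")
        assert set(bonf[bonf["flagged"]]["unit_id"]) <= set(bh[bh["flagged"]]["unit_id"])


class TestBestWindowDistribution:
    def test_most_frequent_latency_is_second_window(self, default_session):
        """Under the default latency profile, [0.5, 1.0) s dominates best windows."""
        tensor = rates.build_rate_tensor(
            default_session.spikes, default_session.trials
        )
        tensor = tensor.select_units(rates.apply_rate_filter(tensor))
        tensor = rates.zscore_rates(tensor)
        results = screen_units(tensor, "stimulus")
        best = results[results["flagged"]]["best_window"].astype(int)
        counts = best.value_counts()
        assert counts.idxmax() == 1
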