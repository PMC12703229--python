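import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from statsmodels.stats.multitest import multipletests

from dpmtp import (PValueFamily, ThresholdSchedule, bh, bonferroni, by, holm,
                   sidak, step_down, step_up, weighted_bonferroni,
                   weighted_bonferroni_sensitivity)
from dpmtp.classical_mtps import bh_schedule, by_schedule, holm_schedule

from conftest import random_families


def brute_force_step_up(sorted_p, delta):
    """Independent oracle: direct maximisation over r of p_(r) <= delta_r."""
    best = 0
    for r in range(1, len(sorted_p) + 1):
        if sorted_p[r - 1] <= delta[r - 1]:
            best = r
    return best


class TestStepUp:
    def test_no_rejection_when_smallest_p_exceeds_all(self):
        fam = PValueFamily([0.9, 0.9, 0.9])
        sched = ThresholdSchedule([0.01, 0.03, 0.05], 0.05, "step_up")
        assert step_up(fam, sched).R == 0

    def test_bh_schedule_rejects_all_three(self):
        fam = PValueFamily([0.01, 0.02, 0.04])
        dec = step_up(fam, bh_schedule(3, 0.05))
        assert dec.R == 3 and dec.rejected.all()

    def test_rejects_smallest_R_pvalues(self):
        fam = PValueFamily([0.5, 0.001, 0.2, 0.9])
        sched = ThresholdSchedule([0.01, 0.25, 0.55, 0.55], 0.05, "step_up")
        dec = step_up(fam, sched)
        assert dec.R == 3
        assert list(dec.rejected) == [True, True, True, False]

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            step_up(PValueFamily([0.1]),
                    ThresholdSchedule([0.1, 0.2], 0.05, "step_up"))

    @settings(max_examples=200, derandomize=True)
    @given(st.data())
    def test_matches_brute_force_oracle(self, data):
        m = data.draw(st.integers(1, 12))
        p = data.draw(st.lists(st.floats(0, 1), min_size=m, max_size=m))
        raw = data.draw(st.lists(st.floats(0, 1), min_size=m, max_size=m))
        delta = np.sort(raw)
        fam = PValueFamily(p)
        dec = step_up(fam, ThresholdSchedule(delta, 0.05, "step_up"))
        assert dec.R == brute_force_step_up(fam.sorted_values, delta)


class TestStepDown:
    def test_all_zero_pvalues_reject_everything(self):
        fam = PValueFamily([0.0] * 4)
        assert step_down(fam, holm_schedule(4, 0.05)).R == 4

    def test_holm_stops_at_first_failure(self):
        fam = PValueFamily([0.001, 0.02, 0.9])
        assert step_down(fam, holm_schedule(3, 0.05)).R == 2

    def test_holm_first_step_failure_rejects_none(self):
        fam = PValueFamily([0.03, 0.9, 0.9])
        assert step_down(fam, holm_schedule(3, 0.05)).R == 0


class TestSingleStepProcedures:
    def test_bonferroni_examples(self):
        assert bonferroni(PValueFamily([1.0, 1.0, 1.0]), 0.05).R == 0
        assert bonferroni(PValueFamily([0.001, 0.02, 0.9]), 0.05).R == 1

    def test_weighted_bonferroni_equal_weights_is_bonferroni(self):
        fam = random_families(1, 40, seed=1)[0]
        w = np.full(40, 1 / 40)
        assert (weighted_bonferroni(fam, w, 0.05).R
                == bonferroni(fam, 0.05).R)

    def test_weighted_bonferroni_weight_direction(self):
        fam = PValueFamily([0.03, 0.9])
        assert weighted_bonferroni(fam, [0.9, 0.1], 0.05).R == 1
        assert weighted_bonferroni(fam, [0.1, 0.9], 0.05).R == 0

    def test_weighted_bonferroni_bad_weights(self):
        fam = PValueFamily([0.03, 0.9])
        with pytest.raises(ValueError):
            weighted_bonferroni(fam, [0.9, 0.2], 0.05)

    def test_sidak_threshold_between_bonferroni_and_alpha(self):
        # 1 - 0.95^(1/3) = 0.016952...
        fam = PValueFamily([0.0168, 0.9, 0.9])
        assert sidak(fam, 0.05).R == 1
        assert bonferroni(fam, 0.05).R == 0

    def test_sidak_single_hypothesis_reduces_to_alpha(self):
        assert sidak(PValueFamily([0.049]), 0.05).R == 1
        assert sidak(PValueFamily([0.051]), 0.05).R == 0


class TestWeightedBonferroniSensitivity:
    def test_degenerate_all_zero(self):
        fam = PValueFamily([0.0, 0.0, 0.0])
        mean_r, sd_r, draws = weighted_bonferroni_sensitivity(
            fam, 0.05, n_draws=50, seed=1)
        assert mean_r == 3.0 and sd_r == 0.0 and np.all(draws == 3)

    def test_single_hypothesis_reduces_to_alpha(self):
        mean_r, _, _ = weighted_bonferroni_sensitivity(
            PValueFamily([0.04]), 0.05, n_draws=50, seed=1)
        assert mean_r == 1.0

    def test_seeded_determinism(self):
        fam = random_families(1, 30, seed=4)[0]
        a = weighted_bonferroni_sensitivity(fam, 0.05, 100, seed=7)
        b = weighted_bonferroni_sensitivity(fam, 0.05, 100, seed=7)
        assert np.array_equal(a[2], b[2])


class TestByProcedure:
    def test_harmonic_scaled_thresholds_reject_none(self):
        # m=3: H_3 = 11/6, thresholds (0.00909..., 0.01818..., 0.02727...)
        fam = PValueFamily([0.01, 0.02, 0.04])
        assert by(fam, 0.05).R == 0

    def test_by_schedule_values(self):
        sched = by_schedule(3, 0.05)
        np.testing.assert_allclose(
            sched.delta, [0.05 / (3 * 11 / 6) * r for r in (1, 2, 3)],
            rtol=1e-12)


class TestAgainstStatsmodels:
    """Independent adjusted-p-value oracle for the five named procedures."""

    @pytest.mark.parametrize("ours,theirs", [
        (bonferroni, "bonferroni"),
        (sidak, "sidak"),
        (holm, "holm"),
        (bh, "fdr_bh"),
        (by, "fdr_by"),
    ])
    def test_rejection_sets_agree(self, ours, theirs):
        for i, fam in enumerate(random_families(20, 60, seed=100)):
            # mix in some tiny p-values so rejections actually occur
            p = fam.values.copy()
            p[: 10] = p[: 10] / (1000 * (i + 1))
            fam = type(fam)(p)
            dec = ours(fam, 0.05)
            ref = multipletests(fam.values, alpha=0.05, method=theirs)[0]
            assert dec.R == int(ref.sum())
            assert np.array_equal(dec.rejected, ref)


class TestProcedureProperties:
    def test_threshold_dominance(self):
        for fam in random_families(50, 40, seed=200):
            assert bonferroni(fam).R <= holm(fam).R
            assert bonferroni(fam).R <= sidak(fam).R
            assert by(fam).R <= bh(fam).R

    def test_monotone_in_alpha(self):
        fams = random_families(10, 50, seed=300)
        for proc in (bonferroni, sidak, holm, bh, by):
            for fam in fams:
                counts = [proc(fam, a).R for a in (0.01, 0.05, 0.1, 0.2)]
                assert counts == sorted(counts)

    def test_permutation_invariance(self, rng):
        fam = random_families(1, 30, seed=400)[0]
        perm = rng.permutation(30)
        shuffled = PValueFamily(fam.values[perm])
        for proc in (bonferroni, sidak, holm, bh, by):
            a, b = proc(fam), proc(shuffled)
            assert a.R == b.R
            assert np.array_equal(a.rejected[perm], b.rejected)
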