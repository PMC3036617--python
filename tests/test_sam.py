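import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from conftest import make_expression
from zdimorph.sam import (
    SamConfig,
    SAMTwoClass,
    compute_d,
    estimate_s0,
    fold_change,
    permutation_null,
    select_delta,
    _scan_criterion,
)


def s0_scan_oracle(num, s):
    """Brute-force direct search over the same candidate grid and criterion,
    written independently of the implementation's loop."""
    candidates = sorted(set(np.percentile(s, np.arange(0, 100, 5)).tolist()))
    scores = [(cand, _scan_criterion(np.asarray(num), np.asarray(s), float(cand))) for cand in candidates]
    best = min(scores, key=lambda t: (round(t[1], 12), t[0]))
    return float(best[0])


def enumeration_oracle(x, n_treatment, s0):
    """Full enumeration of treatment assignments with plain itertools."""
    n = x.shape[1]
    sorted_ds = []
    for combo in itertools.combinations(range(n), n_treatment):
        mask = np.zeros(n, dtype=bool)
        mask[list(combo)] = True
        d, _ = compute_d(x, mask, s0)
        sorted_ds.append(np.sort(d))
    sorted_ds = np.array(sorted_ds)
    return sorted_ds.mean(axis=0), sorted_ds


class TestComputeD:
    def test_equal_group_means_give_zero(self):
        x = np.array([[1.0, 2.0, 3.0, 1.0, 2.0, 3.0]])
        mask = np.array([False, False, False, True, True, True])
        d, s = compute_d(x, mask, s0=0.7)
        assert d[0] == 0.0

    def test_matches_pooled_t_statistic_at_s0_zero(self):
        # control (1,2,3) vs treatment (2,3,4): pooled sd 1, d = 1/sqrt(2/3)
        x = np.array([[1.0, 2.0, 3.0, 2.0, 3.0, 4.0]])
        mask = np.array([False, False, False, True, True, True])
        d, s = compute_d(x, mask, s0=0.0)
        np.testing.assert_allclose(d[0], 1.0 / np.sqrt(2.0 / 3.0))
        t = stats.ttest_ind([2.0, 3.0, 4.0], [1.0, 2.0, 3.0], equal_var=True)
        np.testing.assert_allclose(d[0], t.statistic)

    def test_label_swap_negates_d(self, rng):
        x = rng.normal(0, 1, size=(40, 8))
        mask = np.array([True] * 4 + [False] * 4)
        d1, _ = compute_d(x, mask, s0=0.2)
        d2, _ = compute_d(x, ~mask, s0=0.2)
        np.testing.assert_allclose(d1, -d2)

    def test_zero_variance_nonzero_difference_rejected_at_s0_zero(self):
        x = np.array([[1.0, 1.0, 1.0, 2.0, 2.0, 2.0]])
        mask = np.array([False, False, False, True, True, True])
        with pytest.raises(ValueError, match="infinite d"):
            compute_d(x, mask, s0=0.0)

    def test_constant_est_gets_d_zero(self):
        x = np.array([[5.0] * 6, [1.0, 2.0, 3.0, 2.0, 3.0, 4.0]])
        mask = np.array([False, False, False, True, True, True])
        d, s = compute_d(x, mask, s0=0.0)
        assert d[0] == 0.0 and s[0] == 0.0


class TestS0:
    def test_zero_method(self, rng):
        d = rng.normal(size=100)
        s = rng.uniform(0.1, 1, size=100)
        assert estimate_s0(d, s, method="zero") == 0.0

    def test_identical_s_returns_smallest_candidate(self):
        s = np.full(200, 0.5)
        d = np.linspace(-2, 2, 200)
        assert estimate_s0(d, s) == 0.5

    def test_scan_matches_brute_force_oracle(self, rng):
        x = rng.normal(8, 1, size=(1000, 12)) * rng.uniform(0.5, 2.0, size=(1000, 1))
        mask = np.array([True] * 6 + [False] * 6)
        d, s = compute_d(x, mask, s0=0.0)
        assert estimate_s0(d, s) == s0_scan_oracle(d * s, s)


class TestPermutationNull:
    def test_three_vs_three_enumerates_twenty_assignments(self, rng):
        x = rng.normal(0, 1, size=(30, 6))
        dbar, perm = permutation_null(x, 3, s0=0.1, n_permutations=500, rng=rng)
        assert perm.shape == (20, 30)

    def test_expected_order_statistics_nondecreasing(self, rng):
        x = rng.normal(0, 1, size=(50, 8))
        dbar, _ = permutation_null(x, 4, s0=0.1, n_permutations=70, rng=rng)
        assert (np.diff(dbar) >= 0).all()

    def test_full_enumeration_matches_itertools_oracle(self, rng):
        x = rng.normal(0, 1, size=(25, 8))
        dbar, perm = permutation_null(x, 4, s0=0.05, n_permutations=70, rng=rng)
        o_dbar, o_perm = enumeration_oracle(x, 4, s0=0.05)
        assert perm.shape[0] == 70
        np.testing.assert_allclose(np.sort(perm, axis=0), np.sort(o_perm, axis=0))
        np.testing.assert_allclose(dbar, o_dbar, atol=1e-12)

    def test_sampling_without_replacement_gives_distinct_assignments(self, rng):
        x = rng.normal(0, 1, size=(10, 12))
        dbar, perm = permutation_null(x, 6, s0=0.1, n_permutations=200, rng=rng)
        assert perm.shape[0] == 200
        assert len({tuple(np.round(row, 12)) for row in perm}) == 200

    def test_too_few_samples_rejected(self, rng):
        x = rng.normal(0, 1, size=(5, 2))
        with pytest.raises(ValueError, match="permutation"):
            permutation_null(x, 2, s0=0.1, rng=rng)


@pytest.fixture(scope="module")
def sam_inputs():
    rng = np.random.default_rng(2024)
    n, per = 400, 6
    x = rng.normal(8, 1, size=(n, 2 * per))
    x[:30, per:] += 2.0  # planted treatment-biased block, well separated
    mask = np.array([False] * per + [True] * per)
    d0, s = compute_d(x, mask, 0.0)
    s0 = estimate_s0(d0, s)
    d, _ = compute_d(x, mask, s0)
    dbar, perm = permutation_null(x, per, s0, 500, np.random.default_rng(7))
    return d, dbar, perm


class TestDeltaSelection:

    def test_number_called_nonincreasing_in_delta(self, sam_inputs):
        d, dbar, perm = sam_inputs
        ds = np.sort(d)
        diff = ds - dbar
        previous = None
        for delta in np.arange(0.05, 3.0, 0.05):
            up = np.nonzero(diff > delta)[0]
            lo = np.nonzero(diff < -delta)[0]
            cutup = ds[up[0]] if up.size else np.inf
            cutlow = ds[lo[-1]] if lo.size else -np.inf
            n_called = int(((d >= cutup) | (d <= cutlow)).sum())
            if previous is not None:
                assert n_called <= previous
            previous = n_called

    def test_huge_delta_yields_no_calls_with_warning(self, sam_inputs):
        d, dbar, perm = sam_inputs
        with pytest.warns(UserWarning, match="usable"):
            delta, fdr, cutlow, cutup = select_delta(
                d, dbar, perm, np.array([1e6]), target_fdr=0.03
            )
        assert np.isinf(cutup) and np.isinf(cutlow)
        assert ((d >= cutup) | (d <= cutlow)).sum() == 0

    def test_selected_operating_point_calls_planted_block(self, sam_inputs):
        d, dbar, perm = sam_inputs
        delta, fdr, cutlow, cutup = select_delta(
            d, dbar, perm, np.round(np.arange(0.05, 5.0, 0.01), 10), target_fdr=0.03
        )
        called = (d >= cutup) | (d <= cutlow)
        assert called.sum() >= 15
        assert called[:30].sum() >= 0.8 * called.sum()


class TestModelResults:
    def _fixture(self, rng, n=300, per=6, effect=2.0):
        x = rng.normal(8, 1, size=(n, 2 * per))
        x[:12, :per] += effect  # male-biased block (males first)
        samples = [f"m{i}" for i in range(per)] + [f"f{i}" for i in range(per)]
        expr = make_expression(x, samples=samples)
        groups = ["male"] * per + ["female"] * per
        return expr, groups

    def test_direction_invariant_to_control_designation(self, rng):
        # full enumeration (C(8,4)=70 assignments) makes the permutation
        # null exactly symmetric, so calls and directions must be identical
        # whichever sex is entered as the control group
        expr, groups = self._fixture(rng, per=4, effect=2.5)
        cfg = SamConfig(n_permutations=100, seed=5)
        res1 = SAMTwoClass(expr, groups, control="male", treatment="female").fit(cfg)
        res2 = SAMTwoClass(expr, groups, control="female", treatment="male").fit(cfg)
        assert set(res1.significant) == set(res2.significant)
        pd.testing.assert_series_equal(res1.direction(), res2.direction())

    def test_male_biased_block_called_male(self, rng):
        expr, groups = self._fixture(rng)
        res = SAMTwoClass(expr, groups).fit(SamConfig(n_permutations=60, seed=5))
        direc = res.direction()
        planted = [f"e{i}" for i in range(12)]
        hits = [e for e in planted if e in direc.index]
        assert len(hits) >= 8
        assert all(direc[e] == "male" for e in hits)

    def test_summary_mentions_operating_point(self, rng):
        expr, groups = self._fixture(rng)
        res = SAMTwoClass(expr, groups).fit(SamConfig(n_permutations=60, seed=5))
        text = res.summary()
        assert "delta" in text and "significant" in text

    def test_mismatched_labels_rejected(self, rng):
        expr, groups = self._fixture(rng)
        with pytest.raises(ValueError, match="labels"):
            SAMTwoClass(expr, groups, control="ctrl", treatment="trt")


class TestFoldChange:
    def test_identical_groups_give_one(self):
        unlogged = make_expression([[4.0, 4.0, 4.0, 4.0]], samples=["m1", "m2", "f1", "f2"])
        fc = fold_change(unlogged, ["m1", "m2"], ["f1", "f2"])
        np.testing.assert_allclose(fc, 1.0)

    def test_doubled_males_give_two(self):
        unlogged = make_expression([[8.0, 8.0, 4.0, 4.0]], samples=["m1", "m2", "f1", "f2"])
        np.testing.assert_allclose(fold_change(unlogged, ["m1", "m2"], ["f1", "f2"]), 2.0)

    def test_hand_arithmetic_example(self):
        # males (8, 10, 12), females (5, 5, 5) on the unlogged scale -> 10/5
        unlogged = make_expression(
            [[8.0, 10.0, 12.0, 5.0, 5.0, 5.0]],
            samples=["m1", "m2", "m3", "f1", "f2", "f3"],
        )
        np.testing.assert_allclose(
            fold_change(unlogged, ["m1", "m2", "m3"], ["f1", "f2", "f3"]), 2.0
        )
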