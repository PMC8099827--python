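"""Wakefield ABF colocalisation: closed forms, brute-force oracle, invariants."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from colocpipe import ColocPriors, classify_direction, coloc_posteriors, labf
from conftest import make_records


def brute_force_posteriors(l1, l2, priors):
    """Enumerate every (causal-for-trait-1, causal-for-trait-2) assignment.

    Configuration weights: none/none -> 1; (i, none) -> p1 L1(i);
    (none, j) -> p2 L2(j); (i, j), i != j -> p1 p2 L1(i) L2(j);
    (i, i) -> p12 L1(i) L2(i).  Hypothesis posteriors are the normalized
    sums over the corresponding configuration classes.
    """
    from scipy.special import logsumexp, softmax

    n = len(l1)
    lp1, lp2, lp12 = np.log(priors.p1), np.log(priors.p2), np.log(priors.p12)
    class_logw = {h: [] for h in range(5)}
    class_logw[0].append(0.0)
    for i in range(n):
        class_logw[1].append(lp1 + l1[i])
        class_logw[2].append(lp2 + l2[i])
    for i, j in itertools.product(range(n), range(n)):
        if i == j:
            class_logw[4].append(lp12 + l1[i] + l2[i])
        else:
            class_logw[3].append(lp1 + lp2 + l1[i] + l2[j])
    log_s = np.array([logsumexp(class_logw[h]) if class_logw[h] else -np.inf
                      for h in range(5)])
    return softmax(log_s)


class TestLabf:
    def test_closed_form_at_null_z(self):
        # z = 0 and V = W make r = 1/2, so lABF = 0.5 * ln(1/2)
        assert labf(0.0, 0.2, 0.2) == pytest.approx(0.5 * np.log(0.5), abs=1e-12)

    def test_worked_closed_form(self):
        # r = 0.04/0.0425 = 16/17, z = 2: lABF = (ln(1/17) + 64/17) / 2,
        # evaluated independently beforehand
        assert labf(0.1, 0.05, 0.2) == pytest.approx(0.4657463, abs=1e-6)

    @given(st.floats(-5, 5), st.floats(0.01, 2), st.floats(0.01, 2))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_sign_symmetry(self, beta, se, w):
        assert labf(beta, se, w) == pytest.approx(labf(-beta, se, w), rel=1e-12)

    def test_invalid_inputs_rejected(self):
        for bad in [(np.nan, 0.1, 0.2), (0.1, 0.0, 0.2), (0.1, 0.1, -1.0)]:
            with pytest.raises(ValueError):
                labf(*bad)


class TestColocPosteriors:
    def test_flat_evidence_sums(self):
        # all Bayes factors 1 with two variants: S = (1, 2e-4, 2e-4, 2e-8, 1e-5)
        rec1 = make_records(["a", "b"], [0.0, 0.0], [1e-6, 1e-6])
        rec2 = make_records(["a", "b"], [0.0, 0.0], [1e-6, 1e-6])
        # se -> 0 makes r -> 0 hence lABF -> 0; use prior_sd_w = se scale trick
        res = coloc_posteriors(rec1, rec2, prior_sd_w=1e-12)
        s = np.array([1.0, 2e-4, 2e-4, 2e-8, 1e-5])
        np.testing.assert_allclose(res.posteriors, s / s.sum(), rtol=1e-6)
        assert res.pp0 == pytest.approx(0.99959, abs=1e-4)

    @pytest.mark.parametrize("n,seed", [(3, 0), (2, 1), (5, 2), (4, 3), (1, 4)])
    def test_matches_brute_force_enumeration(self, n, seed):
        rng = np.random.default_rng(seed)
        ids = [f"v{i}" for i in range(n)]
        rec1 = make_records(ids, rng.normal(0, 0.2, n), rng.uniform(0.02, 0.2, n))
        rec2 = make_records(ids, rng.normal(0, 0.2, n), rng.uniform(0.02, 0.2, n))
        priors = ColocPriors()
        res = coloc_posteriors(rec1, rec2, priors)
        l1 = labf(rec1["BETA"].to_numpy(), rec1["SE"].to_numpy(), 0.2)
        l2 = labf(rec2["BETA"].to_numpy(), rec2["SE"].to_numpy(), 0.2)
        expected = brute_force_posteriors(np.atleast_1d(l1), np.atleast_1d(l2), priors)
        np.testing.assert_allclose(res.posteriors, expected, rtol=1e-12)

    def test_posteriors_normalized_and_h4_contributions_sum(self):
        rng = np.random.default_rng(5)
        ids = [f"v{i}" for i in range(30)]
        rec1 = make_records(ids, rng.normal(0, 0.3, 30), rng.uniform(0.02, 0.1, 30))
        rec2 = make_records(ids, rng.normal(0, 0.3, 30), rng.uniform(0.02, 0.1, 30))
        res = coloc_posteriors(rec1, rec2)
        assert res.posteriors.sum() == pytest.approx(1.0, abs=1e-12)
        assert (res.posteriors >= 0).all()
        assert res.h4_contribution.sum() == pytest.approx(res.pp4, rel=1e-10)

    def test_variant_order_invariance(self):
        rng = np.random.default_rng(6)
        ids = [f"v{i}" for i in range(10)]
        rec1 = make_records(ids, rng.normal(0, 0.3, 10), rng.uniform(0.02, 0.1, 10))
        rec2 = make_records(ids, rng.normal(0, 0.3, 10), rng.uniform(0.02, 0.1, 10))
        res = coloc_posteriors(rec1, rec2)
        perm = rng.permutation(10)
        res_p = coloc_posteriors(rec1.iloc[perm].reset_index(drop=True),
                                 rec2.iloc[perm].reset_index(drop=True))
        np.testing.assert_allclose(res.posteriors, res_p.posteriors, rtol=1e-12)

    def test_trait_symmetry(self):
        rng = np.random.default_rng(7)
        ids = [f"v{i}" for i in range(8)]
        rec1 = make_records(ids, rng.normal(0, 0.3, 8), rng.uniform(0.02, 0.1, 8))
        rec2 = make_records(ids, rng.normal(0, 0.3, 8), rng.uniform(0.02, 0.1, 8))
        res = coloc_posteriors(rec1, rec2)
        swapped = coloc_posteriors(rec2, rec1)
        assert res.pp1 == pytest.approx(swapped.pp2, rel=1e-12)
        assert res.pp2 == pytest.approx(swapped.pp1, rel=1e-12)
        for attr in ("pp0", "pp3", "pp4"):
            assert getattr(res, attr) == pytest.approx(getattr(swapped, attr), rel=1e-12)

    def test_overflow_safe_for_extreme_zscores(self):
        rec1 = make_records(["a", "b"], [2.0, 0.0], [0.02, 0.05])  # z = 100
        rec2 = make_records(["a", "b"], [2.0, 0.0], [0.02, 0.05])
        res = coloc_posteriors(rec1, rec2)
        assert np.isfinite(res.posteriors).all()
        assert res.pp4 > 0.99

    def test_empty_intersection_names_harmonization(self):
        rec1 = make_records(["a"], [0.1], [0.05])
        rec2 = make_records(["b"], [0.1], [0.05])
        with pytest.raises(ValueError, match="harmonize"):
            coloc_posteriors(rec1, rec2)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_pp4_monotone_in_p12(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(2, 12)
        ids = [f"v{i}" for i in range(n)]
        rec1 = make_records(ids, rng.normal(0, 0.2, n), rng.uniform(0.02, 0.2, n))
        rec2 = make_records(ids, rng.normal(0, 0.2, n), rng.uniform(0.02, 0.2, n))
        low = coloc_posteriors(rec1, rec2, ColocPriors(p12=5e-6))
        high = coloc_posteriors(rec1, rec2, ColocPriors(p12=1e-5))
        assert high.pp4 >= low.pp4 - 1e-15

    def test_prior_validation(self):
        with pytest.raises(ValueError):
            ColocPriors(p1=1e-4, p2=1e-4, p12=2e-4)  # p12 > min(p1, p2)
        with pytest.raises(ValueError):
            ColocPriors(p1=0.5, p2=0.5, p12=0.4).check_region(10)


class TestClassifyDirection:
    def make_pair(self, beta1, beta2, flip_b=False):
        rec1 = make_records(["top"], [beta1], [0.02])
        if flip_b:
            rec2 = make_records(["top"], [-beta2], [0.02], ref="T", alt="C",
                                freq=0.7)
        else:
            rec2 = make_records(["top"], [beta2], [0.02])
        return rec1, rec2

    def test_opposite_signs_discordant(self):
        # the protective-for-one / susceptible-for-other pattern
        rec1, rec2 = self.make_pair(+0.28, -0.14)
        res = coloc_posteriors(rec1, rec2)
        assert classify_direction(rec1, rec2, res) == "discordant"

    def test_same_signs_concordant(self):
        rec1, rec2 = self.make_pair(0.1, 0.1)
        res = coloc_posteriors(rec1, rec2)
        assert classify_direction(rec1, rec2, res) == "concordant"

    def test_invariant_to_allele_frame_flip(self):
        from colocpipe import harmonize
        rec1, rec2_flipped = self.make_pair(+0.28, -0.14, flip_b=True)
        h1, h2 = harmonize(rec1, rec2_flipped)
        res = coloc_posteriors(h1, h2)
        assert classify_direction(h1, h2, res) == "discordant"

    def test_fallback_to_index_variant(self):
        rec1 = make_records(["a", "b"], [np.nan, 0.2], [np.nan, 0.02])
        rec2 = make_records(["a", "b"], [0.3, -0.2], [0.02, 0.02])
        res = coloc_posteriors(rec1, rec2)
        assert classify_direction(rec1, rec2, res, fallback_index="b") == "discordant"

    def test_no_usable_variant_raises(self):
        rec1 = make_records(["a"], [0.1], [0.02])
        rec2 = make_records(["a"], [0.1], [0.02])
        res = coloc_posteriors(rec1, rec2)
        bad = make_records(["a"], [np.nan], [np.nan])
        with pytest.raises(ValueError):
            classify_direction(bad, rec2, res)
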