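"""Stepwise dissection and conditional summary statistics, both modes."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from colocpipe import (ScenarioConfig, conditional_scan, cojo_conditional,
                       forward_stepwise, score_variants, simulate_case_control,
                       simulate_haplotype_panel)
from colocpipe.conditional import Signal, enumerate_signals
from colocpipe.ld_reference import correlation_matrix
from colocpipe.region_select import Region
from conftest import make_records


def region_for(cohort):
    v = cohort.variants
    return Region(chrom=str(v["chrom"].iloc[0]), start=int(v["pos"].min()),
                  end=int(v["pos"].max()), seed_variant=v["id"].iloc[0])


def simulate_region(seed, causal, n=6_000, n_variants=60, rho=0.9,
                    n_hap=6_000):
    config = ScenarioConfig(n_variants=n_variants, ld_rho=rho, seed=seed,
                            n_panel_haplotypes=n_hap)
    panel = simulate_haplotype_panel(config)
    cohort = simulate_case_control(panel, causal, 0.1, n, n, seed=[seed, 77])
    return cohort, panel


class TestConditionalScan:
    def test_empty_conditioning_equals_marginal_scan(self, shared_causal_run):
        _, cohort1, _, _, _ = shared_causal_run
        region = region_for(cohort1)
        scan = conditional_scan(cohort1, region, [])
        marginal = score_variants(cohort1)
        pd.testing.assert_frame_equal(scan, marginal)

    def test_perfect_proxy_skipped_as_collinear(self):
        cohort, _ = simulate_region(seed=41, causal=[], n=500, n_variants=5)
        # duplicate column 0 into column 1 -> exact proxy
        g = cohort.genotypes.copy()
        g[:, 1] = g[:, 0]
        cohort = type(cohort)(genotypes=g, phenotype=cohort.phenotype,
                              variants=cohort.variants)
        scan = conditional_scan(cohort, region_for(cohort),
                                [cohort.variants["id"].iloc[0]])
        proxy = scan.loc[scan["SNP"] == cohort.variants["id"].iloc[1]]
        assert proxy["FLAG"].iloc[0] == "collinear"

    def test_conditioning_on_causal_leaves_uniform_pvalues(self):
        # moderate LD so the KS test's independence assumption roughly holds;
        # with no residual signal the conditional p-values are null-uniform
        causal_idx = 30
        passes = 0
        for seed in (42, 1042, 2042):
            cohort, _ = simulate_region(seed=seed, rho=0.3,
                                        causal=[(causal_idx, np.log(1.5))])
            region = region_for(cohort)
            causal_id = cohort.variants["id"].iloc[causal_idx]
            scan = conditional_scan(cohort, region, [causal_id])
            p = scan.loc[scan["FLAG"] == ".", "P"].dropna()
            if stats.kstest(p, "uniform").pvalue > 0.01:
                passes += 1
        assert passes >= 2

    def test_agrees_with_statsmodels_joint_fit(self):
        import statsmodels.api as sm
        cohort, _ = simulate_region(seed=43, causal=[(2, 0.3)], n=2_000,
                                    n_variants=6, rho=0.5)
        region = region_for(cohort)
        ids = cohort.variants["id"].tolist()
        scan = conditional_scan(cohort, region, [ids[2]])
        j = ids.index(ids[4])
        X = sm.add_constant(np.column_stack(
            [cohort.genotypes[:, j], cohort.genotypes[:, 2]]).astype(float))
        fit = sm.Logit(cohort.phenotype, X).fit(disp=0)
        row = scan.loc[scan["SNP"] == ids[4]].iloc[0]
        assert row["BETA"] == pytest.approx(fit.params[1], abs=1e-6)
        assert row["SE"] == pytest.approx(fit.bse[1], abs=1e-6)


class TestForwardStepwise:
    def test_zero_entry_threshold_selects_nothing(self, shared_causal_run):
        _, cohort1, _, _, _ = shared_causal_run
        assert forward_stepwise(cohort1, region_for(cohort1), p_enter=0) == []

    def test_unit_entry_threshold_exhausts_candidates(self):
        cohort, _ = simulate_region(seed=45, causal=[], n=500, n_variants=4,
                                    rho=0.2)
        selected = forward_stepwise(cohort, region_for(cohort), p_enter=1.0)
        # every variant enters unless collinear with the growing model
        scan = conditional_scan(cohort, region_for(cohort), selected)
        remaining = scan[~scan["SNP"].isin(selected)]
        assert (remaining["FLAG"] != ".").all() or remaining.empty

    def test_null_region_selects_nothing(self):
        empties = 0
        for seed in range(20):
            cohort, _ = simulate_region(seed=200 + seed, causal=[], n=2_000,
                                        n_variants=40)
            if forward_stepwise(cohort, region_for(cohort), 1e-5) == []:
                empties += 1
        assert empties >= 19

    def test_single_strong_causal_recovered_first(self):
        hits = 0
        reps = 20
        for seed in range(reps):
            causal_idx = 25
            cohort, panel = simulate_region(seed=300 + seed,
                                            causal=[(causal_idx, np.log(1.4))],
                                            n=10_000)
            selected = forward_stepwise(cohort, region_for(cohort), 1e-5)
            if not selected:
                continue
            causal_id = cohort.variants["id"].iloc[causal_idx]
            r, kept = correlation_matrix(panel, [selected[0], causal_id])
            if len(kept) == 2 and r[0, 1] ** 2 > 0.8 or selected[0] == causal_id:
                hits += 1
        assert hits >= 0.9 * reps

    def test_two_unlinked_causals_both_selected(self):
        hits = 0
        reps = 15
        for seed in range(reps):
            cohort, panel = simulate_region(
                seed=400 + seed, causal=[(10, np.log(1.3)), (50, np.log(1.3))],
                n=10_000)
            selected = forward_stepwise(cohort, region_for(cohort), 1e-5)
            if len(selected) < 2:
                continue
            ids = cohort.variants["id"]
            ok = 0
            for causal_idx in (10, 50):
                causal_id = ids.iloc[causal_idx]
                for s in selected[:2]:
                    r, kept = correlation_matrix(panel, [s, causal_id])
                    if s == causal_id or (len(kept) == 2 and r[0, 1] ** 2 > 0.8):
                        ok += 1
                        break
            if ok == 2:
                hits += 1
        assert hits >= 0.8 * reps

    def test_signal_enumeration_ranks_and_conditioning_sets(self):
        cohort, _ = simulate_region(seed=500, causal=[(10, np.log(1.4)),
                                                      (50, np.log(1.4))],
                                    n=10_000)
        signals = enumerate_signals(cohort, region_for(cohort), "trait1", 1e-5)
        assert len(signals) >= 2
        for r, s in enumerate(signals, start=1):
            assert s.rank == r == len(s.conditioning_set) + 1
            assert s.index_variant not in s.conditioning_set
            clean = s.conditional_records.dropna(subset=["P"])
            top = clean.loc[clean["P"].idxmin(), "SNP"]
            assert top == s.index_variant

    def test_index_in_conditioning_set_rejected(self):
        with pytest.raises(ValueError):
            Signal(trait="t", region=Region("1", 1, 10, "v"),
                   index_variant="v", conditioning_set=["v"])


class TestCojoConditional:
    def make_inputs(self, seed=600, n_variants=40, causal=((20, 0.35),), n=20_000):
        cohort, panel = simulate_region(seed=seed, causal=list(causal), n=n,
                                        n_variants=n_variants, n_hap=10_000)
        records = score_variants(cohort)
        ld, ids = correlation_matrix(panel)
        return cohort, panel, records, ld, ids

    def test_empty_conditioning_is_identity(self):
        _, _, records, ld, ids = self.make_inputs(n=2_000)
        out = cojo_conditional(records, ld, ids, [])
        pd.testing.assert_frame_equal(out, records)

    def test_uncorrelated_variant_unchanged(self):
        ids = ["a", "b"]
        records = make_records(ids, [0.2, 0.1], [0.05, 0.05])
        ld = np.eye(2)
        out = cojo_conditional(records, ld, ids, ["a"])
        row = out.loc[out["SNP"] == "b"].iloc[0]
        assert row["BETA"] == pytest.approx(0.1, abs=1e-12)
        assert row["SE"] == pytest.approx(0.05, abs=1e-12)

    def test_conditioned_variants_removed_and_collinear_flagged(self):
        ids = ["a", "b", "c"]
        records = make_records(ids, [0.2, 0.1, 0.05], [0.05, 0.05, 0.05])
        ld = np.array([[1.0, 0.999, 0.1], [0.999, 1.0, 0.1], [0.1, 0.1, 1.0]])
        out = cojo_conditional(records, ld, ids, ["a"])
        assert "a" not in out["SNP"].tolist()
        assert out.loc[out["SNP"] == "b", "FLAG"].iloc[0] == "collinear"

    def test_order_invariance_of_conditioning_set(self):
        _, _, records, ld, ids = self.make_inputs(
            seed=601, causal=((5, 0.3), (30, 0.3)), n=2_000)
        c = [ids[5], ids[30]]
        out1 = cojo_conditional(records, ld, ids, c)
        out2 = cojo_conditional(records, ld, ids, c[::-1])
        np.testing.assert_allclose(out1["BETA"].to_numpy(), out2["BETA"].to_numpy(),
                                   rtol=1e-10)

    def test_zscores_match_individual_level_conditioning(self):
        cohort, panel, records, ld, ids = self.make_inputs(
            seed=602, causal=((10, 0.3), (30, 0.25)), n=20_000)
        region = region_for(cohort)
        condition = [ids[10]]
        summary = cojo_conditional(records, ld, ids, condition)
        individual = conditional_scan(cohort, region, condition)
        merged = summary.merge(individual, on="SNP", suffixes=("_s", "_i"))
        merged = merged[(merged["FLAG_s"] == ".") & (merged["FLAG_i"] == ".")]
        z_s = merged["BETA_s"] / merged["SE_s"]
        z_i = merged["BETA_i"] / merged["SE_i"]
        assert np.corrcoef(z_s, z_i)[0, 1] > 0.95

    def test_frequency_mismatch_dropped(self):
        ids = ["a", "b"]
        records = make_records(ids, [0.2, 0.1], [0.05, 0.05], freq=0.1)
        out = cojo_conditional(records, np.eye(2), ids, ["a"],
                               panel_freq=np.array([0.1, 0.45]))
        assert out.empty
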