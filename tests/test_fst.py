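"""Fixation-index estimators: analytic cases, oracle equivalence, symmetry
and aggregation semantics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from magpop.counts import ParameterError
from magpop.fst import (
    differentiation_class,
    fst_distribution_check,
    locus_fst,
    multipop_locus_fst,
    pairwise_fst,
    region_fst,
)
from magpop.simulate import SimulationConfig, simulate_metapopulation

from conftest import make_counts


def scalar_fst(p1, p2):
    """Brute-force reference implementation of the per-locus estimator."""
    pbar = (p1 + p2) / 2.0
    h_t = 2.0 * pbar * (1.0 - pbar)
    h_s = (2.0 * p1 * (1.0 - p1) + 2.0 * p2 * (1.0 - p2)) / 2.0
    return 0.0 if h_t == 0 else (h_t - h_s) / h_t


class TestLocusFst:
    def test_identical_frequencies_give_zero(self):
        assert locus_fst(0.3, 0.3) == 0.0

    def test_fixed_alternative_alleles_give_one(self):
        assert locus_fst(0.0, 1.0) == 1.0

    def test_hand_computed_value(self):
        # p1=0.2, p2=0.8: H_T = 0.5, H_S = 0.32 -> 0.36
        assert locus_fst(0.2, 0.8) == pytest.approx(0.36)

    def test_out_of_range_frequency_rejected(self):
        with pytest.raises(ParameterError):
            locus_fst(-0.1, 0.5)

    @settings(max_examples=200, derandomize=True)
    @given(
        p1=st.floats(0, 1, allow_nan=False),
        p2=st.floats(0, 1, allow_nan=False),
    )
    def test_symmetry_relabelling_and_bounds(self, p1, p2):
        v = locus_fst(p1, p2)
        assert 0.0 <= v <= 1.0
        assert locus_fst(p2, p1) == pytest.approx(v)
        # allele relabelling p -> 1-p in both pools leaves FST unchanged
        assert locus_fst(1 - p1, 1 - p2) == pytest.approx(v, abs=1e-12)

    def test_hudson_variant_is_unbiased_form(self):
        # ratio-of-expectation check at a single configuration
        assert locus_fst(0.2, 0.8, estimator="hudson") == pytest.approx(
            (0.68 - 0.32) / 0.68
        )

    def test_multipop_reduces_to_pairwise_for_two_pools(self):
        rng = np.random.default_rng(0)
        p = rng.random((2, 50))
        np.testing.assert_allclose(
            multipop_locus_fst(p), locus_fst(p[0], p[1]), atol=1e-12
        )


class TestPairwiseFst:
    def test_vectorised_equals_scalar_bruteforce(self, neutral_dataset):
        res = pairwise_fst(neutral_dataset.counts)
        counts = neutral_dataset.counts
        freqs = counts.alt_frequencies()
        pools = counts.pools
        rng = np.random.default_rng(1)
        lv = res.locus_values
        pos_to_idx = {p: i for i, p in enumerate(counts.positions)}
        for row in lv.sample(n=20, random_state=7).itertuples():
            i = pos_to_idx[row.position]
            a, b = pools.index(row.pool_1), pools.index(row.pool_2)
            assert row.fst == pytest.approx(scalar_fst(freqs[i, a], freqs[i, b]), abs=1e-12)
        del rng

    def test_identical_pools_give_near_zero_median(self):
        ds = simulate_metapopulation(
            SimulationConfig(n_pools=2, n_loci=3000, fst_target=0.0, coverage_mean=100, seed=3)
        )
        res = pairwise_fst(ds.counts)
        assert abs(res.median_matrix.iloc[0, 1]) < 0.01

    def test_monomorphic_loci_suppressed(self):
        counts = make_counts(
            "AA",
            [
                [[9, 0, 0, 0, 0, 0], [9, 0, 0, 0, 0, 0]],  # monomorphic: suppressed
                [[5, 0, 0, 5, 0, 0], [8, 0, 0, 2, 0, 0]],
            ],
        )
        res = pairwise_fst(counts, min_count=2, min_coverage=4, max_coverage=200)
        assert len(res.locus_values) == 1
        assert res.locus_counts.iloc[0, 1] == 1

    def test_requires_two_pools(self):
        counts = make_counts("A", [[[5, 0, 0, 5, 0, 0]]])
        with pytest.raises(ParameterError):
            pairwise_fst(counts)

    def test_count_correction_shrinks_low_coverage_estimates(self):
        counts = make_counts(
            "A", [[[4, 0, 0, 4, 0, 0], [8, 0, 0, 0, 0, 0]]]
        )
        plain = pairwise_fst(counts).locus_values["fst"].iloc[0]
        corrected = pairwise_fst(counts, count_correction=True, pool_size=500)
        assert corrected.locus_values["fst"].iloc[0] <= plain

    def test_median_increases_with_simulated_differentiation(self):
        medians = []
        for f in (0.02, 0.1, 0.25):
            ds = simulate_metapopulation(
                SimulationConfig(n_pools=3, n_loci=1500, fst_target=f, coverage_mean=100, seed=21)
            )
            res = pairwise_fst(ds.counts)
            iu = np.triu_indices(3, 1)
            medians.append(np.nanmean(res.median_matrix.to_numpy()[iu]))
        assert medians[0] < medians[1] < medians[2]


class TestDistributionCheck:
    def test_single_species_simulation_is_unimodal(self, neutral_dataset):
        res = pairwise_fst(neutral_dataset.counts)
        pair = (res.pools[0], res.pools[1])
        _hist, verdict = fst_distribution_check(res, pair, n_boot=200, seed=0)
        assert verdict == "unimodal"

    def test_species_mixture_is_flagged(self):
        # 50/50 mixture of weakly and strongly differentiated locus sets
        low = simulate_metapopulation(
            SimulationConfig(n_pools=2, n_loci=1500, fst_target=0.02, coverage_mean=100, seed=8)
        )
        high = simulate_metapopulation(
            SimulationConfig(n_pools=2, n_loci=1500, fst_target=0.6, coverage_mean=100, seed=9)
        )
        merged = pd.concat(
            [
                pairwise_fst(low.counts).locus_values,
                pairwise_fst(high.counts).locus_values,
            ],
            ignore_index=True,
        )
        res = pairwise_fst(low.counts)
        res.locus_values = merged
        _hist, verdict = fst_distribution_check(
            res, (res.pools[0], res.pools[1]), n_boot=200, seed=0
        )
        assert verdict == "multimodal"

    def test_too_few_loci_is_insufficient(self):
        counts = make_counts(
            "A" * 10,
            [[[5, 0, 0, 5, 0, 0], [8, 0, 0, 2, 0, 0]] for _ in range(10)],
        )
        res = pairwise_fst(counts)
        _hist, verdict = fst_distribution_check(res, (res.pools[0], res.pools[1]))
        assert verdict == "insufficient"


class TestRegionFst:
    def make_matrix(self, samples, value):
        n = len(samples)
        m = np.full((n, n), float(value))
        np.fill_diagonal(m, np.nan)
        return pd.DataFrame(m, index=samples, columns=samples)

    def test_uniform_cross_region_value_is_preserved(self):
        m = self.make_matrix(["s1", "s2", "s3"], 0.2)
        regions = {"s1": "Kara-Laptev", "s2": "Davis-Baffin", "s3": "Davis-Baffin"}
        out = region_fst(m, regions)
        assert out.loc["Kara-Laptev", "Davis-Baffin"] == pytest.approx(0.2)

    def test_mixed_values_are_averaged(self):
        m = self.make_matrix(["s1", "s2", "s3"], 0.0)
        m.loc["s1", "s2"] = m.loc["s2", "s1"] = 0.1
        m.loc["s1", "s3"] = m.loc["s3", "s1"] = 0.3
        regions = {"s1": "Pacific-Arctic", "s2": "Atlantic-Arctic", "s3": "Atlantic-Arctic"}
        out = region_fst(m, regions)
        assert out.loc["Pacific-Arctic", "Atlantic-Arctic"] == pytest.approx(0.2)

    def test_values_pool_across_genomes(self):
        m1 = self.make_matrix(["s1", "s2"], 0.1)
        m2 = self.make_matrix(["s1", "s2"], 0.3)
        regions = {"s1": "Kara-Laptev", "s2": "Arctic Archipelago"}
        out = region_fst([m1, m2], regions)
        assert out.loc["Kara-Laptev", "Arctic Archipelago"] == pytest.approx(0.2)

    def test_empty_region_dropped_with_warning(self):
        m = self.make_matrix(["s1", "s2", "s3"], 0.1)
        regions = {"s1": "Kara-Laptev", "s2": "Davis-Baffin", "s3": "Kara-Laptev", "s9": "Pacific-Arctic"}
        with pytest.warns(UserWarning, match="Pacific-Arctic"):
            out = region_fst(m, regions)
        assert "Pacific-Arctic" not in out.index


class TestDifferentiationClass:
    @pytest.mark.parametrize(
        "value,label",
        [
            (0.0, "low"),
            (0.049, "low"),
            (0.05, "moderate-to-high"),
            (0.14, "moderate-to-high"),
            (0.15, "great"),
            (1.0, "great"),
        ],
    )
    def test_thresholds(self, value, label):
        assert differentiation_class(value) == label

    def test_out_of_range_rejected(self):
        with pytest.raises(ParameterError):
            differentiation_class(1.5)
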