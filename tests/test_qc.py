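"""Recruitment QC cascade: identity filtering, coverage statistics,
unimodality verdicts, admission logic, abundance and co-occurrence."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from magpop.counts import ParameterError
from magpop.qc import (
    QCThresholds,
    SampleRecruitment,
    admit_sample,
    assess_unimodality,
    cooccurrence_matrix,
    coverage_stats,
    filter_reads_by_identity,
    relative_abundance,
)
from magpop.simulate import simulate_coverage_profile


def make_recruitment(identities, depth=None, total=10000, sample_id="s1"):
    identities = np.asarray(identities, dtype=float)
    if depth is None:
        depth = np.full(100, 10)
    return SampleRecruitment(
        sample_id=sample_id,
        identities=identities,
        depth=np.asarray(depth),
        total_read_count=total,
    )


class TestIdentityFilter:
    def test_two_stage_cascade(self):
        rec = make_recruitment([75, 85, 98, 99])
        stage1 = filter_reads_by_identity(rec, 80)
        assert stage1.mapped_read_count == 3
        stage2 = filter_reads_by_identity(stage1, 97)
        assert stage2.mapped_read_count == 2

    def test_zero_threshold_is_identity_map(self):
        rec = make_recruitment([75, 85, 98, 99])
        assert filter_reads_by_identity(rec, 0).mapped_read_count == 4

    def test_empty_recruitment_warns_and_returns_empty(self, caplog):
        rec = make_recruitment([])
        out = filter_reads_by_identity(rec, 80)
        assert out.mapped_read_count == 0

    def test_exact_depth_recomputation_with_read_intervals(self):
        reads = pd.DataFrame(
            {"identity": [99.0, 50.0], "start": [0, 2], "end": [3, 5]}
        )
        rec = SampleRecruitment(
            "s", np.array([99.0, 50.0]), np.array([1, 1, 2, 1, 1]), 100, reads=reads
        )
        out = filter_reads_by_identity(rec, 80)
        np.testing.assert_array_equal(out.depth, [1, 1, 1, 0, 0])

    @settings(max_examples=50, derandomize=True)
    @given(
        identities=st.lists(st.floats(0, 100, allow_nan=False), min_size=1, max_size=40),
        thr=st.floats(0, 100, allow_nan=False),
    )
    def test_idempotence_and_monotonicity(self, identities, thr):
        rec = make_recruitment(identities)
        once = filter_reads_by_identity(rec, thr)
        twice = filter_reads_by_identity(once, thr)
        assert once.mapped_read_count == twice.mapped_read_count
        stricter = filter_reads_by_identity(rec, min(thr + 5, 100))
        assert stricter.mapped_read_count <= once.mapped_read_count


class TestCoverageStats:
    def test_arithmetic(self):
        assert coverage_stats([0, 4, 4, 8]) == (4.0, 75.0)

    def test_all_zero(self):
        assert coverage_stats(np.zeros(10)) == (0.0, 0.0)

    def test_constant_coverage_passes_both_thresholds(self):
        mean, breadth = coverage_stats(np.full(1000, 4))
        assert mean == 4.0 and breadth == 100.0

    def test_empty_vector_rejected(self):
        with pytest.raises(ParameterError):
            coverage_stats([])

    def test_bounds(self):
        rng = np.random.default_rng(0)
        d = rng.poisson(3, 500)
        mean, breadth = coverage_stats(d)
        assert mean >= 0 and 0 <= breadth <= 100


class TestUnimodality:
    def test_unimodal_depths_pass(self):
        prof = simulate_coverage_profile(20000, 30, seed=1)
        _s, _p, status = assess_unimodality(prof.depths, n_boot=200)
        assert status == "pass"

    def test_bimodal_depths_fail(self):
        prof = simulate_coverage_profile(20000, 60, mode="bimodal", seed=1, bimodal_means=(5, 60), dispersion=0.05)
        _s, _p, status = assess_unimodality(prof.depths, n_boot=200)
        assert status == "fail"

    def test_too_few_covered_positions_is_insufficient(self):
        depth = np.zeros(1000)
        depth[:50] = 10
        assert assess_unimodality(depth)[2] == "insufficient"


class TestAdmission:
    def good_sample(self, seed=0):
        prof = simulate_coverage_profile(20000, 30, seed=seed, low_identity_fraction=0.05)
        return SampleRecruitment(
            "good", prof.identities, prof.depths, total_read_count=10**6
        )

    def test_clean_sample_admitted(self):
        verdict = admit_sample(self.good_sample(), QCThresholds(dip_boot=200))
        assert verdict.admitted and verdict.reasons == []

    def test_low_breadth_rejected_with_reason(self):
        rec = self.good_sample()
        depth = rec.depth.copy()
        depth[: int(0.25 * depth.size)] = 0  # breadth 75 < 80
        rec = SampleRecruitment(rec.sample_id, rec.identities, depth, rec.total_read_count)
        verdict = admit_sample(rec, QCThresholds(dip_boot=200))
        assert not verdict.admitted
        assert any(r.startswith("breadth<") for r in verdict.reasons)

    def test_mean_coverage_just_below_threshold_rejected(self):
        rec = self.good_sample()
        depth = np.full(rec.depth.size, 4)
        depth[: int(0.025 * depth.size)] = 0  # mean 3.9, breadth 97.5
        rec = SampleRecruitment(rec.sample_id, rec.identities, depth, rec.total_read_count)
        verdict = admit_sample(rec, QCThresholds(dip_boot=200))
        assert verdict.mean_vertical_coverage < 4.0
        assert not verdict.admitted

    def test_raising_thresholds_never_admits_a_rejected_sample(self):
        rec = self.good_sample()
        loose = admit_sample(rec, QCThresholds(min_coverage=2, min_breadth=50, dip_boot=200))
        strict = admit_sample(rec, QCThresholds(min_coverage=40, min_breadth=99.9, dip_boot=200))
        assert loose.admitted or not strict.admitted
        assert not strict.admitted  # mean coverage is ~30 here


class TestAbundance:
    def test_headline_scale(self):
        assert relative_abundance(71, 10000) == pytest.approx(0.71)

    def test_zero_and_full(self):
        assert relative_abundance(0, 10) == 0.0
        assert relative_abundance(10, 10) == 100.0

    def test_zero_total_rejected(self):
        with pytest.raises(ParameterError):
            relative_abundance(1, 0)


class TestCooccurrence:
    def test_self_correlation_is_one(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({"g1": rng.random(10), "g2": rng.random(10)})
        rho, _p = cooccurrence_matrix(df)
        assert rho.loc["g1", "g1"] == pytest.approx(1.0)

    def test_reversed_ranks_give_minus_one(self):
        df = pd.DataFrame({"g1": np.arange(8.0), "g2": np.arange(8.0)[::-1]})
        rho, _p = cooccurrence_matrix(df)
        assert rho.loc["g1", "g2"] == pytest.approx(-1.0)

    def test_constant_column_reported_missing(self):
        df = pd.DataFrame({"g1": np.arange(6.0), "g2": np.full(6, 2.0)})
        rho, p = cooccurrence_matrix(df)
        assert np.isnan(rho.loc["g1", "g2"]) and np.isnan(p.loc["g1", "g2"])

    def test_null_calibration_about_five_percent(self):
        # independent abundances: ~5% of pairs significant at p < 0.05
        rng = np.random.default_rng(42)
        df = pd.DataFrame(rng.random((30, 46)), columns=[f"g{i}" for i in range(46)])
        _rho, p = cooccurrence_matrix(df)
        iu = np.triu_indices(46, 1)  # 1035 pairs
        frac = np.mean(p.to_numpy()[iu] < 0.05)
        assert frac == pytest.approx(0.05, abs=0.025)

    def test_requires_three_samples(self):
        with pytest.raises(ParameterError):
            cooccurrence_matrix(pd.DataFrame({"g1": [1, 2], "g2": [2, 1]}))
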