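"""ARI implementation, label construction, and the study harnesses."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import hicwalk as hw
from hicwalk.types import DomainPartition, Segment


def brute_force_ari(a, b) -> float:
    """Independent pair-counting ARI: classify all C(n,2) pairs."""
    a, b = np.asarray(a), np.asarray(b)
    n11 = n00 = n10 = n01 = 0
    n = len(a)
    for i in range(n):
        for j in range(i + 1, n):
            sa, sb = a[i] == a[j], b[i] == b[j]
            if sa and sb:
                n11 += 1
            elif sa and not sb:
                n10 += 1
            elif not sa and sb:
                n01 += 1
            else:
                n00 += 1
    num = 2.0 * (n11 * n00 - n10 * n01)
    den = (n11 + n10) * (n10 + n00) + (n11 + n01) * (n01 + n00)
    return num / den if den else 1.0


class TestPartitionToLabels:
    def test_two_domains(self):
        p = DomainPartition(8, (Segment(0, 4), Segment(4, 8)))
        assert hw.partition_to_labels(p).tolist() == [0, 0, 0, 0, 1, 1, 1, 1]

    def test_single_domain(self):
        assert hw.partition_to_labels(hw.single_domain_caller(5)).tolist() == [0] * 5

    def test_gap_run_gets_own_label(self):
        p = DomainPartition(5, (Segment(0, 2), Segment(2, 3, "gap"), Segment(3, 5)))
        assert hw.partition_to_labels(p).tolist() == [0, 0, 1, 2, 2]

    def test_adjacent_gaps_merge_in_run_mode(self):
        p = DomainPartition(
            6, (Segment(0, 2), Segment(2, 3, "gap"), Segment(3, 4, "gap"), Segment(4, 6))
        )
        assert hw.partition_to_labels(p, "run").tolist() == [0, 0, 1, 1, 2, 2]
        assert hw.partition_to_labels(p, "singleton").tolist() == [0, 0, 1, 2, 3, 3]
        assert hw.partition_to_labels(p, "pooled").tolist() == [0, 0, 1, 1, 2, 2]

    def test_pooled_merges_separated_gaps(self):
        p = DomainPartition(
            6,
            (Segment(0, 1, "gap"), Segment(1, 4), Segment(4, 6, "gap")),
        )
        assert hw.partition_to_labels(p, "pooled").tolist() == [0, 1, 1, 1, 0, 0]
        assert hw.partition_to_labels(p, "run").tolist() == [0, 1, 1, 1, 2, 2]

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            hw.partition_to_labels(hw.single_domain_caller(3), "bogus")


class TestAdjustedRandIndex:
    def test_identical_partitions_score_one(self):
        a = [0, 0, 1, 1, 2]
        assert hw.adjusted_rand_index(a, a) == 1.0
        assert hw.adjusted_rand_index(a, [5, 5, 9, 9, 7]) == 1.0  # relabeled

    def test_study1_truth_vs_pairs_is_0p024(self, study1_spec):
        truth = hw.partition_to_labels(study1_spec.truth())
        pairs = hw.partition_to_labels(hw.pair_caller(200))
        ari = hw.adjusted_rand_index(truth, pairs)
        assert round(ari, 3) == 0.024

    def test_single_cluster_vs_nontrivial_is_zero(self):
        assert hw.adjusted_rand_index([0] * 6, [0, 0, 1, 1, 2, 2]) == 0.0

    def test_degenerate_both_single_cluster_is_one(self):
        assert hw.adjusted_rand_index([3] * 4, [7] * 4) == 1.0

    def test_all_singletons_degenerate(self):
        assert hw.adjusted_rand_index([0, 1, 2], [5, 6, 7]) == 1.0

    def test_matches_brute_force_and_library_oracles(self):
        sklearn_metrics = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(0)
        for _ in range(200):
            n = int(rng.integers(5, 40))
            a = rng.integers(0, rng.integers(2, 6), size=n)
            b = rng.integers(0, rng.integers(2, 6), size=n)
            ours = hw.adjusted_rand_index(a, b)
            assert ours == pytest.approx(
                sklearn_metrics.adjusted_rand_score(a, b), abs=1e-12
            )
        # brute force on a handful (O(n^2) oracle)
        for _ in range(10):
            a = rng.integers(0, 3, size=25)
            b = rng.integers(0, 4, size=25)
            assert hw.adjusted_rand_index(a, b) == pytest.approx(
                brute_force_ari(a, b), abs=1e-12
            )

    @given(st.lists(st.integers(0, 4), min_size=2, max_size=30), st.integers(0, 10**6))
    def test_symmetric_bounded_and_permutation_invariant(self, labels, seed):
        rng = np.random.default_rng(seed)
        a = np.array(labels)
        b = rng.integers(0, 3, size=len(a))
        x = hw.adjusted_rand_index(a, b)
        assert -1.0 <= x <= 1.0
        assert x == pytest.approx(hw.adjusted_rand_index(b, a), abs=1e-15)
        # relabeling either argument leaves the score unchanged
        perm = rng.permutation(5)
        assert hw.adjusted_rand_index(perm[a], b) == pytest.approx(x, abs=1e-15)

    def test_rejects_length_mismatch_and_scalars(self):
        with pytest.raises(ValueError):
            hw.adjusted_rand_index([0, 1], [0, 1, 2])
        with pytest.raises(ValueError):
            hw.adjusted_rand_index([0], [1])


class TestStudy1:
    def test_pair_caller_scores_0p024_under_every_condition(self, study1_spec):
        report = hw.run_study1(study1_spec, [hw.PairCaller()], seed=2,
                               rws_steps=(2, 10), rwr_alphas=(0.1,))
        assert len(report.table) == 6  # ideal, noisy, KR, RWS2s, RWS10s, RWR0.1
        assert (report.table["ari"].round(3) == 0.024).all()

    def test_perfect_oracle_caller_scores_one(self, study1_spec):
        class Oracle:
            name = "oracle"

            def __init__(self, truth):
                self.truth = truth

            def __call__(self, M):
                return self.truth

        report = hw.run_study1(
            study1_spec, [Oracle(study1_spec.truth())], seed=2,
            rws_steps=(2,), rwr_alphas=(0.1,),
        )
        assert (report.table["ari"] == 1.0).all()

    def test_insulation_on_ideal_matrix_scores_one(self, study1_spec):
        report = hw.run_study1(
            study1_spec, [hw.InsulationCaller(min_domain=2)], seed=4,
            rws_steps=(2,), rwr_alphas=(0.1,),
        )
        assert report.median("ideal", "insulation") == 1.0


class TestStudy2:
    def test_reports_reproducible_given_seed(self):
        spec = hw.BiophysicalSpec(N=150, k=5)
        kw = dict(n_reps=2, seed=12, rws_steps=(2,), rwr_alphas=(0.1,))
        r1 = hw.run_study2(spec, [hw.InsulationCaller()], **kw)
        r2 = hw.run_study2(spec, [hw.InsulationCaller()], **kw)
        assert r1.table.equals(r2.table)
        assert r1.seeds == r2.seeds

    def test_easy_operating_point_recovers_domains(self):
        # strong domains, no masking: raw counts should carry the structure
        spec = hw.BiophysicalSpec(N=300, k=6, pi1=0.0, pi2=0.0,
                                  lambda_low=2.0, lambda_high=3.0)
        report = hw.run_study2(spec, [hw.InsulationCaller()], n_reps=5, seed=31,
                               rws_steps=(), rwr_alphas=())
        assert report.median("count", "insulation") >= 0.9

    def test_smoothing_grid_labels_present(self):
        spec = hw.BiophysicalSpec(N=120, k=4)
        report = hw.run_study2(spec, [hw.InsulationCaller()], n_reps=1, seed=1)
        assert report.conditions == [
            "count", "KR", "RWS2s", "RWS3s", "RWS4s", "RWS5s", "RWS10s",
            "RWR0.05", "RWR0.1", "RWR0.2", "RWR0.5",
        ]


@pytest.fixture(scope="module")
def bulk():
    return hw.simulate_biophysical(hw.BiophysicalSpec(N=200, k=5), 8)


class TestStudy3AndSweep:

    def test_rate_one_with_pair_caller_scores_one(self, bulk):
        report = hw.run_study3(bulk, 1.0, [hw.PairCaller()], n_reps=1, seed=3,
                               rws_steps=(), rwr_alphas=())
        assert (report.table["ari"] == 1.0).all()

    def test_fixed_seed_reproducible(self, bulk):
        kw = dict(n_reps=2, seed=19, rws_steps=(2,), rwr_alphas=())
        r1 = hw.run_study3(bulk, 0.2, [hw.InsulationCaller()], **kw)
        r2 = hw.run_study3(bulk, 0.2, [hw.InsulationCaller()], **kw)
        assert r1.table.equals(r2.table)

    def test_sparsity_decreases_with_rate(self, bulk):
        tab = hw.sparsity_sweep(bulk, [0.05, 0.25, 0.5], [hw.PairCaller()],
                                n_reps=4, seed=6)
        zeros = tab.groupby("rate")["median_zero_pct"].first()
        assert zeros.loc[0.05] > zeros.loc[0.25] > zeros.loc[0.5]

    def test_empty_rates_rejected(self, bulk):
        with pytest.raises(ValueError):
            hw.sparsity_sweep(bulk, [], [hw.PairCaller()], n_reps=1, seed=0)

    def test_report_summary_and_csv(self, bulk, tmp_path):
        report = hw.run_study3(bulk, 0.3, [hw.PairCaller()], n_reps=2, seed=1,
                               rws_steps=(), rwr_alphas=())
        out = tmp_path / "report.csv"
        report.to_csv(out)
        assert out.read_text().startswith("replicate,condition,caller,ari")
        summary = report.summary()
        assert summary["n_reps"] == 2 and len(summary["seeds"]) == 2
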