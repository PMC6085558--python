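from pathlib import Path

import numpy as np
import pandas as pd
import pytest
from lifelines.statistics import logrank_test

from epsrank.data import GeneRanking, SplitSpec
from epsrank.evaluation import (
    ComparisonTable,
    LogRankResult,
    build_signatures,
    compare_methods,
    evaluate_family,
    evaluate_signature,
    stability_analysis,
    subsample_ids,
)
from epsrank.preprocess import estimate_size_factors, make_split, normalize
from epsrank.synthetic import simulate_dataset, simulate_survival
from oracles import logrank_bruteforce

DATA = Path(__file__).parent / "data"


def ranking_of(genes, method="RF"):
    return GeneRanking(method, genes, np.arange(len(genes), 0, -1, dtype=float))


class TestBuildSignatures:
    def test_default_yields_twenty_nested_prefixes(self):
        ranking = ranking_of([f"G{i}" for i in range(30)])
        family = build_signatures(ranking)
        assert family.i_max == 20
        for i, sig in enumerate(family.signatures, start=1):
            assert len(sig) == i
        assert family.signatures[4] == family.signatures[5][:5]

    def test_too_large_i_max_rejected(self):
        with pytest.raises(ValueError, match="i_max"):
            build_signatures(ranking_of(["a", "b"]), i_max=3)

    def test_shared_prefix_gives_identical_signatures(self):
        a = build_signatures(ranking_of(list("abcde")), i_max=3)
        b = build_signatures(ranking_of(list("abcdz")), i_max=3)
        assert a.signatures[:3] == b.signatures[:3]


class TestLogRankOracle:
    def test_identical_groups_give_zero_statistic(self):
        t = [3.0, 5.0, 8.0, 13.0]
        e = [1, 1, 0, 1]
        stat, p = logrank_bruteforce(t, e, t, e)
        assert stat == 0.0
        assert p == 1.0
        res = logrank_test(t, t, event_observed_A=e, event_observed_B=e)
        assert abs(res.test_statistic) < 1e-10

    def test_eight_subject_worked_example(self):
        """The frozen 8-subject fixture reproduces the brute-force
        statistic, and lifelines matches it to 1e-10."""
        df = pd.read_csv(DATA / "logrank_eight_subjects.tsv", sep="\t")
        a = df[df["group"] == "A"]
        b = df[df["group"] == "B"]
        stat, p = logrank_bruteforce(
            a["time"], a["event"], b["time"], b["event"]
        )
        assert abs(stat - 0.4476013041453191) < 1e-10
        assert abs(p - 0.5034762632953034) < 1e-10
        res = logrank_test(
            a["time"], b["time"], event_observed_A=a["event"], event_observed_B=b["event"]
        )
        assert abs(res.test_statistic - stat) < 1e-10
        assert abs(res.p_value - p) < 1e-10

    def test_lifelines_matches_oracle_on_random_data(self):
        rng = np.random.default_rng(17)
        for _ in range(10):
            na, nb = rng.integers(5, 30, size=2)
            ta = rng.exponential(10, na).round(1)
            tb = rng.exponential(14, nb).round(1)
            ea = rng.integers(0, 2, na)
            eb = rng.integers(0, 2, nb)
            if ea.sum() + eb.sum() == 0:
                continue
            stat, p = logrank_bruteforce(ta, ea, tb, eb)
            res = logrank_test(ta, tb, event_observed_A=ea, event_observed_B=eb)
            assert abs(res.test_statistic - stat) < 1e-10
            assert abs(res.p_value - p) < 1e-10


@pytest.fixture(scope="module")
def survival_cohort():
    matrix, metadata, truth = simulate_dataset(
        n_genes=120, n_case=360, n_control=60, n_signal=6,
        effect_log2fc=1.0, dispersion=0.1, seed=23,
    )
    norm = normalize(matrix, estimate_size_factors(matrix))
    return norm, metadata, truth


class TestEvaluateSignature:
    def test_power_against_survival_driven_by_one_gene(self, survival_cohort):
        """A signature containing the survival-driving gene detects the
        split (p < 0.001) in >= 90% of seeds, n=300 validation."""
        norm, metadata, truth = survival_cohort
        driver = truth.signal_genes[0]
        beta = truth.survival_beta * 0.0
        beta[driver] = 1.0
        from dataclasses import replace

        t = replace(truth, survival_beta=beta)
        split = make_split(metadata, seed=1)
        hits = 0
        for seed in range(20):
            md = simulate_survival(
                norm, t, censor_rate=0.2, seed=900 + seed, metadata=metadata
            )
            res = evaluate_signature([driver, truth.signal_genes[1]], norm, md, split)
            hits += res.p_value < 0.001
        assert hits >= 18

    def test_groups_partition_evaluable_validation_samples(self, survival_cohort):
        norm, metadata, truth = survival_cohort
        md = simulate_survival(norm, truth, censor_rate=0.3, seed=4, metadata=metadata)
        split = make_split(metadata, seed=1)
        res = evaluate_signature(truth.signal_genes[:3], norm, md, split)
        assert res.n_high + res.n_low == len(split.validation_ids)
        assert res.converged
        assert 0 < res.p_value <= 1

    def test_unknown_gene_rejected(self, survival_cohort):
        norm, metadata, truth = survival_cohort
        md = simulate_survival(norm, truth, censor_rate=0.0, seed=4, metadata=metadata)
        split = make_split(metadata, seed=1)
        with pytest.raises(KeyError, match="NOPE"):
            evaluate_signature(["NOPE"], norm, md, split)


class TestCompareMethods:
    @staticmethod
    def results(method, ps):
        return [
            LogRankResult(method, i + 1, 1.0, p, 10, 10) for i, p in enumerate(ps)
        ]

    def test_identical_p_vectors_are_all_ties(self):
        table = compare_methods(
            {"A": self.results("A", [0.1, 0.2]), "B": self.results("B", [0.1, 0.2])}
        )
        assert table.pairs[("A", "B")] == {"wins": 0, "ties": 2, "skipped": 0}

    def test_enumerated_example(self):
        table = compare_methods(
            {
                "A": self.results("A", [0.01, 0.2, 0.03]),
                "B": self.results("B", [0.02, 0.1, 0.03]),
            }
        )
        assert table.pairs[("A", "B")] == {"wins": 1, "ties": 1, "skipped": 0}
        assert table.pairs[("B", "A")] == {"wins": 1, "ties": 1, "skipped": 0}

    def test_accounting_identity(self):
        rng = np.random.default_rng(3)
        pa, pb = rng.uniform(size=20), rng.uniform(size=20)
        table = compare_methods(
            {"A": self.results("A", pa), "B": self.results("B", pb)}
        )
        ab, ba = table.pairs[("A", "B")], table.pairs[("B", "A")]
        assert ab["wins"] + ba["wins"] + ab["ties"] == 20

    def test_mismatched_grids_rejected(self):
        with pytest.raises(ValueError, match="grids"):
            compare_methods(
                {"A": self.results("A", [0.1]), "B": self.results("B", [0.1, 0.2])}
            )

    def test_failed_fits_are_skipped(self):
        a = self.results("A", [0.01, np.nan])
        b = self.results("B", [0.02, 0.5])
        table = compare_methods({"A": a, "B": b})
        assert table.pairs[("A", "B")] == {"wins": 1, "ties": 0, "skipped": 1}


class TestStability:
    def test_deterministic_ranker_has_full_overlap_and_zero_sd(self):
        genes = [f"G{i}" for i in range(40)]

        report = stability_analysis(lambda s: ranking_of(genes), n_iter=4, k=20)
        assert report.mean_pairwise_overlap == 20
        assert (report.rank_stats["sd_rank"] == 0).all()

    def test_disjoint_top_k_gives_zero_overlap(self):
        genes = [f"G{i}" for i in range(8)]

        def pipeline(seed):
            order = genes if seed % 2 == 0 else genes[::-1]
            return ranking_of(order)

        report = stability_analysis(pipeline, n_iter=2, k=4, seeds=[0, 1])
        assert report.mean_pairwise_overlap == 0

    def test_needs_two_iterations(self):
        with pytest.raises(ValueError):
            stability_analysis(lambda s: ranking_of(["a"]), n_iter=1)

    def test_rf_stability_floor_on_planted_fixture(self, rf_recoveries):
        """Five desk forests agree on >= 10 of their top-20 genes on
        average."""
        rankings = {s: r for s, (r, _) in enumerate(rf_recoveries)}
        report = stability_analysis(
            lambda s: rankings[s], n_iter=5, k=20, seeds=list(range(5))
        )
        assert report.mean_pairwise_overlap >= 10

    def test_per_gene_rank_statistics(self):
        r1 = ranking_of(["a", "b", "c"])
        r2 = ranking_of(["b", "a", "c"])
        rankings = {0: r1, 1: r2}
        report = stability_analysis(lambda s: rankings[s], n_iter=2, k=2, seeds=[0, 1])
        assert report.rank_stats.loc["a", "mean_rank"] == 1.5
        assert report.rank_stats.loc["c", "sd_rank"] == 0.0


class TestSubsample:
    @staticmethod
    def cohort(n_cases, n_controls):
        from epsrank.data import SampleMetadata

        ids = [f"t{i}" for i in range(n_cases)] + [f"h{i}" for i in range(n_controls)]
        return SampleMetadata(
            pd.DataFrame(
                {"sample_id": ids, "condition": ["case"] * n_cases + ["control"] * n_controls}
            )
        )

    def test_minimum_controls_rule(self):
        md = self.cohort(450, 50)
        ids = subsample_ids(md, fraction=0.2, min_controls=20, seed=0)
        assert len(ids) == 100
        controls = [s for s in ids if s.startswith("h")]
        assert len(controls) == 20
        assert len(ids) - len(controls) == 80

    def test_full_fraction_is_identity(self):
        md = self.cohort(30, 25)
        ids = subsample_ids(md, fraction=1.0, min_controls=20, seed=0)
        assert sorted(ids) == sorted(md.sample_ids)

    def test_same_seed_same_subset(self):
        md = self.cohort(200, 100)
        a = subsample_ids(md, seed=5)
        b = subsample_ids(md, seed=5)
        assert a == b

    def test_infeasible_counts_rejected(self):
        with pytest.raises(ValueError, match="infeasible"):
            subsample_ids(self.cohort(30, 10), fraction=0.2, min_controls=20, seed=0)
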