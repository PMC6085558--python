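import numpy as np
import pytest

from conftest import recovered
from epsrank.data import SplitSpec
from epsrank.eps import (
    DEFAULT_N_PSEUDO,
    ExtremeRegions,
    PseudoSampleSet,
    Separator,
    draw_pseudo_samples,
    eps_ranking,
    find_extreme_regions,
    fit_separator,
    rank_by_eps,
)
from epsrank.preprocess import estimate_size_factors, normalize, transform_features
from epsrank.synthetic import simulate_dataset
from epsrank.vae import LatentRepresentation, embed


def latent_clouds(gap=6.0, n=40, dim=4, seed=0, sigma=0.3):
    rng = np.random.default_rng(seed)
    z_case = rng.standard_normal((n, dim)) + gap / 2
    z_control = rng.standard_normal((n, dim)) - gap / 2
    z = np.vstack([z_case, z_control])
    labels = np.array([1] * n + [0] * n)
    return LatentRepresentation(
        sample_ids=[f"s{i}" for i in range(2 * n)],
        mu=z.copy(),
        sigma=np.full_like(z, sigma),
        z=z,
        labels=labels,
    )


class TestSeparator:
    def test_separable_clouds_reach_full_accuracy(self):
        sep = fit_separator(latent_clouds())
        assert sep.training_accuracy == 1.0

    def test_shuffled_labels_give_chance_accuracy(self):
        lat = latent_clouds()
        rng = np.random.default_rng(5)
        lat.labels = rng.permutation(lat.labels)
        sep = fit_separator(lat)
        assert abs(sep.training_accuracy - 0.5) <= 0.1

    def test_label_flip_negates_weights(self):
        lat = latent_clouds()
        sep = fit_separator(lat)
        flipped = latent_clouds()
        flipped.labels = 1 - flipped.labels
        sep_flipped = fit_separator(flipped)
        cos = np.dot(sep.weight, sep_flipped.weight) / (
            np.linalg.norm(sep.weight) * np.linalg.norm(sep_flipped.weight)
        )
        assert cos < -0.999

    def test_case_side_is_positive(self):
        lat = latent_clouds()
        sep = fit_separator(lat)
        dist = sep.signed_distance(lat.z)
        assert np.all(dist[lat.labels == 1] > 0)
        assert np.all(dist[lat.labels == 0] < 0)

    def test_degenerate_latent_rejected(self):
        lat = latent_clouds()
        lat.z = np.ones_like(lat.z)
        with pytest.raises(ValueError, match="identical"):
            fit_separator(lat)

    def test_zero_weight_rejected(self):
        with pytest.raises(ValueError, match="nonzero"):
            Separator(np.zeros(3), 0.0, 1.0)


class TestExtremeRegions:
    def test_full_quantile_takes_all_correct_side_samples(self):
        lat = latent_clouds()
        sep = fit_separator(lat)
        regions = find_extreme_regions(lat, sep, quantile_q=1.0)
        dist = sep.signed_distance(lat.z)
        for c, sign in regions.side_signs.items():
            correct = np.flatnonzero((lat.labels == c) & (np.sign(dist) == sign))
            np.testing.assert_array_equal(regions.members[c], np.sort(correct))

    def test_members_are_the_most_distant(self):
        lat = latent_clouds()
        sep = fit_separator(lat)
        regions = find_extreme_regions(lat, sep, quantile_q=0.2)
        dist = np.abs(sep.signed_distance(lat.z))
        for c in (0, 1):
            members = set(regions.members[c].tolist())
            others = [
                i
                for i in np.flatnonzero(lat.labels == c)
                if i not in members
            ]
            assert dist[list(members)].min() >= dist[others].max() - 1e-12

    def test_region_size_is_ceil_of_quantile(self):
        lat = latent_clouds(n=37)
        sep = fit_separator(lat)
        regions = find_extreme_regions(lat, sep, quantile_q=0.1)
        assert len(regions.members[0]) == int(np.ceil(0.1 * 37))
        assert len(regions.members[1]) == int(np.ceil(0.1 * 37))

    def test_invalid_quantile_rejected(self):
        lat = latent_clouds()
        sep = fit_separator(lat)
        with pytest.raises(ValueError, match="quantile"):
            find_extreme_regions(lat, sep, quantile_q=0.0)


class TestDrawPseudoSamples:
    @pytest.fixture()
    def trained(self, blob_data, blob_vae):
        X, y, ids = blob_data
        model, _ = blob_vae
        lat = embed(model, X, ids, y, seed=3)
        sep = fit_separator(lat)
        regions = find_extreme_regions(lat, sep, quantile_q=0.2)
        return X, y, model, lat, sep, regions

    def test_default_draw_count_is_400_per_class(self, trained):
        _, _, model, lat, _, regions = trained
        pseudo = draw_pseudo_samples(regions, lat, model, seed=0)
        assert DEFAULT_N_PSEUDO == 400
        assert pseudo.n_per_class == 400
        assert pseudo.values.shape[0] == 800

    def test_all_latent_points_respect_side_condition(self, trained):
        _, _, model, lat, sep, regions = trained
        pseudo = draw_pseudo_samples(regions, lat, model, n_per_class=50, seed=1)
        dist = sep.signed_distance(pseudo.latent_points)
        signs = np.where(pseudo.labels == 1, 1, -1)
        assert np.all(np.sign(dist) == signs)

    def test_cycle_consistency_on_blobs(self, trained):
        """Decoded pseudo-samples re-embed on their generating class's
        side >= 95% of the time."""
        _, _, model, lat, sep, regions = trained
        pseudo = draw_pseudo_samples(regions, lat, model, n_per_class=100, seed=2)
        re_lat = embed(
            model,
            pseudo.values,
            [f"p{i}" for i in range(len(pseudo.labels))],
            pseudo.labels,
            seed=0,
        )
        dist = sep.signed_distance(re_lat.mu)
        agree = np.mean((dist > 0).astype(int) == pseudo.labels)
        assert agree >= 0.95

    def test_rejection_budget_exhaustion_raises(self, trained):
        _, _, model, lat, sep, regions = trained
        # force an impossible region: control member placed deep on the
        # case side with a negligible posterior spread
        far = lat.mu + 0.0
        far[regions.members[0]] = lat.mu[regions.members[1][:1]] + 50.0
        bad = LatentRepresentation(
            lat.sample_ids, far, np.full_like(far, 1e-6), far, lat.labels
        )
        with pytest.raises(RuntimeError, match="correct side"):
            draw_pseudo_samples(regions, bad, model, n_per_class=3, seed=0)

    def test_seeded_draws_are_reproducible(self, trained):
        _, _, model, lat, _, regions = trained
        a = draw_pseudo_samples(regions, lat, model, n_per_class=20, seed=7)
        b = draw_pseudo_samples(regions, lat, model, n_per_class=20, seed=7)
        np.testing.assert_array_equal(a.values, b.values)


class TestRankByEPS:
    def test_constant_feature_gets_zero_coefficient(self):
        rng = np.random.default_rng(0)
        n = 60
        labels = np.array([0] * n + [1] * n)
        X = rng.standard_normal((2 * n, 5))
        X[:, 2] = 3.14  # constant across pseudo-samples
        X[:, 0] += 3 * labels
        pseudo = PseudoSampleSet(X, labels, np.zeros((2 * n, 2)),
                                 gene_ids=[f"G{i}" for i in range(5)])
        ranking = rank_by_eps(pseudo)
        scores = dict(zip(ranking.gene_ids, ranking.scores))
        assert scores["G2"] == 0.0
        assert ranking.gene_ids[-1] == "G2"
        assert ranking.gene_ids[0] == "G0"

    def test_unbalanced_classes_rejected(self):
        with pytest.raises(ValueError, match="equal"):
            PseudoSampleSet(
                np.zeros((3, 2)), np.array([0, 1, 1]), np.zeros((3, 2))
            )

    def test_too_few_pseudo_samples_rejected(self):
        pseudo = PseudoSampleSet(
            np.zeros((2, 3)), np.array([0, 1]), np.zeros((2, 2)),
            gene_ids=["a", "b", "c"],
        )
        with pytest.raises(ValueError, match="at least 2"):
            rank_by_eps(pseudo)


class TestPipeline:
    def test_recovery_of_planted_genes(self, eps_recoveries, canonical_prepared):
        """The full EPS pipeline recovers >= 7/10 planted genes on
        average over 3 seeds, and each ranking is a permutation of the
        gene universe."""
        norm = canonical_prepared[0]
        recoveries = [r for _, r in eps_recoveries]
        assert np.mean(recoveries) >= 7.0
        for result, _ in eps_recoveries:
            assert sorted(result.ranking.gene_ids) == sorted(norm.gene_ids)
            assert result.pseudo.n_per_class == 400

    def test_fixed_seed_is_bit_reproducible(self):
        matrix, metadata, _ = simulate_dataset(
            n_genes=150, n_case=30, n_control=30, n_signal=5, seed=21
        )
        norm = normalize(matrix, estimate_size_factors(matrix))
        split = SplitSpec(list(matrix.sample_ids), [], 0)
        features = transform_features(norm, split)
        a = eps_ranking(features, metadata, split, epochs=30, seed=5)
        b = eps_ranking(features, metadata, split, epochs=30, seed=5)
        assert a.ranking.gene_ids == b.ranking.gene_ids
        np.testing.assert_array_equal(a.ranking.scores, b.ranking.scores)
        np.testing.assert_array_equal(a.pseudo.values, b.pseudo.values)

    def test_stronger_effects_rank_signal_genes_higher(self):
        """Median planted-gene rank must not get worse as the planted
        effect grows (paired seeds, three effect levels)."""
        medians = {e: [] for e in (0.5, 1.5, 3.0)}
        for seed in (0, 1):
            for effect in medians:
                matrix, metadata, truth = simulate_dataset(
                    n_genes=500, n_case=100, n_control=100, n_signal=10,
                    effect_log2fc=effect, dispersion=0.1, seed=31 + seed,
                )
                norm = normalize(matrix, estimate_size_factors(matrix))
                split = SplitSpec(list(matrix.sample_ids), [], 0)
                features = transform_features(norm, split)
                res = eps_ranking(features, metadata, split, epochs=150, seed=seed)
                ranks = [res.ranking.rank_of(g) for g in truth.signal_genes]
                medians[effect].append(np.median(ranks))
        for seed_idx in range(2):
            assert medians[3.0][seed_idx] <= medians[1.5][seed_idx]
            assert medians[1.5][seed_idx] <= medians[0.5][seed_idx]
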