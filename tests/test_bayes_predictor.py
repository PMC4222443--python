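import numpy as np
import pytest
from helpers import bn_full_joint_posteriors

from pmedianrx.bayesnet import (
    accuracy,
    build_structure,
    fit_cpds,
    predict_drugs,
    trivial_baseline,
)


def _fit_random_model(rng, g=3, K=2, n_drugs=2, n_cells=12, direction="cluster_to_genes",
                      alpha=1.0):
    model = build_structure([f"g{j}" for j in range(g)], K,
                            [f"d{j}" for j in range(n_drugs)], direction)
    genes = rng.integers(-1, 2, size=(n_cells, g))
    labels = rng.integers(1, K + 1, size=n_cells)
    labels[:K] = np.arange(1, K + 1)  # every cluster observed
    drugs = rng.integers(-1, 2, size=(n_cells, n_drugs))
    fit_cpds(model, genes, labels, drugs, alpha=alpha)
    return model, genes, labels, drugs


class TestBuildStructure:
    def test_node_and_edge_counts_at_screen_scale(self):
        model = build_structure([f"g{i}" for i in range(10)], 9,
                                [f"d{i}" for i in range(1400)])
        assert model.n_nodes == 1411
        assert model.n_edges == 1410

    def test_minimal_chain(self):
        model = build_structure(["g"], 1, ["d"])
        assert model.n_nodes == 3 and model.n_edges == 2

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError):
            build_structure(["g", "g"], 2, ["d"])

    def test_direction_flag_validated(self):
        with pytest.raises(ValueError):
            build_structure(["g"], 1, ["d"], direction="sideways")


class TestFitCpds:
    def test_deterministic_mapping_gives_unit_cpts(self):
        model = build_structure(["g"], 2, ["d"], "cluster_to_genes")
        labels = np.array([1, 1, 2, 2])
        genes = np.array([[-1], [-1], [1], [1]])
        drugs = np.array([[1], [1], [-1], [-1]])  # cluster 1 -> resistant, 2 -> sensitive
        fit_cpds(model, genes, labels, drugs, alpha=0.0)
        table = model.drug_given_cluster[0]  # 3 x K, rows ordered (-1, 0, 1)
        np.testing.assert_allclose(table[:, 0], [0.0, 0.0, 1.0])
        np.testing.assert_allclose(table[:, 1], [1.0, 0.0, 0.0])

    def test_huge_alpha_approaches_uniform(self, rng):
        model, *_ = _fit_random_model(rng, alpha=1e9)
        np.testing.assert_allclose(model.drug_given_cluster, 1.0 / 3.0, atol=1e-6)
        np.testing.assert_allclose(model.cluster_prior, 0.5, atol=1e-6)

    def test_laplace_counting_oracle(self):
        model = build_structure(["g"], 2, ["d"], "cluster_to_genes")
        labels = np.array([1, 1, 1, 2, 2, 2, 2, 1])
        genes = np.array([[-1], [0], [1], [0], [0], [1], [1], [-1]])
        drugs = np.array([[1], [1], [0], [-1], [-1], [-1], [0], [1]])
        fit_cpds(model, genes, labels, drugs, alpha=1.0)
        # cluster 1: drug codes (1, 1, 0, 1) -> counts (-1: 0, 0: 1, 1: 3), total 4
        np.testing.assert_allclose(
            model.drug_given_cluster[0][:, 0], [(0 + 1) / 7, (1 + 1) / 7, (3 + 1) / 7]
        )
        # cluster prior: (4 + 1) / (8 + 2) each way
        np.testing.assert_allclose(model.cluster_prior, [5 / 10, 5 / 10])

    def test_cpt_columns_normalised(self, rng):
        for direction in ("genes_to_cluster", "cluster_to_genes"):
            model, *_ = _fit_random_model(rng, direction=direction)
            np.testing.assert_allclose(
                model.drug_given_cluster.sum(axis=1), 1.0, atol=1e-9
            )
            if direction == "genes_to_cluster":
                for post in model.cluster_given_genes.values():
                    assert post.sum() == pytest.approx(1.0, abs=1e-9)
            else:
                np.testing.assert_allclose(
                    model.gene_given_cluster.sum(axis=1), 1.0, atol=1e-9
                )

    def test_empty_training_set_rejected(self):
        model = build_structure(["g"], 1, ["d"])
        with pytest.raises(ValueError, match="empty"):
            fit_cpds(model, np.zeros((0, 1)), np.zeros(0), np.zeros((0, 1)))


class TestPredictDrugs:
    def test_single_cluster_returns_marginal_cpts(self):
        model = build_structure(["g"], 1, ["d"], "cluster_to_genes")
        genes = np.array([[0], [0], [1]])
        drugs = np.array([[1], [1], [-1]])
        fit_cpds(model, genes, np.array([1, 1, 1]), drugs, alpha=0.0)
        res = predict_drugs(model, np.array([0]))
        np.testing.assert_allclose(res.drug_posteriors[0], [1 / 3, 0.0, 2 / 3])
        assert res.predicted_labels[0] == 1  # training majority

    def test_configuration_seen_in_one_cluster_is_point_mass(self):
        model = build_structure(["g1", "g2"], 3, ["d"], "genes_to_cluster")
        genes = np.array([[-1, -1], [0, 0], [1, 1], [1, -1]])
        labels = np.array([1, 2, 3, 3])
        drugs = np.array([[0], [0], [1], [1]])
        fit_cpds(model, genes, labels, drugs, alpha=0.0)
        res = predict_drugs(model, np.array([1, 1]))
        np.testing.assert_allclose(res.cluster_posterior, [0.0, 0.0, 1.0])

    def test_unseen_configuration_falls_back_to_uniform(self, rng):
        model, *_ = _fit_random_model(rng, direction="genes_to_cluster", K=3)
        res = predict_drugs(model, np.array([1, -1, 1]) * 0)  # may or may not be seen
        assert res.cluster_posterior.sum() == pytest.approx(1.0)

    @pytest.mark.parametrize("direction", ["genes_to_cluster", "cluster_to_genes"])
    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_full_joint_enumeration(self, direction, seed):
        rng = np.random.default_rng(seed)
        g = int(rng.integers(1, 5))
        K = int(rng.integers(1, 4))
        n_drugs = int(rng.integers(1, 4))
        model, genes, labels, drugs = _fit_random_model(
            rng, g=g, K=K, n_drugs=n_drugs, n_cells=15, direction=direction
        )
        evidence = rng.integers(-1, 2, size=g)
        res = predict_drugs(model, evidence)
        oracle = bn_full_joint_posteriors(model, evidence)
        np.testing.assert_allclose(res.drug_posteriors, oracle, atol=1e-10)

    def test_posteriors_normalised_and_order_invariant(self, rng):
        model, genes, labels, drugs = _fit_random_model(rng, n_drugs=4)
        evidence = np.array([0, 1, -1])
        res = predict_drugs(model, evidence)
        np.testing.assert_allclose(res.drug_posteriors.sum(axis=1), 1.0, atol=1e-9)
        perm = [2, 0, 3, 1]
        model2 = build_structure(model.gene_ids, model.K,
                                 [model.drug_ids[j] for j in perm], model.direction)
        fit_cpds(model2, genes, labels, drugs[:, perm], alpha=model.alpha)
        res2 = predict_drugs(model2, evidence)
        np.testing.assert_allclose(res2.drug_posteriors, res.drug_posteriors[perm], atol=1e-12)

    def test_unfitted_model_rejected(self):
        model = build_structure(["g"], 1, ["d"])
        with pytest.raises(ValueError, match="not fitted"):
            predict_drugs(model, np.array([0]))


class TestAccuracyAndBaseline:
    def test_all_correct_is_100(self):
        truth = np.array([[1, 0, -1], [0, 0, 1]])
        assert accuracy(truth, truth) == 100.0

    def test_count_oracle_two_thirds(self):
        pred = np.array([[1, 0, -1], [0, 0, 1]])
        truth = np.array([[1, 0, 0], [1, 0, 1]])
        assert accuracy(pred, truth) == pytest.approx(100 * 4 / 6)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            accuracy(np.zeros((2, 3)), np.zeros((3, 2)))

    def test_baseline_is_per_column_mode(self, rng):
        train = rng.integers(-1, 2, size=(30, 6))
        base = trivial_baseline(train, 2)
        for d in range(6):
            counts = {v: (train[:, d] == v).sum() for v in (-1, 0, 1)}
            best = max(counts.values())
            tied = [v for v, c in counts.items() if c == best]
            expected = 0 if len(tied) > 1 else tied[0]
            assert base[0, d] == expected
            assert base[1, d] == expected

    def test_baseline_tie_goes_intermediate(self):
        train = np.array([[-1], [1]])
        assert trivial_baseline(train, 1)[0, 0] == 0

    def test_all_resistant_training_predicts_resistant(self):
        train = np.ones((5, 2), dtype=int)
        np.testing.assert_array_equal(trivial_baseline(train, 3), 1)


class TestNoiseFreePlantedPanel:
    def test_held_in_accuracy_100_with_alpha_zero(self):
        """A deterministic cluster->drug map is reproduced exactly at alpha=0."""
        K, per = 3, 4
        labels = np.repeat(np.arange(1, K + 1), per)
        genes = np.repeat(np.array([[-1, -1], [0, 0], [1, 1]]), per, axis=0)
        drug_map = np.array([[1, -1, 0], [-1, 1, 1], [0, 0, -1]])  # cluster x drug
        drugs = drug_map[labels - 1]
        model = build_structure(["gA", "gB"], K, ["d1", "d2", "d3"], "genes_to_cluster")
        fit_cpds(model, genes, labels, drugs, alpha=0.0)
        pred = np.vstack(
            [predict_drugs(model, genes[i]).predicted_labels for i in range(len(labels))]
        )
        assert accuracy(pred, drugs) == 100.0
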