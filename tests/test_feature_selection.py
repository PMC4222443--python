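import numpy as np
import pytest
from helpers import (
    best_subset_by_powerset,
    cfs_merit_oracle,
    contingency_information_gain,
    entropy_of,
    su_oracle,
)

from pmedianrx.features import (
    cfs_select,
    information_gain,
    select_genes_for_model,
    symmetric_uncertainty,
    top_k,
    vote_across_folds,
)


def random_ternary_table(rng, n=12, m=6, k=3):
    codes = rng.integers(-1, 2, size=(n, m))
    labels = rng.integers(1, k + 1, size=n)
    return codes, labels


class TestInformationGain:
    def test_constant_gene_has_zero_gain(self, rng):
        codes = np.zeros((8, 1), dtype=int)
        labels = rng.integers(1, 3, size=8)
        assert information_gain(codes, labels).scores["0"] == 0.0

    def test_perfect_predictor_reaches_class_entropy(self):
        labels = np.array([1, 1, 2, 2, 3, 3])
        codes = np.array([[-1], [-1], [0], [0], [1], [1]])
        ig = information_gain(codes, labels).scores["0"]
        assert ig == pytest.approx(entropy_of(labels), abs=1e-12)

    def test_matches_contingency_oracle(self, rng):
        for _ in range(10):
            codes, labels = random_ternary_table(rng)
            ranking = information_gain(codes, labels)
            for j in range(codes.shape[1]):
                expected = contingency_information_gain(codes[:, j], labels)
                assert ranking.scores[str(j)] == pytest.approx(expected, abs=1e-12)

    def test_bounded_by_both_entropies(self, rng):
        codes, labels = random_ternary_table(rng, n=20)
        ranking = information_gain(codes, labels)
        hc = entropy_of(labels)
        for j in range(codes.shape[1]):
            ha = entropy_of(codes[:, j])
            assert -1e-12 <= ranking.scores[str(j)] <= min(hc, ha) + 1e-12

    def test_invariant_to_relabeling(self, rng):
        codes, labels = random_ternary_table(rng)
        base = information_gain(codes, labels)
        relabeled = information_gain(-codes, labels * 7 + 1)
        for j in range(codes.shape[1]):
            assert relabeled.scores[str(j)] == pytest.approx(base.scores[str(j)], abs=1e-12)

    def test_length_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            information_gain(np.zeros((5, 2)), np.zeros(4))


class TestTopK:
    def test_k_equals_m_returns_full_ranking(self, rng):
        codes, labels = random_ternary_table(rng)
        ranking = information_gain(codes, labels)
        assert top_k(ranking, codes.shape[1]) == ranking.ordered_ids

    def test_equal_scores_keep_original_order(self):
        labels = np.array([1, 1, 2, 2])
        codes = np.array([[1, 1], [1, 1], [0, 0], [0, 0]])  # duplicated gene
        assert top_k(information_gain(codes, labels), 2) == ["0", "1"]

    def test_matches_sort_oracle(self, rng):
        codes, labels = random_ternary_table(rng, n=25, m=10)
        ranking = information_gain(codes, labels)
        oracle = sorted(ranking.scores, key=lambda g: (-ranking.scores[g], int(g)))
        assert top_k(ranking, 10) == oracle

    def test_k_too_large_rejected(self, rng):
        codes, labels = random_ternary_table(rng)
        with pytest.raises(ValueError):
            top_k(information_gain(codes, labels), codes.shape[1] + 1)


class TestCFS:
    def test_single_predictive_gene_selected(self, rng):
        labels = np.tile([1, 2], 10)
        signal = np.where(labels == 1, -1, 1).reshape(-1, 1)
        noise = rng.integers(-1, 2, size=(20, 4))
        codes = np.hstack([signal, noise])
        subset = cfs_select(codes, labels)
        assert "0" in subset.gene_ids

    def test_duplicate_gene_never_joins_its_twin(self):
        labels = np.array([1, 1, 2, 2, 3, 3])
        gene = np.array([-1, -1, 0, 0, 1, 1])
        codes = np.column_stack([gene, gene, gene])
        subset = cfs_select(codes, labels)
        assert len(subset.gene_ids) == 1  # identical twins are pure redundancy

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_incumbent_matches_powerset_search(self, seed):
        rng = np.random.default_rng(seed)
        codes = rng.integers(-1, 2, size=(14, 5))
        labels = rng.integers(1, 3, size=14)
        subset = cfs_select(codes, labels)
        _, best_merit = best_subset_by_powerset(codes, labels)
        assert subset.merit == pytest.approx(best_merit, abs=1e-10)

    def test_merit_recomputes_on_returned_subset(self, rng):
        codes, labels = random_ternary_table(rng, n=16, m=5)
        subset = cfs_select(codes, labels)
        chosen = tuple(int(g) for g in subset.gene_ids)
        assert subset.merit == pytest.approx(
            cfs_merit_oracle(codes, labels, chosen), abs=1e-10
        )

    def test_singleton_merit_is_class_correlation(self, rng):
        codes, labels = random_ternary_table(rng, n=20, m=1)
        su = symmetric_uncertainty(codes[:, 0], labels)
        assert su == pytest.approx(su_oracle(codes[:, 0], labels), abs=1e-12)


class TestVoteAcrossFolds:
    def test_identical_lists_returned_verbatim(self):
        lists = [["a", "b", "c"]] * 5
        assert vote_across_folds(lists, 3) == ["a", "b", "c"]

    def test_more_votes_ranks_first(self):
        lists = [["always", "sometimes"]] * 59 + [["always", "other"]]
        result = vote_across_folds(lists, 2)
        assert result[0] == "always"
        assert result[1] == "sometimes"

    def test_matches_counting_oracle(self, rng):
        genes = [f"g{i}" for i in range(12)]
        lists = [list(rng.choice(genes, size=5, replace=False)) for _ in range(20)]
        result = vote_across_folds(lists, 6)
        counts = {g: sum(g in fold for fold in lists) for g in genes}
        result_counts = [counts[g] for g in result]
        assert result_counts == sorted(result_counts, reverse=True)
        worst_selected = min(result_counts)
        for g, c in counts.items():
            if g not in result:
                assert c <= worst_selected

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            vote_across_folds([])


class TestSelectGenesForModel:
    def test_cfs_padded_to_n_top_by_ig_rank(self):
        labels = np.array([1, 1, 2, 2, 3, 3])
        gene = np.array([-1, -1, 0, 0, 1, 1])
        codes = np.column_stack([gene, gene, gene, gene])
        chosen = select_genes_for_model(codes, labels, ["a", "b", "c", "d"], "cfs", n_top=3)
        assert len(chosen) == 3
        assert chosen[0] == "a"

    def test_ig_policy_equals_top_k(self, rng):
        codes, labels = random_ternary_table(rng, n=20, m=8)
        ids = [f"g{j}" for j in range(8)]
        chosen = select_genes_for_model(codes, labels, ids, "ig", n_top=4)
        assert chosen == top_k(information_gain(codes, labels, ids), 4)
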