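import numpy as np
import pytest

from biasdiag import (
    Alignment,
    AnalysisError,
    RootedTree,
    cluster_overlap,
    coverage_stats,
    fitch_length,
    gene_admission_filter,
    make_benchmark,
    missing_on_tree,
    position_coverage_filter,
    shared_missing_overlap,
)
from biasdiag.alphabet import MISSING
from biasdiag.missingness import OverlapMatrix

from conftest import random_alignment, random_yule_tree


def _masked(rng, n_taxa, n_cols, missing_prob):
    return random_alignment(rng, n_taxa, n_cols, missing_prob=missing_prob)


class TestCoverageStats:
    def test_complete_alignment(self, rng):
        aln = random_alignment(rng, 3, 10)
        assert coverage_stats(aln).overall_coverage == pytest.approx(100.0)

    def test_direct_arithmetic(self):
        mat = np.zeros((2, 4), dtype=np.uint8)
        mat[0, 0] = MISSING
        mat[1, 3] = MISSING
        aln = Alignment(["a", "b"], mat)
        stats = coverage_stats(aln)
        assert stats.overall_coverage == pytest.approx(75.0)
        assert stats.per_taxon_missing["a"] == pytest.approx(0.25)

    def test_invariant_identity(self, rng):
        aln = _masked(rng, 6, 40, 0.3)
        stats = coverage_stats(aln)
        expected = 100.0 * stats.per_column_present.sum() / (6 * 40)
        assert stats.overall_coverage == pytest.approx(expected)


class TestPositionCoverageFilter:
    def test_identity_without_missing(self, rng):
        aln = random_alignment(rng, 4, 20)
        filtered, kept = position_coverage_filter(aln, 0.5)
        assert filtered == aln
        assert kept.tolist() == list(range(20))

    def test_boundary_inclusive(self):
        mat = np.zeros((4, 1), dtype=np.uint8)
        mat[2:, 0] = MISSING  # exactly 2 of 4 present
        aln = Alignment(list("abcd"), mat)
        filtered, _ = position_coverage_filter(aln, 0.5)
        assert filtered.n_columns == 1

    def test_all_removed_errors(self):
        mat = np.full((2, 3), MISSING, dtype=np.uint8)
        aln = Alignment(["a", "b"], mat)
        with pytest.raises(AnalysisError):
            position_coverage_filter(aln, 0.5)

    def test_min_fraction_bounds(self, rng):
        aln = random_alignment(rng, 4, 10)
        with pytest.raises(AnalysisError):
            position_coverage_filter(aln, 0.0)
        with pytest.raises(AnalysisError):
            position_coverage_filter(aln, 1.5)

    def test_epsilon_removes_only_all_missing(self, rng):
        aln = _masked(rng, 5, 60, 0.5)
        filtered, kept = position_coverage_filter(aln, 1e-9)
        all_missing = np.nonzero(aln.missing_mask.all(axis=0))[0]
        assert set(range(60)) - set(kept.tolist()) == set(all_missing.tolist())

    def test_one_keeps_only_complete_columns(self, rng):
        aln = _masked(rng, 5, 60, 0.3)
        filtered, kept = position_coverage_filter(aln, 1.0)
        assert np.all(~filtered.missing_mask.any(axis=0))
        complete = np.nonzero(~aln.missing_mask.any(axis=0))[0]
        assert kept.tolist() == complete.tolist()

    @pytest.mark.parametrize("frac", [0.25, 0.5, 0.75])
    def test_coverage_monotone_improvement(self, rng, frac):
        aln = _masked(rng, 8, 100, 0.45)
        before = coverage_stats(aln).overall_coverage
        filtered, _ = position_coverage_filter(aln, frac)
        assert coverage_stats(filtered).overall_coverage >= before


class TestGeneAdmission:
    def test_boundaries(self, rng):
        short = random_alignment(rng, 30, 99)
        exact = random_alignment(rng, 25, 100)
        admitted, report = gene_admission_filter([short, exact])
        assert admitted == [exact]
        assert report.admitted == [1]

    def test_taxa_threshold_counts_taxa_with_data(self):
        mat = np.zeros((30, 120), dtype=np.uint8)
        mat[24:, :] = MISSING  # only 24 taxa carry data
        g = Alignment([f"t{i}" for i in range(30)], mat)
        admitted, _ = gene_admission_filter([g])
        assert admitted == []

    def test_empty_input(self):
        admitted, report = gene_admission_filter([])
        assert admitted == [] and report.admitted == []

    def test_recount_oracle(self, rng):
        genes = []
        for _ in range(20):
            n_taxa = int(rng.integers(20, 31))
            n_cols = int(rng.integers(80, 130))
            genes.append(_masked(rng, n_taxa, n_cols, 0.2))
        admitted, _ = gene_admission_filter(genes)
        expected = sum(
            1
            for g in genes
            if g.n_columns >= 100
            and ((~g.missing_mask).sum(axis=1) > 0).sum() >= 25
        )
        assert len(admitted) == expected


class TestSharedMissingOverlap:
    def test_no_missing_all_zero(self, rng):
        aln = random_alignment(rng, 4, 30)
        o = shared_missing_overlap(aln)
        assert np.all(o.o == 0)

    def test_half_shared(self):
        mat = np.zeros((2, 10), dtype=np.uint8)
        mat[:, :5] = MISSING
        aln = Alignment(["a", "b"], mat)
        o = shared_missing_overlap(aln)
        assert o.o[0, 1] == pytest.approx(0.5)

    def test_diagonal_is_own_missing_fraction(self, rng):
        aln = _masked(rng, 5, 50, 0.4)
        o = shared_missing_overlap(aln)
        for i in range(5):
            assert o.o[i, i] == pytest.approx(aln.missing_mask[i].mean())

    def test_set_intersection_oracle(self, rng):
        aln = _masked(rng, 6, 80, 0.35)
        o = shared_missing_overlap(aln)
        for i in range(6):
            for j in range(6):
                si = set(np.nonzero(aln.missing_mask[i])[0])
                sj = set(np.nonzero(aln.missing_mask[j])[0])
                assert o.o[i, j] == pytest.approx(len(si & sj) / 80)

    def test_offdiagonal_mean_drops_after_filter(self, rng):
        aln = _masked(rng, 10, 200, 0.45)
        before = shared_missing_overlap(aln).off_diagonal().mean()
        filtered, _ = position_coverage_filter(aln, 0.5)
        after = shared_missing_overlap(filtered).off_diagonal().mean()
        assert after < before


class TestClusterOverlap:
    def test_three_taxon_hand_case(self):
        o = OverlapMatrix(
            ["t1", "t2", "t3"],
            np.array([[0.5, 0.6, 0.1], [0.6, 0.5, 0.1], [0.1, 0.1, 0.5]]),
        )
        clustering = cluster_overlap(o)
        # t1 and t2 share the most missingness: they merge first
        first = clustering.linkage[0, :2].astype(int).tolist()
        assert sorted(first) == [0, 1]

    def test_degenerate_equal_patterns(self):
        mat = np.zeros((4, 10), dtype=np.uint8)
        mat[:, :3] = MISSING
        aln = Alignment(list("abcd"), mat)
        clustering = cluster_overlap(shared_missing_overlap(aln))
        heights = clustering.linkage[:, 2]
        assert np.allclose(heights, heights[0])

    def test_too_few_taxa(self):
        o = OverlapMatrix(["a", "b"], np.zeros((2, 2)))
        with pytest.raises(AnalysisError):
            cluster_overlap(o)

    def test_planted_block_forms_clan(self, tmp_path):
        aln, tree, truth = make_benchmark(
            "planted_block_missing", tmp_path / "bench", seed=5
        )
        planted = set(truth.spec["planted_missing_taxa"])
        clustering = cluster_overlap(shared_missing_overlap(aln))
        # walk the merges: some cluster must contain exactly the planted taxa
        n = aln.n_taxa
        members = {i: {clustering.labels[i]} for i in range(n)}
        found = False
        for step, (a, b, _h, _c) in enumerate(clustering.linkage):
            merged = members[int(a)] | members[int(b)]
            members[n + step] = merged
            if merged == planted:
                found = True
        assert found

    def test_heatmap_written(self, tmp_path, rng):
        from biasdiag.missingness import plot_overlap_heatmap

        aln = _masked(rng, 6, 50, 0.3)
        o = shared_missing_overlap(aln)
        clustering = cluster_overlap(o)
        out = tmp_path / "heat.png"
        plot_overlap_heatmap(o, clustering, str(out))
        assert out.stat().st_size > 0


class TestMissingOnTree:
    def test_complete_taxon_scores_zero(self, rng):
        tree = random_yule_tree(6, 2)
        aln = random_alignment(rng, 6, 40, missing_prob=0.0)
        aln.matrix[1, :10] = MISSING  # t002 only
        bm = missing_on_tree(aln, tree)
        assert bm.per_node_missing_pct["t001"] == 0.0
        assert bm.per_node_missing_pct["t002"] == pytest.approx(25.0)

    def test_acctran_pulls_loss_rootward(self):
        t = RootedTree.from_newick("((a,b),(c,d));")
        mat = np.zeros((4, 2), dtype=np.uint8)
        mat[0, 0] = MISSING
        mat[1, 0] = MISSING
        aln = Alignment(list("abcd"), mat)
        bm = missing_on_tree(aln, t)
        ab = t.mrca_id(["a", "b"])
        assert bm.per_node_missing_pct[ab] == pytest.approx(50.0)
        assert bm.per_node_missing_pct[t.root_id] == pytest.approx(0.0)

    def test_tip_values_match_observation(self, rng):
        tree = random_yule_tree(8, 4)
        aln = random_alignment(rng, 8, 60, missing_prob=0.3)
        bm = missing_on_tree(aln, tree)
        for lab in aln.taxon_labels:
            assert bm.per_node_missing_pct[lab] == pytest.approx(
                100.0 * (aln.row(lab) == MISSING).mean()
            )

    def test_conservation_against_binary_fitch(self, rng):
        tree = random_yule_tree(7, 6)
        aln = random_alignment(rng, 7, 50, missing_prob=0.4)
        binary = (~aln.missing_mask).astype(np.uint8)
        per_col, total = fitch_length(aln, tree, matrix=binary, n_states=2)
        from biasdiag import acctran_reconstruct

        rec = acctran_reconstruct(
            aln, tree, matrix=binary, n_states=2, state_symbols="01",
            state_preference=[1, 0],
        )
        assert rec.length == total
        # implied changes from the assignment equal the parsimony minimum
        changes = 0
        for nid in tree.postorder_ids():
            parent = tree.parent_id(nid)
            if parent is None:
                continue
            i, j = rec.node_index[nid], rec.node_index[parent]
            changes += int((rec.raw_states[i] != rec.raw_states[j]).sum())
        assert changes == total

    def test_annotated_newick_contains_percentages(self, rng):
        tree = random_yule_tree(5, 1)
        aln = random_alignment(rng, 5, 20, missing_prob=0.3)
        bm = missing_on_tree(aln, tree)
        nwk = bm.annotated_newick()
        assert "missing_pct" in nwk

    def test_tree_plot_written(self, tmp_path, rng):
        from biasdiag.missingness import plot_missing_tree

        tree = random_yule_tree(6, 3)
        aln = random_alignment(rng, 6, 30, missing_prob=0.3)
        bm = missing_on_tree(aln, tree)
        out = tmp_path / "tree.png"
        plot_missing_tree(bm, str(out))
        assert out.stat().st_size > 0
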