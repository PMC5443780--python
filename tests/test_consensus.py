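"""Replicate consensus, BF/SNT Venn bookkeeping and column clustering."""

import io
import itertools

import numpy as np
import pandas as pd
import pytest
from Bio import Phylo

from metasecretome.consensus import (
    VennSummary,
    cluster_heatmap_matrix,
    consensus_filter,
    linkage_to_newick,
    replicate_histogram,
    scale_rows,
    venn_summary,
)
from metasecretome.pipeline import ProteinIdentification


def ident(orf, rep, fraction="BF", sample="WS"):
    return ProteinIdentification(
        orf_id=orf, sample=sample, fraction=fraction, replicate=rep,
        peptides=frozenset({"PEPTIDEK"}),
    )


def presence(orf, reps_bf=(), reps_snt=(), sample="WS"):
    return [ident(orf, r, "BF", sample) for r in reps_bf] + [
        ident(orf, r, "SNT", sample) for r in reps_snt
    ]


class TestConsensusFilter:
    def test_all_replicates_is_consensus(self):
        (cp,) = consensus_filter(presence("o1", reps_bf=(1, 2, 3)), 3)
        assert cp.consensus
        assert cp.fraction_class == "BF-only"

    def test_two_of_three_is_not(self):
        (cp,) = consensus_filter(presence("o1", reps_bf=(1, 3)), 3)
        assert not cp.consensus

    def test_fraction_union_across_replicates(self):
        (cp,) = consensus_filter(
            presence("o1", reps_bf=(1, 2), reps_snt=(3,)), 3
        )
        assert cp.consensus  # overall presence in all three replicates
        assert cp.fraction_class == "both"

    def test_per_fraction_variant_is_stricter(self):
        (cp,) = consensus_filter(
            presence("o1", reps_bf=(1, 2, 3), reps_snt=(1,)), 3,
            per_fraction=True,
        )
        assert cp.fraction_class == "BF-only"

    def test_histogram_matches_planted_matrix(self):
        idents = (
            presence("a", reps_bf=(1, 2, 3))
            + presence("b", reps_bf=(1, 3))
            + presence("c", reps_bf=(2,))
            + presence("d", reps_snt=(1, 2, 3))
        )
        hist = replicate_histogram(consensus_filter(idents, 3), 3)
        bf = hist[hist.fraction == "BF"].set_index("k_of_n")["count"]
        assert bf.to_dict() == {"3/3": 1, "2/3": 1, "1/3": 1}
        snt = hist[hist.fraction == "SNT"].set_index("k_of_n")["count"]
        assert snt.to_dict() == {"3/3": 1}

    def test_consensus_shrinks_as_requirement_rises(self):
        idents = list(
            itertools.chain.from_iterable(
                presence(f"o{k}", reps_bf=tuple(range(1, k + 1)))
                for k in (1, 2, 3)
            )
        )
        cps = consensus_filter(idents, 3)
        # proteins present in >= n replicates shrink monotonically in n
        sizes = [
            sum(len(c.replicate_presence) >= n for c in cps) for n in (1, 2, 3)
        ]
        assert sizes == [3, 2, 1]
        assert sum(c.consensus for c in cps) == 1


class TestVennSummary:
    def test_worked_example_bf_dominant(self):
        # 312 consensus proteins: 239 in BF of which 17 shared with SNT
        idents = []
        for i in range(222):
            idents += presence(f"b{i:03d}", reps_bf=(1, 2, 3))
        for i in range(17):
            idents += presence(f"s{i:03d}", reps_bf=(1, 2, 3), reps_snt=(1,))
        for i in range(73):
            idents += presence(f"n{i:03d}", reps_snt=(1, 2, 3))
        v = venn_summary(consensus_filter(idents, 3))
        assert (v.n_total_consensus, v.n_bf, v.n_snt) == (312, 239, 90)
        assert (v.n_bf_only, v.n_snt_only) == (222, 73)
        assert round(v.pct_shared, 1) == 5.4

    def test_all_shared_is_100pct(self):
        idents = []
        for i in range(10):
            idents += presence(f"o{i}", reps_bf=(1, 2, 3), reps_snt=(1, 2, 3))
        v = venn_summary(consensus_filter(idents, 3))
        assert v.pct_shared == pytest.approx(100.0)

    def test_identity_invariant_on_random_presence(self, rng):
        idents = []
        for i in range(200):
            bf = tuple(r for r in (1, 2, 3) if rng.random() < 0.6)
            snt = tuple(r for r in (1, 2, 3) if rng.random() < 0.4)
            if bf or snt:
                idents += presence(f"o{i:03d}", bf, snt)
        v = venn_summary(consensus_filter(idents, 3))
        assert v.n_bf + v.n_snt - v.n_shared == v.n_total_consensus

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            VennSummary(n_total_consensus=10, n_bf=5, n_snt=4, n_shared=2)


def naive_average_linkage_heights(X):
    """O(n^3) UPGMA oracle: average pairwise Euclidean distance between
    clusters, merging the closest pair; returns sorted merge heights."""
    points = [np.array([x]) for x in X]
    clusters = [[i] for i in range(len(X))]
    heights = []
    while len(clusters) > 1:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                d = np.mean(
                    [
                        np.linalg.norm(X[i] - X[j])
                        for i in clusters[a]
                        for j in clusters[b]
                    ]
                )
                if best is None or d < best[0]:
                    best = (d, a, b)
        d, a, b = best
        heights.append(d)
        merged = clusters[a] + clusters[b]
        clusters = [c for k, c in enumerate(clusters) if k not in (a, b)]
        clusters.append(merged)
    return sorted(heights)


class TestClustering:
    def test_row_zscore_example(self):
        mat = pd.DataFrame([[1.0, 2.0, 3.0]], index=["p"], columns=list("abc"))
        unclipped, _ = scale_rows(mat)
        np.testing.assert_allclose(unclipped.to_numpy(), [[-1.0, 0.0, 1.0]])

    def test_constant_rows_become_zero(self):
        mat = pd.DataFrame([[5.0, 5.0, 5.0]], index=["p"], columns=list("abc"))
        unclipped, _ = scale_rows(mat)
        np.testing.assert_allclose(unclipped.to_numpy(), 0.0)

    def test_clipping_affects_display_only(self, rng):
        mat = pd.DataFrame(rng.uniform(0, 10, size=(30, 6)),
                           columns=[f"r{i}" for i in range(6)])
        unclipped, display = scale_rows(mat)
        assert display.to_numpy().max() <= 2.0
        assert display.to_numpy().min() >= -2.0
        inside = np.abs(unclipped.to_numpy()) <= 2.0
        np.testing.assert_allclose(
            display.to_numpy()[inside], unclipped.to_numpy()[inside]
        )

    def test_identical_columns_merge_first_at_zero(self):
        rng = np.random.default_rng(3)
        base = rng.uniform(0, 5, size=20)
        mat = pd.DataFrame(
            {"a": base, "b": base, "c": rng.uniform(0, 5, size=20),
             "d": rng.uniform(0, 5, size=20)}
        )
        # duplicate columns survive row scaling identically
        _display, link, _labels, _nwk = cluster_heatmap_matrix(mat)
        assert link[0, 2] == pytest.approx(0.0, abs=1e-12)
        assert {int(link[0, 0]), int(link[0, 1])} == {0, 1}

    def test_merge_heights_match_naive_oracle(self, rng):
        for _ in range(5):
            mat = pd.DataFrame(
                rng.uniform(0, 8, size=(50, 6)),
                columns=[f"r{i}" for i in range(6)],
            )
            _display, link, _labels, _nwk = cluster_heatmap_matrix(mat)
            scaled, _ = scale_rows(mat)
            X = scaled.to_numpy().T
            np.testing.assert_allclose(
                sorted(link[:, 2]), naive_average_linkage_heights(X),
                atol=1e-9,
            )

    def test_single_run_skipped_with_warning(self):
        mat = pd.DataFrame({"only": [1.0, 2.0]})
        with pytest.warns(UserWarning):
            display, link, labels, nwk = cluster_heatmap_matrix(mat)
        assert labels == ["only"] and nwk == ""

    def test_newick_is_parseable_with_all_leaves(self, rng):
        mat = pd.DataFrame(rng.uniform(0, 8, size=(40, 6)),
                           columns=[f"run{i}" for i in range(6)])
        _d, _l, _order, nwk = cluster_heatmap_matrix(mat)
        tree = Phylo.read(io.StringIO(nwk), "newick")
        assert sorted(t.name for t in tree.get_terminals()) == sorted(mat.columns)

    def test_fractions_separate_for_disjoint_pools(self, quant_table):
        # default community has 27/30 fraction-exclusive proteins: BF and
        # SNT columns must form the two top-level clusters
        from metasecretome.quant import abundance_matrix

        mat = abundance_matrix(quant_table)
        _d, link, _labels, nwk = cluster_heatmap_matrix(mat)
        tree = Phylo.read(io.StringIO(nwk), "newick")
        top = sorted(
            (
                sorted(t.name for t in clade.get_terminals())
                for clade in tree.root.clades
            ),
            key=len,
        )
        flat = ["".join(sorted({n.split(":")[1] for n in grp})) for grp in top]
        assert flat == ["BF", "SNT"] or flat == ["SNT", "BF"]
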