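import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from qtrimbench.evaluation import (
    build_composition_row,
    composition_table,
    expected_joined_products,
    fp_fn_percent,
    jaccard_matrix,
    pcoa_coordinates,
    pcoa_gold_distance,
)
from qtrimbench.io_formats import ReadRecord


def _read(read_id, seq="ACGT"):
    return ReadRecord(read_id, seq, (40,) * len(seq))


class TestComposition:
    def test_provenance_counts(self):
        reads = [_read("s1.refA.1"), _read("s1.refA.2"), _read("s1.refB.1")]
        counts, unassigned = build_composition_row(reads)
        assert dict(counts) == {"refA": 2, "refB": 1}
        assert unassigned == 0

    def test_provenance_rejects_malformed_id(self):
        with pytest.raises(ValueError, match="oops"):
            build_composition_row([_read("oops")])

    def test_exact_match_assigns_and_counts_unassigned(self, small_refs):
        products = expected_joined_products(small_refs)
        ref = small_refs[0]
        product = ref.amplicon[17 : len(ref.amplicon) - 21]
        mutated = ("A" if product[0] != "A" else "C") + product[1:]
        reads = [_read("x.y.1", product), _read("x.y.2", mutated)]
        counts, unassigned = build_composition_row(
            reads, mode="exact_match", products=products
        )
        assert dict(counts) == {ref.ref_id: 1}
        assert unassigned == 1

    def test_table_drops_all_zero_columns(self):
        table = composition_table(
            {"s1": {"a": 2, "b": 0}, "s2": {"a": 1, "c": 3}}
        )
        assert set(table.columns) == {"a", "c"}
        assert table.loc["s1", "a"] == 2 and table.loc["s2", "c"] == 3


class TestFpFn:
    def test_mixed_sets(self):
        fp, fn = fp_fn_percent({"a", "b", "c"}, {"a", "b", "d"})
        assert fp == pytest.approx(100 / 3)
        assert fn == pytest.approx(100 / 3)

    def test_perfect_recovery(self):
        assert fp_fn_percent({"a", "b"}, {"a", "b"}) == (0.0, 0.0)

    def test_strict_superset(self):
        fp, fn = fp_fn_percent({"a", "b", "c"}, {"a", "b"})
        assert fn == 0.0 and fp > 0.0

    def test_empty_observed(self):
        fp, fn = fp_fn_percent(set(), {"a"})
        assert (fp, fn) == (0.0, 100.0)

    def test_empty_gold_rejected(self):
        with pytest.raises(ValueError):
            fp_fn_percent({"a"}, set())

    def test_invariant_under_relabeling(self):
        obs, gold = {"a", "b", "c"}, {"b", "c", "d"}
        relabel = {k: k.upper() for k in obs | gold}
        assert fp_fn_percent(obs, gold) == fp_fn_percent(
            {relabel[k] for k in obs}, {relabel[k] for k in gold}
        )


class TestJaccard:
    def test_binary_example(self):
        table = pd.DataFrame(
            [[1, 5, 0], [0, 2, 7]], index=["s1", "s2"], columns=["a", "b", "c"]
        )
        dist = jaccard_matrix(table, "binary")
        assert dist.loc["s1", "s2"] == pytest.approx(2 / 3)
        assert dist.loc["s1", "s1"] == 0.0

    def test_identical_and_disjoint_rows(self):
        table = pd.DataFrame(
            [[3, 1, 0], [3, 1, 0], [0, 0, 9]], index=list("xyz"),
            columns=list("abc"),
        )
        dist = jaccard_matrix(table, "binary")
        assert dist.loc["x", "y"] == 0.0
        assert dist.loc["x", "z"] == 1.0

    def test_abundance_variant(self):
        table = pd.DataFrame(
            [[2, 4], [1, 6]], index=["s1", "s2"], columns=["a", "b"]
        )
        dist = jaccard_matrix(table, "abundance")
        # 1 - (min(2,1)+min(4,6)) / (max(2,1)+max(4,6)) = 1 - 5/8
        assert dist.loc["s1", "s2"] == pytest.approx(1 - 5 / 8)

    def test_all_zero_row_rejected(self):
        table = pd.DataFrame([[1, 0], [0, 0]], index=["s1", "s2"])
        with pytest.raises(ValueError, match="s2"):
            jaccard_matrix(table)


@given(
    st.lists(
        st.lists(st.integers(0, 9), min_size=4, max_size=4),
        min_size=2,
        max_size=8,
    ).filter(lambda rows: all(any(r) for r in rows))
)
@settings(max_examples=100, deadline=None)
def test_jaccard_is_a_bounded_symmetric_dissimilarity(rows):
    table = pd.DataFrame(rows)
    for mode in ("binary", "abundance"):
        dist = jaccard_matrix(table, mode).to_numpy()
        assert np.allclose(dist, dist.T)
        assert np.allclose(np.diag(dist), 0)
        assert (dist >= 0).all() and (dist <= 1).all()


class TestPcoa:
    def test_two_points_at_unit_distance(self):
        dist = pd.DataFrame(
            [[0.0, 1.0], [1.0, 0.0]], index=["a", "b"], columns=["a", "b"]
        )
        distances = pcoa_gold_distance(dist, [("a", "b")])
        assert distances[("a", "b")] == pytest.approx(1.0)
        coords = pcoa_coordinates(dist)
        assert np.allclose(np.abs(coords.to_numpy().ravel()), 0.5)

    def test_identical_points_have_zero_distance(self):
        dist = pd.DataFrame(
            [[0, 0, 0.6], [0, 0, 0.6], [0.6, 0.6, 0]],
            index=list("sgt"), columns=list("sgt"),
        )
        assert pcoa_gold_distance(dist, [("s", "g")])[("s", "g")] == pytest.approx(0.0)

    def test_metric_preservation_on_euclidean_input(self, rng):
        """PCoA of a Euclidean distance matrix reproduces every pairwise
        distance (all eigenvalues non-negative)."""
        points = rng.normal(size=(6, 3))
        from scipy.spatial.distance import pdist, squareform

        d = squareform(pdist(points))
        dist = pd.DataFrame(d, index=list("abcdef"), columns=list("abcdef"))
        coords = pcoa_coordinates(dist).to_numpy()
        rebuilt = squareform(pdist(coords))
        assert np.allclose(rebuilt, d, atol=1e-8)

    def test_agrees_with_skbio_ordination(self, rng):
        """Independent cross-check of the embedding against scikit-bio."""
        skbio_pcoa = pytest.importorskip("skbio.stats.ordination").pcoa
        from scipy.spatial.distance import pdist, squareform
        from skbio import DistanceMatrix

        points = rng.normal(size=(7, 4))
        d = squareform(pdist(points))
        ids = [f"s{i}" for i in range(7)]
        dist = pd.DataFrame(d, index=ids, columns=ids)
        ours = pcoa_gold_distance(dist, [("s0", "s1"), ("s2", "s5")])
        theirs = skbio_pcoa(DistanceMatrix(d, ids)).samples.to_numpy()
        for (a, b), value in ours.items():
            i, j = ids.index(a), ids.index(b)
            assert value == pytest.approx(
                float(np.linalg.norm(theirs[i] - theirs[j])), abs=1e-6
            )

    def test_asymmetric_input_rejected(self):
        dist = pd.DataFrame([[0, 1], [2, 0]], index=["a", "b"], columns=["a", "b"])
        with pytest.raises(ValueError):
            pcoa_coordinates(dist)
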