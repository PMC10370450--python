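"""Cross-prediction, relation resolution, and progressive tree updates."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from celltypetree import (
    DatasetSpec,
    HierarchyBuilder,
    LabeledEmbedding,
    SyntheticConfig,
    ValidationError,
    binarize,
    build_hierarchy,
    create_tree,
    generate,
    resolve_relations,
)
from celltypetree.knn import REJECTED

VERDICTS = {"perfect", "subpopulation", "merge", "new_root_child", "unresolved"}


class TestBinarize:
    def test_threshold_comparison(self):
        conf = pd.DataFrame(
            [[0.6, 0.1, 0.3]], index=["L"], columns=["A1", "A2", REJECTED]
        )
        b = binarize(conf, 0.25)
        assert b.loc["L"].tolist() == [True, False, True]

    def test_identity_confusion(self):
        conf = pd.DataFrame(np.eye(3), index=list("XYZ"), columns=list("XYZ"))
        assert np.array_equal(binarize(conf).to_numpy(), np.eye(3, dtype=bool))

    def test_even_split_matches_both(self):
        conf = pd.DataFrame([[0.5, 0.5]], index=["L"], columns=["A", "B"])
        assert binarize(conf).loc["L"].all()

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.1, 1.5])
    def test_threshold_domain(self, bad):
        conf = pd.DataFrame([[1.0]], index=["L"], columns=["A"])
        with pytest.raises(ValueError):
            binarize(conf, bad)


def flat_tree(names):
    t = create_tree("root")
    for n in names:
        t.add_node("root", [("ref", n)])
    return t


def bmat(rows, cols, true_pairs):
    df = pd.DataFrame(False, index=rows, columns=cols + [REJECTED])
    for r, c in true_pairs:
        df.loc[r, c] = True
    return df


class TestResolveRelations:
    def test_identity_all_perfect(self):
        tree = flat_tree(["X", "Y", "Z"])
        fwd = bmat(["X", "Y", "Z"], ["X", "Y", "Z"], [("X", "X"), ("Y", "Y"), ("Z", "Z")])
        rev = bmat(["X", "Y", "Z"], ["X", "Y", "Z"], [("X", "X"), ("Y", "Y"), ("Z", "Z")])
        rel = resolve_relations(fwd, rev, tree)
        assert all(v == ("perfect", n) for n, v in rel.verdicts.items())

    def test_subpopulation_group(self):
        """CD4 and CD8 each map only to T; T spreads over both."""
        tree = flat_tree(["T", "B"])
        fwd = bmat(["CD4", "CD8", "B"], ["T", "B"],
                   [("CD4", "T"), ("CD8", "T"), ("B", "B")])
        rev = bmat(["T", "B"], ["CD4", "CD8", "B"],
                   [("T", "CD4"), ("T", "CD8"), ("B", "B")])
        rel = resolve_relations(fwd, rev, tree)
        assert rel.verdicts["CD4"] == ("subpopulation", "T")
        assert rel.verdicts["CD8"] == ("subpopulation", "T")
        assert rel.verdicts["B"] == ("perfect", "B")

    def test_small_label_absent_from_reverse_is_subpopulation(self):
        """A tiny new type mapping wholly into N refines N even when N's
        reverse row never crosses the threshold for it."""
        tree = flat_tree(["N"])
        fwd = bmat(["tiny"], ["N"], [("tiny", "N")])
        rev = bmat(["N"], ["tiny"], [])
        rel = resolve_relations(fwd, rev, tree)
        assert rel.verdicts["tiny"] == ("subpopulation", "N")

    def test_merge_of_siblings(self):
        tree = flat_tree(["N1", "N2", "N3"])
        fwd = bmat(["L", "M"], ["N1", "N2", "N3"],
                   [("L", "N1"), ("L", "N2"), ("M", "N3")])
        rev = bmat(["N1", "N2", "N3"], ["L", "M"],
                   [("N1", "L"), ("N2", "L"), ("N3", "M")])
        rel = resolve_relations(fwd, rev, tree)
        assert rel.verdicts["L"] == ("merge", ("N1", "N2"))
        assert rel.verdicts["M"] == ("perfect", "N3")

    def test_rejected_both_ways_is_new(self):
        tree = flat_tree(["N"])
        fwd = bmat(["nov", "N"], ["N"], [("nov", REJECTED), ("N", "N")])
        rev = bmat(["N"], ["nov", "N"], [("N", "N")])
        rel = resolve_relations(fwd, rev, tree)
        assert rel.verdicts["nov"] == ("new_root_child", None)

    def test_non_sibling_span_unresolved(self):
        tree = create_tree("root")
        tree.add_node("root", [("ref", "N1")])
        tree.add_node("N1", [("ref", "N2")])
        fwd = bmat(["L"], ["N1", "N2"], [("L", "N1"), ("L", "N2")])
        rev = bmat(["N1", "N2"], ["L"], [("N1", "L"), ("N2", "L")])
        rel = resolve_relations(fwd, rev, tree)
        assert rel.verdicts["L"] == ("unresolved", None)

    def test_crossing_many_to_many_unresolved(self):
        tree = flat_tree(["N1", "N2"])
        fwd = bmat(["L1", "L2"], ["N1", "N2"],
                   [("L1", "N1"), ("L2", "N1"), ("L2", "N2")])
        rev = bmat(["N1", "N2"], ["L1", "L2"],
                   [("N1", "L1"), ("N1", "L2"), ("N2", "L2")])
        rel = resolve_relations(fwd, rev, tree)
        assert rel.verdicts["L1"] == ("unresolved", None)
        assert rel.verdicts["L2"] == ("unresolved", None)

    def test_rejected_forward_but_claimed_in_reverse_unresolved(self):
        tree = flat_tree(["N"])
        fwd = bmat(["L"], ["N"], [("L", REJECTED)])
        rev = bmat(["N"], ["L"], [("N", "L")])
        assert resolve_relations(fwd, rev, tree).verdicts["L"] == ("unresolved", None)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.integers(0, 2 ** 12 - 1), st.integers(0, 2 ** 12 - 1))
    def test_partition_is_exhaustive_and_exclusive(self, fbits, rbits):
        """Every 3x3 binary cross-prediction pattern maps to exactly one of
        the five verdicts (enumerated by bit pattern)."""
        labels, nodes = ["L1", "L2", "L3"], ["N1", "N2", "N3"]
        tree = flat_tree(nodes)
        fwd = bmat(labels, nodes, [])
        rev = bmat(nodes, labels, [])
        cols_f = nodes + [REJECTED]
        cols_r = labels + [REJECTED]
        for i, lab in enumerate(labels):
            for j, c in enumerate(cols_f):
                fwd.loc[lab, c] = bool((fbits >> (i * 4 + j)) & 1)
        for i, n in enumerate(nodes):
            for j, c in enumerate(cols_r):
                rev.loc[n, c] = bool((rbits >> (i * 4 + j)) & 1)
        rel = resolve_relations(fwd, rev, tree)
        assert set(rel.verdicts) == set(labels)
        for verdict, _ in rel.verdicts.values():
            assert verdict in VERDICTS


def two_blob_embedding(rng, ds_id, labels=("P", "Q"), sep=12.0, n=80, d=6):
    X, y = [], []
    for i, lab in enumerate(labels):
        mu = np.zeros(d)
        mu[i % d] = sep * (1 + i // d)
        X.append(mu + rng.standard_normal((n, d)))
        y.extend([lab] * n)
    ids = [f"{ds_id}:{i}" for i in range(len(y))]
    return LabeledEmbedding(ds_id, np.vstack(X), ids, np.array(y, dtype=object))


class TestBuilder:
    def test_single_dataset_flat_tree(self, rng):
        ds = two_blob_embedding(rng, "d1", labels=("A", "B", "C"))
        builder = build_hierarchy([ds], k=20)
        assert {c.display_name for c in builder.tree_.root.children} == {"A", "B", "C"}

    def test_empty_dataset_list(self):
        with pytest.raises(ValueError):
            build_hierarchy([])

    def test_identical_second_dataset_all_perfect(self, rng):
        d1 = two_blob_embedding(rng, "d1")
        d2 = two_blob_embedding(rng, "d2")
        builder = build_hierarchy([d1, d2], k=20)
        report = builder.reports_[0]
        assert set(report.verdict) == {"perfect"}
        # shape unchanged, every node gained an alias
        for child in builder.tree_.root.children:
            assert len(child.aliases) == 2
            assert child.is_leaf()

    def test_dimension_mismatch_rejected(self, rng):
        d1 = two_blob_embedding(rng, "d1", d=6)
        d2 = two_blob_embedding(rng, "d2", d=5)
        with pytest.raises(ValidationError):
            build_hierarchy([d1, d2], k=20)

    def test_unlabeled_dataset_rejected(self, rng):
        d1 = two_blob_embedding(rng, "d1")
        q = LabeledEmbedding("q", d1.X, [f"q{i}" for i in range(d1.n_cells)])
        with pytest.raises(ValidationError):
            build_hierarchy([q])

    def test_coarse_label_merges_fine_nodes(self, rng):
        """Adding a coarser relabeling after the fine one inserts the
        coarse label as a parent of its fine populations."""
        cfg = SyntheticConfig(
            tree_spec={
                "name": "root",
                "children": [
                    {
                        "name": "T",
                        "children": [
                            {"name": "CD4", "weight": 0.3},
                            {"name": "CD8", "weight": 0.3},
                        ],
                    },
                    {"name": "B", "weight": 0.4},
                ],
            },
            datasets=[
                DatasetSpec("fine"),
                DatasetSpec("coarse", resolution_map={"CD4": "T", "CD8": "T"}),
            ],
            n_cells=300, d=8, separation=8.0, seed=1,
        )
        embs, _ = generate(cfg)
        builder = build_hierarchy(embs)
        report = builder.reports_[0]
        assert report.set_index("label").loc["T", "verdict"] == "merge"
        t_node = builder.tree_.find("T")
        assert {c.display_name for c in t_node.children} == {"CD4", "CD8"}
        assert builder.tree_.find("B").is_leaf()

    def test_conservation_after_updates(self, ladder, ladder_builder):
        """Every label of every incorporated dataset ends housed or missing."""
        amap = ladder_builder.tree_.alias_map()
        for emb in ladder["embeddings"][:3]:
            for label in emb.label_set():
                alias = (emb.dataset_id, label)
                housed = alias in amap
                missing = alias in ladder_builder.tree_.missing
                assert housed ^ missing

    def test_perfect_match_symmetry(self, rng):
        d1 = two_blob_embedding(rng, "d1")
        d2 = two_blob_embedding(rng, "d2")
        b12 = build_hierarchy([d1, d2], k=20)
        b21 = build_hierarchy([d2, d1], k=20)
        pairs12 = {frozenset(n.aliases) for n in b12.tree_.root.descendants()}
        pairs21 = {frozenset(n.aliases) for n in b21.tree_.root.descendants()}
        assert pairs12 == pairs21

    def test_confusion_rows_sum_to_one(self, ladder):
        builder = build_hierarchy(ladder["embeddings"][:1])
        fwd, rev = builder.cross_predict(ladder["embeddings"][1])
        assert np.allclose(fwd.sum(axis=1), 1.0, atol=1e-9)
        assert np.allclose(rev.sum(axis=1), 1.0, atol=1e-9)
        assert (fwd.to_numpy() >= 0).all()

    def test_self_cross_prediction_is_near_identity(self, rng):
        """A dataset cross-predicted against a tree built from itself gives
        a diagonal confusion matrix (well-separated classes)."""
        d1 = two_blob_embedding(rng, "d1", labels=("A", "B", "C"))
        builder = build_hierarchy([d1], k=20)
        fwd, _ = builder.cross_predict(
            LabeledEmbedding("copy", d1.X, d1.cell_ids, d1.labels)
        )
        for lab in ("A", "B", "C"):
            assert fwd.loc[lab, lab] > 0.95

    def test_far_cluster_rejected_row(self, rng):
        d1 = two_blob_embedding(rng, "d1")
        X = np.vstack([d1.X, np.full((40, 6), 80.0)])
        y = np.concatenate([d1.labels, np.full(40, "far", dtype=object)])
        ids = [f"x{i}" for i in range(len(y))]
        builder = build_hierarchy([d1], k=20)
        fwd, _ = builder.cross_predict(LabeledEmbedding("d2", X, ids, y))
        assert fwd.loc["far", REJECTED] > 0.95
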