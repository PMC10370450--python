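"""Cross-dataset cell-type matching and progressive hierarchy building.

Given a hierarchy learned from previously incorporated datasets and one new
labeled dataset sharing the same latent space, the matcher cross-predicts
labels in both directions -- the tree's hierarchical classifier annotates
the new cells, and a flat kNN classifier trained on the new dataset
annotates the tree's pooled training cells -- tabulates both confusion
matrices, binarizes them, and resolves each new label against the tree:

- *perfect*: reciprocal one-to-one match; the label becomes an alias of the
  existing node;
- *subpopulation*: the new label maps wholly into one node that spreads
  over several new labels; each becomes a child of that node;
- *merge*: the new label covers several sibling nodes that each map back
  to it alone; a new node adopts them as children;
- *new_root_child*: the label is rejected in both directions; a new cell
  type attached to the root;
- *unresolved*: any crossing many-to-many pattern; the label is reported
  as missing rather than forced into the tree, and its cells never enter
  classifier training pools.

After every update each internal node's classifier is refit on the pooled
cells housed at or below its children.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .errors import StateError, ValidationError
from .io import LabeledEmbedding
from .knn import REJECTED, KNNRejectClassifier
from .predict import PredictionResult, predict_tree
from .tree import CellTypeNode, HierarchyTree


@dataclass
class RelationSet:
    """Resolved verdict per incoming label.

    ``verdicts`` maps each new label to a (verdict, payload) pair where the
    payload is the matched node name (perfect / subpopulation), the tuple
    of merged sibling names (merge), or ``None``.
    """

    verdicts: dict[str, tuple[str, object]] = field(default_factory=dict)


class HierarchyBuilder(BaseEstimator):
    """Progressively build and update a cell-type hierarchy.

    The estimator is fit on an ordered list of labeled embeddings: the
    first dataset seeds a flat tree (one child of the root per label), each
    later dataset is matched against the current tree and folded in.  After
    fitting, the builder doubles as a hierarchical classifier for query
    cells (:meth:`predict`).

    Parameters mirror :class:`~celltypetree.knn.KNNRejectClassifier`, plus
    ``match_threshold`` -- the row fraction of a binarized confusion matrix
    above which a label and a node are considered matched.

    Attributes
    ----------
    tree_ : HierarchyTree
    datasets_ : dict of dataset_id -> LabeledEmbedding
    reports_ : list of per-update verdict DataFrames
    """

    def __init__(self, k=50, dynamic_neighbors=True, tau_posterior=0.5,
                 fn_rate=0.005, variance_kept=0.9, n_folds=5,
                 metric="euclidean", reject_distance=True,
                 reject_reconstruction=True, reject_posterior=True,
                 match_threshold=0.25, root_name="root", random_state=0):
        self.k = k
        self.dynamic_neighbors = dynamic_neighbors
        self.tau_posterior = tau_posterior
        self.fn_rate = fn_rate
        self.variance_kept = variance_kept
        self.n_folds = n_folds
        self.metric = metric
        self.reject_distance = reject_distance
        self.reject_reconstruction = reject_reconstruction
        self.reject_posterior = reject_posterior
        self.match_threshold = match_threshold
        self.root_name = root_name
        self.random_state = random_state

    # ----------------------------------------------------------- plumbing

    def _knn_params(self) -> dict:
        return dict(
            k=self.k, dynamic_neighbors=self.dynamic_neighbors,
            tau_posterior=self.tau_posterior, fn_rate=self.fn_rate,
            variance_kept=self.variance_kept, n_folds=self.n_folds,
            metric=self.metric, reject_distance=self.reject_distance,
            reject_reconstruction=self.reject_reconstruction,
            reject_posterior=self.reject_posterior,
            random_state=self.random_state,
        )

    def _check_dataset(self, ds: LabeledEmbedding, need_labels=True):
        if need_labels and not ds.is_labeled:
            raise ValidationError(f"dataset {ds.dataset_id!r} is unlabeled")
        if self.datasets_:
            d0 = next(iter(self.datasets_.values())).d
            if ds.d != d0:
                raise ValidationError(
                    f"dataset {ds.dataset_id!r} has d={ds.d}, tree uses d={d0}; "
                    "all datasets must share one latent space"
                )
        if ds.dataset_id in self.datasets_:
            raise ValidationError(f"dataset {ds.dataset_id!r} already incorporated")

    # ---------------------------------------------------------------- fit

    def fit(self, datasets: list[LabeledEmbedding]):
        """Build the hierarchy from an ordered list of labeled datasets."""
        if not datasets:
            raise ValueError("need at least one dataset")
        self.tree_ = HierarchyTree(self.root_name)
        self.datasets_ = {}
        self.reports_ = []
        first = datasets[0]
        self._check_dataset(first)
        for label in first.label_set():
            self.tree_.add_node(self.root_name, [(first.dataset_id, label)])
        self.tree_.dataset_ids.append(first.dataset_id)
        self.datasets_[first.dataset_id] = first
        self.refit_classifiers()
        for ds in datasets[1:]:
            self.update(ds)
        return self

    # ------------------------------------------------------ training pools

    def _cells_by_node(self) -> dict[str, list[np.ndarray]]:
        """Latent rows housed at each node (unresolved labels excluded)."""
        amap = self.tree_.alias_map()
        pools: dict[str, list[np.ndarray]] = {}
        for ds_id, emb in self.datasets_.items():
            for label in emb.label_set():
                node = amap.get((ds_id, label))
                if node is None:
                    continue  # missing / unresolved label
                rows = emb.X[emb.labels == label]
                pools.setdefault(node.display_name, []).append(rows)
        return pools

    def _subtree_matrix(self, node: CellTypeNode, pools) -> np.ndarray:
        blocks = []
        for n in [node, *node.descendants()]:
            blocks.extend(pools.get(n.display_name, []))
        if not blocks:
            return np.empty((0, next(iter(self.datasets_.values())).d))
        return np.vstack(blocks)

    def refit_classifiers(self) -> None:
        """Refit the classifier of every internal node with >= 2 children.

        A node's classes are its direct children; each child's training
        pool is every cell housed at or below it.  Cells carrying a coarse
        label housed at an internal node train only that node's parent
        (they are not split across the node's children).
        """
        pools = self._cells_by_node()
        for node in self.tree_.nodes():
            if len(node.children) < 2:
                node.classifier_ref = None
                continue
            X_parts, y_parts = [], []
            for child in node.children:
                Xc = self._subtree_matrix(child, pools)
                if Xc.shape[0] == 0:
                    raise ValidationError(
                        f"child {child.display_name!r} has no training cells"
                    )
                X_parts.append(Xc)
                y_parts.append(
                    np.full(Xc.shape[0], child.display_name, dtype=object)
                )
            clf = KNNRejectClassifier(**self._knn_params())
            clf.fit(np.vstack(X_parts), np.concatenate(y_parts))
            node.classifier_ref = clf

    def pooled_training(self) -> tuple[np.ndarray, np.ndarray]:
        """All housed cells and the display name of the node housing them."""
        pools = self._cells_by_node()
        X_parts, names = [], []
        for node_name, blocks in pools.items():
            for b in blocks:
                X_parts.append(b)
                names.append(np.full(b.shape[0], node_name, dtype=object))
        return np.vstack(X_parts), np.concatenate(names)

    # ------------------------------------------------------------ predict

    def predict_result(self, Q, cell_ids=None) -> PredictionResult:
        if not hasattr(self, "tree_"):
            raise StateError("builder is not fitted")
        if isinstance(Q, LabeledEmbedding):
            return predict_tree(self.tree_, Q.X, Q.cell_ids)
        return predict_tree(self.tree_, Q, cell_ids)

    def predict(self, Q) -> np.ndarray:
        """Deepest accepted node name per query cell, ``"REJECTED"`` where a
        novelty criterion fired at any level (ambiguity keeps the partial
        label)."""
        res = self.predict_result(Q)
        out = res.final_labels.copy()
        out[res.rejected] = REJECTED
        return out

    # ------------------------------------------------------------- update

    def cross_predict(self, ds: LabeledEmbedding):
        """Row-normalized confusion matrices in both directions.

        Forward (tree -> ds): the hierarchical classifier annotates the new
        cells; rows are the new labels, columns tree node names + REJECTED.
        Reverse (ds -> tree): a flat kNN trained on the new dataset
        annotates the tree's pooled cells; rows are node names, columns the
        new labels + REJECTED.
        """
        if not hasattr(self, "tree_"):
            raise StateError("builder is not fitted")
        if ds.d != next(iter(self.datasets_.values())).d:
            raise ValidationError("latent dimension mismatch")
        node_names = [n.display_name for n in self.tree_.nodes(include_root=False)]
        ds_labels = ds.label_set()

        res = self.predict_result(ds)
        fwd_pred = res.final_labels.copy()
        fwd_pred[res.rejected] = REJECTED
        fwd = pd.DataFrame(
            0.0, index=ds_labels, columns=node_names + [REJECTED]
        )
        for label in ds_labels:
            preds, counts = np.unique(
                fwd_pred[ds.labels == label], return_counts=True
            )
            for p, c in zip(preds, counts):
                fwd.loc[label, p] += c
        fwd = fwd.div(fwd.sum(axis=1), axis=0)

        flat = KNNRejectClassifier(**self._knn_params())
        flat.fit(ds.X, ds.labels)
        pool_X, pool_names = self.pooled_training()
        rev_pred = flat.predict(pool_X)
        rev = pd.DataFrame(
            0.0, index=node_names, columns=ds_labels + [REJECTED]
        )
        for name in node_names:
            mask = pool_names == name
            if not mask.any():
                # node with no direct cells of its own cannot occur: every
                # non-root node houses at least one labeled alias
                continue
            preds, counts = np.unique(rev_pred[mask], return_counts=True)
            for p, c in zip(preds, counts):
                rev.loc[name, p] += c
        rev = rev.div(rev.sum(axis=1), axis=0)
        return fwd, rev

    def update(self, ds: LabeledEmbedding) -> pd.DataFrame:
        """Match a new labeled dataset against the tree and fold it in."""
        if not hasattr(self, "tree_"):
            raise StateError("builder is not fitted; call fit first")
        self._check_dataset(ds)
        fwd, rev = self.cross_predict(ds)
        bin_fwd = binarize(fwd, self.match_threshold)
        bin_rev = binarize(rev, self.match_threshold)
        relations = resolve_relations(bin_fwd, bin_rev, self.tree_)
        report = self._apply(relations, ds)
        self.tree_.dataset_ids.append(ds.dataset_id)
        self.datasets_[ds.dataset_id] = ds
        self.refit_classifiers()
        self.tree_.check_invariants()
        self.reports_.append(report)
        return report

    def _apply(self, relations: RelationSet, ds: LabeledEmbedding) -> pd.DataFrame:
        rows = []
        order = {"perfect": 0, "merge": 1, "subpopulation": 2,
                 "new_root_child": 3, "unresolved": 4}
        items = sorted(
            relations.verdicts.items(), key=lambda kv: order[kv[1][0]]
        )
        for label, (verdict, payload) in items:
            alias = (ds.dataset_id, label)
            placed = ""
            if verdict == "perfect":
                self.tree_.merge_alias(payload, alias)
                placed = payload
            elif verdict == "merge":
                siblings = list(payload)
                try:
                    node = self.tree_.insert_parent(siblings, [alias])
                    placed = node.parent.display_name
                except ValueError:
                    # a concurrent merge broke the sibling group
                    verdict = "unresolved"
                    self.tree_.missing.append(alias)
            elif verdict == "subpopulation":
                self.tree_.add_node(payload, [alias])
                placed = payload
            elif verdict == "new_root_child":
                self.tree_.add_node(self.tree_.root.display_name, [alias])
                placed = self.tree_.root.display_name
            else:  # unresolved
                self.tree_.missing.append(alias)
            rows.append(
                {"label": label, "verdict": verdict, "placed_under": placed}
            )
        return pd.DataFrame(rows, columns=["label", "verdict", "placed_under"])


# --------------------------------------------------------- pure operations


def binarize(conf: pd.DataFrame, match_threshold: float = 0.25) -> pd.DataFrame:
    """Threshold a row-normalized confusion matrix into a match matrix."""
    if not 0.0 < match_threshold < 1.0:
        raise ValueError("match_threshold must lie strictly between 0 and 1")
    return conf.ge(match_threshold)


def resolve_relations(bin_fwd: pd.DataFrame, bin_rev: pd.DataFrame,
                      tree: HierarchyTree) -> RelationSet:
    """Reduce the binarized cross-prediction pattern to per-label verdicts.

    Every label receives exactly one verdict; patterns that are not
    reducible to perfect / subpopulation / merge / new (crossing
    many-to-many, matches spanning non-sibling nodes) come out unresolved.
    """
    fwd_matches = {
        label: set(bin_fwd.columns[bin_fwd.loc[label]]) - {REJECTED}
        for label in bin_fwd.index
    }
    rev_matches = {
        name: set(bin_rev.columns[bin_rev.loc[name]]) - {REJECTED}
        for name in bin_rev.index
    }
    out = RelationSet()
    for label, f in fwd_matches.items():
        rev_has = {n for n, s in rev_matches.items() if label in s}
        if not f:
            if not rev_has:
                out.verdicts[label] = ("new_root_child", None)
            else:
                out.verdicts[label] = ("unresolved", None)
        elif len(f) == 1:
            (node,) = f
            back = rev_matches.get(node, set())
            if back == {label}:
                out.verdicts[label] = ("perfect", node)
            elif all(fwd_matches.get(lp, set()) == {node} for lp in back):
                # the node spreads over a group of new labels, each of
                # which maps only into it: the group refines the node
                out.verdicts[label] = ("subpopulation", node)
            else:
                out.verdicts[label] = ("unresolved", None)
        else:
            nodes = []
            ok = True
            for name in f:
                try:
                    nodes.append(tree.find(name))
                except KeyError:
                    ok = False
                    break
            siblings = ok and len({id(n.parent) for n in nodes}) == 1
            exclusive = all(rev_matches.get(n, set()) == {label} for n in f)
            if siblings and exclusive:
                out.verdicts[label] = ("merge", tuple(sorted(f)))
            else:
                out.verdicts[label] = ("unresolved", None)
    return out


def cross_predict(builder: HierarchyBuilder, ds: LabeledEmbedding):
    return builder.cross_predict(ds)


def update_tree(builder: HierarchyBuilder, ds: LabeledEmbedding) -> pd.DataFrame:
    return builder.update(ds)


def build_hierarchy(datasets: list[LabeledEmbedding], **params) -> HierarchyBuilder:
    """Build a hierarchy progressively over ``datasets`` (given order)."""
    return HierarchyBuilder(**params).fit(datasets)
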