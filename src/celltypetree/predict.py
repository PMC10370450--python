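"""Top-down hierarchical label transfer with rejection.

A query cell starts at the root and descends: at each internal node the
node's classifier either assigns it to a child (descend), rejects it by
distance or reconstruction error (terminal: the cell is flagged as
potentially novel), or rejects it by posterior (ambiguity: the cell keeps
the current node's coarser label -- a partial annotation -- except at the
root, where there is no label to keep and the cell is rejected outright).
Single-child pass-through nodes are descended unconditionally.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np

from .errors import StateError, ValidationError
from .knn import REJECTED
from .tree import HierarchyTree


@dataclass
class PredictionResult:
    """Per-cell outcome of hierarchical prediction.

    ``paths`` lists the accepted root-to-node chain per cell (empty when the
    cell was rejected at the root); ``final_labels`` is the deepest accepted
    node, or ``"REJECTED"``; ``level_records`` keeps, per cell, one
    (node_name, chosen_label, winning_posterior) triple per classifier the
    cell passed through, for audit.
    """

    cell_ids: np.ndarray
    paths: list[list[str]]
    final_labels: np.ndarray
    rejected: np.ndarray
    reasons: np.ndarray
    level_records: list[list[tuple[str, str, float]]] = field(default_factory=list)


def predict_tree(tree: HierarchyTree, Q, cell_ids=None) -> PredictionResult:
    """Annotate query cells with the learned hierarchy.

    Requires every internal node with >= 2 children to carry a fitted
    classifier (``classifier_ref``).
    """
    Q = np.asarray(Q, dtype=np.float64)
    if Q.ndim != 2:
        raise ValidationError("Q must be a cells x d matrix")
    m = Q.shape[0]
    if cell_ids is None:
        cell_ids = np.array([f"cell:{i}" for i in range(m)], dtype=object)

    root_name = tree.root.display_name
    paths: list[list[str]] = [[root_name] for _ in range(m)]
    final = np.full(m, root_name, dtype=object)
    rejected = np.zeros(m, dtype=bool)
    reasons = np.full(m, "", dtype=object)
    levels: list[list[tuple[str, str, float]]] = [[] for _ in range(m)]

    stack: list[tuple[object, np.ndarray]] = [(tree.root, np.arange(m))]
    while stack:
        node, idx = stack.pop()
        if idx.size == 0 or not node.children:
            continue
        if len(node.children) == 1:
            # pass-through: descend unconditionally
            child = node.children[0]
            for i in idx:
                paths[i].append(child.display_name)
            final[idx] = child.display_name
            stack.append((child, idx))
            continue
        clf = node.classifier_ref
        if clf is None:
            raise StateError(
                f"internal node {node.display_name!r} has no fitted classifier"
            )
        out = clf.classify(Q[idx])
        at_root = node is tree.root
        child_by_name = {c.display_name: c for c in node.children}
        routed: dict[str, list[int]] = {c: [] for c in child_by_name}
        for j, i in enumerate(idx):
            levels[i].append(
                (node.display_name, str(out["labels"][j]),
                 float(out["best_posterior"][j]))
            )
            if out["rejected"][j]:
                reason = out["reasons"][j]
                if reason == "posterior" and not at_root:
                    # ambiguity: keep the coarse label of the current node
                    final[i] = node.display_name
                else:
                    rejected[i] = True
                    reasons[i] = reason
                    if at_root:
                        paths[i] = []
                        final[i] = REJECTED
                    else:
                        final[i] = node.display_name
            else:
                routed[out["labels"][j]].append(i)
        for name, cells in routed.items():
            if not cells:
                continue
            cells = np.asarray(cells)
            child = child_by_name[name]
            for i in cells:
                paths[i].append(name)
            final[cells] = name
            if child.children:
                stack.append((child, cells))
    return PredictionResult(
        cell_ids=np.asarray(cell_ids, dtype=object),
        paths=paths,
        final_labels=final,
        rejected=rejected,
        reasons=reasons,
        level_records=levels,
    )


@dataclass
class AgreementReport:
    """How predictions under an updated hierarchy relate to earlier ones.

    Fractions are exact rationals over the cell count, so they sum to 1
    exactly.
    """

    n: int
    unchanged: Fraction
    refined: Fraction
    changed: Fraction

    def as_floats(self) -> dict[str, float]:
        return {
            "unchanged": float(self.unchanged),
            "refined": float(self.refined),
            "changed": float(self.changed),
        }

    def to_text(self) -> str:
        f = self.as_floats()
        return "\n".join(f"{k}: {v:.4f}" for k, v in f.items())


def prediction_agreement(pred_old, pred_new, tree_new: HierarchyTree) -> AgreementReport:
    """Classify per-cell prediction pairs as unchanged, refined (the new
    label is a strict descendant of the old one), or changed."""
    pred_old = np.asarray(pred_old, dtype=object)
    pred_new = np.asarray(pred_new, dtype=object)
    if pred_old.shape != pred_new.shape:
        raise ValidationError("prediction vectors must have equal length")
    known = {n.display_name for n in tree_new.nodes()} | {REJECTED}
    for lab in set(pred_old) | set(pred_new):
        if lab not in known:
            raise ValidationError(f"label {lab!r} not in tree")
    n = pred_old.shape[0]
    unchanged = refined = 0
    for old, new in zip(pred_old, pred_new):
        if old == new:
            unchanged += 1
        elif old != REJECTED and new != REJECTED and tree_new.is_ancestor(old, new):
            refined += 1
    changed = n - unchanged - refined
    return AgreementReport(
        n=n,
        unchanged=Fraction(unchanged, n),
        refined=Fraction(refined, n),
        changed=Fraction(changed, n),
    )
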