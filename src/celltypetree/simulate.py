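"""Synthetic latent-space datasets with a known cell-type hierarchy.

Emulates the output of a batch-corrected integration model: each cell type
is an isotropic Gaussian cluster (unit within-cluster sigma) in a shared
d-dimensional latent space, cluster means drift hierarchically (a child
mean sits at a fixed ``separation`` from its parent mean, in sigma units,
in a random direction), datasets may annotate the same cells at different
resolutions (a leaf's cells relabeled with an ancestor's name), carry
dataset-specific novel clusters placed far from everything else, and may
be translated by a residual batch shift.

Counts, dropout, and the integration model itself are deliberately not
simulated; the generator produces exactly what the downstream matching
machinery consumes, together with the ground-truth hierarchy for
evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import ValidationError
from .io import LabeledEmbedding
from .tree import EdgeGraph, HierarchyTree

#: minimum spacing between any two real cluster means, in separation units
_MIN_SPACING = 0.9
#: minimum spacing between a novel-cluster mean and any real mean,
#: in separation units
_NOVEL_SPACING = 1.0


@dataclass
class DatasetSpec:
    """One dataset's annotation scheme.

    ``resolution_map`` relabels leaf cell types to one of their ancestors
    (coarser annotation); ``novel_clusters`` lists dataset-specific types
    as (name, mean_offset_sigma, n_cells) triples.
    """

    dataset_id: str
    resolution_map: dict[str, str] = field(default_factory=dict)
    novel_clusters: list[tuple[str, float, int]] = field(default_factory=list)


@dataclass
class SyntheticConfig:
    """Full description of a simulated study.

    ``tree_spec`` is a nested dict: internal nodes carry ``name`` and
    ``children``; leaves carry ``name`` and a positive mixing ``weight``.
    ``separation`` is the parent-child mean distance in within-cluster
    sigma units; ``batch_shift`` translates each dataset by a random
    direction of that magnitude (0 = perfectly integrated).
    """

    tree_spec: dict
    datasets: list[DatasetSpec]
    d: int = 10
    separation: float = 8.0
    n_cells: int = 1200
    batch_shift: float = 0.0
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "tree_spec": self.tree_spec,
            "datasets": [
                {
                    "dataset_id": s.dataset_id,
                    "resolution_map": s.resolution_map,
                    "novel_clusters": [list(t) for t in s.novel_clusters],
                }
                for s in self.datasets
            ],
            "d": self.d,
            "separation": self.separation,
            "n_cells": self.n_cells,
            "batch_shift": self.batch_shift,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "SyntheticConfig":
        datasets = [
            DatasetSpec(
                dataset_id=s["dataset_id"],
                resolution_map=dict(s.get("resolution_map", {})),
                novel_clusters=[tuple(t) for t in s.get("novel_clusters", [])],
            )
            for s in payload["datasets"]
        ]
        return cls(
            tree_spec=payload["tree_spec"],
            datasets=datasets,
            d=int(payload.get("d", 10)),
            separation=float(payload.get("separation", 8.0)),
            n_cells=int(payload.get("n_cells", 1200)),
            batch_shift=float(payload.get("batch_shift", 0.0)),
            seed=int(payload.get("seed", 0)),
        )


@dataclass
class GroundTruth:
    """The hierarchy and labels the generator actually used."""

    tree: HierarchyTree
    edge_graph: EdgeGraph
    #: per dataset: the finest ground-truth label each cell could carry
    #: given the union of annotation resolutions (novel cells keep their name)
    true_labels: dict[str, np.ndarray]
    #: per dataset: the raw generating leaf (or novel) name of each cell
    leaf_labels: dict[str, np.ndarray]
    leaf_means: dict[str, np.ndarray]


# ----------------------------------------------------------- tree walking


def _walk(spec: dict, parent: Optional[str] = None):
    """Yield (name, parent_name, children_specs, weight) preorder."""
    children = spec.get("children", [])
    yield spec["name"], parent, children, spec.get("weight")
    for child in children:
        yield from _walk(child, spec["name"])


def _leaves_and_ancestors(tree_spec: dict):
    """Return (ordered leaf list with weights, name -> ancestor chain)."""
    parents: dict[str, Optional[str]] = {}
    leaves: list[tuple[str, float]] = []
    for name, parent, children, weight in _walk(tree_spec):
        if name in parents:
            raise ValidationError(f"duplicate node name {name!r} in tree_spec")
        parents[name] = parent
        if not children:
            if weight is None or weight <= 0:
                raise ValidationError(f"leaf {name!r} needs a positive weight")
            leaves.append((name, float(weight)))
    ancestors: dict[str, list[str]] = {}
    for name in parents:
        chain = []
        p = parents[name]
        while p is not None:
            chain.append(p)
            p = parents[p]
        ancestors[name] = chain
    return leaves, ancestors


def largest_remainder(n: int, weights: np.ndarray) -> np.ndarray:
    """Apportion ``n`` cells across clusters exactly, by largest remainder
    (ties broken by cluster index)."""
    weights = np.asarray(weights, dtype=np.float64)
    quota = n * weights / weights.sum()
    counts = np.floor(quota).astype(int)
    remainder = n - counts.sum()
    order = np.lexsort((np.arange(len(weights)), -(quota - counts)))
    counts[order[:remainder]] += 1
    return counts


def _unit_vector(rng: np.random.Generator, d: int) -> np.ndarray:
    v = rng.standard_normal(d)
    return v / np.linalg.norm(v)


def _place_mean(rng, d, anchor, radius, others, min_dist, max_tries=1000):
    """Anchor + radius * random direction, redrawn until at least
    ``min_dist`` away from every mean in ``others``."""
    best, best_score = None, -np.inf
    for _ in range(max_tries):
        cand = anchor + radius * _unit_vector(rng, d)
        score = min(
            (np.linalg.norm(cand - o) for o in others), default=np.inf
        )
        if score >= min_dist:
            return cand
        if score > best_score:
            best, best_score = cand, score
    return best  # geometrically crowded spec: best effort


# --------------------------------------------------------------- generate


def generate(config: SyntheticConfig) -> tuple[list[LabeledEmbedding], GroundTruth]:
    """Draw all datasets and the matching ground truth.

    Deterministic: the same config (including seed) yields bit-identical
    arrays.
    """
    rng = np.random.default_rng(config.seed)
    leaves, ancestors = _leaves_and_ancestors(config.tree_spec)
    leaf_names = [n for n, _ in leaves]
    weights = np.array([w for _, w in leaves])

    # validate resolution maps before drawing anything
    for ds in config.datasets:
        for src, dst in ds.resolution_map.items():
            if src not in ancestors:
                raise ValidationError(f"{ds.dataset_id}: unknown leaf {src!r}")
            if dst not in ancestors.get(src, []):
                raise ValidationError(
                    f"{ds.dataset_id}: relabel target {dst!r} is not an "
                    f"ancestor of {src!r}"
                )

    # hierarchical cluster means, preorder; root mean at the origin
    means: dict[str, np.ndarray] = {}
    placed: list[np.ndarray] = []
    for name, parent, children, _ in _walk(config.tree_spec):
        if parent is None:
            means[name] = np.zeros(config.d)
        else:
            means[name] = _place_mean(
                rng, config.d, means[parent], config.separation, placed,
                _MIN_SPACING * config.separation,
            )
        placed.append(means[name])

    # novel-cluster means: norm = stated offset, kept clear of real means
    novel_means: dict[tuple[str, str], np.ndarray] = {}
    for ds in config.datasets:
        for name, offset, _n in ds.novel_clusters:
            novel_means[(ds.dataset_id, name)] = _place_mean(
                rng, config.d, np.zeros(config.d), offset * 1.0, placed,
                _NOVEL_SPACING * config.separation,
            )
            placed.append(novel_means[(ds.dataset_id, name)])

    counts = largest_remainder(config.n_cells, weights)

    embeddings: list[LabeledEmbedding] = []
    leaf_labels: dict[str, np.ndarray] = {}
    for ds in config.datasets:
        blocks, raw, labels = [], [], []
        for leaf, n_leaf in zip(leaf_names, counts):
            blocks.append(means[leaf] + rng.standard_normal((n_leaf, config.d)))
            raw.extend([leaf] * n_leaf)
            labels.extend([ds.resolution_map.get(leaf, leaf)] * n_leaf)
        for name, _offset, n_nov in ds.novel_clusters:
            mu = novel_means[(ds.dataset_id, name)]
            blocks.append(mu + rng.standard_normal((n_nov, config.d)))
            raw.extend([name] * n_nov)
            labels.extend([name] * n_nov)
        X = np.vstack(blocks)
        if config.batch_shift > 0:
            X = X + config.batch_shift * _unit_vector(rng, config.d)
        cell_ids = np.array(
            [f"{ds.dataset_id}:{i}" for i in range(X.shape[0])], dtype=object
        )
        embeddings.append(
            LabeledEmbedding(ds.dataset_id, X, cell_ids, np.array(labels, dtype=object))
        )
        leaf_labels[ds.dataset_id] = np.array(raw, dtype=object)

    truth = _ground_truth(config, ancestors, leaf_labels, means)
    return embeddings, truth


def _ground_truth(config, ancestors, leaf_labels, means) -> GroundTruth:
    """Build the truth hierarchy over the names any dataset actually uses.

    Spec nodes no dataset annotates at are contracted away (their children
    splice up to the nearest used ancestor); novel clusters become children
    of the root.
    """
    used: set[str] = set()
    for ds in config.datasets:
        leaf_set = set(np.unique(leaf_labels[ds.dataset_id]))
        novel = {n for n, _, _ in ds.novel_clusters}
        for name in leaf_set - novel:
            used.add(ds.resolution_map.get(name, name))
        used.update(novel)

    tree = HierarchyTree("root")

    def build(spec: dict, parent_name: str) -> None:
        name = spec["name"]
        if name in used:
            aliases = [
                (ds.dataset_id, name)
                for ds in config.datasets
                if name in _dataset_label_set(ds, leaf_labels)
            ]
            tree.add_node(parent_name, aliases)
            attach_under = name
        else:
            attach_under = parent_name
        for child in spec.get("children", []):
            build(child, attach_under)

    for child in config.tree_spec.get("children", []):
        build(child, tree.root.display_name)
    for ds in config.datasets:
        for name, _, _ in ds.novel_clusters:
            tree.add_node(tree.root.display_name, [(ds.dataset_id, name)])
    tree.dataset_ids = [ds.dataset_id for ds in config.datasets]
    tree.check_invariants()

    # finest used name on each cell's leaf-to-root path
    finest: dict[str, str] = {}
    for leaf in ancestors:
        for cand in [leaf] + ancestors[leaf]:
            if cand in used:
                finest[leaf] = cand
                break
    true_labels = {}
    for ds_id, raw in leaf_labels.items():
        true_labels[ds_id] = np.array(
            [finest.get(l, l) for l in raw], dtype=object
        )

    return GroundTruth(
        tree=tree,
        edge_graph=tree.to_graph(include_root=False),
        true_labels=true_labels,
        leaf_labels=leaf_labels,
        leaf_means={k: v for k, v in means.items()},
    )


def _dataset_label_set(ds: DatasetSpec, leaf_labels) -> set[str]:
    raw = set(np.unique(leaf_labels[ds.dataset_id]))
    novel = {n for n, _, _ in ds.novel_clusters}
    return {ds.resolution_map.get(n, n) for n in raw - novel} | novel


# ----------------------------------------------------------------- presets

#: immune-like ground-truth hierarchy used by the shipped scenarios
_PBMC_TREE = {
    "name": "root",
    "children": [
        {
            "name": "Group1",
            "children": [
                {
                    "name": "T cells",
                    "children": [
                        {"name": "CD4 T cells", "weight": 0.15},
                        {"name": "CD8 T cells", "weight": 0.15},
                    ],
                },
                {"name": "B cells", "weight": 0.2},
                {"name": "NK cells", "weight": 0.2},
            ],
        },
        {
            "name": "Monocytes",
            "children": [
                {"name": "CD14 Monocytes", "weight": 0.1},
                {"name": "CD16 Monocytes", "weight": 0.1},
            ],
        },
        {"name": "HSPC", "weight": 0.1},
    ],
}

_FLAT_TREE = {
    "name": "root",
    "children": [{"name": f"type {c}", "weight": 0.2} for c in "ABCDE"],
}


def preset_scenarios(seed: int = 0) -> dict[str, SyntheticConfig]:
    """Named study designs used throughout the tests.

    - ``"pbmc-like ladder"``: three reference datasets annotated at coarse,
      mid, and fine resolution plus one fine-resolution query carrying two
      small novel cell types of 21 and 18 cells.
    - ``"novelty-stress"``: three equal-resolution datasets, each with its
      own 10-sigma novel cluster.
    - ``"equal-resolution permutation"``: three identically labeled
      datasets (order-invariance testbed).
    """
    coarse = {
        "CD4 T cells": "Group1", "CD8 T cells": "Group1",
        "B cells": "Group1", "NK cells": "Group1",
        "CD14 Monocytes": "Monocytes", "CD16 Monocytes": "Monocytes",
    }
    mid = {"CD4 T cells": "T cells", "CD8 T cells": "T cells"}
    ladder = SyntheticConfig(
        tree_spec=_PBMC_TREE,
        datasets=[
            DatasetSpec("ref-coarse", resolution_map=coarse),
            DatasetSpec("ref-mid", resolution_map=mid),
            DatasetSpec("ref-fine"),
            DatasetSpec(
                "query",
                novel_clusters=[
                    ("Plasma cells", 10.0, 21),
                    ("MK progenitors", 10.0, 18),
                ],
            ),
        ],
        d=10, separation=8.0, n_cells=1200, batch_shift=0.2, seed=seed,
    )
    novelty = SyntheticConfig(
        tree_spec=_FLAT_TREE,
        datasets=[
            DatasetSpec("ds1", novel_clusters=[("novel-1", 10.0, 60)]),
            DatasetSpec("ds2", novel_clusters=[("novel-2", 10.0, 60)]),
            DatasetSpec("ds3", novel_clusters=[("novel-3", 10.0, 60)]),
        ],
        d=10, separation=8.0, n_cells=600, batch_shift=0.2, seed=seed,
    )
    equal = SyntheticConfig(
        tree_spec=_FLAT_TREE,
        datasets=[DatasetSpec("ds1"), DatasetSpec("ds2"), DatasetSpec("ds3")],
        d=10, separation=8.0, n_cells=600, batch_shift=0.2, seed=seed,
    )
    return {
        "pbmc-like ladder": ladder,
        "novelty-stress": novelty,
        "equal-resolution permutation": equal,
    }
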