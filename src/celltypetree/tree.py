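"""Cell-type hierarchy: nodes, the tree, and its ancestor-descendant graph.

A hierarchy is a rooted tree whose nodes are cell types.  An edge means the
child is a subpopulation of the parent.  Each node aggregates the
(dataset_id, label) pairs -- *aliases* -- that different studies use for the
same population; a node with two aliases records a perfect match between two
datasets' annotations.  The root is a structural anchor and carries no
aliases.  Labels that admit no consistent placement are parked on the tree's
``missing`` list instead of being forced into a node.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterator, Optional

from .errors import ConflictError, NotFoundError, ParseError

Alias = tuple[str, str]  # (dataset_id, label)


def _clean_alias(alias) -> Alias:
    ds, label = alias
    return (str(ds).strip(), str(label).strip())


class CellTypeNode:
    """One cell type in the hierarchy.

    Parameters
    ----------
    aliases
        Set of (dataset_id, label) pairs naming this population.  Empty only
        for the root.
    display_name
        Canonical printable name; unique among siblings (and, in practice,
        within the whole tree).
    """

    __slots__ = ("aliases", "display_name", "children", "parent", "classifier_ref")

    def __init__(self, display_name: str, aliases=()):
        self.display_name = display_name
        self.aliases: set[Alias] = {_clean_alias(a) for a in aliases}
        self.children: list[CellTypeNode] = []
        self.parent: Optional[CellTypeNode] = None
        self.classifier_ref = None  # fitted per-parent classifier, internal nodes only

    def is_leaf(self) -> bool:
        return not self.children

    def descendants(self) -> Iterator["CellTypeNode"]:
        for child in self.children:
            yield child
            yield from child.descendants()

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"CellTypeNode({self.display_name!r}, aliases={sorted(self.aliases)})"


@dataclass
class EdgeGraph:
    """Directed ancestor->descendant edge set of a hierarchy.

    Transitively closed by construction: an edge is added from every node to
    every one of its descendants, not just its children.
    """

    edges: set[tuple[str, str]] = field(default_factory=set)
    node_names: set[str] = field(default_factory=set)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            for a, b in sorted(self.edges):
                fh.write(f"{a}\t{b}\n")

    @classmethod
    def from_tsv(cls, path) -> "EdgeGraph":
        edges = set()
        names = set()
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line:
                    continue
                a, b = line.split("\t")
                edges.add((a, b))
                names.update((a, b))
        return cls(edges=edges, node_names=names)


class HierarchyTree:
    """The evolving cell-type hierarchy across datasets.

    Doubles as the hierarchical classifier once per-node classifiers are
    attached (see :mod:`celltypetree.matching`).
    """

    def __init__(self, root_name: str = "root"):
        if not root_name:
            raise ValueError("root_name must be a non-empty string")
        self.root = CellTypeNode(root_name)
        self.dataset_ids: list[str] = []
        self.missing: list[Alias] = []

    # ---------------------------------------------------------------- lookup

    def nodes(self, include_root: bool = True) -> Iterator[CellTypeNode]:
        if include_root:
            yield self.root
        yield from self.root.descendants()

    def find(self, name: str) -> CellTypeNode:
        for node in self.nodes():
            if node.display_name == name:
                return node
        raise NotFoundError(f"no node named {name!r} in tree")

    def has_node(self, name: str) -> bool:
        return any(n.display_name == name for n in self.nodes())

    def alias_map(self) -> dict[Alias, CellTypeNode]:
        """Map every housed (dataset_id, label) alias to its node."""
        out: dict[Alias, CellTypeNode] = {}
        for node in self.root.descendants():
            for alias in node.aliases:
                out[alias] = node
        return out

    def parent_of(self, node: CellTypeNode) -> Optional[CellTypeNode]:
        return node.parent

    def is_ancestor(self, ancestor_name: str, descendant_name: str) -> bool:
        node = self.find(descendant_name)
        while node.parent is not None:
            node = node.parent
            if node.display_name == ancestor_name:
                return True
        return False

    # ------------------------------------------------------------- mutation

    def _display_name_for(self, aliases: set[Alias]) -> str:
        """Default display name: first alias's label, dataset-qualified only
        when the bare label collides with an existing node name."""
        ds, label = sorted(aliases)[0]
        if not self.has_node(label):
            return label
        return f"{label} - {ds}"

    def _check_unhoused(self, aliases) -> None:
        housed = self.alias_map()
        for alias in aliases:
            if alias in housed:
                raise ConflictError(
                    f"alias {alias!r} already housed in node "
                    f"{housed[alias].display_name!r}"
                )

    def add_node(self, parent_name: str, aliases) -> CellTypeNode:
        """Append a new child carrying ``aliases`` under ``parent_name``."""
        aliases = {_clean_alias(a) for a in aliases}
        if not aliases:
            raise ValueError("a non-root node needs at least one alias")
        parent = self.find(parent_name)
        self._check_unhoused(aliases)
        node = CellTypeNode(self._display_name_for(aliases), aliases)
        node.parent = parent
        parent.children.append(node)
        return node

    def merge_alias(self, node_name: str, alias) -> CellTypeNode:
        """Record that ``alias`` denotes the same population as ``node_name``."""
        node = self.find(node_name)
        if node is self.root:
            raise ValueError("the root carries no aliases")
        alias = _clean_alias(alias)
        self._check_unhoused([alias])
        node.aliases.add(alias)
        return node

    def insert_parent(self, child_names: list[str], aliases) -> CellTypeNode:
        """Insert a new node between a sibling group and their parent.

        Used when an incoming coarse label merges several existing nodes: the
        new node adopts the named siblings as children.
        """
        aliases = {_clean_alias(a) for a in aliases}
        children = [self.find(n) for n in child_names]
        parents = {id(c.parent) for c in children}
        if len(parents) != 1:
            raise ValueError("insert_parent requires a sibling group")
        self._check_unhoused(aliases)
        parent = children[0].parent
        node = CellTypeNode(self._display_name_for(aliases), aliases)
        node.parent = parent
        idx = min(parent.children.index(c) for c in children)
        for c in children:
            parent.children.remove(c)
            c.parent = node
            node.children.append(c)
        parent.children.insert(idx, node)
        return node

    def delete_subtree(self, name: str) -> CellTypeNode:
        """Detach and return the subtree rooted at ``name`` (not the root)."""
        node = self.find(name)
        if node is self.root:
            raise ValueError("cannot delete the root")
        node.parent.children.remove(node)
        node.parent = None
        return node

    # ------------------------------------------------------------ structure

    def check_invariants(self) -> None:
        """Raise if the housed-alias partition or tree shape is violated."""
        seen: dict[Alias, str] = {}
        for node in self.root.descendants():
            if not node.aliases:
                raise ValueError(f"non-root node {node.display_name!r} has no aliases")
            for alias in node.aliases:
                if alias in seen:
                    raise ValueError(f"alias {alias!r} housed twice")
                seen[alias] = node.display_name
        for alias in self.missing:
            if alias in seen:
                raise ValueError(f"missing alias {alias!r} is also housed")
        for node in self.nodes():
            names = [c.display_name for c in node.children]
            if len(names) != len(set(names)):
                raise ValueError(f"duplicate sibling names under {node.display_name!r}")
            for c in node.children:
                if c.parent is not node:
                    raise ValueError("broken parent pointer")

    def to_graph(self, include_root: bool = False) -> EdgeGraph:
        """Ancestor->descendant edge set ("adding edges between a parent and
        all descendants"); the root is excluded unless requested."""
        graph = EdgeGraph()
        for node in self.nodes(include_root=True):
            if node is self.root and not include_root:
                continue
            graph.node_names.add(node.display_name)
            for desc in node.descendants():
                graph.edges.add((node.display_name, desc.display_name))
                graph.node_names.add(desc.display_name)
        if not include_root:
            graph.node_names.discard(self.root.display_name)
        return graph

    # -------------------------------------------------------- serialization

    def _node_to_dict(self, node: CellTypeNode) -> dict:
        return {
            "name": node.display_name,
            "aliases": [list(a) for a in sorted(node.aliases)],
            "children": [self._node_to_dict(c) for c in node.children],
        }

    def to_dict(self) -> dict:
        return {
            "tree": self._node_to_dict(self.root),
            "dataset_ids": list(self.dataset_ids),
            "missing": [list(a) for a in self.missing],
        }

    def save_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)
            fh.write("\n")

    @classmethod
    def from_dict(cls, payload: dict) -> "HierarchyTree":
        try:
            rootd = payload["tree"]
            tree = cls(rootd["name"])
            tree.dataset_ids = [str(x) for x in payload.get("dataset_ids", [])]
            tree.missing = [_clean_alias(a) for a in payload.get("missing", [])]

            def attach(parent: CellTypeNode, d: dict) -> None:
                node = CellTypeNode(d["name"], [tuple(a) for a in d["aliases"]])
                node.parent = parent
                parent.children.append(node)
                for cd in d["children"]:
                    attach(node, cd)

            for cd in rootd["children"]:
                attach(tree.root, cd)
        except (KeyError, TypeError, ValueError) as exc:
            raise ParseError(f"malformed tree payload: {exc}") from exc
        tree.check_invariants()
        return tree

    @classmethod
    def load_json(cls, path) -> "HierarchyTree":
        with open(path) as fh:
            try:
                payload = json.load(fh)
            except json.JSONDecodeError as exc:
                raise ParseError(
                    f"{path}: invalid JSON at line {exc.lineno}, column {exc.colno}"
                ) from exc
        return cls.from_dict(payload)

    def to_newick(self) -> str:
        """Newick export (lossy: aliases flattened into node names)."""

        def quote(name: str) -> str:
            if any(c in name for c in "(),:;'\t\n []"):
                return "'" + name.replace("'", "''") + "'"
            return name

        def render(node: CellTypeNode) -> str:
            if node.is_leaf():
                return quote(node.display_name)
            inner = ",".join(render(c) for c in node.children)
            return f"({inner}){quote(node.display_name)}"

        return render(self.root) + ";"

    def __eq__(self, other) -> bool:
        if not isinstance(other, HierarchyTree):
            return NotImplemented
        return self.to_dict() == other.to_dict()

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        n = sum(1 for _ in self.root.descendants())
        return f"HierarchyTree({self.root.display_name!r}, {n} nodes)"

    def render(self) -> str:
        """Simple indented text rendering of the tree."""
        lines: list[str] = []

        def walk(node: CellTypeNode, depth: int) -> None:
            datasets = sorted({ds for ds, _ in node.aliases})
            suffix = f"  [{', '.join(datasets)}]" if datasets else ""
            lines.append("  " * depth + node.display_name + suffix)
            for c in node.children:
                walk(c, depth + 1)

        walk(self.root, 0)
        return "\n".join(lines)


# Thin functional wrappers over the estimator-style classes ----------------


def create_tree(root_name: str) -> HierarchyTree:
    """Create an empty hierarchy with a single childless root."""
    return HierarchyTree(root_name)


def add_node(tree: HierarchyTree, parent_name: str, aliases) -> CellTypeNode:
    return tree.add_node(parent_name, aliases)


def merge_alias(tree: HierarchyTree, node_name: str, alias) -> CellTypeNode:
    return tree.merge_alias(node_name, alias)


def tree_to_graph(tree: HierarchyTree, include_root: bool = False) -> EdgeGraph:
    return tree.to_graph(include_root=include_root)


def serialize(tree: HierarchyTree, path, format: str = "json") -> None:
    if format == "json":
        tree.save_json(path)
    elif format == "newick":
        with open(path, "w") as fh:
            fh.write(tree.to_newick() + "\n")
    else:
        raise ValueError(f"unknown format {format!r}")


def deserialize(path, format: str = "json") -> HierarchyTree:
    if format != "json":
        raise ValueError("only JSON round-trips; newick export is lossy")
    return HierarchyTree.load_json(path)
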