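"""Score a learned hierarchy against a ground truth by edge comparison.

Both hierarchies are flattened to directed ancestor->descendant edge sets
(an edge from every node to every descendant).  Direction carries the
biological claim "is a subpopulation of", so an inverted relation costs
one wrong plus one missing edge.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

from .tree import EdgeGraph, HierarchyTree


@dataclass
class GraphComparison:
    correct_edges: int
    wrong_edges: int
    missing_edges: int
    wrong_listing: list[tuple[str, str, str]] = field(default_factory=list)
    missing_listing: list[tuple[str, str]] = field(default_factory=list)
    #: learned edges whose endpoints map to the same truth name (a perfect
    #: match expressed as a subpopulation, or vice versa); dropped from the
    #: wrong count but reported
    collapsed_self_edges: int = 0

    def to_dict(self) -> dict:
        return {
            "correct_edges": self.correct_edges,
            "wrong_edges": self.wrong_edges,
            "missing_edges": self.missing_edges,
            "collapsed_self_edges": self.collapsed_self_edges,
            "wrong_listing": [list(e) for e in self.wrong_listing],
            "missing_listing": [list(e) for e in self.missing_listing],
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)
            fh.write("\n")

    def to_text(self) -> str:
        return (
            f"correct edges: {self.correct_edges}\n"
            f"wrong edges:   {self.wrong_edges}\n"
            f"missing edges: {self.missing_edges}\n"
        )


def alias_name_map(tree: HierarchyTree) -> dict[str, set[str]]:
    """Map each node's display name to the set of labels of its aliases.

    Perfect-match nodes housing several aliases expand to all their names
    before comparison.
    """
    return {
        node.display_name: {label for _ds, label in node.aliases}
        for node in tree.nodes(include_root=False)
    }


def compare_graphs(learned: EdgeGraph, truth: EdgeGraph,
                   name_map: dict[str, set[str]] | None = None) -> GraphComparison:
    """Directed set difference between learned and truth edge sets.

    With a ``name_map``, every learned edge expands over the truth names of
    its endpoints; an unmappable learned node's edges are counted wrong
    with a reason rather than silently dropped, and edges collapsing to a
    self-loop (both endpoints naming the same truth node) are excluded from
    the wrong count but reported.
    """
    wrong_listing: list[tuple[str, str, str]] = []
    collapsed = 0
    if name_map is None:
        mapped = set(learned.edges)
    else:
        mapped = set()
        for a, b in sorted(learned.edges):
            if a not in name_map or b not in name_map:
                miss = a if a not in name_map else b
                wrong_listing.append((a, b, f"unmapped node {miss!r}"))
                continue
            expanded = {
                (ta, tb) for ta in name_map[a] for tb in name_map[b] if ta != tb
            }
            if not expanded:
                collapsed += 1
                continue
            mapped |= expanded

    correct = mapped & truth.edges
    wrong = mapped - truth.edges
    missing = truth.edges - mapped
    wrong_listing.extend((a, b, "not in truth") for a, b in sorted(wrong))
    return GraphComparison(
        correct_edges=len(correct),
        wrong_edges=len(wrong) + sum(
            1 for *_e, r in wrong_listing if r.startswith("unmapped")
        ),
        missing_edges=len(missing),
        wrong_listing=wrong_listing,
        missing_listing=sorted(missing),
        collapsed_self_edges=collapsed,
    )
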