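# celltypetree

Cross-dataset cell-type matching, updatable cell-type hierarchies, and
hierarchical kNN label transfer with novelty rejection — for single-cell
datasets that already share an integrated latent space.

## The problem

Different single-cell studies annotate the same tissue at different depths
and with different vocabularies: one lab's "T cells" are another lab's
"CD4+ T cells" and "CD8+ T cells". Once several labeled datasets have been
embedded into one batch-corrected latent space (by scVI/scANVI-style
integration, which is upstream of and outside this package), two questions
remain:

1. **Which cell types across datasets are the same population, and which
   are sub- or super-populations of each other?**
2. **How do we annotate a new query dataset against that harmonized
   reference — including flagging cells of types the reference has never
   seen, such as disease-associated states?**

`celltypetree` answers both with a single data structure: a cell-type
hierarchy whose nodes aggregate each dataset's name for a population
(*aliases*) and whose edges mean "is a subpopulation of". The hierarchy is
built progressively, one dataset at a time, and doubles as a hierarchical
classifier.

## The method

**Matching.** For a new labeled dataset *D* and the current tree *T*,
labels are cross-predicted in both directions: *T*'s hierarchical
classifier annotates *D*'s cells, and a flat multiclass kNN trained on *D*
annotates *T*'s pooled training cells. Both row-normalized confusion
matrices are binarized (default: a match is any fraction ≥ 0.25) and each
new label *L* is resolved against the tree:

| pattern | verdict |
| --- | --- |
| *L* ↔ node *N*, reciprocal and exclusive | perfect match → *L* becomes an alias of *N* |
| *L* maps only into *N*; *N* spreads over new labels that each map only to *N* | *L* is a subpopulation → new child of *N* |
| *L* covers sibling nodes that each map back to *L* alone | *L* merges them → new parent node |
| *L* rejected in both directions | new cell type → child of the root |
| anything else (crossing many-to-many) | unresolved → reported as missing, never forced |

**Classification.** Every internal node with ≥ 2 children carries one
multiclass kNN classifier (k = 50 by default, automatically shrunk to the
smallest child class size). A query cell descends from the root; at each
node it is either routed to a child, **rejected** as potentially novel —
when its mean neighbor distance exceeds the 99th percentile of the
training distribution, or its PCA reconstruction error exceeds a threshold
calibrated by nested cross-validation to a 0.5% inlier false-negative
rate — or stopped as **ambiguous** when the winning vote fraction falls
below 0.5, in which case it keeps the current node's coarser label.

**Evaluation.** A hierarchy is scored against a ground truth by flattening
both to directed ancestor→descendant edge sets (an edge from every node to
every descendant) and counting correct, wrong, and missing edges.

## Worked example

Three synthetic reference datasets annotated at coarse, mid, and fine
resolution (the `"pbmc-like ladder"` scenario), plus a query with two
small novel types of 21 and 18 cells:

```python
from celltypetree import preset_scenarios, generate, build_hierarchy, compare_graphs

config = preset_scenarios(seed=0)["pbmc-like ladder"]
embeddings, truth = generate(config)     # 4 LabeledEmbeddings + ground truth

builder = build_hierarchy(embeddings[:3])
print(builder.tree_.render())
```

```
root
  Group1  [ref-coarse]
    T cells  [ref-mid]
      CD4 T cells  [ref-fine]
      CD8 T cells  [ref-fine]
    B cells  [ref-fine, ref-mid]
    NK cells  [ref-fine, ref-mid]
  Monocytes  [ref-coarse]
    CD14 Monocytes  [ref-fine, ref-mid]
    CD16 Monocytes  [ref-fine, ref-mid]
  HSPC  [ref-coarse, ref-fine, ref-mid]
```

The mid-resolution "B cells" perfectly matched the fine-resolution
"B cells" (one node, two aliases), while "CD4 T cells" and "CD8 T cells"
were placed as subpopulations of "T cells". The learned graph is exact:

```python
cmp = compare_graphs(builder.tree_.to_graph(), truth.edge_graph)
print(cmp.wrong_edges, cmp.missing_edges)   # -> 0 0
```

Updating with the labeled query attaches its 21-cell and 18-cell
dataset-specific types to the root as new cell types and perfect-matches
everything else:

```python
report = builder.update(embeddings[3])
print(report.tail(3).to_string(index=False))
```

```
         label         verdict placed_under
          HSPC         perfect         HSPC
  Plasma cells  new_root_child         root
MK progenitors  new_root_child         root
```

The same workflows are available from the shell:

```bash
celltypetree simulate --preset "pbmc-like ladder" --seed 0 --out sim/
celltypetree build sim/ref-coarse.tsv sim/ref-mid.tsv sim/ref-fine.tsv --out run/
celltypetree evaluate --learned run/edges.tsv --truth sim/truth_edges.tsv --out cmp.json
celltypetree predict --tree run/tree.json --ref sim/ref-coarse.tsv \
    --ref sim/ref-mid.tsv --ref sim/ref-fine.tsv --query sim/query.tsv --out pred.tsv
```

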