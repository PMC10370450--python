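# Methods

This note records the model assumptions, parameter choices, numerical
conventions, and known limitations of `celltypetree`, in the spirit of the
methods documentation of packages like `statsmodels` or `msprime`.

## Setting and assumptions

All computation happens in a shared low-dimensional latent space
(typically 10–30 dimensions) in which multiple labeled datasets have
already been integrated. The package assumes that integration has (a)
largely removed batch effects, so that cells of the same type from
different datasets are neighbors, and (b) preserved biological variation,
so that genuinely novel populations are *not* forced onto reference
populations. Both assumptions belong to the upstream integration model;
when they fail, matching degrades in a characteristic way (novel types
multiply, cross-matches become unresolved) rather than silently.

Euclidean distance is the default metric: the latent coordinates come
from VAE-style encoders for which Euclidean kNN is the community default.
The metric is configurable on every classifier.

## The hierarchy

The hierarchy is a rooted tree. Node identity is carried by the set of
(dataset, label) aliases, not by display strings; the display name
defaults to the first alias's label and is dataset-qualified
("MK progenitors - tenx") only when the bare label would collide with an
existing node. Sibling order is insertion order and is preserved by the
JSON serialization, so structurally equal histories produce identical
files. Labels are compared exactly (case-sensitive) after stripping
leading/trailing whitespace at ingest; silent case-folding would hide
annotation inconsistencies that the tool is meant to surface.

Trees serialize to JSON (lossless round trip) and export to Newick
(lossy: aliases flattened into names). Manual curation is supported as
delete-subtree + add-node; classifiers must be refit afterwards, which is
the caller's responsibility.

For evaluation a tree is flattened to the directed edge set linking every
node to every descendant. The root is excluded by default: root→X edges
carry no biological claim and would inflate all methods' counts equally.
Edges are directed because direction *is* the claim ("subpopulation of");
an inverted relation therefore costs one wrong plus one missing edge.

## The node classifier

Every internal node with at least two children carries one multiclass kNN
classifier whose classes are the direct children; each child's training
pool is every cell housed at or below it. Cells carrying a coarse label
housed at an internal node train only the classifier *above* that node
(as members of its class); they are never split heuristically across its
children.

- **Neighbor count.** Requested k defaults to 50; with
  `dynamic_neighbors` (default on) it shrinks to the smallest child class
  size, so a 18-cell type can still win a vote. Exactly `k_effective`
  neighbors are used; distance ties at the k-th position are broken by
  training-row index (stable sort), making predictions invariant to
  training-row permutation up to that declared tie-break. Neighbor search
  is exact (pairwise distances + stable argsort) rather than
  tree/graph-accelerated: the package's instances are small enough that
  exactness and bit-reproducibility are worth more than speed.
- **Posterior.** The vote fraction among the k nearest neighbors. On tied
  maxima the class with the smaller summed neighbor distance wins, then
  the lexicographically smaller name — deterministic and data-driven.
- **Rejection.** Three independent criteria, evaluated in the order
  distance, reconstruction, posterior; the first that fires is reported.
  All comparisons are strict (equality accepts).
  - *Distance* (novelty): mean distance to the k nearest training
    neighbors exceeds the 99th percentile of that statistic over the
    training cells themselves (self excluded, so duplicated cells count
    as zero-distance neighbors). Percentiles use linear interpolation
    between order statistics — pinned so the threshold is
    bit-reproducible.
  - *Reconstruction* (novelty): squared error of projecting onto a PCA
    basis of the node's training cells and back. The basis retains 90% of
    variance by default; keeping all components is also supported and
    makes the criterion inert (a full-rank
    basis is the identity, and its error is computed as exactly zero
    rather than rounding noise). The threshold is fitted by a nested CV:
    5 outer folds (stratified by class when every class has ≥ 5 cells,
    plain K-fold otherwise), per fold the (1 − fn_rate) quantile of
    held-out errors, threshold = median of fold quantiles, basis refit on
    all cells. `fn_rate` defaults to 0.5%, i.e. the threshold misrejects
    about that fraction of genuine inliers.
  - *Posterior* (ambiguity): winning fraction below `tau_posterior`
    (default 0.5). During hierarchical prediction this is *not* a
    terminal rejection below the root: the cell keeps the current node's
    coarser label, preserving the hierarchy's value at partial
    resolution. At the root there is no label to keep, so root-level
    posterior ambiguity is reported as a rejection with reason
    `posterior`; interpreting it as novelty is left to the caller.

A node with a single child is a pass-through: queries descend
unconditionally. The fold seed (`random_state`) is the only stochastic
element of fitting and is propagated from the caller.

## Matching

Cross-prediction runs in both directions. Tree → new dataset uses the
full hierarchical classifier with rejection; new dataset → tree trains a
single flat kNN on the incoming labels (the incoming dataset has no tree
yet) with identically fitted rejection thresholds, and predicts the
tree's pooled training cells, whose "true" label is the node housing
them. Confusion matrices are row-normalized with a reserved REJECTED
column, then binarized at `match_threshold` (default 0.25 — tolerant of
4-way ambiguity while preserving majority structure; exposed as a knob
and guarded by the threshold-sweep check in the acceptance script).

Relation resolution is local per incoming label *L* with forward match
set *F(L)* and reverse match sets *R(N)* (REJECTED excluded from both):

1. *F(L)* empty and no node matches *L* in reverse → **new root child**.
2. *F(L)* = {N} and *R(N)* = {L} → **perfect**.
3. *F(L)* = {N} and every label in *R(N)* maps only to *N* →
   **subpopulation** of *N*. *L* itself need not appear in *R(N)*: a
   21-cell subtype can fall below the row fraction of a large node and
   must still be placeable. The group condition keeps crossing
   many-to-many patterns out.
4. *F(L)* a set of sibling nodes, each mapping back to {L} alone →
   **merge**: a new node with alias (dataset, L) adopts those siblings.
5. Anything else → **unresolved**: the alias is recorded as missing,
   and its cells are excluded from all subsequent training pools (they
   would contaminate neighborhoods).

Verdicts are applied perfect → merge → subpopulation → new; a merge whose
sibling group was broken by an earlier merge degrades to unresolved.
After each update every internal node's classifier is refit from scratch;
training pools are subtree-cumulative, so almost all of them change
anyway, and a full refit is simpler and provably consistent. Reference
cells are never re-assigned between existing nodes by an update.

## The synthetic generator

The generator emulates integrated latent data, not expression data: each
cell type is an isotropic unit-σ Gaussian; a child type's mean sits at
`separation`·σ (default 8) from its parent's mean in a uniformly random
direction; datasets may relabel leaves to ancestors (annotation
resolution), carry dataset-specific novel clusters (mean norm = stated
offset, default 10σ), and be translated by a residual batch shift
(presets use 0.2σ — integration that worked, imperfectly). Directions are
drawn on the sphere, not axis-aligned, to avoid coordinate artifacts in
kNN tests. Mean placement uses seeded rejection resampling enforcing at
least 0.9·separation between any two real means and a full separation
between novel and real means, so "well-separated" is a property of the
generator rather than seed luck. Cell counts per leaf follow
largest-remainder apportionment of the configured mixing weights (exact,
deterministic). Identical configs (including seed) produce bit-identical
arrays.

The ground-truth tree contains exactly the names some dataset uses;
unused intermediate levels are contracted. What passing tests on this
generator shows: the matching logic, rejection calibration, and
hierarchy bookkeeping are correct under the stated geometry. What it does
not show: robustness to overlapping types with diffuse boundaries,
partially wrong annotations, residual nonlinear batch structure, or
count-level noise — on real data these produce exactly the unresolved /
missing verdicts the method is designed to surface rather than hide.

Preset scenario sizes (chosen as the package's standard testbed): ladder,
4 datasets × 1200 cells + 39 novel query cells in d = 10; novelty-stress
and equal-resolution, 3 datasets × 600–660 cells.

## Known limitations

- Progressive, order-dependent construction: at unequal annotation
  resolutions, datasets should be added coarse → fine. At equal
  resolution the result is order-invariant (checked).
- Novel types attach to the root, never to an intermediate node; placing
  them deeper requires prior knowledge the data alone does not give.
- Small cell types (tens of cells) are matchable thanks to dynamic k, but
  remain the most fragile case; the shipped 21/18-cell scenario works at
  8σ separation, not as a guarantee for diffuse real data.
- DAG-shaped (non-tree) hierarchies and ontology integration are out of
  scope.
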