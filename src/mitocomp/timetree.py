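"""Relative-rate divergence dating (RelTime-style) with one calibration.

Branch lengths of a rooted tree (substitutions/site) are converted into
relative node heights by a post-order relative-rate recursion: at each
internal node the lineage length through each child is the child's branch
plus the child's own relative height, and sibling lineages are reconciled by
the geometric mean of those lengths. Heights are then propagated root-to-tip
so that every leaf sits at age 0 (an ultrametric tree), and finally scaled so
the calibrated node takes its calibration age — by default the midpoint of
the [lo, hi] interval, or a configured point value inside it.

Under a strict clock this reduces to exact node depths; under rate variation
the geometric-mean reconciliation absorbs lineage-specific rates. The
published method's variance and confidence-interval machinery is not
implemented.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import dendropy


@dataclass(frozen=True)
class Calibration:
    taxa: tuple[str, ...]  # calibrated node = MRCA of these taxa
    lo: float  # Ma
    hi: float
    point: float | None = None  # defaults to the interval midpoint

    @property
    def age(self) -> float:
        t = (self.lo + self.hi) / 2.0 if self.point is None else self.point
        if not (self.lo <= t <= self.hi):
            raise ValueError(f"calibration point {t} outside [{self.lo}, {self.hi}]")
        return t


@dataclass
class TimeTree:
    tree: dendropy.Tree  # branch lengths in Ma, node.age set on every node
    calibration: Calibration

    def age_of(self, taxa: list[str] | set[str]) -> float:
        node = _mrca(self.tree, set(taxa))
        return node.age

    def leaf_ages(self) -> dict[str, float]:
        return {lf.taxon.label: lf.age for lf in self.tree.leaf_node_iter()}

    def max_ultrametric_deviation(self) -> float:
        root_age = self.tree.seed_node.age
        dev = 0.0
        for leaf in self.tree.leaf_node_iter():
            depth = 0.0
            node = leaf
            while node.parent_node is not None:
                depth += node.edge.length or 0.0
                node = node.parent_node
            dev = max(dev, abs(depth - root_age), abs(leaf.age))
        return dev


def _mrca(tree: dendropy.Tree, taxa: set[str]) -> dendropy.Node:
    leaves = {lf.taxon.label for lf in tree.leaf_node_iter()}
    if not taxa <= leaves:
        raise ValueError(f"taxa not in tree: {sorted(taxa - leaves)}")
    best = None
    for node in tree.postorder_node_iter():
        below = {lf.taxon.label for lf in node.leaf_iter()}
        if taxa <= below and (best is None or len(below) < len(best[0])):
            best = (below, node)
    return best[1]


def _gmean(values: list[float]) -> float:
    if any(v <= 0 for v in values):
        return 0.0
    return math.exp(sum(math.log(v) for v in values) / len(values))


def relative_heights(tree: dendropy.Tree) -> dict[dendropy.Node, float]:
    """Bottom-up relative height of each node (leaves at 0)."""
    H: dict[dendropy.Node, float] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            H[node] = 0.0
        else:
            lineage = [(ch.edge.length or 0.0) + H[ch] for ch in node.child_nodes()]
            H[node] = _gmean(lineage)
    return H


def reltime_scale(tree: dendropy.Tree, calibration: Calibration) -> TimeTree:
    """Date a rooted tree with branch lengths using one calibration interval.

    The calibrated node must be internal. The returned tree is ultrametric,
    with node ages (Ma) on every node and branch lengths rescaled to age
    differences.
    """
    work = tree.clone(depth=1)
    if len(work.seed_node.child_nodes()) < 2:
        raise ValueError("tree must be rooted with a bifurcating root")
    cal_node = _mrca(work, set(calibration.taxa))
    if cal_node.is_leaf():
        raise ValueError("calibration node must be internal, not a leaf")

    H = relative_heights(work)
    rel_age: dict[dendropy.Node, float] = {}
    root = work.seed_node
    rel_age[root] = H[root]
    for node in work.preorder_node_iter():
        if node is root:
            continue
        if node.is_leaf():
            rel_age[node] = 0.0
            continue
        parent_age = rel_age[node.parent_node]
        denom = (node.edge.length or 0.0) + H[node]
        rel_age[node] = parent_age * (H[node] / denom) if denom > 0 else parent_age

    rel_cal = rel_age[cal_node]
    if rel_cal <= 0:
        raise ValueError("calibrated node has zero relative height")
    factor = calibration.age / rel_cal
    for node in work.preorder_node_iter():
        node.age = rel_age[node] * factor
    for node in work.preorder_node_iter():
        if node.parent_node is not None:
            node.edge.length = node.parent_node.age - node.age
    return TimeTree(tree=work, calibration=calibration)
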