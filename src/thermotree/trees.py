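"""Calibrated phylogenies: container, supertree grafting, age calibration.

The central object is :class:`CalibratedTree`, a thin wrapper around a rooted
``dendropy.Tree`` with branch lengths in (relative) time units plus optional
per-tip family and order annotations.  It provides the two matrices every
comparative method in this package consumes:

* the Brownian-motion covariance ``C`` with ``C[i, j]`` equal to the depth of
  the most recent common ancestor of tips *i* and *j* (shared path length
  from the root), and
* the patristic distance matrix ``D = diag(C) + diag(C)' - 2 C``.

Tree-building operations mirror the supertree workflow used for barcode
communities: per-family subtrees are grafted onto a family-level backbone,
node ages are calibrated by even interpolation between constrained nodes
(the "bladj" rule), and terminal branches are stretched so all tips reach
the same height.
"""

from __future__ import annotations

import warnings
from collections import deque
from dataclasses import dataclass, field

import dendropy
import numpy as np

from .errors import ConstraintViolationError, UnknownFamilyError

__all__ = [
    "CalibratedTree",
    "graft_subtrees",
    "calibrate_ages",
    "equalize_tip_heights",
]


@dataclass
class CalibratedTree:
    """Rooted tree with branch lengths plus tip-level taxonomy.

    Parameters
    ----------
    tree:
        A rooted ``dendropy.Tree``.  Branch lengths are interpreted as
        (relative) time; a missing root edge length is treated as zero.
    family, order:
        Optional maps from tip label to family / order name.
    """

    tree: dendropy.Tree
    family: dict = field(default_factory=dict)
    order: dict = field(default_factory=dict)

    # -- construction --------------------------------------------------

    @classmethod
    def from_newick(cls, newick: str, family=None, order=None) -> "CalibratedTree":
        tree = dendropy.Tree.get(
            data=newick, schema="newick", preserve_underscores=True
        )
        return cls(tree, dict(family or {}), dict(order or {}))

    @classmethod
    def read_newick(cls, path, family=None, order=None) -> "CalibratedTree":
        with open(path) as fh:
            return cls.from_newick(fh.read(), family=family, order=order)

    def write_newick(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.as_newick() + "\n")

    def as_newick(self) -> str:
        return _serialize(self.tree.seed_node) + ";"

    def copy(self) -> "CalibratedTree":
        return CalibratedTree.from_newick(
            self.as_newick(), family=dict(self.family), order=dict(self.order)
        )

    # -- basic queries -------------------------------------------------

    @property
    def tip_labels(self) -> list:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return sum(1 for _ in self.tree.leaf_node_iter())

    def node_depths(self) -> dict:
        """Distance of every node from the root (root edge ignored)."""
        depths = {}
        for node in self.tree.preorder_node_iter():
            parent = node.parent_node
            if parent is None:
                depths[node] = 0.0
            else:
                depths[node] = depths[parent] + (node.edge.length or 0.0)
        return depths

    @property
    def depth(self) -> float:
        """Maximum root-to-tip path length."""
        depths = self.node_depths()
        return max(depths[leaf] for leaf in self.tree.leaf_node_iter())

    def is_ultrametric(self, rel_tol: float = 1e-6, abs_tol: float = 1e-9) -> bool:
        depths = self.node_depths()
        tip_depths = [depths[leaf] for leaf in self.tree.leaf_node_iter()]
        lo, hi = min(tip_depths), max(tip_depths)
        return (hi - lo) <= max(abs_tol, rel_tol * max(hi, 1e-300))

    # -- matrices ------------------------------------------------------

    def bm_covariance(self):
        """Brownian covariance structure of the tips.

        Returns ``(labels, C)`` with ``C[i, j]`` the depth of the MRCA of
        tips ``labels[i]`` and ``labels[j]`` and ``C[i, i]`` the tip depth.
        """
        labels = self.tip_labels
        index = {lab: i for i, lab in enumerate(labels)}
        n = len(labels)
        C = np.zeros((n, n))
        depths = self.node_depths()
        tipsets: dict = {}
        for node in self.tree.postorder_node_iter():
            if node.is_leaf():
                i = index[node.taxon.label]
                C[i, i] = depths[node]
                tipsets[node] = [i]
            else:
                groups = [tipsets.pop(ch) for ch in node.child_nodes()]
                d = depths[node]
                for a in range(len(groups)):
                    ia = np.asarray(groups[a])
                    for b in range(a + 1, len(groups)):
                        ib = np.asarray(groups[b])
                        C[np.ix_(ia, ib)] = d
                        C[np.ix_(ib, ia)] = d
                tipsets[node] = [i for g in groups for i in g]
        return labels, C

    def patristic_matrix(self):
        """Pairwise tip-to-tip path lengths, ordered like ``tip_labels``."""
        labels, C = self.bm_covariance()
        d = np.diag(C)
        return labels, d[:, None] + d[None, :] - 2.0 * C


def _serialize(node) -> str:
    if node.is_leaf():
        base = node.taxon.label if node.taxon is not None else (node.label or "")
    else:
        inner = ",".join(_serialize(ch) for ch in node.child_nodes())
        base = "(" + inner + ")" + (node.label or "")
    if node.edge.length is not None:
        base += ":" + format(node.edge.length, ".17g")
    return base


# ---------------------------------------------------------------------------
# supertree assembly
# ---------------------------------------------------------------------------


def graft_subtrees(
    backbone: CalibratedTree,
    subtrees: dict,
    singleton_branch: float | None = None,
) -> CalibratedTree:
    """Replace family tips of a backbone tree by per-family subtrees.

    Each backbone tip whose label matches a key of ``subtrees`` is replaced
    by the root of the corresponding subtree; the backbone terminal branch
    length is kept as the branch subtending the grafted subtree.  A family
    represented by a single tip becomes one pendant branch whose length is
    ``singleton_branch`` (default: half the family's backbone terminal
    branch).  Backbone families without a subtree are dropped with a
    warning.

    Raises
    ------
    UnknownFamilyError
        If a key of ``subtrees`` is not a backbone tip label.
    """
    tip_labels = set(backbone.tip_labels)
    unknown = sorted(set(subtrees) - tip_labels)
    if unknown:
        raise UnknownFamilyError(
            f"subtree families not found in backbone: {', '.join(unknown)}"
        )
    missing = sorted(tip_labels - set(subtrees))
    if missing:
        warnings.warn(
            f"dropping {len(missing)} backbone families without subtrees: "
            + ", ".join(missing),
            stacklevel=2,
        )

    family_map: dict = {}
    order_map: dict = {}

    def build(node) -> str | None:
        if node.is_leaf():
            fam = node.taxon.label
            if fam not in subtrees:
                return None
            term = node.edge.length or 0.0
            sub = subtrees[fam]
            subtree = sub.tree if isinstance(sub, CalibratedTree) else sub
            leaves = [lf for lf in subtree.leaf_node_iter()]
            for lf in leaves:
                family_map[lf.taxon.label] = fam
                if fam in backbone.order:
                    order_map[lf.taxon.label] = backbone.order[fam]
            if len(leaves) == 1:
                pend = (
                    singleton_branch if singleton_branch is not None else 0.5 * term
                )
                return "({}:{:.17g}):{:.17g}".format(leaves[0].taxon.label, pend, term)
            body = ",".join(_serialize(ch) for ch in subtree.seed_node.child_nodes())
            return "({}):{:.17g}".format(body, term)
        parts = [build(ch) for ch in node.child_nodes()]
        parts = [p for p in parts if p is not None]
        if not parts:
            return None
        if len(parts) == 1:
            return parts[0]
        base = "(" + ",".join(parts) + ")"
        if node.edge.length is not None:
            base += ":" + format(node.edge.length, ".17g")
        return base

    newick = build(backbone.tree.seed_node)
    if newick is None:
        raise UnknownFamilyError("no backbone family has a subtree; nothing to graft")
    return CalibratedTree.from_newick(newick + ";", family=family_map, order=order_map)


# ---------------------------------------------------------------------------
# age calibration (even interpolation between constrained nodes)
# ---------------------------------------------------------------------------


def calibrate_ages(tree: CalibratedTree, fixed_ages: dict) -> CalibratedTree:
    """Assign node ages by even interpolation between constrained nodes.

    ``fixed_ages`` maps internal-node labels to ages (time before present);
    tips are implicitly constrained at age 0 and the root age must be fixed.
    Every unconstrained internal node receives the age obtained by spacing
    nodes evenly (by node count) along the path from its nearest constrained
    ancestor to its nearest constrained descendant.  Branch lengths are then
    recomputed from the ages.

    Raises
    ------
    ConstraintViolationError
        If a constrained descendant is older than a constrained ancestor,
        or the root age is not fixed.
    """
    out = tree.copy()
    ages: dict = {}
    by_label = {}
    for node in out.tree.preorder_node_iter():
        if node.is_leaf():
            ages[node] = 0.0
            if node.taxon.label in fixed_ages:
                ages[node] = float(fixed_ages[node.taxon.label])
        elif node.label is not None:
            by_label[node.label] = node
    unknown = sorted(set(fixed_ages) - set(by_label) - set(tree.tip_labels))
    if unknown:
        raise ConstraintViolationError(
            f"fixed ages refer to unknown node labels: {', '.join(unknown)}"
        )
    for label, age in fixed_ages.items():
        if label in by_label:
            ages[by_label[label]] = float(age)

    root = out.tree.seed_node
    if root not in ages:
        raise ConstraintViolationError("root age must be fixed")

    # consistency among constrained nodes
    for node, age in ages.items():
        anc = node.parent_node
        while anc is not None:
            if anc in ages and ages[anc] < age - 1e-12:
                raise ConstraintViolationError(
                    f"constrained node at age {age} has constrained ancestor at "
                    f"younger age {ages[anc]}"
                )
            anc = anc.parent_node

    def nearest_constrained_descendant(node):
        """(age, steps) of the closest constrained node below, by edge count."""
        queue = deque((ch, 1) for ch in node.child_nodes())
        best = None
        while queue:
            nd, steps = queue.popleft()
            if nd in ages:
                if best is None or steps < best[1]:
                    best = (ages[nd], steps)
                continue  # do not search past a constrained node
            for ch in nd.child_nodes():
                queue.append((ch, steps + 1))
        return best

    for node in out.tree.preorder_node_iter():
        if node in ages or node.is_leaf():
            continue
        steps_up, anc = 1, node.parent_node
        while anc not in ages:
            steps_up += 1
            anc = anc.parent_node
        age_a = ages[anc]
        age_d, steps_down = nearest_constrained_descendant(node)
        ages[node] = age_a - (age_a - age_d) * steps_up / (steps_up + steps_down)

    for node in out.tree.preorder_node_iter():
        parent = node.parent_node
        if parent is None:
            continue
        length = ages[parent] - ages[node]
        if length < -1e-9:
            warnings.warn(
                "even-interpolation produced a negative branch; clamping to 0",
                stacklevel=2,
            )
            length = 0.0
        node.edge.length = max(length, 0.0)
    return out


def equalize_tip_heights(tree: CalibratedTree) -> CalibratedTree:
    """Stretch terminal branches so every tip reaches the maximum depth.

    Internal branches are untouched; a terminal branch that would become
    negative is clamped to zero with a warning.  The result passes the
    ultrametric check (up to clamping).
    """
    out = tree.copy()
    depths = out.node_depths()
    target = max(depths[leaf] for leaf in out.tree.leaf_node_iter())
    for leaf in out.tree.leaf_node_iter():
        new_len = (leaf.edge.length or 0.0) + (target - depths[leaf])
        if new_len < 0:
            warnings.warn(
                f"terminal branch of {leaf.taxon.label} clamped to 0", stacklevel=2
            )
            new_len = 0.0
        leaf.edge.length = new_len
    return out
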