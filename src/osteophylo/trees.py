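"""Time-calibrated phylogenies: Newick I/O, recalibration, fossil grafting,
and lambda-scaled phylogenetic covariance matrices.

Trees are rooted, binary, with branch lengths in millions of years (Ma).
Non-ultrametric trees are first-class citizens: a fossil tip ends above the
present, so its root-to-tip path length (its *height*) is smaller than the
root age, and its *age* (Ma before present) is positive.  The diagonal of
the phylogenetic covariance matrix equals tip heights, which is what makes
the variance-heterogeneity weights of the downstream GLS meaningful.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterator

import dendropy
import numpy as np

__all__ = [
    "Node",
    "TimeTree",
    "FossilGraft",
    "read_tree",
    "write_tree",
    "recalibrate_divergence",
    "graft_fossil",
    "phylo_vcv",
]


class TreeError(ValueError):
    """Structural or calibration problem with a time tree."""


class Node:
    """A node of a rooted tree; ``length`` is the edge to the parent (Ma)."""

    __slots__ = ("name", "length", "children", "parent")

    def __init__(self, name: str | None = None, length: float = 0.0):
        self.name = name
        self.length = float(length)
        self.children: list[Node] = []
        self.parent: Node | None = None

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Node({self.name!r}, length={self.length})"


class TimeTree:
    """Rooted binary tree with branch lengths in Ma.

    Depths are measured from the root (root depth 0); the *root age* is the
    maximum root-to-tip depth, so extant tips have age 0 and truncated
    (fossil) tips have positive age.
    """

    def __init__(self, root: Node):
        self.root = root
        self._validate()

    # -- construction / validation -------------------------------------
    def _validate(self) -> None:
        names = []
        for node in self.preorder():
            if len(node.children) == 1:
                raise TreeError("unifurcation encountered")
            if len(node.children) > 2:
                raise TreeError(
                    "polytomy encountered; only binary trees are supported"
                )
            if node is not self.root and node.length <= 0:
                raise TreeError(
                    f"non-positive branch length at {node.name or 'internal node'}"
                )
            if node.is_leaf:
                if not node.name:
                    raise TreeError("unnamed tip")
                names.append(node.name)
        if len(set(names)) != len(names):
            raise TreeError("duplicate tip names")

    # -- traversal ------------------------------------------------------
    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator[Node]:
        out = list(self.preorder())
        return iter(reversed(out))

    def tips(self) -> list[Node]:
        return [n for n in self.preorder() if n.is_leaf]

    def tip_names(self) -> list[str]:
        return [n.name for n in self.tips()]

    def internal_nodes(self) -> list[Node]:
        return [n for n in self.preorder() if not n.is_leaf]

    # -- geometry -------------------------------------------------------
    def depths(self) -> dict[Node, float]:
        """Root-to-node path lengths (root at depth 0)."""
        d: dict[Node, float] = {self.root: self.root.length * 0.0}
        for node in self.preorder():
            if node is self.root:
                d[node] = 0.0
            else:
                d[node] = d[node.parent] + node.length
        return d

    @property
    def root_age(self) -> float:
        d = self.depths()
        return max(d[t] for t in self.tips())

    def tip_heights(self) -> dict[str, float]:
        d = self.depths()
        return {t.name: d[t] for t in self.tips()}

    def tip_ages(self) -> dict[str, float]:
        """Ma before present; 0 for extant tips, >0 for fossil tips."""
        ra = self.root_age
        return {name: ra - h for name, h in self.tip_heights().items()}

    def node_age(self, node: Node) -> float:
        return self.root_age - self.depths()[node]

    def is_ultrametric(self, tol: float = 1e-8) -> bool:
        h = list(self.tip_heights().values())
        return max(h) - min(h) <= tol

    def find_tip(self, name: str) -> Node:
        for t in self.tips():
            if t.name == name:
                return t
        raise KeyError(f"tip {name!r} not in tree")

    def mrca(self, *names: str) -> Node:
        """Most recent common ancestor of the named tips (a single name is
        its own MRCA, i.e. the tip node)."""
        if not names:
            raise ValueError("mrca requires at least one tip name")
        paths = []
        for nm in names:
            node = self.find_tip(nm)
            path = []
            while node is not None:
                path.append(node)
                node = node.parent
            paths.append(set(path[:]) if len(names) > 1 else path)
        if len(names) == 1:
            return paths[0][0]
        common = set.intersection(*[set(p) for p in paths])
        # deepest common ancestor
        d = self.depths()
        return max(common, key=lambda n: d[n])

    # -- copying / editing ----------------------------------------------
    def copy(self) -> "TimeTree":
        def rec(node: Node) -> Node:
            new = Node(node.name, node.length)
            for c in node.children:
                new.add_child(rec(c))
            return new

        return TimeTree(rec(self.root))

    def prune_tip(self, name: str) -> "TimeTree":
        """Return a copy with the named tip removed and the resulting
        unifurcation suppressed (branch lengths merged)."""
        new = self.copy()
        tip = new.find_tip(name)
        parent = tip.parent
        if parent is None:
            raise TreeError("cannot prune the only node")
        parent.children.remove(tip)
        (sibling,) = parent.children
        grand = parent.parent
        if grand is None:
            # parent was the root: sibling becomes the new root
            sibling.parent = None
            sibling.length = 0.0
            return TimeTree(sibling)
        sibling.length += parent.length
        grand.children[grand.children.index(parent)] = sibling
        sibling.parent = grand
        return TimeTree(new.root)

    # -- Newick ---------------------------------------------------------
    def to_newick(self) -> str:
        def rec(node: Node) -> str:
            if node.is_leaf:
                core = node.name
            else:
                core = "(" + ",".join(rec(c) for c in node.children) + ")"
                if node.name:
                    core += node.name
            if node is self.root:
                return core
            return f"{core}:{node.length:.12g}"

        return rec(self.root) + ";"

    @classmethod
    def from_newick(cls, newick: str) -> "TimeTree":
        return read_tree(newick)

    def __len__(self) -> int:
        return len(self.tips())


def read_tree(newick: str) -> TimeTree:
    """Parse a Newick string (or file-like content) into a :class:`TimeTree`.

    Branch lengths are required on every non-root edge; polytomies are
    rejected (the source timetrees are binary, and a polytomy would make
    the covariance construction ambiguous).
    """
    dtree = dendropy.Tree.get(
        data=newick, schema="newick", suppress_internal_node_taxa=False
    )

    def convert(dnode) -> Node:
        label = None
        if dnode.taxon is not None:
            label = dnode.taxon.label
        elif dnode.label:
            label = dnode.label
        length = dnode.edge.length
        if length is None:
            if dnode.parent_node is not None:
                raise TreeError("missing branch length in Newick input")
            length = 0.0
        node = Node(label, length)
        for c in dnode.child_nodes():
            node.add_child(convert(c))
        return node

    root = convert(dtree.seed_node)
    return TimeTree(root)


def write_tree(tree: TimeTree) -> str:
    """Serialize to Newick; ``read_tree(write_tree(t))`` preserves topology
    and branch lengths to well below 1e-9."""
    return tree.to_newick()


@dataclass
class FossilGraft:
    """Specification for attaching a fossil tip to a tree.

    The attachment clade is named by one or two spanning tips (one tip means
    the fossil goes on that terminal branch).  ``rule`` selects where on the
    clade's stem edge the new divergence sits:

    - ``{"fraction": f}``: at fraction ``f`` of the stem edge measured from
      the older (rootward) node.
    - ``{"divergence_age": a}``: at an explicit age ``a`` Ma.
    - ``{"push_node": delta}``: at age ``fossil_age + delta`` Ma (used to
      accommodate fossils older than the clade's crown age).
    """

    name: str
    age: float
    spanning: tuple[str, ...]
    rule: dict = field(default_factory=lambda: {"fraction": 0.5})
    variant_label: str = ""


def recalibrate_divergence(
    tree: TimeTree, tip_a: str, tip_b: str, new_age: float
) -> TimeTree:
    """Move the divergence (MRCA) of two tips to ``new_age`` Ma.

    Adjacent branch lengths absorb the change; every other node age is
    untouched.  The new age must lie strictly between the ages of the
    clade's parent node and its children.
    """
    new = tree.copy()
    node = new.mrca(tip_a, tip_b)
    if node.is_leaf:
        raise TreeError("cannot recalibrate a terminal node")
    depths = new.depths()
    root_age = new.root_age
    cur_depth = depths[node]
    new_depth = root_age - new_age
    parent = node.parent
    if parent is not None and new_depth <= depths[parent]:
        raise TreeError(
            f"calibration conflict: new age {new_age} Ma is older than the "
            f"parent node ({root_age - depths[parent]:.6g} Ma)"
        )
    for c in node.children:
        if new_depth >= depths[c]:
            raise TreeError(
                f"calibration conflict: new age {new_age} Ma is younger than "
                f"child node/tip ({root_age - depths[c]:.6g} Ma)"
            )
    shift = new_depth - cur_depth
    if parent is not None:
        node.length += shift
    for c in node.children:
        c.length -= shift
    return new


def graft_fossil(tree: TimeTree, graft: FossilGraft) -> TimeTree:
    """Attach a fossil tip according to a :class:`FossilGraft`.

    The new divergence node is inserted on the stem edge of the attachment
    clade; the fossil's terminal branch length is the divergence age minus
    the fossil age and must be positive.
    """
    new = tree.copy()
    root_age = new.root_age  # fixed by the extant tips; grafting cannot deepen it
    host = new.mrca(*graft.spanning)
    parent = host.parent
    if parent is None:
        raise TreeError("cannot graft onto the root edge")
    depths = new.depths()
    stem_len = host.length
    depth_parent = depths[parent]
    depth_host = depths[host]

    rule = dict(graft.rule)
    if "fraction" in rule:
        f = float(rule["fraction"])
        if not 0.0 < f < 1.0:
            raise TreeError("placement fraction must lie in (0, 1)")
        depth_div = depth_parent + f * stem_len
    elif "divergence_age" in rule:
        depth_div = root_age - float(rule["divergence_age"])
    elif "push_node" in rule:
        depth_div = root_age - (graft.age + float(rule["push_node"]))
    else:
        raise TreeError(f"unknown graft rule {rule!r}")

    if not (depth_parent < depth_div < depth_host + 1e-12):
        age_div = root_age - depth_div
        raise TreeError(
            f"calibration conflict: divergence age {age_div:.6g} Ma does not "
            f"fit on the stem edge (parent age "
            f"{root_age - depth_parent:.6g} Ma, node age "
            f"{root_age - depth_host:.6g} Ma)"
        )
    fossil_height = root_age - graft.age
    terminal = fossil_height - depth_div
    if terminal <= 0:
        raise TreeError(
            f"calibration conflict: fossil {graft.name!r} (age {graft.age} Ma) "
            f"is older than its divergence ({root_age - depth_div:.6g} Ma)"
        )

    div = Node(None, depth_div - depth_parent)
    parent.children[parent.children.index(host)] = div
    div.parent = parent
    host.length = depth_host - depth_div
    div.add_child(host)
    div.add_child(Node(graft.name, terminal))
    return TimeTree(new.root)


def phylo_vcv(
    tree: TimeTree, lam: float = 1.0, tip_order: list[str] | None = None
) -> tuple[list[str], np.ndarray]:
    """Lambda-scaled phylogenetic covariance matrix.

    ``V[i, j]`` for i != j is the shared root-to-MRCA path length multiplied
    by ``lam``; ``V[i, i]`` is the tip height, left unscaled.  Scaling only
    the off-diagonals is Pagel's lambda transform in its correlation-structure
    form; it keeps the diagonal equal to tip heights, which the GLS stage
    uses as variance-heterogeneity weights on non-ultrametric trees.
    """
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lambda must lie in [0, 1]")
    tips = tree.tips()
    names = [t.name for t in tips]
    idx = {t: i for i, t in enumerate(tips)}
    n = len(tips)
    depths = tree.depths()
    V = np.zeros((n, n))

    # tip index sets per subtree, bottom-up; cross products get the node depth
    subtree: dict[Node, list[int]] = {}
    for node in tree.postorder():
        if node.is_leaf:
            subtree[node] = [idx[node]]
            V[idx[node], idx[node]] = depths[node]
        else:
            left, right = (subtree[c] for c in node.children)
            d = depths[node]
            for i in left:
                V[i, right] = d
                V[right, i] = d
            subtree[node] = left + right

    off = ~np.eye(n, dtype=bool)
    V[off] *= lam

    if tip_order is not None:
        order = [names.index(nm) for nm in tip_order]
        V = V[np.ix_(order, order)]
        names = list(tip_order)
    return names, V
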