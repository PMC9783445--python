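"""Synthetic study systems: Yule timetrees, subterranean regime paintings,
BM/OU trait evolution, and trabecular voxel phantoms of known geometry.

The defaults emulate the study system of the downstream analysis: a
mammal-scale timetree (155 tips, root age 160 Ma) on which a subterranean
lifestyle arose independently about a dozen times, one of those origins
(the "talpid-like" clade) having pushed the phenotype beyond the optimum
apparently shared by the other subterranean lineages.  Traits evolve under
Brownian motion (the null of the convergence test) or under a
multi-optimum Ornstein-Uhlenbeck process with one optimum per regime.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .trees import Node, TimeTree, TreeError
from .volumes import VoxelVolume

__all__ = [
    "RegimeTree",
    "TraitSimConfig",
    "PhantomSpec",
    "VoxelVolume",
    "simulate_tree",
    "paint_regimes",
    "simulate_traits",
    "generate_phantom",
    "DEFAULT_N_TIPS",
    "DEFAULT_ROOT_AGE",
    "DEFAULT_N_SHIFTS",
]

DEFAULT_N_TIPS = 155
DEFAULT_ROOT_AGE = 160.0  # Ma; span of the deepest therian divergences
DEFAULT_N_SHIFTS = 11  # independent subterranean acquisitions sampled

BACKGROUND = "background"
SUBTERRANEAN = "subterranean"
TALPID_LIKE = "talpid_like"


@dataclass
class RegimeTree:
    """A timetree with a regime painted on every branch and tip.

    Each subterranean shift paints a connected subtree rooted at the shift
    edge, so shifts are independent (no painted edge is ancestral to
    another shift edge) and the number of acquisitions is recoverable.
    """

    tree: TimeTree
    regime_of_tip: dict[str, str]
    regime_of_branch: dict[Node, str]
    shift_nodes: list[Node] = field(default_factory=list)

    def acquisition_members(self) -> dict[str, list[str]]:
        """Map acquisition name -> member tip names (one entry per shift)."""
        out: dict[str, list[str]] = {}
        for k, node in enumerate(self.shift_nodes):
            members = (
                [node.name]
                if node.is_leaf
                else [t.name for t in _subtree_tips(node)]
            )
            regime = self.regime_of_branch[node]
            out[f"acq_{k + 1:02d}_{regime}"] = members
        return out


def _subtree_tips(node: Node) -> list[Node]:
    stack, tips = [node], []
    while stack:
        n = stack.pop()
        if n.is_leaf:
            tips.append(n)
        else:
            stack.extend(reversed(n.children))
    return tips


@dataclass
class TraitSimConfig:
    """Parameters of the trait-evolution simulation.

    sigma2 is the Brownian rate (trait units squared per Ma); alpha the OU
    pull towards the optimum (per Ma, 0 for BM); theta_by_regime maps each
    regime to its optimum (ignored under BM).
    """

    model: str = "BM"  # "BM" or "OU"
    sigma2: float = 0.02
    alpha: float = 0.0
    theta_by_regime: dict[str, float] = field(
        default_factory=lambda: {
            BACKGROUND: 0.0,
            SUBTERRANEAN: 1.0,
            TALPID_LIKE: 2.0,
        }
    )
    root_state: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.model not in ("BM", "OU"):
            raise ValueError("model must be 'BM' or 'OU'")
        if self.sigma2 <= 0:
            raise ValueError("sigma2 must be positive")
        if self.alpha < 0:
            raise ValueError("alpha must be non-negative")
        if self.model == "OU" and self.alpha == 0:
            raise ValueError("OU requires alpha > 0 (use model='BM' instead)")


@dataclass
class PhantomSpec:
    """Voxel phantom of known bone fraction and strut geometry.

    kind: solid | empty | rod_lattice | plate_stack | grf.
    element_thickness is the rod diameter or plate thickness in mm;
    target_bvtv applies to Gaussian-random-field ("grf") phantoms only.
    """

    kind: str
    dims: int = 64
    voxel_size: float = 0.01
    element_thickness: float = 0.1
    target_bvtv: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if self.kind not in ("solid", "empty", "rod_lattice", "plate_stack", "grf"):
            raise ValueError(f"unknown phantom kind {self.kind!r}")
        if self.kind in ("rod_lattice", "plate_stack", "grf"):
            if self.dims < 32:
                raise ValueError("dims must be >= 32 for structured phantoms")
            if self.element_thickness < 3 * self.voxel_size:
                raise ValueError(
                    "element thickness must be at least 3 voxels for the "
                    "discretized thickness to be meaningful"
                )
        if self.kind == "grf" and not 0.0 < self.target_bvtv < 1.0:
            raise ValueError("target_bvtv must lie in (0, 1)")


# ---------------------------------------------------------------------------
# trees and regimes
# ---------------------------------------------------------------------------

def simulate_tree(
    n_tips: int,
    seed: int = 0,
    fossil_tips: int = 0,
    root_age: float = DEFAULT_ROOT_AGE,
) -> TimeTree:
    """Pure-birth (Yule) tree scaled to ``root_age`` Ma.

    ``fossil_tips`` randomly chosen tips are truncated above the present
    (terminal branch shortened by a uniform fraction of its length), making
    the tree non-ultrametric the way fossil-bearing timetrees are.
    """
    if n_tips < 4:
        raise ValueError("n_tips must be >= 4")
    if fossil_tips >= n_tips:
        raise ValueError("fossil_tips must be smaller than n_tips")
    rng = np.random.default_rng(seed)

    # Yule process: grow by splitting a uniformly chosen extant lineage at
    # exponential waiting times, then extend all pendant branches to the
    # final epoch and rescale depth to root_age.
    root = Node()
    t = 0.0
    birth = 1.0
    active: list[tuple[Node, float]] = []  # (node, birth time of its edge)
    a, b = Node(), Node()
    root.add_child(a)
    root.add_child(b)
    active = [(a, 0.0), (b, 0.0)]
    while len(active) < n_tips:
        t += rng.exponential(1.0 / (birth * len(active)))
        i = rng.integers(len(active))
        node, t0 = active.pop(i)
        node.length = t - t0
        c1, c2 = Node(), Node()
        node.add_child(c1)
        node.add_child(c2)
        active.append((c1, t))
        active.append((c2, t))
    t += rng.exponential(1.0 / (birth * len(active)))
    for k, (node, t0) in enumerate(active):
        node.length = t - t0
        node.name = f"t{k + 1}"
    tree = TimeTree(root)

    # scale to root_age
    scale = root_age / tree.root_age
    for node in tree.preorder():
        node.length *= scale

    if fossil_tips:
        tips = tree.tips()
        chosen = rng.choice(len(tips), size=fossil_tips, replace=False)
        for i in sorted(chosen):
            tip = tips[i]
            frac = rng.uniform(0.1, 0.9)
            tip.length *= 1.0 - frac
    return TimeTree(tree.root)


def paint_regimes(
    tree: TimeTree,
    n_shifts: int,
    seed: int = 0,
    talpid_like: bool = True,
    max_tries: int = 1000,
) -> RegimeTree:
    """Paint ``n_shifts`` independent (non-nested) subterranean origins.

    Shift edges are drawn by rejection sampling among non-root edges until
    no chosen edge is ancestral to another; each shift paints its whole
    subtree.  With ``talpid_like`` one shift (the first) is flagged as the
    extreme-optimum clade.
    """
    nodes = [n for n in tree.preorder() if n is not tree.root]
    internal = [n for n in nodes if not n.is_leaf]
    if n_shifts > len(internal) + len(nodes):
        raise TreeError("more shifts requested than available edges")
    rng = np.random.default_rng(seed)

    ancestors: dict[Node, set] = {}
    for node in tree.preorder():
        anc = ancestors.get(node.parent, set()) | (
            {node.parent} if node.parent is not None else set()
        )
        ancestors[node] = anc

    shift_nodes: list[Node] = []
    if n_shifts > 0:
        for _ in range(max_tries):
            picks = list(rng.choice(len(nodes), size=n_shifts, replace=False))
            cand = [nodes[i] for i in picks]
            cset = set(cand)
            if any(ancestors[c] & cset for c in cand):
                continue
            shift_nodes = cand
            break
        else:
            raise TreeError(
                f"could not place {n_shifts} non-nested shifts in "
                f"{max_tries} tries"
            )

    regime_of_branch: dict[Node, str] = {
        n: BACKGROUND for n in tree.preorder() if n is not tree.root
    }
    for k, shift in enumerate(shift_nodes):
        regime = TALPID_LIKE if (talpid_like and k == 0) else SUBTERRANEAN
        stack = [shift]
        while stack:
            n = stack.pop()
            regime_of_branch[n] = regime
            stack.extend(n.children)

    regime_of_tip = {
        t.name: regime_of_branch.get(t, BACKGROUND) for t in tree.tips()
    }
    return RegimeTree(tree, regime_of_tip, regime_of_branch, shift_nodes)


def simulate_traits(
    rtree: RegimeTree | TimeTree, cfg: TraitSimConfig
) -> dict[str, float]:
    """Simulate a continuous trait along the tree, branch by branch.

    BM: child = parent + N(0, sigma2 * t).  OU uses the exact transition
    density, mean theta + (parent - theta) * exp(-alpha t) and variance
    sigma2 * (1 - exp(-2 alpha t)) / (2 alpha), so no discretization error
    enters recovery experiments.  The regime of each branch selects theta.
    """
    if isinstance(rtree, TimeTree):
        tree = rtree
        regime_of_branch: dict[Node, str] = {}
    else:
        tree = rtree.tree
        regime_of_branch = rtree.regime_of_branch
    rng = np.random.default_rng(cfg.seed)
    state: dict[Node, float] = {tree.root: cfg.root_state}
    out: dict[str, float] = {}
    for node in tree.preorder():
        if node is tree.root:
            continue
        parent = state[node.parent]
        t = node.length
        if cfg.model == "BM":
            val = parent + rng.normal(0.0, np.sqrt(cfg.sigma2 * t))
        else:
            theta = cfg.theta_by_regime.get(
                regime_of_branch.get(node, BACKGROUND), 0.0
            )
            decay = np.exp(-cfg.alpha * t)
            mean = theta + (parent - theta) * decay
            var = cfg.sigma2 * (1.0 - decay**2) / (2.0 * cfg.alpha)
            val = mean + rng.normal(0.0, np.sqrt(var))
        state[node] = val
        if node.is_leaf:
            out[node.name] = val
    return out


# ---------------------------------------------------------------------------
# voxel phantoms
# ---------------------------------------------------------------------------

def generate_phantom(spec: PhantomSpec) -> VoxelVolume:
    """Binary voxel phantom of known bone fraction / strut thickness."""
    n = spec.dims
    if spec.kind == "solid":
        grid = np.ones((n, n, n), dtype=np.uint8)
    elif spec.kind == "empty":
        grid = np.zeros((n, n, n), dtype=np.uint8)
    elif spec.kind == "plate_stack":
        grid = _plate_stack(n, spec.element_thickness / spec.voxel_size)
    elif spec.kind == "rod_lattice":
        grid = _rod_lattice(n, spec.element_thickness / spec.voxel_size)
    else:
        grid = _grf(spec)
    return VoxelVolume(grid, spec.voxel_size, binary=True)


def _plate_stack(n: int, thickness_vox: float) -> np.ndarray:
    """Parallel slabs of the stated thickness normal to z, separated by gaps
    of twice the thickness (plates never merge).  Plates are kept clear of
    the volume faces so the distance transform sees both plate surfaces."""
    t = int(round(thickness_vox))
    period = 3 * t
    grid = np.zeros((n, n, n), dtype=np.uint8)
    for start in range(t, n - t, period):
        grid[:, :, start : start + t] = 1
    return grid


def _rod_lattice(n: int, diameter_vox: float) -> np.ndarray:
    """Three orthogonal families of axis-aligned cylinders on a regular grid
    (spacing 4x the diameter), forming a connected strut lattice."""
    r = diameter_vox / 2.0
    spacing = max(int(round(4 * diameter_vox)), 1)
    centers = np.arange(spacing // 2, n, spacing)
    ax = np.arange(n)
    # per-axis distance to the nearest rod centerline coordinate
    dc = np.min(np.abs(ax[:, None] - centers[None, :]), axis=1).astype(float)
    cross = dc[:, None] ** 2 + dc[None, :] ** 2 <= r * r
    grid = np.zeros((n, n, n), dtype=bool)
    grid |= cross[None, :, :]  # rods along x (cross-section in y, z)
    grid |= cross[:, None, :]  # rods along y
    grid |= cross[:, :, None]  # rods along z
    return grid.astype(np.uint8)


def _grf(spec: PhantomSpec) -> np.ndarray:
    """Smoothed Gaussian noise thresholded to the target bone fraction.

    Smoothing kernel sigma is half the element thickness (in voxels); the
    threshold is found by bisection on the achieved BV/TV, so the realized
    fraction is within 0.01 of the target by construction.
    """
    n = spec.dims
    rng = np.random.default_rng(spec.seed)
    noise = rng.standard_normal((n, n, n))
    sigma = (spec.element_thickness / spec.voxel_size) / 2.0
    field_ = ndimage.gaussian_filter(noise, sigma=sigma)

    lo, hi = float(field_.min()), float(field_.max())
    target = spec.target_bvtv
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        frac = float((field_ >= mid).mean())
        if abs(frac - target) < 1e-4:
            break
        if frac > target:
            lo = mid
        else:
            hi = mid
    return (field_ >= mid).astype(np.uint8)
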