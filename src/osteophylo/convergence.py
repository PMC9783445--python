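"""Univariate convergence test: the C1 statistic of Stayton on an
acquisition-collapsed tree, with BM ancestral-state reconstruction and a
Brownian-motion simulation null.

C1 for a pair of focal tips is 1 - Dtip/Dmax, where Dtip is the present
phenotypic distance between the tips and Dmax the largest phenotypic
distance attained between any two of their ancestors (tips included) since
their divergence; ancestral phenotypes are maximum-likelihood BM
reconstructions.  Over several focal tips, Dtip and Dmax are summed across
all pairs before taking the ratio.  C1 = 1 means the tips converged all
the way back from their most disparate ancestors; C1 = 0 means they are
now as distant as their lineages ever were.

Significance is assessed against BM: the Brownian rate is estimated from
the observed traits on the collapsed tree, replicate datasets are
simulated under that rate, and the p-value is the (add-one-corrected)
fraction of replicates whose C1 reaches the observed value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve, cholesky

from .trees import Node, TimeTree, phylo_vcv

__all__ = [
    "CollapsedTree",
    "ConvergenceResult",
    "collapse_acquisitions",
    "asr_bm",
    "C1Engine",
    "c1_statistic",
    "c1_significance",
    "UndefinedC1Error",
]


class UndefinedC1Error(ValueError):
    """All reconstructed states identical: the C1 denominator is zero."""


@dataclass
class CollapsedTree:
    """Tree in which each independent acquisition is a single tip.

    ``members`` records which source-tree tips each collapsed tip stands
    for; collapsed traits are arithmetic means of member values, and each
    collapsed tip sits on its clade's stem with height equal to the mean
    member tip height.
    """

    tree: TimeTree
    traits: dict[str, float]
    members: dict[str, list[str]]

    @property
    def acquisition_tips(self) -> list[str]:
        return list(self.members)


@dataclass
class ConvergenceResult:
    c1: float
    p_value: float | None = None
    n_sim: int = 0
    n_dropped: int = 0
    sigma2_used: float | None = None
    per_pair: list[tuple[str, str, float, float]] = field(default_factory=list)
    seed: int | None = None
    focal_tips: list[str] = field(default_factory=list)


def collapse_acquisitions(
    tree: TimeTree,
    clade_map: dict[str, list[str]],
    traits: dict[str, float],
) -> CollapsedTree:
    """Collapse each acquisition's member tips to a single stem tip.

    Each acquisition's members must form a monophyletic tip set (singletons
    allowed) and memberships must not overlap.  The collapsed tip's trait
    is the mean of the member traits; its height is the mean member height.
    """
    seen: set[str] = set()
    for name, members in clade_map.items():
        if not members:
            raise ValueError(f"acquisition {name!r} has no members")
        overlap = seen & set(members)
        if overlap:
            raise ValueError(f"overlapping clade memberships: {sorted(overlap)}")
        seen |= set(members)

    new = tree.copy()
    for name, members in clade_map.items():
        for m in members:
            if m not in traits:
                raise ValueError(f"no trait value for member {m!r}")
        heights = new.tip_heights()
        mean_height = float(np.mean([heights[m] for m in members]))
        mean_trait = float(np.mean([traits[m] for m in members]))
        if len(members) == 1:
            tip = new.find_tip(members[0])
            tip.name = name
        else:
            node = new.mrca(*members)
            clade_tips = sorted(
                t.name for t in new.tips()
                if _is_descendant(t, node) or t is node
            )
            if clade_tips != sorted(members):
                raise ValueError(
                    f"acquisition {name!r} is not monophyletic: clade of the "
                    f"MRCA contains {clade_tips}"
                )
            parent = node.parent
            if parent is None:
                raise ValueError(
                    f"acquisition {name!r} spans the whole tree"
                )
            depth_parent = new.depths()[parent]
            leaf = Node(name, mean_height - depth_parent)
            parent.children[parent.children.index(node)] = leaf
            leaf.parent = parent
        traits = {**traits, name: mean_trait}
    collapsed = TimeTree(new.root)
    tip_set = set(collapsed.tip_names())
    collapsed_traits = {
        k: float(v) for k, v in traits.items() if k in tip_set
    }
    missing = tip_set - set(collapsed_traits)
    if missing:
        raise ValueError(f"tips without traits after collapsing: {sorted(missing)}")
    return CollapsedTree(collapsed, collapsed_traits, dict(clade_map))


def _is_descendant(node: Node, ancestor: Node) -> bool:
    p = node.parent
    while p is not None:
        if p is ancestor:
            return True
        p = p.parent
    return False


def asr_bm(tree: TimeTree, traits: dict[str, float]) -> dict[Node, float]:
    """Maximum-likelihood ancestral states under Brownian motion.

    Equivalent to the GLS reconstruction: the root state is the GLS mean
    and each internal state is the conditional expectation of the BM
    process given the tip data.  Returns a map over *all* nodes (tips carry
    their observed values).
    """
    engine = C1Engine(tree)
    y = np.array([traits[nm] for nm in engine.tip_names], dtype=float)
    states = engine.ancestral_states(y[:, None])[:, 0]
    out: dict[Node, float] = {}
    for i, tip in enumerate(engine.tips):
        out[tip] = float(y[i])
    for k, node in enumerate(engine.internal):
        out[node] = float(states[k])
    return out


class C1Engine:
    """Precomputed machinery for repeated ASR / C1 evaluation on one tree.

    Building the engine factors the BM covariance once; each subsequent
    trait vector (or batch of simulated vectors) costs a matrix-vector
    solve, which is what makes the simulation null affordable.
    """

    def __init__(self, tree: TimeTree):
        self.tree = tree
        self.tips = tree.tips()
        self.tip_names = [t.name for t in self.tips]
        self.internal = tree.internal_nodes()
        self._int_index = {n: k for k, n in enumerate(self.internal)}
        self._tip_index = {t.name: i for i, t in enumerate(self.tips)}
        self.depths = tree.depths()

        _, C = phylo_vcv(tree, 1.0, tip_order=self.tip_names)
        self._C = C
        self._cho = cho_factor(C, lower=True)
        self._w1 = cho_solve(self._cho, np.ones(len(self.tips)))
        self._w1_sum = float(self._w1.sum())
        # cross-covariance of internal nodes with tips: shared root-to-MRCA
        # path length.  For a tip inside the node's subtree the MRCA is the
        # node itself (depth of the node); for any other tip the node's
        # path to the root coincides with that of any of its descendant
        # tips, so the shared path equals the tip-tip covariance of a
        # representative descendant.
        subtree_idx: dict[Node, list[int]] = {}
        for node in tree.postorder():
            if node.is_leaf:
                subtree_idx[node] = [self._tip_index[node.name]]
            else:
                subtree_idx[node] = [
                    i for c in node.children for i in subtree_idx[c]
                ]
        A = np.zeros((len(self.internal), len(self.tips)))
        for k, node in enumerate(self.internal):
            below = subtree_idx[node]
            A[k, :] = C[below[0], :]
            A[k, below] = self.depths[node]
        self._K = cho_solve(self._cho, A.T).T  # A @ C^-1
        self._chol_L = cholesky(C, lower=True)  # for BM simulation

    # -- ancestral states ------------------------------------------------
    def gls_root(self, Y: np.ndarray) -> np.ndarray:
        """GLS (BM ML) root estimate for each column of Y (n_tips x m)."""
        return (self._w1 @ Y) / self._w1_sum

    def ancestral_states(self, Y: np.ndarray) -> np.ndarray:
        """ML internal-node states, (n_internal x m) for Y (n_tips x m)."""
        mu = self.gls_root(Y)
        return mu[None, :] + self._K @ (Y - mu[None, :])

    def sigma2_reml(self, y: np.ndarray) -> float:
        """REML estimate of the BM rate from one trait vector."""
        mu = float(self.gls_root(y[:, None])[0])
        r = y - mu
        return float(r @ cho_solve(self._cho, r)) / (len(y) - 1)

    def simulate_bm(self, mu: float, sigma2: float, n_sim: int, rng) -> np.ndarray:
        """Tip states of BM datasets, exact MVN(mu, sigma2 * C) sampling."""
        Z = rng.standard_normal((len(self.tips), n_sim))
        return mu + np.sqrt(sigma2) * (self._chol_L @ Z)

    # -- C1 ---------------------------------------------------------------
    def _pair_paths(self, focal: list[str]):
        """For each focal pair: tip indices and internal-node index lists of
        the two tip-to-MRCA paths (MRCA included)."""
        pairs = []
        for a in range(len(focal)):
            for b in range(a + 1, len(focal)):
                ti, tj = focal[a], focal[b]
                mrca = self.tree.mrca(ti, tj)
                pairs.append(
                    (
                        ti,
                        tj,
                        self._tip_index[ti],
                        self._tip_index[tj],
                        self._path_internal(self.tree.find_tip(ti), mrca),
                        self._path_internal(self.tree.find_tip(tj), mrca),
                    )
                )
        return pairs

    def _path_internal(self, tip: Node, mrca: Node) -> np.ndarray:
        idx = []
        node = tip.parent
        while node is not None:
            idx.append(self._int_index[node])
            if node is mrca:
                break
            node = node.parent
        else:  # pragma: no cover - mrca is always on the path
            raise RuntimeError("MRCA not found on tip path")
        return np.asarray(idx, dtype=int)

    def c1_values(
        self, Y: np.ndarray, focal: list[str]
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """C1 for each column of Y; returns (c1, sum_dtip, sum_dmax).

        Columns whose total Dmax is zero yield NaN (undefined C1).
        """
        S = self.ancestral_states(Y)
        pairs = self._pair_paths(focal)
        m = Y.shape[1]
        sum_dtip = np.zeros(m)
        sum_dmax = np.zeros(m)
        for _, _, i, j, pi, pj in pairs:
            si = np.vstack([Y[i][None, :], S[pi]])
            sj = np.vstack([Y[j][None, :], S[pj]])
            dmax = np.maximum(
                si.max(axis=0) - sj.min(axis=0), sj.max(axis=0) - si.min(axis=0)
            )
            sum_dtip += np.abs(Y[i] - Y[j])
            sum_dmax += dmax
        with np.errstate(invalid="ignore", divide="ignore"):
            c1 = 1.0 - sum_dtip / sum_dmax
        c1[sum_dmax == 0.0] = np.nan
        return c1, sum_dtip, sum_dmax

    def per_pair(self, y: np.ndarray, focal: list[str]):
        S = self.ancestral_states(y[:, None])[:, 0]
        out = []
        for ti, tj, i, j, pi, pj in self._pair_paths(focal):
            si = np.concatenate([[y[i]], S[pi]])
            sj = np.concatenate([[y[j]], S[pj]])
            dmax = max(si.max() - sj.min(), sj.max() - si.min())
            out.append((ti, tj, float(abs(y[i] - y[j])), float(dmax)))
        return out


def _as_engine_inputs(
    ctree: CollapsedTree | TimeTree, traits: dict[str, float] | None
):
    if isinstance(ctree, CollapsedTree):
        return ctree.tree, dict(ctree.traits)
    if traits is None:
        raise ValueError("traits are required when passing a bare tree")
    return ctree, dict(traits)


def c1_statistic(
    ctree: CollapsedTree | TimeTree,
    focal_tips: list[str],
    traits: dict[str, float] | None = None,
) -> ConvergenceResult:
    """Observed C1 over all pairs of focal tips (no significance)."""
    tree, traits = _as_engine_inputs(ctree, traits)
    if len(focal_tips) < 2:
        raise ValueError("need at least two focal tips")
    engine = C1Engine(tree)
    y = np.array([traits[nm] for nm in engine.tip_names], dtype=float)
    c1, _, sum_dmax = engine.c1_values(y[:, None], list(focal_tips))
    if sum_dmax[0] == 0.0:
        raise UndefinedC1Error("all reconstructed states identical (Dmax = 0)")
    return ConvergenceResult(
        c1=float(c1[0]),
        per_pair=engine.per_pair(y, list(focal_tips)),
        focal_tips=list(focal_tips),
    )


def c1_significance(
    ctree: CollapsedTree | TimeTree,
    focal_tips: list[str],
    n_sim: int = 1000,
    seed: int = 0,
    traits: dict[str, float] | None = None,
) -> ConvergenceResult:
    """C1 with a BM simulation p-value.

    The Brownian rate is REML-estimated from the observed traits on the
    collapsed tree; ``n_sim`` BM datasets (root at the GLS estimate) are
    simulated, C1 recomputed on each, and
    p = (#{simulated C1 >= observed} + 1) / (n_sim + 1).  Replicates with
    undefined C1 are dropped (warned about beyond 10%).
    """
    if n_sim < 100:
        raise ValueError("n_sim must be >= 100")
    tree, traits = _as_engine_inputs(ctree, traits)
    if len(focal_tips) < 2:
        raise ValueError("need at least two focal tips")
    engine = C1Engine(tree)
    y = np.array([traits[nm] for nm in engine.tip_names], dtype=float)
    focal = list(focal_tips)

    c1_obs, _, sum_dmax = engine.c1_values(y[:, None], focal)
    if sum_dmax[0] == 0.0:
        raise UndefinedC1Error("all reconstructed states identical (Dmax = 0)")
    obs = float(c1_obs[0])

    sigma2 = engine.sigma2_reml(y)
    mu = float(engine.gls_root(y[:, None])[0])
    rng = np.random.default_rng(seed)
    Y = engine.simulate_bm(mu, sigma2, n_sim, rng)
    c1_sim, _, _ = engine.c1_values(Y, focal)
    valid = ~np.isnan(c1_sim)
    n_dropped = int(n_sim - valid.sum())
    if n_dropped > 0.1 * n_sim:
        warnings.warn(
            f"{n_dropped}/{n_sim} simulated replicates had undefined C1",
            stacklevel=2,
        )
    n_valid = int(valid.sum())
    p = (float((c1_sim[valid] >= obs).sum()) + 1.0) / (n_valid + 1.0)
    return ConvergenceResult(
        c1=obs,
        p_value=p,
        n_sim=n_valid,
        n_dropped=n_dropped,
        sigma2_used=sigma2,
        per_pair=engine.per_pair(y, focal),
        seed=seed,
        focal_tips=focal,
    )
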