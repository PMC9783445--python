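"""Independent reference implementations used only by the tests.

These deliberately avoid the analytic code paths of the package: ancestral
states are found by numerically maximizing the joint Brownian-motion
density over all internal states, and C1 by exhaustively enumerating every
ancestor pair.  Feasible only on small trees, which is the point.
"""

from __future__ import annotations

import numpy as np
from scipy import optimize

from osteophylo.trees import TimeTree


def brute_force_asr(tree: TimeTree, traits: dict[str, float]) -> dict:
    """BM ancestral states by direct numerical maximization.

    The joint BM density over all node states is Gaussian, so the maximizer
    over internal states equals the conditional mean given the tips; here it
    is found by minimizing the sum of squared independent contrasts
    (x_child - x_parent)^2 / branch_length with a generic optimizer.
    """
    internal = tree.internal_nodes()
    idx = {n: k for k, n in enumerate(internal)}
    edges = []  # (parent internal idx, child internal idx or None, tip value)
    for node in tree.preorder():
        if node is tree.root:
            continue
        pi = idx[node.parent]
        if node.is_leaf:
            edges.append((pi, None, traits[node.name], node.length))
        else:
            edges.append((pi, idx[node], None, node.length))

    def objective(x):
        q = 0.0
        for pi, ci, tipval, t in edges:
            child = tipval if ci is None else x[ci]
            q += (child - x[pi]) ** 2 / t
        return q

    # the sum of squared contrasts is quadratic in the internal states, so
    # its exact minimizer solves the assembled normal equations; a BFGS run
    # from a crude start double-checks that the stationary point is a minimum
    m = len(internal)
    M = np.zeros((m, m))
    b = np.zeros(m)
    for pi, ci, tipval, t in edges:
        w = 1.0 / t
        M[pi, pi] += w
        if ci is None:
            b[pi] += w * tipval
        else:
            M[ci, ci] += w
            M[pi, ci] -= w
            M[ci, pi] -= w
    x = np.linalg.solve(M, b)
    x0 = np.full(m, np.mean(list(traits.values())))
    res = optimize.minimize(objective, x0, method="BFGS")
    assert objective(x) <= res.fun + 1e-9
    states = {n: float(x[k]) for n, k in idx.items()}
    for tip in tree.tips():
        states[tip] = float(traits[tip.name])
    return states


def brute_force_c1(
    tree: TimeTree, traits: dict[str, float], focal: list[str]
) -> tuple[float, list[tuple[str, str, float, float]]]:
    """C1 by exhaustive enumeration of all ancestor pairs per focal pair."""
    states = brute_force_asr(tree, traits)
    per_pair = []
    sum_dtip = sum_dmax = 0.0
    for a in range(len(focal)):
        for b in range(a + 1, len(focal)):
            ti, tj = tree.find_tip(focal[a]), tree.find_tip(focal[b])
            mrca = tree.mrca(focal[a], focal[b])
            path_i = _path_to(ti, mrca)
            path_j = _path_to(tj, mrca)
            dtip = abs(traits[focal[a]] - traits[focal[b]])
            dmax = max(
                abs(states[u] - states[v]) for u in path_i for v in path_j
            )
            per_pair.append((focal[a], focal[b], dtip, dmax))
            sum_dtip += dtip
            sum_dmax += dmax
    return 1.0 - sum_dtip / sum_dmax, per_pair


def _path_to(tip, mrca):
    path = [tip]
    node = tip
    while node is not mrca:
        node = node.parent
        path.append(node)
    return path


def ols_fit(y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Textbook least squares via lstsq (oracle for the star-tree case)."""
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return beta
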