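"""Felsenstein pruning, vectorized across alignment columns.

The engine is state-space agnostic: the same code computes codon-level
(61-state) and amino-acid-level (20-state) column log-likelihoods. Partial
likelihoods are rescaled per node and per site to avoid underflow on deep
trees, so valid inputs never return -inf.
"""

from __future__ import annotations

import numpy as np
import scipy.linalg

from .trees import PhyloTree

__all__ = ["ReversibleKernel", "column_logliks"]


class ReversibleKernel:
    """Eigendecomposition of a reversible rate matrix for cheap ``exp(Qt)``.

    A rate matrix reversible with respect to ``pi`` is symmetrized as
    ``B = D^{1/2} Q D^{-1/2}`` (``D = diag(pi)``); one symmetric
    eigendecomposition then yields the transition matrix for any ``t``.
    """

    def __init__(self, q: np.ndarray, pi: np.ndarray):
        q = np.asarray(q, dtype=float)
        pi = np.asarray(pi, dtype=float)
        if np.any(pi <= 0):
            raise ValueError("stationary distribution must be strictly positive")
        self.pi = pi
        d = np.sqrt(pi)
        b = q * (d[:, None] / d[None, :])
        b = 0.5 * (b + b.T)  # symmetric up to round-off for reversible q
        self._w, self._v = scipy.linalg.eigh(b)
        self._left = self._v / d[:, None]  # D^{-1/2} V
        self._right = self._v.T * d[None, :]  # V^T D^{1/2}

    def transition(self, t: float) -> np.ndarray:
        """``P(t) = exp(Qt)``, clipped to [0, 1] against round-off."""
        p = (self._left * np.exp(self._w * t)) @ self._right
        return np.clip(p, 0.0, 1.0)


def column_logliks(
    tree: PhyloTree,
    leaf_states: np.ndarray,
    edge_transition,
    pi: np.ndarray,
) -> np.ndarray:
    """Log-likelihood of every alignment column on a fixed tree.

    Parameters
    ----------
    tree
        The phylogeny; leaves are matched by position, i.e. row ``k`` of
        ``leaf_states`` belongs to ``tree.leaf_labels[k]``.
    leaf_states
        Integer state matrix, shape ``(n_taxa, n_sites)``.
    edge_transition
        Either a single ``(S, S)`` transition matrix applied to every edge
        (the balanced-tree case) or a callable ``node_id -> (S, S)`` matrix
        for the edge above that node.
    pi
        Root state distribution (the model's stationary distribution).

    Returns
    -------
    ndarray, shape (n_sites,)
        Per-column log-likelihoods.
    """
    leaf_states = np.asarray(leaf_states)
    n_sites = leaf_states.shape[1]
    if leaf_states.shape[0] != tree.n_taxa:
        raise ValueError("leaf_states rows do not match tree taxa")

    if tree.n_nodes == 1:  # single-leaf tree: no edges, just the root prior
        return np.log(np.asarray(pi)[leaf_states[0]])

    if callable(edge_transition):
        get_p = edge_transition
    else:
        p_shared = np.asarray(edge_transition)
        get_p = lambda node: p_shared  # noqa: E731

    leaf_row = {node: k for k, node in enumerate(tree.leaf_ids)}
    messages: dict[int, np.ndarray] = {}
    logscale = np.zeros(n_sites)

    for node in tree.postorder:
        ch = tree.children[node]
        if not ch:
            p = get_p(node)
            _check_finite(p, node)
            # message to parent: P[x_parent, observed_state]
            messages[node] = p.T[leaf_states[leaf_row[node]]]
            continue
        partial = messages.pop(ch[0])
        for c in ch[1:]:
            partial = partial * messages.pop(c)
        # rescale to dodge underflow on deep trees
        m = partial.max(axis=1)
        if np.any(m <= 0):
            raise ValueError(f"zero partial likelihood at node {node}")
        partial = partial / m[:, None]
        logscale += np.log(m)
        if node == tree.root:
            return np.log(partial @ pi) + logscale
        p = get_p(node)
        _check_finite(p, node)
        messages[node] = partial @ p.T

    raise AssertionError("tree traversal did not reach the root")


def _check_finite(p: np.ndarray, node: int) -> None:
    if not np.all(np.isfinite(p)):
        raise ValueError(f"non-finite transition probabilities on the edge above node {node}")
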