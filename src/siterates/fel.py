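"""One-rate fixed-effects likelihood (FEL1) per-site dN/dS estimation.

Each site gets its own maximum-likelihood nonsynonymous rate dN under an
MG94-style codon model, with the synonymous rate shared across all sites
and anchored at dS = 1 (one global scale is unidentifiable from the ratio,
so dN then *is* dN/dS). Branch lengths are taken as given — the benchmark
supplies the true tree to inference, and for empirical work an optional
global branch-scale factor can be estimated first.

After fitting, every site whose translated column shows a single residue
state is assigned dN/dS = 0: with a shared nonzero dS, a column with no
amino-acid change carries no evidence of nonsynonymous divergence, yet an
unconstrained per-site likelihood would drift to dN/dS = 1 there.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from ._pruning import ReversibleKernel, column_logliks
from .alignments import CodonAlignment
from .codon_models import SiteRateProfile, mg94_matrix
from .genetic_code import SENSE_CODONS
from .rates import RateEstimates
from .trees import PhyloTree

__all__ = ["Fel1", "Fel1Results", "site_loglik", "fel1_fit"]

N_CODONS = len(SENSE_CODONS)


def _uniform_freqs() -> np.ndarray:
    return np.full(N_CODONS, 1.0 / N_CODONS)


def _edge_lengths(tree: PhyloTree) -> np.ndarray:
    mask = np.arange(tree.n_nodes) != tree.root
    return np.unique(np.round(tree.edge_length[mask], 12))


def _transition_lookup(tree: PhyloTree, kernel: ReversibleKernel, scale: float = 1.0):
    """Per-edge transition matrices, one exponentiation per unique length."""
    p_by_length = {
        ell: kernel.transition(scale * ell) for ell in _edge_lengths(tree)
    }
    if len(p_by_length) == 1:
        return next(iter(p_by_length.values()))
    lengths = np.round(tree.edge_length, 12)
    return lambda node: p_by_length[lengths[node]]


class Fel1:
    """FEL1 model: a codon alignment plus a fixed tree.

    Parameters
    ----------
    alignment
        Gapless codon alignment; taxa must match the tree's leaves.
    tree
        Phylogeny with branch lengths in neutral substitutions per codon
        site. Taken as given (not re-estimated).
    codon_freqs
        Equilibrium codon frequencies of the MG94 process (uniform over the
        61 sense codons by default).
    dn_max
        Upper bound of the per-site dN search; estimates at the bound are
        flagged in the results.
    estimate_branch_scale
        If True, a single multiplicative branch-scale factor is estimated
        under the neutral model before the per-site fits (for trees whose
        lengths are not already on the codon clock).
    """

    def __init__(
        self,
        alignment: CodonAlignment,
        tree: PhyloTree,
        codon_freqs: np.ndarray | None = None,
        dn_max: float = 10.0,
        grid_size: int = 64,
        estimate_branch_scale: bool = False,
    ):
        if sorted(alignment.labels) != sorted(tree.leaf_labels):
            raise ValueError("alignment and tree leaf sets do not match")
        self.alignment = alignment.reordered(tree.leaf_labels)
        self.tree = tree
        self.codon_freqs = _uniform_freqs() if codon_freqs is None else np.asarray(codon_freqs)
        self.dn_max = float(dn_max)
        self.grid_size = int(grid_size)
        self.estimate_branch_scale = estimate_branch_scale

    # -- likelihood --------------------------------------------------------

    def _logliks(self, dn: float, ds: float = 1.0, branch_scale: float = 1.0) -> np.ndarray:
        """Per-site log-likelihoods under a shared (dN, dS)."""
        q = mg94_matrix(SiteRateProfile(dN=dn, dS=ds), self.codon_freqs)
        kernel = ReversibleKernel(q, self.codon_freqs)
        trans = _transition_lookup(self.tree, kernel, branch_scale)
        return column_logliks(self.tree, self.alignment.states, trans, self.codon_freqs)

    def site_loglik(self, site: int, dn: float, ds: float = 1.0) -> float:
        """Log-likelihood of one column (0-based site) at a given (dN, dS)."""
        column = self.alignment.states[:, [site]]
        q = mg94_matrix(SiteRateProfile(dN=dn, dS=ds), self.codon_freqs)
        kernel = ReversibleKernel(q, self.codon_freqs)
        trans = _transition_lookup(self.tree, kernel, self._branch_scale)
        return float(column_logliks(self.tree, column, trans, self.codon_freqs)[0])

    _branch_scale: float = 1.0

    # -- fitting -----------------------------------------------------------

    def fit(self) -> "Fel1Results":
        """Maximize each site's likelihood over dN on [0, dn_max].

        A geometric candidate grid shared across sites (vectorized pruning)
        brackets each site's optimum; bounded local refinement finishes the
        job. Ties on the grid resolve toward the smaller dN.
        """
        if self.estimate_branch_scale:
            self._branch_scale = self._fit_branch_scale()

        grid = np.geomspace(1e-4, self.dn_max, self.grid_size)
        ll = np.stack(
            [self._logliks(d, branch_scale=self._branch_scale) for d in grid]
        )  # (grid, sites)
        best = ll.argmax(axis=0)  # first (smallest-dN) maximizer on ties

        n_sites = self.alignment.n_sites
        dn_hat = np.empty(n_sites)
        loglik = np.empty(n_sites)
        for s in range(n_sites):
            lo = grid[best[s] - 1] if best[s] > 0 else 0.0
            hi = grid[best[s] + 1] if best[s] < len(grid) - 1 else self.dn_max
            res = minimize_scalar(
                lambda d: -self.site_loglik(s, d),
                bounds=(lo, hi),
                method="bounded",
                options={"xatol": 1e-4},
            )
            dn_hat[s] = res.x
            loglik[s] = -res.fun

        at_bound = dn_hat > 0.999 * self.dn_max

        aa = self.alignment.translate().states
        invariant = np.array([np.unique(aa[:, s]).size == 1 for s in range(n_sites)])
        dn_hat[invariant] = 0.0

        return Fel1Results(
            model=self,
            estimates=RateEstimates(scores=dn_hat, score_kind="dnds"),
            loglik=loglik,
            invariant=invariant,
            at_bound=at_bound,
            branch_scale=self._branch_scale,
        )

    def _fit_branch_scale(self) -> float:
        res = minimize_scalar(
            lambda logc: -float(np.sum(self._logliks(1.0, branch_scale=np.exp(logc)))),
            bounds=(np.log(1e-3), np.log(1e3)),
            method="bounded",
        )
        return float(np.exp(res.x))


@dataclass
class Fel1Results:
    """Per-site dN/dS estimates and diagnostics from a FEL1 fit."""

    model: Fel1
    estimates: RateEstimates
    loglik: np.ndarray
    invariant: np.ndarray
    at_bound: np.ndarray
    branch_scale: float = 1.0

    @property
    def dnds(self) -> np.ndarray:
        return self.estimates.scores

    def normalized(self, mode: str = "mean1") -> RateEstimates:
        return self.estimates.normalized(mode)

    def to_frame(self) -> pd.DataFrame:
        n = self.estimates.n_sites
        return pd.DataFrame(
            {
                "site": np.arange(1, n + 1),
                "dN": self.dnds,
                "dS": np.ones(n),
                "dnds": self.dnds,
                "invariant_flag": self.invariant.astype(int),
                "loglik": self.loglik,
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")

    def summary(self) -> str:
        d = self.dnds
        lines = [
            "FEL1 per-site dN/dS",
            f"  sites:            {d.size}",
            f"  taxa:             {self.model.alignment.n_taxa}",
            f"  invariant sites:  {int(self.invariant.sum())} (set to 0)",
            f"  at dn_max bound:  {int(self.at_bound.sum())}",
            f"  branch scale:     {self.branch_scale:.4g}",
            f"  dN/dS mean (var): {d.mean():.4f} ({d.var():.4f})",
            f"  dN/dS range:      [{d.min():.4f}, {d.max():.4f}]",
            f"  total loglik:     {self.loglik.sum():.2f}",
        ]
        return "\n".join(lines)


# -- spec-style functional facade -------------------------------------------


def site_loglik(
    column: np.ndarray, tree: PhyloTree, dn: float, ds: float = 1.0,
    codon_freqs: np.ndarray | None = None,
) -> float:
    """Log-likelihood of one codon column (length n_taxa, in tree leaf
    order) under the MG94 model with the given (dN, dS)."""
    freqs = _uniform_freqs() if codon_freqs is None else np.asarray(codon_freqs)
    q = mg94_matrix(SiteRateProfile(dN=dn, dS=ds), freqs)
    kernel = ReversibleKernel(q, freqs)
    trans = _transition_lookup(tree, kernel)
    states = np.asarray(column, dtype=np.intp)[:, None]
    return float(column_logliks(tree, states, trans, freqs)[0])


def fel1_fit(alignment: CodonAlignment, tree: PhyloTree, **kwargs) -> Fel1Results:
    """Convenience wrapper: ``Fel1(alignment, tree, **kwargs).fit()``."""
    return Fel1(alignment, tree, **kwargs).fit()
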