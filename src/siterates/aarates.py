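"""Empirical-Bayes site-specific relative rates from amino-acid alignments.

The model behind Rate4Site-style conservation scoring: divergence at site
``k`` along branch ``i`` decomposes as ``r_k * t_i``, with a site rate
multiplier ``r_k`` shared across branches. Site rates follow a discretized
gamma prior (mean 1, K equal-probability categories at quantile midpoints);
the gamma shape is fitted by maximizing the whole-alignment likelihood
under an empirical replacement matrix (JTT by default), and each site's
score is the posterior mean category rate. Because the ``r_k t_i``
decomposition is invariant under a global rescaling, scores are reported
raw and compared after mean-1 normalization (or as z-scores).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import logsumexp
from scipy.stats import gamma as gamma_dist

from ._pruning import ReversibleKernel, column_logliks
from .aa_models import ReplacementModel, get_replacement_matrix
from .alignments import AminoAcidAlignment, CodonAlignment
from .rates import RateEstimates
from .trees import PhyloTree

__all__ = [
    "AminoAcidRateModel",
    "AARateResults",
    "discretized_gamma_rates",
    "translate",
    "aa_rates",
]


def translate(alignment: CodonAlignment) -> AminoAcidAlignment:
    """Position-wise standard-code translation of a codon alignment."""
    return alignment.translate()


def discretized_gamma_rates(shape: float, n_categories: int) -> np.ndarray:
    """Equal-probability quantile-midpoint discretization of Gamma(shape)
    with mean 1, renormalized so the category mean is exactly 1."""
    if shape <= 0:
        raise ValueError("gamma shape must be positive")
    if n_categories < 1:
        raise ValueError("need at least one rate category")
    probs = (2 * np.arange(n_categories) + 1) / (2 * n_categories)
    rates = gamma_dist.ppf(probs, a=shape, scale=1.0 / shape)
    return rates / rates.mean()


class AminoAcidRateModel:
    """Relative-rate model: an amino-acid alignment plus a fixed tree.

    Parameters
    ----------
    alignment
        Amino-acid alignment (a codon alignment is translated on the fly).
    tree
        Phylogeny, taken as given; any global branch-length scale is
        absorbed by the mean-1 normalization of the scores.
    matrix
        Empirical replacement model name ("JTT", "LG", "WAG") or a
        :class:`~siterates.aa_models.ReplacementModel`.
    n_categories
        Number of discretized gamma rate categories (K >= 4).
    shape
        Fixed gamma shape; if None (default) the shape is estimated by
        maximizing the summed column log-likelihoods (empirical Bayes).
    """

    def __init__(
        self,
        alignment: AminoAcidAlignment | CodonAlignment,
        tree: PhyloTree,
        matrix: str | ReplacementModel = "JTT",
        n_categories: int = 16,
        shape: float | None = None,
        shape_bounds: tuple[float, float] = (0.05, 20.0),
    ):
        if isinstance(alignment, CodonAlignment):
            alignment = alignment.translate()
        if sorted(alignment.labels) != sorted(tree.leaf_labels):
            raise ValueError("alignment and tree leaf sets do not match")
        if n_categories < 4:
            raise ValueError("n_categories must be >= 4")
        self.alignment = alignment.reordered(tree.leaf_labels)
        self.tree = tree
        self.replacement = (
            matrix if isinstance(matrix, ReplacementModel) else get_replacement_matrix(matrix)
        )
        self.n_categories = int(n_categories)
        self.shape = shape
        self.shape_bounds = shape_bounds
        self._kernel = ReversibleKernel(
            self.replacement.rate_matrix, self.replacement.frequencies
        )
        mask = np.arange(tree.n_nodes) != tree.root
        self._lengths = np.round(tree.edge_length, 12)
        self._unique_lengths = np.unique(self._lengths[mask])

    def _category_logliks(
        self, shape: float, rates: np.ndarray | None = None
    ) -> tuple[np.ndarray, np.ndarray]:
        """(rates, ll) with ll[c, k] the loglik of column k at category c."""
        if rates is None:
            rates = discretized_gamma_rates(shape, self.n_categories)
        pi = self.replacement.frequencies
        ll = np.empty((len(rates), self.alignment.n_sites))
        for c, r in enumerate(rates):
            p_by_len = {ell: self._kernel.transition(r * ell) for ell in self._unique_lengths}
            if len(p_by_len) == 1:
                trans = next(iter(p_by_len.values()))
            else:
                lengths = self._lengths
                trans = lambda node: p_by_len[lengths[node]]  # noqa: B023,E731
            ll[c] = column_logliks(self.tree, self.alignment.states, trans, pi)
        return rates, ll

    def _marginal_loglik(self, shape: float) -> float:
        _, ll = self._category_logliks(shape)
        return float(np.sum(logsumexp(ll, axis=0) - np.log(self.n_categories)))

    def fit(self) -> "AARateResults":
        """Fit the gamma shape (unless fixed) and score every site with its
        posterior mean rate; scores are strictly positive."""
        if self.shape is None:
            res = minimize_scalar(
                lambda a: -self._marginal_loglik(a),
                bounds=self.shape_bounds,
                method="bounded",
                options={"xatol": 1e-3},
            )
            shape_hat = float(res.x)
        else:
            shape_hat = float(self.shape)

        rates, ll = self._category_logliks(shape_hat)
        log_norm = logsumexp(ll, axis=0)  # (n_sites,)
        weights = np.exp(ll - log_norm)  # posterior over categories per site
        scores = weights.T @ rates
        loglik = float(np.sum(log_norm - np.log(self.n_categories)))
        return AARateResults(
            model=self,
            estimates=RateEstimates(scores=scores, score_kind="aa_rate"),
            gamma_shape=shape_hat,
            category_rates=rates,
            posterior=weights,
            loglik=loglik,
        )


@dataclass
class AARateResults:
    """Posterior-mean site rates and the fitted rate-variation prior."""

    model: AminoAcidRateModel
    estimates: RateEstimates
    gamma_shape: float
    category_rates: np.ndarray
    posterior: np.ndarray  # (K, n_sites)
    loglik: float

    @property
    def rates(self) -> np.ndarray:
        return self.estimates.scores

    def normalized(self, mode: str = "mean1") -> RateEstimates:
        return self.estimates.normalized(mode)

    def to_frame(self) -> pd.DataFrame:
        n = self.estimates.n_sites
        mean1 = self.estimates.normalized("mean1").scores
        z = self.estimates.normalized("zscore").scores if self.rates.std() > 0 else np.zeros(n)
        return pd.DataFrame(
            {
                "site": np.arange(1, n + 1),
                "raw_rate": self.rates,
                "mean1_rate": mean1,
                "zscore": z,
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")

    def summary(self) -> str:
        r = self.rates
        lines = [
            "Empirical-Bayes amino-acid site rates",
            f"  sites:             {r.size}",
            f"  taxa:              {self.model.alignment.n_taxa}",
            f"  replacement model: {self.model.replacement.name}",
            f"  gamma categories:  {self.model.n_categories}",
            f"  gamma shape:       {self.gamma_shape:.4f}"
            + ("" if self.model.shape is None else " (fixed)"),
            f"  rate mean (var):   {r.mean():.4f} ({r.var():.4f})",
            f"  rate range:        [{r.min():.4f}, {r.max():.4f}]",
            f"  total loglik:      {self.loglik:.2f}",
        ]
        return "\n".join(lines)


def aa_rates(
    alignment: AminoAcidAlignment | CodonAlignment,
    tree: PhyloTree,
    **kwargs,
) -> AARateResults:
    """Convenience wrapper: ``AminoAcidRateModel(alignment, tree, **kwargs).fit()``."""
    return AminoAcidRateModel(alignment, tree, **kwargs).fit()
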