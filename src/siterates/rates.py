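"""Per-site rate score containers and normalization.

Both inference routes produce a :class:`RateEstimates`: codon-level fits
carry ``score_kind="dnds"``, amino-acid-level fits ``score_kind="aa_rate"``.
Because amino-acid relative rates are only identified up to a global
constant (the ``r_k t_i`` decomposition is invariant under ``r -> C r``,
``t -> t / C``), cross-method comparisons are made on mean-1 normalized
scores; the ``normalization`` field tracks that state explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = ["RateEstimates", "normalize"]

_KINDS = ("dnds", "aa_rate")
_NORMS = ("raw", "mean1", "zscore")


@dataclass(frozen=True)
class RateEstimates:
    """Per-site scores with provenance and normalization state."""

    scores: np.ndarray
    score_kind: str
    normalization: str = "raw"

    def __post_init__(self) -> None:
        s = np.asarray(self.scores, dtype=float)
        if s.ndim != 1 or s.size == 0:
            raise ValueError("scores must be a nonempty 1-D array")
        if not np.all(np.isfinite(s)):
            raise ValueError("scores must be finite")
        if self.score_kind not in _KINDS:
            raise ValueError(f"score_kind must be one of {_KINDS}")
        if self.normalization not in _NORMS:
            raise ValueError(f"normalization must be one of {_NORMS}")
        if self.normalization != "zscore" and np.any(s < 0):
            raise ValueError("raw and mean1 scores must be nonnegative")
        if self.normalization == "mean1" and abs(s.mean() - 1.0) > 1e-9:
            raise ValueError("mean1 scores must average to 1 within 1e-9")
        object.__setattr__(self, "scores", s)

    @property
    def n_sites(self) -> int:
        return self.scores.size

    def normalized(self, mode: str = "mean1") -> "RateEstimates":
        return normalize(self, mode)


def normalize(est: RateEstimates, mode: str) -> RateEstimates:
    """Renormalize scores: ``mean1`` divides by the mean, ``zscore`` centers
    and scales by the standard deviation (the Rate4Site default output)."""
    s = est.scores
    if mode == "mean1":
        m = s.mean()
        if m <= 0:
            raise ValueError("cannot mean-normalize scores with nonpositive mean")
        return replace(est, scores=s / m, normalization="mean1")
    if mode == "zscore":
        sd = s.std()
        if sd == 0:
            raise ValueError("cannot z-score constant scores (zero variance)")
        return replace(est, scores=(s - s.mean()) / sd, normalization="zscore")
    raise ValueError(f"unknown normalization mode {mode!r}")
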