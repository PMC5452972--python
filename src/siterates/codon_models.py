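"""Codon substitution processes: MG94-style dN/dS and HB98 mutation-selection.

Two model families are implemented over the 61 sense codons:

* a Muse-Gaut-style (MG94) model in which each site carries its own
  synonymous rate ``dS`` and nonsynonymous rate ``dN``, with substitution
  rates proportional to the target codon's equilibrium frequency;
* the Halpern-Bruno (HB98) mutation-selection model, in which a nucleotide
  mutation process is modulated per codon pair by the fixation factor
  ``S / (1 - exp(-S))`` of the scaled selection coefficient
  ``S_ij = f_j - f_i`` between codon fitnesses.

Rate matrices are anchored by one global convention: the *neutral* process
(``dN = dS = 1`` for MG94; all fitnesses equal for HB98) has mean rate 1
substitution per codon site per unit time, so tree branch lengths read as
expected substitutions per codon site at a neutral site. The anchoring
constant is identical across sites, so per-site ``dN/dS`` keeps its exact
parametric meaning.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg
from scipy.sparse.csgraph import connected_components

from .genetic_code import CODON_AA_INDEX, NEIGHBOR, SENSE_CODONS, SYNONYMOUS, TARGET_NUC

__all__ = [
    "SiteRateProfile",
    "MutSelSiteProfile",
    "mg94_matrix",
    "hb98_matrix",
    "hky_mutation_matrix",
    "lift_mutation",
    "neutral_codon_matrix",
    "expected_dnds",
    "stationary_distribution",
    "fitness_from_aa_frequencies",
    "profiles_to_tsv",
    "profiles_from_tsv",
]

N_CODONS = len(SENSE_CODONS)
NONSYNONYMOUS = NEIGHBOR & ~SYNONYMOUS
SYN_NEIGHBOR = NEIGHBOR & SYNONYMOUS

#: |S| below this is treated as neutral in the fixation factor (removable
#: singularity of S / (1 - exp(-S))).
FIXATION_TOL = 1e-8


@dataclass(frozen=True)
class SiteRateProfile:
    """Per-site (dN, dS) pair; the simulator's ground truth under MG94."""

    dN: float
    dS: float = 1.0

    def __post_init__(self) -> None:
        if not (self.dS > 0):
            raise ValueError(f"dS must be positive, got {self.dS}")
        if self.dN < 0:
            raise ValueError(f"dN must be nonnegative, got {self.dN}")

    @property
    def ratio(self) -> float:
        """dN/dS, the selection parameter the study recovers."""
        return self.dN / self.dS


@dataclass(frozen=True)
class MutSelSiteProfile:
    """Per-site codon fitness vector for the HB98 mutation-selection model.

    Fitnesses are population-scaled and defined only up to an additive
    constant; every derived quantity (``S_ij``, the stationary distribution,
    the rate matrix, expected dN/dS) is invariant under that shift.
    """

    fitness: np.ndarray  # (61,)

    def __post_init__(self) -> None:
        f = np.asarray(self.fitness, dtype=float)
        if f.shape != (N_CODONS,):
            raise ValueError(f"fitness must have shape (61,), got {f.shape}")
        if not np.all(np.isfinite(f)):
            raise ValueError("fitness vector contains non-finite values")
        object.__setattr__(self, "fitness", f)

    def selection_coefficients(self) -> np.ndarray:
        """Matrix of scaled selection coefficients ``S_ij = f_j - f_i``."""
        return self.fitness[None, :] - self.fitness[:, None]

    def stationary(self, mutation_matrix: np.ndarray) -> np.ndarray:
        """Stationary codon distribution ``pi_i ∝ m_i exp(f_i)``.

        ``m`` is the stationary distribution of the codon-lifted mutation
        process; the closed form requires a reversible mutation model.
        """
        _, m = lift_mutation(mutation_matrix)
        w = m * np.exp(self.fitness - self.fitness.max())
        return w / w.sum()


# ---------------------------------------------------------------------------
# MG94


def _check_freqs(freqs: np.ndarray) -> np.ndarray:
    freqs = np.asarray(freqs, dtype=float)
    if freqs.shape != (N_CODONS,):
        raise ValueError(f"codon frequency vector must have shape (61,), got {freqs.shape}")
    if not np.all(freqs > 0) or abs(freqs.sum() - 1.0) > 1e-8:
        raise ValueError("codon frequencies must be positive and sum to 1")
    return freqs


def mg94_matrix(
    profile: SiteRateProfile, codon_freqs: np.ndarray | None = None
) -> np.ndarray:
    """Site-specific MG94-style rate matrix.

    ``q_ij = c * dS * pi_j`` for synonymous single-nucleotide neighbours,
    ``c * dN * pi_j`` for nonsynonymous ones, 0 for multi-nucleotide changes.
    The constant ``c`` makes the neutral (dN = dS = 1) process have mean rate
    1; it depends only on ``codon_freqs``, never on the profile, so dN/dS
    ratios across sites are exact. Stationary distribution is ``codon_freqs``.
    """
    if codon_freqs is None:
        codon_freqs = np.full(N_CODONS, 1.0 / N_CODONS)
    pi = _check_freqs(codon_freqs)

    base = np.where(NEIGHBOR, pi[None, :], 0.0)
    scale = 1.0 / (pi @ base.sum(axis=1))  # neutral mean rate -> 1
    q = scale * base * np.where(SYN_NEIGHBOR, profile.dS, np.where(NONSYNONYMOUS, profile.dN, 0.0))
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    return q


# ---------------------------------------------------------------------------
# mutation models and HB98

_NUC_ORDER = "ACGT"


def hky_mutation_matrix(
    freqs: tuple[float, float, float, float] = (0.32, 0.18, 0.18, 0.32),
    kappa: float = 1.0,
) -> np.ndarray:
    """HKY-style 4x4 nucleotide mutation rate matrix (A, C, G, T order).

    ``kappa`` multiplies transition rates (A<->G, C<->T); the default 1 gives
    the F81-like special case. Off-diagonals are ``pi_target`` (times kappa),
    diagonals set for zero row sums. Unequal default frequencies follow the
    study's unequal-nucleotide-frequency setting.
    """
    p = np.asarray(freqs, dtype=float)
    if p.shape != (4,) or not np.all(p > 0) or abs(p.sum() - 1.0) > 1e-8:
        raise ValueError("nucleotide frequencies must be 4 positive values summing to 1")
    q = np.tile(p, (4, 1))
    transitions = np.zeros((4, 4), dtype=bool)
    transitions[0, 2] = transitions[2, 0] = True  # A<->G
    transitions[1, 3] = transitions[3, 1] = True  # C<->T
    q[transitions] *= kappa
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    return q


def _check_mutation(mutation_matrix: np.ndarray) -> np.ndarray:
    mu = np.asarray(mutation_matrix, dtype=float)
    if mu.shape != (4, 4):
        raise ValueError("mutation matrix must be 4x4")
    off = mu[~np.eye(4, dtype=bool)]
    if np.any(off < 0) or np.any(np.abs(mu.sum(axis=1)) > 1e-10):
        raise ValueError("mutation matrix needs nonnegative off-diagonals and zero row sums")
    return mu


def _nuc_stationary(mu: np.ndarray) -> np.ndarray:
    a = np.vstack([mu.T, np.ones(4)])
    b = np.zeros(5)
    b[-1] = 1.0
    v, *_ = np.linalg.lstsq(a, b, rcond=None)
    return np.clip(v, 0.0, None) / np.clip(v, 0.0, None).sum()


_SOURCE_NUC = TARGET_NUC.T  # nucleotide replaced, i.e. i's base at the differing position


def lift_mutation(mutation_matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Lift a 4x4 nucleotide mutation process to the 61 sense codons.

    Returns ``(M, m)`` where ``M[i, j]`` is the mutation rate between
    single-nucleotide codon neighbours (diagonal zeroed, not a proper rate
    matrix) and ``m`` the stationary codon distribution of the lifted
    process, ``m_i ∝ prod_p pi_nuc(codon_i[p])`` renormalized over the sense
    codons (exact for reversible mutation because forbidding stop codons
    preserves detailed balance).
    """
    mu = _check_mutation(mutation_matrix)
    m61 = np.zeros((N_CODONS, N_CODONS))
    mask = NEIGHBOR
    m61[mask] = mu[_SOURCE_NUC[mask], TARGET_NUC[mask]]
    p = _nuc_stationary(mu)
    codon_p = np.array(
        [p[_NUC_ORDER.index(c[0])] * p[_NUC_ORDER.index(c[1])] * p[_NUC_ORDER.index(c[2])]
         for c in SENSE_CODONS]
    )
    return m61, codon_p / codon_p.sum()


def neutral_codon_matrix(mutation_matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Neutral codon process (all fixation factors 1), anchored to mean rate 1.

    Returns ``(Q0, pi0)``; the same anchoring constant is used by
    :func:`hb98_matrix` for any profile under this mutation model.
    """
    m61, m = lift_mutation(mutation_matrix)
    scale = 1.0 / (m @ m61.sum(axis=1))
    q0 = scale * m61
    np.fill_diagonal(q0, -q0.sum(axis=1))
    return q0, m


def fixation_factor(s: np.ndarray) -> np.ndarray:
    """HB98 fixation factor ``S / (1 - exp(-S))`` with its limit 1 at S = 0."""
    s = np.asarray(s, dtype=float)
    out = np.ones_like(s)
    big = np.abs(s) >= FIXATION_TOL
    out[big] = s[big] / -np.expm1(-s[big])
    return out


def hb98_matrix(profile: MutSelSiteProfile, mutation_matrix: np.ndarray) -> np.ndarray:
    """HB98 mutation-selection rate matrix for one site.

    ``q_ij = c * mu_ij * S_ij / (1 - exp(-S_ij))`` for single-nucleotide
    neighbours (0 otherwise), where ``S_ij = f_j - f_i`` and ``c`` anchors
    the *neutral* process under this mutation model to mean rate 1. For a
    reversible mutation model the chain is reversible with stationary
    distribution ``pi_i ∝ m_i exp(f_i)``.
    """
    m61, m = lift_mutation(mutation_matrix)
    scale = 1.0 / (m @ m61.sum(axis=1))
    s = profile.selection_coefficients()
    q = scale * m61 * fixation_factor(s)
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    return q


def expected_dnds(profile: MutSelSiteProfile, mutation_matrix: np.ndarray) -> float:
    """Expected dN/dS implied by a site's scaled selection coefficients.

    The stationary nonsynonymous substitution flux of the HB98 process,
    divided by the same flux under neutrality (all fixation factors 1,
    neutral stationary distribution). Neutral profiles give exactly 1;
    strong purifying selection drives the value toward 0.
    """
    q = hb98_matrix(profile, mutation_matrix)
    pi = profile.stationary(mutation_matrix)
    q0, pi0 = neutral_codon_matrix(mutation_matrix)

    flux = (pi[:, None] * q)[NONSYNONYMOUS].sum()
    flux0 = (pi0[:, None] * q0)[NONSYNONYMOUS].sum()
    return float(flux / flux0)


# ---------------------------------------------------------------------------
# generic stationary distribution


def stationary_distribution(q: np.ndarray, tol: float = 1e-10) -> np.ndarray:
    """Stationary distribution of a rate matrix via a constrained solve.

    Solves ``vQ = 0, sum(v) = 1``; rejects matrices whose positive-rate graph
    is not a single (strongly connected) communicating class, and verifies
    the residual ``||vQ||_inf <= tol``.
    """
    q = np.asarray(q, dtype=float)
    n = q.shape[0]
    if q.shape != (n, n):
        raise ValueError("rate matrix must be square")
    adjacency = (q > 0).astype(np.int8)
    n_comp, _ = connected_components(adjacency, directed=True, connection="strong")
    if n_comp != 1:
        raise ValueError(
            f"rate matrix is reducible: {n_comp} communicating classes; "
            "stationary distribution is not unique"
        )
    a = np.vstack([q.T, np.ones(n)])
    b = np.zeros(n + 1)
    b[-1] = 1.0
    v, *_ = scipy.linalg.lstsq(a, b)
    v = np.clip(v, 0.0, None)
    v /= v.sum()
    residual = np.abs(v @ q).max()
    if residual > tol:
        raise ValueError(f"stationary solve residual {residual:.2e} exceeds {tol:.0e}")
    return v


# ---------------------------------------------------------------------------
# MutSel profile construction and profile serialization


def fitness_from_aa_frequencies(
    aa_freqs: np.ndarray, mutation_matrix: np.ndarray
) -> np.ndarray:
    """Codon fitnesses realizing target amino-acid stationary frequencies.

    Chooses ``f`` so that under HB98 with the given (reversible) mutation
    model the stationary probability of each amino acid equals ``aa_freqs``;
    synonymous codons of one amino acid get equal fitness (neutral synonymous
    codons), so their stationary shares follow the mutation bias.
    """
    g = np.asarray(aa_freqs, dtype=float)
    if g.shape != (20,) or np.any(g <= 0) or abs(g.sum() - 1.0) > 1e-8:
        raise ValueError("aa_freqs must be 20 positive values summing to 1")
    _, m = lift_mutation(mutation_matrix)
    class_mass = np.bincount(CODON_AA_INDEX, weights=m, minlength=20)
    f = np.log(g[CODON_AA_INDEX]) - np.log(class_mass[CODON_AA_INDEX])
    return f - f.max()


def profiles_to_tsv(profiles: list, path) -> None:
    """Serialize rate profiles to TSV (site, dN, dS or site + 61 fitnesses)."""
    if all(isinstance(p, SiteRateProfile) for p in profiles):
        df = pd.DataFrame(
            {"site": np.arange(1, len(profiles) + 1),
             "dN": [p.dN for p in profiles],
             "dS": [p.dS for p in profiles]}
        )
    elif all(isinstance(p, MutSelSiteProfile) for p in profiles):
        df = pd.DataFrame([p.fitness for p in profiles], columns=list(SENSE_CODONS))
        df.insert(0, "site", np.arange(1, len(profiles) + 1))
    else:
        raise TypeError("profiles must be all SiteRateProfile or all MutSelSiteProfile")
    df.to_csv(path, sep="\t", index=False)


def profiles_from_tsv(path) -> list:
    df = pd.read_csv(path, sep="\t")
    if {"dN", "dS"} <= set(df.columns):
        return [SiteRateProfile(dN=row.dN, dS=row.dS) for row in df.itertuples()]
    if set(SENSE_CODONS) <= set(df.columns):
        return [MutSelSiteProfile(fitness=row) for row in df[list(SENSE_CODONS)].to_numpy()]
    raise ValueError(f"unrecognized profile TSV columns in {path}")
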