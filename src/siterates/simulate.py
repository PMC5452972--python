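"""Synthetic-data engine: site-specific rate draws and sequence simulation.

Emulates the benchmark's study conditions: balanced binary trees (branch
lengths 0.0025-0.64, 16-2,048 taxa), 100-codon alignments, and five rate
regimes:

* ``constant_dS`` — dN ~ U(0.1, 1.6) per site, dS = 1 everywhere;
* ``variable_dS`` — dN/dS ~ U(0.1, 1.6), dS ~ U(0.5, 2), dN = dS * ratio;
* ``gamma`` — dN/dS ~ Gamma(shape alpha, rate beta), dS = 1, with the six
  HIV-1 protein (alpha, beta) pairs available as presets;
* ``mutsel_neutral_syn`` — HB98 fitness profiles with equal synonymous-codon
  fitness, amino-acid targets drawn from a symmetric Dirichlet;
* ``mutsel_codon_bias`` — as above plus mean-zero normal fitness offsets
  among synonymous codons, making dS site-variable.

Sites evolve independently and rates do not change over time. Everything is
reproducible from a single master seed: each (grid cell, replicate) gets an
independent child seed through ``numpy.random.SeedSequence`` spawn keys.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .alignments import CodonAlignment
from .codon_models import (
    MutSelSiteProfile,
    SiteRateProfile,
    expected_dnds,
    fitness_from_aa_frequencies,
    hb98_matrix,
    hky_mutation_matrix,
    mg94_matrix,
)
from ._pruning import ReversibleKernel
from .genetic_code import SENSE_CODONS
from .trees import PhyloTree, make_balanced_tree

__all__ = [
    "REGIMES",
    "HIV1_GAMMA_PARAMS",
    "BENCHMARK_BRANCH_LENGTHS",
    "BENCHMARK_TAXA_COUNTS",
    "GridConfig",
    "draw_profiles",
    "build_site_models",
    "true_rates",
    "evolve",
    "tree_grid",
    "enumerate_grid",
    "generate_grid",
    "benchmark_uniform_design",
]

logger = logging.getLogger(__name__)

REGIMES = (
    "constant_dS",
    "variable_dS",
    "gamma",
    "mutsel_neutral_syn",
    "mutsel_codon_bias",
)

#: Gamma (shape alpha, rate beta) of site-wise dN/dS previously estimated for
#: six HIV-1 proteins; used by the ``gamma`` regime.
HIV1_GAMMA_PARAMS: dict[str, tuple[float, float]] = {
    "integrase": (0.312, 1.027),
    "capsid": (0.230, 0.659),
    "gp120": (0.350, 0.249),
    "matrix": (0.647, 0.861),
    "protease": (0.378, 1.016),
    "reverse_transcriptase": (0.238, 0.627),
}

BENCHMARK_BRANCH_LENGTHS = (0.0025, 0.01, 0.04, 0.16, 0.64)
BENCHMARK_TAXA_COUNTS = (16, 32, 64, 128, 256, 512, 1024, 2048)
#: taxa counts used by the uniform-rate (constant/variable dS) designs
UNIFORM_DESIGN_TAXA = (128, 256, 512, 1024, 2048)


@dataclass
class GridConfig:
    """One simulation design: a (branch length x taxa) grid with replicates."""

    branch_lengths: tuple[float, ...] = BENCHMARK_BRANCH_LENGTHS
    taxa_counts: tuple[int, ...] = UNIFORM_DESIGN_TAXA
    n_sites: int = 100
    n_replicates: int = 50
    regime: str = "constant_dS"
    gamma_shape: float | None = None
    gamma_rate: float | None = None
    dirichlet_concentration: float = 0.5
    codon_bias_sd: float = 0.5
    mutation_freqs: tuple[float, float, float, float] = (0.32, 0.18, 0.18, 0.32)
    master_seed: int = 0

    def __post_init__(self) -> None:
        self.branch_lengths = tuple(float(b) for b in self.branch_lengths)
        self.taxa_counts = tuple(int(t) for t in self.taxa_counts)
        if not self.branch_lengths or not self.taxa_counts:
            raise ValueError("branch_lengths and taxa_counts must be nonempty")
        if any(b <= 0 for b in self.branch_lengths):
            raise ValueError("branch lengths must be positive")
        if self.n_sites < 1 or self.n_replicates < 1:
            raise ValueError("n_sites and n_replicates must be >= 1")
        if self.regime not in REGIMES:
            raise ValueError(f"unknown regime {self.regime!r}; expected one of {REGIMES}")
        if self.regime == "gamma":
            if self.gamma_shape is None or self.gamma_rate is None:
                raise ValueError("gamma regime requires gamma_shape and gamma_rate")
            if self.gamma_shape <= 0 or self.gamma_rate <= 0:
                raise ValueError("gamma_shape and gamma_rate must be positive")

    @property
    def cells(self) -> list[tuple[float, int]]:
        return [(b, t) for b in self.branch_lengths for t in self.taxa_counts]

    def params(self) -> dict:
        return {
            "gamma_shape": self.gamma_shape,
            "gamma_rate": self.gamma_rate,
            "dirichlet_concentration": self.dirichlet_concentration,
            "codon_bias_sd": self.codon_bias_sd,
            "mutation_freqs": self.mutation_freqs,
        }

    def rng_for(self, cell_index: int, replicate: int) -> np.random.Generator:
        """Independent child generator for one (cell, replicate) pair."""
        return np.random.default_rng(self.seed_sequence_for(cell_index, replicate))

    def seed_sequence_for(self, cell_index: int, replicate: int) -> np.random.SeedSequence:
        return np.random.SeedSequence(
            entropy=self.master_seed, spawn_key=(cell_index, replicate)
        )

    @classmethod
    def from_yaml(cls, path) -> "GridConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("branch_lengths", "taxa_counts", "mutation_freqs"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    def to_yaml(self, path) -> None:
        data = dataclasses.asdict(self)
        for key in ("branch_lengths", "taxa_counts", "mutation_freqs"):
            data[key] = list(data[key])
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# rate profile draws


def draw_profiles(
    regime: str,
    n_sites: int,
    params: dict | None = None,
    rng: np.random.Generator | None = None,
) -> list[SiteRateProfile] | list[MutSelSiteProfile]:
    """Draw one site-specific rate profile per site under a named regime."""
    if regime not in REGIMES:
        raise ValueError(f"unknown regime {regime!r}; expected one of {REGIMES}")
    params = params or {}
    rng = rng if rng is not None else np.random.default_rng()

    if regime == "constant_dS":
        dn = rng.uniform(0.1, 1.6, size=n_sites)
        return [SiteRateProfile(dN=d, dS=1.0) for d in dn]
    if regime == "variable_dS":
        ratio = rng.uniform(0.1, 1.6, size=n_sites)
        ds = rng.uniform(0.5, 2.0, size=n_sites)
        return [SiteRateProfile(dN=r * s, dS=s) for r, s in zip(ratio, ds)]
    if regime == "gamma":
        alpha = params["gamma_shape"]
        beta = params["gamma_rate"]
        ratio = rng.gamma(shape=alpha, scale=1.0 / beta, size=n_sites)
        return [SiteRateProfile(dN=max(r, 1e-8), dS=1.0) for r in ratio]

    # MutSel regimes: Dirichlet amino-acid targets -> codon fitnesses
    conc = params.get("dirichlet_concentration", 0.5)
    mu = hky_mutation_matrix(params.get("mutation_freqs", (0.32, 0.18, 0.18, 0.32)))
    profiles = []
    for _ in range(n_sites):
        g = rng.dirichlet(np.full(20, conc))
        g = np.clip(g, 1e-8, None)
        g /= g.sum()
        f = fitness_from_aa_frequencies(g, mu)
        if regime == "mutsel_codon_bias":
            f = f + rng.normal(0.0, params.get("codon_bias_sd", 0.5), size=len(SENSE_CODONS))
        profiles.append(MutSelSiteProfile(fitness=f))
    return profiles


def build_site_models(
    profiles, codon_freqs=None, mutation_matrix=None
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Per-site rate matrices and stationary distributions for simulation."""
    qs, pis = [], []
    for p in profiles:
        if isinstance(p, SiteRateProfile):
            q = mg94_matrix(p, codon_freqs)
            pi = (
                np.full(len(SENSE_CODONS), 1.0 / len(SENSE_CODONS))
                if codon_freqs is None
                else np.asarray(codon_freqs, dtype=float)
            )
        elif isinstance(p, MutSelSiteProfile):
            mu = mutation_matrix if mutation_matrix is not None else hky_mutation_matrix()
            q = hb98_matrix(p, mu)
            pi = p.stationary(mu)
        else:
            raise TypeError(f"unsupported profile type {type(p).__name__}")
        qs.append(q)
        pis.append(pi)
    return qs, pis


def true_rates(profiles, mutation_matrix=None) -> np.ndarray:
    """Ground-truth per-site rate: dN/dS for (dN, dS) profiles, expected
    dN/dS from the scaled selection coefficients for MutSel profiles."""
    out = np.empty(len(profiles))
    for k, p in enumerate(profiles):
        if isinstance(p, SiteRateProfile):
            out[k] = p.ratio
        else:
            mu = mutation_matrix if mutation_matrix is not None else hky_mutation_matrix()
            out[k] = expected_dnds(p, mu)
    return out


# ---------------------------------------------------------------------------
# sequence evolution


def evolve(
    tree: PhyloTree,
    site_models: list[np.ndarray],
    rng: np.random.Generator | None = None,
    stationary: list[np.ndarray] | None = None,
    site_rngs: list[np.random.Generator] | None = None,
) -> CodonAlignment:
    """Evolve one codon alignment along a tree, independently per site.

    Root states are drawn from each site's stationary distribution and child
    states from ``exp(Q t)`` down every edge. ``site_models`` holds one 61x61
    rate matrix per site (sites may share a matrix object; the exponential is
    computed once per distinct object and edge length). ``stationary`` may
    supply the matching stationary distributions, saving an eigen-solve.

    Each site consumes its own random substream (spawned from ``rng`` unless
    ``site_rngs`` is given), so sites are independent and a site's realized
    column depends only on its model and its own stream — permuting the
    site models together with their streams permutes the columns identically.
    """
    from .codon_models import stationary_distribution

    n_sites = len(site_models)
    if n_sites == 0:
        raise ValueError("need at least one site model")
    if site_rngs is None:
        if rng is None:
            raise ValueError("pass either rng or site_rngs")
        site_rngs = rng.spawn(n_sites)
    elif len(site_rngs) != n_sites:
        raise ValueError("site_rngs must have one generator per site")

    # one kernel per distinct matrix object
    kernel_of: dict[int, int] = {}
    kernels: list[ReversibleKernel] = []
    pis: list[np.ndarray] = []
    site_kernel = np.empty(n_sites, dtype=np.intp)
    for s, q in enumerate(site_models):
        key = id(q)
        if key not in kernel_of:
            pi = (
                stationary[s]
                if stationary is not None
                else stationary_distribution(q)
            )
            kernel_of[key] = len(kernels)
            kernels.append(ReversibleKernel(q, pi))
            pis.append(np.asarray(pi, dtype=float))
        site_kernel[s] = kernel_of[key]

    mask = np.arange(tree.n_nodes) != tree.root
    lengths = np.unique(np.round(tree.edge_length[mask], 12))
    cdf_by_length: dict[float, np.ndarray] = {}
    for ell in lengths:
        p = np.stack([k.transition(ell) for k in kernels])  # (n_kernels, S, S)
        if not np.all(np.isfinite(p)):
            bad = int(np.argwhere(~np.isfinite(p).all(axis=(1, 2)))[0][0])
            raise ValueError(
                f"non-finite transition probabilities for site model {bad}, edge length {ell}"
            )
        cdf = np.cumsum(p, axis=2)
        cdf[:, :, -1] = 1.0
        cdf_by_length[ell] = cdf

    # uniforms per site, in a fixed traversal order: root draw, then one per
    # edge in preorder; drawn from each site's own stream
    u_all = np.stack([g.random(tree.n_nodes) for g in site_rngs])  # (n_sites, n_nodes)

    states = np.empty((tree.n_nodes, n_sites), dtype=np.intp)
    pi_cdf = np.cumsum(np.stack(pis), axis=1)[site_kernel]
    pi_cdf[:, -1] = 1.0
    states[tree.root] = (u_all[:, 0][:, None] < pi_cdf).argmax(axis=1)

    draw = 1
    for node in tree.postorder[::-1]:  # preorder: parents before children
        for child in tree.children[node]:
            ell = round(float(tree.edge_length[child]), 12)
            rows = cdf_by_length[ell][site_kernel, states[node], :]  # (n_sites, S)
            states[child] = (u_all[:, draw][:, None] < rows).argmax(axis=1)
            draw += 1

    leaf_states = states[tree.leaf_ids]
    return CodonAlignment(labels=tree.leaf_labels, states=leaf_states)


# ---------------------------------------------------------------------------
# grid materialization


def tree_grid(
    branch_lengths=BENCHMARK_BRANCH_LENGTHS, taxa_counts=BENCHMARK_TAXA_COUNTS
) -> dict[tuple[float, int], PhyloTree]:
    """All pairwise (branch length, taxa count) balanced trees."""
    return {
        (b, t): make_balanced_tree(t, b) for b in branch_lengths for t in taxa_counts
    }


def enumerate_grid(config: GridConfig) -> pd.DataFrame:
    """The registry of a design: one row per replicate alignment.

    Pure bookkeeping — no simulation happens here. Paths are relative and
    deterministic; seeds derive from the master seed via spawn keys.
    """
    rows = []
    for cell_index, (b, t) in enumerate(config.cells):
        cell = f"bl{b:g}_taxa{t}"
        for rep in range(config.n_replicates):
            seed_id = int(config.seed_sequence_for(cell_index, rep).generate_state(1)[0])
            rows.append(
                {
                    "regime": config.regime,
                    "cell_index": cell_index,
                    "branch_length": b,
                    "n_taxa": t,
                    "replicate": rep,
                    "seed": seed_id,
                    "tree_path": f"trees/{cell}.nwk",
                    "aln_path": f"alignments/{config.regime}/{cell}_rep{rep}.fasta",
                    "truth_path": f"truth/{config.regime}/{cell}_rep{rep}.tsv",
                }
            )
    return pd.DataFrame(rows)


def simulate_replicate(
    config: GridConfig, cell_index: int, replicate: int, tree: PhyloTree | None = None
) -> tuple[CodonAlignment, list, np.ndarray]:
    """Simulate one replicate: returns (alignment, profiles, true rates)."""
    b, t = config.cells[cell_index]
    if tree is None:
        tree = make_balanced_tree(t, b)
    rng = config.rng_for(cell_index, replicate)
    profiles = draw_profiles(config.regime, config.n_sites, config.params(), rng)
    mu = (
        hky_mutation_matrix(config.mutation_freqs)
        if config.regime.startswith("mutsel")
        else None
    )
    qs, pis = build_site_models(profiles, mutation_matrix=mu)
    aln = evolve(tree, qs, rng, stationary=pis)
    return aln, profiles, true_rates(profiles, mutation_matrix=mu)


def generate_grid(
    config: GridConfig, out_dir, resume: bool = False, overwrite: bool = False
) -> pd.DataFrame:
    """Materialize a full design to disk; returns the registry table.

    Writes one Newick tree per cell, one FASTA + truth TSV per replicate,
    and ``registry.tsv``. A prior partial run is rejected unless ``resume``
    (skip existing replicate files) or ``overwrite`` is set.
    """
    out = Path(out_dir)
    registry_path = out / "registry.tsv"
    if registry_path.exists() and not (resume or overwrite):
        raise FileExistsError(
            f"{registry_path} exists; pass resume=True to continue or overwrite=True to redo"
        )
    registry = enumerate_grid(config)
    for sub in ("trees", f"alignments/{config.regime}", f"truth/{config.regime}"):
        (out / sub).mkdir(parents=True, exist_ok=True)

    for (b, t), group in registry.groupby(["branch_length", "n_taxa"], sort=False):
        tree = make_balanced_tree(int(t), float(b))
        tree_path = out / group.iloc[0]["tree_path"]
        if overwrite or not tree_path.exists():
            tree.write(tree_path)
        for row in group.itertuples():
            aln_path = out / row.aln_path
            truth_path = out / row.truth_path
            if resume and aln_path.exists() and truth_path.exists():
                continue
            aln, profiles, truth = simulate_replicate(
                config, row.cell_index, row.replicate, tree=tree
            )
            aln.to_fasta(aln_path)
            _write_truth(profiles, truth, truth_path)
        logger.info("cell bl=%g taxa=%d done (%d replicates)", b, t, len(group))

    registry.to_csv(registry_path, sep="\t", index=False)
    return registry


def _write_truth(profiles, truth: np.ndarray, path) -> None:
    df = pd.DataFrame({"site": np.arange(1, len(truth) + 1)})
    if profiles and isinstance(profiles[0], SiteRateProfile):
        df["dN"] = [p.dN for p in profiles]
        df["dS"] = [p.dS for p in profiles]
    df["true_rate"] = truth
    df.to_csv(path, sep="\t", index=False)


def benchmark_uniform_design(master_seed: int = 0, **overrides) -> list[GridConfig]:
    """The two uniform-rate designs (constant and variable dS) of the study:
    50 replicates x 5 branch lengths x 5 taxa counts each, 2,500 alignments
    in total. Keyword overrides (e.g. reduced replicate counts) apply to both."""
    return [
        GridConfig(regime=regime, master_seed=master_seed, **overrides)
        for regime in ("constant_dS", "variable_dS")
    ]
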