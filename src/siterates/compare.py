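"""Agreement statistics between per-site rate vectors, and the study driver.

Codon-level dN/dS and amino-acid relative rates live on different scales,
so magnitude comparisons are made after normalizing both vectors to mean 1;
correlations (Spearman by default, Pearson also reported) are scale-free.
Replicates aggregate to mean +/- standard error per (branch length, taxa)
cell. :func:`run_study` runs the whole pipeline — simulate, infer both rate
kinds, normalize, compare, aggregate — for a :class:`~siterates.simulate.GridConfig`.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .aarates import AminoAcidRateModel
from .fel import Fel1
from .rates import RateEstimates
from .simulate import GridConfig, make_balanced_tree, simulate_replicate

__all__ = [
    "correlate",
    "rmsd",
    "ComparisonResult",
    "aggregate",
    "run_study",
]

logger = logging.getLogger(__name__)


def correlate(a, b, method: str = "spearman") -> float:
    """Correlation between two score vectors; NaN when either is constant."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("inputs must be 1-D arrays of equal length")
    if a.size < 3:
        raise ValueError("need at least 3 sites to correlate")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("inputs must be finite")
    if a.std() == 0 or b.std() == 0:
        return float("nan")  # undefined: zero variance
    if method == "pearson":
        return float(stats.pearsonr(a, b).statistic)
    if method == "spearman":
        return float(stats.spearmanr(a, b).statistic)
    raise ValueError(f"unknown correlation method {method!r}")


def _as_mean1(x) -> np.ndarray:
    if isinstance(x, RateEstimates):
        if x.normalization != "mean1":
            raise ValueError("rmsd requires mean-1 normalized scores")
        return x.scores
    x = np.asarray(x, dtype=float)
    if abs(x.mean() - 1.0) > 1e-6:
        raise ValueError("rmsd requires mean-1 normalized scores (mean != 1)")
    return x


def rmsd(a, b) -> float:
    """Root-mean-square deviation between two mean-1 normalized vectors."""
    a = _as_mean1(a)
    b = _as_mean1(b)
    if a.shape != b.shape:
        raise ValueError("inputs must have equal length")
    return float(np.sqrt(np.mean((a - b) ** 2)))


@dataclass
class ComparisonResult:
    """One replicate's agreement between two score kinds in one grid cell."""

    branch_length: float
    n_taxa: int
    regime: str
    replicate: int
    comparison: str  # e.g. "truth_vs_aa_rate"
    spearman: float
    pearson: float
    rmsd: float
    n_sites: int
    n_dropped: int = 0

    def __post_init__(self) -> None:
        for r in (self.spearman, self.pearson):
            if np.isfinite(r) and not -1.0 <= r <= 1.0 + 1e-12:
                raise ValueError(f"correlation {r} outside [-1, 1]")
        if np.isfinite(self.rmsd) and self.rmsd < 0:
            raise ValueError("rmsd must be nonnegative")


def aggregate(results: list[ComparisonResult] | pd.DataFrame) -> pd.DataFrame:
    """Mean and standard error (sd/sqrt(n)) per cell and comparison.

    Replicates with undefined (NaN) statistics are dropped and counted in
    ``n_undefined``; single-replicate cells get SE 0 and a flag.
    """
    df = (
        pd.DataFrame([vars(r) for r in results])
        if not isinstance(results, pd.DataFrame)
        else results.copy()
    )
    if df.empty:
        raise ValueError("no comparison results to aggregate")

    def _agg(group: pd.DataFrame) -> pd.Series:
        out: dict[str, float] = {}
        for stat in ("spearman", "pearson", "rmsd"):
            vals = group[stat].dropna()
            out[f"{stat}_mean"] = vals.mean() if len(vals) else np.nan
            out[f"{stat}_se"] = (
                vals.std(ddof=1) / np.sqrt(len(vals)) if len(vals) > 1 else 0.0
            )
            out[f"{stat}_n"] = len(vals)
            out[f"{stat}_n_undefined"] = group[stat].isna().sum()
        out["single_replicate"] = float(len(group) == 1)
        return pd.Series(out)

    keys = ["regime", "comparison", "branch_length", "n_taxa"]
    return df.groupby(keys, sort=True).apply(_agg, include_groups=False).reset_index()


DEFAULT_COMPARISONS = ("truth_vs_aa_rate", "fel1_vs_aa_rate")


def run_study(
    config: GridConfig,
    comparisons: tuple[str, ...] = DEFAULT_COMPARISONS,
    out_dir=None,
    correlation_methods: tuple[str, ...] = ("spearman", "pearson"),
    aa_kwargs: dict | None = None,
    fel_kwargs: dict | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the grid, infer rates, and tabulate agreement statistics.

    ``comparisons`` draws from {"truth_vs_aa_rate", "fel1_vs_aa_rate",
    "truth_vs_fel1"}. Returns ``(per_replicate, per_cell)`` tidy tables;
    with ``out_dir`` set, per-cell TSVs are written as cells finish and
    finished cells are skipped on a re-run (resumability). Replicates whose
    inference fails are recorded and excluded from aggregation.
    """
    valid = {"truth_vs_aa_rate", "fel1_vs_aa_rate", "truth_vs_fel1"}
    unknown = set(comparisons) - valid
    if unknown:
        raise ValueError(f"unknown comparisons: {sorted(unknown)}")
    need_fel = any("fel1" in c for c in comparisons)
    aa_kwargs = aa_kwargs or {}
    fel_kwargs = fel_kwargs or {}
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    rows: list[ComparisonResult] = []
    for cell_index, (b, t) in enumerate(config.cells):
        cell_tag = f"{config.regime}_bl{b:g}_taxa{t}"
        cell_file = out / f"cell_{cell_tag}.tsv" if out is not None else None
        if cell_file is not None and cell_file.exists():
            logger.info("cell %s: resuming from %s", cell_tag, cell_file)
            rows.extend(
                ComparisonResult(**rec)
                for rec in pd.read_csv(cell_file, sep="\t").to_dict("records")
            )
            continue
        t0 = time.perf_counter()
        tree = make_balanced_tree(t, b)
        cell_rows: list[ComparisonResult] = []
        for rep in range(config.n_replicates):
            try:
                cell_rows.extend(
                    _compare_replicate(
                        config, cell_index, rep, tree, comparisons, need_fel,
                        aa_kwargs, fel_kwargs,
                    )
                )
            except Exception:
                logger.exception(
                    "cell %s replicate %d failed; excluded", cell_tag, rep
                )
        rows.extend(cell_rows)
        if cell_file is not None and cell_rows:
            pd.DataFrame([vars(r) for r in cell_rows]).to_csv(
                cell_file, sep="\t", index=False
            )
        logger.info(
            "cell %s: %d replicates in %.1fs", cell_tag,
            config.n_replicates, time.perf_counter() - t0,
        )

    per_replicate = pd.DataFrame([vars(r) for r in rows])
    per_cell = aggregate(per_replicate)
    if out is not None:
        per_replicate.to_csv(out / "replicates.tsv", sep="\t", index=False)
        per_cell.to_csv(out / "cells.tsv", sep="\t", index=False)
    return per_replicate, per_cell


def _compare_replicate(
    config, cell_index, rep, tree, comparisons, need_fel, aa_kwargs, fel_kwargs
) -> list[ComparisonResult]:
    b, t = config.cells[cell_index]
    aln, _, truth = simulate_replicate(config, cell_index, rep, tree=tree)

    scores: dict[str, np.ndarray] = {"truth": truth}
    aa_res = AminoAcidRateModel(aln, tree, **aa_kwargs).fit()
    scores["aa_rate"] = aa_res.rates
    if need_fel:
        scores["fel1"] = Fel1(aln, tree, **fel_kwargs).fit().dnds

    out = []
    for comp in comparisons:
        left, right = comp.split("_vs_")
        a, bvec = scores[left], scores[right]
        keep = np.isfinite(a) & np.isfinite(bvec)
        a, bvec = a[keep], bvec[keep]
        sp = correlate(a, bvec, "spearman")
        pe = correlate(a, bvec, "pearson")
        # mean-1 normalization for the magnitude comparison
        if a.mean() > 0 and bvec.mean() > 0:
            r = rmsd(a / a.mean(), bvec / bvec.mean())
        else:
            r = float("nan")
        out.append(
            ComparisonResult(
                branch_length=b,
                n_taxa=t,
                regime=config.regime,
                replicate=rep,
                comparison=comp,
                spearman=sp,
                pearson=pe,
                rmsd=r,
                n_sites=int(keep.sum()),
                n_dropped=int((~keep).sum()),
            )
        )
    return out
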