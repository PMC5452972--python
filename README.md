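# siterates

Site-specific evolutionary rates can be estimated from codon sequences —
usually as a per-site dN/dS ratio — or from amino-acid sequences, as a
relative conservation score of the kind Rate4Site reports. The two score
kinds are used by largely separate communities (selection analysis in
viruses vs. structural conservation analysis in proteins), and it is not
obvious how comparable their results are. `siterates` is a simulation and
inference toolkit for answering exactly that question: it simulates codon
alignments with *known* per-site rates, infers rates at both levels, and
quantifies how well the frameworks agree across divergence levels and
alignment sizes.

The package provides:

* **Simulation** under two codon model families on balanced binary trees:
  an MG94-style model with per-site (dN, dS), and the Halpern–Bruno
  mutation–selection model (HB98) with per-site codon fitnesses, where
  the expected dN/dS at a site is derived from its scaled selection
  coefficients `S_ij` via the stationary nonsynonymous flux.
* **Codon-level inference**: FEL1 — one maximum-likelihood dN per site with
  a shared synonymous rate anchored at dS = 1, so the per-site dN *is*
  dN/dS. Sites whose translated column shows no amino-acid variation are
  assigned dN/dS = 0.
* **Amino-acid-level inference**: empirical-Bayes relative rates. Divergence
  at site *k* on branch *i* decomposes as `r_k · t_i`; site rates follow a
  discretized gamma prior (16 categories) whose shape is fitted to the whole
  alignment, and each site's score is its posterior mean rate under a JTT
  (or LG/WAG) replacement matrix.
* **Comparison**: Spearman/Pearson correlations and RMSD between mean-1
  normalized score vectors, with replicate aggregation (mean ± standard
  error) per grid cell, plus an end-to-end study driver.

## Worked example

Simulate a 128-taxon, 100-codon alignment at branch length 0.64 with
per-site dN ~ U(0.1, 1.6) and dS = 1, then infer rates both ways:

```python
import siterates as sr
from siterates.simulate import simulate_replicate

cfg = sr.GridConfig(branch_lengths=(0.64,), taxa_counts=(128,),
                    n_replicates=1, master_seed=7)
tree = sr.make_balanced_tree(128, 0.64)
aln, profiles, truth = simulate_replicate(cfg, 0, 0, tree=tree)

aa = sr.AminoAcidRateModel(aln, tree).fit()   # Rate4Site-style scores
fel = sr.Fel1(aln, tree).fit()                # per-site dN/dS

print(aa.summary())
print("Spearman(aa scores, true dN/dS):     %.3f" % sr.correlate(truth, aa.rates))
print("Spearman(aa scores, FEL1 dN/dS):     %.3f" % sr.correlate(fel.dnds, aa.rates))
print("RMSD(mean-1 aa scores, mean-1 true): %.3f" %
      sr.rmsd(aa.rates / aa.rates.mean(), truth / truth.mean()))
```

prints

```
Empirical-Bayes amino-acid site rates
  sites:             100
  taxa:              128
  replacement model: JTT
  gamma categories:  16
  gamma shape:       1.6697
  rate mean (var):   0.8581 (0.2208)
  rate range:        [0.1038, 2.2819]
  total loglik:      -29739.03
Spearman(aa scores, true dN/dS):     0.949
Spearman(aa scores, FEL1 dN/dS):     0.973
RMSD(mean-1 aa scores, mean-1 true): 0.218
```

At this divergence the amino-acid scores rank sites almost exactly as the
true dN/dS does (ρ ≈ 0.95), and they agree with the *inferred* dN/dS even
more strongly (ρ ≈ 0.97) — both methods see the same realized
substitutions, so they mis-estimate in the same way. The RMSD of 0.22
between the mean-normalized score vectors says the two score kinds also
agree in magnitude once placed on a common scale.

The same pipeline is scriptable from the shell:

```bash
siterates simulate      --config grid.yaml --out grid/
siterates infer-dnds    --aln aln.fasta --tree tree.nwk --out dnds.tsv
siterates infer-aarates --aln aln.fasta --codon --tree tree.nwk --out aa.tsv
siterates compare       --scores-a dnds.tsv --scores-b aa.tsv
siterates study         --config grid.yaml --out results/
```

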