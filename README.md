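# microstab

Diagnostics for gut-microbiome collapse and recovery in longitudinal
cohorts: diversity and stability statistics, random-matrix-theory (RMT)
thresholded co-occurrence networks with topology and keystone analysis,
community cohesion, and taxa–SCFA association — plus a synthetic cohort
generator with planted ground truth so every stage can be validated.

## The problem

Patients on a strict sterile diet (for example around a cord-blood
transplant) lose most of their gut microbial diversity within weeks;
opportunistic taxa bloom, short-chain fatty acids (SCFAs) drop, and the
community's interaction structure simplifies. When a normal diet resumes,
diversity and interactions recover. Quantifying that collapse-and-recovery
arc takes more than alpha diversity: it needs a community *stability*
index, interaction *networks* whose construction does not depend on an
arbitrary correlation cutoff, and per-sample measures of cooperation and
competition.

`microstab` packages that whole apparatus for OTU count tables from a
design of the form: subjects sampled at ordered timepoints S1 (baseline),
S2–S5 (sterile diet), S6–S9 (normal diet), plus one healthy family member
per subject (F).

## Methods at the core

* **AVD stability index.** For a group of k samples and the n OTUs with
  nonzero within-group dispersion,
  `AVD = Σ_j Σ_i |x_ij − x̄_i| / δ_i / (k·n)`,
  with `x̄_i`, `δ_i` the within-group mean and standard deviation of OTU i
  on rarefied counts. Lower AVD = more stable community.
* **RMT threshold selection.** The correlation cutoff for network adjacency
  is placed where the nearest-neighbour spacing distribution (NNSD) of the
  thresholded matrix's eigenvalues crosses from Gaussian-orthogonal-ensemble
  statistics (Wigner surmise, `P(d) = (πd/2)e^{−πd²/4}`, random noise) to
  Poisson statistics (`P(d) = e^{−d}`, system-specific structure). The scan
  unfolds each spectrum, tests both laws by χ², and returns the smallest
  threshold where Poisson fits and beats the Wigner surmise for two
  consecutive steps, with a full diagnostics table for audit.
* **Topology and keystones.** n, L, avgK = 2L/n, mean clustering, mean
  shortest-path distance, degree centralization, small-world σ against a
  matched Erdős–Rényi ensemble, random-removal robustness, and worst-case
  efficiency-loss vulnerability. Node roles follow the within-module degree
  z-score Zi and among-module connectivity Pi with the 2.5 / 0.62 grid
  (module hubs, connectors, network hubs = keystones).
* **Cohesion.** Pairwise correlations corrected by a taxa-shuffle null
  model, averaged per taxon into positive/negative connectedness, then
  abundance-weighted per sample into C_pos ≥ 0 and C_neg ≤ 0 (community
  cooperation and competition).
* **Association.** Spearman screens with Benjamini–Hochberg correction
  (top-30 taxa × six SCFAs), Mantel tests between distance matrices, and
  phase-to-phase abundance changes in percentage points or fold mode.

## Worked example

```python
import numpy as np
from microstab import *
from microstab import pipeline

cfg = SimulationConfig(seed=1)          # 9 subjects, S1-S9 + family
table, meta, scfa, truth = simulate_cohort(cfg)

sh = {r.sample_id: r.shannon for r in alpha_diversity(table)}
for tp in ["S1", "S5", "S9", "F"]:
    ids = meta.samples_for(timepoint=tp)
    print(f"mean Shannon {tp}: {np.mean([sh[s] for s in ids]):.2f}")

rare = rarefy(table, default_rarefaction_depth(table), seed=1)
aligned = meta.align_to(rare)
res = {r.group: r.avd for r in avd(rare, aligned.frame['timepoint'].to_numpy())}
print(f"AVD S5: {res['S5']:.3f}   AVD F: {res['F']:.3f}")

pair = pipeline.collapse_network_pair(table, meta, seed=1)
for name in ["baseline", "sterile"]:
    n, t = pair[name]["net"], pair[name]["topology"]
    print(f"{name} network: threshold {pair[name]['scan'].threshold:.2f}, "
          f"n={n.n_nodes}, L={n.n_edges}, sigma={t.sigma:.2f}, "
          f"positive edges {100*n.positive_edge_fraction():.1f}%")
```

prints

```
mean Shannon S1: 4.12
mean Shannon S5: 1.84
mean Shannon S9: 3.99
mean Shannon F: 2.90
AVD S5: 0.726   AVD F: 0.698
baseline network: threshold 0.68, n=203, L=319, sigma=7.36, positive edges 97.2%
sterile network: threshold 0.68, n=65, L=110, sigma=3.37, positive edges 99.1%
```

Read: Shannon collapses from 4.1 to 1.8 at the sterile endpoint and
recovers by S9 (the planted V-shape); the sterile timepoints are less
stable (higher AVD) than the family reference; the sterile-endpoint
network keeps a third of the baseline nodes and a third of its edges while
both remain small-world (σ > 1) and positive-edge dominated.

The same stages are available from a shell:

```bash
microstab simulate --out-dir cohort --seed 1
microstab run-all --otu cohort/otu_table.tsv --metadata cohort/metadata.tsv \
    --scfa cohort/scfa.tsv --out-dir results --seed 1
```

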