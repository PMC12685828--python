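# micronet

Downstream analysis of soil microbiome amplicon surveys from
intercropping field trials — the kind of study that compares cropping
systems (e.g. wheat monoculture **W**, soybean monoculture **S**, and
wheat–soybean intercropping **SW**) across bulk and rhizosphere soil in
a randomized block design, with matched soil chemistry and enzyme
assays.  It is written for microbial ecologists who have ASV feature
tables (16S for bacteria, 18S for eukaryotes), sample metadata, and a
soil-property table, and want the full battery of community statistics
as reproducible, tested code rather than a mosaic of one-off scripts.

## What it computes

* **Soil-property machinery** — two-factor block ANOVA
  (response ~ block + location × cropping system), Fisher's-LSD compact
  letter displays, marginal means over locations/systems, and percent
  differences.  Because the design is balanced, the decomposition
  SS_block + SS_L + SS_T + SS_L×T + SS_resid = SS_total is exact.
* **Alpha diversity** — Shannon H = −Σ pᵢ ln pᵢ, Gini–Simpson
  1 − Σ pᵢ², Chao1 = S_obs + F₁(F₁−1)/(2(F₂+1)); optional seeded
  rarefaction.
* **Beta diversity** — Bray–Curtis d = Σ|x−y| / Σ(x+y), principal
  coordinates (PCoA via Gower double-centering), and a permutation
  PERMANOVA with pseudo-F = (SS_b/(k−1))/(SS_w/(n−k)) and
  p = (1 + #{F* ≥ F})/(1 + N).
* **LEfSe-style biomarkers** — per-feature Kruskal–Wallis screen, then
  a bootstrap one-axis LDA effect size on relative abundance × 10⁶,
  reported on a log₁₀ scale with the conventional threshold of 2.
* **Co-occurrence networks** — all-pairs Spearman (or Pearson)
  correlations, Benjamini–Hochberg FDR across pairs, edges at
  |r| > 0.6 and q < 0.05; topology (vertices, edges, signed edge
  counts, average degree 2E/V, clustering coefficient); a complexity
  composite (mean of indices normalized to their maximum across
  compared networks); robustness under random node removal (remaining
  connectivity = fraction of original nodes that keep ≥ 1 edge);
  vulnerability = max relative drop of global efficiency
  E = mean 1/d_ij after deleting a single node.
* **dbRDA** — constrained ordination of the Bray–Curtis PCoA on
  standardized soil variables, per-axis percent of total inertia, and
  marginal envfit-style r² per variable with permutation p-values.
* **A synthetic-data generator** — an 18-sample (or inflated)
  Dirichlet-multinomial community simulator with planted diversity
  offsets, planted differential taxa, Gaussian-copula correlation
  modules and soil variables linked to latent community gradients, so
  every stage above has a recovery test with known truth
  (`micronet.simulate_dataset`, presets `paper`, `test`, `null`).

## Worked example

```python
import micronet as mn

sim = mn.simulate_dataset(mn.test_scale_design(), seed=42)
table = sim.feature_tables["bacterial"]
meta = sim.metadata

alpha = mn.alpha_diversity(table)
print(alpha["shannon"].groupby(meta["treatment"]).mean().round(3))

dm = mn.bray_curtis(table)
print(mn.permanova(dm, list(meta["treatment"]),
                   n_permutations=999, seed=0).summary())

fit = mn.dbrda_fit(dm, sim.soil, ["TP", "AP", "pH", "EOC"],
                   n_permutations=999, seed=0)
print(fit.summary())
```

prints

```
treatment
S     3.460
SW    3.843
W     3.433
PERMANOVA: F = 13.1, R2 = 0.369, p = 0.001 (999 permutations)
dbRDA: constrained 31.56% of total inertia
  axis 1: 23.64%
  axis 2: 5.45%
  ...
             r2  axis1_correlation     p
TP       0.8141             0.9023 0.001
AP       0.4672             0.6824 0.001
pH       0.2716           -0.01319 0.002
EOC      0.3485             0.4237 0.001
```

The intercropped system's planted Shannon boost (≈ ln 2 above
baseline at infinite depth) shows up as SW > W/S; the cropping-system
signal separates communities (PERMANOVA p at its minimum attainable
value); and TP — tied to the first latent community gradient by the
generator — is recovered as the strongest soil correlate.

The same stages are available from the shell:

```bash
micronet simulate --preset test --seed 42 --out-dir sim/
micronet permanova --table sim/features_bacterial.tsv --metadata sim/metadata.tsv
micronet network --table sim/features_bacterial.tsv --metadata sim/metadata.tsv \
    --group SW --out-prefix sw_net
micronet run-all --preset paper --seed 7 --out-dir run/
```

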