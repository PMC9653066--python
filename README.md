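# paircomm

Statistical analysis of **paired-design soil microbiome studies** — the
complete post-OTU workflow for comparing two treatments applied to matched
site pairs (e.g. disturbed vs undisturbed pasture soils): diversity,
differential taxa and functions, co-occurrence network structure and
stability, niche metrics, community-assembly inference, and a Bayesian
mediation model tying it all together. It is written for microbial
ecologists who have an OTU/ASV count table, sample metadata with a treatment
label and a pair id, and optionally a phylogeny and predicted-function
tables.

Because raw reads for such studies are often not deposited, the package
ships a synthetic paired-community generator with planted ground truth
(differential taxa, correlation blocks, niche- vs dispersal-assembled
metacommunities) so every method can be exercised and benchmarked end to
end.

## What it computes

- **Diversity** — rarefaction (without replacement); observed richness,
  Chao1 (`S + F1²/2F2`), ACE, Shannon (nats), inverse Simpson, Pielou
  `J = H/ln S`, Fisher's α (root of `S = α ln(1+N/α)`), Good's coverage
  `1 − F1/N`, Faith's PD; the same indices for function tables.
- **Group inference** — Shapiro–Wilk/Levene-gated test selection (t/ANOVA
  vs Wilcoxon/Kruskal–Wallis), Benjamini–Hochberg correction, Bray–Curtis
  and Jaccard distances, PERMANOVA (pseudo-F, R², permutation p with
  exhaustive enumeration for small designs), Venn partitioning of unique and
  shared taxa, a random-forest + Kruskal–Wallis differential screen, Welch's
  t on function rows.
- **Networks** — prevalence/abundance OTU filter, Pearson networks on
  relative abundances (`|r| > 0.8`, BH-adjusted `p < 0.001`), a full scalar
  property suite (connectance, clusters, modularity Q, Freeman
  centralization, max eigenvector centrality, vulnerability, natural
  connectivity `ln mean eᵏ`), bootstrap node-attribute distributions with KS
  comparison, stochastic node/edge-removal stability, robustness sweeps, and
  high/low-degree class partitions across two networks.
- **Niche & assembly** — Levins breadth `B = 1/Σ P²`, Pianka overlap,
  generalist/specialist calls against a fixed–fixed permutation null, SIMPER
  contributions, and a dispersal–niche continuum test selecting the
  assembly regime whose constrained null best reproduces the ranked SIMPER
  profile (lowest E).
- **Path model** — OLS regressions of degree on niche width and of Δdegree
  on niche overlap, and a Gibbs-sampled Bayesian mediation model
  `M = α₀ + aT`, `Y = β₀ + bM + cT` with Normal(0, 10²)/Inverse-Gamma(0.001,
  0.001) priors; a pathway is accepted when its 95% credible interval
  excludes 0.

See `docs/methods.md` for models, defaults and caveats.

## Worked example

```python
import paircomm as pc

config = pc.PipelineConfig(
    output_dir="results_demo",
    seed=42,
    synthetic=dict(
        n_taxa=150, n_pairs=15, depth_mean=20000, abundance_shape=1.0,
        diff_taxa=[(0, 5.0, "camping"), (1, 4.0, "no_camping")],
        corr_blocks=[(list(range(2, 11)), 1.0, "positive"),
                     ([10, 11, 12, 13, 14], 0.97, "positive"),
                     ([15, 16], 0.9, "negative")],
    ),
    rf_trees=2000, n_boot=10000, stability_replicates=500,
    robustness_replicates=50, niche_permutations=500, dnci_permutations=100,
    sem_chains=2, sem_iterations=2000, sem_burn_in=500,
)
report = pc.run_pipeline(config)
```

This simulates 15 site pairs under two treatments with two planted
differential taxa and three planted correlation blocks, then runs every
stage. Highlights of the bundle it writes (numbers from this exact
configuration):

- `permanova.json` — Bray–Curtis `R² = 0.400`, `p = 1e-4` (9,999
  permutations): the planted treatment effects shift composition, which the
  abundance-sensitive distance detects while presence/absence Jaccard
  (`p = 0.94`) does not.
- `network_properties.json` — per-treatment networks over the 128 filtered
  taxa: 31 edges (no camping) vs 32 (camping), natural connectivity 2.26 vs
  2.06; the planted 9-taxon block appears as a clique in both.
- `rf_importance.tsv` — the two planted differential taxa rank in the
  importance list's discriminating set (`kw_p < 0.05`).
- `dnci.json` — mean E: dispersal-controlled 0.0036, niche-controlled 0.614;
  the paired generator spreads taxa by abundance, not by group-structured
  site suitability, so the dispersal-controlled null reproduces its SIMPER
  profile and is correctly selected.
- `path_model.json` — width→degree model: `b = −0.23` with 95% CI
  `[−0.34, −0.11]` (accepted: taxa with narrower niches hold more planted
  edges in this fixture), treatment paths `a`, `c` not accepted, as planted.

Every output table is byte-identical when the same config and seed are
re-run; `run_log.json` records the per-stage seeds.

A command-line interface wraps the same stages:

```bash
paircomm simulate --out-prefix demo --seed 1
paircomm network --counts demo_counts.tsv --metadata demo_metadata.tsv --out net.graphml
paircomm run --config pipeline.yaml
```

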