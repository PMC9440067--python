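# spongiome

Analysis toolkit for deep-sea sponge microbiome surveys. Starting from an
ASV count table, host/environment sample metadata, a feature taxonomy and a
rooted phylogeny, it computes:

- **Diversity** — seeded rarefaction, Shannon (bits) / Pielou / observed
  richness / Faith's PD, weighted UniFrac (raw and normalized), Jaccard and
  Bray-Curtis distance matrices, UPGMA/complete-linkage sample dendrograms.
- **Membership** — core / variable / individual classification (core =
  presence in strictly more than 70% of sponge samples, individual = exactly
  one sample), optionally across greedy OTU clustering thresholds
  (ASV/99/97/95/90% global-alignment identity); sample-type sharing classes
  and abundance–occupancy correlation.
- **Specificity** — host-specific ASVs per host rank (present in one group,
  absent from all others and from seawater/sediment references) and
  exclusive ASVs (within-group prevalence strictly above 90%).
- **Adapted rarefaction** — microbial richness as a function of the number
  of host species, the "microbiome carrying capacity" curve per sponge type.
- **Sea distances** — least-cost sea paths below a depth threshold on a
  bathymetry raster (Dijkstra over an 8/16-neighbour navigation graph) and
  log-log distance-decay regression with a Mantel permutation test.
- **Multivariate statistics** — Dunn's test with tie correction, PERMANOVA
  (Gower centering, permutation p, pairwise + BH), Mantel, environmental
  PCA, VIF pruning, Hellinger RDA adjusted R², and 2–4-set variation
  partitioning with exact inclusion–exclusion fractions.
- **Networks** — location Jaccard similarity networks with betweenness,
  bipartite Zi-Pi module roles, weighted correlation modules
  (soft power / topological overlap / eigenprofiles / kME / trait
  correlations), and a simplified indicator-taxon analysis.
- **Classifiers** — HMA/LMA status prediction by random forest on
  phylum+class profiles with per-species majority votes, and rectangular
  T-S water-mass box classification.
- **Synthetic data** — a fully labelled generator (Dirichlet-multinomial
  counts, planted specific/exclusive/core ASVs, spatial decay,
  environmental effects, host taxonomy, coalescent trees, bathymetry
  grids) so every stage is testable offline; ground truth is emitted as
  JSON next to the bundle.

## Tests

```bash
python -m pytest -q            # default: skips the slow calibration suite
python -m pytest -q -o addopts=   # everything, incl. calibration
```

## CLI

All commands are subcommands of `spongiome`:

```bash
spongiome simulate --out bundle/ --seed 7
spongiome diversity --bundle bundle/ --out div/ --metric weighted_unifrac
spongiome membership --bundle bundle/ --out membership.tsv
spongiome specificity --bundle bundle/ --out specificity.tsv
spongiome rarefaction --bundle bundle/ --type HMA --reps 100 --out curve.tsv
spongiome seadist --grid bathy.asc --sites sites.tsv --min-depth 200 --out d.tsv
spongiome decay --community beta.tsv --geo d.tsv
spongiome stats permanova --distances beta.tsv --bundle bundle/ --group-column sponge_type
spongiome stats mantel --d1 a.tsv --d2 b.tsv
spongiome network --bundle bundle/ --out net/
spongiome status --bundle bundle/ --out status.tsv
spongiome watermass --boxes boxes.tsv --samples ts.tsv --out wm.tsv
spongiome pipeline --stages simulate,filter,diversity,membership --out run/ --seed 1
```

A *bundle* directory holds `counts.tsv` (features × samples, `#FeatureID`
header), `metadata.tsv` (`sample-id` first column), optional `taxonomy.tsv`
(semicolon-ranked lineages), optional `tree.nwk`, and — for synthetic data —
`ground_truth.json` and `bathymetry.asc` (ESRI ASCII grid).

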