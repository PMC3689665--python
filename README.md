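# phyloconserve

Phylogenetic conservation analysis toolkit: per-species evolutionary
metrics, regional community phylogenetic structure, phylogenetic signal
and PGLS threat models, and equal-area spatial phylodiversity layers —
with a seeded synthetic-study generator so the full pipeline runs
end-to-end without any external data.

## What it does

- **tree** — Newick I/O (quoted labels, comments, polytomies), terminal
  branch lengths ("species ages"), fair-proportion evolutionary
  distinctiveness (ED), patristic distance matrices, and the Brownian
  phylogenetic covariance matrix.
- **community** — MPD / MNTD per assemblage, a tip-pool null model
  (equally sized random draws from all tree tips), and the NRI / NTI
  standardized indices with one-tailed clustering and two-sided rank
  p-values.
- **comparative** — Blomberg's K with a tip-shuffling permutation test,
  and PGLS with Pagel's lambda estimated by bounded ML on [0, 1]
  (coefficients, SEs, t/p, multiple and adjusted R², model-level F/p,
  profile likelihood).
- **risk** — IUCN category → 50-year extinction probability via a
  configurable monotone mapping (a default IUCN50-style table ships as
  package data), human pressure as the count of distinct recorded uses
  (16-label controlled vocabulary), Yates-corrected chi-squared tests of
  per-use association with decline, and log10-transformed complete-case
  model frames aligned with a pruned covariance.
- **grids** — cylindrical equal-area ("Behrmann", standard parallel
  30°) gridding at 0.25° equatorial-arc cells, rasterization of WGS84
  polygons / lon-lat rectangles by cell-center containment, species
  richness and mean-metric layers, and Pearson layer correlations.
- **simulate** — seeded synthetic studies: Yule trees, Brownian/lambda
  traits, clustered / overdispersed / random regional assemblages,
  coastal-strip rectangular ranges, IUCN categories, use sets, and a
  global-decline variable with a configurable dependence on terminal
  branch length.
- **pipeline / cli** — config-driven orchestration producing plain CSV
  and ESRI ASCII-grid outputs plus a JSON manifest, deterministic under
  a single master seed.

## CLI

```sh
# generate a 54-species synthetic study (writes tree.nwk, species.csv,
# assemblages.csv, ranges.csv, config.yaml, run.yaml)
phyloconserve simulate --seed 7 --out study/

# full report: layers + correlations, NRI/NTI, Blomberg K, PGLS tables,
# per-use chi-squared tests (raw and Holm-adjusted)
phyloconserve report --config study/run.yaml

# individual stages
phyloconserve metrics   --tree study/tree.nwk --out metrics.csv
phyloconserve community --tree study/tree.nwk --assemblages study/assemblages.csv \
                        --reps 999 --seed 1 --out community.csv
phyloconserve signal    --tree study/tree.nwk --species study/species.csv \
                        --trait global_decline --out k.csv
phyloconserve pgls      --tree study/tree.nwk --species study/species.csv \
                        --response global_decline --predictors bl --out pgls.csv
phyloconserve grid      --tree study/tree.nwk --species study/species.csv \
                        --ranges study/ranges.csv --out layers/
```

Input formats: single-tree Newick; species table CSV
(`species,iucn_category,global_decline,h_max,propagule_size,uses,...`
with `uses` semicolon-delimited or wide `use_<name>` 0/1 columns);
assemblages as long `region,species` CSV; ranges as
`species,min_lon,min_lat,max_lon,max_lat` rectangles (antimeridian
crossings are split automatically) or GeoJSON polygons; the extinction
probability mapping as a small YAML (`horizon`, `probabilities`).

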