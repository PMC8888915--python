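# orchardnet

Community-structure analysis of soil-microbiome OTU tables, built around
the comparison of agricultural management regimes (integrated pest
management vs. organic apple orchards, crop rows vs. drive rows) against a
semi-natural grassland benchmark. The package implements the full desk
side of such a study — everything downstream of read clustering — as a
tested, reusable pipeline, plus a planted-structure community simulator so
every stage can be validated end to end without sequencing data.

Intended users: microbial ecologists analysing amplicon count tables
(fungi or bacteria) across land-use strata, and method developers who need
a co-occurrence/indicator pipeline with verifiable behaviour.

## What it computes

Given a taxa × samples count table, sample metadata (land-use × location
strata with site/plot nesting), an optional phylogeny and an optional
guild annotation:

1. **Rarefaction** — every sample is subsampled *without replacement*
   (multivariate hypergeometric) to an even depth (defaults 10,000 reads
   for fungi, 20,000 for bacteria), removing library-size bias.
2. **Alpha diversity** — Hill numbers ⁰D (richness) and
   ¹D = exp(−Σᵢ pᵢ ln pᵢ) (effective number of equally common taxa), and
   Faith's phylogenetic diversity PD = total branch length of the union of
   the observed leaves' root paths.
3. **Co-occurrence networks** — one per stratum: nodes are taxa, edges are
   positive, significant Spearman rank correlations (ρ > 0.6 and p < 0.05,
   strict; p from the t approximation t = ρ√((n−2)/(1−ρ²)) on n−2 df).
   Topology: degree, diameter, average path length, unnormalized closeness
   C(u) = 1/Σᵥ d(u,v), unnormalized betweenness B(u) = Σ_{s<t} σ_st(u)/σ_st,
   number of components, and Newman modularity Q of a Leiden partition.
4. **Keystone taxa** — nodes jointly passing strict thresholds: degree > 5,
   closeness > 0.005, betweenness < 40 (fungal preset) or degree > 15,
   closeness > 0.03, betweenness < 50 (bacterial preset).
5. **Indicator analysis** — per taxon, the group-equalized point-biserial
   correlation r.g between abundance and membership of every nonempty
   proper stratum combination; the maximizing combination gets a p-value
   from 999 whole-sample label permutations of the maximized statistic,
   p = (1 + #{perm ≥ obs})/(n_perm + 1). Significant taxa are exported as a
   bipartite strata↔taxa association network.
6. **Guild responses** — per-sample read counts summed by functional-guild
   label (single-label model), with dominant-guild ranking.

The simulator (`orchardnet.simulate`) plants known structure — correlated
taxon modules and hub taxa via a latent-factor Gaussian copula, stratum
indicator taxa via log fold changes, guild labels by configured fractions —
and serializes the ground truth, so recovery can be scored exactly.

## Worked example

The numbered scripts under `analysis/` run the benchmark study end to end
(shared seed 42); each writes its tables under `results/` and prints a
summary. `python analysis/01_simulate.py` then `02`–`05`:

```
simulated 240 taxa x 450 samples (seed 42) -> results/simulated
library sizes: min 12000, median 19925, max 32523
planted: 10 factor groups, 3 hubs, 20 indicator taxa
```

After rarefying to 10,000 reads, the per-stratum network comparison
(`03_networks.py`) prints:

```
                   n_nodes  n_edges  mean_degree  modularity  n_keystones
IPM_crop_row           240       10        0.083       0.000            0
IPM_drive_row          240        6        0.050       0.000            0
grassland              240      243        2.025       0.829           57
organic_crop_row       240        6        0.050       0.000            0
organic_drive_row      240        6        0.050       0.000            0

planted grassland hubs flagged keystone: 3/3
```

The semi-natural grassland stratum — where the simulator plants the
densest module structure — yields by far the most connected network and
all of the keystone taxa, the qualitative signature such studies report.
Indicator analysis (`04_indicators.py`) finds 37 significantly associated
taxa, 62.2% of them single-stratum specialists, and recovers the true
stratum combination for 20/20 planted indicator taxa at p < 0.05. Guild
aggregation (`05_guilds.py`) conserves reads exactly (guild + unassigned =
sample depth) and ranks the planted dominant guilds correctly.

The same pipeline runs on real tables from a single YAML config:

```bash
orchardnet pipeline --config run.yaml     # or: orchardnet simulate/rarefy/...
```

with stratification presets `management` (four orchard strata),
`land_use` (drive rows + grassland; crop rows omitted) or `all`.

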