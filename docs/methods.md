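# Methods

This note documents the statistical procedures, conventions and design
choices behind `orchardnet`, and what validation on synthetic data does
and does not establish.

## Rarefaction

Each sample is subsampled to a common depth *without replacement*: the
rarefied vector is one multivariate-hypergeometric draw from the sample's
reads. This is the standard meaning of rarefaction and gives the classic
closed-form expectation for rarefied richness,
E[S] = Σᵢ [1 − C(N−cᵢ, d)/C(N, d)], which the tests use for calibration.
Default depths are 10,000 (fungal) and 20,000 (bacterial) reads,
configurable. Samples shallower than the target depth are an error by
default — an analysis should notice them — with an explicit
`drop_shallow` escape hatch.

Reproducibility: a single global seed, with each sample's substream
derived from (seed, BLAKE2b(sample_id)). Results are therefore invariant
to sample order and stable across processes (Python's string hash is
randomized per process and is deliberately not used). The pipeline
rarefies once per seed; callers wanting rarefaction averaging can loop
over seeds.

## Diversity

Hill ⁰D counts positive taxa; ¹D = exp(−Σ pᵢ ln pᵢ) with natural log (the
exponential makes the base immaterial). ¹D ≤ ⁰D with equality only for
perfectly even communities; both are property-tested.

Faith's PD is presence-only. The default convention is **root-inclusive**:
PD is the total length of the union of the observed leaves' root paths,
so a single observed taxon contributes its full root path. This matches
the dominant implementation convention (e.g. scikit-bio, against which the
implementation is cross-checked on random trees). A `include_root=False`
variant subtracts the stem above the most recent common ancestor of the
observed set. Rooted-vs-unrooted is a genuine convention choice; both are
exposed because published values can follow either.

## Co-occurrence networks

Spearman ρ is the Pearson correlation of mid-ranks; the two-sided p-value
uses the t approximation on n−2 df, standard at the per-stratum n ≈ 90
this pipeline targets (an exact-permutation mode would only matter at
n ≲ 10). Zero-variance taxa are excluded (a constant cannot be
rank-correlated) with a warning. No prevalence filter and no
multiple-testing correction are applied by default — edges use raw
p < 0.05 with ρ > 0.6, both strict — but `min_prevalence` and a
Benjamini–Hochberg option exist for users who want them.

Metric conventions, chosen so the published keystone cutoffs make sense:

* **closeness**: unnormalized, 1/Σ distances within the node's component,
  0 for isolated nodes. On a several-hundred-node graph this is O(1/n),
  the only scale on which cutoffs like 0.005/0.03 are meaningful;
  component-rescaled variants would push every node far above them.
* **betweenness**: unnormalized Brandes count, each unordered pair once —
  again matching the magnitude of the 40/50 cutoffs.
* **diameter / average path length**: over connected pairs only;
  undefined (null) for edgeless graphs rather than 0.
* **modularity**: Newman Q of a partition found by the Leiden algorithm
  (igraph/leidenalg), run to convergence with seeds derived
  deterministically from the run seed, best of 5 restarts. Leiden was
  chosen over networkx's Louvain after the latter proved able to oscillate
  indefinitely on certain small graphs; Leiden is deterministic under a
  seed, fast, and attains the exhaustive-search optimum on every small
  graph in the validation suite. Q is recomputed from the returned
  partition with Newman's formula, so the reported value never depends on
  the optimizer's internal bookkeeping.

Keystone identification is a pure threshold rule (degree, closeness,
betweenness jointly, all strict inequalities) applied to node metrics of
the same network; presets carry the fungal and bacterial cutoffs.

## Indicator analysis

The statistic is the group-equalized point-biserial correlation r.g:
sites are reweighted so each stratum contributes total weight N/K before
correlating abundance with the 0/1 combo-membership indicator. With equal
stratum sizes this reduces exactly to the plain point-biserial
correlation (property-tested against scipy's Pearson). All 2^K − 2
nonempty proper subsets of strata are scored (K capped at 5, i.e. 30
combos); ties break toward smaller, then lexicographically earlier,
combos.

Significance: whole-sample permutation of site labels; at every
permutation the statistic is re-maximized over combos, so the p-value
accounts for selection of the best combination, with
p = (1 + #{perm ≥ obs})/(n_perm + 1) and default n_perm = 999.
Permutations are drawn independently per taxon. Abundance enters as
rarefied counts: Spearman-style rank invariance does not apply to the
point-biserial statistic, and even depth is what makes counts comparable
across samples. Permutations are unrestricted (no within-plot blocking)
by default; nested designs that need restricted shuffling should filter
to the relevant stratum level first.

## Guild aggregation

Single-label model: each taxon carries exactly one guild or `unassigned`.
Multi-guild annotation strings are rejected with instructions to collapse
them upstream — silently splitting or double-counting reads would break
the conservation invariant (guild totals + unassigned = sample depth)
that the tests enforce. Dominant guilds are ranked by total read count
with lexicographic tie-breaks. Statistical modelling of the guild
response table (GLMMs etc.) is out of scope; the table is the product.

## The community simulator

What it emulates: the five land-use/location strata of an
orchard-vs-grassland design, 90 samples each with site/plot/subplot
nesting; uneven library sizes (lognormal, benchmark ≈ 20,000 ± 4,000
reads, truncated ≥ 12,000 so every sample supports the 10,000-read
rarefaction depth); correlated taxon modules and hub taxa; stratum
indicator taxa; guild labels; a random bifurcating phylogeny.

Generative model per sample: each module or hub group has a latent
standard-normal factor, active only in its designated stratum. A taxon's
log-abundance is base + σ·(λ·factor + √(1−λ²)·noise) (σ = 1), plus the
log fold change for indicator taxa in their strata. Log-abundances are
softmaxed to relative abundances; counts are Dirichlet-multinomial at the
sample's depth. The latent-factor construction is a Gaussian copula: it
plants rank correlation directly, which is what the Spearman stage
estimates, and its induced pairwise latent correlation is simply λᵢλⱼ.

Calibration facts that shaped the defaults (all verified by the test
suite):

* Rank conversion plus counting/Dirichlet noise attenuate latent
  correlations by roughly 0.10–0.15 at the benchmark's depths, so module
  loadings of 0.93–0.95 (hub 0.97, partners 0.92) are needed to plant
  count-scale ρ clearly above the 0.6 edge threshold.
* **Compositional closure**: if planted taxa carry a large share of total
  abundance, the softmax denominator co-moves with their shared factor
  and cancels it. Planted structure must be a minority of the community;
  the benchmark plants 91 structured taxa among 240.
* Low-abundance taxa cannot be hubs: at a handful of reads, counting
  noise destroys rank correlation. Structured taxa therefore draw their
  base abundance from a tighter distribution (sd 0.5) around an elevated
  mean (+1.5 log units), and hub taxa a further +0.75 — mirroring the
  empirical fact that network hubs are consistently abundant, prevalent
  taxa.
* The Dirichlet concentration (benchmark 5,000 over 240 taxa) sets
  overdispersion; decreasing it monotonically degrades planted
  correlations (property-tested), and the `null_community` preset shows
  the (ρ > 0.6, p < 0.05) rule yields a tiny false-positive edge fraction
  (≈0.3% of pairs at n = 20) with no structure.

What passing tests do **not** show about real data: the simulator has no
taxonomic structure, no sequencing-error or chimera model, no spatial
autocorrelation, no negative interactions and no compositional effects
beyond the softmax; indicator effects are clean mean shifts. Recovery
rates on the benchmark certify the *pipeline's* correctness and power
under its own generative assumptions, not effect sizes in field data.

## Problem sizes used in validation

The benchmark analysis uses 240 taxa × 450 samples, 999 permutations, and
one rarefaction per seed; oracle suites use 200 random graphs (≤ 7 nodes)
for exact metric equivalence, exhaustive partition search on ≤ 8-node
graphs for modularity, 2,000 replicate draws for rarefaction calibration
and 2,000 null taxa for permutation type-I error. These sizes give
Monte-Carlo standard errors comfortably inside the asserted tolerances
while keeping the whole validation run at desk scale.

## Numerical and degenerate-input conventions

Strict inequalities everywhere thresholds appear (edges and keystones),
as published. Edgeless graphs report diameter, path length and modularity
as undefined rather than 0. All-zero abundance vectors are errors for
diversity (undefined) and skips-with-warning for correlation/indicator
statistics (a constant has no ranks). Count tables must be nonnegative
integers; parse errors name the offending cell. Output tables pin float
formatting (`%.10g`), so identical runs are byte-identical.
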