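# Methods

This note records the models, conventions and deliberate choices behind
`grainscape`, in the spirit of a methods supplement: what is computed, under
which assumptions, and what the synthetic data does and does not emulate.

## OTU table processing

An OTU table is an integer matrix of samples × OTUs. Two filtering
conventions matter and are fixed as follows:

- **Rare-OTU removal.** `remove_rare_otus(table, min_total=3)` drops OTUs
  whose summed count across *all* samples in the table is below three —
  absolute singletons and doubletons. "All samples" means grains and bulk
  together when they are analyzed as one sequencing run; a per-sample mode
  (`per_sample=True`) is available for datasets processed separately.
- **Rarefaction.** `subsample` draws each sample's reads without
  replacement (multivariate hypergeometric via
  `numpy.random.Generator.multivariate_hypergeometric`), defaulting to the
  lowest per-sample depth so all samples are compared at identical depth.
  Rarefying a sample at its own depth is the identity, which several exact
  tests rely on.
- **Rare-biosphere thresholds.** `abundance_threshold(table, permille)`
  zeroes counts whose within-sample relative abundance is *not strictly
  greater than* the threshold, and is meant to be applied after
  rarefaction, so "0.1‰ at depth 44901" removes counts ≤ 4.
- **Aggregation.** `aggregate_by_rank` buckets OTUs missing from the
  taxonomy as `unclassified` and partial lineages as
  `unclassified_<deepest known taxon>`; grand totals are conserved.

## Diversity metrics

All metrics are implemented from their defining formulas and cross-checked
in the test suite against scikit-bio and a brute-force enumeration oracle
(leaf sets per edge / root-path sums) to 1e-9 on random fixtures.

- **Chao1** uses the bias-corrected form `S_obs + f1(f1−1)/(2(f2+1))`
  (the default in mothur); the classical `S_obs + f1²/(2 f2)` sits behind
  `bias_corrected=False`.
- **Inverse Simpson** is the plug-in `1/Σ p_i²` (vegan's `invsimpson`);
  the unbiased finite-sample form is behind a flag.
- **Faith's PD** is root-inclusive (picante's `include.root=TRUE`): the
  summed length of every branch on a path from an observed leaf to the
  root. With all leaves present it equals the tree's total branch length.
- **UniFrac.** Both variants run off one postorder traversal that
  accumulates, per branch, the read mass descending through it for each
  sample (O(nodes) per table). Unweighted UniFrac is unique/observed branch
  length with presence defined as ≥ 1 read below the branch. Weighted
  UniFrac defaults to the normalized form
  `Σ L_b |p_A−p_B| / Σ L_b (p_A+p_B)`; this is algebraically identical to
  the classical leaf-depth normalization (the branch sum telescopes onto
  leaf-to-root distances), so either reference implementation can check
  it. The unnormalized variant (numerator only) is behind
  `normalized=False`. Similarities quoted in reports are `1 − distance`.

Trees are dendropy objects read from newick; branch lengths must be
non-negative, `None` is treated as zero, and a zero-length root edge is
allowed. Collapsing zero-length branches provably changes neither metric
(tested).

## Core community

Core = OTUs with count ≥ `presence_min` (default 1) in at least
`min_prevalence` (default 1.0, i.e. all) of the grain samples, computed on
equal-depth tables (unequal depths warn). Bulk samples never enter the
prevalence computation but remain available for comparative reporting.
The family breakdown reports shares of *total* sample reads; core families
below 0.5% mean share pool into "other core community", and the non-core
remainder completes each row to 1. Lowering the prevalence can only grow
the core set (tested monotone).

## Pooling-coverage procedure

Grains are rarefied once to a common depth `n`, ordered by their rarefied
observed richness (ties broken by sample id), and pooled consecutively, so
a pool of `k` grains holds exactly `k·n` reads. The bulk reference is the
concatenation of the bulk replicates ("bulk_pooled"); for each `k` it is
rarefied to `k·n` reads (replicated, default 10×, mean ± sd reported) and
coverage is the fraction of the bulk subsample's OTUs present in the grain
pool. When `k·n` exceeds the bulk reference's depth the comparison
truncates to the full bulk with a warning, and the depth actually compared
is recorded per point. Grain subsamples stay fixed across `k` — only the
bulk subsample is replicated — so pools are strictly nested and the curve
is non-decreasing up to Monte-Carlo noise.

## Colonization geometry

Inputs: total cell count per cm³ of sediment (default 1.1×10⁹), grain
surface area per cm³ from micro-CT (default 1.2×10¹⁰ µm²), cell footprint
(default 0.43 µm²), grain diameters (defaults 202 and 635 µm), porosity.

- density ρ = cells / surface area (cells µm⁻²)
- area per cell a = 1/ρ; lattice spacing s = √a (square-lattice
  convention: each cell centered in its own equal square)
- colonized fraction f = footprint × ρ
- cells per grain, surface route: sphere surface π d² times ρ
- cells per grain, packing route: grains per cm³ = (1 − porosity)/(π d³/6)
  with d in cm, then cells per cm³ ÷ grains per cm³.

Raw values are never rounded internally. The `printed` view of
`geometry_report` applies the conventional reporting precisions (density 2
decimals; area and spacing 1 decimal; whole-percent coverage; 2
significant figures for cells per grain) and — deliberately — recomputes
the derived chain from the two-decimal density, because that is how such
chains are quoted in practice (1/0.09 = 11.1 µm², √11.1 = 3.3 µm). The
porosity default (0.423) is a fitted value chosen so the packing route's
two-significant-figure endpoints bracket 8.2×10³–2.6×10⁵ cells per grain
over 202–635 µm; it is not a measured quantity and should be overridden
when porosity is known. The surface route scales as d², the packing route
as d³; over the default diameter range the two agree within a factor of
three.

## Spatial statistics

Point patterns are 2-D cell coordinates on maximum-intensity projections,
each labelled `exposed` (convex, abrasion-prone surface) or `protected`
(depressions and cracks). Nearest-neighbor distances are computed within
patch class by default (cross-class neighbors allowed via
`within_class=False`), with plain Euclidean distances and no edge
correction. "Touching" cells — any point with a neighbor strictly closer
than the touching radius (default 1.0 µm, about one cell diameter) — are
excluded by default before the neighbor search, emulating automated
detectors that cannot separate abutting cells; this can only bias the mean
upward (tested), which is the correct direction to interpret reported
means. Classes with fewer than two retained points get `n_cells` but null
statistics. `theoretical_vs_observed` juxtaposes the observed class means
with two references at a given density ρ: the square-lattice spacing
√(1/ρ) and the homogeneous-Poisson nearest-neighbor expectation 1/(2√ρ)
(at ρ = 0.09 µm⁻²: 3.33 and 1.67 µm).

## Synthetic data generator

The community generator plants the structure the analyses are designed to
detect. Defaults are fixed to the study conditions this package targets:
17 grain + 3 bulk samples; 394 core OTUs carrying 60% of each grain's
reads (the middle of "one-half to two-thirds"); 4000 rare OTUs each
included on a grain with probability 0.15; grain depths uniform in
44901–58769 reads and bulk depths in 75134–137585; 800 bulk-only OTUs at
5% of bulk reads so grains recover only part of bulk richness.

Mechanics: OTU base abundances are lognormal (σ = `abundance_shape`,
default 1.5 — a long-tailed rank-abundance curve), jittered per grain by a
second lognormal (σ = 0.5); each grain's read mass is split
`core_read_fraction` : remainder between core and included rare OTUs, and
counts are multinomial at the drawn depth. Because a multinomial draw
cannot guarantee presence, any core OTU drawn at zero on a grain is
floored to one read, compensated within that grain's largest core counts,
so "core present on every grain" holds by construction at exact depth.
Bulk samples are multinomial draws from the average grain mixture blended
with bulk-only mass. The tree is a random bifurcating topology built by
iterative random joins with exponential branch lengths (mean 0.1) — any
valid rooted tree exercises the phylogenetic metrics. Taxonomy assigns
families Zipf-weighted from 120 grain families, with bulk-only OTUs drawn
from a disjoint family pool.

The point-pattern generator tiles the window into a 16×16 grid, marks a
random cell subset as protected (matching the requested area fraction),
and populates each class at its own intensity: homogeneous Poisson within
the class region, or a Thomas process (Poisson parents, Gaussian daughters
at `cluster_scale`, daughters thinned to the parent's class region) when
clustering is requested. Default intensities (exposed 0.012, protected 1.0
cells µm⁻², 8% protected area) give a window-wide density near 0.09
cells µm⁻² with the ~10-fold spacing contrast between patch classes.

What the generator does **not** emulate: sequencing error and chimeras,
taxon-specific ecological structure (phylogenetic signal in abundance),
overdispersion between PCR replicates, grain-size effects on community
composition, 3-D surface curvature in point patterns, and cell-size
variation in touching detection. Tests passing on synthetic data therefore
demonstrate correctness of the computations under the planted statistical
structure, not robustness to those real-data complications.

## Problem sizes and numerical conventions

The test suite runs the full pipeline at the defaults above (17 grains at
~5×10⁴ reads); metric cross-checks use 20 random 8–16-leaf trees;
rarefaction moments use 10⁴ replicate draws; the Poisson nearest-neighbor
check uses ~10⁴ points at λ = 0.09 µm⁻² (3-standard-error tolerance, where
boundary effects at this window size are an order of magnitude smaller
than the tolerance). Coverage-curve replication defaults to 10 bulk
subsamples per pool size. Ties in richness ordering break by sample id;
all generators and rarefactions are seeded, and pipeline stage seeds are
spawned deterministically from the run seed, so identical configs give
byte-identical outputs.

## Known limitations

- Faith's PD and UniFrac require every observed OTU to be a tree leaf;
  there is no fallback for missing placements.
- The packing-route cells-per-grain depends on the fitted porosity default
  unless overridden; treat its output as a consistency check, not a
  measurement.
- Coverage curves treat the bulk pool as the richness reference; they do
  not extrapolate richness beyond the observed pools.
- No multiple-grain point-pattern registration: each pattern is analyzed
  in its own window.
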