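# Methods

This document states the models, conventions, parameter defaults and
numerical choices implemented in `hotroutes`, and the known limits of
the synthetic-data generator.

## Grid, ranges and hotspot delineation

The analysis grid is a rectangular lattice of square cells
(default 100 km side). A species' range size is its occupied cell
count; per-cell **weighted endemism** is

WE(c) = Σ over species present in c of 1 / range-size,

so WE summed over all cells equals the number of species exactly — a
conservation property the tests check to 1e-9. Cells with no species
are omitted (their WE is zero by definition).

Delineations:

- **Top quantile**: the top 20% (configurable) of *occupied* cells by
  a metric (WE or SR) are hotspot; exactly ceil(0.2 n) cells are
  selected, with ties at the threshold broken by cell id so the
  partition is deterministic.
- **Narrow-range species (NRS)**: a range-area threshold in km² is
  converted to a cell count as floor(area / cell_km²) — 100,000 km²
  on a 100-km grid is 10 cells — and a cell is hotspot if it holds at
  least one species at or below the threshold.
- **Overlap** between two partitions is |A ∩ B| / min(|A|, |B|) × 100.

## Tip rates (DR) and residual contrasts

DR is the inverse of the equal-splits measure: walking from a tip to
the root, the j-th edge contributes its length × 2^−(j−1); DR = 1/ES.
DR scales exactly as 1/c when all branch lengths are multiplied by c.
Species are split into quartiles by ascending DR (Q1 "ancient", Q4
"recent"); group sizes differ by at most one with remainders assigned
to lower quartiles and ties broken by species name.

Per-cell Q1 and Q4 richness are regressed on total richness by OLS
*within each realm*; a realm with constant richness or fewer than
three occupied cells is dropped with a warning. Hotspot vs non-hotspot
residual contrasts are reported two ways: a Hodges–Lehmann shift
(median of all pairwise differences) with a CI from inverting the
Wilcoxon rank-sum test, and the hotspot-indicator coefficient of a
spatial-autoregressive error regression (below), whose whitened
residuals feed a second HL contrast.

## SAR error model

`sar.fit_sar_error` maximizes the likelihood of y = Xβ + u,
u = λWu + ε by 1-D profile likelihood in λ. W is the row-standardized
adjacency of cells within a distance band (default 1000 km);
log|I − λW| is computed exactly from the eigenvalues of the similar
symmetric matrix D^−1/2 A D^−1/2, so each additional λ evaluation is
cheap. λ is searched inside the interval where I − λW is nonsingular.
With an empty neighbour graph the fit reduces exactly to OLS (λ = 0).
Standard errors of β are GLS errors conditional on λ̂.

## Historical biogeography

State space: three areas — H (hotspot region of the focal realm), N
(rest of the focal realm), E (everything external) — and ranges of
size one or two: {H, N, E, HN, HE, NE}. An absorbing null range is
used internally by the simulator and path sampler.

Anagenesis: dispersal adds an area at rate d per (source area ×
addable area), local extinction removes an area from a two-area range
or kills a single-area range at rate e. Cladogenesis follows the
family's weight table:

- **DEC**: single-area parents duplicate; two-area parents split into
  subset-sympatry (4 outcomes) and vicariance (2 outcomes), all equal
  weight (1/6 each).
- **DIVALIKE**: no subset sympatry; duplication and vicariance only.
- **BAYAREALIKE**: both daughters copy the parent range.
- **+J** adds founder outcomes (one daughter jumps to an unoccupied
  single area) with weight j per ordered outcome, before per-parent
  normalization.

The likelihood is computed by pruning with per-node rescaling; branch
transition probabilities are rows of exp(Qt). **By default each row is
renormalized by its survival probability** (`conditioning="branch"`):
every branch of a reconstructed tree is known to have left extant
descendants, and the renormalized rows are exactly the law of a
forward simulator that resimulates branches whose range dies — the
generator used here and by common simulation tools. Without this
conditioning the maximum-likelihood extinction rate collapses to the
boundary at zero; with it, both d and e are recovered consistently.
`conditioning="none"` restores the classic defective-generator
convention. The root prior is uniform over the six non-null ranges
(a custom probability vector can be supplied).

Fitting uses multi-start (3) L-BFGS-B on (log d, log e, and j when
present), with d, e ∈ [1e−12, 5] and j ∈ [0, 3]. Models are compared
by AICc with n = number of tips. exp(Qt) is computed by
eigendecomposition with a `scipy.linalg.expm` fallback when the
eigenvector matrix is ill-conditioned.

## Biogeographic stochastic mapping

Sampling is backward–forward: pruning tables give per-node partial
likelihoods; the root state, each cladogenetic outcome and each
daughter start state are drawn from their joint conditional
distributions, and each branch's path is drawn conditional on its two
endpoint states by **uniformization** (Poisson jump-count inversion
with cached powers of the uniformized transition matrix), falling back
to rejection sampling in the rare case the jump-count cap is hit. The
per-branch survival conditioning cancels for endpoint-conditioned
paths, so path sampling uses the plain conservative generator.
Unbiasedness is verified in the tests against numerical integration of
conditional occupancy times and against true forward histories.

Events are typed as dispersal (area gained anagenetically), local
extinction (area lost), within-region cladogenesis (region shared by
both daughters), vicariance, and founder jumps.

**Rate series** use half-open 2-Ma bins on [2, 26) Ma by default. The
dispersal rate for a bin is the event count divided by the lineage
count of the *normalizing region* at the older boundary of the
previous bin — destination by default, source by option. Bins whose
median denominator falls below `min_lineages` (default 10) are masked
as NaN, never zero-filled. The in situ cladogenesis series defaults to
the time-weighted mean of per-branch speciation rates (mean descendant
tip DR by default; externally estimated rates can be substituted) over
in-region branch segments; an event-count estimator mirroring the
dispersal series is also provided.

The **standardized difference** between two series is (a − b) divided
by the pooled SD of all non-masked per-map rate values of both series,
reported per bin (median and 10–90% across maps) and as a window
aggregate (each map's mean over defined bins, summarized across maps).
Note that per-destination-lineage rates confound per-lineage dispersal
intensity with occupancy: a directional asymmetry that fills the
destination region lowers its per-destination rate. For questions
about directional intensity, use `normalize_by="source"`.

**Colonization age** of a region is the median (across maps) age of
the oldest event or node state that first places a lineage in the
region.

## Spatial nulls

Ripley's K uses the translation edge correction (exact on rectangular
windows). A Thomas cluster process — Poisson parents (intensity κ),
Gaussian-displaced offspring (scale σ), K(r) = πr² +
(1/κ)(1 − exp(−r²/4σ²)) — is fitted by minimum contrast on K^0.25
over L-BFGS-B with identifiability bounds κ ∈ [λ̂/10⁴, 5λ̂],
σ ∈ [side/1000, side]; a fit at the σ upper bound is flagged
`weak_clustering` (Poisson-like pattern). Control hotspot sets are
simulated from the fitted process (parents drawn in a 4σ-padded
window), snapped to grid cells and accreted/trimmed to exactly the
observed hotspot cell count. The observed contiguity statistic
(mean per-cell median distance to a same-class cell) is ranked in the
control distribution; the two-sided rank envelope flags values outside
the central 90% (ties get half weight; at least 20 controls are
required, and 99 controls give an exact 10% nominal flag rate).

## Environmental contrasts

Layers: terrain ruggedness (mean absolute elevation difference to the
eight neighbours, optionally block-averaged), climate-change velocity
(temporal change / spatial gradient, gradient floored to avoid
division by zero), tectonic movement (SD of centred inter-neighbour
distance series), and arbitrary per-cell variables. The contrast fits
one SAR-error regression per variable of the standardized variable on
the hotspot indicator; variables are screened for pairwise |r| > 0.7
(later-listed variable dropped) and zero-variance variables are
skipped with a warning; p-values are Bonferroni-corrected across the
retained variables. The weights graph should match the spatial scale
of the data — an over-connected graph under-whitens and inflates
significance.

## Synthetic-data generator

One seed drives independent substreams (tree, ranges, occurrences,
environment) via `numpy` `SeedSequence` spawning, so changing one
component's draw does not perturb the others.

- Tree: Gillespie birth–death (birth 0.15, death 0.05 per Ma)
  conditioned on the tip count by stopping at the (n+1)-th birth;
  extinct subtrees pruned; ~40–60 Ma crown ages at the default size.
- Ranges: forward simulation of the configured model; branches whose
  range dies are resimulated (count recorded). A `dispersal_mult`
  matrix can scale directional dispersal rates in the generator only
  (fitting remains symmetric).
- Occurrences: per species one contiguous, breadth-first-grown patch
  per occupied area with heavy-tailed (Lomax) sizes, plus 15% extra
  species without a tip on the tree (distribution data only).
- Environment: effect × hotspot-indicator + (I − λW)⁻¹ε on the rook
  graph, λ = 0.5.

Known limits: occupancy patches are geometrically simple (no
environmental niche structure); the tree and ranges are independent of
geography within a region; realms are vertical bands; diversification
is rate-homogeneous, so DR variation across tips reflects tree shape
only.

## Pipeline determinism

`pipeline.run_all` derives per-stage seeds as
sha256(f"{seed}:{stage}") mod 2³¹, writes every stage table as CSV and
a `manifest.json` containing the configuration hash, stage seeds and
the assumption register. The manifest is a pure function of the
configuration: running the same configuration twice produces
byte-identical outputs (wall time is reported only in the returned
summary, not in the file).
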