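# Methods

This note documents the models and procedures implemented in `ssnpatterns`,
the choices made where the design was genuinely open, and what the synthetic
corpus does and does not establish about real data.

## Problem setting

Environmental 18S rDNA V4 metabarcoding yields *metabarcodes* — sequences
representative of read clusters (ASVs/OTUs) — of which a large fraction,
especially among parasitic Syndiniales (marine alveolates, MALV groups
I–V), cannot be assigned to any referenced genus. The package infers spatial
and temporal ecological patterns for such lineages without taxonomic
assignment, by clustering metabarcodes from heterogeneous sampling projects
at 100% sequence identity and analysing the resulting clusters as
genus-level proxy units.

## Harmonization

Datasets from different projects are made comparable by applying identical
screens to each dataset independently, in this order:

1. **Blocklist** — removal of multicellular taxa at any of the 8 taxonomic
   ranks (default: Metazoa, Streptophyta, Florideophyceae, Bangiophyceae,
   Phaeophyceae, Ulvophyceae).
2. **Reference identity** — removal of records whose best reference-database
   hit is strictly below 80% identity. The identity is an *input* column:
   the package never queries reference databases. Records without a value
   are kept by default (configurable), since the screen targets upstream
   assignments.
3. **Length** — only sequences strictly longer than 200 bp are kept.

A record failing several screens is attributed to the first failing one for
reporting; the retained set is order-invariant (tested). Merged tables cover
the union of samples, missing entries are zero, and each sample is
renormalized to relative abundances (column / column sum). "Scaled from 0 to
1" is interpreted as exactly this per-sample relative abundance — values
already lie in [0, 1] — with no extra min–max pass; the transform is
idempotent.

### Taxonomy semantics

Each metabarcode carries an 8-rank path (kingdom … species) in which
`"Unknown"` marks missing assignment. A rank labelled `Unknown` is
**unassigned** when no more specific rank is assigned, and a **gap** in the
hierarchy when some lower rank is assigned. Gaps are never counted as
unassigned ranks.

### Depth layers

Surface (≤ 5 m), mesopelagic (≥ 200 m) and bathypelagic (≥ 1000 m) are
derived from depth; the deep chlorophyll maximum cannot be, so DCM is an
explicit metadata flag that takes precedence. Depths in (5, 200) m without a
DCM flag fall into `OTHER`; `NET` (vertical profiles) is accepted only as an
explicit metadata value.

## Sequence similarity network

Two records are linked when they share a **gap-free identical segment**
covering at least `min_cov = 0.8` of *both* sequences. Design choices:

* **100% identity as longest common substring.** A local alignment with
  zero mismatches and zero indels is exactly a shared contiguous segment, so
  the edge statistic is the longest common substring (LCS), computed by
  vectorized dynamic programming. Reverse-complement matching is off
  (amplicons are orientation-normalized upstream).
* **Coverage boundary inclusive.** The operative definition of the cluster
  unit is "a minimum of 80% coverage", so the rule is `≥ 0.80`
  (configurable). A 320 bp exact prefix of a 400 bp sequence is an edge; a
  319 bp one is not.
* **Short-amplicon asymmetry.** When exactly one record of a pair comes
  from a dataset with systematically short amplicons (flagged
  `short_amplicon`), the coverage rule is applied to that record only, so a
  230 bp amplicon fully contained in a 430 bp one is linked even though the
  long side's coverage is ~0.53. When loading files, a dataset is flagged
  short when its longest sequence is ≤ 260 bp.
* **Exact prefilter.** All unordered pairs are evaluated; a shared-k-mer
  index (k = ⌈min_cov · L_min⌉, L_min the shortest sequence present) skips
  pairs that cannot contain a qualifying segment. Any qualifying pair shares
  a segment of at least k bp and hence a k-mer, so the prefilter provably
  never changes the edge set (also tested against exhaustive evaluation).
* An e-value style screen is not modelled: any segment passing the coverage
  rule on >200 bp sequences is far beyond such thresholds.

Connected components (CCs) of this graph are the analysis units; components
with fewer than 6 members (the number of integrated datasets) are removed.
When exactly one assigned genus occurs among members it is extrapolated to
the whole component; no assigned genus gives `"unknown"`, conflicting genera
give `"ambiguous"` (the conflicting case has no upstream convention; this is
the package's). Components are labelled `CC_<genus>_<n>` with numbering by
descending total abundance. Component order labels work the same way at the
order rank with the `"Unknown"` sentinel.

## Spatial patterns

* **Occurrence profiles.** A CC occupies a region (and a depth layer within
  it) when it has positive relative abundance in at least one sample there.
  Region combinations are counted as exact sets.
* **Depth-layer sharing.** For CCs exclusively shared between two regions,
  cell (ℓy, ℓx) holds the percentage present in layer ℓx of the first
  region and ℓy of the second; a CC occupying several layers contributes to
  several cells, so sums may exceed 100%.
* **Dissimilarity.** Bray–Curtis B = Σ|x−y| / Σ(x+y) on per-region
  composite vectors, transformed to the abundance-based Jaccard
  J = 2B/(1+B). Composites are the *mean* of normalized sample vectors per
  region, neutralizing very unequal sample counts (the aggregation was
  open; sums would weight regions by sampling effort). Cross-dataset
  comparisons are made at CC level — the same lineage sequenced by two
  projects is one component but two metabarcode rows, and row-level
  composites of regions covered by disjoint projects would be trivially
  disjoint. The abundance-based 2B/(1+B) form is used rather than
  presence/absence Jaccard because it is the formula the method prescribes.
* **RDA.** Y (samples × CCs, column-centered relative abundances; no
  Hellinger transform by default, flag available) is regressed on X
  (samples × 10 environmental variables, centered and standardized;
  complete-case rows). Fitted values Ŷ = X(XᵀX)⁻¹XᵀY are decomposed by SVD;
  constrained proportion = SS(Ŷ)/SS(Y); axis proportions from squared
  singular values. Under independence the constrained proportion has
  expectation q/(n−1), which the null simulation test checks.
* **Permutation ANOVA.** Pseudo-F = (SS(Ŷ)/q)/(SS(residual)/(n−q−1));
  unrestricted row permutation of Y; p = (1 + #{F* ≥ F}) / (1 + n_perm);
  default 999 permutations, seeded. Axis tests are sequential: the fit of
  earlier canonical axes is held fixed and the remainder's rows are
  permuted (the axis permutation scheme was open; this is the package's
  choice). At a numerically perfect fit the observed F is +∞ and p attains
  its minimum 1/(1+n_perm).
* **Forward selection.** Greedy: at each step the candidate adding the most
  constrained variance is admitted when its partial pseudo-F is significant
  at α = 0.05 under permutation of current-model residuals (Freedman–Lane
  style); collinear candidates add no variance and are never admitted.

## Temporal patterns

Analyses run per time-series site on the CC × date matrix.

* **Diversity.** Richness S (positive entries), Shannon H in nats,
  Pielou J = H/ln S (0 for S = 1). The literature phrase "reverse Pielou"
  has no standard definition; standard evenness is computed, with an option
  to emit 1 − J.
* **Escoufier equivalent vectors.** CCs present on fewer than 5 dates are
  excluded ("present at least 5 times" = 5 sampling dates with positive
  abundance). Greedy forward selection over CC columns maximizes at each
  step the RV coefficient
  RV(X, Y) = tr(XXᵀYYᵀ)/√(tr((XXᵀ)²)·tr((YYᵀ)²))
  between the growing subset and the full matrix (raw normalized
  abundances, column-centered). Cumulative RV is non-decreasing and reaches
  1 at full selection; the *selected* set is the shortest prefix reaching
  the cumulated correlation level, default 75% (100% would return the whole
  matrix). Ties break toward larger total abundance, then lexicographic id.
  Per-step greedy choices are tested against exhaustive candidate search.
* **Lomb–Scargle periodogram.** The classical normalized periodogram for
  unevenly sampled series: power at each frequency is the Lomb form with
  the τ phase correction (computed by `scipy.signal.lombscargle`), divided
  by the sample variance (ddof = 1), which makes PN invariant to affine
  transforms of the values. Frequency grid: 1/span to n/(2·span)
  (pseudo-Nyquist), oversampling factor 4. Peak p-value uses the
  extreme-value form p = 1 − (1 − e^(−PNmax))^M with M = 2·n_grid/ofac
  independent frequencies — the convention of the classical R
  implementation of this periodogram, slightly conservative under white
  noise (measured type-I rate at p < 0.01 is below but within three
  binomial standard errors of 1%). A series is **rhythmic** when
  PNmax > 10 (strictly), corresponding to p ≈ < 0.01. Preconditions: ≥ 8
  observations, nonzero variance.
* **Rhythmic indicators** are the intersection of the Escoufier-selected
  and rhythmic sets. **Seasonal prevalence** of a CC in a year is the
  number of meteorological northern-hemisphere seasons (DJF/MAM/JJA/SON,
  by month) with at least one positive observation. **Annual mean monthly
  abundance** averages within observed months first, then across months;
  unobserved months are excluded, never imputed.

## Synthetic corpus

The generator emulates, at desk scale, an integrated corpus of six
projects: two multi-depth surveys (tropical/subtropical and Mediterranean;
3 stations × SRF/DCM/MESO/BATHY each), one coastal project covering four
single-station regions (SRF + DCM), and three bimonthly coastal time series
(8 years × 24 dates; one Mediterranean site yields 230 bp short amplicons).
Default 40 planted groups of 6–10 members plus 5 decoy groups of size 1–5,
master sequences of 380–460 bp.

Guarantees are constructive, not probabilistic:

* **In-group edges.** Members are exact copies or prefixes of ≥ 0.8 of the
  master (short-amplicon members are 230 bp prefixes), so every member pair
  satisfies the edge rule — two prefixes of length ≥ 0.8L overlap in their
  common anchor and cover ≥ 0.8 of the longer one.
* **No cross-group edges.** Masters are re-drawn until no two share any
  k-mer of length ⌈0.8 · min length⌉, which upper-bounds every cross-group
  LCS below the edge requirement; the check runs at generation time.
* **Region occupancy.** Each group's region combination is drawn from a
  configurable distribution (dominated by the Mediterranean/Tropical pair,
  with endemics, other pairs, triples and a small ubiquitous fraction,
  mirroring the biogeography the pipeline is meant to resolve); every
  occupied region is guaranteed at least one positive sample, and no sample
  outside the combination is ever positive, so the planted combination
  histogram is recovered exactly by construction.
* **Rhythmicity.** A configurable fraction of time-series groups (default
  10%) receives sinusoidal series x(t) = a(1 + sin(2πt/P + φ)) + ε,
  ε ~ N(0, a/SNR), SNR = 2, with periods cycling through {182, 365, 548}
  days, truncated at 0; other groups receive stationary noise, a few are
  sparse (3 dates, below the occurrence cutoff). Rhythmic groups are the
  planted *dominant* set: the background noise scale is set per site so
  that, in the diagonal-dominant covariance approximation
  RV(j of k) ≈ √(j·c² / (k·c² + m)), the cumulated RV crosses the 75%
  level exactly after the k rhythmic columns. The planted
  rhythmic-indicator set is therefore the rhythmic set itself, and the
  recovery test demands exact equality per site.
* **Environment.** Temperature decays with depth from region-specific
  surface values (with a seasonal term at the surface), nutrients and
  silicate increase with depth, chlorophyll-a peaks at the DCM — enough
  depth/region structure for the RDA to latch onto.
* A few contaminant records (blocklisted taxa, sub-80% identity, ≤ 200 bp)
  exercise the harmonization filters and are absent downstream.

Everything is driven by one integer seed; outputs are byte-reproducible.

**What the synthetic corpus does not emulate:** PCR/sequencing error and
chimeras, phylogenetically realistic sequence divergence (masters are
independent random sequences, so there are no borderline near-miss pairs),
read-count noise (abundances are continuous), compositional coupling beyond
per-sample normalization, and missing-data patterns of real environmental
records. Passing the recovery tests shows the pipeline implements its own
definitions exactly; it does not show robustness to upstream artefacts that
the non-goals exclude.

## Numerical choices and degenerate inputs

* Normalization rejects all-zero samples by name; tables reject negatives,
  duplicates and missing values.
* `longest_common_substring` rejects empty strings; networks of one record
  are a single isolated node.
* RDA rejects n ≤ q+1, zero-variance predictors (named) and collinear
  predictors (named); forward selection tolerates collinearity instead.
* Permutation p-values always include the observed statistic
  (p ≥ 1/(1+n_perm)); permutation counts below 99 are rejected.
* The periodogram rejects constant series and series shorter than 8 points;
  p-values are clamped into (0, 1].
* Escoufier RV tie-breaks are deterministic (larger total abundance, then
  id); cumulative RV is clamped only by floating tolerance 1e-12 at the
  level comparison.

## Problem sizes

Default test and acceptance runs use the desk-scale corpus above
(~350 metabarcodes, ~640 samples), 100-instance oracle sweeps for the
network stage, 1000 white-noise series for periodogram calibration, and
199–999 permutations for the RDA tests. All sizes are configurable upward
through `SyntheticSpec` and the function parameters.
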