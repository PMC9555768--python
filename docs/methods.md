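# Methods

## Rescued-gene classification

**Model.** Each contrast is summarized per gene by a log2 fold change and a
posterior probability of differential expression (PP), as emitted by a
nonparametric DEG caller; rescuekit consumes these summaries and does not
perform DEG calling, normalization or batch correction. A gene is a DEG for
a contrast when `PP >= min_pp` and `|log2FC| >= log2(min_abs_fc)`; defaults
are `min_pp = 0.95` and `min_abs_fc = 1.2` (linear scale). Both cuts are
inclusive. Fold changes are held internally on the log2 scale so that sign
carries direction and up/down thresholds are symmetric; signed linear fold
changes are converted on input as `sign(fc) * log2(|fc|)`.

**Classification.** With signed DEG sets for the mutant contrast (up/down
relative to wild type) and the treatment contrast (up/down under
treatment), the shared genes partition into four disjoint categories:
rescued-up (mutant-up ∩ treatment-down), rescued-down (mutant-down ∩
treatment-up), further-up and further-down (same direction twice). Genes
tested in only one contrast are treated as non-DEG in the other and so
never enter the shared set — the intersection is over DEG lists, not
tables.

**Enrichment.** Overlap significance conditions on a single tested-gene
universe of size `N` shared by both contrasts (supplied explicitly;
mismatched set sizes larger than `N` are an error). The test statistic is
the inclusive upper tail `P(X >= q)` of the hypergeometric distribution,
computed as the survival function above `q − 1` (identical to R's
`phyper(q−1, m, N−m, k, lower.tail=FALSE)`). The overlap test uses the two
full DEG lists; each category test uses the two directional subsets it
intersects. The tail is symmetric in the two set sizes, a property the
suite asserts. Human-readable reports round p-values to two significant
figures; machine-readable output keeps full precision with every
`q/m/k/N` argument echoed for auditability.

## Spatial quantification

**Grid.** A 5-row × 4-column grid (20 bins) spans the gridded region,
anchored at the lateral-distal corner; rows run distal→proximal, columns
lateral→medial, and bins are numbered row-major from the anchor (bin 1).
The orientation and numbering are configuration — published figures do not
pin them down — so real data can be matched post hoc. Bins are half-open:
a point on an interior boundary belongs to the higher-index bin, a point
on the far outer edge to the last bin, so the closed region is covered
with no double counting. Points outside the region are tallied, never
silently dropped; the suite asserts `sum(bins) + overflow = n_points` on
random sections. Bin areas default to equal rectangles but accept per-bin
overrides, since in practice areas are measured on the image. Density is
`100 × count / area` (cells per 100 µm²).

**Statistical stack.** Embryos, not sections, are the independent unit:
sections are pooled within embryo, and the per-embryo density is the mean
per-section density (pooled counts over area × section count).

* χ² homogeneity on the 2 × 20 table of genotype-pooled bin counts, after
  dropping bins empty in both groups (degrees of freedom = non-degenerate
  bins − 1, no continuity correction); a warning fires when any expected
  count falls below 1. Counts, not densities, enter the table — with fixed
  areas they carry the same composition information.
* Per-bin unpaired one-tailed Student's *t*-tests on per-embryo densities,
  default alternative "non-reference genotype denser than reference"
  (density increases as gene dosage decreases); the 20 bins of one
  comparison form one Benjamini–Hochberg family. Degenerate zero-variance
  bins resolve to p = 0.5 (equal means) or 0/1 by sign rather than NaN.
* Numerosity: Kruskal–Wallis across genotypes on per-embryo totals, then
  pairwise one-tailed Mann–Whitney against the reference genotype — exact
  when both groups have ≤ 8 embryos and no ties, mid-rank asymptotic
  otherwise. All-tied inputs report p = 1 with a warning; groups of fewer
  than 2 embryos error (the numerosity stage of a full fit records the
  error and lets density reporting proceed).

**Heat maps.** Per genotype × segment, bin means across embryos are mapped
to color classes; the class index is the number of break points strictly
below the mean. Default breaks are the quartiles of the pooled bin means
(four balanced classes); breaks must be strictly increasing.

## Synthetic data

**DEG tables.** The generator plants categories (rescued-up/-down,
further-up/-down, single-contrast DEGs, null) at configured sizes over the
universe, then emits full per-gene tables: planted DEGs get
`|log2FC| = effect ± N(0, fc_noise_sd)` with the category's signs and
`PP = pp_de`; the rest get `log2FC ~ N(0, fc_noise_sd)`, `PP = pp_null`.
Defaults are the study-scale sizes (universe 14,488; 851/558 and 1862/2092
DEGs; overlaps 259/85/59/65) with `effect = 1.0`, `fc_noise_sd = 0.1`,
`pp_de = 0.99`, `pp_null = 0.1`. At these defaults the planted effect sits
about 7 noise standard deviations above the fold-change cut, so
classification recovers the planted truth essentially perfectly — the
generator validates plumbing and argument flow, not caller robustness. It
deliberately does not emulate correlated counts, library-size or batch
structure, or PP values estimated from data; conclusions about upstream
DEG calling are out of its reach.

**Section patterns.** Per section the cell total is Poisson with mean
`base_intensity × area / 100`, boosted by `anterior_boost` (default 1.3)
in anterior sections of untreated mutant genotypes — the direction, not
the magnitude, of the anterior numerosity increase is the modeled claim.
Defaults: 200 × 160 µm region, 8 anterior + 5 posterior sections, 5
embryos, `base_intensity = 0.5` cells/100 µm² (≈160 cells per section,
the order of magnitude countable by eye per section). The wild-type-like
process is homogeneous (`cluster_fraction = 0`). The mutant-like preset is
a Neyman–Scott process: a 0.6 share of cells placed as Gaussian offspring
(sd 10 µm) around 3 uniformly placed parents per section, the rest
uniform. The cluster process is a stand-in for the observed cell
condensation — no generative model is implied by the imaging data — and
its detectability is the test surface: the χ² comparison rejects the
clustered process against the homogeneous one essentially always at
α = 0.001 at these sizes, while two homogeneous groups reject at the
nominal 5%. Cluster offspring may fall outside the region; they land in
the overflow tally like any other outside point. Both generators are
deterministic given seed (the genotype label is folded into the stream so
genotypes differ under a shared seed).

## Numerical and design choices

* Threshold strictness: inclusive (≥) at both DEG cuts, following the
  operational description of the upstream analysis; both thresholds are
  exposed.
* The χ² construction (which contingency table) and the bin-index
  convention were genuinely open; the choices above are flagged in report
  metadata (`provenance.decisions`) so downstream users can audit them.
* Per-embryo (not per-section) replicates for the *t*-tests: sections from
  one embryo are not independent.
* Mann–Whitney ties: mid-rank with normal approximation when exact
  enumeration is infeasible.
* Reports embed tool version, seed and a config hash.

## Problem sizes used in the checked claims

Calibration and power claims in the suite use 5 embryos × 8 anterior
sections per group: type-I error of the χ² comparison over 1,000
replicate pairs of homogeneous groups (α = 0.05, binomial 95% interval),
power ≥ 90% at α = 0.001 over 500 replicates against the clustered
preset. Per-bin test power uses a +5 sd planted shift at n = 5 per group
over 500 simulations. Hypergeometric oracle equivalence is exhaustive for
universes up to 12.

## Limitations

* The spatial module quantifies given coordinates; it does not segment
  images or detect cells, and it does not reconstruct 3D structure across
  sections.
* The hypergeometric model assumes the two DEG lists are independent draws
  from the universe under the null; shared replicates between contrasts
  violate this in ways the test cannot see.
* Passing tests on the synthetic generators show the pipeline's arithmetic
  and statistics are correct at realistic sizes; they do not certify
  performance on real section data with anatomy-driven density gradients,
  which the homogeneous null does not emulate.
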