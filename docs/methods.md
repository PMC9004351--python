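# Methods

## The problem

Exocellular DNA — the fraction of seawater DNA passing a 0.1 µm filter —
comprises vesicle-enclosed, virus-encapsidated and free DNA. Two questions
drive the analyses here: *which organisms* contributed the DNA in each
fraction, and *from which water-column depth* it originated (mesopelagic
free DNA can be dominated by surface-derived sequences, implicating export
by sinking particles or migrating zooplankton). Inputs are per-sample gene
count tables from read mapping against a depth-resolved reference gene
catalog; read mapping itself, wet-lab separation and sequencing are out of
scope.

## Composition bookkeeping (`count_io`)

Counts are normalized by the total mapped count per sample; all downstream
math is on proportions. Domain-level composition uses the **all-counts
denominator**, so unannotated sequences (genes with no taxonomy, or genes
absent from the catalog — the two are not distinguished) appear as an
explicit "unknown" category and the five domain proportions sum to 1.
Family-level composition defaults to the **annotated-only denominator**
(proportions of family-annotated counts), matching how family percentages
are conventionally reported; the all-counts denominator is a switch. Tag
composition (ecotypes, viral known hosts) normalizes over counts carrying
any tag in the requested universe. "Major" taxa are those contributing
**strictly more than** 0.5 % in at least one sample; ties at the cutoff
are excluded, and the selection is monotone in the cutoff.

## Depth-of-origin attribution (`depth_origin`)

For gene *g* and depth *d*, `P[g,d] = cov[g,d] / Σ_d' cov[g,d']`. By
default each catalog depth **column is first renormalized to unit sum**, so
depths that happened to be sequenced more deeply do not dominate the
ratios; the switch `renormalize_depths=False` uses coverage as stored.
Sample-side weights are per-gene proportions (`use_proportions=False`
gives raw counts for linearity checks). Portions accumulate into
(depth × domain) cells over the five domains (bacteria, archaea,
eukaryote, virus, unknown). Genes with zero catalog coverage at every
depth, and sample genes absent from the catalog, go to an explicit
unassigned bucket, keyed by domain — conservation
(Σ cells + unassigned = sample total) holds to 1e-9 and is tested.

Attribution is linear in the input table and exactly recovers a generating
depth mixture when the catalog's genes are depth-exclusive. The converse
degeneracy is deliberate and surfaced: a depth-uniform catalog attributes
every sample to the uniform distribution regardless of true origin —
attribution sharpness is a property of the catalog, not the method.

Depth bins default to upper euphotic (0–75 m], DCM band (75–175 m], upper
mesopelagic (175–250 m], lower mesopelagic (250–1,000 m], deep (>1,000 m).
Intervals are contiguous and **right-closed**, so the canonical sampling
depths 75, 175, 250 and 1,000 m fall inside the zone that conventionally
bears their name and binning conserves mass; edges and names are
configuration. The euphotic-derived summary reports the 0–200 m share
both of depth-assigned mass and of the total including unassigned.

## Export flux (`export_flux`)

Particle flux attenuates as `F(z) = F_ref (z/z_ref)^(-b)` below the
reference depth; the model is undefined above `z_ref` and errors there.
Defaults: `z_ref = 175 m` (base of the euphotic zone at an oligotrophic
time-series site) and `b = 0.86` (canonical open-ocean attenuation); both,
like `F_ref` (µg DNA m⁻² d⁻¹), are configuration, never hard-coded claims —
`F_ref` must be supplied from export efficiency × production × DNA quota
for the site of interest. The areal flux is converted to a volumetric
daily supply by spreading it over a configurable remineralization layer
(default 100 m; the conversion areal→volumetric is otherwise
underdetermined) with 1 m³ = 1,000 L, and reported as percent of the
free-DNA standing stock per day. A steady state is assumed; there is no
time stepping and no mechanistic particle model. `sweep_parameters` brackets
the ratio over (F_ref, b) ranges, mirroring how printed ranges reflect
parameter uncertainty.

## Size spectra (`size_spectrum`)

Traces arrive sized in bp (75–50,000, vendor-software output) and
baseline-subtracted; a rolling-minimum baseline option exists for raw
traces. Normalization scales the trace to unit trapezoidal integral over
size. Band fractions are read off the cumulative integral with linear
interpolation at the band edges, so fractions over a partition sum to the
full-range value exactly (tested to 1e-6 over the standard partition
75/350/1,000/40,000/50,000 bp). The LMW/HMW boundary (1,000 bp) and the
HMW cap (40,000 bp) are constants with config overrides.

Peak detection runs on the **mass density per log10(bp)** (`rfu × size`):
CE sizing is approximately log-linear, and on this axis a log-symmetric
band peaks at its true center (on the per-bp axis the apex shifts left).
`scipy.signal.find_peaks` with prominence expressed as a fraction of the
maximum density finds apexes; widths at half prominence are mapped back to
the bp axis, and mass fractions are integrals between the flanking minima.
Width classes: distinct < 5,000 bp, broad > 10,000 bp, intermediate
between; thresholds and the width convention (half prominence) are
configurable. Peak count is non-increasing in the prominence threshold.

## Ordination (`ordination`)

Proportional composition tables are square-root transformed elementwise
(no renormalization), then Bray-Curtis dissimilarities
`Σ|xᵢ−yᵢ| / Σ(xᵢ+yᵢ)` are computed between samples. PERMANOVA uses
Anderson's distance-matrix formulation: `SS_total = Σ_{i<j} d²ᵢⱼ / N`,
within-group analogues per group, and
`F = (SS_among/(g−1)) / (SS_within/(N−g))`; the permutation p-value is
`(1 + #{F_perm ≥ F_obs}) / (1 + n_perm)` over whole-sample label
permutations from a seeded generator (minimum attainable `1/(n_perm+1)`;
degenerate all-equal matrices report p = 1). The null distribution is
evaluated with vectorized quadratic forms over stacked permutation
indicator matrices. Pairwise comparisons run PERMANOVA on every group
pair and Benjamini–Hochberg-adjust across all pairs (the family of tests
is the set of pairs). The pseudo-F is cross-checked in tests against both
an independent pure-python implementation (exhaustively, over all balanced
relabelings of a 6-sample matrix) and scikit-bio; BH against statsmodels.

NMDS delegates numerical optimization to scikit-learn's nonmetric SMACOF —
one start from the classical (metric) MDS solution plus seeded random
restarts — and reports Kruskal stress-1 computed via isotonic regression of
embedding distances on the input dissimilarities. The composition level
defaults to family (the level at which the fraction-vs-community contrasts
are most interpretable with the catalog's annotation fields).

## Synthetic data (`synthetic`)

The generator emulates the statistical structure the analysis assumes, at
desk scale:

* **Catalog** — each gene belongs to one taxon; taxon depth profiles are
  Dirichlet(α = 0.3) over a 16-depth grid (5–4,000 m), giving the patchy,
  depth-localized distributions that make attribution informative (α is
  configurable). A chosen fraction of genes is depth-exclusive (coverage
  at exactly one depth — identifiability markers), a chosen fraction
  unannotated (default 25 %, echoing the large unannotated portion of
  environmental libraries), and depth columns are normalized to unit sum.
  Taxon labels are drawn from a pool of plausible marine families with
  ecotype/host tags.
* **Samples** — expected coverage is the weight-mixture of catalog depth
  columns; realized counts are one multinomial draw at fixed sequencing
  effort (totals exactly `read_depth`), matching fixed-effort sampling
  rather than per-gene Poisson noise.
* **Electropherograms** — Gaussian peaks on the log10(bp) axis plus an
  exponential degradation smear, sampled at 2,000 log-spaced sizes; each
  component is renormalized to unit mass on the grid so band masses match
  the requested fractions up to discretization.

All randomness flows from one integer seed per call; no global state.
What the generator does **not** emulate: real taxon co-occurrence and
phylogenetic structure, depth-correlated gene content, mapping bias and
chimeric assignments, instrument baseline drift and sizing error. Passing
tests therefore demonstrate the correctness of the bookkeeping and the
identifiability behavior of the attribution — not field accuracy of any
published estimate. Real-study headline figures depend on deep-sequenced
ocean metagenomes and a supplementary flux parameterization whose exact
constants are not published in the main text, and are not reproduced here.

## Problem sizes and numerical choices

The test suite and acceptance script use: 100 random 50-gene catalogs for
conservation/oracle checks; 1,500–3,000-gene depth-exclusive catalogs at
read depth 10⁶ (10 seeds) for mixture recovery (tolerance: 3 binomial SD);
500 structureless 12-sample datasets × 999 permutations for PERMANOVA
type-I calibration (tolerance: 3 SE around α = 0.05); 2,000-point traces
with analytic Gaussian band masses (tolerance 0.02); and a 14-sample,
2,000-gene demo configuration for end-to-end determinism (fixed float
formatting makes reruns byte-identical). Comparisons to closed forms use
1e-12; conservation invariants 1e-9. These sizes were chosen to make
Monte-Carlo error small relative to the tolerances while keeping a full
run in seconds to minutes on one CPU.

## Known limitations

* Attribution assumes the catalog's per-depth coverage is an unbiased
  depth signature; systematic depth-dependent mapping bias would propagate
  directly into origin estimates.
* The export model is bookkeeping, not mechanism: no disaggregation
  kinetics, zooplankton transport or time dependence, and the
  areal-to-volumetric conversion is a single-layer approximation.
* Peak "width" conventions differ across instruments and software; only
  the half-prominence convention is implemented (configurable thresholds).
* PERMANOVA assumes exchangeable samples under the null; no strata or
  repeated-measures designs.
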