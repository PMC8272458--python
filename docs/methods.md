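# Methods

## The screening model

A 384-well plate carries three working well classes: active controls (AC),
in which the desired phenotype is maintained (doxycycline-driven reporter
colonies in the motivating assay); negative controls (NC), in which it is
allowed to collapse; and compound-treated wells. Each well is imaged in one
or more fields, objects are segmented, and the well is reduced to a feature
vector. The analysis asks, per well, "does this look like the AC or the NC
population?", and answers it with a Mahalanobis distance to a Gaussian
model of each control population.

The default plate geometry places 32 AC wells (columns 1 and 23), 32 NC
wells (columns 2 and 24) and 320 compound wells (columns 3–22). Outer
control columns are the common physical design; 32 wells per control also
keep the covariance fit well-conditioned relative to the default 10
selected features. The minimum accepted control count is 8 per role
(configurable).

## Feature catalog

Each object contributes 11 measures: area, circumference (perimeter),
diameter (2·√(area/π)), circularity (4πA/P², capped at 1.1 to absorb
rasterization error), anisometry (major/minor second-moment axis ratio,
≥ 1), compactness (convex-hull solidity — deliberately distinct from
circularity so the two names never alias one number), and five intensity
statistics (mean, median, total, max, min) over the object's pixels.

The well-level catalog is fixed and ordered:

* 11 measures × 9 statistics {mean, median, sum, sd, cv, min, max, p10,
  p90} = 99. SD is the sample (n−1) standard deviation; a single-object
  well defines sd = cv = 0 rather than NaN, so distances stay finite.
* 6 covariances of each shape measure with per-object mean intensity.
* 7 well scalars: object count, foreground area fraction, total foreground
  intensity, background mean and SD, mean nearest-neighbour centroid
  distance (computed within each field, since fields have separate
  coordinate frames), and the fraction of objects brighter than background
  mean + 3 SD.

Total: 112. The acquisition software of the original assay does not publish
its feature list; this catalog is a reconstruction constrained to the named
measure families and the stated total, and is overridable per run. Wells
with no segmented objects are imputed to an all-zero vector with a
`no_objects` flag instead of being dropped — cell-death wells must remain
scoreable as NC-like. Objects of a well's fields are pooled before
aggregation (pooling-first is a design choice; per-field aggregation then
averaging is the plausible alternative).

Segmentation is Otsu thresholding per field with a minimum object area of
10 px². On an object-free field, Otsu would bisect the background noise,
so a guard declares the field empty when the threshold fails to clear the
robust background level (median + 3·1.4826·MAD). This costs nothing on real
fields, where foreground is far above that line.

## Z′-factor, selection, scoring

Z′ = 1 − 3(σ₊+σ₋)/|μ₊−μ₋| with sample SDs; it is symmetric, ≤ 1, equals 1
only in the noiseless limit, and is undefined (raised as a degenerate-
separation error) when the means coincide. Constant features are excluded
as degenerate. Selection keeps features with Z′ ≥ 0 (floor), ranked
descending, ties broken by catalog order, truncated to 10. The small cap
keeps the control covariance estimable from 32 wells; in practice a
combination of size and intensity features carries the assay window.

Control models are fit per plate (plate-to-plate intensity drift makes a
pooled model risky), on features z-scaled by the pooled-control mean/SD of
that plate. Scaling is mathematically irrelevant at λ = 0 — the Mahalanobis
distance is affine invariant — and numerically safer; it does affect λ > 0
results, which is documented behaviour. The shrinkage target is the scaled
identity, Σ = (1−λ)S + λ·tr(S)/d·I with λ = 0.1 by default; its smallest
eigenvalue is bounded below by λ·tr(S)/d, so the model stays positive
definite even when wells ≤ features. Distances are computed by Cholesky
solve, never by explicit inversion.

Plate QC is the Z′ between AC and NC wells' MHD-to-AC values; plates below
the QC floor (default 0.4) are flagged and excluded from hit calling.

## Triage and hit rule

Triage assigns exactly one class per well: **dead** if the object count is
below 5 (only when an imaging-derived count exists); **disparate** if the
well is far from *both* controls (MHD-to-AC above the NC wells' 95th
percentile *and* MHD-to-NC above the AC wells' 95th percentile); else
**ac_like**/**nc_like** by whichever model is nearer. The Q95 quantiles and
the count floor are pragmatic constants, surfaced in the run summary.

The hit rule: per replicate, a compound passes when its MHD-to-AC is
strictly more than `k_sd` = 1 SD *below* the mean of the NC wells'
MHD-to-AC. A final hit must pass in every replicate (logical AND across the
duplicate runs) and, when triage is available, be triaged ac_like in every
replicate. The opposite reading of the 1-SD threshold (MHD-to-NC more than
1 SD above the NC self-distance) is available behind `rule="nc_distance"`
but is not the default. Under the null (no actives), the duplicate 1-SD
rule alone admits ≈ P(Z<−1)² ≈ 2.5% of compound wells; the ac_like gate
then removes essentially all of these in practice, because a well drawn
from the NC population that drifts 1 SD toward the AC model is still far
closer to the NC model.

Dose validation declares a compound validated when at least `m` = 2
consecutive concentrations of the 8-point range pass in both replicates at
the same concentrations (replicate-wise AND, then longest run). The
criterion is a package definition — "validated" has no published
mathematical form — and is echoed into reports. When one screen is run at
two concentrations, each concentration is hit-called separately and the
lists are unioned.

## Synthetic screen generator

The generator defines the study conditions; its defaults are fixed
documented constants, not tuning knobs.

**Image path.** Objects are additive anisotropic 2-D Gaussian blobs with
random orientation over Gaussian background noise (no Poisson shot noise —
segmentation robustness is not the point of this package), clipped to
16 bits. AC wells: Poisson mean 25 objects, log-normal radius around 9 px,
peak intensity 3200 over a 400 ± 25 background (≈ 8× background); NC wells:
mean 4 objects, radius ≈ 3.5 px, intensity 900, higher eccentricity.
Centers are rejection-sampled to avoid overlap (dense wells may still
overlap after 100 attempts). Planted actives interpolate every parameter
from NC toward AC by `active_effect`; a `dimmer_active_fraction` (default
0.25) of actives instead get 15% larger radii and 60% of the
above-background intensity — the "larger but dimmer" phenotype real screens
produce. Pixel size, bit depth and object scale are stated constants, not
inferences from any instrument. Default 4 fields per well, 256 px fields.

**Feature-space path.** Wells are drawn from multivariate normals in
standardized units (NC mean 0, SD 1). Twelve strongly separating features
(colony count/size/brightness summaries) sit `control_separation` SDs from
NC in AC wells and are mutually correlated at ρ = 0.5 — real size and
intensity summaries of the same well are strongly correlated — while 24
moderate features move by 0.3× that at ρ = 0.3, and the remaining 76 are
independent noise. Actives are drawn at mean μ_N + effect·(μ_A−μ_N) with
the AC covariance; dim actives scale the size components by 1.1 and the
intensity components by 0.6. Duplicate plates share one truth assignment
and draw independent noise.

`control_separation` = 11.0 was calibrated once, by a grid scan of the full
select→fit→score pipeline, so that the default screen's mean plate QC lands
at Z′ ≈ 0.63 (per-plate SD ≈ 0.05) — the performance band of a
well-behaved real screen — and was not revisited. At that separation each
strong feature individually shows Z′ ≈ 0.45, consistent with per-feature
windows being "acceptable" while the multivariate score does better.

**What passing tests do and do not show.** The generator emulates the
*statistical* structure the analysis assumes: separated control
populations, correlated informative features, duplicate structure, planted
effects. It does not emulate illumination gradients, well-edge effects,
colony texture, plate drift or batch effects, so recovery results here
bound what the method can do on clean data, not what it will do on any
particular instrument's output.

## Problem sizes and numerics

Simulation-backed checks use 10 plates for the QC band and 20 seeded
screens (two replicates of 384 wells each) for null-specificity and
recovery properties — enough for three-binomial-SD comparisons while
keeping the full suite around ten seconds. Mahalanobis oracle equivalence
is checked to 1e−8 against explicit inversion at d ≤ 5; Z′ arithmetic to
1e−12. Degenerate inputs (constant features, equal control means, singular
covariance at λ = 0, empty wells, blank images) raise typed errors or take
documented imputations rather than propagating NaN.

## Known limitations

No robust (median/MAD) Z′ variant, no B-score or spatial-artifact
correction, no dose–response curve fitting, no illumination correction, no
sub-colony segmentation. The 112-feature catalog is a reconstruction: only
its cardinality and measure families are externally constrained. Whether
wells should be scored per field rather than pooled, and whether features
should be standardized before distance computation, are open choices in the
underlying method; this package pools fields and standardizes, and records
both decisions here.
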