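# Methods

This note documents the models and procedures the package implements, the
defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the numerical decisions a user auditing results
should know about.

## Distances

**Gower dissimilarity.** For species *i*, *j* and trait *k*, the
contribution is |x_ik − x_jk| / range_k for continuous traits, the same on
average ranks (ties averaged) for ordinal traits, and a 0/1 mismatch for
nominal and binary traits. The distance is the mean contribution over the
traits observed in *both* species (pairwise deletion with renormalization),
so species with missing values stay usable. A trait with zero observed
range has an undefined contribution and is dropped with a warning; a pair
of species sharing no observed trait is an error naming the pair. Results
lie in [0, 1].

**PCoA (classical metric scaling).** The squared-distance matrix is
double-centered (−½ J D² J) and eigendecomposed. Gower matrices are
generally non-Euclidean, so negative eigenvalues are expected; they are
never retained, and a warning reports how many occurred. No correction is
applied by default — the retained positive axes are used as the functional
space — but Lingoes (constant added to squared off-diagonal distances) and
Cailliez (constant added to off-diagonal distances, from the standard
2n × 2n eigenproblem) corrections are available. Axis retention defaults to
the smallest set of positive-eigenvalue axes whose relative eigenvalues
(shares of the positive mass) sum to ≥ 0.80; a fixed axis count is also
accepted. The embedding is implemented directly with `scipy.linalg.eigh`
for speed — it is called once per site inside the evenness and scan loops —
and is cross-checked against scikit-bio's PCoA in the test suite.

**FDist** is the Euclidean distance on the retained axes. When the input
distances are themselves Euclidean and all axes are kept, this reproduces
them exactly (a test asserts it to 1e-8).

**PDist** is the patristic distance: the sum of branch lengths along the
tip-to-tip path, computed in one postorder pass and checked against a
brute-force path-summing oracle.

**FPDist(a).** Both matrices are rescaled by their maximum entry, then
combined entrywise as (a·P′^p + (1−a)·F′^p)^(1/p). Defaults p = 2 and
max-rescaling follow the published construction of functional–phylogenetic
distances; both are exposed as configuration. Endpoints are exact: a = 0
returns rescaled FDist, a = 1 rescaled PDist. For a fixed pair the blend is
monotone in *a* toward whichever component is larger (property-tested).

## Null models and SES

The default **frequency** algorithm permutes each species' column of
presences across sites independently, preserving every species' occurrence
frequency exactly. Two alternatives are provided: **richness** (each site's
row permuted across species, preserving site richness) and
**independentswap** (checkerboard swaps preserving both margins). The
randomization stream is a pure function of the `NullSpec` seed, so the
a-scan and the envelope rebuild the *same* randomized matrices at every
grid value — adjusted-R² differences across *a* then reflect the weight,
not Monte-Carlo noise.

SES uses the sample (n−1) standard deviation of the null distribution; a
site whose null SD is zero (up to float accumulation noise) is flagged
undefined and excluded from regressions. The two-tailed p is
2·min(q, 1−q) for the mid-rank quantile q, clipped to (0, 1]. Default
iteration counts: 999 for SES, 1000 for envelope curves. The significance
threshold for calling a site clustered/dispersed defaults to |SES| > 1.96
and is recorded in the run report.

Two properties of this classical SES machinery are worth knowing:

- **Mild anti-conservatism of the z-threshold.** The null MFPD
  distribution is not exactly normal, so |SES| > 1.96 rejects slightly
  more than 5% of truly neutral sites (≈ 6–8% in our calibration
  simulations, with run-to-run variation because all sites share one
  randomization stream). The rank-based p-value in the SES table is better
  calibrated; the z-threshold is kept as the conventional display rule.
- **Frequency nulls are conservative for shared processes.** When *every*
  site is shaped by the same process, the process signature moves into the
  occurrence frequencies themselves, and a null that preserves those
  frequencies absorbs much of it (in our simulations, limiting-similarity
  communities score mean SES ≈ +0.1 under the frequency null versus ≈ +1.2
  under the richness null at identical strengths). The frequency algorithm
  remains the pipeline default; the richness null is the appropriate
  choice when the design makes frequencies themselves informative, and the
  validation scenarios for direction recovery use it for exactly that
  reason.

## Evenness (FPDve / COMP)

FEve builds the Euclidean minimum spanning tree over the species of a site
embedded (by site-level PCoA of the site's own FPDist submatrix, same
retention rule) in functional–phylogenetic space. Each edge (i, j) gets
EW = dist/(w_i + w_j); with partial weights PEW = EW/ΣEW and S species,

    FEve = ( Σ min(PEW, 1/(S−1)) − 1/(S−1) ) / ( 1 − 1/(S−1) ).

Presence/absence data imply equal weights w_i = 1/S. Sites with fewer than
3 species, or with all-coincident points, are flagged undefined. MST ties
are broken deterministically (species presented in a fixed order; scipy's
MST is deterministic for a fixed input). The implementation is checked
exactly against a naive Prim's-algorithm oracle.

## Inference

**Collinearity screen.** Spearman correlations (average ranks on ties)
among covariates; pairs with |ρ| ≥ 0.7 (configurable) are flagged and the
member with more high-correlation partners (ties: larger mean |ρ|) is
proposed for removal. The model front applies the proposals automatically;
the CLI records them in the run report.

**a-scan.** For each grid value (default 0 to 1, step 0.01): build
FPDist(a), compute SES.MFPD against the shared null stream and FPDve
(COMP), drop flagged sites, and fit OLS of SES on all screened covariates
plus COMP. a* is the argmax of adjusted R². A degenerate single-point grid
returns that point.

**Selection and importance.** Backward elimination removes the covariate
with the largest p-value while any exceeds α = 0.05 (intercept never
removed; full trace kept). LMG relative importance is computed by the
subset-averaging identity — weights s!(k−1−s)!/k! over all subsets not
containing the focal covariate — which equals the average sequential R²
increment over all k! orderings (verified against explicit enumeration);
shares sum to the full model's R² and are also reported as percents of R².

**Moran's I** uses haversine great-circle distances (radius 6,378,137 m),
inverse-distance weights without row standardization, expectation
−1/(n−1), and the variance under the normality assumption with a
two-tailed normal p. Coincident coordinates are an error (jitter or
exclude); constant values give an undefined statistic.

## Envelope diagnostics

For each site and grid value, observed MFPD is drawn over the null
quantiles (0.025/0.975, 0.25/0.75, 0.495/0.505) of the same 1000-matrix
stream. Classification windows are a ∈ [0, 0.25] (functional end) and
a ∈ [0.75, 1] (phylogenetic end); an end is "significant" when at least
80% (configurable) of its grid points fall outside the 95% band. The four
labels: significant at both ends (traits matched and conserved), low end
only (traits matched, weak signal), high end only (conserved driver not
among measured traits), neither (random). Plotting is a thin optional
layer; classification consumes only stored numbers.

## Synthetic data

The generator emulates the shape of a riverine bird survey: a birth–death
phylogeny over a species pool (default 105 species; GSA conditioning so
terminal branches are strictly positive), mixed continuous/nominal traits
with Pagel-λ signal (MVN with covariance σ²·C(λ); nominal traits from
tertile-discretized liabilities), per-site assemblages of 23–55 species by
default, and six covariates named for the field's usual suspects (TEMP,
PREC, NDVI, NPP, HII, ALT) plus site coordinates. A master seed fans out
to stage-specific child seeds, so bundles are byte-reproducible.

Assembly processes: **filtering** samples species without replacement with
Gaussian weight exp(−‖x − optimum‖²/2σ²) in the driver space, with σ =
(rms driver spread)/strength; **limiting similarity** seeds randomly and
adds the candidate maximizing nearest-neighbor distance, acting greedily
with probability 1 − e^(−strength) per step; **neutral** draws uniformly.
Filtering sites sit on a one-sided optimum gradient (distance from the
pool centroid, mirrored in the ALT covariate): a one-sided gradient keeps
the optimum's effect on SES monotone, so a linear regression can absorb
it — with a two-sided gradient the effect is V-shaped and drowns the
signal of interest. The HII covariate equals per-site strength plus noise
at sites of the coupled process.

Four driver options control *what* filtering acts on: the first measured
trait (`measured`), all measured continuous traits (`measured_all`),
hidden λ = 1 Brownian traits not included in the trait table
(`unmeasured_conserved`), or patristic proximity to a site-specific focal
lineage (`phylogeny`) — the limiting case of a perfectly conserved
unmeasured niche.

What the generator does **not** emulate: spatially explicit dispersal,
abundance dynamics, detection error, trait measurement error, and
covariate collinearity structures beyond what the user injects. Passing
tests therefore demonstrate that the pipeline recovers known structure
under its own assumptions, not that those assumptions hold in any
particular field system.

## Validation scenarios and their design

`fpdiv.scenarios` freezes four configurations used by the test suite and
the acceptance script:

- **Neutral calibration**: 200 neutral sites over a 100-species pool, 999
  frequency nulls; mean SES should be near 0 with ≈ 5% of |SES| > 1.96.
- **Direction recovery**: 20 replicate single-process studies (20 sites,
  pool 100, richness 8–15, strengths 4–6); filtering should give mean
  SES ≤ −1, limiting similarity ≥ +1, under the richness null (see above
  for why the frequency null is conservative in this design).
- **Weight recovery**: 80 sites, pool 150, richness 15–30, all sites
  filtering with strength 1–6 coupled to HII, and **12** measured λ = 0
  continuous traits. The trait-driven variant filters on all 12 measured
  traits (median a* should be ≤ 0.3 over 20 replicate scans at a-step
  0.05 with 199 nulls); the phylogeny-driven variant filters on patristic
  proximity (`phylogeny` driver; median a* ≥ 0.7).

Two design choices here came out of explicit failure analysis. First, a
λ = 1 Brownian hidden trait correlates with patristic distance only weakly
(ρ ≈ 0.2–0.45 per tree realization), so MPD-level phylogenetic clustering
built from it is unreliable; the patristic-kernel driver is used as the
clean limiting case of a conserved niche. Second, SES and the evenness
covariate COMP are computed from the same distances on the same
composition, so in a low-dimensional trait space they share sampling
noise, which inflates adjusted R² at the functional end of the scan; a
12-trait measured space averages that shared noise away and leaves the
scan profile signal-dominated. Problem sizes throughout (replicate counts,
null counts, the 0.05 scan step) are the scenarios' definitions, chosen to
keep a full validation run to a few minutes on one CPU.

## Known limitations

- The argmax over a flat adjusted-R² profile is sensitive to noise; the
  scan result object exposes the whole profile so users can judge the
  plateau rather than trusting a* alone.
- Max-rescaling makes the blend's effective mixing nonlinear in *a*: the
  component with the larger dispersion of rescaled entries dominates
  interior weights, so a* is not interpretable as a variance share.
- Abundance weighting (for MPD and FEve) is out of scope: the pipeline is
  built for presence/absence matrices.
- The independent-swap null uses simple checkerboard trial swaps with a
  fixed thinning count; for matrices with very constrained margins its
  mixing may be slow.
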