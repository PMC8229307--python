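# Methods

This note documents the statistical models, conventions and design choices
behind `saltscape`, in the spirit of a package vignette: what is computed,
under which assumptions, and what the synthetic experiments do and do not
demonstrate.

## Intake estimation and cohort filtering

FFQ-estimated sodium is calibrated with sex-specific affine equations
validated against 24-h urine collections, expressed on the salt scale and
converted to sodium with 1 g Na = 2.54 g NaCl:

    men:    Na = (8.2  + 0.38 · ffq_na) / 2.54      [g/day]
    women:  Na = (4.55 + 0.67 · ffq_na) / 2.54

The Na:K ratio is the exact quotient of calibrated Na over K (both g/day).
Note the equations impose hard floors (3.23 g/day for men, 1.79 for women
at zero FFQ sodium); the synthetic generator respects them when inverting.

Exclusion filters run in a fixed order (outside region; age; missing civil
status, occupation, education, nationality, intakes, zone income; extreme
energy) and attribute each excluded participant to the *first* failing
rule, so per-rule counts are reproducible; the retained set itself is
order-invariant. Conventions pinned by tests, chosen where the inequality
direction was not stated: age bounds **inclusive** (20 and 74 retained),
energy bounds **strict** (exactly 850 or 4500 kcal retained). Region
membership is point-in-rectangle for synthetic regions; a `region_test`
callable hook accepts arbitrary polygon tests.

## Food-environment accessibility

Outlet density per participant and category is

    D = Σ_outlets max(0, 1 − d_network / 800 m),

a linear decay kernel over street-network shortest-path distance, the
standard "gravity within walking distance" accessibility measure. Both
participants and outlets snap to the nearest network **node** within 50 m;
with the synthetic 70 m street grid the node-vs-segment positional error is
bounded by half an edge (35 m). Edge-interpolated snapping is left as a
hook (`snap_fn` would slot into `outlet_density`); the decay is measured
from the snapped node, not including the snap distance itself. Points
farther than 50 m from the network are flagged and get missing densities;
the pipeline drops them with a manifest count. Outlet listings are matched
to each participant's survey year by nearest available listing year
(2003–2018 without 2006/2007), ties broken toward the earlier year so no
future environment leaks backward. Zone median income uses the covered
years 2005–2016, with earlier surveys mapped to 2005 and later ones to 2016.

## Spatial weights and Moran statistics

Weights are binary within a fixed distance band (Euclidean `d ≤ threshold`,
inclusive — pinned by a test at the exact boundary), row-standardized by
default. Islands (no neighbor in band) keep an all-zero row, stay in `n`,
and are reported; LISA classes them not-significant by definition.

Global Moran's I uses the standard cross-product form; inference is by
random value permutation. The pseudo p-value counts permuted statistics
whose deviation from the permutation mean is at least the observed
deviation in magnitude, plus one, over R+1. This magnitude rule keeps the
null p super-uniform (P(p ≤ t) ≤ t + 1/(R+1)), which the suite verifies on
spatially random cohorts; a direction-picked one-sided rule would double
the type-I rate. The z-score is (I − mean_perm)/sd_perm.

Local Moran's I standardizes with the population (divide-by-n) SD — pinned
because then `Σᵢ Iᵢ / S0` equals the global statistic exactly, which a test
asserts to 1e-10. Inference is **conditional** permutation: observation i
is held fixed and the other n−1 values are permuted into its neighbor
slots (a shared bank of R permutations serves all observations). Cluster
quadrants come from the signs of zᵢ and its spatial lag, with `≥ 0`
counting as "high" (pinned). No multiplicity correction is applied by
default, matching common LISA practice; `fdr=True` switches to a
Benjamini-Hochberg cut. Map output uses the integer coding 1=HH, 2=LH,
3=LL, 4=HL, 0=not significant.

Scale selection evaluates global Moran's I at incremental bands (default
200–1000 m in 200 m steps) and picks the band with the largest z-score
among those significant at α; if none is significant a configurable
fallback band is used and the applied rule is recorded.

## Regression models

Model 1 = food-environment densities; model 2 = socio-demographics + zone
income; model 3 = union; all plus total energy and survey year. Dummy
reference levels: male, not married/cohabiting, low occupation, primary
education, non-Swiss. Column order is fixed and tested against a
hand-coded matrix.

OLS is fitted via statsmodels behind the package surface; reported
AICc = AIC + 2k(k+1)/(n−k−1) with the Gaussian likelihood and k = number of
design columns (intercept included).

GWR solves a weighted least-squares problem at every observation location
with the fixed Gaussian kernel `exp(−½(d/b)²)`. The hat diagonal is
accumulated exactly (`Sᵢᵢ = xᵢᵀ(XᵀWᵢX)⁻¹XᵀWᵢeᵢ`), and

    AICc = 2n·ln(σ̂) + n·ln(2π) + n(n + tr(S))/(n − 2 − tr(S)),  σ̂² = RSS/n.

Local standard errors use `σ̂² diag(CCᵀ)` with `C = (XᵀWX)⁻¹XᵀW` and the
global `σ̂² = RSS/(n − tr S)`; local t-values are reported unadjusted for
dependent hypotheses (an adjustment flag could be added, but surfaces are
meant for exploratory mapping). Bandwidth is chosen by golden-section
search on AICc to 1 m, over [2× mean nearest-neighbor distance, region
diagonal] by default — the lower bound keeps every local system
well-conditioned. A detectably non-unimodal AICc trace triggers a warning
and the global minimum over evaluations is returned. Covariates enter on
their raw scales. Fits are O(n²) in memory (dense distance matrix) and are
intended for cohorts up to a few thousand points.

## Cluster characterization

High-high vs low-low members are contrasted with Welch's unequal-variance
t-test (continuous) and Fisher's exact test (binary; two-sided by the
standard sum-of-less-probable-tables definition), multi-level categoricals
expanded into per-level indicators. Radar tables standardize each group
summary against the **full cohort** mean and population SD (pooled-cluster
standardization would exaggerate contrasts when clusters are small); stars
mark p < 0.05. Both tests run through scipy behind the package surface and
are cross-checked in the suite against a hand Welch formula and an
exhaustive hypergeometric enumeration.

## Synthetic study region

The generator emulates the *structure* of an urban population nutrition
survey, not any real geography:

- 9.8 × 9.8 km region; 70 m grid street network, so every interior address
  is within the 50 m snap cap (half cell diagonal ≈ 49.5 m); 500 m square
  zones for the income join.
- 1000 participants by default, 60% placed in a 2.5 km urban core;
  outlets (20 supermarkets, 55 groceries, 140 convenience stores) 75%
  urban-concentrated and replicated across all listing years (no turnover),
  yielding mean 800 m densities of ≈0.3/0.6/1.8 — the magnitude order of
  published walkable-density tables.
- Socio-demographic composition varies smoothly in space through a latent
  neighborhood score (urban-core offset plus a 1.2 km-range Gaussian
  process simulated on a coarse 500 m lattice): tertiary education and
  younger age concentrate where the score is high (downtown), Swiss
  nationality and married status where it is low. Marginals stay near
  typical survey tables (50% women, ~70% Swiss, ~40% tertiary, mean age
  ≈50, mean energy 2300 kcal).
- Outcomes: `intake = baseline + covariate effects + field loading · GP +
  Gaussian noise` with baselines 3.7 (Na) and 2.7 (K) g/day, defaults for
  the effects carrying the usual signs (women and older adults more K;
  Swiss nationality more Na:K; tertiary education more K; supermarket
  access slightly more K). Noise is Gaussian by default — real intake
  distributions are right-skewed; this is a simplification, flagged, that
  the rank-based spatial statistics are insensitive to. FFQ sodium is
  derived by inverting the calibration equations (with the sex-specific
  floors), so the downstream pipeline reproduces the planted effects after
  calibration.
- The latent field uses the J-Bessel ("wave"/hole-effect) correlation
  `corr(d) = J0(1.8412·d/R)`. Two reasons. First, it makes the stated
  range R *operational*: for distance-band weights the idealized Moran
  z-profile is ∝ J1(κd), maximized at κd = 1.8412, so parametrizing
  κ = 1.8412/R places the detectability peak of the incremental-band
  analysis exactly at R — with monotone kernels (exponential,
  squared-exponential) the profile is nearly flat between 0.75R and 1.25R
  and the selected band is close to arbitrary. Second, its weak negative
  lobe beyond 1.306R (alternating patches) is a recognized covariance
  family in geostatistics. Simulation is dense Cholesky (documented O(n³),
  fine to a few thousand points); covariance fidelity is tested by
  Monte-Carlo against the closed form at n = 2.
- Field loadings default to 0.6 (Na) and −0.15 (K) times the 0.3 g/day
  field SD. The asymmetry mirrors the qualitative finding this class of
  study reports: potassium's spatial clustering is largely *explainable*
  by socio-demographic composition (adjustment dissolves it), while part
  of the sodium surface stays unexplained. The design condition for that
  behavior — the composition-driven spatial variance times the noise
  variance must exceed the unexplained-field variance times the
  non-spatial covariate variance — guided these defaults.
- Missingness knockout per field (education 1.1%, occupation 0.7%, etc.)
  mirrors well-run survey rates; with the default energy distribution and
  filters, ≈92% of a simulated cohort is retained.
- `plant_cluster` shifts an outcome by δ inside a disk and records the
  membership in the `truth` table (sodium shifts applied through the
  inverse calibration).

**What the synthetic experiments show** — that the estimators are
numerically correct (oracle equivalence), honestly calibrated under the
null, and able to recover planted structure (clusters, scales, coefficient
surfaces) under realistic sizes and noise. **What they do not show** — 
anything about real intake geography: the generator has no skewed intake
distributions, no reporting bias, no irregular street topology or
administrative boundaries, and its composition gradients are stylized.

## Pipeline and reproducibility

`pipeline.run` chains the stages for each outcome and writes CSV/GeoJSON
outputs plus a YAML manifest recording versions, the full configuration
and per-stage counts (retained n, islands, class counts, AICc, bandwidth).
All randomness flows from one root seed through deterministic per-stage
child seeds (CRC-based, so independent of Python hash randomization); the
suite asserts byte-identical outputs across repeated runs. A failing stage
aborts with the stage name, records the error in the manifest, and leaves
a `STALE` marker so partial outputs are never mistaken for results.

Problem sizes used by the acceptance experiments (cohorts of 1000, 100
null replicates at n = 500 with 199 permutations, 50 scale-recovery runs
with 999 permutations, 5-cohort residual-attenuation aggregate) were chosen
to give stable Monte-Carlo margins at desk scale; rates reported by
`scripts/acceptance.py` are computed fresh at run time from `--seed`.
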