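# Methods notes

## The estimation problem

A fine-scale acoustic positioning array yields, per tagged fish, a sequence
of solved fixes (x, y in planar meters; depth in meters from a pressure
sensor; a unitless hyperbolic positioning error, HPE) at irregular
intervals of a few hundred seconds. The package estimates, per fish-day,
the volume of lake habitat used under three constructions — time-geography
potential path volumes (PPV), full-water-column 2D kernel utilization
distributions (KUD), and depth-aware 3D KUDs — and compares methods,
seasons, and parameterizations with mixed-effects models.

## Preprocessing

Positions are removed when (i) they fall outside the shoreline or in a
no-data bathymetry cell, (ii) their depth exceeds the local lake depth plus
a 2 m buffer (sensor/solver artifacts), or (iii) HPE > 20. Each rejection
is tallied under the first failing rule in that order; the order affects
tallies only, never the kept set, and filtering is idempotent. Consecutive
fixes of one fish within one UTC calendar day (a configurable fixed offset
can move the day boundary) form path segments; duplicate timestamps keep
the first fix. Segments whose time interval exceeds 1080 s — three times
the nominal few-minute transmission cadence — are omitted entirely, i.e.
treated as contributing 0 m³, which deliberately under- rather than
over-estimates daily volume. Fish-days with no retained segment produce no
record (not a zero).

Seasons follow surface temperature and ice phenology: winter is ice-on to
ice-off; spring runs from ice-off until the daily mean surface (<6 m)
temperature first strictly exceeds 15 °C; summer until it first falls back
strictly below 15 °C; fall until ice-on. First crossings are taken as-is,
with no smoothing window — with noisy series near the threshold a smoothing
rule would shift boundaries by a few days.

## The voxel lattice and movement metric

The grid spans the bathymetry bounding box with horizontal voxel side
L (default 20 m) and vertical side L/rescale (rescale = 100, so 0.2 m): in
the depth-stretched coordinate system every voxel is a cube of side L. A
voxel belongs to the lake mask iff its horizontal center lies inside the
shoreline and its center depth does not exceed the local lake depth; mask
and grid geometry are fixed once per study area. V_voxel = L²·(L/rescale):
1.25, 10, and 80 m³ for L = 5, 10, 20.

One design question is genuinely open: in which metric do the observed
segment speed, the swim-speed parameter, and the ellipsoid live? This
package computes **all movement geometry in real meters**. The swim-speed
parameter is a quantile of daily movement rates measured in real m/s, so
comparing it against a depth-stretched v_obs (where a 1 m depth change
counts as 100 m) would flag essentially every segment as degenerate, hand
every segment the enlarged adjustment budget, and inflate daily volumes to
an implausible half of the lake. With the real-space metric the degeneracy
adjustment fires only for genuinely fast segments, and daily volumes come
out at ~1% of lake volume — the scale a benthivore in a small lake
plausibly uses. The vertical rescale keeps two roles: it sets the thin
vertical voxel size (so the narrow depth band a benthic fish occupies is
resolved) and it makes the vertical kernel scale commensurate with the
horizontal one in the 3D KUD.

## PPV computation

Per segment, the speed budget is v_swim, replaced by
1.01·v_obs + (v_obs − v_swim) whenever v_obs ≥ v_swim (this guarantees a
budget strictly above v_obs, hence a non-degenerate spheroid). A voxel is
included iff its center satisfies the inclusive inequality
|c − p₁| + |c − p₂| ≤ v·Δt; center-in/out is the discretization rule, ties
are deterministic, and out-of-lake portions are simply clipped by the mask.
The implementation scans only the spheroid's bounding box; tests assert
exact equality with a full-grid scan.

A consequence worth knowing: because the adjusted budget *decreases* in
v_swim on the degenerate branch (2.01·v_obs − v_swim) and jumps down at
v_swim = v_obs, daily habitat volume is **not** globally monotone in
v_swim. It is monotone where v_swim acts as a pure budget (v_swim above all
observed segment speeds of the day), and the tests pin both facts. In
practice the v_swim quantile ladder moves mean daily volume by only a few
percent in either direction.

Daily counts (how many segment spheroids contained each voxel) support the
relative-use summaries: the share of habitat voxels never used, used by
≥5 segments, and the maximum per-voxel inclusion fraction. The denominator
is either all in-mask lake voxels (default) or the day's footprint
(in-mask voxels inside the bounding box of the used set) — both are
exposed since either convention is defensible. Habitat volume counts
voxels with inclusion count ≥ threshold; the default threshold is 1
(a voxel used once was used), with stricter thresholds one flag away.

## KUD estimation

Both KUDs use Gaussian kernels with Silverman's rule by default ("scott"
optionally); no multivariate plug-in selector exists in the scientific
Python stack, and the rule actually used is recorded in every result.
Densities are evaluated at voxel/cell centers of the shared lattice and
renormalized over the lake mask, so KUD regions, PPV masks, and overlap all
live on one grid. The highest-density region accumulates cells until ≥ the
isopleth level (default 0.95) of total mass; ties at the cutoff density are
all included, which makes regions deterministic and nested across levels.
Fish-days with fewer than 5 fixes yield no KUD record; an all-identical
point cloud (singular bandwidth) falls back to the cells containing the
fixes, with a warning. The 3D fit evaluates only within ±5 marginal kernel
SDs of the data — density outside is numerically negligible — which keeps a
fish-day fit at a few hundredths of a second. The 3D-KUD fits rescaled
depth by default (`rescale_depth=False` fits raw meters).

Note one deliberate asymmetry: the 2D-KUD *volume* integrates bathymetric
depth over selected columns (cell area × lake depth), while *overlap* for
every method counts shared voxels × V_voxel. The two disagree by
discretization (a percent or so), so a 2D-KUD overlap can marginally exceed
the smaller member's reported volume.

## Overlap

One record per (date, unordered pair, method) where both fish have a valid
estimate that day; a fish-day without an estimate yields no record rather
than a zero, so the presence/absence denominators count evaluable pairs.
PPV overlap uses the binary used-voxel mask, not count weighting.

## Mixed models

All model comparisons use maximum likelihood (not REML), since AIC across
fixed-effect structures is only meaningful under ML; AIC counts fixed
effects plus both variance components, matching lme4's bookkeeping (and
cross-checked against lme4 in the test suite). Marginal and conditional R²
are variance ratios Var_f/(Var_f+Var_u+Var_e) and
(Var_f+Var_u)/(Var_f+Var_u+Var_e); the logistic model uses the latent
residual variance π²/3. Coefficient t-values use residual degrees of
freedom (recorded as such in each result) — a Satterthwaite approximation
is not available in the underlying fitter.

The logistic presence model (random intercept per fish pair) is fitted by
direct Gauss–Hermite quadrature (25 nodes) of the marginal likelihood —
exact ML up to quadrature error, since no frequentist logistic GLMM exists
in the installed stack — and validated against ordinary logistic ML in the
zero-variance limit. Under apparent complete separation (runaway
coefficients or non-convergence with an inflating variance) the model is
refitted with a ridge penalty on the fixed effects and the random-intercept
SD held at its starting value (0.5); the variance component is not
identifiable under separation. Penalized fits are flagged.

## The synthetic study

The generator emulates the statistical structure the analysis assumes,
sized to desk scale:

* **Lake**: paraboloid (or two-basin) bowl, radius 400 m, max depth 34 m,
  17 m grid — a ~50 ha, 8.5M m³ basin; the grid volume agrees with the
  closed-form paraboloid volume to <1%.
* **Movement**: per-fish Ornstein–Uhlenbeck attraction to a home center
  placed on the ~8 m depth contour (the nearshore zone a benthivore
  occupies), stationary SD 25 m, relaxation time 1 h, sampled *exactly* at
  transmission times via the closed-form OU transition; proposed moves
  leaving the lake are rejected (shoreline reflection). Home centers
  cluster at 3 shoreline sites (50 m along-shore scatter) so some pairs
  share habitat and others never meet.
* **Depth**: local bottom minus a temporally correlated exponential offset
  (mean 1 m, ~2 h correlation time) — benthic bottom-hugging with smooth
  vertical movement.
* **Observation**: exponential transmission gaps (mean 360 s) thinned by
  15% dropout, producing a realistic share of gaps beyond the 1080 s
  filter; horizontal Gaussian noise with a heavy-tailed (lognormal)
  magnitude; HPE rank-correlated with the realized noise and scaled so
  6.9% of fixes draw HPE > 20 (so the HPE filter removes the worst fixes
  at the reported rate); small (0.2 m) depth-sensor noise.
* **Temperature**: a sinusoid crossing 15 °C once upward (early May) and
  once downward (early October) between ice-off (April 10) and ice-on
  (November 25), plus small noise — all four seasons non-empty.

With these defaults the daily movement rates fall in the 0.013–0.158 m/s
band observed for lake benthivores, and the default scenario (run from
late March) spans winter, spring, and summer. Everything is deterministic
under a master seed with independent per-fish substreams.

What the generator does **not** emulate: spatially varying positioning
error (HPE geometry near the array edge), seasonally varying movement or
aggregation (home sites are static, so seasonal overlap differences arise
only through season-specific v_swim), diel behavior, thermal habitat
selection, and receiver-level detection processes. Tests passing on this
generator therefore validate the estimators' algebra, geometry, ordering
properties, and parameter recovery — not any claim about how a particular
wild population uses its lake.

## Problem sizes

The test suite runs the full pipeline on 4 fish × 8 days and the recovery
exercises on 9 fish × 200 days × 20 replicates; the acceptance script uses
6 fish × 75 days. These sizes give stable means and model ranks while a
full run stays in the minutes range on one CPU; all sizes are parameters,
and nothing in the code depends on them.

## Known limitations

* The voxel-center inclusion rule undercounts partial voxel coverage;
  volumes converge as L shrinks, and the 5/10/20 m ladder moves mean PPV
  volume by well under the discretization one might fear (~percent level).
* Daily speed uses 3D path length; for a benthic fish the vertical
  contribution is negligible, but for strongly diving species the 2D/3D
  choice would matter.
* The Gauss–Hermite logistic fitter supports a single random intercept
  only — crossed random effects (e.g., both members of a pair) would need
  a different integrator.
* KUD fits ignore temporal autocorrelation between fixes, as kernel
  home-range methods do; the PPV, being path-based, inherits the data's
  temporal structure by construction.
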