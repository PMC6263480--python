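# Methods

This note documents the models, conventions and numerical choices behind
canopy3d, and what the synthetic experiments do and do not demonstrate.

## Coordinate frames and the processing state machine

The cart frame puts the origin at the LiDAR optical center: X across the
plots toward increasing plot index, Y along the travel direction, Z up.
Polar records decode with azimuth measured from +Y
(x = r cos ω sin α, y = r cos ω cos α, z = r sin ω); the figure-level frame
definition of the original acquisition software is not recoverable, so this
is a documented reconstruction — the split axis must be X and Z must be up
for Z percentiles to be heights, which pins everything except the azimuth
zero.

Clouds carry a forward-only state: `raw → trimmed → corrected →
above_ground`. Trimming retains |x| ≤ 1.5 × plot width (closed interval);
splitting partitions at ±0.5 × plot width with border points assigned to
the middle plot. Both boundary conventions are arbitrary but fixed: the
data place essentially no mass on the measure-zero boundaries, and
determinism matters more than the choice.

## Tilt correction

The estimator fits ordinary least squares lines to the x–y, x–z and y–z
projections of the cloud (over **all** points, not segmented ground: canopy
tops parallel the ground under the assumption that slope variation across
one scan's three plots is negligible), converts each slope to an angle, and
counter-rotates about the perpendicular axis through the sensor origin
(keeping sensor-height semantics intact). One fit-and-rotate application
multiplies the residual plane covariance by roughly var(ordinate)/var(abscissa),
which is strongly contractive for the x-dominated planes but only ~0.4 per
pass in y–z; the implementation therefore repeats the step within a plane
until its slope is below tolerance (slope units, default 1e-6), with an
exact covariance-zeroing angle as a safeguard if a pass ever fails to
contract, and sweeps the three planes to joint convergence (default 10
sweeps). At convergence the result is independent of the sweep order. The
estimated cart attitude is the zyx Euler decomposition of the inverse of
the net correction rotation, directly comparable to a pose given as
Rz(yaw)·Ry(pitch)·Rx(roll).

Two properties of the all-points fit matter for interpretation:

* **Uniform-sward validation.** Plots of different heights contribute a
  genuine x–z covariance (taller side plot ⇒ apparent pitch), which the fit
  cannot distinguish from cart tilt. Pose round-trip validation therefore
  uses scenes with equal plot heights; on mixed-height scans the correction
  still removes most of the tilt (the processed-versus-raw experiments use
  mixed heights) but carries a deterministic bias of order a degree per
  0.1 m of side-plot height difference. This is a real limitation of the
  method, inherited by any user of unsegmented projection fits.
* **Windowing.** Correction is validated on the scan as generated (the
  simulator produces exactly the three-plot window in world coordinates).
  Trimming a tilted cloud in the sensor frame slices it obliquely, which
  perturbs the second moments the fit relies on by a few tenths of a
  degree; in the study pipeline the correction runs after trimming, as the
  acquisition chain does, and this perturbation is part of the modeled
  error budget.

## Ground baseline

Default strategy: the Z histogram over the cloud's lower half-range at
0.01 m bins; the center of the most populated bin is the ground level
(ground returns pile into a sharp mode, canopy mass is dispersed). The bin
width bounds the quantization error at ±0.005 m. If fewer than 50 points
lie below the median, the histogram is unreliable (dense canopy, few ground
returns) and the measured sensor height is used instead (`ground_z = −H_s`);
that strategy is also available directly, and is the exact choice on
simulated noise-free scenes. A `fixed` strategy accepts an external survey
value.

## Percentile ladders

The candidate-height grid runs over (0, 100]: step 0.5 % ⇒ exactly 200
levels, step 1 % ⇒ exactly 100. (A grid including both endpoints would
have 201/101 levels; excluding 0 %, which is never a useful height anyway,
is the only uniform grid matching both counts.) Heights interpolate
linearly between adjacent order statistics — the common default of
scientific software — and the same rule is used both to evaluate a ladder
at an off-grid percentile and to invert it (the generator records the
percentile at which a plot's true height sits, by exactly this rule, which
is what makes noise-free recovery exact to 1e-9 m rather than approximate).

## Ultrasonic conversion

The calibration D = 29.116 V + 11.641 is implemented with the coefficients
exactly as calibrated. Taken at face value in meters, a 0–10 V sensor with
a 4.27 m reach would report 302.8 m at full scale; the coefficients are
dimensionally consistent with centimeters, so a configurable `unit_scale`
(default 0.01, i.e. centimeter reading → meters; 1.0 selects the as-printed
interpretation) scales D before H_c = H_s − D·unit_scale. Neither
interpretation is silently corrected — the default is a documented choice.
Negative H_c values are returned with a flag, never clamped: they occur
physically when a slanted cart's beam path to the ground exceeds the
measured H_s.

## UAS surface processing

Soil pixels are sampled uniformly without replacement (default 40 % of the
mask). The DTM is local ordinary kriging: exponential variogram
γ(h) = nugget + sill·(1 − e^(−h/range)) fitted by least squares to the
binned empirical semivariance (pair distances on a fixed-seed subset of at
most 1200 samples, 18 bins to half the maximum distance; nugget floored at
1e-6 m²; heuristic fallback sill = sample variance, range = span/6 if the
fit fails); each cell is predicted from its 16 nearest samples by solving
the ordinary-kriging system with a Lagrange multiplier, batched across
cells. γ(0) = 0 by convention (the nugget applies only at h > 0), which is
what makes the interpolator exact at sampled cells. Inverse-distance
weighting (power 2) is the fallback for degenerate layouts. The height map
is cellwise DSM − DTM; nodata propagates and negative values are preserved
(clamping would bias the low percentiles that the optimal-percentile search
must be free to reject). Zonal extraction uses the cell-center rule,
boundary-inclusive on minimum-x/minimum-y edges so tiling delineations
partition the cells.

## The synthetic scene generator

The generator's defaults are the study conditions; they are set once from
the field protocol where stated and from field realism where not.

| parameter | default | basis |
| --- | --- | --- |
| plot width | 1.524 m | field layout |
| points per plot (side/middle) | 6000 / 8000 | scan statistics |
| ground-return fraction | 0.30 | chosen so baseline estimation has support |
| canopy element heights | trunc-normal on [0, 1.05 H], mean 0.85 H, sd 0.08 H | plausible sward with a thin upper tail |
| canopy cover | 0.85 | dense post-jointing stand |
| terrain | slopes 0.01 / 0.005 m/m + smooth roughness sd 0.01 m | gently sloped, uneven field |
| cart pose per scan | roll, pitch ~ N(0, 3°), yaw ~ N(0, 2°), clipped ±10° | few-degree slants on rough ground |
| LiDAR ranging noise | 0.003 m | typical for a spinning ToF scanner |
| reference heights | mean of 3 replicates, sd 0.01 m | yardstick protocol |
| ultrasonic echo depth | 25th percentile of footprint canopy | echoes form in the dense lower canopy |
| DSM GSD / per-cell noise | 0.1 m / 0.02 m | survey-scale product |
| DSM canopy error field | sd 0.05 m, periods 3–9 m | see below |
| soil sampling fraction | 0.40 | protocol |
| campaign growth factors | 0.35, 0.55, 0.80, 0.95, 1.0 | season trajectory over five campaigns |

Choices that deserve justification:

* **Balanced area sampling.** Within-plot LiDAR samples are mirrored about
  the plot center in x and the scan line in y (four copies sharing one
  canopy height), which zeroes the untilted scene's cross-plane sample
  covariances by construction. Without this, ~20 000-point scans carry
  covariance sampling noise worth 0.1–0.15° of apparent tilt — indistinguishable
  from pose and therefore an artifact of the simulator, not of the method
  under test. Mirroring removes it while leaving all marginal
  distributions, densities and percentile structure unchanged.
* **True height as a percentile.** The canopy element distribution puts the
  plot's true height H at roughly the 98th percentile of a plot's
  above-ground height set (70 % canopy returns with ~2.4 % of mass above H,
  plus 30 % ground returns), so optimal percentiles land below 100 as
  percentile-based height extraction assumes. The recorded
  `empirical_true_percentile` makes this self-verifying per plot.
* **Ultrasonic echo model.** The echo forms at a configurable percentile of
  the canopy heights inside the 7° half-angle cone (default 25th): thin
  upper organs return weak echoes, so the effective reflector sits low.
  An empty footprint echoes from the ground at path length
  H_s/(cos roll · cos pitch), reproducing near-zero and negative readings.
  The returned voltage is the exact inverse of the calibration.
* **DSM canopy error field.** Photogrammetry reconstructs textured, static
  soil well but errs smoothly over vegetation (sub-resolution organs, wind
  motion between exposures). A smooth fixed-phase random field (sd 0.05 m,
  periods 3–9 m) is added to canopy cells only; because soil is unaffected,
  the DTM — and hence DSM − DTM differencing — cannot remove it, which is
  exactly why height maps inherit it in the field. Without this term a
  simulated DSM with only IID per-cell noise would make the UAS route
  implausibly accurate (zonal percentiles average IID noise away).
* **Degenerate limit.** `height_sd_fraction = 0` collapses the canopy to a
  uniform sward at exactly H, used by exactness tests.

What the generator does **not** emulate: multi-return echo physics,
radiometry, wind deformation of the canopy during a scan, within-plot
height gradients, occlusion (canopy shadowing ground returns), and any
correlation between ultrasonic error and canopy structure beyond the echo
depth. Consequently, passing tests demonstrate the correctness and internal
consistency of the processing chain under the stated error model — not
field-accuracy claims. In particular the simulated ultrasonic estimates
remain well-correlated with truth (their error is mostly a proportional
bias), whereas field ultrasonic data can decorrelate almost completely.

## The synthetic study and problem sizes

The default study is one 100-plot field (10 × 10, plots 1.524 m × 1.5 m at
a 2.0 m row pitch) measured in five campaigns, campaigns 1–2 labeled method
A and 3–5 method B. Cart stops sit at every third column plus one extra
stop to cover the row end, so each campaign yields 100 plot estimates (500
over the season; each plot keeps its first estimate when stops overlap).
The DSM covers the field at 0.1 m GSD (~33 000 cells; ~7000 kriging
samples). These sizes keep a full study at a few seconds on one core while
leaving every estimator in its asymptotic regime; all randomness flows from
one master seed through named per-stage seeds, making a report bundle a
pure function of (config, seed).

## Evaluation conventions

R² is the squared Pearson correlation, not 1 − SS_res/SS_tot about the
identity line: bias is reported separately, and a systematically biased but
tightly correlated sensor should score high R² alongside its nonzero bias.
The optimal-percentile argmin breaks ties toward the lowest percentile.
Derived percentages are rounded half-up to two decimals and derived meters
to four, matching how such tables are printed; `average_rmse_increase` uses
the unweighted mean of the side/middle RMSEs within each category before
averaging across categories. The maximum-R² percentile is reported
alongside the minimum-RMSE percentile where requested; the two need not
agree and the package decides nothing between them.

## Known limitations

* The all-points projection fit confounds cart tilt with cross-plot height
  differences and with the terrain slope itself (removing the latter is
  intended — heights are measured from local soil).
* Histogram baselining needs ground returns; under full canopy closure it
  falls back to the measured sensor height, inheriting that measurement's
  error.
* Kriging with a 16-neighbor moving neighborhood is not a global
  interpolator; on pathological sample layouts (long empty corridors) IDW
  may be preferable.
* The calibration-unit ambiguity (meters as stated versus centimeters as
  dimensional analysis suggests) is configurable, not resolved.
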