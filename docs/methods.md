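# Methods

This note records the models, parameter choices, and numerical conventions
behind `smtz`, and what the synthetic-data tests do and do not demonstrate
about real data.

## Headspace equilibration

A jar holds sediment (volume *V*ₛ, porosity φ), added distilled water
(*V*𝓌), and a headspace (*V*ₕ) that equilibrates with all dissolved CH₄.
Total methane is partitioned by the ideal gas law and Henry's law and
attributed to the original porewater volume *V*ₛ·φ:

C (mol L⁻¹) = [x·P·Vₕ/(R·T) + Kₕ(T)·x·P·(V𝓌 + Vₛ·φ)] / (Vₛ·φ)

with x the headspace mixing ratio (ppm·10⁻⁶). Defaults follow the field
protocol: 600 mL jar, 133 mL sediment, 200 mL water, 200 mL headspace,
φ = 0.8 (uncompacted muddy sediment).

Choices where the protocol is silent:

- **Equilibration conditions**: 294.15 K (21 °C lab) and 1 atm; both config
  fields.
- **Solubility**: CH₄ Henry constant 1.4·10⁻³ mol L⁻¹ atm⁻¹ at 298.15 K with
  a van 't Hoff parameter of 1700 K, standard values for fresh water.
  Salinity effects are neglected because the jars are topped with distilled
  water, which dominates the aqueous phase.
- **Aqueous phase**: added water *plus* porewater, since both contact the
  headspace; a biocide is assumed to stop all microbial turnover, so there
  is no production or consumption term.
- **Dissolved fraction**: included by default; `include_dissolved=False`
  gives the headspace-only approximation some labs use (at the default
  geometry the dissolved fraction is ~5% of the total).

The generator's inverse (`ppm_for_concentration`) is exact because both
phases are linear in the mixing ratio; round-trip error is at machine
precision, and the tests require < 10⁻⁶ relative over 0.001–0.8 mM.

## Sulfate gradient, DNS, and diffusive flux

Sulfate in the porewater profile is fit by OLS over a window chosen in two
steps:

1. Start at the depth of **maximum** sulfate, not at the surface. Winter
   profiles can show a sulfate minimum at the seafloor with a subsurface
   peak at ~5–10 cm (fresher overlying water); a surface-depressed layer
   violates the linear steady-state diffusion assumption, so the fit begins
   at the peak. The window ends at the first zero concentration (the
   contiguous positive run).
2. **Iterative trimming**: compute the x-intercept (implied DNS), drop
   window points deeper than it, refit, and repeat until stable (≤ 20
   iterations; usually 1–2). Near the depletion horizon, measured
   concentrations cannot go below zero, so noise leaves scattered small
   positive readings just *below* the true DNS; including them attenuates
   the slope. On 500 noisy replicates the trimming reduces the mean DNS
   error from ~1.5–3.5% to ~0.0–0.3% and restores nominal 3-standard-error
   coverage of the slope.

DNS = −intercept/slope (requires slope < 0; a non-decreasing profile is an
error for DNS and excludes the core from fluxes). Fick's first law with the
standard diagenetic porosity factor gives

J = −φ · Ds · dC/dx,  Ds = D0/(1 − ln φ²),  D0 = (m0 + m1·T)·10⁻⁶ cm² s⁻¹

reported in mmol m⁻² d⁻¹ (conversion factor 8.64·10⁵ from
cm² s⁻¹ · mM cm⁻¹). Defaults m0 = 4.88, m1 = 0.232 come from standard
seawater diffusion tabulations; both are config fields, as is
`include_porosity_factor` for labs that report the bare −Ds·dC/dx. The
sediment temperature per (bay, season) defaults to the corresponding logger
window mean. Temperatures outside −2…40 °C warn rather than fail.

Cores are excluded from group averages when the sulfate fit has R² < 0.90 —
a quantitative proxy for "clearly non-linear" profiles (concave
production-dominated shapes fail it immediately); the threshold is config.
Group summaries average flux and DNS over included cores only and keep
empty groups as missing-value rows.

## Season and bay comparison

- Season windows default to 1 June–22 September (summer) and 21 December–20
  March (winter); both config.
- Welch's unequal-variance t-test (scipy backend) with the convention
  t = 0, p = 1 for two constant, equal samples.
- Methane fold changes match depths to the nearest slice midpoint within
  ±1 cm and divide by max(C, ε) with detection floor ε = 10⁻⁴ mM — below
  the smallest concentration the method resolves (~10⁻³ mM) — flagging any
  record where the floor engaged. "4 cm depth" is the midpoint of the
  2–6 cm jar interval, so fold changes are computed from the jar-derived
  methane table whose midpoints (4, 11, 18, 25 cm) are shared by both
  seasons' sampling schemes.
- Summaries report both the maximum ("up to") and the mean of per-site
  ratios, because an "average fold change" is ambiguous; when the two bays
  share no site labels, the bay contrast uses the ratio of across-site mean
  concentrations instead (one record per season, site = "mean").

## Community analysis

All four operations are implemented directly (scikit-bio and scipy serve
only as independent cross-checks in the tests):

- **Aggregation** sums ASV counts sharing a label at the requested rank
  (domain…species); lineages short of the rank pool into "Unassigned".
  Per-sample totals are conserved.
- **Relative abundance** selects the top-k taxa by mean relative abundance
  (ties lexicographic) and pools the rest as "Other_Families"; rows sum
  to 1.
- **Bray–Curtis** is computed on relative abundances by default because
  library sizes differ; `use_relative=False` operates on raw counts. A pair
  of all-zero samples is an error (the dissimilarity is undefined).
- **PCoA** is classical metric scaling: Gower-center −½D², eigendecompose,
  scale eigenvectors by √λ for positive eigenvalues. Negative eigenvalues
  (possible for semi-metric dissimilarities) are reported but excluded from
  the coordinates; no Lingoes/Cailliez correction is applied — the simplest
  defensible convention, visible in the output. Proportions explained are
  relative to the positive-eigenvalue sum. Axis signs are fixed by making
  each axis's largest-magnitude loading positive.
- **PERMANOVA** partitions tr(G), G the Gower-centered matrix, over model
  terms added sequentially (Type-I), using orthonormal bases of the growing
  design: SS(term) = tr(HⱼG) − tr(Hⱼ₋₁G). Categorical factors get treatment
  dummies, numeric covariates enter linearly, `a:b` denotes the product
  interaction; a term adding no rank raises a rank-deficiency error naming
  it. Pseudo-F uses the residual mean square; p-values come from free
  permutation of sample rows, p = (#{F* ≥ F} + 1)/(N + 1), so p is never
  below 1/(N+1). Term order is caller-specified, as it must be for
  sequential sums of squares.

## Synthetic data: what it emulates

The generator encodes the study geometry, not sediment physics — profiles
are parametric shapes, not reaction-transport solutions.

- **Sulfate**: linear from a surface value to zero at a true DNS, optional
  multiplicative surface depression (winter subsurface peak), additive
  Gaussian noise truncated at zero.
- **Methane**: a near-seafloor background above a transition 5 cm above the
  DNS, then a linear ramp to a deep value at 32 cm; noise scales with the
  expected value (a single absolute noise level cannot serve both the ~mM
  sulfate scale and the ~µM near-seafloor methane scale).
- **Temperature**: annual sinusoid peaking in late July plus white noise;
  the heated series is the control plus a constant offset (default 5.1 °C)
  plus independent noise. The default mean (11.5 °C) and amplitude (9.9 °C)
  solve the window-averaged sinusoid for a control bay averaging 19.9 °C
  over the summer window and 2.7 °C over the winter one.
- **Communities**: expected family proportions are
  softmax(base + depth_slope·depth + bay_effect·heated); counts are
  Dirichlet-multinomial (concentration 50, library size 25,000), so every
  sample sums to the library size. The default archaeal scenario plants the
  qualitative gradients seen in warmed-bay sediments: ANME-1 and BA1
  increasing with depth and in the heated bay, Nitrosopumilaceae peaking at
  the surface, Bathyarchaeia families dominating throughout.

Default study scenario (3 cores per bay per season): brackish Baltic
surface sulfate 5.6 mM; DNS 25/37 cm (control summer/winter) and 22/28 cm
(heated), encoding a shallower sulfate zone in the warmed bay; sulfate noise
0.3 mM, methane noise CV 0.1; near-seafloor methane set so the generated
contrasts show few-fold (control season), hundreds-fold (heated season),
and ~50-fold (heated vs control summer) increases. Porewater grids are
2 cm (summer) and 4 cm (winter) spacing; jars cover 2–6, 9–13, 16–20, and
23–27 cm; community samples sit at 0.5–22.5 cm, five depths × 3 cores.

One RNG stream (`numpy.random.default_rng(seed)`) per generator call; no
global state; identical seeds give byte-identical pipeline outputs.

**Known limitations.** (1) Winter profiles with a surface depression are
not exactly linear below the peak, so the linear DNS estimate runs ~1–2 cm
(occasionally more at 4 cm grid spacing) deeper than the underlying line's
intercept — a property of the linear method on such profiles, visible in
the acceptance output. (2) The temperature model has no synoptic
variability, so within-window standard deviations and ranges are narrower
than logger data. (3) Count tables have no spatial autocorrelation between
cores and a single overdispersion parameter. Passing tests therefore
demonstrate correctness of the computations and recoverability under the
stated noise models, not that real sediments satisfy those models.

## Problem sizes

The default synthetic study uses 12 cores, one year of hourly logger data
(~8,700 points per bay), 48 jars, and 60 community samples with 8 families;
PERMANOVA uses 999 permutations (config). Monte-Carlo checks in the test
suite use 100–500 replicates; the null-calibration check runs 500
simulations at 99 permutations each.
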