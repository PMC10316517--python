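# Methods

## Scope and state

The package simulates a single well-mixed 8 L microcosm (25 cm diameter,
water height ≈ 0.163 m) over a 19-day stressor exposure. Producer groups:
two phytoplankton trait groups (α fast-growing/herbicide-sensitive, β
slow-growing/resistant), wall periphyton, epiphyton on macrophyte surfaces,
and rooted submerged macrophytes. Pools per group: live, exudate and dead
carbon; additionally sedimented dead phytoplankton per planktonic group and
dissolved inorganic phosphorus. Nitrogen, grazers, decomposer biomass,
sediment chemistry, pH/DIC and oxygen are deliberately outside scope; the
nitrate in the run-off mixture is carried in treatment definitions for
reporting only and is assumed non-limiting.

Unit regimes follow the habit of each group: volumetric (mg C m⁻³) for
planktonic pools and all exudates, areal (mg C m⁻²) for the wall biofilm
and the sediment pool, whole-microcosm mass (mg C) for macrophytes. All
rates are per day; configuration values are given at the reference
temperature of 22 °C.

**Epiphyton bookkeeping.** Epiphyton live/dead pools are tracked as
whole-microcosm mass, not as areal density. The colonizable area
`A_epi = σ_epi · C_live,macro` changes with plant biomass; an areal-density
formulation on a moving area silently creates or destroys carbon (and hence
phosphorus) whenever the area changes. Tracking mass keeps the governing
equation in the same `(p − l)·C` form, conserves phosphorus exactly, and
the density used for space limitation and reporting is simply mass/area
(with growth shut off when the area vanishes).

## Process formulations

- **Temperature**: every process rate scales with `Q10^((T−T_ref)/10)`.
  Defaults: Q10 = 2.0 for growth, losses and biodegradation — standard
  mid-range values for mesophilic producers and decomposers.
- **Growth**: `p = p_max · f_T · f_I · f_P · f_space · f_tox`, all factors
  multiplicative. Light and phosphorus limitation are Monod; space
  limitation is linear (`1 − C/C_max`) and applies only to the benthic
  biofilms; macrophytes take phosphorus from the water column at quota
  `q_P` (a sediment-fed alternative would break the closed P budget that
  the tests rely on).
- **Light**: constant effective forcing equal to mean surface irradiance ×
  photoperiod (77.2 × 16/24 ≈ 51.5 µmol m⁻² s⁻¹); endpoint comparisons are
  insensitive to diel phase and a smooth right-hand side integrates
  faster. The water column attenuates with `k = k_bg + k_chl·ΣC_phyto`;
  planktonic groups and the wall receive the depth-averaged profile,
  macrophytes mid-depth light further reduced by `exp(−k_epi·D_epi)` for
  their epiphyton cover, epiphyton the mid-depth light itself. Periphyton
  self-shading within the mat is not modelled (the space cap already limits
  mat thickness).
- **Losses and recycling**: death and exudation are first-order with Q10
  scaling; dead and exudate pools biodegrade first-order, releasing P at
  the producer's quota. Live and dead phytoplankton sink at constant
  velocities into the sediment dead pool, which biodegrades and releases P
  back to the water column.
- **Herbicide**: only the herbicide of the run-off mixture acts on the
  producers (a PSII inhibitor; the insecticide, fungicide and copper are
  inert here). Exposure: 10 % immediate application loss, then first-order
  decay with default `k = −ln(0.70)/18 ≈ 0.0198 d⁻¹`, i.e. 70 % of the
  post-application concentration remains at day 18, the midpoint of the
  55–90 % measured range. Decay is temperature-independent. Inhibition is
  log-logistic `1/(1+(c/EC50)^h)` with default Hill slope 1.

## Scenarios

The sensitive-group EC50 anchor is 3 µg L⁻¹ (an EC20 of 0.75 µg L⁻¹ — the
herbicide's 1x concentration — converted by `EC50 = EC20·4^(1/h)` at
h = 1). Scenario families use ×/÷4 offsets: A — all groups equal except β
(20× anchor); B — macrophytes ÷4; C — microscopic groups ÷4; D — starts as
C. Suffix-2 scenarios double every EC50 in the warm treatment
(`theta_T = 2`). D scenarios add tolerance development for the microscopic
groups only: EC50 rises as a saturating exponential from its initial value
to 16× that value with time constant `tau = kappa_tol/p_max`
(`kappa_tol = 40`), so faster growers adapt faster; the sensitive
microscopic groups cross the constant macrophyte EC50 around day 6 (phyto
α) to day 11 (periphyton). Only directionality of these processes is
empirically anchored; magnitudes are declared defaults, all
config-overridable.

## Design, integration, endpoints

The factorial design crosses run-off levels {0, 1, 2, 4, 8, 16}× with
temperatures {22, 26} °C (12 treatments); community sets 1/2/3 put group α,
group β, or both (inoculum split evenly) in the water. The 1x constituent
vector is terbuthylazine 0.75, pirimicarb 3.75, tebuconazole 22.5, copper
10.5, NO₃-N 2250 µg L⁻¹, scaled linearly by level.

Nutrient pulses fall on an even twice-weekly grid (days 3, 7, 10, 14, 17),
each adding 50 mg P m⁻³; the initial dissolved P equals one pulse. The
pulse mass is not reported for the underlying experiment; 50 mg P m⁻³ (0.4
mg P per microcosm per pulse) is chosen as the smallest round amount at
which the community is productive rather than starved — with an order of
magnitude less P no group grows appreciably in 19 days and the scenario
comparison degenerates, contradicting the stated purpose of the repeated
nutrient loading. Macrophyte `q_P = 0.005` mg P/mg C reflects plant tissue
being P-poorer than algae (0.01).

Integration uses `scipy.integrate.solve_ivp` (LSODA, rtol 1e-6, atol 1e-9),
restarted at each pulse with an instantaneous P increment, sampled 4×
daily. Trajectory values in [−1e-9, 0) are clipped to zero on output;
anything below −1e-9 aborts with a diagnostic naming pool and time.
Endpoints are taken at day 19 for all groups (the experiment sampled
microscopic groups on days 16–18 and macrophytes from day 19; a single
uniform day keeps treatments comparable and is configurable). Endpoint
conversion to whole-microcosm mass: phytoplankton × V, periphyton ×
A_peri, macrophytes (and optionally epiphyton, which is simulated but not
part of the three-group assessment currency) as-is.

## Assessment and selection

Response curves are the six endpoint biomasses along the run-off gradient
per group × temperature. Observed replicates are collapsed to cell means
(means, not medians). Pearson r with two-sided p from the t distribution at
n−2 = 4 df; tiers 90/95/99 % at p < 0.1/0.05/0.01. Hedges' g uses the
pooled SD and the small-sample correction `J = 1 − 3/(4(n₁+n₂)−9)`, with
the Hedges–Olkin large-sample variance. Upscaling multiplies strip
periphyton by wall/strip area (0.128/0.045 m²), phytoplankton
concentration by the water volume, and reports group shares plus totals
relative to the cool control.

Selection proceeds in three stages: (1) keep scenarios whose macrophyte
correlation is positive and at least 90 %-significant at *both*
temperatures — 90 % being the lowest starred tier; (2) keep scenarios with
a positive phytoplankton correlation at ≥ 1 temperature; (3) rank
survivors lexicographically by (number of significant periphyton
correlations, summed periphyton r, summed macrophyte r). The third stage
formalizes a narrative comparison ("periphyton correlations higher and
more significant") as a deterministic tie-break. Scenario input order
never affects the outcome, and an audit trail records every elimination.

## Synthetic observations

Replicates are drawn lognormally around per-cell means with a per-group CV
(lognormal for strict positivity of biomass); the draw mean equals the
specified mean exactly (`µ = ln m − σ²/2`). The shipped default pattern
encodes the qualitative endpoint responses of the underlying experiment on
each group's sampling basis: cool macrophytes depressed at every run-off
level relative to a high control, warm macrophytes flat, phytoplankton
rising with level with an irregular dip at 8x, periphyton flat with heavy
scatter (CV 0.5, doubled in the controls; macrophytes 0.25, phytoplankton
0.35). Observation sets can also be generated from simulated endpoint
tables for recovery experiments: noise-corrupted truth curves are
re-assessed against all eight scenarios to measure how often selection
returns the generator.

What passing these tests shows — and does not: the generator reproduces
the *structure* (design, replication, noise family, qualitative shapes) of
endpoint data, not the actual unpublished replicate values; recovery rates
measure internal consistency of the selection procedure under the model's
own dynamics, not field validity. Real data add sampling-day heterogeneity,
non-lognormal outliers and between-microcosm structure that the generator
omits.

## Numerical and design choices

- Time unit: days internally; all configuration rates are per day.
- Fixed-step classical Runge–Kutta at dt = 1e-3 d serves as an independent
  integration oracle in the tests (agreement < 1e-4 relative over 2 days).
- Phosphorus closure (quota-weighted total P constant between pulses) holds
  to < 1e-6 relative drift per simulated day at default tolerances; in
  practice drift is at machine precision because conservation is structural
  in the right-hand side.
- Degenerate inputs: zero biomass is a fixed point; zero macrophyte biomass
  removes the epiphyton habitat (growth factor 0); a control treatment
  short-circuits the dose-response to exactly 1, making control
  trajectories bitwise identical across scenarios.
- Problem sizes in tests and the acceptance script (e.g. 25–100 synthetic
  draws, 288-design completion) were chosen to give stable statistics at
  interactive runtimes on one CPU.

## Known limitations

- Single herbicide action; no mixture toxicity, no toxicokinetics inside
  organisms, no copper speciation.
- Tolerance kinetics (saturating exponential, 16× rise, `kappa_tol = 40`)
  are declared, not fitted; only their direction and the generation-time
  link are empirically anchored.
- Constant light forcing ignores diel and day-to-day variation; the square
  of the light:dark cycle is available only as the photoperiod average.
- The linear space cap treats the biofilm as two-dimensional; no mat
  micro-structure.
- Whole-microcosm upscaling assumes strips sample wall growth
  representatively.
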