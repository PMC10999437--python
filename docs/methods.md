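# Methods

## Model structure

The model tracks a cohort of *Philaenus spumarius* through seven stages:
post-diapausing egg (stage 1), nymphal instars N1–N5 (stages 2–6) and
adult (stage 7). Within stages 1–6 an individual is located by its
physiological age x ∈ [0, 1], the fraction of within-stage development
completed; x advances at the stage's temperature-dependent rate v_i(T)
and the individual moves to the next stage when x reaches 1. The
population is the density n_i(t, x) obeying the pure-advection transport
equation ∂n_i/∂t + v_i(T(t)) ∂n_i/∂x = 0, coupled through boundary
fluxes. The adult stage is a scalar accumulator of the flux leaving N5:
adult physiology (parapause, ovary maturation, oviposition), mortality,
reproduction and density dependence are all outside the model's scope, so
total individuals are conserved.

Related stage-structured frameworks add a stochastic (diffusion) term to
this transport equation to represent inter-individual rate variability.
Here the distributional spread is carried entirely by the initial age
condition, and the baseline solver is pure advection; a constant
diffusivity hook exists in the design but defaults to zero, since no
spread magnitude is available to parameterize it and the pure-advection
model already reproduces every quantity we target.

## Development rates

Each of stages 1–6 carries a Brière rate function
v(T) = a·T·(T − T_inf)·√(T_sup − T) on [T_inf, T_sup], zero outside and
clamped at zero from below (development cannot be negative; for T < 0 the
piecewise definition already returns 0). The optimum temperature is the
larger root of 5T² − (4·T_sup + 3·T_inf)T + 2·T_inf·T_sup = 0, computed
in closed form rather than numerically for exactness and testability.

Published parameter tables typically report the *peak rate* v_max rather
than the raw constant a, so the loader accepts either; a is reconstructed
as v_max / [T_opt(T_opt − T_inf)√(T_sup − T_opt)].

Two presets are bundled (`src/philaenus/data/presets.yaml`). Values not
individually published are interpolated and flagged in the file:

* `parameterized` — N5's peak rate is not reported; we use 0.16 day⁻¹,
  between the reported N2 minimum (0.1747) and the N1/N4 maximum
  (0.2382), and above the post-calibration N5 value (0.1441), consistent
  with the statement that calibration *decreased* the nymphal peak rates.
* `calibrated` — N1/N2/N4 peak rates are set slightly below their
  chamber-derived values (0.2200/0.1650/0.2100) for the same reason; N4's
  lower threshold is set to 4.0 °C (its increase is reported as smaller
  than N5's +2.0 °C, which puts N5 at 5.0 °C — the top of the published
  2.1–5.0 °C range). With these choices the nymphal optima span
  26.6–27.0 °C, matching the published range endpoint to endpoint.

## Diapause termination

Eggs overwinter in diapause and resume development after accumulating
DD_e degree-days above a threshold T_e, counted from 1 January. The
accumulation formula is not prescribed beyond "degree-days above a
minimum temperature threshold"; we use the simplest consistent rule —
daily sum of max(0, T̄_d − T_e) on daily mean temperatures, hourly inputs
averaged per calendar day — with an hourly variant
(Σ max(0, T_h − T_e)/24) behind a `method` switch for sensitivity checks.
All eggs terminate together on the first day the running sum meets DD_e
(a single population-level switch: one (T_e, DD_e) pair, no among-egg
distribution), and development begins on the termination day itself. A
series that ends before the requirement is met yields an explicit
"not reached" result (`None`), not an exception.

## Initial condition

100 diapausing eggs on 1 January with ages drawn from Beta(α, β);
bundled values α = 5.67, β = 1.05 put 90% of initial ages in
[0.58, 0.99] — embryogenesis largely completed before winter, so first
hatchings follow soon after diapause ends. Discretization uses exact
Beta-CDF cell masses renormalized so the discrete total is exactly the
egg count.

## Numerics

Conservative first-order upwind on a uniform age grid, 200 cells by
default, with a fixed sub-step chosen once per run from the CFL
condition max_i v_i·dt ≤ Δx using the analytic per-stage maximum rates
(≈48 sub-steps/day at 200 cells). Boundary fluxes are transferred within
the same sub-step, so mass is conserved to round-off per step; the
`step` API rejects a CFL-violating dt and reports the maximal admissible
value. Daily temperature series are held constant at the daily mean
within each day; hourly series are linearly interpolated to sub-step
midpoints. First-order upwinding smears sharp fronts; the test suite's
refinement study verifies that reported 50%-emergence dates converge at
first order, and the characteristics comparison bounds the error at 200
cells to about one grid cell's time-equivalent plus the one-day output
resolution.

For constant temperature the transport system also has an exact
method-of-characteristics solution (entry times are the push-forward of
the initial Beta distribution), implemented separately in
`characteristics.py`. It serves three roles: the independent oracle for
solver tests, the sampling engine of the chamber-experiment generator
(deliberately independent of the finite-volume solver so those tests are
non-circular), and the exact forward model inside the chamber-data fit,
where temperature is constant by design.

## Parameterization from chamber data

The chamber design: four constant temperatures (10, 18, 24, 30 °C), nine
replicates, cohorts censused Monday/Wednesday/Friday; the observable is
the cumulative count of individuals having reached each stage. Eggs
enter the experiment post-storage, so the diapause phase is bypassed and
the unknown pre-history is absorbed by the free initial Beta age
distribution.

The fit minimizes the sum over temperatures, stages and census dates of
squared differences between observed and predicted cumulative emergence
percentages. Stages are fitted sequentially in developmental order — the
egg triple jointly with (α, β) against the hatch curves, then each
instar's triple with upstream parameters fixed — because the objective
is nearly separable in that order and a 20-parameter joint search is
needlessly fragile. Each sub-fit is bounded Nelder-Mead
(t_inf ∈ [0, 15], t_sup ∈ [25, 40], v_max ∈ (0, 1], shapes ∈ (0, 50])
with step tolerance 1e−6 and objective-change tolerance 1e−1; the
best-so-far parameters are kept if an optimizer step fails to improve,
so the final objective never exceeds the initial one. The Gamma-CDF
layer (`fit_gamma_emergence`) smooths observed curves for display and
can supply pseudo-observations at arbitrary dates; by default the
minimization targets the raw censored curves (`target="gamma"` switches
to the smoothed ones).

## Field calibration

Two steps, one pass (the procedure is not iterated):

1. **Rates** — with a provisional diapause pair fixing each site-year's
   development start, the six Brière triples are refined sequentially
   (same bounded Nelder-Mead) against all N1–N5 weekly curves, plus a
   half-weight squared-day penalty on the 1%-adult date when a
   first-adult observation exists — first adult appearances are part of
   the calibration information even though adult curves are not.
2. **Diapause** — rates fixed, exhaustive grid search over
   T_e ∈ [3.0, 10.0] °C and DD_e ∈ [30, 130]; default steps 0.5 °C and
   10 DD (not prescribed; chosen so the bundled calibrated pair lies on
   the grid). The objective is restricted to the N3–N5 curves — the
   instars the field data resolve best. A pair that never terminates
   diapause in a survey contributes that survey's all-zero prediction,
   a natural penalty rather than an exception. Ties are broken
   deterministically: smallest objective, then smallest DD_e, then
   smallest T_e. Because the forward run depends on the candidate pair
   only through the integer termination day, trajectories are cached per
   (survey, termination day), which cuts the 165-pair search to a few
   dozen simulations per survey.

Real nymphal field data are known to resolve N1/N2 poorly (early-instar
sampling is hard and early phenology is most sensitive to the diapause
uncertainty); that is a property of field data collection, not
reproducible synthetically, and is one reason the diapause objective
uses N3–N5 only.

## Synthetic data

The generators are pure functions of (spec, seed).

* **Weather** — T(t) = mean − A_annual·cos(2πd/365) +
  A_diurnal·sin(2πh/24) + N(0, σ²), hourly or daily. The default
  "Mediterranean" preset (mean 15 °C, annual amplitude 8 °C, diurnal
  amplitude 4 °C, σ = 1.5 °C) gives mild winters in which the bundled
  diapause pair terminates in early March. Real weather has day-to-day
  autocorrelation, fronts and heat waves that this sinusoid lacks, so
  passing recovery tests demonstrate identifiability under smooth
  forcing, not robustness to real weather variance.
* **Chamber experiments** — individual stage-entry times sampled exactly
  along characteristics from Beta-distributed ages, censored to the
  thrice-weekly census; default 9 replicates of 20 eggs. An analytic
  (infinite-cohort) mode returns the exact CDF for noiseless recovery
  experiments. The census horizon is set automatically so ~99.9% of the
  cohort reaches adulthood (≈270 days at 10 °C, ≈60–75 days at 18–30 °C).
* **Field surveys** — the full forward model run on generated weather;
  weekly sampling on Julian days 64–148 (early March to late May);
  binomial observation noise on a 100-individual cohort per date,
  monotonized by a running maximum so cumulative curves remain valid.
  Sites receive cycled mean-temperature offsets (0, +1.5, −1.0,
  +0.5 °C), a realistic inter-site climatic spread that also
  decorrelates termination-day ties across sites in the grid search.

## Problem sizes used in the shipped experiments

The recovery experiments run at the study's own design sizes: 4
temperatures × 9 replicates for chamber fits, 4 site-years × 13 weekly
dates × 100-egg cohorts for the diapause grid search (165 grid pairs,
full forward simulations at 200 cells). The rate-refinement examples in
the test suite use 1–2 site-years, 100-cell grids and capped optimizer
evaluations, which suffice to demonstrate objective reduction and
refinement direction.

## Known limitations

* Diapause is driven by heat accumulation alone; chilling contributions
  and photoperiod are not modelled (no published rate function exists to
  parameterize them).
* The single population-level termination switch makes the earliest
  hatch dates sharper than field observations suggest.
* First-order upwinding slightly widens emergence curves at coarse
  grids; use ≥200 cells when curve shape matters.
* The sequential (rather than joint) fitting strategy can leave a small
  residual when stages are strongly misspecified simultaneously; a
  second pass over the stages is a straightforward extension.
* Chamber identifiability of v_max for the egg stage is weakened by an
  approximate trade-off with the Beta age distribution (scaling both the
  rate and 1 − x0 leaves hatch times nearly unchanged); the four-
  temperature design and the bounded age support break the degeneracy,
  but egg v_max estimates are the least robust under noise.
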