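# Methods

## Problem and model

German male life expectancy has converged only partially between East and
West since reunification, and the remaining gap is concentrated at working
ages. One candidate explanation is compositional: if a larger share of East
German men carries severe health limitations, the East's total death rate
can exceed the West's even when like is compared with like. This package
operationalizes "severe health limitation" as receipt of a disability
pension (DP) — an administratively assessed, hence comparatively objective,
health marker — and splits the regional mortality difference into what is
due to (i) mortality among men without DP, (ii) mortality among men with
DP, and (iii) the prevalence of DP itself.

Within each 5-year age group $a \in \{[30,35), \dots, [55,60)\}$ the male
death rate is the mixture $m_a = \pi_a m_a^{DP} + (1-\pi_a) m_a^{ND}$. All
rates are per 100,000 person-years; $\pi_a \in [0,1]$. Age structure is
removed by direct standardization, $\mathrm{SDR} = \sum_a c_a m_a$ with
fixed weights $c_a$.

Assumptions baked into this model:

* two homogeneous subpopulations per cell (no severity gradient within DP);
* prevalence and hazards constant within a 5-year age group and calendar
  year;
* person-years approximated by mid-year population, the average of two
  successive year-end stocks;
* the register covers the population of interest (no coverage correction
  for civil servants or the self-employed is attempted).

## Data reconstruction

The register's stock sample contains 1% of pension records at year-end and
its death sample 10% of pension terminations through death, and the two
cannot be linked at the individual level. Consequently:

* disability records are counted per cell and weighted by 100 (stock) or 10
  (deaths); records of other pension types are filtered out first;
* all inter-stage interfaces are cell-level `CountTable`s — no stage ever
  joins individual records;
* mid-year DP exposure for year $t$ uses year-end stocks of $t-1$ and $t$.
  Which adjacent pair "the average of two successive years" denotes is not
  observable from outputs; the $(t-1, t)$ reading matches the standard
  mid-year convention, and the generator supplies the lead-in year so that
  exposure exists from the first analysis year. The earliest stock year is
  dropped from exposure (logged);
* non-DP population and deaths are totals minus DP. A negative difference
  is an error naming every offending cell, never clamped: clamping would
  silently bias non-DP rates, and no clamping rule is defined for the
  original data.

## Synthetic data generator

The generator emulates the *structure* of the register and national count
data, not any real trajectory:

* **Populations.** Year-end total stock $N$ per cell is a fixed input
  (national population counts are treated as known, not sampled). Defaults:
  550,000 men per age group in the East, 2,750,000 in the West — the
  real-world magnitude of German male populations aged 30–59 (≈3.3M vs
  ≈16.5M) — constant over time.
* **DP membership.** Deterministic mode: DP stock $= N\pi$ (real-valued).
  Stochastic mode: $\mathrm{Binomial}(N, \pi)$ per cell.
* **Deaths.** Generated against mid-year exposure with the same $(t-1,t)$
  convention the reconstruction uses, so deterministic round trips are
  exact; stochastic deaths are Poisson with mean exposure × hazard. Hazards
  above 1/person-year are rejected at configuration time (expected deaths
  would exceed exposure). DP + non-DP deaths = total deaths cell-wise by
  construction.
* **Sampling.** Within each cell every unit is retained independently with
  the sampling fraction (binomial thinning). The real samples' exact
  stratification is unpublished; per-cell thinning is the declared modeling
  assumption and is sufficient because all downstream computation is
  cell-level. `draw_sample` additionally expands thinned cells into
  record-level rows and pads them with `pension_type = other` filler
  (default: 2% of the male population holds a survivor-type pension before
  60), so the reconstruction's filtering step is exercised. The pipeline's
  stochastic mode thins at cell level directly — the identical distribution
  without the row blow-up; its deterministic mode skips thinning entirely
  (the fraction-1/weight-1 identity), keeping deterministic runs exact.
* **Baseline scenario** (`default_scenario`): years 1995–2013, East
  prevalence 0.05 vs West 0.03 in every age group, non-DP hazards rising
  from 0.0008 (30–34) to 0.0065 (55–59) per person-year — the order of
  magnitude of west-European male working-age mortality around 2000 —
  *shared by both regions*, and DP hazards nine times the non-DP hazard,
  matching the reported ninefold excess mortality of DP recipients. Because
  only prevalence differs, the true decomposition of this scenario is 100%
  compositional: a known ground truth that the full sample→reconstruct→
  rates→decompose chain must recover.

What the generator does **not** emulate: individual careers and durations
on pension, diagnoses, cohort effects, time trends in prevalence or
mortality, migration, and any register coverage gaps. Passing tests
therefore demonstrate the correctness of the estimation machinery under the
stated sampling model, not the substantive accuracy of any real-world
series.

## Rates and standardization

Rates are deaths/exposure × 100,000. A cell with zero exposure and zero
deaths gets rate 0 (logged); zero exposure with positive deaths is an
error. The standard population defaults to an *approximate* German male
2005 age distribution (rounded thousands; synthetic stand-in, since the
exact weights used originally are unpublished). Within this package SDR
comparisons are structurally standard-invariant — both regions are weighted
with the same $c_a$ — and any replacement standard can be supplied as a
CSV. SDR series for reporting are smoothed with a centered 3-year moving
average (small DP death counts at younger ages make annual SDRs noisy); the
endpoint years are dropped, so a 1995–2013 series yields 1996–2012.

## Decomposition

Stepwise replacement credits each parameter element with the SDR change at
its replacement step; contributions telescope exactly. A single order is
arbitrary, so per-age contributions are defined as the average over all
$3! = 6$ within-age replacement orders — the Shapley value of the three
elements. For the multilinear mixture this average has the closed midpoint
form given in the README; `decompose_cell` implements it, and the
exhaustive-permutation `shapley_oracle` provides the independent route the
tests compare against (1e-10 agreement on ≥1,000 random instances). The
SDR is additively separable over age groups, so cross-age replacement order
cannot matter; the generic 18-element `stepwise_replacement` engine is kept
as the surface on which the tests assert exactly that.

Numerical contracts:

* components sum to the total difference within 1e-9 relative tolerance,
  enforced at construction of every `DecompositionResult` and re-checked
  before rendering;
* swapping the two regions negates every component exactly (antisymmetry);
* component shares are percentages of the total, rounded to one decimal,
  undefined (rejected) for a zero total difference.

Sign convention: the core `decompose_year(west, east, …)` returns East −
West, so the formula-level identities hold in the natural direction of
"replace West's values by East's". Reported tables follow the printed
convention West − East (negative = advantage of the West); the pipeline
flips direction via the exact antisymmetry.

The decomposition consumes unsmoothed annual inputs by default — the
year-by-year table spans the full 1995–2013 range, whereas smoothing would
trim it to 1996–2012. `smooth_decomposition_inputs=True` instead smooths
the age-specific rate and prevalence series with the same 3-year window
before decomposing; both modes are provided because which variant produced
the original published table is not stated.

## Problem sizes and tolerances

Monte-Carlo checks use 200 seeds for full-pipeline share recovery, 500
seeds for sampling/reconstruction unbiasedness (3 standard errors of the
seed mean, on cell-aggregated totals — per-cell bands across hundreds of
cells would fail by multiplicity alone), and ≥1,000 random instances for
oracle equivalence. The unbiasedness scenarios use a compact two-year world
(N = 100,000 per cell) since sampling properties do not depend on the grid
size; pipeline-level checks run the full baseline scenario.

## Known limitations

* Parameters are constant over calendar time unless a frame-valued spec is
  supplied; no built-in trend or reform-shock machinery.
* Stochastic totals condition on fixed $N$; only DP membership, deaths and
  sampling are random.
* The negative-cell guard in `derive_nondp` means extremely small margins
  (DP ≈ total) can make stochastic runs fail loudly rather than degrade
  gracefully — intended behaviour, but worth knowing when designing
  scenarios with prevalence near 1.
* Life-table quantities (life expectancy), cause-of-death splits, and
  survival regression on transition to DP are out of scope.
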