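# Methods

## The model

`thrombosim` implements a mechanistic, individualized ordinary-differential-
equation model of human thrombopoiesis under multi-cyclic cytotoxic
chemotherapy.  Bone-marrow thrombopoiesis is represented as a chain of
compartments — active and dormant stem cells, a transit chain of
megakaryocyte progenitors (CM), ploidy-resolved megakaryocytes (MKC) with
active and dormant states, a proplatelet stage, and age-structured spleen and
circulating platelet pools — coupled to thrombopoietin (TPO) kinetics,
osteoblast/osteoclast dynamics and the pharmacokinetics/-dynamics of four
cytotoxic drugs.  All cell pools are integrated in units normalized to their
steady state; the observable scales (platelets in 1e9/L, TPO in pg/mL) enter
only through two individual scale parameters.

The main mechanisms, and the assumptions behind them:

* **Regulation kernels.** Every TPO-dependent feedback goes through a common
  bounded sigmoid ("Z") kernel parameterized by the minimal, normal and
  maximal value of the regulated quantity, a steepness exponent, and a
  saturation bound on the transformed argument
  (`exp(lim_sig·tanh(ln x / lim_sig))`) that behaves like the identity near
  the steady state and caps the exponent for extreme signals.  Decreasing
  regulations evaluate the increasing kernel at `1/x`, which keeps the
  `y_min < y_nor < y_max` ordering uniform.
* **Stem cells.** An active pool cycles every 24 h with self-renewal
  probability `p = 0.1·tanh(c^-b - c^b) + 0.5` of the relative active count
  `c`; `p = 0.5` at baseline and `p ∈ (0.4, 0.6)`.  Megakaryocyte mass
  (`CTTB_rel`) promotes transition into a dormant pool; the ratio of dormant
  to active cells at baseline, `rk_dorm_act ∈ [20, 209]`, fixes the
  reactivation rate.  Dormancy entry is limited by the bone-marrow capacity
  and dormant cells are protected from chemotherapy; they die only when
  supporting osteoblasts are lost.
* **Bone-marrow capacity.** Osteoblast/osteoclast counts follow a power-law
  interaction model (exponents +0.5/-0.5, four rate constants taken from the
  bone-remodelling literature, converted to hours).  Chemotherapy removes
  both cell types through a first-order delayed loss state (relaxation ~3
  days) driven by a toxicity proportional to the CM toxicity.  The relative
  osteoblast count is the capacity for dormant stem cells and dormant MKC —
  the mechanistic carrier of cumulative, long-term toxicity.
* **Progenitors (CM).** Seven 15-hour sub-compartments; the first four
  amplify TPO-dependently (per-stage amplification `Z(delayed TPO)` with
  normal value 2), the rest amplify by exactly 2.  Per-stage amplification
  `A` is split `sqrt(A)` at influx and efflux, preserving total
  amplification and steady-state fluxes.
* **Megakaryocytes.** Ploidy classes 2–128 mature in parallel with a 15-hour
  endomitosis stage.  Ploidies 2–4 neither form proplatelets nor go dormant.
  Ploidies 8–32 have three fates: proplatelet formation (probability `p1`,
  suppressed by delayed TPO), endomitosis to the next ploidy
  (`(1-p1)·p2`), or dormancy (`(1-p1)·(1-p2)` over a 12-hour transit, scaled
  by capacity).  Ploidy 64 advances to 128 only at elevated TPO; ploidy 128
  only forms proplatelets.  Dormant cells reactivate at a rate inversely
  proportional to capacity and regulated by delayed TPO, with a longer delay
  for ploidy 32.
* **Proplatelets and platelets.** Proplatelet-committed MKC contribute
  platelet-equivalents proportional to half their ploidy (`2^(k-1)`); the
  committed flux, not the whole active pool, feeds the proplatelet
  compartment; writing the fate probability into the influx keeps the
  balance consistent with the fate algebra and is what makes TPO's
  suppression of proplatelet formation produce the observed transient
  platelet dip.
  `npt_pcu ∈ [125, 1000]` platelets arise per ploidy unit.  Platelets age
  through 7 spleen and 7 circulating classes (Erlang chain, total transit
  `t_pl`); half of the production is first sequestered in the spleen and
  released age-dependently (`k_i ∝ (i/n)^2`).  On top of senescence, a
  quasi-constant consumption `k_s·Circ^4/(Circ^4 + h_s^4)` (fixed vessel
  support) makes survival non-exponential and shortens half-lives in
  thrombocytopenic subjects, whose smaller production shares the same
  absolute consumption.
* **TPO.** Constant production (fixed by the steady-state condition, not a
  free parameter), unspecific first-order degradation, and receptor-mediated
  Michaelis–Menten consumption by circulating and spleen platelets, MKC
  (weight proportional to ploidy) and proplatelets.  Pegylated TPO enters
  through a two-compartment subcutaneous absorption path with a direct-entry
  fraction; the depot drains through both routes so the absorbed mass equals
  the dose.  Both TPO species share one degradation law, apportioned by
  abundance.  Two first-order lag states provide the delayed TPO signals.
* **Chemotherapy.** Cyclophosphamide (1-compartment), doxorubicin and
  etoposide (2-compartment) and procarbazine (oral absorption; its
  pharmacodynamic effect is fixed to zero as unidentifiable) with
  concentrations normalized per standard dose, so toxicity coefficients read
  as per-standard-dose effects.  Compartment toxicities are dose-linear and
  additive across drugs (no interactions).  Parsimony ties: stem = CM
  toxicity, cyclophosphamide = doxorubicin, tied MKC transition
  probabilities for ploidies 8/16/32, tied reactivation times for 16/32.

## Parameters

The registry (`thrombosim.registry`) carries ~90 named parameters with unit,
status, bounds, tie-group and note; the default configuration exposes 22
population-estimated and 9 patient-level (IIV) parameters — 31 estimated in
total — with the printed structural constants (24 h stem cycle, 15 h CM/MKC
stages, 12 h dormancy transit, `p_delta = 0.1`) fixed.  The IIV set is
`pd_cyclo, d_osteo_loss, b_s_act, r_pl_0_nor, rk_dorm_act, npt_pcu, t_pl,
k_s_rel` plus `r_tpo_nor_0` when TPO concentrations are fitted.

The clinical data behind this model class are not publicly deposited, and
many kinetic constants have never been measured directly.  All defaults were
therefore chosen once, from the documented structural constraints plus a
one-time calibration to the qualitative response patterns reported in the
clinical literature, and are not data-fitted constants:

* The baseline MKC transition parameters (`p1 = 0.216`, `p2 = 0.204`,
  `t_pp = 16.3 h`, reactivation times 1.9 h / 97.7 h) come from calibrating
  the steady ploidy distribution to the published baseline table
  (19/47/21/0.6 % for ploidies 8/16/32/64, residual mass split over 2 and
  4); `calibrate_ploidy_baseline` reproduces this from arbitrary starting
  points to ~1e-6.
* Toxicity and feedback defaults (`pd_cyclo = 0.3` per standard dose,
  immature/mature MKC toxicities 0.2/0.1, `c_pd_osteo = 0.008`,
  `d_osteo_loss = 1.0`, `b_s_act = 0.4`, CM amplification range
  [1.05, 2.2]) reproduce: a first-cycle platelet nadir at days 7–14 followed
  by rebound; strictly declining per-cycle nadirs, strictly rising
  cycle-mean TPO and a mildest first cycle over six 14- or 21-day cycles;
  and a TPO peak near day 2 after a 3 µg/kg peg-TPO dose returning to
  baseline by days 7–9 with a biphasic platelet response.  The amplification
  ceiling of 2.2 (rather than a larger span) is what damps the
  rebound-driven oscillation enough for the cumulative decline to be
  monotone.
* Platelet-survival defaults (`t_pl = 240 h`, `k_s_rel = 0.25`,
  `h_s_rel = 0.04`) put the normal labeled-platelet half-life at 3.8 days
  (within the 3.5–4.5-day band) and give strictly shorter, more concave
  survival at 60 and 25 ×1e9/L.
* PK rate constants are structural placeholders with literature-plausible
  half-lives; because concentrations are dose-normalized and multiply fitted
  toxicity coefficients, their absolute scale is deliberately confounded
  into `pd` and never interpreted on its own.

Two behaviours of the default configuration are worth knowing.  The
simulated MKC count rises only ~1.3-fold after peg-TPO (healthy subjects
show a ~2-fold peak); reduced TPO responsiveness of this kind is also what
fitted elderly-patient parameter sets exhibit.  And recovery of the stem pool
after dormant-cell loss is slow by construction — pool regrowth is capped at
`(2p-1)/T_cycle ≤ 0.2/24 h⁻¹` of the active pool — so heavy osteoblast
damage leaves months-long platelet deficits; this is the mechanism behind
cumulative toxicity, not a numerical artifact.

## Steady state and integration

`init_steady_state` back-solves every balance analytically (osteoblast fixed
point; dormant:active ratio; CM/MKC flux chain as the linear fixed point of
the MKC fate algebra; platelet chain by a 1-D root-find of the circulating
total against the consumption term; TPO production from the steady-state
condition, with receptor weights distributed over the pools by configurable
shares).  The residual of the full right-hand side at the constructed state
is at machine precision, and 1000 event-free days drift < 1e-12 relative.

Integration uses `scipy.integrate.solve_ivp` (BDF, rtol 1e-6 / atol 1e-9 in
normalized units), restarted at every therapy event; boluses are state
jumps, infusions piecewise-constant inputs.  The full right-hand side is a
single numba-compiled function over a packed parameter vector; a consistency
test pins it to the composition of the readable per-module functions.
Halving tolerances changes platelet observables by < 0.1 %.  Degenerate
inputs are guarded: a floor of 1e-9 on the osteoblast count inside the
power-law term, 1e-6 on the capacity inside reactivation, and the Hill form
of the consumption term itself guarantees nonnegative platelet counts.

## Estimation

The per-patient fitness combines the patient's own series (Gaussian
likelihood on log observables, residual SD profiled per series) with
"virtual participation" terms that compare the patient's simulated response
to the published population protocols (peg-TPO study, labeled-platelet
survival, pre/post osteoblast counts) against the published means and SDs;
a per-dataset weight controls the balance.  MAP estimation with lognormal
priors is posed as weighted least squares on log residuals (priors as extra
residuals) and solved with trust-region Gauss-Newton on log parameters under
bounds, with seeded multi-starts; a simplex search at the feasible budgets
did not converge on the 8-parameter problem, which is why the least-squares
route was chosen.  Standard errors and correlations come from the `J'J`
covariance scaled by the weighted residual variance, with a vanishing
information diagonal reported as infinite uncertainty rather than hidden.
Parsimony uses `BIC = -2 logL + k ln(n_obs)` with `n_obs` the number of
observation points.  Backward selection of the IIV set evaluates every
single drop per round (ordered by uncertainty) and keeps the best while the
BIC improves; a dropped parameter is fixed at its population value.

## Synthetic data

The clinical and population datasets behind the model are not publicly
deposited, so the `synthetic` module generates all dataset classes with
known ground truth: virtual cohorts (lognormal parameter draws with
documented CVs around the defaults; close-meshed designs with 2–4-day
measurement gaps; 12 % lognormal measurement noise by default, reflecting
residual errors about twice the natural fluctuation of healthy subjects),
and fixed population tables for the peg-TPO study (baseline ploidy table and
day-0/7/11/17 design), labeled-platelet survival (5-day design, half-life
targets) and pre/post osteoblast counts.  Quantities not printed in the
source literature are synthetic stand-ins and carry a `synthetic` flag in
the tables.  What passing tests show is therefore that the *method* recovers
known truth under the stated noise model — not that the defaults reproduce
any particular patient; real data add irregularities (transfusion-record
gaps, G-CSF interactions, infections) that the generator deliberately
omits.

Problem sizes used in the validation suite: parameter recovery uses 20
virtual patients on 4-cycle schedules with the 8-parameter NHL-B-style IIV
set, and backward selection a 3-patient cohort with heterogeneity only in
`pd_cyclo`; both sizes were chosen to exercise the full pipeline at
desk scale.

## Known limitations

* Kinetic constants that were never directly measured ship as calibrated
  stand-ins honoring every documented structural constraint; they are not
  literature-fitted values.
* G-CSF co-medication, drug–drug PK interactions, bleeding/infection-driven
  platelet consumption and granulopoiesis are out of scope.
* The quadratic platelet-loss term of the older survival model is omitted
  (badly identifiable); elimination acts on circulating platelets only.
* The ploidy-64 TPO response is conservative (peak ~1.3 % vs the published
  3.5 %), and full post-therapy recovery of the stem pool takes longer than
  the simulated follow-up windows.
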