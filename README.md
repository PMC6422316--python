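# thrombosim

Mechanistic simulation and individual parameter estimation of human
thrombopoiesis under multi-cyclic chemotherapy.

Thrombocytopenia — a shortage of circulating platelets — is a major
dose-limiting side effect of intensive chemotherapy regimens such as
CHOP/CHOEP, and its severity varies widely between patients.  `thrombosim`
is for modellers and pharmacometricians who want to simulate and fit
individual platelet time courses mechanistically rather than with
semi-mechanistic transit models.  It implements:

* a stiff ODE model of bone-marrow thrombopoiesis: active/dormant stem
  cells (dormant:active ratio `rk ∈ [20, 209]`, self-renewal
  `p = 0.1·tanh(c^{-b} − c^{b}) + 0.5`), a TPO-regulated megakaryocyte
  progenitor chain, megakaryocytes resolved by ploidy 2N–128N with
  active/dormant states and TPO-dependent fate probabilities, proplatelets,
  and age-structured spleen/circulating platelets with a quasi-constant
  consumption term `k_s·Circ^p/(Circ^p + h_s^p)` that makes platelet
  survival non-exponential;
* osteoblast/osteoclast dynamics (power-law remodelling model) that set the
  bone-marrow capacity for dormant cells — the carrier of cumulative,
  long-term chemotherapy toxicity;
* TPO production/consumption with Michaelis–Menten receptor kinetics and a
  subcutaneous absorption model for pegylated TPO injections;
* PK/PD of cyclophosphamide, doxorubicin, etoposide and procarbazine with
  compartment toxicities `Ψ_Y = Σ_X pd_{X,Y}·C_{X,1}`;
* individual parameter estimation ("virtual participation"): per-patient
  MAP fits that combine the patient's own series with published population
  datasets, BIC-based parsimony and backward selection of the
  heterogeneous-parameter set;
* a synthetic-data module generating virtual cohorts and population-style
  fixture tables with known ground truth.

## Worked example

Simulate six cycles of CHOP-14 for the default (population-typical) patient
and summarize per-cycle nadirs:

```python
import thrombosim as ts

build = ts.init_steady_state()                      # steady state, 250e9/L
sched = ts.built_in_schedule("CHOP-14", n_cycles=6)
traj  = ts.simulate(build, sched, days=112)
print(ts.cycle_nadirs(traj, sched.cycle_starts).round(2).to_string(index=False))
```

```
 cycle  start_day  nadir  grade  mean_tpo_rel
     1        0.0 216.55      0          1.33
     2       14.0 168.58      0          1.46
     3       28.0 129.22      0          1.75
     4       42.0  90.92      1          2.00
     5       56.0  57.03      2          2.25
     6       70.0  29.18      3          2.05
```

The per-cycle platelet nadir (in 1e9/L) declines cycle over cycle while the
cycle-averaged relative TPO rises — the cumulative-toxicity signature driven
by chemotherapy-induced osteoblast loss; by cycle 6 the default patient
reaches CTCAE grade 3 (nadir below 50e9/L).  The last row's TPO average dips
only because its window extends over the 42-day follow-up, where TPO relaxes
as platelets recover.

Compare timings of the last chemotherapy cycle:

```bash
thrombosim scenario --schedule CHOEP-21 --cycles 6 --shift-set -5,0,5,10,omit
```

```
shift    -5: nadir    10.6  grade 4
shift     0: nadir    15.1  grade 4
shift     5: nadir    21.4  grade 4
shift    10: nadir    20.0  grade 4
shift  omit: nadir    32.7  grade 3
```

Omitting the last cycle always yields the highest post-therapy nadir, and an
earlier start of the last cycle (−5 days) deepens it — the nadir (1e9/L,
minimum from the penultimate cycle through a 90-day follow-up) shifts by how
the cycle timing interferes with the recovery oscillation.

Other entry points: `thrombosim simulate` (trajectory CSV),
`thrombosim synth` (virtual cohorts / fixture tables), `thrombosim fit`
(per-patient MAP fit from an observations CSV), `thrombosim audit`
(parameter-registry constraint check), and the library API
(`ts.fit_individual`, `ts.backward_select_iiv`,
`ts.generate_virtual_cohort`, `ts.calibrate_ploidy_baseline`, ...).

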