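"""Individual parameter estimation with population priors.

The estimation scheme combines, in one fitness function per patient,

* the patient's own time series (platelets, TPO), with residual standard
  deviations profiled out per series on the log scale, and
* "virtual participation" terms: the patient's simulated response to the
  published population protocols (peg-TPO stimulation, labeled-platelet
  survival, pre/post-chemotherapy osteoblast counts) compared against the
  published means with their published standard deviations.

Only a small subset of parameters (the IIV set) is estimated per patient;
the rest stay at their population values.  Estimation maximizes the
log-posterior (log-likelihood plus Gaussian prior on log-parameters): the
problem is posed as weighted least squares on log-residuals (observations
and priors) and solved by trust-region Gauss-Newton on log-parameters, with
seeded multi-starts; residual standard deviations are profiled on the log
scale afterwards, and standard errors and correlations come from the
Gauss-Newton Hessian (J'J) at the optimum.  Model parsimony is judged by
the Bayesian Information Criterion, and backward selection drops IIV
assumptions of the most uncertain parameters while the BIC improves.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .platelets import (PlateletParams, simulate_labeled_transfusion,
                        steady_state_chain)
from .registry import ModelParameters
from .schedules import TherapySchedule
from .simulator import ModelBuild, Trajectory, init_steady_state, simulate

__all__ = ["ObservationSeries", "FitDataset", "Prior", "FitResult",
           "log_likelihood", "fit_individual", "bic", "backward_select_iiv",
           "DEFAULT_IIV_NHLB", "DEFAULT_IIV_ENGEL"]

#: IIV parameter sets: 9 for fits that include TPO concentration data
#: (Engel-style) and 8 once the TPO scale is dropped (NHL-B-style).
DEFAULT_IIV_NHLB = ("pd_cyclo", "d_osteo_loss", "b_s_act", "r_pl_0_nor",
                    "rk_dorm_act", "npt_pcu", "t_pl", "k_s_rel")
DEFAULT_IIV_ENGEL = DEFAULT_IIV_NHLB + ("r_tpo_nor_0",)

_LOG2PI = math.log(2.0 * math.pi)


@dataclass
class ObservationSeries:
    """Timestamped observations of one observable for one patient/dataset."""

    dataset_id: str
    patient_id: str
    observable: str  # platelets | tpo_rel | tpo_total | mkc_count_rel |
    #                  ploidy_fraction_<k> | osteoblast_rel | labeled_halflife_days
    times: np.ndarray          # days
    values: np.ndarray
    sds: np.ndarray | None = None  # natural-scale SDs (population data)
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if np.any(np.diff(self.times) < 0):
            raise ValueError("observation times must be sorted")
        if self.sds is not None:
            self.sds = np.asarray(self.sds, dtype=float)
            if np.any(self.sds <= 0):
                raise ValueError("SDs must be positive where present")

    @property
    def n(self) -> int:
        return self.values.size


@dataclass
class FitDataset:
    """A protocol (schedule + horizon) with its observation series.

    ``kind='timecourse'`` simulates the schedule and reads observables off
    the trajectory; ``kind='hanson'`` evaluates labeled-platelet half-lives
    for subjects at the counts given in each series' ``meta['count']``.
    ``weight`` scales the dataset's log-likelihood contribution (population
    weight knob of the virtual-participation scheme).
    """

    schedule: TherapySchedule
    series: list
    days: float = 100.0
    kind: str = "timecourse"
    weight: float = 1.0


@dataclass
class Prior:
    """Gaussian prior on the natural log of one parameter."""

    name: str
    log_location: float
    log_scale: float

    def __post_init__(self):
        if self.log_scale <= 0:
            raise ValueError("prior scale must be positive")

    @classmethod
    def from_samples(cls, name: str, samples) -> "Prior":
        logs = np.log(np.asarray(samples, dtype=float))
        scale = float(np.std(logs, ddof=1))
        return cls(name, float(np.mean(logs)), max(scale, 1e-3))

    def logpdf(self, value: float) -> float:
        z = (math.log(value) - self.log_location) / self.log_scale
        return -0.5 * (z * z + _LOG2PI) - math.log(self.log_scale)


@dataclass
class FitResult:
    estimates: dict
    rel_se: dict
    correlation: np.ndarray
    logL: float
    bic: float
    residual_cv: dict
    n_obs: int
    n_iiv: int
    converged: bool
    n_evals: int = 0
    trace: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# prediction
# ---------------------------------------------------------------------------

def _predict_timecourse(build: ModelBuild, traj: Trajectory,
                        series: ObservationSeries) -> np.ndarray:
    obs = series.observable
    if obs == "platelets":
        return traj.value_at(series.times, "platelets")
    if obs == "tpo_rel":
        return traj.value_at(series.times, "tpo_rel")
    if obs == "tpo_total":
        return traj.value_at(series.times, "tpo_rel") * build.params["r_tpo_nor_0"]
    if obs == "mkc_count_rel":
        return traj.value_at(series.times, "mkc_total_rel")
    if obs == "osteoblast_rel":
        return traj.value_at(series.times, "c_ob_rel")
    if obs.startswith("ploidy_fraction_"):
        ploidy = obs.removeprefix("ploidy_fraction_")
        col = f"ploidy_{ploidy}"
        frac = build.ploidy_fractions(traj.y)[col].to_numpy()
        return np.interp(series.times * 24.0, traj.t_h, frac)
    raise KeyError(f"unknown observable {obs!r}")


def labeled_survival_for_count(build: ModelBuild, count: float,
                               followup_days: float = 12.0):
    """Labeled-platelet survival for a subject at steady-state ``count``.

    The subject shares the reference consumption parameters (absolute
    quasi-constant consumption and half-effect count) but has platelet
    production scaled so that the circulating steady state equals ``count``
    (1e9/L) — the model's reading of bone-marrow-failure thrombocytopenia.
    """
    params = build.params
    pp_nor = build.norms[build.layout["PP"]]
    production_nor = params["npt_pcu"] * pp_nor / params["t_pp"]
    import thrombosim._core as _core
    plt = PlateletParams.from_registry(params, k_s=build.theta[_core.K_S],
                                       h_s=build.theta[_core.H_S])
    target = count / build.plt_scale

    def gap(scale):
        return float(np.sum(steady_state_chain(scale * production_nor,
                                               plt).plc)) - target

    scale = brentq(gap, 1e-6, 4.0, xtol=1e-10)
    chain = steady_state_chain(scale * production_nor, plt)
    grid = np.linspace(0.0, 24.0 * followup_days, int(followup_days * 12) + 1)
    return simulate_labeled_transfusion(chain, 1e-3 * target, plt, grid,
                                        scale * production_nor)


def _predict_hanson(build: ModelBuild, series: ObservationSeries) -> np.ndarray:
    """Labeled-platelet half-life (days) for a subject at a given count."""
    curve = labeled_survival_for_count(build, float(series.meta["count"]))
    half = curve.half_life_h
    if half is None:
        half = curve.time_h[-1]
    return np.full(series.times.shape, half / 24.0)


def predict_dataset(params: ModelParameters, dataset: FitDataset,
                    rtol: float = 1e-5, atol: float = 1e-8) -> list:
    """Model predictions for every series of a dataset (shared simulation)."""
    build = init_steady_state(params, check_residual=False)
    if dataset.kind == "hanson":
        return [_predict_hanson(build, s) for s in dataset.series]
    obs_days = np.unique(np.concatenate([s.times for s in dataset.series]))
    traj = simulate(build, dataset.schedule, days=dataset.days,
                    rtol=rtol, atol=atol, points_per_day=1,
                    extra_days=obs_days)
    return [_predict_timecourse(build, traj, s) for s in dataset.series]


# ---------------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------------

def _series_loglik(pred: np.ndarray, series: ObservationSeries):
    """Gaussian log-likelihood on log observables.

    Series with published SDs use them (converted to log scale relative to
    the mean); series without SDs have their residual SD profiled out
    (maximum-likelihood estimate), which is reported as the residual CV.
    """
    eps = 1e-12
    r = np.log(np.maximum(pred, eps)) - np.log(np.maximum(series.values, eps))
    n = series.n
    if series.sds is not None:
        sig = series.sds / np.maximum(series.values, eps)  # approx log-scale SD
        ll = float(-0.5 * np.sum((r / sig) ** 2 + 2.0 * np.log(sig) + _LOG2PI))
        return ll, float(np.sqrt(np.mean((r / 1.0) ** 2)))
    sigma2 = max(float(np.mean(r * r)), 1e-12)
    ll = -0.5 * n * (math.log(sigma2) + _LOG2PI + 1.0)
    return ll, math.sqrt(sigma2)


def log_likelihood(params: ModelParameters, datasets: list,
                   weights: dict | None = None, rtol: float = 1e-5):
    """Total log-likelihood over datasets; returns ``(logL, residual_cv)``.

    ``weights`` optionally overrides per-dataset weights by ``dataset_id``
    prefix of the first series.
    """
    total = 0.0
    residual_cv = {}
    for ds in datasets:
        try:
            preds = predict_dataset(params, ds, rtol=rtol)
        except (RuntimeError, ValueError) as err:
            return -np.inf, {"error": str(err)}
        w = ds.weight
        if weights and ds.series and ds.series[0].dataset_id in weights:
            w = weights[ds.series[0].dataset_id]
        for s, pred in zip(ds.series, preds):
            ll, cv = _series_loglik(pred, s)
            total += w * ll
            residual_cv[f"{s.dataset_id}:{s.patient_id}:{s.observable}"] = cv
    return total, residual_cv


def bic(logL: float, k: int, n_obs: int) -> float:
    """Bayesian Information Criterion ``-2 logL + k ln(n)``."""
    if k < 0 or n_obs < 1:
        raise ValueError("need k >= 0 and n_obs >= 1")
    return -2.0 * logL + k * math.log(n_obs)


# ---------------------------------------------------------------------------
# individual fitting
# ---------------------------------------------------------------------------

def fit_individual(data: list, fixed_population_params: ModelParameters,
                   priors: list | None = None, iiv_names=DEFAULT_IIV_NHLB,
                   seeds=(1,), maxfev: int = 400, rtol: float = 1e-5,
                   compute_se: bool = True, assumed_cv: float = 0.12) -> FitResult:
    """MAP estimate of the IIV parameters of one patient.

    ``data`` is a list of :class:`FitDataset`; ``fixed_population_params``
    provides every non-IIV value.  The log-posterior is maximized as a
    weighted nonlinear least-squares problem over log-residuals: series
    without published SDs are weighted by the working residual CV
    ``assumed_cv`` (the final residual SDs are profiled afterwards for
    reporting), series with SDs by their log-scale SDs, and each prior adds
    one Gaussian residual.  The first start is the prior location; further
    seeds add log-normal jitters.  Deterministic for a fixed seed list.
    """
    from scipy.optimize import least_squares

    iiv_names = list(iiv_names)
    priors = list(priors or [])
    prior_map = {p.name: p for p in priors}
    base = fixed_population_params.copy()
    k = len(iiv_names)
    bounds_lo = np.empty(k)
    bounds_hi = np.empty(k)
    x0 = np.empty(k)
    for i, name in enumerate(iiv_names):
        par = base.param(name)
        lo, hi = par.bounds if par.bounds else (par.value / 100, par.value * 100)
        bounds_lo[i], bounds_hi[i] = math.log(lo), math.log(hi)
        x0[i] = (prior_map[name].log_location if name in prior_map
                 else math.log(base[name]))
        x0[i] = np.clip(x0[i], bounds_lo[i] + 1e-6, bounds_hi[i] - 1e-6)

    n_evals = 0
    eps = 1e-12

    def trial_params(x):
        trial = base.copy()
        for name, xi in zip(iiv_names, x):
            trial.set(name, math.exp(xi))
        return trial

    def residual_vector(x):
        nonlocal n_evals
        n_evals += 1
        trial = trial_params(x)
        res = []
        try:
            for ds in data:
                preds = predict_dataset(trial, ds, rtol=rtol)
                sw = math.sqrt(ds.weight)
                for s, pred in zip(ds.series, preds):
                    r = (np.log(np.maximum(pred, eps))
                         - np.log(np.maximum(s.values, eps)))
                    if s.sds is not None:
                        sig = s.sds / np.maximum(s.values, eps)
                    else:
                        sig = assumed_cv
                    res.append(sw * r / sig)
        except (RuntimeError, ValueError):
            n_res = sum(s.n for ds in data for s in ds.series) + len(prior_map)
            return np.full(n_res, 1e3)
        for name, xi in zip(iiv_names, x):
            if name in prior_map:
                pr = prior_map[name]
                res.append(np.array([(xi - pr.log_location) / pr.log_scale]))
        return np.concatenate(res)

    best = None
    for s_i, seed in enumerate(seeds):
        rng = np.random.default_rng(int(seed))
        start = x0.copy()
        if s_i > 0:  # first start is the prior location itself
            start = np.clip(x0 + rng.normal(0.0, 0.2, size=k),
                            bounds_lo + 1e-6, bounds_hi - 1e-6)
        sol = least_squares(residual_vector, start, method="trf",
                            bounds=(bounds_lo, bounds_hi), diff_step=0.02,
                            max_nfev=maxfev, xtol=1e-8, ftol=1e-8)
        if best is None or sol.cost < best.cost:
            best = sol
    x_hat = best.x

    # final likelihood with profiled residual SDs, for reporting and BIC
    final = trial_params(x_hat)
    logL, residual_cv = log_likelihood(final, data, rtol=rtol)
    n_obs = sum(s.n for ds in data for s in ds.series)

    rel_se = {name: float("nan") for name in iiv_names}
    corr = np.full((k, k), np.nan)
    if compute_se and k > 0:
        J = best.jac
        # scale by the weighted residual variance (accounts for residual
        # misfit beyond the working CV, as in standard WLS practice)
        dof = max(J.shape[0] - k, 1)
        s2 = max(2.0 * best.cost / dof, 1.0)
        info = J.T @ J
        try:
            cov = s2 * np.linalg.pinv(info)
            diag = np.clip(np.diag(cov), 1e-12, None)
            se = np.sqrt(diag)
            # a vanishing information diagonal means the data do not
            # constrain the parameter at all: report it, don't hide it
            se[np.diag(info) < 1e-10] = np.inf
            corr = np.clip(cov / np.outer(se, se), -1.0, 1.0)
            rel_se = {name: float(se[i]) for i, name in enumerate(iiv_names)}
        except np.linalg.LinAlgError:
            pass

    return FitResult(
        estimates={name: float(math.exp(xi))
                   for name, xi in zip(iiv_names, x_hat)},
        rel_se=rel_se, correlation=corr, logL=float(logL),
        bic=bic(logL, k, max(n_obs, 1)), residual_cv=residual_cv,
        n_obs=n_obs, n_iiv=k, converged=bool(best.status > 0),
        n_evals=n_evals)


# ---------------------------------------------------------------------------
# backward selection of the IIV set
# ---------------------------------------------------------------------------

def backward_select_iiv(candidate_params, patient_datasets: list,
                        population_params: ModelParameters,
                        priors: list | None = None, maxfev: int = 120,
                        rtol: float = 1e-4):
    """Greedy backward selection of the IIV parameter set.

    Starting from all candidates, repeatedly drops the parameter with the
    highest mean relative standard error (fixing it at its population value)
    while the cohort BIC decreases.  ``patient_datasets`` is a list of
    per-patient dataset lists (at least two patients).  Returns
    ``(selected, trace)`` with one trace row per evaluated configuration.
    """
    if len(patient_datasets) < 2:
        raise ValueError("backward selection needs at least two patients")
    current = list(candidate_params)
    n_obs = sum(s.n for data in patient_datasets
                for ds in data for s in ds.series)

    def evaluate(iiv):
        total_ll = 0.0
        ses = {name: [] for name in iiv}
        for data in patient_datasets:
            if iiv:
                fr = fit_individual(data, population_params, priors,
                                    iiv_names=iiv, maxfev=maxfev, rtol=rtol)
                total_ll += fr.logL
                for name in iiv:
                    ses[name].append(fr.rel_se[name])
            else:
                ll, _ = log_likelihood(population_params, data, rtol=rtol)
                total_ll += ll
        k = len(iiv) * len(patient_datasets)
        return total_ll, bic(total_ll, k, n_obs), {
            name: float(np.nanmean(v)) for name, v in ses.items()}

    trace = []
    ll, b, ses = evaluate(current)
    trace.append({"iiv": tuple(current), "logL": ll, "bic": b,
                  "rel_se": dict(ses)})
    while current:
        # candidates ordered by decreasing uncertainty; every single-drop is
        # evaluated and the one with the lowest BIC is taken (standard
        # backward elimination; the SE ranking orders the evaluations)
        order = sorted(current, key=lambda name: -(
            ses.get(name, np.inf) if np.isfinite(ses.get(name, np.inf))
            else np.inf))
        best_drop = None
        for drop in order:
            reduced = [name for name in current if name != drop]
            ll_new, b_new, ses_new = evaluate(reduced)
            if best_drop is None or b_new < best_drop[1]:
                best_drop = (reduced, b_new, ll_new, ses_new)
        if best_drop[1] < b:
            current, b, ll, ses = (best_drop[0], best_drop[1], best_drop[2],
                                   best_drop[3])
            trace.append({"iiv": tuple(current), "logL": ll, "bic": b,
                          "rel_se": dict(ses)})
        else:
            break
    return current, trace
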