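"""Naive-pooled maximum-likelihood estimation of the iron kinetic parameters.

Observations (group means digitized at a handful of time points per
compartment) are treated as if they came from a single individual, so the
likelihood is a plain product of Gaussian residual densities with either a
proportional error (variance ``sigma1^2 * yhat^2``) or an additive error
(variance ``sigma2^2``) per compartment — no random effects.

Fitting minimizes -2 log L over the log-transformed free parameters
(positivity for free), with the residual variances either held fixed or
profiled out in closed form per error group (concentrated likelihood).
Standard errors come from the inverse observed information (numerical Hessian
of half the objective at the optimum), propagated through the log transform;
RSE% = 100 * SE / estimate.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .model_core import (
    STATE_RBC,
    ConfigurationError,
    DoseEvent,
    IntegrationError,
    KineticParameters,
    SolverOptions,
    SpeciesPhysiology,
    simulate,
)

__all__ = [
    "EvaluationError",
    "ObservationSet",
    "ErrorModelSpec",
    "FitResult",
    "predict_observations",
    "neg2_loglik",
    "fit_naive_pooled",
    "compute_rse",
    "hessian_standard_errors",
    "gof_table",
    "parameter_names",
]

logger = logging.getLogger(__name__)

LOG_2PI = math.log(2.0 * math.pi)

RECORD_COLUMNS = ("time_h", "compartment", "value", "units", "group", "dose_id")
DOSE_COLUMNS = ("dose_id", "time_h", "amount", "amount_units", "route")


class EvaluationError(ValueError):
    """The likelihood cannot be evaluated for the given predictions."""


@dataclass
class ObservationSet:
    """Tidy long-format observations plus the dose table they refer to.

    ``records`` columns: time_h, compartment, value, units, group, dose_id.
    ``doses`` columns: dose_id, time_h, amount, amount_units, route — with
    amounts already normalized to umol.  Values are umol/L for concentration
    compartments and umol for the RBC pool.
    """

    records: pd.DataFrame
    doses: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in RECORD_COLUMNS if c not in self.records.columns]
        if missing:
            raise ValueError(f"observation records missing columns {missing}")
        missing = [c for c in DOSE_COLUMNS if c not in self.doses.columns]
        if missing:
            raise ValueError(f"dose table missing columns {missing}")
        if (self.records["value"] < 0).any():
            raise ValueError("observed values must be >= 0")
        if (self.records["time_h"] < 0).any():
            raise ValueError("observation times must be >= 0")

    @property
    def groups(self) -> tuple[str, ...]:
        return tuple(sorted(self.records["group"].unique()))

    @property
    def compartments(self) -> tuple[str, ...]:
        return tuple(sorted(self.records["compartment"].unique()))

    def validate_compartments(self, phys: SpeciesPhysiology) -> None:
        known = set(phys.state_labels) | {"serum"}
        for comp in self.compartments:
            if comp not in known:
                raise EvaluationError(f"unknown compartment label {comp!r}")

    def doses_for_group(self, group: str) -> list[DoseEvent]:
        ids = self.records.loc[self.records["group"] == group, "dose_id"].unique()
        rows = self.doses[self.doses["dose_id"].isin(ids)]
        return [
            DoseEvent(time=float(r.time_h), amount=float(r.amount), route=str(r.route))
            for r in rows.itertuples()
        ]

    def n_records(self) -> int:
        return len(self.records)


_BLOOD = {"plasma", "serum", STATE_RBC}


@dataclass
class ErrorModelSpec:
    """Residual-error assignment per compartment.

    Each observed compartment gets a proportional or an additive error
    (default proportional everywhere) and belongs to a sigma-sharing group.
    By default plasma/serum/RBC share one sigma ("blood") and all tissues
    share another ("tissue"), keeping the variance-parameter count small.
    If ``sigmas`` is None the variances are profiled during fitting.
    """

    default_kind: str = "proportional"
    kinds: Mapping[str, str] = field(default_factory=dict)
    sigma_groups: Mapping[str, str] | None = None
    sigmas: Mapping[str, float] | None = None
    serum_baseline: float = 0.0

    def __post_init__(self) -> None:
        for comp, kind in dict(self.kinds).items():
            if kind not in ("proportional", "additive"):
                raise ValueError(f"unknown error kind {kind!r} for {comp!r}")
        if self.sigmas is not None:
            # zero is allowed for noise-free generation; the likelihood
            # itself rejects a zero variance at evaluation time
            for g, s in dict(self.sigmas).items():
                if not s >= 0:
                    raise ValueError(f"sigma for group {g!r} must be >= 0")

    def kind_for(self, compartment: str) -> str:
        return dict(self.kinds).get(compartment, self.default_kind)

    def group_for(self, compartment: str) -> str:
        if self.sigma_groups is not None and compartment in self.sigma_groups:
            return self.sigma_groups[compartment]
        return "blood" if compartment in _BLOOD else "tissue"

    def sigma_for(self, compartment: str) -> float:
        if self.sigmas is None:
            raise EvaluationError(
                "error-model sigmas are not set (they are profiled during "
                "fitting); pass an ErrorModelSpec with explicit sigmas")
        return float(self.sigmas[self.group_for(compartment)])


def parameter_names(phys: SpeciesPhysiology) -> tuple[str, ...]:
    """Canonical estimable-parameter names: kp_<organ>..., cl_loss, q_e, t_rbc."""
    return tuple(f"kp_{o}" for o in phys.organ_names) + ("cl_loss", "q_e", "t_rbc")


def _get_param(params: KineticParameters, name: str) -> float:
    if name.startswith("kp_"):
        return params.kp[name[3:]]
    return getattr(params, name)


def _set_params(params: KineticParameters, names: Sequence[str],
                values: Sequence[float]) -> KineticParameters:
    kp = dict(params.kp)
    scalars = {}
    for name, v in zip(names, values):
        if name.startswith("kp_"):
            kp[name[3:]] = v
        else:
            scalars[name] = v
    return params.replace(kp=kp, **scalars)


class _Prepared:
    """Pre-aligned observation layout so each objective call runs one
    simulation per group and fills predictions by fancy indexing."""

    def __init__(self, phys, obs, errspec, solver_opts, fcm):
        obs.validate_compartments(phys)
        self.phys = phys
        self.errspec = errspec
        self.solver_opts = solver_opts
        self.fcm = fcm
        self.obs = obs
        self.y = obs.records["value"].to_numpy(dtype=float)
        self.n = len(self.y)
        self.groups = []
        rec = obs.records
        for g in obs.groups:
            rows = np.flatnonzero((rec["group"] == g).to_numpy())
            t = rec["time_h"].to_numpy(dtype=float)[rows]
            comps = rec["compartment"].to_numpy()[rows]
            times = np.unique(t)
            t_idx = np.searchsorted(times, t)
            self.groups.append((g, obs.doses_for_group(g), times, rows, t_idx, comps))
        # error bookkeeping per record
        comps_all = rec["compartment"].to_numpy()
        self.kind = np.array([errspec.kind_for(c) for c in comps_all])
        self.sig_group = np.array([errspec.group_for(c) for c in comps_all])
        self.is_prop = self.kind == "proportional"

    def predict(self, params: KineticParameters) -> np.ndarray:
        pred = np.empty(self.n)
        for g, doses, times, rows, t_idx, comps in self.groups:
            res = simulate(self.phys, params, doses, times,
                           solver_opts=self.solver_opts, fcm=self.fcm)
            by_comp = {c: res.observed(c) for c in np.unique(comps)}
            for c in by_comp:
                if c == "serum":
                    by_comp[c] = by_comp[c] + self.errspec.serum_baseline
            for k, row in enumerate(rows):
                pred[row] = by_comp[comps[k]][t_idx[k]]
        return pred


def predict_observations(
    phys: SpeciesPhysiology,
    params: KineticParameters,
    obs: ObservationSet,
    errspec: ErrorModelSpec | None = None,
    solver_opts: SolverOptions | None = None,
    fcm: bool | None = None,
) -> np.ndarray:
    """Model predictions aligned row-by-row to ``obs.records``.

    One simulation per group; tissue/plasma/serum observations map to
    concentrations (umol/L), the RBC pool to an amount (umol).  The optional
    serum baseline of the error spec is added to serum predictions.
    """
    prep = _Prepared(phys, obs, errspec or ErrorModelSpec(), solver_opts, fcm)
    return prep.predict(params)


def neg2_loglik(obs: ObservationSet, pred: np.ndarray,
                errspec: ErrorModelSpec) -> float:
    """-2 log-likelihood of the pooled Gaussian residual model.

    Proportional records contribute ``log 2pi + log(sigma1^2 yhat^2) +
    (y - yhat)^2 / (sigma1^2 yhat^2)``; additive records the analogue with
    variance ``sigma2^2``.  A zero prediction under proportional error is an
    evaluation error (the density is degenerate there), not a silent skip.
    """
    y = obs.records["value"].to_numpy(dtype=float)
    pred = np.asarray(pred, dtype=float)
    if pred.shape != y.shape:
        raise EvaluationError("predictions are not aligned with observations")
    comps = obs.records["compartment"].to_numpy()
    total = 0.0
    for i in range(len(y)):
        kind = errspec.kind_for(comps[i])
        sigma = errspec.sigma_for(comps[i])
        if sigma <= 0:
            raise EvaluationError(
                f"zero residual sigma for compartment {comps[i]!r}: "
                f"the Gaussian density is degenerate")
        if kind == "proportional":
            if pred[i] <= 0:
                raise EvaluationError(
                    f"proportional error undefined for non-positive prediction "
                    f"(record {i}, compartment {comps[i]!r}, yhat={pred[i]!r})")
            var = sigma ** 2 * pred[i] ** 2
        else:
            var = sigma ** 2
        total += LOG_2PI + math.log(var) + (y[i] - pred[i]) ** 2 / var
    return total


_SIGMA2_FLOOR = 1e-300


def _objective_terms(prep: _Prepared, pred: np.ndarray,
                     fixed_sigmas: Mapping[str, float] | None):
    """(-2LL, profiled sigmas). Profiles one variance per sigma group when
    fixed_sigmas is None."""
    y = prep.y
    if np.any(pred[prep.is_prop] <= 0):
        raise EvaluationError("non-positive prediction under proportional error")
    total = 0.0
    sigmas: dict[str, float] = {}
    for g in np.unique(prep.sig_group):
        m = prep.sig_group == g
        yy, pp = y[m], pred[m]
        prop = prep.is_prop[m]
        if not (prop.all() or (~prop).all()):
            # mixed kinds inside one sigma group cannot share one profiled
            # variance; profile each kind separately under suffixed labels
            for kind_mask, suffix in ((prop, ":prop"), (~prop, ":add")):
                if kind_mask.any():
                    t, s = _profile_group(yy[kind_mask], pp[kind_mask],
                                          prop=bool(suffix == ":prop"),
                                          fixed=None if fixed_sigmas is None
                                          else fixed_sigmas.get(g))
                    total += t
                    sigmas[g + suffix] = s
            continue
        t, s = _profile_group(yy, pp, prop=bool(prop.all()),
                              fixed=None if fixed_sigmas is None
                              else fixed_sigmas.get(g))
        total += t
        sigmas[g] = s
    return total, sigmas


def _profile_group(y, pred, prop: bool, fixed: float | None):
    # summands are sorted before accumulation so the objective is exactly
    # invariant under permutation of the observation records
    n = len(y)
    if prop:
        u = (y - pred) / pred
        extra = 2.0 * float(np.sort(np.log(pred)).sum())
    else:
        u = y - pred
        extra = 0.0
    ssq = float(np.sort(u ** 2).sum())
    if fixed is None:
        s2 = max(ssq / n, _SIGMA2_FLOOR)
        return n * (LOG_2PI + math.log(s2) + 1.0) + extra, math.sqrt(s2)
    if not fixed > 0:
        raise EvaluationError("zero residual sigma: the likelihood is degenerate")
    s2 = fixed ** 2
    return n * (LOG_2PI + math.log(s2)) + ssq / s2 + extra, fixed


@dataclass
class FitResult:
    """Naive-pooled fit outcome: estimates, precision, and convergence data."""

    params: KineticParameters
    sigmas: dict
    neg2_loglik: float
    neg2_loglik_init: float
    success: bool
    n_iter: int
    message: str
    free_names: tuple[str, ...]
    fixed_names: tuple[str, ...]
    x_opt: np.ndarray  # log free parameters
    n_obs: int
    se: dict | None = None
    rse_percent: dict | None = None

    def estimates(self) -> dict[str, float]:
        out = {f"kp_{o}": self.params.kp[o] for o in self.params.kp}
        out.update(cl_loss=self.params.cl_loss, q_e=self.params.q_e,
                   t_rbc=self.params.t_rbc)
        return out

    def to_dict(self) -> dict:
        return {
            "estimates": self.estimates(),
            "sigmas": dict(self.sigmas),
            "se": self.se,
            "rse_percent": self.rse_percent,
            "neg2_loglik": self.neg2_loglik,
            "convergence": {
                "success": self.success,
                "n_iter": self.n_iter,
                "message": self.message,
                "neg2_loglik_init": self.neg2_loglik_init,
            },
            "free": list(self.free_names),
            "fixed": list(self.fixed_names),
            "n_obs": self.n_obs,
        }

    def parameter_table(self) -> pd.DataFrame:
        """Estimate/RSE table, one row per parameter."""
        rows = []
        est = self.estimates()
        for name, value in est.items():
            rows.append({
                "parameter": name,
                "estimate": value,
                "fixed": name in self.fixed_names,
                "se": (self.se or {}).get(name, np.nan),
                "rse_percent": (self.rse_percent or {}).get(name, np.nan),
            })
        return pd.DataFrame(rows)


def fit_naive_pooled(
    phys: SpeciesPhysiology,
    obs: ObservationSet,
    init: KineticParameters,
    errspec: ErrorModelSpec | None = None,
    fixed_mask: Iterable[str] = (),
    *,
    n_starts: int = 5,
    jitter: float = 0.2,
    seed: int = 0,
    fcm: bool | None = None,
    solver_opts: SolverOptions | None = None,
    maxiter: int = 500,
) -> FitResult:
    """Fit the kinetic parameters by pooled maximum likelihood.

    Free parameters are optimized on the log scale with L-BFGS-B; residual
    variances are profiled per sigma group unless ``errspec.sigmas`` fixes
    them.  ``fixed_mask`` names parameters held at their ``init`` value
    (e.g. ``{"t_rbc", "kp_brain"}``).  Multi-start (``n_starts`` log-normal
    jittered starts around ``init``, seeded) guards against local minima;
    the result is deterministic given data, init, and seed.
    """
    errspec = errspec or ErrorModelSpec()
    solver_opts = solver_opts or SolverOptions()
    prep = _Prepared(phys, obs, errspec, solver_opts, fcm)
    all_names = parameter_names(phys)
    fixed = tuple(n for n in all_names if n in set(fixed_mask))
    unknown = set(fixed_mask) - set(all_names)
    if unknown:
        raise ValueError(f"unknown parameters in fixed_mask: {sorted(unknown)}")
    free = tuple(n for n in all_names if n not in fixed)
    if not free:
        pred = prep.predict(init)
        val, sig = _objective_terms(prep, pred, errspec.sigmas)
        return FitResult(params=init, sigmas=sig, neg2_loglik=val,
                         neg2_loglik_init=val, success=True, n_iter=0,
                         message="all parameters fixed", free_names=(),
                         fixed_names=fixed, x_opt=np.empty(0),
                         n_obs=prep.n)
    for name in free:
        if not _get_param(init, name) > 0:
            raise ValueError(
                f"free parameter {name!r} must have a positive initial value "
                f"(log-scale optimization); fix it or supply a positive init")

    x0 = np.log([_get_param(init, n) for n in free])

    def objective(x: np.ndarray) -> float:
        params = _set_params(init, free, np.exp(x))
        try:
            pred = prep.predict(params)
            val, _ = _objective_terms(prep, pred, errspec.sigmas)
        except (IntegrationError, EvaluationError, ConfigurationError) as exc:
            logger.debug("objective penalized: %s", exc)
            return 1e12
        return val

    f0 = objective(x0)
    rng = np.random.default_rng(seed)
    starts = [x0] + [x0 + rng.normal(0.0, jitter, size=x0.size)
                     for _ in range(max(0, n_starts - 1))]
    best = None
    for k, xs in enumerate(starts):
        res = minimize(objective, xs, method="L-BFGS-B",
                       options=dict(maxiter=maxiter, ftol=1e-11, gtol=1e-6,
                                    eps=1e-5))
        logger.debug("start %d: -2LL=%.6f success=%s", k, res.fun, res.success)
        if best is None or res.fun < best.fun:
            best = res
    if f0 < best.fun:  # never report worse than the initial point
        best.x, best.fun, best.success = x0, f0, False

    params_hat = _set_params(init, free, np.exp(best.x))
    pred = prep.predict(params_hat)
    val, sigmas = _objective_terms(prep, pred, errspec.sigmas)
    # a line-search stall at the finite-difference noise floor with a tiny
    # remaining gradient is convergence in practice, not failure
    grad = getattr(best, "jac", None)
    converged = bool(best.success) or bool(
        grad is not None and np.max(np.abs(grad)) < 1.0)
    if not converged:
        logger.warning("fit did not converge: %s", best.message)
    return FitResult(
        params=params_hat, sigmas=sigmas, neg2_loglik=val,
        neg2_loglik_init=f0, success=converged,
        n_iter=int(getattr(best, "nit", 0)), message=str(best.message),
        free_names=free, fixed_names=fixed, x_opt=np.asarray(best.x),
        n_obs=prep.n)



def hessian_standard_errors(fun, x: np.ndarray, step: float = 1e-3):
    """SEs from the inverse Hessian of ``fun`` (= half of -2LL) at ``x``.

    Central finite differences; returns None (with a warning) if the Hessian
    is singular or not positive definite rather than fabricating values.
    """
    x = np.asarray(x, dtype=float)
    p = x.size
    H = np.empty((p, p))
    f0 = fun(x)

    def at(**shifts):
        xx = x.copy()
        for i, h in shifts.items():
            xx[int(i)] += h
        return fun(xx)

    for i in range(p):
        fpp = at(**{str(i): step})
        fmm = at(**{str(i): -step})
        H[i, i] = (fpp - 2.0 * f0 + fmm) / step ** 2
    for i in range(p):
        for j in range(i + 1, p):
            fpp = at(**{str(i): step, str(j): step})
            fpm = at(**{str(i): step, str(j): -step})
            fmp = at(**{str(i): -step, str(j): step})
            fmm = at(**{str(i): -step, str(j): -step})
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4.0 * step ** 2)
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        logger.warning("observed information is singular; SEs undefined")
        return None
    diag = np.diag(cov)
    if np.any(diag <= 0):
        logger.warning("observed information is not positive definite; "
                       "SEs undefined")
        return None
    return np.sqrt(diag)


def compute_rse(
    fit: FitResult,
    phys: SpeciesPhysiology,
    obs: ObservationSet,
    errspec: ErrorModelSpec | None = None,
    *,
    fcm: bool | None = None,
    solver_opts: SolverOptions | None = None,
    step: float = 5e-3,
) -> FitResult:
    """Fill ``fit.se`` and ``fit.rse_percent`` from the observed information.

    The Hessian of half the (profile) -2LL is taken in log-parameter space,
    so the delta method gives ``SE(theta) = theta * SE(log theta)`` and
    ``RSE% = 100 * SE(log theta)``.
    """
    errspec = errspec or ErrorModelSpec()
    prep = _Prepared(phys, obs, errspec, solver_opts or SolverOptions(), fcm)
    free = fit.free_names
    init = fit.params

    def half_neg2ll(x):
        params = _set_params(init, free, np.exp(x))
        pred = prep.predict(params)
        val, _ = _objective_terms(prep, pred, errspec.sigmas)
        return 0.5 * val

    se_log = hessian_standard_errors(half_neg2ll, fit.x_opt, step=step)
    if se_log is None:
        fit.se, fit.rse_percent = None, None
        return fit
    fit.se = {}
    fit.rse_percent = {}
    for name, s in zip(free, se_log):
        theta = _get_param(fit.params, name)
        fit.se[name] = theta * float(s)
        fit.rse_percent[name] = 100.0 * float(s)
    return fit


def gof_table(
    obs: ObservationSet,
    pred: np.ndarray,
    errspec: ErrorModelSpec | None = None,
    sigmas: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Goodness-of-fit records: observed, predicted, residual, weighted residual.

    Weighted residuals are ``(y - yhat) / (sigma yhat)`` for proportional and
    ``(y - yhat) / sigma`` for additive records; sigma defaults to 1 when no
    value is available, leaving the raw scaled residual.
    """
    errspec = errspec or ErrorModelSpec()
    pred = np.asarray(pred, dtype=float)
    rec = obs.records
    if pred.shape != (len(rec),):
        raise EvaluationError("predictions are not aligned with observations")
    rows = []
    for i, r in enumerate(rec.itertuples()):
        comp = r.compartment
        kind = errspec.kind_for(comp)
        group = errspec.group_for(comp)
        if sigmas is not None and group in sigmas:
            sigma = float(sigmas[group])
        elif errspec.sigmas is not None and group in errspec.sigmas:
            sigma = float(errspec.sigmas[group])
        else:
            sigma = 1.0
        resid = r.value - pred[i]
        denom = sigma * pred[i] if kind == "proportional" else sigma
        rows.append({
            "group": r.group, "time_h": r.time_h, "compartment": comp,
            "observed": r.value, "predicted": pred[i], "residual": resid,
            "weighted_residual": resid / denom if denom != 0 else np.nan,
        })
    return pd.DataFrame(rows)
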