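"""Whole-body PBPK model of intravenous iron: data types and the linear ODE core.

The body is a set of perfusion-limited organ compartments in parallel between
a single plasma pool and the tissues, plus a circulating red-blood-cell (RBC)
iron pool.  Iron enters each organ at the organ plasma flow ``Q_O * C_P`` and
returns at ``Q_O / KP_O * C_O``, where ``KP_O`` is the steady-state
tissue:plasma partition coefficient.  Three organs are special:

* bone additionally feeds the RBC pool at the erythropoietic utilization rate
  ``Q_E * C_bone`` (iron incorporated into haemoglobin);
* the RBC pool empties into the spleen at ``RBC / T_RBC`` (erythrophagocytosis
  of senescent cells at the end of the RBC lifespan);
* gut and spleen drain portally into the liver rather than back to plasma.

Plasma additionally loses iron irreversibly at the clearance ``CL_loss``
(physiologic exfoliation); the cumulative loss is carried as an explicit sink
state so the system conserves mass exactly.  An optional depot state models an
iron-carbohydrate complex (e.g. ferric carboxymaltose, FCM): the complex is
taken up by splenic macrophages, represented as a depot->spleen flux at the
spleen plasma flow, ``Q_S * A_depot / V_plasma``.

Because every flux is linear in the amounts, the system is ``dA/dt = M A``
with a constant generator matrix ``M`` whose columns sum to zero; two
independent solution paths (adaptive stiff ODE integration and piecewise
matrix exponentials) are provided so each can validate the other.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.integrate import ODEintWarning, odeint
from scipy.linalg import expm

__all__ = [
    "ORGAN_NAMES",
    "PORTAL_ORGANS",
    "STATE_PLASMA",
    "STATE_RBC",
    "STATE_DEPOT",
    "STATE_LOSS",
    "ConfigurationError",
    "IntegrationError",
    "OrganSpec",
    "SpeciesPhysiology",
    "KineticParameters",
    "DoseEvent",
    "ModelState",
    "SimulationResult",
    "SolverOptions",
    "build_rate_matrix",
    "simulate",
    "simulate_matexp",
    "steady_state_ratios",
]

#: canonical organ labels of the whole-body model
ORGAN_NAMES = (
    "brain", "bone", "fat", "gut", "heart", "kidney",
    "liver", "lung", "muscle", "skin", "spleen", "remainder",
)
#: organs whose venous outflow drains portally into the liver
PORTAL_ORGANS = frozenset({"gut", "spleen"})

STATE_PLASMA = "plasma"
STATE_RBC = "rbc"
STATE_DEPOT = "fcm_depot"
STATE_LOSS = "cum_loss"

IV_PLASMA = "iv_plasma"
FCM_DEPOT = "fcm_depot"
DOSE_ROUTES = (IV_PLASMA, FCM_DEPOT)


class ConfigurationError(ValueError):
    """A physiology/parameter configuration is inconsistent or incomplete."""


class IntegrationError(RuntimeError):
    """The ODE solver failed or produced a physically inadmissible state."""


@dataclass(frozen=True)
class OrganSpec:
    """One perfused organ compartment.

    Parameters
    ----------
    name : str
        Compartment label (one of :data:`ORGAN_NAMES`).
    volume : float
        Tissue volume in litres.
    flow : float
        Plasma flow through the organ in L/h.
    drains_to : str
        ``"liver"`` for the portal organs gut and spleen, ``"plasma"`` otherwise.
    """

    name: str
    volume: float
    flow: float
    drains_to: str = ""

    def __post_init__(self) -> None:
        if self.name not in ORGAN_NAMES:
            raise ConfigurationError(f"unknown organ name {self.name!r}")
        if not self.volume > 0:
            raise ConfigurationError(f"{self.name}: volume must be > 0, got {self.volume}")
        if not self.flow > 0:
            raise ConfigurationError(f"{self.name}: flow must be > 0, got {self.flow}")
        expected = "liver" if self.name in PORTAL_ORGANS else "plasma"
        if self.drains_to == "":
            object.__setattr__(self, "drains_to", expected)
        elif self.drains_to != expected:
            raise ConfigurationError(
                f"{self.name} must drain to {expected!r}, got {self.drains_to!r}"
            )


@dataclass(frozen=True)
class SpeciesPhysiology:
    """Physiology of one species: body size, plasma pool, and organ set.

    ``cardiac_output`` is carried as descriptive metadata; mass balance is
    closed over the per-organ flows (plasma outflow is the sum of organ
    inflows), so the model never multiplies cardiac output into a flux.
    """

    species: str
    body_weight: float  # kg
    cardiac_output: float  # L/h
    plasma_volume: float  # L
    organs: tuple[OrganSpec, ...]

    def __post_init__(self) -> None:
        if not self.body_weight > 0 or not self.cardiac_output > 0:
            raise ConfigurationError("body_weight and cardiac_output must be > 0")
        if not self.plasma_volume > 0:
            raise ConfigurationError("plasma_volume must be > 0")
        names = [o.name for o in self.organs]
        if len(set(names)) != len(names):
            raise ConfigurationError(f"duplicate organ names: {names}")
        if STATE_PLASMA in names:
            raise ConfigurationError("plasma is the central pool, not an organ")
        object.__setattr__(self, "organs", tuple(self.organs))

    @property
    def organ_names(self) -> tuple[str, ...]:
        return tuple(o.name for o in self.organs)

    def organ(self, name: str) -> OrganSpec:
        for o in self.organs:
            if o.name == name:
                return o
        raise KeyError(name)

    @property
    def state_labels(self) -> tuple[str, ...]:
        """Ordered labels of the amount vector: plasma, organs, rbc, depot, loss."""
        return (STATE_PLASMA, *self.organ_names, STATE_RBC, STATE_DEPOT, STATE_LOSS)

    def volume_of(self, label: str) -> float | None:
        """Distribution volume of a state, or None for amount-only states."""
        if label == STATE_PLASMA:
            return self.plasma_volume
        if label in (STATE_RBC, STATE_DEPOT, STATE_LOSS):
            return None
        return self.organ(label).volume


@dataclass(frozen=True)
class KineticParameters:
    """Estimated iron kinetic parameters.

    kp : mapping organ name -> tissue:plasma partition coefficient (dimensionless)
    cl_loss : plasma loss clearance, L/h
    q_e : erythropoietic iron utilization rate, L/h
    t_rbc : red-blood-cell lifespan, h
    """

    kp: Mapping[str, float]
    cl_loss: float
    q_e: float
    t_rbc: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "kp", dict(self.kp))
        for name, value in self.kp.items():
            if not value > 0:
                raise ConfigurationError(f"KP[{name}] must be > 0, got {value}")
        if self.cl_loss < 0:
            raise ConfigurationError(f"cl_loss must be >= 0, got {self.cl_loss}")
        if self.q_e < 0:
            raise ConfigurationError(f"q_e must be >= 0, got {self.q_e}")
        if not self.t_rbc > 0:
            raise ConfigurationError(f"t_rbc must be > 0, got {self.t_rbc}")

    def validate_against(self, phys: SpeciesPhysiology) -> None:
        for name in phys.organ_names:
            if name not in self.kp:
                raise ConfigurationError(f"no partition coefficient for organ {name!r}")

    def replace(self, **changes) -> "KineticParameters":
        return replace(self, **changes)

    def to_dict(self) -> dict:
        return {
            "kp": dict(self.kp),
            "cl_loss": self.cl_loss,
            "q_e": self.q_e,
            "t_rbc": self.t_rbc,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "KineticParameters":
        return cls(kp=dict(d["kp"]), cl_loss=float(d["cl_loss"]),
                   q_e=float(d["q_e"]), t_rbc=float(d["t_rbc"]))


@dataclass(frozen=True)
class DoseEvent:
    """A timed iron input: IV bolus to plasma, or charge of the FCM depot."""

    time: float  # h
    amount: float  # umol iron
    route: str = IV_PLASMA

    def __post_init__(self) -> None:
        if self.amount < 0:
            raise ConfigurationError(f"dose amount must be >= 0, got {self.amount}")
        if self.time < 0:
            raise ConfigurationError(f"dose time must be >= 0, got {self.time}")
        if self.route not in DOSE_ROUTES:
            raise ConfigurationError(f"unknown route {self.route!r}; expected {DOSE_ROUTES}")


@dataclass(frozen=True)
class ModelState:
    """The amount vector (umol) at one instant, with its state labels."""

    amounts: np.ndarray
    time: float
    labels: tuple[str, ...]

    def __getitem__(self, label: str) -> float:
        return float(self.amounts[self.labels.index(label)])


@dataclass(frozen=True)
class SolverOptions:
    """Adaptive stiff-solver settings (LSODA).

    Flow/volume ratios in the model span several orders of magnitude, so the
    defaults are tight: rtol 1e-8, atol 1e-12 umol.
    """

    rtol: float = 1e-8
    atol: float = 1e-12
    mxstep: int = 500_000
    mass_balance_rtol: float = 1e-6
    negativity_tol: float = 1e-9  # relative to total dose


@dataclass(frozen=True)
class SimulationResult:
    """Amount and concentration trajectories on an output time grid."""

    times: np.ndarray  # h
    amounts: np.ndarray  # (n_times, n_states), umol
    labels: tuple[str, ...]
    phys: SpeciesPhysiology
    dose_total: float  # umol

    def amount(self, label: str) -> np.ndarray:
        return self.amounts[:, self.labels.index(label)]

    def concentration(self, label: str) -> np.ndarray:
        """Concentration (umol/L) for plasma/organs; amount states have no volume."""
        volume = self.phys.volume_of(label)
        if volume is None:
            raise KeyError(f"{label!r} is an amount state, not a concentration")
        return self.amount(label) / volume

    @property
    def cumulative_loss(self) -> np.ndarray:
        return self.amount(STATE_LOSS)

    def observed(self, compartment: str) -> np.ndarray:
        """Value on the observation scale: concentration, except RBC (amount).

        ``serum`` is an alias for the plasma concentration.
        """
        if compartment == STATE_RBC:
            return self.amount(STATE_RBC)
        if compartment == "serum":
            return self.concentration(STATE_PLASMA)
        return self.concentration(compartment)

    def to_tidy(self):
        """Long-format table: time_h, compartment, amount_umol, conc_umol_per_L."""
        import pandas as pd

        frames = []
        for label in self.labels:
            volume = self.phys.volume_of(label)
            frames.append(pd.DataFrame({
                "time_h": self.times,
                "compartment": label,
                "amount_umol": self.amount(label),
                "conc_umol_per_L": self.amount(label) / volume if volume else np.nan,
            }))
        return pd.concat(frames, ignore_index=True)


def build_rate_matrix(
    phys: SpeciesPhysiology,
    params: KineticParameters,
    fcm: bool = False,
) -> tuple[np.ndarray, tuple[str, ...]]:
    """Assemble the generator matrix M of the linear system dA/dt = M A.

    Every flux enters M twice — negative on the source diagonal, positive on
    the sink row — so each column sums to zero and total mass (including the
    cumulative-loss sink) is conserved identically.  With ``fcm`` the depot
    state feeds the spleen at rate ``Q_spleen / V_plasma``.

    Returns the matrix and the state labels indexing it.
    """
    params.validate_against(phys)
    labels = phys.state_labels
    index = {label: i for i, label in enumerate(labels)}
    n = len(labels)
    M = np.zeros((n, n))
    i_plasma = index[STATE_PLASMA]
    v_plasma = phys.plasma_volume

    def add_flux(src: int, dst: int, rate: float) -> None:
        M[src, src] -= rate
        M[dst, src] += rate

    for organ in phys.organs:
        i_org = index[organ.name]
        # plasma -> organ at the organ plasma flow
        add_flux(i_plasma, i_org, organ.flow / v_plasma)
        # organ -> plasma (or portally to liver) at Q/KP
        add_flux(i_org, index[organ.drains_to],
                 organ.flow / params.kp[organ.name] / organ.volume)

    # the erythropoiesis/recycling loop needs bone (source) and spleen (sink);
    # reduced physiologies without them are allowed as long as the loop is off
    has_bone = "bone" in index
    has_spleen = "spleen" in index
    if params.q_e > 0 and not (has_bone and has_spleen):
        raise ConfigurationError("q_e > 0 requires bone and spleen compartments")
    if has_bone and has_spleen:
        bone = phys.organ("bone")
        add_flux(index["bone"], index[STATE_RBC], params.q_e / bone.volume)
        add_flux(index[STATE_RBC], index["spleen"], 1.0 / params.t_rbc)
    add_flux(i_plasma, index[STATE_LOSS], params.cl_loss / v_plasma)
    if fcm:
        if not has_spleen:
            raise ConfigurationError("the FCM depot requires a spleen compartment")
        add_flux(index[STATE_DEPOT], index["spleen"],
                 phys.organ("spleen").flow / v_plasma)
    return M, labels


def _prepare(phys, params, doses, times, fcm):
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or len(times) == 0:
        raise ValueError("times must be a non-empty 1-D grid")
    if np.any(np.diff(times) < 0) or times[0] < 0:
        raise ValueError("times must be sorted and non-negative")
    doses = sorted(doses, key=lambda d: d.time)
    if fcm is None:
        fcm = any(d.route == FCM_DEPOT for d in doses)
    M, labels = build_rate_matrix(phys, params, fcm=fcm)
    return M, labels, doses, times


def _apply_dose(amounts: np.ndarray, dose: DoseEvent, labels: tuple[str, ...]) -> None:
    target = STATE_PLASMA if dose.route == IV_PLASMA else STATE_DEPOT
    amounts[labels.index(target)] += dose.amount


def _segments(doses: Sequence[DoseEvent], times: np.ndarray):
    """Breakpoints of the piecewise-autonomous solution: dose times then t_end."""
    events = sorted({d.time for d in doses if d.time <= times[-1]})
    return events


def _check_result(amounts, times, doses, opts) -> None:
    dosed = np.array([sum(d.amount for d in doses if d.time <= t) for t in times])
    total = amounts.sum(axis=1)
    scale = max(dosed.max(initial=0.0), 0.0)
    if scale > 0:
        err = np.max(np.abs(total - dosed)) / scale
        if err > opts.mass_balance_rtol:
            raise IntegrationError(f"mass balance violated: relative error {err:.3e}")
        if amounts.min() < -opts.negativity_tol * scale:
            raise IntegrationError(
                f"negative state beyond tolerance: min {amounts.min():.3e} umol"
            )


def _integrate_piecewise(step, phys, params, doses, times, fcm, opts):
    """Shared piecewise-in-time driver; `step` advances a segment of constant M."""
    M, labels, doses, times = _prepare(phys, params, doses, times, fcm)
    n = len(labels)
    out = np.zeros((len(times), n))
    state = np.zeros(n)
    t_now = 0.0
    # output times at a dose instant report the post-dose (0+) state
    breakpoints = _segments(doses, times) + [float(times[-1])]
    pending = list(doses)  # sorted by time; each applied exactly once
    for t_next in breakpoints:
        if t_next > t_now:
            mask = (times > t_now) & (times < t_next)
            inner = times[mask]
            state, captured = step(M, state, t_now, t_next, inner)
            out[mask] = captured
            t_now = t_next
        while pending and pending[0].time == t_now:
            _apply_dose(state, pending.pop(0), labels)
        out[times == t_now] = state
    # times exactly at 0 with no dose there: already zeros in `out`
    _check_result(out, times, doses, opts)
    return out, labels, times, doses


def simulate(
    phys: SpeciesPhysiology,
    params: KineticParameters,
    doses: Iterable[DoseEvent],
    times: Sequence[float],
    solver_opts: SolverOptions | None = None,
    fcm: bool | None = None,
) -> SimulationResult:
    """Integrate the model with an adaptive stiff ODE solver (LSODA).

    Bolus doses are handled by restarting the integration at each dose time
    and adding the dose amount to the target state (plasma or FCM depot).
    Output times that coincide with a dose report the post-dose state.
    ``fcm`` defaults to True whenever any dose uses the depot route.

    Raises
    ------
    IntegrationError
        If the solver fails, mass balance is violated beyond tolerance, or a
        state goes negative beyond tolerance.
    """
    opts = solver_opts or SolverOptions()

    def step(M, state, t0, t1, inner):
        grid = np.concatenate(([t0], inner, [t1]))
        try:
            with warnings.catch_warnings():
                # lsoda grumbles on extreme parameter draws; the mass-balance
                # check below is the authoritative accuracy gate
                warnings.simplefilter("ignore", ODEintWarning)
                sol = odeint(
                    lambda y, t: M @ y, state, grid,
                    Dfun=lambda y, t: M,
                    rtol=opts.rtol, atol=opts.atol, mxstep=opts.mxstep,
                    full_output=False, tfirst=False,
                )
        except Exception as exc:  # pragma: no cover - defensive
            raise IntegrationError(f"ODE integration failed: {exc}") from exc
        if not np.all(np.isfinite(sol)):
            raise IntegrationError("ODE integration produced non-finite values")
        return sol[-1], sol[1:-1]

    out, labels, times, doses = _integrate_piecewise(
        step, phys, params, doses, times, fcm, opts)
    return SimulationResult(times=times, amounts=out, labels=labels, phys=phys,
                            dose_total=sum(d.amount for d in doses))


def simulate_matexp(
    phys: SpeciesPhysiology,
    params: KineticParameters,
    doses: Iterable[DoseEvent],
    times: Sequence[float],
    solver_opts: SolverOptions | None = None,
    fcm: bool | None = None,
) -> SimulationResult:
    """Closed-form solution via piecewise matrix exponentials.

    Between dose events the system is autonomous and linear, so
    ``A(t) = expm(M (t - t0)) A(t0)`` exactly.  This path shares no numerics
    with :func:`simulate` and serves as its independent cross-check.
    """
    opts = solver_opts or SolverOptions()

    def step(M, state, t0, t1, inner):
        captured = np.empty((len(inner), len(state)))
        t_prev, a = t0, state
        for k, t in enumerate(inner):
            a = expm(M * (t - t_prev)) @ a
            captured[k] = a
            t_prev = t
        a = expm(M * (t1 - t_prev)) @ a
        return a, captured

    out, labels, times, doses = _integrate_piecewise(
        step, phys, params, doses, times, fcm, opts)
    return SimulationResult(times=times, amounts=out, labels=labels, phys=phys,
                            dose_total=sum(d.amount for d in doses))


def steady_state_ratios(
    phys: SpeciesPhysiology,
    params: KineticParameters,
) -> dict[str, float]:
    """Analytic stationary tissue:plasma concentration ratios of the closed system.

    Requires ``cl_loss == 0`` (with loss the only stationary point is empty).
    At stationarity each simple organ equilibrates at its partition
    coefficient, ``C_O / C_P = KP_O``.  Bone is shifted below its KP by the
    erythropoietic drain::

        C_B / C_P = Q_B KP_B / (Q_B + KP_B Q_E)

    and the RBC recycling flux ``Q_E C_B`` re-enters through spleen and liver:

        C_S / C_P = KP_S (Q_S + Q_E C_B/C_P) / Q_S
        C_L / C_P = KP_L (Q_L + Q_G + Q_S + Q_E C_B/C_P) / Q_L
    """
    params.validate_against(phys)
    if params.cl_loss != 0:
        raise ValueError("steady-state ratios require cl_loss == 0 (closed system)")
    kp = params.kp
    names = set(phys.organ_names)
    if "bone" in names:
        bone = phys.organ("bone")
        r_bone = bone.flow * kp["bone"] / (bone.flow + kp["bone"] * params.q_e)
    else:
        r_bone = math.nan
    rbc_flux_per_cp = params.q_e * r_bone if params.q_e > 0 else 0.0  # Q_E * C_B / C_P
    ratios: dict[str, float] = {}
    for organ in phys.organs:
        if organ.name == "bone":
            ratios["bone"] = r_bone
        elif organ.name == "spleen":
            ratios["spleen"] = kp["spleen"] * (organ.flow + rbc_flux_per_cp) / organ.flow
        elif organ.name == "liver":
            q_g = phys.organ("gut").flow if "gut" in names else 0.0
            q_s = phys.organ("spleen").flow if "spleen" in names else 0.0
            ratios["liver"] = kp["liver"] * (
                organ.flow + q_g + q_s + rbc_flux_per_cp) / organ.flow
        else:
            ratios[organ.name] = kp[organ.name]
    return ratios
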