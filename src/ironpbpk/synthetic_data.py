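"""Synthetic observation studies with the error structure the fits assume.

Three designs are emulated so every pipeline stage can be exercised without
external data:

* **mouse**: 0.2 umol/kg IV radiotracer bolus in a 25 g mouse, three diet
  states (iron-deficient / adequate / loaded), 13 observed compartments
  (plasma, RBC, 11 tissues) sampled at 15 min, 12 h, 24 h and days 4, 7, 14,
  28;
* **rat**: 30 mg Fe/kg ferric carboxymaltose (FCM, depot route) in a 345 g
  iron-deficient rat, serum plus six tissues;
* **human**: single ascending FCM doses of 100/500/800/1000 mg, serum only.

Noise follows the residual model (proportional by default); negative draws
are redrawn (not truncated) and the redraw count is reported in the manifest.
Rat/human sampling grids are geometric reconstructions (not study-reported).
The seed fully determines the output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .config import MOUSE_DIETS, load_parameters, load_physiology
from .estimation import ErrorModelSpec, ObservationSet
from .model_core import (
    STATE_RBC,
    DoseEvent,
    KineticParameters,
    SolverOptions,
    SpeciesPhysiology,
    simulate,
)
from .units import dose_to_umol

__all__ = [
    "StudyDesign",
    "MOUSE_SAMPLING_TIMES_H",
    "MOUSE_OBSERVED_COMPARTMENTS",
    "RAT_OBSERVED_COMPARTMENTS",
    "generate_mouse_study",
    "generate_rat_study",
    "generate_human_study",
]

#: 15 min, 12 h, 24 h, days 4/7/14/28
MOUSE_SAMPLING_TIMES_H = (0.25, 12.0, 24.0, 96.0, 168.0, 336.0, 672.0)
MOUSE_OBSERVED_COMPARTMENTS = (
    "plasma", "rbc", "brain", "bone", "fat", "gut", "heart",
    "kidney", "liver", "lung", "muscle", "skin", "spleen",
)
RAT_OBSERVED_COMPARTMENTS = ("serum", "bone", "heart", "kidney", "liver",
                             "muscle", "spleen")
HUMAN_DOSES_MG = (100.0, 500.0, 800.0, 1000.0)


def _geometric_grid(t_min: float, t_max: float, n: int) -> tuple[float, ...]:
    return tuple(float(t) for t in np.geomspace(t_min, t_max, n))


#: reconstructed sampling grids (h) for the FCM studies
RAT_SAMPLING_TIMES_H = _geometric_grid(0.25, 72.0, 10)
HUMAN_SAMPLING_TIMES_H = _geometric_grid(0.25, 168.0, 12)


@dataclass(frozen=True)
class StudyDesign:
    """A fully specified synthetic study; the seed determines the output."""

    species: str
    groups: Mapping[str, tuple[KineticParameters, tuple[DoseEvent, ...]]]
    times: tuple[float, ...]
    compartments: tuple[str, ...]
    errspec: ErrorModelSpec
    replicates: int = 1
    mean_data: bool = True
    seed: int = 0
    fcm: bool = False

    def __post_init__(self) -> None:
        times = tuple(float(t) for t in self.times)
        if any(t < 0 for t in times) or list(times) != sorted(times):
            raise ValueError("sampling times must be sorted and non-negative")
        if self.replicates < 1:
            raise ValueError("replicate count must be >= 1")
        object.__setattr__(self, "times", times)


def _noisy(pred: np.ndarray, kind: np.ndarray, sigma: np.ndarray,
           replicates: int, rng: np.random.Generator) -> tuple[np.ndarray, int]:
    """Draw noisy replicates; negative values are redrawn, and the number of
    redraws is returned alongside the values."""
    n = pred.size
    values = np.empty((replicates, n))
    redraws = 0
    for r in range(replicates):
        eps = rng.standard_normal(n)
        v = np.where(kind == "proportional", pred * (1.0 + sigma * eps),
                     pred + sigma * eps)
        bad = (v < 0) & (pred > 0)
        while bad.any():
            redraws += int(bad.sum())
            eps = rng.standard_normal(int(bad.sum()))
            v[bad] = np.where(kind[bad] == "proportional",
                              pred[bad] * (1.0 + sigma[bad] * eps),
                              pred[bad] + sigma[bad] * eps)
            bad = (v < 0) & (pred > 0)
        v[pred == 0] = 0.0
        values[r] = v
    return values, redraws


def generate_study(design: StudyDesign,
                   phys: SpeciesPhysiology,
                   solver_opts: SolverOptions | None = None) -> ObservationSet:
    """Simulate a design and attach residual noise; returns an ObservationSet.

    With ``mean_data`` the noisy replicates are averaged per record (one row
    per group x compartment x time, mirroring digitized group means);
    otherwise every replicate becomes its own row with a ``replicate`` column.
    """
    errspec = design.errspec
    if errspec.sigmas is None:
        raise ValueError("the study design must fix the noise sigmas")
    rng = np.random.default_rng(design.seed)
    rec_frames, dose_rows = [], []
    total_redraws = 0
    times = np.asarray(design.times, dtype=float)
    for group in sorted(design.groups):
        params, doses = design.groups[group]
        dose_id = f"dose_{group}"
        for d in doses:
            dose_rows.append({"dose_id": dose_id, "time_h": d.time,
                              "amount": d.amount, "amount_units": "umol",
                              "route": d.route})
        res = simulate(phys, params, list(doses), times,
                       solver_opts=solver_opts, fcm=design.fcm or None)
        for comp in design.compartments:
            pred = res.observed(comp)
            if comp == "serum":
                pred = pred + errspec.serum_baseline
            kind = np.full(pred.size, errspec.kind_for(comp))
            sigma = np.full(pred.size, errspec.sigma_for(comp))
            values, redraws = _noisy(pred, kind, sigma, design.replicates, rng)
            total_redraws += redraws
            units = "umol" if comp == STATE_RBC else "umol/L"
            if design.mean_data:
                rec_frames.append(pd.DataFrame({
                    "time_h": times, "compartment": comp,
                    "value": values.mean(axis=0), "units": units,
                    "group": group, "dose_id": dose_id,
                }))
            else:
                for r in range(design.replicates):
                    rec_frames.append(pd.DataFrame({
                        "time_h": times, "compartment": comp,
                        "value": values[r], "units": units,
                        "group": group, "dose_id": dose_id,
                        "replicate": r,
                    }))
    records = pd.concat(rec_frames, ignore_index=True)
    n_values = design.replicates * len(times) * len(design.compartments) * len(design.groups)
    manifest = {
        "species": design.species,
        "seed": design.seed,
        "replicates": design.replicates,
        "mean_data": design.mean_data,
        "times_h": list(design.times),
        "compartments": list(design.compartments),
        "groups": sorted(design.groups),
        "noise": {
            "kinds": {c: errspec.kind_for(c) for c in design.compartments},
            "sigmas": {c: errspec.sigma_for(c) for c in design.compartments},
        },
        "redraws": total_redraws,
        "redraw_rate": total_redraws / n_values,
    }
    doses_df = pd.DataFrame(dose_rows).drop_duplicates(ignore_index=True)
    return ObservationSet(records=records, doses=doses_df, metadata=manifest)


def _uniform_errspec(sigma: float, kind: str, serum_baseline: float = 0.0):
    return ErrorModelSpec(default_kind=kind,
                          sigmas={"blood": sigma, "tissue": sigma},
                          serum_baseline=serum_baseline)


def generate_mouse_study(
    params_by_diet: Mapping[str, KineticParameters] | None = None,
    *,
    dose_umol_per_kg: float = 0.2,
    times: Sequence[float] = MOUSE_SAMPLING_TIMES_H,
    compartments: Sequence[str] = MOUSE_OBSERVED_COMPARTMENTS,
    sigma: float = 0.05,
    error_kind: str = "proportional",
    replicates: int = 1,
    mean_data: bool = True,
    seed: int = 0,
    phys: SpeciesPhysiology | None = None,
) -> ObservationSet:
    """Radiotracer bolus study in mice across the three diet states.

    Each diet group is simulated from its parameter preset with a single
    0.2 umol/kg IV bolus at t = 0 and sampled at the 7 standard times across
    the 13 observed compartments (3 x 13 x 7 = 273 records per replicate).
    """
    phys = phys or load_physiology("mouse")
    if params_by_diet is None:
        params_by_diet = {d: load_parameters(f"mouse_{d}") for d in MOUSE_DIETS}
    for diet in params_by_diet:
        if diet not in MOUSE_DIETS:
            raise KeyError(f"unknown diet key {diet!r}; expected one of {MOUSE_DIETS}")
    dose = dose_to_umol(dose_umol_per_kg, "umol/kg", phys.body_weight)
    groups = {diet: (p, (DoseEvent(time=0.0, amount=dose, route="iv_plasma"),))
              for diet, p in params_by_diet.items()}
    design = StudyDesign(
        species="mouse", groups=groups, times=tuple(times),
        compartments=tuple(compartments),
        errspec=_uniform_errspec(sigma, error_kind),
        replicates=replicates, mean_data=mean_data, seed=seed, fcm=False)
    return generate_study(design, phys)


def generate_rat_study(
    params: KineticParameters | None = None,
    *,
    dose_mg_per_kg: float = 30.0,
    times: Sequence[float] = RAT_SAMPLING_TIMES_H,
    compartments: Sequence[str] = RAT_OBSERVED_COMPARTMENTS,
    sigma: float = 0.05,
    error_kind: str = "proportional",
    serum_baseline: float = 0.0,
    replicates: int = 1,
    mean_data: bool = True,
    seed: int = 0,
    phys: SpeciesPhysiology | None = None,
) -> ObservationSet:
    """Single-dose FCM study in an iron-deficient rat (serum + 6 tissues)."""
    phys = phys or load_physiology("rat")
    params = params or load_parameters("rat_ida")
    dose = dose_to_umol(dose_mg_per_kg, "mg/kg", phys.body_weight)
    groups = {"ida_rat": (params,
                          (DoseEvent(time=0.0, amount=dose, route="fcm_depot"),))}
    design = StudyDesign(
        species="rat", groups=groups, times=tuple(times),
        compartments=tuple(compartments),
        errspec=_uniform_errspec(sigma, error_kind, serum_baseline),
        replicates=replicates, mean_data=mean_data, seed=seed, fcm=True)
    return generate_study(design, phys)


def generate_human_study(
    params: KineticParameters | None = None,
    *,
    doses_mg: Sequence[float] = HUMAN_DOSES_MG,
    times: Sequence[float] = HUMAN_SAMPLING_TIMES_H,
    sigma: float = 0.05,
    error_kind: str = "proportional",
    serum_baseline: float = 0.0,
    replicates: int = 1,
    mean_data: bool = True,
    seed: int = 0,
    phys: SpeciesPhysiology | None = None,
) -> ObservationSet:
    """Single-ascending-dose FCM study in humans (serum only, 4 dose arms)."""
    from .interspecies import build_human_model

    phys = phys or load_physiology("human")
    if params is None:
        params, _ = build_human_model(
            load_parameters("rat_ida"), load_parameters("mouse_iron_adequate"), phys)
    groups = {
        f"dose_{int(mg)}mg": (
            params,
            (DoseEvent(time=0.0, amount=dose_to_umol(mg, "mg"), route="fcm_depot"),))
        for mg in doses_mg
    }
    design = StudyDesign(
        species="human", groups=groups, times=tuple(times),
        compartments=("serum",),
        errspec=_uniform_errspec(sigma, error_kind, serum_baseline),
        replicates=replicates, mean_data=mean_data, seed=seed, fcm=True)
    return generate_study(design, phys)
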