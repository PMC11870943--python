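"""Interspecies scaling of the iron model: mouse -> rat -> human.

Physiology is substituted wholesale per species.  Kinetic parameters follow
the chain used for iron-carbohydrate complexes (FCM):

* partition coefficients of tissues observed in the target study are
  re-estimated on target data; unobserved tissues inherit the source values;
* the plasma loss clearance is inherited unchanged;
* the erythropoietic utilization rate scales allometrically with the RBC
  lifespan, ``Q_E(target) = Q_E(source) * (T_RBC(target)/T_RBC(source))^b``
  with b = 0.75 by default;
* cardiac output scales linearly with body weight, ``Q2 = BW2 * Q1 / BW1``.

Body-weight-based allometry of Q_E is deliberately not provided (the
lifespan-based rule supersedes it for this model).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .model_core import ConfigurationError, KineticParameters, SpeciesPhysiology

__all__ = [
    "AllometricSpec",
    "ScalingRecipe",
    "scale_cardiac_output",
    "scale_qe_allometric",
    "build_rat_model",
    "build_human_model",
    "RAT_OBSERVED_TISSUES",
]

#: tissues with measured concentrations in the rat FCM study
RAT_OBSERVED_TISSUES = ("bone", "liver", "spleen", "heart", "muscle", "kidney")

#: default RBC lifespans (h) used as allometric anchors
T_RBC_REFERENCE = {"mouse": 34.44, "rat": 1440.0, "human": 2880.0}


@dataclass(frozen=True)
class AllometricSpec:
    """RBC-lifespan-based allometry: exponent and per-species lifespan anchors.

    The human anchor is 120 days = 2880 h; the exponent defaults to the
    fixed value 0.75.
    """

    b: float = 0.75
    t_rbc_reference: Mapping[str, float] = field(
        default_factory=lambda: dict(T_RBC_REFERENCE))

    def __post_init__(self) -> None:
        for sp, t in dict(self.t_rbc_reference).items():
            if not t > 0:
                raise ConfigurationError(f"t_rbc_reference[{sp!r}] must be > 0")


@dataclass(frozen=True)
class ScalingRecipe:
    """Provenance of a scaled parameter set: what was inherited vs estimated."""

    source_species: str
    target_species: str
    route: str  # "pure_iron" | "fcm"
    inherited: tuple[str, ...]
    estimated: tuple[str, ...]

    def __post_init__(self) -> None:
        both = set(self.inherited) & set(self.estimated)
        if both:
            raise ConfigurationError(
                f"parameters both inherited and estimated: {sorted(both)}")

    def to_dict(self) -> dict:
        return {
            "source_species": self.source_species,
            "target_species": self.target_species,
            "route": self.route,
            "inherited": list(self.inherited),
            "estimated": list(self.estimated),
        }


def scale_cardiac_output(q1: float, bw1: float, bw2: float) -> float:
    """Linear body-weight scaling of cardiac output, Q2 = BW2 * Q1 / BW1."""
    if not (q1 > 0 and bw1 > 0 and bw2 > 0):
        raise ConfigurationError("cardiac output and body weights must be > 0")
    return q1 * bw2 / bw1


def scale_qe_allometric(qe_source: float, t_rbc_source: float,
                        t_rbc_target: float, b: float = 0.75) -> float:
    """RBC-lifespan allometry of the erythropoietic utilization rate.

    ``Q_E(target) = Q_E(source) * (T_RBC(target) / T_RBC(source))^b``.
    """
    if not (t_rbc_source > 0 and t_rbc_target > 0):
        raise ConfigurationError("RBC lifespans must be > 0")
    if not qe_source >= 0:
        raise ConfigurationError("Q_E must be >= 0")
    return qe_source * (t_rbc_target / t_rbc_source) ** b


def build_rat_model(
    mouse_fit: KineticParameters,
    rat_phys: SpeciesPhysiology,
    observed_tissues: Iterable[str] = RAT_OBSERVED_TISSUES,
    allo: AllometricSpec | None = None,
    t_rbc_mouse: float | None = None,
) -> tuple[KineticParameters, ScalingRecipe]:
    """Rat FCM model inputs from a mouse fit.

    Every KP and the plasma loss clearance are inherited from the mouse fit;
    the KPs of ``observed_tissues`` are flagged for re-estimation on rat data
    (the returned parameters still carry the inherited values as starting
    points).  Q_E is lifespan-scaled from the mouse value and T_RBC set to the
    rat anchor.  The returned recipe's ``inherited`` names, complementary to
    ``estimated``, double as the ``fixed_mask`` of a subsequent rat fit.
    """
    allo = allo or AllometricSpec()
    observed = tuple(observed_tissues)
    for t in observed:
        if t not in rat_phys.organ_names:
            raise ConfigurationError(f"observed tissue {t!r} not in rat physiology")
    t_rbc_rat = allo.t_rbc_reference["rat"]
    t_src = t_rbc_mouse if t_rbc_mouse is not None else mouse_fit.t_rbc
    params = KineticParameters(
        kp=dict(mouse_fit.kp),
        cl_loss=mouse_fit.cl_loss,
        q_e=scale_qe_allometric(mouse_fit.q_e, t_src, t_rbc_rat, allo.b),
        t_rbc=t_rbc_rat,
    )
    params.validate_against(rat_phys)
    estimated = tuple(f"kp_{t}" for t in observed)
    inherited = tuple(
        n for n in ([f"kp_{o}" for o in rat_phys.organ_names]
                    + ["cl_loss", "q_e", "t_rbc"])
        if n not in estimated)
    recipe = ScalingRecipe(source_species="mouse", target_species="rat",
                           route="fcm", inherited=inherited, estimated=estimated)
    return params, recipe


def build_human_model(
    rat_fit: KineticParameters | None,
    mouse_fit: KineticParameters,
    human_phys: SpeciesPhysiology,
    allo: AllometricSpec | None = None,
    t_rbc_mouse: float | None = None,
) -> tuple[KineticParameters, ScalingRecipe]:
    """Human FCM model inputs: KP/CL_loss from the rat chain, Q_E from mouse.

    Partition coefficients and CL_loss inherit rat-first with mouse fallback
    (``rat_fit=None`` falls back entirely to the mouse fit); T_RBC is fixed at
    the human anchor (2880 h) and Q_E is lifespan-scaled from the *mouse*
    value.  Construction is deterministic; nothing is estimated on human data.
    """
    allo = allo or AllometricSpec()
    source = rat_fit if rat_fit is not None else mouse_fit
    kp = {}
    for organ in human_phys.organ_names:
        if rat_fit is not None and organ in rat_fit.kp:
            kp[organ] = rat_fit.kp[organ]
        elif organ in mouse_fit.kp:
            kp[organ] = mouse_fit.kp[organ]
        else:
            raise ConfigurationError(f"no inherited KP available for {organ!r}")
    t_src = t_rbc_mouse if t_rbc_mouse is not None else mouse_fit.t_rbc
    t_rbc_human = allo.t_rbc_reference["human"]
    params = KineticParameters(
        kp=kp,
        cl_loss=source.cl_loss,
        q_e=scale_qe_allometric(mouse_fit.q_e, t_src, t_rbc_human, allo.b),
        t_rbc=t_rbc_human,
    )
    params.validate_against(human_phys)
    names = tuple([f"kp_{o}" for o in human_phys.organ_names]
                  + ["cl_loss", "q_e", "t_rbc"])
    recipe = ScalingRecipe(source_species="rat" if rat_fit is not None else "mouse",
                           target_species="human", route="fcm",
                           inherited=names, estimated=())
    return params, recipe
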