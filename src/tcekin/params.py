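"""Parameter containers for the mouse TCE PBPK model.

Units are mg, L and hr throughout.  The default values describe a male
B6C3F1/J mouse receiving a single corn-oil gavage and are nominal,
literature-typical values; every field can be overridden from a config
file, and nothing downstream depends on the specific defaults.

Allometry: maximal metabolic rates (``VMax``-type parameters) scale with
body weight to the 0.75 power and flows (cardiac output, alveolar
ventilation) with the 0.74 power when constructing defaults for a body
weight other than the reference animal.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field, fields


class ConfigurationError(ValueError):
    """A parameter set or configuration violates its structural contract."""


PERFUSED_COMPARTMENTS: tuple[str, ...] = (
    "fat",
    "liver",
    "gut",
    "kidney",
    "rapidly_perfused",
    "slowly_perfused",
)

#: reference body weight (kg); 76.4 mg administered at 2,100 mg/kg
REFERENCE_BODY_WEIGHT_KG = 76.4 / 2100.0


@dataclass
class PhysiologyParams:
    """Fixed physiological covariates: volumes, flows and partitioning.

    ``tissue_volume_fractions`` are fractions of body weight (1 kg tissue
    assumed = 1 L); ``blood_flow_fractions`` are fractions of cardiac
    output over the perfused compartments and must sum to 1.  The gut
    blood flow drains into the liver (portal circulation), so total
    hepatic outflow is the hepatic-arterial plus portal flow.
    """

    body_weight: float
    cardiac_output: float
    alveolar_ventilation: float
    tissue_volume_fractions: dict[str, float]
    blood_flow_fractions: dict[str, float]
    partition_coefficients: dict[str, float]
    venous_blood_fraction: float = 2.0 / 3.0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        scalars = {
            "body_weight": self.body_weight,
            "cardiac_output": self.cardiac_output,
            "alveolar_ventilation": self.alveolar_ventilation,
        }
        for name, value in scalars.items():
            if not (math.isfinite(value) and value > 0):
                raise ConfigurationError(f"{name} must be finite and > 0, got {value}")
        required_vols = set(PERFUSED_COMPARTMENTS) | {"blood"}
        if set(self.tissue_volume_fractions) != required_vols:
            raise ConfigurationError(
                f"tissue_volume_fractions must have keys {sorted(required_vols)}"
            )
        if set(self.blood_flow_fractions) != set(PERFUSED_COMPARTMENTS):
            raise ConfigurationError(
                f"blood_flow_fractions must have keys {sorted(PERFUSED_COMPARTMENTS)}"
            )
        required_pcs = set(PERFUSED_COMPARTMENTS) | {"blood_air"}
        if set(self.partition_coefficients) != required_pcs:
            raise ConfigurationError(
                f"partition_coefficients must have keys {sorted(required_pcs)}"
            )
        for d in (
            self.tissue_volume_fractions,
            self.blood_flow_fractions,
            self.partition_coefficients,
        ):
            for name, value in d.items():
                if not (math.isfinite(value) and value > 0):
                    raise ConfigurationError(
                        f"{name} must be finite and > 0, got {value}"
                    )
        if sum(self.tissue_volume_fractions.values()) > 1.0 + 1e-9:
            raise ConfigurationError("tissue volume fractions sum to > 1")
        flow_sum = sum(self.blood_flow_fractions.values())
        if abs(flow_sum - 1.0) > 1e-9:
            raise ConfigurationError(
                f"blood flow fractions must sum to 1, got {flow_sum!r}"
            )
        if not 0.0 < self.venous_blood_fraction < 1.0:
            raise ConfigurationError("venous_blood_fraction must be in (0, 1)")

    def volume(self, compartment: str) -> float:
        """Absolute volume (L) of a tissue compartment."""
        return self.tissue_volume_fractions[compartment] * self.body_weight

    def flow(self, compartment: str) -> float:
        """Absolute blood flow (L/hr) to a perfused compartment."""
        return self.blood_flow_fractions[compartment] * self.cardiac_output


@dataclass
class MetabolismParams:
    """Metabolic and metabolite-disposition rate constants.

    Liver oxidation (``VMax``/``KM``) and glutathione conjugation
    (``VMaxDCVG``/``KMDCVG``) are saturable; everything downstream is
    first order.  The oxidation flux is split by molar yield fractions
    into TCA, TCOH and direct DCA (the remainder is untracked "other
    oxidation").  DCA arises both from direct TCE oxidation and from
    enzymatic dehalogenation of TCA; DCVG clears by metabolism to DCVC.
    """

    VMax: float
    KM: float
    VMaxDCVG: float
    KMDCVG: float
    frac_TCA: float
    frac_TCOH: float
    frac_DCA_direct: float
    k_TCA_to_DCA: float
    k_TCOH_to_TCA: float
    k_TCOH_gluc: float
    k_TCOG_excr: float
    k_urn_TCA: float
    k_DCVG_to_DCVC: float
    k_DCVC_elim: float
    k12_DCA: float
    k21_DCA: float
    kE_DCA: float
    V_dist: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for f in fields(self):
            value = getattr(self, f.name)
            if f.name == "V_dist":
                continue
            if not (isinstance(value, (int, float)) and math.isfinite(value)):
                raise ConfigurationError(f"{f.name} must be finite, got {value}")
            if value < 0:
                raise ConfigurationError(f"{f.name} must be >= 0, got {value}")
        if not self.KM > 0:
            raise ConfigurationError("KM must be > 0")
        if not self.KMDCVG > 0:
            raise ConfigurationError("KMDCVG must be > 0")
        yield_sum = self.frac_TCA + self.frac_TCOH + self.frac_DCA_direct
        if yield_sum > 1.0 + 1e-9:
            raise ConfigurationError(
                f"oxidation yield fractions sum to {yield_sum} > 1"
            )
        required = {"TCA", "TCOH", "TCOG", "DCA", "DCVG", "DCVC"}
        if set(self.V_dist) != required:
            raise ConfigurationError(f"V_dist must have keys {sorted(required)}")
        for name, value in self.V_dist.items():
            if not (math.isfinite(value) and value > 0):
                raise ConfigurationError(f"V_dist[{name}] must be > 0, got {value}")

    def replace(self, **changes) -> "MetabolismParams":
        return dataclasses.replace(self, **changes)


@dataclass
class DoseRegimen:
    """Dosing description; the reference study is a single oral gavage.

    Oral absorption uses two sequential first-order gastrointestinal
    lumen compartments (stomach -> duodenum), each absorbing into the
    liver, which captures the prolonged uptake of a corn-oil vehicle and
    collapses to a single first-order compartment when the transfer rate
    is zero.  ``iv`` (venous bolus) and ``ia`` (arterial bolus) routes
    are provided as stubs for submodel testing.
    """

    route: str = "oral_gavage"
    dose_per_bw: float = 2100.0  # mg/kg
    vehicle_volume_per_bw: float = 10.0  # mL/kg
    absorption_rates: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ABSORPTION_RATES)
    )
    dose_time: float = 0.0  # hr

    def __post_init__(self) -> None:
        if self.route not in ("oral_gavage", "iv", "ia"):
            raise ConfigurationError(f"unsupported route {self.route!r}")
        if self.dose_per_bw < 0:
            raise ConfigurationError("dose_per_bw must be >= 0")
        if self.dose_time < 0:
            raise ConfigurationError("dose_time must be >= 0")
        for name in ("k_stomach_abs", "k_stomach_duodenum", "k_duodenum_abs"):
            value = self.absorption_rates.get(name)
            if value is None or value < 0:
                raise ConfigurationError(
                    f"absorption_rates[{name!r}] must be present and >= 0"
                )

    def total_dose(self, body_weight: float) -> float:
        """Administered dose in mg for a given body weight (kg)."""
        return self.dose_per_bw * body_weight

    def replace(self, **changes) -> "DoseRegimen":
        return dataclasses.replace(self, **changes)


DEFAULT_ABSORPTION_RATES: dict[str, float] = {
    "k_stomach_abs": 1.4,       # 1/hr, stomach lumen -> liver
    "k_stomach_duodenum": 0.6,  # 1/hr, stomach -> duodenum transfer
    "k_duodenum_abs": 0.8,      # 1/hr, duodenum lumen -> liver
}


def default_physiology(body_weight: float = REFERENCE_BODY_WEIGHT_KG) -> PhysiologyParams:
    """Nominal mouse physiology at the given body weight (kg)."""
    bw074 = body_weight**0.74
    return PhysiologyParams(
        body_weight=body_weight,
        cardiac_output=16.5 * bw074,
        alveolar_ventilation=29.0 * bw074,
        tissue_volume_fractions={
            "fat": 0.07,
            "liver": 0.055,
            "gut": 0.042,
            "kidney": 0.017,
            "rapidly_perfused": 0.05,
            "slowly_perfused": 0.65,
            "blood": 0.049,
        },
        blood_flow_fractions={
            "fat": 0.07,
            "liver": 0.02,
            "gut": 0.141,
            "kidney": 0.091,
            "rapidly_perfused": 0.468,
            "slowly_perfused": 0.21,
        },
        partition_coefficients={
            "fat": 36.0,
            "liver": 1.7,
            "gut": 1.9,
            "kidney": 1.3,
            "rapidly_perfused": 1.7,
            "slowly_perfused": 0.63,
            "blood_air": 15.0,
        },
    )


def default_metabolism(body_weight: float = REFERENCE_BODY_WEIGHT_KG) -> MetabolismParams:
    """Nominal B6C3F1/J metabolism parameters at the given body weight."""
    scale = (body_weight / REFERENCE_BODY_WEIGHT_KG) ** 0.75
    vd_scale = body_weight / REFERENCE_BODY_WEIGHT_KG
    return MetabolismParams(
        VMax=2.1 * scale,
        KM=3.3,
        VMaxDCVG=0.006 * scale,
        KMDCVG=0.06,
        frac_TCA=0.12,
        frac_TCOH=0.78,
        frac_DCA_direct=0.015,
        k_TCA_to_DCA=0.002,
        k_TCOH_to_TCA=0.25,
        k_TCOH_gluc=1.5,
        k_TCOG_excr=0.6,
        k_urn_TCA=0.12,
        k_DCVG_to_DCVC=0.3,
        k_DCVC_elim=0.25,
        k12_DCA=0.6,
        k21_DCA=0.4,
        kE_DCA=2.0,
        V_dist={
            "TCA": 0.012 * vd_scale,
            "TCOH": 0.025 * vd_scale,
            "TCOG": 0.015 * vd_scale,
            "DCA": 0.015 * vd_scale,
            "DCVG": 0.030 * vd_scale,
            "DCVC": 0.030 * vd_scale,
        },
    )


def default_regimen() -> DoseRegimen:
    """Single oral gavage of 2,100 mg/kg TCE in 10 mL/kg corn oil."""
    return DoseRegimen()
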