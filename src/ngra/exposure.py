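"""Consumer exposure scenarios, bioactivity-exposure ratios and margins of safety.

The exposure conventions follow the SCCS Notes of Guidance for a leave-on
body lotion: 7.82 g applied per day, a distribution-based product amount of
123.2 mg/kg bw/day (an independent SCCS figure, never recomputed from
7.82/60), a 60 kg default body weight and 15,670 cm² treated skin surface.

The bioactivity-exposure ratio (BER) divides an internal point of departure
by an internal exposure metric; values above 1 indicate an acceptable margin,
values at or below 1 call for refining the assessment.  The margin of safety
(MoS) is the traditional external analogue: absorption-adjusted external PoD
over the systemic exposure dose (SED).
"""

from __future__ import annotations

from typing import Literal

import pandas as pd
from pydantic import BaseModel, Field, model_validator

__all__ = [
    "SCCS_BODY_LOTION_DAILY_G",
    "SCCS_PRODUCT_MG_PER_KG_BW",
    "SCCS_BODY_SURFACE_CM2",
    "DEFAULT_BODY_WEIGHT_KG",
    "ExposureScenario",
    "BERResult",
    "MoSResult",
    "applied_dose_per_area",
    "systemic_exposure_dose",
    "compute_ber",
    "margin_of_safety",
    "format_ber",
    "ber_table",
    "body_lotion_scenario",
]

#: SCCS Notes of Guidance daily applied amount for a body lotion (g/day)
SCCS_BODY_LOTION_DAILY_G = 7.82
#: SCCS distribution-based relative product amount (mg/kg bw/day)
SCCS_PRODUCT_MG_PER_KG_BW = 123.2
#: SCCS default body surface treated by a body lotion (cm²)
SCCS_BODY_SURFACE_CM2 = 15_670.0
#: default adult body weight (kg)
DEFAULT_BODY_WEIGHT_KG = 60.0


class ExposureScenario(BaseModel):
    """A single-product consumer exposure scenario."""

    product_type: str = "body lotion"
    daily_amount: float = Field(gt=0, default=SCCS_BODY_LOTION_DAILY_G, description="g/day")
    product_amount_per_bw: float = Field(
        gt=0, default=SCCS_PRODUCT_MG_PER_KG_BW, description="mg/kg bw/day"
    )
    concentration: float = Field(ge=0, le=1, description="mass fraction of the ingredient")
    body_weight: float = Field(gt=0, default=DEFAULT_BODY_WEIGHT_KG, description="kg")
    surface_area: float = Field(gt=0, default=SCCS_BODY_SURFACE_CM2, description="cm²")
    route: Literal["dermal", "oral"] = "dermal"


def applied_dose_per_area(scenario: ExposureScenario) -> float:
    """External applied dose of the ingredient in µg/cm² per day.

    daily product amount × ingredient mass fraction spread over the treated
    surface; a 0.1% body lotion gives 7.82 g × 0.001 / 15,670 cm² ≈ 0.5 µg/cm².
    """
    if scenario.route != "dermal":
        raise ValueError("applied dose per area is defined for the dermal route")
    return scenario.daily_amount * 1e6 * scenario.concentration / scenario.surface_area


def systemic_exposure_dose(scenario: ExposureScenario, absorbed_fraction: float) -> float:
    """Systemic exposure dose (SED) in mg/kg bw/day."""
    if not 0 <= absorbed_fraction <= 1:
        raise ValueError("absorbed_fraction must be within [0, 1]")
    return scenario.product_amount_per_bw * scenario.concentration * absorbed_fraction


class BERResult(BaseModel):
    """Bioactivity-exposure ratio for one internal exposure metric."""

    pod_internal: float = Field(gt=0, description="nM")
    exposure_metric: Literal[
        "cmax_total_mean", "cmax_total_ci", "cmax_fu_mean", "cmax_fu_ci"
    ]
    exposure_value: float = Field(gt=0, description="nM")
    ber: float
    interpretation: Literal["acceptable_margin", "refine_assessment"]

    @model_validator(mode="after")
    def _consistent(self) -> "BERResult":
        expected = self.pod_internal / self.exposure_value
        if abs(self.ber - expected) > 1e-9 * expected:
            raise ValueError("ber must equal pod_internal / exposure_value")
        want = "acceptable_margin" if self.ber > 1 else "refine_assessment"
        if self.interpretation != want:
            raise ValueError("interpretation inconsistent with BER > 1 rule")
        return self

    @property
    def display(self) -> str:
        return format_ber(self.ber)


class MoSResult(BaseModel):
    """Traditional margin of safety from an external PoD."""

    pod_external: float = Field(gt=0, description="mg/kg/day")
    absorption_adjustment: float = Field(gt=0, le=1)
    sed: float = Field(gt=0, description="mg/kg/day")
    mos: float

    @model_validator(mode="after")
    def _consistent(self) -> "MoSResult":
        expected = self.pod_external * self.absorption_adjustment / self.sed
        if abs(self.mos - expected) > 1e-9 * expected:
            raise ValueError("mos must equal pod_external × adjustment / sed")
        return self


def format_ber(ber: float) -> str:
    """Display rounding for BER values, matching the case-study table.

    ≥ 20 → nearest integer (33, 167, 56, 250, 100, 20); 0.1–20 → one decimal
    (1.7, 8.5, 3.0, 1.0, 14.7, 5.1); below 0.1 → one significant figure
    (0.003 for the dietary comparison).  Full precision is always retained in
    the result objects; this is presentation only.
    """
    if ber >= 20:
        return f"{ber:.0f}"
    if ber >= 0.1:
        return f"{ber:.1f}"
    from .units import round_sig

    return f"{round_sig(ber, 1):g}"


def compute_ber(
    pod_internal: float,
    exposure_value: float,
    exposure_metric: Literal[
        "cmax_total_mean", "cmax_total_ci", "cmax_fu_mean", "cmax_fu_ci"
    ] = "cmax_total_mean",
) -> BERResult:
    """BER = internal PoD / internal exposure, interpreted against 1."""
    if pod_internal <= 0 or exposure_value <= 0:
        raise ValueError("PoD and exposure must be positive, in the same units (nM)")
    ber = pod_internal / exposure_value
    return BERResult(
        pod_internal=pod_internal,
        exposure_metric=exposure_metric,
        exposure_value=exposure_value,
        ber=ber,
        interpretation="acceptable_margin" if ber > 1 else "refine_assessment",
    )


def margin_of_safety(
    pod_external: float, absorption_adjustment: float, sed: float
) -> MoSResult:
    """MoS = absorption-adjusted external PoD / systemic exposure dose."""
    if sed <= 0:
        raise ValueError("SED must be positive")
    if pod_external <= 0 or absorption_adjustment <= 0:
        raise ValueError("PoD and absorption adjustment must be positive")
    return MoSResult(
        pod_external=pod_external,
        absorption_adjustment=absorption_adjustment,
        sed=sed,
        mos=pod_external * absorption_adjustment / sed,
    )


def ber_table(pod_internal: float, exposures: pd.DataFrame) -> pd.DataFrame:
    """BERs for a table of exposure metrics.

    ``exposures`` needs columns ``exposure_metric`` (one of the BERResult
    metrics), ``exposure_value_nM`` and optionally ``scenario`` — the layout
    produced by the packaged exposure fixture.  Returns the input with
    ``ber`` (full precision) and ``ber_display`` columns appended.
    """
    out = exposures.copy()
    results = [
        compute_ber(pod_internal, row.exposure_value_nM, row.exposure_metric)
        for row in out.itertuples()
    ]
    out["pod_internal_nM"] = pod_internal
    out["ber"] = [r.ber for r in results]
    out["ber_display"] = [r.display for r in results]
    out["interpretation"] = [r.interpretation for r in results]
    return out


def body_lotion_scenario(concentration: float) -> ExposureScenario:
    """SCCS default body-lotion scenario at a given ingredient mass fraction."""
    return ExposureScenario(concentration=concentration)
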