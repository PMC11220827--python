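"""In vitro biokinetics metrics for cell-based assay refinement.

Converts measured medium and cell-lysate concentration time courses into the
exposure metrics used to judge whether nominal assay concentrations are
adequate dose metrics: AUC0–24 in the medium, the fold difference between
measured Cmax and nominal concentration (default adequacy threshold
1.3-fold), the intracellular concentration implied by lysate amounts and
cell volumes (typically orders of magnitude above nominal for lipophilic
chemicals), and a no-cell stability check against degradation, evaporation
or plastic binding.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from pydantic import BaseModel, Field, field_validator, model_validator

__all__ = [
    "BiokineticsMeasurement",
    "NoCellControl",
    "trapezoid_auc",
    "nominal_fold",
    "intracellular_concentration",
    "stability_check",
]

#: default adequacy threshold: measured within 1.3-fold of nominal
DEFAULT_FOLD_THRESHOLD = 1.3


def trapezoid_auc(timepoints: Sequence[float], concentrations: Sequence[float]) -> float:
    """Trapezoidal AUC over [first, last] timepoint (µM·h for µM vs h input)."""
    t = np.asarray(timepoints, dtype=float)
    c = np.asarray(concentrations, dtype=float)
    if t.size < 2:
        raise ValueError("AUC needs at least two timepoints")
    if t.size != c.size:
        raise ValueError("timepoints and concentrations differ in length")
    if np.any(np.diff(t) <= 0):
        raise ValueError("timepoints must be strictly increasing")
    if np.any(c < 0):
        raise ValueError("concentrations must be non-negative")
    return float(np.trapezoid(c, t))


def nominal_fold(
    measured_cmax: float, nominal: float, threshold: float = DEFAULT_FOLD_THRESHOLD
) -> dict:
    """Symmetric fold difference between measured Cmax and nominal.

    fold = max/min of the two values, so the metric does not care which way
    the deviation goes; ``within`` is True when fold ≤ threshold.
    """
    if measured_cmax <= 0 or nominal <= 0:
        raise ValueError("measured and nominal concentrations must be positive")
    fold = max(measured_cmax, nominal) / min(measured_cmax, nominal)
    return {"fold": fold, "within": fold <= threshold}


def intracellular_concentration(
    lysate_amount_nmol: float, n_cells: float, cell_volume_pl: float
) -> float:
    """Concentration inside the cells, in mM.

    amount / (n_cells × cell volume): 2 nmol across 10⁶ cells of 2 pL is
    2·10⁻⁹ mol in 2·10⁻⁶ L = 1 mM.  This lumps free and bound chemical — it
    is the total cell-associated concentration, the conservative comparator
    against nominal.
    """
    if lysate_amount_nmol <= 0:
        raise ValueError("lysate amount must be positive")
    if n_cells <= 0 or cell_volume_pl <= 0:
        raise ValueError("cell count and volume must be positive")
    return lysate_amount_nmol * 1e6 / (n_cells * cell_volume_pl)


class NoCellControl(BaseModel):
    """Chemical concentration in cell-free wells at 0 h and 24 h (µM)."""

    conc_0h: float = Field(gt=0)
    conc_24h: float = Field(gt=0)


def stability_check(
    no_cell_control: NoCellControl | dict,
    nominal: float,
    threshold: float = DEFAULT_FOLD_THRESHOLD,
) -> dict:
    """Stability of the chemical in cell-free incubations.

    Stable when both the 0 h and 24 h cell-free concentrations are within
    ``threshold``-fold of nominal, ruling out degradation, evaporation and
    non-specific binding to the plastic as confounders.
    """
    if isinstance(no_cell_control, dict):
        no_cell_control = NoCellControl.model_validate(no_cell_control)
    f0 = nominal_fold(no_cell_control.conc_0h, nominal, threshold)
    f24 = nominal_fold(no_cell_control.conc_24h, nominal, threshold)
    return {
        "stable": f0["within"] and f24["within"],
        "fold_0h": f0["fold"],
        "fold_24h": f24["fold"],
    }


class BiokineticsMeasurement(BaseModel):
    """One chemical × cell-line biokinetics experiment.

    ``lysate_amount`` carries per-timepoint cell-associated amounts in nmol;
    if the laboratory reports a lysate-volume concentration instead, convert
    upstream through the same n_cells × cell_volume product.
    """

    chemical_id: str
    cell_line: str
    well_format: str = "48-well"
    nominal: float = Field(gt=0, description="µM")
    timepoints: list[float] = Field(description="h")
    medium_conc: list[float] = Field(description="µM per timepoint")
    lysate_amount: list[float] | None = Field(default=None, description="nmol per timepoint")
    n_cells: float | None = Field(default=None, gt=0)
    cell_volume: float | None = Field(default=None, gt=0, description="pL")
    no_cell_control: NoCellControl | None = None

    @field_validator("timepoints")
    @classmethod
    def _increasing(cls, v: list[float]) -> list[float]:
        if any(b <= a for a, b in zip(v, v[1:])):
            raise ValueError("timepoints must be strictly increasing")
        return v

    @model_validator(mode="after")
    def _lengths(self) -> "BiokineticsMeasurement":
        if len(self.medium_conc) != len(self.timepoints):
            raise ValueError("medium_conc length must match timepoints")
        if self.lysate_amount is not None and len(self.lysate_amount) != len(self.timepoints):
            raise ValueError("lysate_amount length must match timepoints")
        if any(c < 0 for c in self.medium_conc):
            raise ValueError("concentrations must be non-negative")
        return self

    def metrics(self, threshold: float = DEFAULT_FOLD_THRESHOLD) -> dict:
        """All derived exposure metrics for this experiment."""
        out: dict = {
            "auc_medium_uM_h": trapezoid_auc(self.timepoints, self.medium_conc),
            "nominal_vs_measured": nominal_fold(
                max(self.medium_conc), self.nominal, threshold
            ),
        }
        if (
            self.lysate_amount is not None
            and self.n_cells is not None
            and self.cell_volume is not None
        ):
            intracellular_mM = intracellular_concentration(
                max(self.lysate_amount), self.n_cells, self.cell_volume
            )
            out["intracellular_mM"] = intracellular_mM
            # nominal is µM; intracellular in mM → fold over nominal
            out["intracellular_over_nominal"] = intracellular_mM * 1e3 / self.nominal
        if self.no_cell_control is not None:
            out["stability"] = stability_check(self.no_cell_control, self.nominal, threshold)
        return out
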