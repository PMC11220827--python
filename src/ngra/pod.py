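"""Point-of-departure (PoD) derivation from multi-assay in vitro panels.

Implements the read-across PoD logic of the case study: transcriptomic
gene-level benchmark doses (BMDs) are aggregated into pathway medians with a
minimum-genes filter; the governing PoD is selected from *functional*
endpoint classes (receptor transactivation first), never from bare receptor
binding; ±S9 assay pairs collapse to their minimum; and the safety-factor
chain LOEC → NOEC (÷3) → safe internal concentration (÷3.3 for
intra-individual variability) is applied at full precision with display
rounding only at presentation.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .units import round_sig

__all__ = [
    "EndpointClass",
    "AssayResult",
    "AssayPanel",
    "GeneBMD",
    "PathwayBMDSummary",
    "PoDDerivation",
    "SelectionRules",
    "pathway_median_bmd",
    "lowest_median_bmd",
    "bmd_fold_ratio",
    "select_pod",
    "derive_pod",
]

EndpointClass = Literal[
    "functional_transactivation",
    "receptor_binding",
    "enzyme_inhibition",
    "cell_stress",
    "transcriptomic_pathway",
    "steroidogenesis",
]

# which measures are meaningful for each endpoint class
_MEASURE_MATRIX: dict[str, set[str]] = {
    "functional_transactivation": {"LOEC", "NOEC", "PC50"},
    "receptor_binding": {"LOEC", "IC50", "Ki"},
    "enzyme_inhibition": {"LOEC", "NOEC", "IC50"},
    "cell_stress": {"LOEC", "NOEC"},
    "transcriptomic_pathway": {"BMD_median", "NOEC"},
    "steroidogenesis": {"LOEC", "NOEC"},
}


class AssayResult(BaseModel):
    """One assay readout for one chemical; concentrations in nM."""

    chemical_id: str
    assay_id: str
    endpoint_class: EndpointClass
    measure: Literal["LOEC", "NOEC", "IC50", "Ki", "PC50", "BMD_median"]
    value: float = Field(gt=0, description="nM")
    sd: float | None = Field(default=None, ge=0, description="nM")
    s9: Literal["plus", "minus", "n/a"] = "n/a"
    direction: Literal["agonist", "antagonist", "inhibition", "up", "down", "n/a"] = "n/a"

    @model_validator(mode="after")
    def _measure_allowed(self) -> "AssayResult":
        if self.measure not in _MEASURE_MATRIX[self.endpoint_class]:
            raise ValueError(
                f"measure {self.measure} not valid for class {self.endpoint_class}"
            )
        return self


class AssayPanel(BaseModel):
    """All assay results collected for one chemical."""

    chemical_id: str
    results: list[AssayResult]

    @model_validator(mode="after")
    def _consistent_chemical(self) -> "AssayPanel":
        for r in self.results:
            if r.chemical_id != self.chemical_id:
                raise ValueError("panel contains results for a different chemical")
        return self

    def __len__(self) -> int:
        return len(self.results)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, chemical_id: str) -> "AssayPanel":
        sub = df[df["chemical_id"] == chemical_id]
        results = []
        def _clean(x, default):
            if x is None or (isinstance(x, float) and math.isnan(x)):
                return default
            return x

        for rec in sub.to_dict("records"):
            results.append(
                AssayResult(
                    chemical_id=rec["chemical_id"],
                    assay_id=rec["assay_id"],
                    endpoint_class=rec["endpoint_class"],
                    measure=rec["measure"],
                    value=float(rec["value_nM"]),
                    sd=_clean(rec.get("sd"), None),
                    s9=_clean(rec.get("s9"), "n/a"),
                    direction=_clean(rec.get("direction"), "n/a"),
                )
            )
        return cls(chemical_id=chemical_id, results=results)

    @classmethod
    def from_csv(cls, path: str | Path, chemical_id: str) -> "AssayPanel":
        return cls.from_dataframe(pd.read_csv(path), chemical_id)


class GeneBMD(BaseModel):
    """Gene-level benchmark dose (µM); filter status is an upstream input."""

    gene_id: str
    bmd: float = Field(gt=0, description="µM")
    passes_filters: bool = True


class PathwayBMDSummary(BaseModel):
    """Median BMD over the passing genes of one pathway."""

    pathway_id: str
    n_genes_passing: int = Field(ge=1)
    median_bmd: float = Field(gt=0, description="µM")
    direction: Literal["up", "down"] | None = None


class PoDDerivation(BaseModel):
    """Safety-factor chain from the selected assay LOEC.

    All values are carried at full precision; printed values in reports are
    display-rounded to 2 significant figures (e.g. 33.33 nM prints as 33 nM).
    """

    chemical_id: str
    selected_assay: AssayResult
    loec: float = Field(gt=0, description="nM")
    noec: float = Field(gt=0, description="nM")
    sf_loec_to_noec: float = Field(gt=0, default=3.0)
    sf_intraindividual: float = Field(gt=0, default=3.3)
    safe_internal_concentration: float = Field(gt=0, description="nM")
    selection_log: list[dict] = Field(default_factory=list)

    @model_validator(mode="after")
    def _chain(self) -> "PoDDerivation":
        if not math.isclose(self.noec, self.loec / self.sf_loec_to_noec, rel_tol=1e-12):
            raise ValueError("noec must equal loec / sf_loec_to_noec")
        if not math.isclose(
            self.safe_internal_concentration,
            self.noec / self.sf_intraindividual,
            rel_tol=1e-12,
        ):
            raise ValueError("safe concentration must equal noec / sf_intraindividual")
        return self

    def display(self) -> dict[str, float]:
        """Presentation rounding (2 significant figures)."""
        return {
            "loec_nM": round_sig(self.loec, 2),
            "noec_nM": round_sig(self.noec, 2),
            "safe_internal_concentration_nM": round_sig(self.safe_internal_concentration, 2),
        }

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.model_dump(), indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


# ---------------------------------------------------------------------------
# pathway BMD aggregation
# ---------------------------------------------------------------------------


def pathway_median_bmd(
    gene_bmds: Sequence[GeneBMD],
    pathway_map: Mapping[str, Sequence[str]],
    min_genes: int = 3,
    directions: Mapping[str, str] | None = None,
) -> list[PathwayBMDSummary]:
    """Aggregate gene BMDs into per-pathway medians.

    ``pathway_map`` maps gene_id → pathway ids (a gene may serve several
    pathways).  Only genes with ``passes_filters`` contribute; pathways with
    fewer than ``min_genes`` passing genes are dropped.  Empty input yields
    an empty list.
    """
    by_gene = {g.gene_id: g for g in gene_bmds}
    unmapped = set(by_gene) - set(pathway_map)
    if unmapped:
        raise ValueError(f"genes without pathway membership: {sorted(unmapped)[:5]}")

    pathway_genes: dict[str, list[float]] = {}
    for gene_id, pathways in pathway_map.items():
        g = by_gene.get(gene_id)
        if g is None or not g.passes_filters:
            continue
        for pw in pathways:
            pathway_genes.setdefault(pw, []).append(g.bmd)

    out = []
    for pw in sorted(pathway_genes):
        bmds = pathway_genes[pw]
        if len(bmds) < min_genes:
            continue
        direction = (directions or {}).get(pw)
        out.append(
            PathwayBMDSummary(
                pathway_id=pw,
                n_genes_passing=len(bmds),
                median_bmd=float(np.median(bmds)),
                direction=direction,
            )
        )
    return out


def lowest_median_bmd(summaries: Sequence[PathwayBMDSummary]) -> PathwayBMDSummary:
    """The pathway with the lowest median BMD; ties break lexicographically."""
    if not summaries:
        raise ValueError("no pathway summaries")
    best = min(summaries, key=lambda s: (s.median_bmd, s.pathway_id))
    ties = [s.pathway_id for s in summaries if s.median_bmd == best.median_bmd]
    if len(ties) > 1:
        import logging

        logging.getLogger(__name__).info(
            "tie at median BMD %g between %s; keeping %s", best.median_bmd, ties, best.pathway_id
        )
    return best


def bmd_fold_ratio(bmd_a: float, bmd_b: float) -> float:
    """Fold difference a/b, half-up rounded to an integer when it reaches 2.

    Below 2-fold the exact ratio is returned (e.g. x/x → 1.0); from 2-fold
    upward the convention of the case study's reporting is nearest-integer
    (33.1/0.040 → 828).
    """
    if bmd_a <= 0 or bmd_b <= 0:
        raise ValueError("BMDs must be positive")
    ratio = bmd_a / bmd_b
    rounded = math.floor(ratio + 0.5)
    return float(rounded) if rounded >= 2 else ratio


# ---------------------------------------------------------------------------
# PoD selection
# ---------------------------------------------------------------------------


class SelectionRules(BaseModel):
    """Governing-class hierarchy and measure rules for PoD selection.

    Functional activity governs over binding affinity: transactivation
    results outrank enzyme inhibition and steroidogenesis, which outrank
    nonspecific cell stress.  Receptor-binding and transcriptomic-pathway
    results are flag-only supporting evidence and never govern.
    """

    governing_classes: list[list[str]] = Field(
        default_factory=lambda: [
            ["functional_transactivation"],
            ["enzyme_inhibition", "steroidogenesis"],
            ["cell_stress"],
        ]
    )
    governing_measures: list[str] = Field(default_factory=lambda: ["LOEC"])


def _collapse_s9(
    candidates: list[AssayResult], log: list[dict]
) -> list[AssayResult]:
    """Collapse ±S9 pairs of the same assay to the minimum value."""
    groups: dict[str, list[AssayResult]] = {}
    for r in candidates:
        groups.setdefault(r.assay_id, []).append(r)
    collapsed = []
    for assay_id in sorted(groups):
        group = sorted(groups[assay_id], key=lambda r: (r.value, r.s9))
        keep = group[0]
        if len(group) > 1:
            other = group[1]
            overlap = None
            if keep.sd is not None and other.sd is not None:
                overlap = abs(keep.value - other.value) <= (keep.sd + other.sd)
            log.append(
                {
                    "rule": "s9_pair_minimum",
                    "assay_id": assay_id,
                    "kept": {"s9": keep.s9, "value_nM": keep.value},
                    "excluded": [
                        {"s9": r.s9, "value_nM": r.value} for r in group[1:]
                    ],
                    "difference_within_sd": overlap,
                }
            )
        collapsed.append(keep)
    return collapsed


def select_pod(panel: AssayPanel, rules: SelectionRules | None = None) -> AssayResult:
    """Select the governing assay result for the PoD.

    Walks the governing-class hierarchy; within the first tier that has any
    eligible result, the lowest concentration wins (±S9 pairs collapse to
    their minimum first).  Every exclusion is appended to the selection log,
    retrievable afterwards via ``last_selection_log``.  The result is
    invariant to the ordering of the panel rows.
    """
    rules = rules or SelectionRules()
    if len(panel) == 0:
        raise ValueError("empty assay panel")
    log: list[dict] = []

    flag_only = [
        r
        for r in panel.results
        if r.endpoint_class in ("receptor_binding", "transcriptomic_pathway")
    ]
    for r in sorted(flag_only, key=lambda r: (r.value, r.assay_id)):
        log.append(
            {
                "rule": "supporting_evidence_only",
                "assay_id": r.assay_id,
                "endpoint_class": r.endpoint_class,
                "value_nM": r.value,
                "reason": "binding/transcriptomic results flag targets but do not "
                "define biological potency",
            }
        )

    for tier in rules.governing_classes:
        candidates = [
            r
            for r in panel.results
            if r.endpoint_class in tier and r.measure in rules.governing_measures
        ]
        if not candidates:
            continue
        collapsed = _collapse_s9(candidates, log)
        collapsed.sort(key=lambda r: (r.value, r.assay_id))
        winner = collapsed[0]
        for r in collapsed[1:]:
            log.append(
                {
                    "rule": "higher_concentration_in_tier",
                    "assay_id": r.assay_id,
                    "value_nM": r.value,
                    "reason": f"LOEC above selected {winner.assay_id} ({winner.value} nM)",
                }
            )
        log.append(
            {
                "rule": "selected",
                "assay_id": winner.assay_id,
                "endpoint_class": winner.endpoint_class,
                "s9": winner.s9,
                "value_nM": winner.value,
            }
        )
        select_pod.last_selection_log = log  # type: ignore[attr-defined]
        return winner

    raise ValueError(
        "no functional assay result in panel: broaden the panel with "
        "transactivation, enzyme-inhibition, steroidogenesis or cell-stress data"
    )


select_pod.last_selection_log = []  # type: ignore[attr-defined]


def derive_pod(
    selected: AssayResult, sf1: float = 3.0, sf2: float = 3.3
) -> PoDDerivation:
    """Apply the safety-factor chain to the selected LOEC.

    ``sf1`` converts the LOEC to an estimated NOEC; ``sf2`` accounts for
    intra-individual variability (pass 1.0 to skip, e.g. for a like-for-like
    comparison against an in vivo plasma concentration).
    """
    if selected.measure != "LOEC":
        raise ValueError("PoD derivation starts from a LOEC")
    if sf1 <= 0 or sf2 <= 0:
        raise ValueError("safety factors must be positive")
    noec = selected.value / sf1
    safe = noec / sf2
    log = list(getattr(select_pod, "last_selection_log", []))
    log.append(
        {
            "rule": "safety_factors",
            "loec_nM": selected.value,
            "sf_loec_to_noec": sf1,
            "noec_nM": noec,
            "sf_intraindividual": sf2,
            "safe_internal_concentration_nM": safe,
        }
    )
    return PoDDerivation(
        chemical_id=selected.chemical_id,
        selected_assay=selected,
        loec=selected.value,
        noec=noec,
        sf_loec_to_noec=sf1,
        sf_intraindividual=sf2,
        safe_internal_concentration=safe,
        selection_log=log,
    )
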