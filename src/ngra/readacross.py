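"""Weight-of-evidence dossier for analogue suitability in read-across.

Collects the transparent evidence that a source chemical (the data-rich
analogue) can stand in for a target chemical: a property-by-property
physicochemical comparison with explicit modes and tolerances, categorical
concordance of in silico profiler alerts, and cross-assay potency ratios.
The dossier conclusion is deterministic given the configuration, and every
rule firing is appended to a narrative log.

No fingerprint- or structure-based similarity score is computed here;
ingested profiler calls are categorical data.  The optional ``similarity
summary`` (fraction of similar property verdicts) is simple plumbing and is
not equivalent to any proprietary analogue-quality score.
"""

from __future__ import annotations

from typing import Literal, Mapping, Sequence

import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .pod import AssayPanel

__all__ = [
    "PhyschemProfile",
    "SimilarityVerdict",
    "AlertConcordance",
    "ReadAcrossDossier",
    "DEFAULT_TOLERANCES",
    "compare_physchem",
    "categorical_concordance",
    "potency_ratio_table",
    "build_dossier",
]


class PhyschemProfile(BaseModel):
    """Physicochemical properties relevant to bioavailability."""

    chemical_id: str
    log_pow: float
    molecular_weight: float = Field(gt=0, description="g/mol")
    water_solubility: float = Field(ge=0, description="mg/mL")
    melting_point: float | None = Field(default=None, description="°C")
    boiling_point: float | None = Field(default=None, description="°C")
    vapor_pressure: float | None = Field(default=None, ge=0, description="mmHg")
    pka: list[float] = Field(default_factory=list)
    density: float | None = Field(default=None, gt=0, description="g/cm³")


class SimilarityVerdict(BaseModel):
    """One property comparison between target and source."""

    property: str
    target_value: float
    source_value: float
    comparison_mode: Literal["abs_diff", "fold"]
    tolerance: float = Field(gt=0)
    similar: bool

    @model_validator(mode="after")
    def _consistent(self) -> "SimilarityVerdict":
        if self.comparison_mode == "abs_diff":
            within = abs(self.target_value - self.source_value) <= self.tolerance
        else:
            hi = max(abs(self.target_value), abs(self.source_value))
            lo = min(abs(self.target_value), abs(self.source_value))
            within = lo > 0 and hi / lo <= self.tolerance
        if within != self.similar:
            raise ValueError("similar flag inconsistent with comparison")
        return self


#: per-property (mode, tolerance, mandatory) defaults; the case study asserts
#: similarity without numeric thresholds, so these are package choices.
DEFAULT_TOLERANCES: dict[str, tuple[str, float, bool]] = {
    "log_pow": ("abs_diff", 1.0, True),
    "molecular_weight": ("fold", 1.25, True),
    "water_solubility": ("fold", 10.0, True),
    "melting_point": ("abs_diff", 60.0, False),
    "boiling_point": ("abs_diff", 100.0, False),
    "vapor_pressure": ("fold", 100.0, False),
    "pka": ("abs_diff", 1.0, False),
    "density": ("abs_diff", 0.3, False),
}


def _property_value(profile: PhyschemProfile, prop: str) -> float | None:
    if prop == "pka":
        return profile.pka[0] if profile.pka else None
    return getattr(profile, prop)


def compare_physchem(
    target: PhyschemProfile,
    source: PhyschemProfile,
    tolerances: Mapping[str, tuple[str, float, bool]] | None = None,
) -> list[SimilarityVerdict]:
    """Property-by-property similarity verdicts.

    ``abs_diff`` mode is symmetric under a target/source swap; ``fold`` mode
    compares the max/min ratio so it is symmetric too.  A missing mandatory
    property raises; missing optional properties are skipped.
    """
    tolerances = dict(tolerances or DEFAULT_TOLERANCES)
    verdicts = []
    for prop, (mode, tol, mandatory) in tolerances.items():
        tv = _property_value(target, prop)
        sv = _property_value(source, prop)
        if tv is None or sv is None:
            if mandatory:
                raise ValueError(f"mandatory property {prop!r} missing from a profile")
            continue
        if mode == "abs_diff":
            similar = abs(tv - sv) <= tol
        else:
            hi, lo = max(abs(tv), abs(sv)), min(abs(tv), abs(sv))
            similar = lo > 0 and hi / lo <= tol
        verdicts.append(
            SimilarityVerdict(
                property=prop,
                target_value=tv,
                source_value=sv,
                comparison_mode=mode,
                tolerance=tol,
                similar=similar,
            )
        )
    return verdicts


class AlertConcordance(BaseModel):
    """Concordance of categorical in silico profiler calls."""

    per_profiler: dict[str, bool]
    n_concordant: int
    n_total: int
    fraction: float

    @property
    def all_concordant(self) -> bool:
        return self.n_concordant == self.n_total


def categorical_concordance(
    alert_calls: Sequence[Mapping[str, str]],
) -> AlertConcordance:
    """Per-profiler agreement of target vs source categorical calls.

    Each element needs keys ``profiler``, ``target_call`` and
    ``source_call``; calls agree when the strings match exactly (case- and
    whitespace-insensitive).  Empty input is an error — concordance of
    nothing is not evidence.
    """
    if not alert_calls:
        raise ValueError("no profiler calls to compare")
    per: dict[str, bool] = {}
    for call in alert_calls:
        profiler = call["profiler"]
        if "target_call" not in call or "source_call" not in call:
            raise ValueError(f"unpaired profiler {profiler!r}")
        t = str(call["target_call"]).strip().lower()
        s = str(call["source_call"]).strip().lower()
        per[profiler] = t == s
    n_conc = sum(per.values())
    return AlertConcordance(
        per_profiler=per,
        n_concordant=n_conc,
        n_total=len(per),
        fraction=n_conc / len(per),
    )


def potency_ratio_table(
    target_panel: AssayPanel, source_panel: AssayPanel
) -> pd.DataFrame:
    """Target/source potency ratios for endpoints shared by both panels.

    Endpoints are matched on (assay_id, measure, s9); unmatched endpoints are
    listed with a NaN ratio rather than raising.  A ratio above 1 means the
    target is less potent (higher effective concentration) on that endpoint.
    """
    key = lambda r: (r.assay_id, r.measure, r.s9)
    source_by_key = {key(r): r for r in source_panel.results}
    rows = []
    seen = set()
    for r in target_panel.results:
        k = key(r)
        seen.add(k)
        s = source_by_key.get(k)
        rows.append(
            {
                "assay_id": r.assay_id,
                "measure": r.measure,
                "s9": r.s9,
                "target_value_nM": r.value,
                "source_value_nM": s.value if s else float("nan"),
                "ratio_target_over_source": r.value / s.value if s else float("nan"),
                "matched": s is not None,
            }
        )
    for k, s in source_by_key.items():
        if k not in seen:
            rows.append(
                {
                    "assay_id": s.assay_id,
                    "measure": s.measure,
                    "s9": s.s9,
                    "target_value_nM": float("nan"),
                    "source_value_nM": s.value,
                    "ratio_target_over_source": float("nan"),
                    "matched": False,
                }
            )
    return pd.DataFrame(rows).sort_values(["assay_id", "measure", "s9"]).reset_index(
        drop=True
    )


class ReadAcrossDossier(BaseModel):
    """Assembled weight of evidence for (or against) the analogue hypothesis."""

    target_id: str
    source_id: str
    physchem_verdicts: list[SimilarityVerdict]
    categorical_alerts: list[dict]
    potency_ratios: list[dict]
    conclusion: Literal["supported", "not_supported"]
    narrative_log: list[str]

    def similarity_summary(self) -> float:
        """Fraction of similar property verdicts (simple transparency metric,
        not an analogue-quality score)."""
        if not self.physchem_verdicts:
            return 0.0
        return sum(v.similar for v in self.physchem_verdicts) / len(self.physchem_verdicts)

    def to_markdown(self) -> str:
        lines = [
            f"# Read-across dossier: {self.target_id} ← {self.source_id}",
            "",
            f"**Conclusion: {self.conclusion}**",
            "",
            "## Physicochemical comparison",
        ]
        for v in self.physchem_verdicts:
            mark = "similar" if v.similar else "NOT similar"
            lines.append(
                f"- {v.property}: target {v.target_value:g} vs source "
                f"{v.source_value:g} ({v.comparison_mode} ≤ {v.tolerance:g}) → {mark}"
            )
        lines += ["", "## Narrative log"]
        lines += [f"- {entry}" for entry in self.narrative_log]
        return "\n".join(lines)


def build_dossier(
    target: PhyschemProfile,
    source: PhyschemProfile,
    alert_calls: Sequence[Mapping[str, str]],
    target_panel: AssayPanel | None = None,
    source_panel: AssayPanel | None = None,
    tolerances: Mapping[str, tuple[str, float, bool]] | None = None,
) -> ReadAcrossDossier:
    """Assemble the dossier and decide whether the read-across is supported.

    Supported requires every *mandatory* physicochemical verdict to be
    similar and every profiler call to be concordant; potency ratios are
    informative context (a potency difference is expected and handled by the
    read-across arithmetic, not a reason to reject the analogue).
    """
    tolerances = dict(tolerances or DEFAULT_TOLERANCES)
    log: list[str] = []
    verdicts = compare_physchem(target, source, tolerances)
    mandatory_ok = True
    for v in verdicts:
        mandatory = tolerances[v.property][2]
        log.append(
            f"physchem {v.property}: {'similar' if v.similar else 'dissimilar'}"
            f" ({'mandatory' if mandatory else 'supporting'})"
        )
        if mandatory and not v.similar:
            mandatory_ok = False

    concordance = categorical_concordance(alert_calls)
    for profiler, ok in concordance.per_profiler.items():
        log.append(f"profiler {profiler}: {'concordant' if ok else 'discordant'}")

    ratios: list[dict] = []
    if target_panel is not None and source_panel is not None:
        table = potency_ratio_table(target_panel, source_panel)
        ratios = table[table.matched].to_dict("records")
        matched = [r["ratio_target_over_source"] for r in ratios]
        if matched:
            import numpy as np

            gm = float(np.exp(np.mean(np.log(matched))))
            log.append(
                f"potency: geometric-mean target/source ratio over "
                f"{len(matched)} shared endpoints = {gm:.3g}"
            )

    supported = mandatory_ok and concordance.all_concordant
    log.append(
        "conclusion: "
        + (
            "supported (mandatory physchem similar, all profiler calls concordant)"
            if supported
            else "not supported (a mandatory verdict or profiler concordance failed)"
        )
    )
    return ReadAcrossDossier(
        target_id=target.chemical_id,
        source_id=source.chemical_id,
        physchem_verdicts=verdicts,
        categorical_alerts=[dict(c) for c in alert_calls],
        potency_ratios=ratios,
        conclusion="supported" if supported else "not_supported",
        narrative_log=log,
    )
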