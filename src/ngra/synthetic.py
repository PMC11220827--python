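"""Seeded synthetic inputs with the statistical structure the pipeline assumes.

Generators are pure functions of (spec, seed): a paired source/target assay
panel with a configurable target/source potency ratio under multiplicative
lognormal noise; gene-level BMD tables clustered into pathways with one
designated lowest-median pathway; lognormal PK parameter variability specs;
and medium/lysate concentration time courses for the biokinetics metrics.

The lognormal noise is median-one (log-mean zero), so the geometric mean of
recovered target/source ratios is an unbiased estimate of the configured
potency ratio.
"""

from __future__ import annotations

import numpy as np
from pydantic import BaseModel, Field

from .biokinetics import BiokineticsMeasurement, NoCellControl
from .pod import AssayPanel, AssayResult, GeneBMD
from .readacross import PhyschemProfile

__all__ = [
    "SyntheticSpec",
    "generate_chemical_pair",
    "generate_gene_bmds",
    "generate_timecourse",
    "paper_fixtures",
]

# re-exported here because packaged fixtures logically belong to data
# generation; the implementation lives in ngra.datasets
from .datasets import paper_fixtures  # noqa: E402  (re-export)


class SyntheticSpec(BaseModel):
    """Configuration for all synthetic generators.

    ``potency_ratio`` is the target/source LOEC ratio: a ratio of 15 makes
    the target chemical 15-fold less potent (higher effective
    concentrations), mirroring the order-of-magnitude potency gap between
    the case study's pair.
    """

    seed: int = 0
    potency_ratio: float = Field(gt=0, default=15.0)
    assay_noise_cv: float = Field(ge=0, default=0.3)
    n_pathways: int = Field(ge=1, default=20)
    genes_per_pathway: int = Field(ge=1, default=10)
    lowest_pathway_median: float = Field(gt=0, default=0.038, description="µM")
    pathway_median_spread: tuple[float, float] = (2.0, 1000.0)
    pk_cvs: dict[str, float] = Field(
        default_factory=lambda: {"hepatic_clint": 0.45, "ka_oral": 0.3, "fu_plasma": 0.2}
    )
    n_individuals: int = Field(ge=1, default=1000)
    timecourse_hours: tuple[float, ...] = (0.0, 1.0, 3.0, 6.0, 24.0)
    nominal_uM: float = Field(gt=0, default=1.3)


# baseline source-chemical panel: endpoint structure of the case study's
# in vitro battery, values in nM (potent functional transactivation, a
# binding flag below it, weaker enzyme/steroidogenesis/cell-stress endpoints)
_SOURCE_PANEL_BASE: list[dict] = [
    dict(assay_id="calux_er_alpha", endpoint_class="functional_transactivation",
         measure="LOEC", value=5.2, s9="plus", direction="agonist"),
    dict(assay_id="calux_er_alpha", endpoint_class="functional_transactivation",
         measure="LOEC", value=6.5, s9="minus", direction="agonist"),
    dict(assay_id="pharmacology_er_beta", endpoint_class="receptor_binding",
         measure="LOEC", value=0.52, s9="n/a", direction="agonist"),
    dict(assay_id="pharmacology_er_alpha", endpoint_class="receptor_binding",
         measure="LOEC", value=44.0, s9="n/a", direction="agonist"),
    dict(assay_id="ttr_binding", endpoint_class="enzyme_inhibition",
         measure="LOEC", value=210.0, s9="minus", direction="inhibition"),
    dict(assay_id="htpo_inhibition", endpoint_class="enzyme_inhibition",
         measure="LOEC", value=19000.0, s9="minus", direction="inhibition"),
    dict(assay_id="h295r_androgen_synthesis", endpoint_class="steroidogenesis",
         measure="LOEC", value=3200.0, s9="minus", direction="inhibition"),
    dict(assay_id="cell_stress_mmp", endpoint_class="cell_stress",
         measure="LOEC", value=11600.0, s9="n/a", direction="down"),
    dict(assay_id="transcriptomics_mcf7", endpoint_class="transcriptomic_pathway",
         measure="BMD_median", value=6.5, s9="n/a", direction="up"),
]

_SOURCE_PHYSCHEM = dict(
    log_pow=3.04, molecular_weight=270.24, water_solubility=0.12,
    melting_point=301.5, boiling_point=555.5, vapor_pressure=1.33e-9,
    pka=[7.25, 9.47], density=1.5,
)


def _lognormal_factor(rng: np.random.Generator, cv: float, size=None):
    """Median-one lognormal multiplier(s) with coefficient of variation cv."""
    if cv == 0:
        return np.ones(size) if size is not None else 1.0
    sigma = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(mean=0.0, sigma=sigma, size=size)


def generate_chemical_pair(
    spec: SyntheticSpec,
) -> tuple[AssayPanel, AssayPanel, tuple[PhyschemProfile, PhyschemProfile]]:
    """Source and target assay panels plus matched physchem profiles.

    Target values are potency_ratio × source value × lognormal(CV) noise,
    endpoint by endpoint; with CV = 0 every target/source ratio equals the
    configured potency ratio exactly.  The noise factor is drawn once per
    assay (±S9 variants of the same assay measure the same endpoint, so
    their potency shift is shared), keeping the recovered ratio unbiased
    through the ±S9 minimum rule downstream.
    """
    rng = np.random.default_rng(spec.seed)
    source_results = [
        AssayResult(chemical_id="source", **base) for base in _SOURCE_PANEL_BASE
    ]
    assay_noise: dict[str, float] = {}
    target_results = []
    for base in _SOURCE_PANEL_BASE:
        if base["assay_id"] not in assay_noise:
            assay_noise[base["assay_id"]] = float(
                _lognormal_factor(rng, spec.assay_noise_cv)
            )
        noisy = dict(base)
        noisy["value"] = (
            spec.potency_ratio * base["value"] * assay_noise[base["assay_id"]]
        )
        target_results.append(AssayResult(chemical_id="target", **noisy))

    source_profile = PhyschemProfile(chemical_id="source", **_SOURCE_PHYSCHEM)
    # the target mirrors the source with small property offsets (an analogue)
    target_profile = PhyschemProfile(
        chemical_id="target",
        log_pow=_SOURCE_PHYSCHEM["log_pow"] + float(rng.normal(0, 0.2)),
        molecular_weight=_SOURCE_PHYSCHEM["molecular_weight"]
        * float(rng.uniform(0.92, 1.08)),
        water_solubility=_SOURCE_PHYSCHEM["water_solubility"]
        * float(_lognormal_factor(rng, 0.4)),
        melting_point=_SOURCE_PHYSCHEM["melting_point"] + float(rng.normal(0, 15)),
        boiling_point=_SOURCE_PHYSCHEM["boiling_point"] + float(rng.normal(0, 25)),
        vapor_pressure=_SOURCE_PHYSCHEM["vapor_pressure"]
        * float(_lognormal_factor(rng, 0.8)),
        pka=[7.25 + float(rng.normal(0, 0.3))],
        density=1.45,
    )
    return (
        AssayPanel(chemical_id="source", results=source_results),
        AssayPanel(chemical_id="target", results=target_results),
        (source_profile, target_profile),
    )


def generate_gene_bmds(
    spec: SyntheticSpec,
) -> tuple[list[GeneBMD], dict[str, list[str]], str]:
    """Gene-level BMD table, gene→pathway map and the designated lowest pathway.

    Pathway ``pw000`` is constructed so the median BMD of its passing genes
    equals ``lowest_pathway_median`` exactly (genes are rescaled after
    sampling); every other pathway median is strictly higher by at least the
    lower edge of ``pathway_median_spread``.  Each pathway also carries two
    non-passing genes that must not influence any median.
    """
    if spec.genes_per_pathway < 1:
        raise ValueError("genes_per_pathway must be >= 1")
    rng = np.random.default_rng(spec.seed)
    lo_mult, hi_mult = spec.pathway_median_spread
    if lo_mult <= 1:
        raise ValueError("pathway_median_spread lower edge must exceed 1")

    genes: list[GeneBMD] = []
    pathway_map: dict[str, list[str]] = {}
    lowest_id = "pw000"
    medians = [spec.lowest_pathway_median] + [
        spec.lowest_pathway_median
        * float(np.exp(rng.uniform(np.log(lo_mult), np.log(hi_mult))))
        for _ in range(spec.n_pathways - 1)
    ]
    for p, median in enumerate(medians):
        pw = f"pw{p:03d}"
        raw = _lognormal_factor(rng, 0.5, size=spec.genes_per_pathway) * median
        # rescale so the passing-gene median is exact by construction
        raw = raw * (median / float(np.median(raw)))
        for g, bmd in enumerate(raw):
            gene_id = f"{pw}_g{g:03d}"
            genes.append(GeneBMD(gene_id=gene_id, bmd=float(bmd), passes_filters=True))
            pathway_map[gene_id] = [pw]
        for g in range(2):  # filtered-out genes, extreme values on purpose
            gene_id = f"{pw}_fail{g}"
            genes.append(
                GeneBMD(
                    gene_id=gene_id,
                    bmd=float(median * 10 ** rng.uniform(-3, 3)),
                    passes_filters=False,
                )
            )
            pathway_map[gene_id] = [pw]
    return genes, pathway_map, lowest_id


def generate_timecourse(spec: SyntheticSpec, cell_line: str = "HepG2") -> BiokineticsMeasurement:
    """Medium/lysate concentration time course for the biokinetics metrics.

    Medium concentration stays near nominal (mild first-order decline with
    measurement noise); the cell-associated amount accumulates toward a
    plateau high enough that the implied intracellular concentration is
    orders of magnitude above nominal, as observed for lipophilic chemicals.
    """
    rng = np.random.default_rng(spec.seed + 1)
    t = np.asarray(spec.timecourse_hours)
    medium = spec.nominal_uM * np.exp(-0.005 * t) * _lognormal_factor(rng, 0.05, t.size)
    n_cells = 51_000.0
    cell_volume_pl = 2.0
    # plateau ~2000x nominal inside the cells
    target_mM = spec.nominal_uM * 2000.0 / 1e3
    plateau_nmol = target_mM * n_cells * cell_volume_pl / 1e6
    lysate = plateau_nmol * (1 - np.exp(-0.5 * t)) * _lognormal_factor(rng, 0.08, t.size)
    lysate[0] = 0.0
    return BiokineticsMeasurement(
        chemical_id="source",
        cell_line=cell_line,
        nominal=spec.nominal_uM,
        timepoints=list(t),
        medium_conc=[float(x) for x in medium],
        lysate_amount=[float(x) for x in np.maximum(lysate, 0.0)],
        n_cells=n_cells,
        cell_volume=cell_volume_pl,
        no_cell_control=NoCellControl(
            conc_0h=float(spec.nominal_uM * _lognormal_factor(rng, 0.05)),
            conc_24h=float(spec.nominal_uM * _lognormal_factor(rng, 0.05)),
        ),
    )
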