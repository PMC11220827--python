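"""Packaged, checksummed fixtures: the case-study tables and PBPK configs.

Every loader reads a versioned CSV/YAML shipped inside the package and, for
the transcribed tables, verifies a frozen SHA-256 checksum before returning,
so silently edited fixtures fail loudly.  Calibrated PBPK parameter sets
(rat oral genistein/daidzein, human dermal daidzein) are regression anchors
fitted to the study's printed dosimetry values, not independent predictions.
"""

from __future__ import annotations

import hashlib
import json
from importlib import resources
from pathlib import Path

import pandas as pd

from .pbpk import PBPKParameters

__all__ = [
    "fixture_path",
    "physchem_profiles",
    "insilico_alerts",
    "pharmacology_screen",
    "er_binding",
    "pathway_bmd_summaries",
    "assay_panel_table",
    "ber_exposures",
    "stability_controls",
    "invivo_anchors",
    "uncertainty_table",
    "load_pbpk_config",
    "paper_fixtures",
    "FixtureChecksumError",
]

_DATA = resources.files("ngra") / "data"


class FixtureChecksumError(RuntimeError):
    """A packaged fixture does not match its frozen checksum."""


def fixture_path(name: str) -> Path:
    p = Path(str(_DATA / name))
    if not p.exists():
        raise FileNotFoundError(f"no packaged fixture named {name!r}")
    return p


def _checksums() -> dict[str, str]:
    return json.loads(fixture_path("checksums.json").read_text())


def _verified(name: str) -> Path:
    path = fixture_path(name)
    digest = hashlib.sha256(path.read_bytes()).hexdigest()
    expected = _checksums().get(name)
    if expected is None or digest != expected:
        raise FixtureChecksumError(
            f"fixture {name!r} checksum {digest} does not match frozen {expected}"
        )
    return path


def _csv(name: str) -> pd.DataFrame:
    return pd.read_csv(_verified(name))


def physchem_profiles() -> pd.DataFrame:
    """Physicochemical properties of the source/target pair."""
    return _csv("physchem.csv")


def insilico_alerts() -> pd.DataFrame:
    """Categorical in silico profiler calls (source vs target)."""
    return _csv("insilico_alerts.csv")


def pharmacology_screen() -> pd.DataFrame:
    """83-target pharmacology screen hits with follow-up IC50s."""
    return _csv("pharmacology_screen.csv")


def er_binding() -> pd.DataFrame:
    """ERα/ERβ binding potency (IC50, Ki, LOEC in nM)."""
    return _csv("er_binding.csv")


def pathway_bmd_summaries() -> pd.DataFrame:
    """Per-cell-line lowest pathway median BMDs under 3- and 5-gene filters (µM)."""
    return _csv("pathway_bmd.csv")


def assay_panel_table() -> pd.DataFrame:
    """The combined in vitro assay panel for both chemicals (values in nM)."""
    return _csv("assay_panel.csv")


def ber_exposures() -> pd.DataFrame:
    """Internal exposure metrics (nM) for the BER table scenarios."""
    return _csv("ber_exposures.csv")


def stability_controls() -> pd.DataFrame:
    """No-cell control concentrations from the biokinetics pilot (µM)."""
    return _csv("stability_controls.csv")


def invivo_anchors() -> pd.DataFrame:
    """Literature anchor values (in vivo PoDs, reported plasma metrics)."""
    return _csv("invivo_anchors.csv")


def anchor(name: str) -> float:
    """Look up a single literature anchor value by name."""
    df = invivo_anchors().set_index("name")
    return float(df.loc[name, "value"])


def uncertainty_table() -> pd.DataFrame:
    """Structured uncertainty/confidence entries for the report."""
    return _csv("uncertainty.csv")


_PBPK_CONFIGS = {
    "genistein-rat-oral": "pbpk_genistein_rat_oral.yaml",
    "daidzein-rat-oral": "pbpk_daidzein_rat_oral.yaml",
    "daidzein-human-dermal": "pbpk_daidzein_human_dermal.yaml",
}


def load_pbpk_config(name: str) -> PBPKParameters:
    """A shipped calibrated PBPK parameter set by name.

    Available: genistein-rat-oral, daidzein-rat-oral, daidzein-human-dermal.
    """
    if name not in _PBPK_CONFIGS:
        raise KeyError(f"unknown PBPK config {name!r}; have {sorted(_PBPK_CONFIGS)}")
    return PBPKParameters.from_yaml(_verified(_PBPK_CONFIGS[name]))


def paper_fixtures() -> dict[str, pd.DataFrame]:
    """All transcribed tables at once, checksum-verified."""
    return {
        "physchem": physchem_profiles(),
        "insilico_alerts": insilico_alerts(),
        "pharmacology_screen": pharmacology_screen(),
        "er_binding": er_binding(),
        "pathway_bmd": pathway_bmd_summaries(),
        "assay_panel": assay_panel_table(),
        "ber_exposures": ber_exposures(),
        "stability_controls": stability_controls(),
        "invivo_anchors": invivo_anchors(),
        "uncertainty": uncertainty_table(),
    }
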