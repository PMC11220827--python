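"""Unit conversions used throughout the toolkit.

Internal amounts are nmol and internal concentrations nM; external doses are
mg/kg/day (oral) or µg/cm² × treated area (dermal).  All conversions between
mass and molar units go through the molecular weight (g/mol).
"""

from __future__ import annotations


def mg_to_nmol(mass_mg: float, molecular_weight: float) -> float:
    """Convert a mass in mg to an amount in nmol."""
    if molecular_weight <= 0:
        raise ValueError("molecular_weight must be positive")
    return mass_mg * 1e6 / molecular_weight


def ug_to_nmol(mass_ug: float, molecular_weight: float) -> float:
    """Convert a mass in µg to an amount in nmol."""
    return mg_to_nmol(mass_ug * 1e-3, molecular_weight)


def nmol_to_mg(amount_nmol: float, molecular_weight: float) -> float:
    """Convert an amount in nmol to a mass in mg."""
    if molecular_weight <= 0:
        raise ValueError("molecular_weight must be positive")
    return amount_nmol * molecular_weight / 1e6


def um_to_nm(conc_um: float) -> float:
    """µM → nM."""
    return conc_um * 1e3


def nm_to_um(conc_nm: float) -> float:
    """nM → µM."""
    return conc_nm * 1e-3


def log_molar_to_nm(log_molar: float) -> float:
    """log10(M) → nM (e.g. an EATS LOEC of −8.2 log M ≈ 6.3 nM)."""
    return 10.0**log_molar * 1e9


def round_sig(x: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures (display convention for PoDs)."""
    if x == 0:
        return 0.0
    from math import floor, log10

    return round(x, -int(floor(log10(abs(x)))) + (sig - 1))
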