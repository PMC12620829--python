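"""Mass/molar unit conversions.

Internal convention throughout the package: concentrations in nM, amounts in
nmol, volumes in L, time in hours.  Mass-based interface quantities (mg doses,
ng/mL assay thresholds) are converted at the boundary using the molecular
weight in g/mol.
"""

from __future__ import annotations

IGG_MW_G_PER_MOL = 150_000.0  # default molecular weight assumed for ADA (IgG)


def mg_to_nmol(mass_mg: float, mw_g_per_mol: float) -> float:
    """Convert a mass in mg to an amount in nmol."""
    if mw_g_per_mol <= 0:
        raise ValueError("molecular weight must be positive")
    return mass_mg * 1e6 / mw_g_per_mol


def nmol_to_mg(amount_nmol: float, mw_g_per_mol: float) -> float:
    return amount_nmol * mw_g_per_mol / 1e6


def nM_to_ng_per_ml(conc_nM, mw_g_per_mol: float):
    """1 nM of a 150 kDa protein is 150 ng/mL."""
    return conc_nM * mw_g_per_mol * 1e-3


def ng_per_ml_to_nM(conc_ng_per_ml, mw_g_per_mol: float):
    if mw_g_per_mol <= 0:
        raise ValueError("molecular weight must be positive")
    return conc_ng_per_ml * 1e3 / mw_g_per_mol
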