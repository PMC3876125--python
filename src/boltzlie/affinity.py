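"""IC50-to-binding-free-energy conversion.

Relative experimental binding free energies for inhibitors are derived from
half-maximal inhibitory concentrations via

    dG_exp = R * T * ln(IC50 / c_ref)

with the gas constant R in kJ/(mol K), temperature T in K and a standard-state
reference concentration c_ref of 1 mol/L.  For an IC50 reported with a
standard deviation sigma, the uncertainty propagated onto dG is

    dG_err = R * T * ln(IC50 / (IC50 - sigma))

i.e. the (one-sided, larger) log-interval half-width; it diverges as sigma
approaches IC50.  No Cheng-Prusoff correction is applied: the resulting
values are *relative* binding free energies, adequate for calibrating an
empirical model against a single assay.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

#: Molar gas constant, kJ mol^-1 K^-1.
R_KJ_PER_MOL_K = 0.0083145

#: Default absolute temperature, K.
DEFAULT_TEMPERATURE = 300.0

#: Standard-state reference concentration, mol/L.
REFERENCE_CONCENTRATION = 1.0


def ic50_to_dg(ic50: float, temperature: float = DEFAULT_TEMPERATURE,
               reference: float = REFERENCE_CONCENTRATION) -> float:
    """Convert an IC50 in mol/L to a relative binding free energy in kJ/mol.

    Parameters
    ----------
    ic50 : float
        Half-maximal inhibitory concentration, mol/L. Must be positive.
    temperature : float
        Absolute temperature in K (default 300 K, the assay/simulation
        temperature).
    reference : float
        Standard-state concentration in mol/L (default 1 M).

    Returns
    -------
    float
        dG_exp = R*T*ln(ic50/reference), negative for sub-molar binders.
    """
    if not ic50 > 0:
        raise ValueError(f"IC50 must be positive, got {ic50!r}")
    if not temperature > 0:
        raise ValueError(f"temperature must be positive, got {temperature!r}")
    return R_KJ_PER_MOL_K * temperature * math.log(ic50 / reference)


def ic50_uM_to_dg(ic50_uM: float,
                  temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Convenience wrapper: IC50 given in micromolar."""
    return ic50_to_dg(ic50_uM * 1e-6, temperature)


def ic50_error_to_dg_error(ic50: float, sigma: float,
                           temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Propagate an IC50 standard deviation onto dG, in kJ/mol.

    Uses the asymmetric log-interval width R*T*ln(ic50/(ic50-sigma)); both
    concentrations may be in any common unit (only their ratio enters).
    Requires 0 <= sigma < ic50.
    """
    if not ic50 > 0:
        raise ValueError(f"IC50 must be positive, got {ic50!r}")
    if sigma < 0:
        raise ValueError(f"sigma must be non-negative, got {sigma!r}")
    if sigma >= ic50:
        raise ValueError(
            f"sigma ({sigma}) must be smaller than IC50 ({ic50}): "
            "the propagated log-interval diverges")
    if not temperature > 0:
        raise ValueError(f"temperature must be positive, got {temperature!r}")
    return R_KJ_PER_MOL_K * temperature * math.log(ic50 / (ic50 - sigma))


def convert_experimental_table(table: pd.DataFrame,
                               temperature: float = DEFAULT_TEMPERATURE
                               ) -> pd.DataFrame:
    """Fill dg_exp / dg_err columns of an experimental table from IC50 data.

    Rows that already carry ``dg_exp`` keep it; rows with ``ic50_uM`` get the
    converted value.  Returns a new DataFrame with columns
    ``ligand_id, dg_exp, dg_err`` (dg_err is NaN where not derivable).
    """
    out = []
    for _, row in table.iterrows():
        dg = row.get("dg_exp")
        err = row.get("dg_err")
        ic50 = row.get("ic50_uM")
        sigma = row.get("ic50_sigma_uM")
        if pd.isna(dg) if dg is not None else True:
            if ic50 is None or pd.isna(ic50):
                raise ValueError(
                    f"ligand {row['ligand_id']}: neither dg_exp nor ic50_uM")
            dg = ic50_uM_to_dg(float(ic50), temperature)
        if (err is None or pd.isna(err)) and ic50 is not None \
                and not pd.isna(ic50) and sigma is not None \
                and not pd.isna(sigma):
            err = ic50_error_to_dg_error(float(ic50), float(sigma),
                                         temperature)
        out.append({"ligand_id": row["ligand_id"], "dg_exp": float(dg),
                    "dg_err": float(err) if err is not None
                    and not pd.isna(err) else np.nan})
    return pd.DataFrame(out, columns=["ligand_id", "dg_exp", "dg_err"])
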