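"""Boltzmann-weighted linear interaction energy (LIE) primitives.

The LIE estimate for a ligand bound in pose/conformation i is

    dG_i = beta * dV_el_i + alpha * dV_vdw_i            (alpha/beta form)
    dG_i = alpha * dV_vdw_i + gamma                     (alpha/gamma form)

where dV_el_i and dV_vdw_i are differences of ensemble-averaged
electrostatic and van der Waals ligand-surrounding interaction energies
between the protein-bound simulation i and the ligand free in water.

When several independent simulations (protein conformations x ligand poses
x replicates) exist per ligand, each contributes with a Boltzmann weight

    W_i = exp(-dG_i / kT) / sum_j exp(-dG_j / kT)

and the combined prediction is the weight-averaged model

    dG_calc = beta * sum_i W_i dV_el_i + alpha * sum_i W_i dV_vdw_i (+ gamma)

which equals sum_i W_i dG_i.  Replicate runs started from the same
protein-ligand configuration can either enter the sum individually
("separate" scheme) or have their energy averages pooled first
("replicate_averaged" scheme); in the limit of exhaustive sampling the two
coincide.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: Default thermal energy k_B*T at 300 K, kJ/mol (R = 0.0083145 kJ/mol/K).
KT_300K = 0.0083145 * 300.0

#: Columns identifying one MD run.
KEY_COLUMNS = ["ligand_id", "protein_conf", "pose", "replicate"]

SCHEMES = ("separate", "replicate_averaged")
VARIANTS = ("alpha_beta", "alpha_gamma")


@dataclass(frozen=True)
class LIEParams:
    """Empirical LIE coefficients plus the weighting temperature.

    Exactly one of ``beta`` (electrostatic coefficient) or ``gamma``
    (constant offset, kJ/mol, used with beta fixed at 0) must be set;
    ``alpha`` scales the van der Waals term and ``kT`` (kJ/mol) is the
    thermal energy used in the Boltzmann weights.
    """

    alpha: float
    beta: float | None = None
    gamma: float | None = None
    kT: float = KT_300K

    def __post_init__(self) -> None:
        if not self.kT > 0:
            raise ValueError(f"kT must be positive, got {self.kT}")
        if (self.beta is None) == (self.gamma is None):
            raise ValueError(
                "exactly one of beta (alpha/beta model) or gamma "
                "(alpha/gamma model) must be given")

    @property
    def variant(self) -> str:
        return "alpha_beta" if self.gamma is None else "alpha_gamma"

    def with_coefficients(self, vec: np.ndarray) -> "LIEParams":
        """New params from the fit vector ([beta, alpha] or [alpha, gamma])."""
        if self.variant == "alpha_beta":
            return replace(self, beta=float(vec[0]), alpha=float(vec[1]))
        return replace(self, alpha=float(vec[0]), gamma=float(vec[1]))

    def coefficient_vector(self) -> np.ndarray:
        if self.variant == "alpha_beta":
            return np.array([self.beta, self.alpha], float)
        return np.array([self.alpha, self.gamma], float)


def delta_energies(bound: pd.DataFrame, free: pd.DataFrame) -> pd.DataFrame:
    """Bound-minus-free interaction-energy differences per simulation.

    Parameters
    ----------
    bound : DataFrame
        Per-simulation averages with columns KEY_COLUMNS + v_el_bound,
        v_vdw_bound.
    free : DataFrame
        Per-ligand free-state averages (ligand_id, v_el_free, v_vdw_free).

    Returns
    -------
    DataFrame
        bound plus columns ``d_el`` and ``d_vdw`` (kJ/mol).
    """
    missing = set(bound["ligand_id"]) - set(free["ligand_id"])
    if missing:
        raise ValueError(
            f"no free-state record for ligand(s): {sorted(missing)}")
    merged = bound.merge(free[["ligand_id", "v_el_free", "v_vdw_free"]],
                         on="ligand_id", how="left", validate="many_to_one")
    merged["d_el"] = merged["v_el_bound"] - merged["v_el_free"]
    merged["d_vdw"] = merged["v_vdw_bound"] - merged["v_vdw_free"]
    return merged.drop(columns=["v_el_free", "v_vdw_free"])


def pose_free_energy(params: LIEParams, d_el, d_vdw):
    """Per-simulation LIE free energy dG_i, kJ/mol. Vectorised."""
    d_el = np.asarray(d_el, float)
    d_vdw = np.asarray(d_vdw, float)
    if params.variant == "alpha_beta":
        return params.beta * d_el + params.alpha * d_vdw
    return params.alpha * d_vdw + params.gamma


def boltzmann_weights(dg: np.ndarray, kT: float = KT_300K) -> np.ndarray:
    """Normalised Boltzmann weights over one ligand's simulations.

    Computed shift-stably (the minimum dG is subtracted before
    exponentiating, which leaves the normalised weights unchanged).
    """
    dg = np.asarray(dg, float)
    if dg.size == 0:
        raise ValueError("cannot weight an empty set of simulations")
    if not kT > 0:
        raise ValueError(f"kT must be positive, got {kT}")
    z = np.exp(-(dg - dg.min()) / kT)
    return z / z.sum()


def combine_replicates(bound: pd.DataFrame, scheme: str) -> pd.DataFrame:
    """Apply a replicate-combination scheme to a bound-state table.

    ``separate`` returns the table unchanged (every replicate keeps its own
    Boltzmann weight); ``replicate_averaged`` pools the replicate runs of
    each (ligand, protein_conf, pose) configuration into a single record
    whose energies are the arithmetic means over replicates, labelled by the
    joined replicate names (e.g. "S1+S2").
    """
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; expected one of {SCHEMES}")
    if scheme == "separate":
        return bound.copy()
    group_cols = ["ligand_id", "protein_conf", "pose"]

    def _pool(g: pd.DataFrame) -> pd.Series:
        return pd.Series({
            "replicate": "+".join(sorted(g["replicate"].astype(str))),
            "v_el_bound": g["v_el_bound"].mean(),
            "v_vdw_bound": g["v_vdw_bound"].mean(),
        })

    pooled = (bound.groupby(group_cols, sort=False)
              .apply(_pool, include_groups=False).reset_index())
    return pooled[KEY_COLUMNS + ["v_el_bound", "v_vdw_bound"]]


def combined_free_energy(params: LIEParams, d_el, d_vdw
                         ) -> tuple[float, np.ndarray]:
    """Boltzmann-combined dG_calc and the weights for one ligand.

    Returns ``(dG_calc, W)`` where W are the normalised weights over the
    given simulations and dG_calc is the weighted LIE model evaluated on the
    weight-averaged energy differences (identically sum_i W_i dG_i).
    """
    d_el = np.atleast_1d(np.asarray(d_el, float))
    d_vdw = np.atleast_1d(np.asarray(d_vdw, float))
    if d_el.size == 0:
        raise ValueError("ligand has no simulations to combine")
    dg_i = pose_free_energy(params, d_el, d_vdw)
    w = boltzmann_weights(dg_i, params.kT)
    dg_calc = pose_free_energy(params, float(w @ d_el), float(w @ d_vdw))
    return float(dg_calc), w


@dataclass
class LIEDataset:
    """Assembled inputs for calibration/prediction.

    bound : per-simulation averages (KEY_COLUMNS + v_el_bound, v_vdw_bound)
    free  : per-ligand free-state averages
    experimental : per-ligand dg_exp (kJ/mol) and optional dg_err
    """

    bound: pd.DataFrame
    free: pd.DataFrame
    experimental: pd.DataFrame
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        ligs = set(self.bound["ligand_id"])
        for name, table in (("free-state", self.free),
                            ("experimental", self.experimental)):
            absent = ligs - set(table["ligand_id"])
            if absent:
                raise ValueError(
                    f"bound-state ligand(s) missing from {name} table: "
                    f"{sorted(absent)}")
        dup = self.bound.duplicated(subset=KEY_COLUMNS)
        if dup.any():
            rows = self.bound.loc[dup, KEY_COLUMNS].to_records(index=False)
            raise ValueError(f"duplicate simulation key(s): {list(rows)}")

    @property
    def ligands(self) -> list[str]:
        return list(dict.fromkeys(self.bound["ligand_id"]))

    def dg_exp(self) -> pd.Series:
        s = self.experimental.set_index("ligand_id")["dg_exp"]
        return s.loc[self.ligands]
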