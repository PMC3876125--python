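"""Reading and writing of energy and affinity tables.

All energies are in kJ/mol.  Three columnar text formats are supported
(delimiter auto-detected among tab, comma and semicolon; decimal points
only):

* bound-state table — one row per MD simulation of the protein-bound ligand:
  ``ligand_id, protein_conf, pose, replicate, v_el_bound, v_vdw_bound``
  (optional: ``n_frames, se_el, se_vdw, unit``)
* free-state table — one row per ligand free in water:
  ``ligand_id, v_el_free, v_vdw_free``
* experimental table — ``ligand_id`` plus ``dg_exp``/``dg_err`` (kJ/mol)
  and/or ``ic50_uM``/``ic50_sigma_uM``

Raw two-column interaction-energy time series (time_ps, v_el, v_vdw;
``#`` comments) can be averaged into bound-state rows with
:func:`average_timeseries`.
"""

from __future__ import annotations

import logging
import math
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from . import affinity
from .core import KEY_COLUMNS, LIEDataset

logger = logging.getLogger(__name__)

KCAL_TO_KJ = 4.184

#: Tolerated discrepancy when both dg_exp and ic50 are given, kJ/mol.
CONSISTENCY_TOL = 0.02


class TableFormatError(ValueError):
    """Missing/odd columns or an unreadable table layout."""


class TableValidationError(ValueError):
    """Well-formed table whose content violates an invariant."""


def _sniff_sep(path) -> str:
    with open(path) as fh:
        header = fh.readline()
    for sep in ("\t", ";", ","):
        if sep in header:
            return sep
    return "\t"


def _read_table(path, dialect: str | None, required: Sequence[str],
                numeric: Sequence[str]) -> pd.DataFrame:
    sep = dialect or _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, comment="#", skip_blank_lines=True,
                     dtype=str)
    df.columns = [c.strip() for c in df.columns]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TableFormatError(
            f"{path}: missing required column(s) {missing}; "
            f"found {list(df.columns)}")
    for col in numeric:
        if col not in df.columns:
            continue
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            row = int(bad.idxmax()) + 2  # 1-based, after header
            raise TableFormatError(
                f"{path}: non-numeric value {df.loc[bad.idxmax(), col]!r} "
                f"in column {col!r} at line {row}")
        df[col] = converted
    if "unit" in df.columns:
        units = set(df["unit"].dropna().str.strip())
        if units - {"kJ/mol"}:
            raise TableValidationError(
                f"{path}: energies must be in kJ/mol, found unit(s) {units}")
    return df


def _apply_kcal(df: pd.DataFrame, cols: Sequence[str], kcal: bool) -> None:
    if kcal:
        for c in cols:
            if c in df.columns:
                df[c] = df[c] * KCAL_TO_KJ


def read_bound_energies(path, dialect: str | None = None,
                        kcal_input: bool = False) -> pd.DataFrame:
    """Read a bound-state energy table; one row per simulation.

    Duplicate (ligand, conformation, pose, replicate) keys are rejected.
    ``kcal_input=True`` converts the energy columns from kcal/mol.
    """
    df = _read_table(path, dialect,
                     required=KEY_COLUMNS + ["v_el_bound", "v_vdw_bound"],
                     numeric=["v_el_bound", "v_vdw_bound", "n_frames",
                              "se_el", "se_vdw"])
    if df.empty:
        logger.warning("%s: bound-state table has a header but no rows", path)
        return df
    for col in KEY_COLUMNS:
        if (df[col].isna() | (df[col].str.strip() == "")).any():
            raise TableValidationError(f"{path}: empty value in {col!r}")
    dup = df.duplicated(subset=KEY_COLUMNS)
    if dup.any():
        keys = df.loc[dup, KEY_COLUMNS].astype(str).agg(",".join, axis=1)
        raise TableValidationError(
            f"{path}: duplicate simulation key(s): {sorted(set(keys))}")
    if "n_frames" in df.columns and (df["n_frames"].dropna() <= 0).any():
        raise TableValidationError(f"{path}: n_frames must be positive")
    if not np.isfinite(df[["v_el_bound", "v_vdw_bound"]].to_numpy()).all():
        raise TableValidationError(f"{path}: non-finite energy value")
    _apply_kcal(df, ["v_el_bound", "v_vdw_bound", "se_el", "se_vdw"],
                kcal_input)
    return df.reset_index(drop=True)


def read_free_energies(path, dialect: str | None = None,
                       kcal_input: bool = False) -> pd.DataFrame:
    """Read a free-state (ligand in water) table; one row per ligand."""
    df = _read_table(path, dialect,
                     required=["ligand_id", "v_el_free", "v_vdw_free"],
                     numeric=["v_el_free", "v_vdw_free"])
    if df.empty:
        logger.warning("%s: free-state table has a header but no rows", path)
        return df
    dup = df.duplicated(subset=["ligand_id"])
    if dup.any():
        raise TableValidationError(
            f"{path}: ligand(s) listed twice: "
            f"{sorted(set(df.loc[dup, 'ligand_id']))}")
    if not np.isfinite(df[["v_el_free", "v_vdw_free"]].to_numpy()).all():
        raise TableValidationError(f"{path}: non-finite energy value")
    _apply_kcal(df, ["v_el_free", "v_vdw_free"], kcal_input)
    return df.reset_index(drop=True)


def read_experimental(path, dialect: str | None = None,
                      temperature: float = affinity.DEFAULT_TEMPERATURE
                      ) -> pd.DataFrame:
    """Read an experimental-affinity table.

    Each row needs at least one of ``dg_exp`` (kJ/mol) or ``ic50_uM``; when
    both are present they must agree within 0.02 kJ/mol after conversion at
    ``temperature``.  Returns columns ligand_id, dg_exp, dg_err, ic50_uM,
    ic50_sigma_uM (NaN where absent).
    """
    df = _read_table(path, dialect, required=["ligand_id"],
                     numeric=["dg_exp", "dg_err", "ic50_uM", "ic50_sigma_uM"])
    if "dg_exp" not in df.columns and "ic50_uM" not in df.columns:
        raise TableFormatError(
            f"{path}: need a dg_exp or an ic50_uM column")
    for col in ("dg_exp", "dg_err", "ic50_uM", "ic50_sigma_uM"):
        if col not in df.columns:
            df[col] = np.nan
    if df.empty:
        logger.warning("%s: experimental table has a header but no rows", path)
        return df[["ligand_id", "dg_exp", "dg_err", "ic50_uM",
                   "ic50_sigma_uM"]]
    dup = df.duplicated(subset=["ligand_id"])
    if dup.any():
        raise TableValidationError(
            f"{path}: ligand(s) listed twice: "
            f"{sorted(set(df.loc[dup, 'ligand_id']))}")
    for _, row in df.iterrows():
        has_dg = not pd.isna(row["dg_exp"])
        has_ic = not pd.isna(row["ic50_uM"])
        if not (has_dg or has_ic):
            raise TableValidationError(
                f"{path}: ligand {row['ligand_id']}: neither dg_exp nor "
                "ic50_uM given")
        if has_ic and row["ic50_uM"] <= 0:
            raise TableValidationError(
                f"{path}: ligand {row['ligand_id']}: IC50 must be positive")
        if has_dg and has_ic:
            dg_conv = affinity.ic50_uM_to_dg(row["ic50_uM"], temperature)
            if abs(dg_conv - row["dg_exp"]) > CONSISTENCY_TOL:
                raise TableValidationError(
                    f"{path}: ligand {row['ligand_id']}: dg_exp "
                    f"{row['dg_exp']} kJ/mol inconsistent with IC50 "
                    f"{row['ic50_uM']} uM (-> {dg_conv:.4f} kJ/mol)")
        if not pd.isna(row["dg_err"]) and row["dg_err"] < 0:
            raise TableValidationError(
                f"{path}: ligand {row['ligand_id']}: dg_err must be >= 0")
    return df[["ligand_id", "dg_exp", "dg_err", "ic50_uM",
               "ic50_sigma_uM"]].reset_index(drop=True)


def write_table(df: pd.DataFrame, path, sep: str = "\t") -> None:
    """Write a table in the canonical tab-separated text form."""
    df.to_csv(path, sep=sep, index=False)


class TimeseriesAverages(NamedTuple):
    mean_el: float
    mean_vdw: float
    se_el: float
    se_vdw: float
    n_frames: int


def _block_se(x: np.ndarray, n_blocks: int) -> float:
    """Standard error of the mean from block averaging.

    The series is split into ``n_blocks`` equal contiguous blocks (trailing
    remainder frames are attached to the last block); the SE is the standard
    deviation of block means over sqrt(n_blocks).  With serially correlated
    MD data this is less optimistic than the naive sqrt(n) formula.
    """
    n_blocks = min(n_blocks, len(x))
    edges = np.linspace(0, len(x), n_blocks + 1).astype(int)
    means = np.array([x[a:b].mean() for a, b in zip(edges[:-1], edges[1:])])
    if n_blocks < 2:
        return float("nan")
    return float(means.std(ddof=1) / math.sqrt(n_blocks))


def average_timeseries(time_ps, v_el, v_vdw, discard: float = 0.0,
                       n_blocks: int = 10) -> TimeseriesAverages:
    """Average a per-frame interaction-energy time series.

    Parameters
    ----------
    time_ps, v_el, v_vdw : array-like
        Frame times (strictly increasing) and the two energy series, kJ/mol.
    discard : float
        Initial fraction of frames to drop (default 0; production data are
        assumed post-equilibration).
    n_blocks : int
        Number of blocks for the block-averaged standard error.

    Returns
    -------
    TimeseriesAverages
        Plain arithmetic means over the retained frames, block-averaged
        standard errors and the retained frame count.
    """
    t = np.asarray(time_ps, float)
    el = np.asarray(v_el, float)
    vdw = np.asarray(v_vdw, float)
    if not (len(t) == len(el) == len(vdw)):
        raise ValueError("time and energy series differ in length")
    if np.any(np.diff(t) <= 0):
        raise ValueError("frame times must be strictly increasing")
    if not 0 <= discard < 1:
        raise ValueError(f"discard fraction must be in [0, 1), got {discard}")
    start = int(math.floor(discard * len(t)))
    el, vdw = el[start:], vdw[start:]
    if len(el) < 2:
        raise ValueError(
            f"need at least 2 frames after discarding, have {len(el)}")
    return TimeseriesAverages(
        mean_el=float(el.mean()), mean_vdw=float(vdw.mean()),
        se_el=_block_se(el, n_blocks), se_vdw=_block_se(vdw, n_blocks),
        n_frames=len(el))


def read_timeseries(path) -> pd.DataFrame:
    """Read a whitespace-delimited time series (time_ps, v_el, v_vdw)."""
    df = pd.read_csv(path, sep=r"\s+", comment="#", header=None,
                     names=["time_ps", "v_el", "v_vdw"])
    if df.isna().any().any():
        raise TableFormatError(f"{path}: malformed time-series row")
    return df


def assemble_dataset(bound: pd.DataFrame, free: pd.DataFrame,
                     experimental: pd.DataFrame,
                     temperature: float = affinity.DEFAULT_TEMPERATURE
                     ) -> LIEDataset:
    """Cross-validate the three tables and build a :class:`LIEDataset`.

    Experimental rows lacking dg_exp are converted from IC50; configurations
    with a single replicate are allowed but logged (they contribute one run
    under either combination scheme).
    """
    exp = affinity.convert_experimental_table(experimental, temperature)
    warnings: list[str] = []
    counts = bound.groupby(["ligand_id", "protein_conf", "pose"],
                           sort=False)["replicate"].nunique()
    for key, n in counts.items():
        if n == 1:
            msg = ("configuration %s has a single replicate; it enters both "
                   "combination schemes as one run" % (key,))
            warnings.append(msg)
            logger.warning(msg)
    return LIEDataset(bound=bound.reset_index(drop=True),
                      free=free.reset_index(drop=True),
                      experimental=exp, warnings=warnings)
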