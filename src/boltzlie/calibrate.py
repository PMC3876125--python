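"""Self-consistent calibration of Boltzmann-weighted LIE models.

Because the Boltzmann weights W_i depend on the coefficients being fitted,
calibration is a fixed-point problem: starting from an initial guess the
coefficients and weights are updated alternately (block coordinate descent)

    1. evaluate per-simulation dG_i and per-ligand weights at the current
       coefficients;
    2. refit the coefficients by unweighted least squares of dG_exp on the
       weight-averaged energy differences (weights frozen);
    3. repeat until both the coefficients and the RMSE stop changing.

Several fixed points may exist, so a small grid of restarts is run and the
lowest-RMSE converged solution returned.  If a refit step increases the
RMSE, the parameter step is halved (up to 10 times) before the restart is
declared non-convergent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core import (KT_300K, LIEDataset, LIEParams, boltzmann_weights,
                   combine_replicates, delta_energies, pose_free_energy)

logger = logging.getLogger(__name__)

#: 1 kcal/mol — a prediction deviating by more than this is an outlier.
OUTLIER_THRESHOLD = 4.184

#: Default restart grid for the alpha/beta variant (plus the linear-response
#: theoretical point beta = 0.5 with alpha = 0.5).
DEFAULT_RESTARTS_AB = tuple(
    (a, b) for a in (0.1, 0.4, 0.7) for b in (0.1, 0.4, 0.7)
) + ((0.5, 0.5),)

#: Restart grid for the alpha/gamma variant (gamma shifts every pose dG
#: equally, so weights are insensitive to it; alpha carries the restarts).
DEFAULT_RESTARTS_AG = ((0.1, 0.0), (0.4, 0.0), (0.7, 0.0), (0.5, -10.0))


class DegenerateDesignError(ValueError):
    """Regression design is rank deficient (nothing to fit)."""


class ConvergenceError(RuntimeError):
    """No restart reached a self-consistent fixed point."""

    def __init__(self, message: str, restart_log: list):
        super().__init__(message)
        self.restart_log = restart_log


@dataclass(frozen=True)
class ModelSpec:
    """Which simulations enter a LIE model, and in what form.

    ``protein_confs`` / ``poses`` restrict the simulations included (None
    means no restriction) — e.g. a traditional single-simulation model uses
    one conformation and one pose.  ``scheme`` chooses whether replicate
    runs are weighted separately or pooled first, and ``variant`` selects
    the alpha/beta or alpha/gamma (beta = 0 plus offset) functional form.
    """

    name: str = "all"
    protein_confs: frozenset[str] | None = None
    poses: frozenset[str] | None = None
    replicates: frozenset[str] | None = None
    scheme: str = "separate"
    variant: str = "alpha_beta"

    def __post_init__(self) -> None:
        for attr in ("protein_confs", "poses", "replicates"):
            val = getattr(self, attr)
            if val is not None and not isinstance(val, frozenset):
                object.__setattr__(self, attr, frozenset(val))
        if self.scheme not in ("separate", "replicate_averaged"):
            raise ValueError(f"unknown scheme {self.scheme!r}")
        if self.variant not in ("alpha_beta", "alpha_gamma"):
            raise ValueError(f"unknown variant {self.variant!r}")

    def initial_params(self, kT: float) -> list[LIEParams]:
        if self.variant == "alpha_beta":
            return [LIEParams(alpha=a, beta=b, kT=kT)
                    for a, b in DEFAULT_RESTARTS_AB]
        return [LIEParams(alpha=a, gamma=g, kT=kT)
                for a, g in DEFAULT_RESTARTS_AG]


@dataclass
class CalibrationResult:
    """Fitted coefficients with per-ligand predictions and diagnostics."""

    params: LIEParams
    param_se: dict[str, float]
    per_ligand: pd.DataFrame      # index ligand_id: dg_calc, dg_exp, residual
    weights: pd.DataFrame         # rows ligands, columns simulation labels
    rmse: float
    outliers: list[tuple[str, float]]
    converged: bool
    n_iter: int
    restart_log: list[dict]
    spec: ModelSpec

    def to_dict(self) -> dict:
        p = self.params
        d = {"model": self.spec.name, "variant": p.variant,
             "scheme": self.spec.scheme, "kT": p.kT,
             "alpha": p.alpha, "beta": p.beta, "gamma": p.gamma,
             "param_se": self.param_se, "rmse": self.rmse,
             "converged": self.converged, "n_iter": self.n_iter,
             "outliers": [{"ligand_id": l, "abs_error": e}
                          for l, e in self.outliers],
             "per_ligand": {
                 lig: {"dg_calc": float(r["dg_calc"]),
                       "dg_exp": float(r["dg_exp"]),
                       "residual": float(r["residual"])}
                 for lig, r in self.per_ligand.iterrows()},
             "weights": {lig: {c: float(v) for c, v in row.dropna().items()}
                         for lig, row in self.weights.iterrows()},
             "restart_log": self.restart_log}
        return d


def rmse(calc: pd.Series, exp: pd.Series) -> float:
    """Root-mean-square error between predicted and experimental dG, kJ/mol."""
    if set(calc.index) != set(exp.index):
        raise ValueError(
            f"ligand sets differ: {sorted(set(calc.index) ^ set(exp.index))}")
    if len(calc) == 0:
        raise ValueError("empty ligand set")
    resid = calc - exp.loc[calc.index]
    return float(np.sqrt(np.mean(np.square(resid.to_numpy()))))


def find_outliers(residuals: pd.Series,
                  threshold: float = OUTLIER_THRESHOLD
                  ) -> list[tuple[str, float]]:
    """Ligands whose |residual| strictly exceeds ``threshold`` (kJ/mol).

    Returned as (ligand_id, |error| rounded to 2 decimals), sorted by
    ligand id.
    """
    out = [(str(lig), round(abs(float(r)), 2))
           for lig, r in residuals.items() if abs(float(r)) > threshold]
    return sorted(out)


def simulation_label(row: pd.Series, scheme: str) -> str:
    base = f"{row['protein_conf']}-{row['pose']}"
    return base if scheme == "replicate_averaged" else \
        f"{base}-{row['replicate']}"


def prepare_deltas(dataset: LIEDataset, spec: ModelSpec) -> pd.DataFrame:
    """Filter, combine replicates and form energy differences for a model.

    Returns one row per effective simulation with columns ligand_id, label,
    d_el, d_vdw.  Raises if any ligand ends up with no simulation.
    """
    bound = dataset.bound
    if spec.protein_confs is not None:
        bound = bound[bound["protein_conf"].isin(spec.protein_confs)]
    if spec.poses is not None:
        bound = bound[bound["pose"].isin(spec.poses)]
    if spec.replicates is not None:
        bound = bound[bound["replicate"].isin(spec.replicates)]
    empty = set(dataset.ligands) - set(bound["ligand_id"])
    if empty:
        raise ValueError(
            f"model {spec.name!r}: no simulations left for ligand(s) "
            f"{sorted(empty)}")
    combined = combine_replicates(bound, spec.scheme)
    deltas = delta_energies(combined, dataset.free)
    deltas = deltas.assign(
        label=deltas.apply(simulation_label, axis=1, scheme=spec.scheme))
    return deltas[["ligand_id", "label", "d_el", "d_vdw"]].reset_index(
        drop=True)


@dataclass
class Evaluation:
    """One ligand-set evaluation at fixed coefficients."""

    dg_calc: pd.Series
    weights: pd.DataFrame
    weighted: pd.DataFrame        # index ligand: wd_el, wd_vdw
    rmse: float
    residuals: pd.Series = field(init=False)
    dg_exp: pd.Series | None = None

    def __post_init__(self) -> None:
        self.residuals = (self.dg_calc - self.dg_exp
                          if self.dg_exp is not None
                          else self.dg_calc * np.nan)


def evaluate(deltas: pd.DataFrame, params: LIEParams,
             dg_exp: pd.Series | None = None) -> Evaluation:
    """Weights, weighted energy differences and predictions at ``params``."""
    rows_w, rows_wd, dg_rows = {}, {}, {}
    for lig, grp in deltas.groupby("ligand_id", sort=False):
        d_el = grp["d_el"].to_numpy()
        d_vdw = grp["d_vdw"].to_numpy()
        dg_i = pose_free_energy(params, d_el, d_vdw)
        w = boltzmann_weights(dg_i, params.kT)
        wd_el, wd_vdw = float(w @ d_el), float(w @ d_vdw)
        rows_w[lig] = pd.Series(w, index=grp["label"].to_numpy())
        rows_wd[lig] = {"wd_el": wd_el, "wd_vdw": wd_vdw}
        dg_rows[lig] = float(pose_free_energy(params, wd_el, wd_vdw))
    dg_calc = pd.Series(dg_rows, name="dg_calc")
    weights = pd.DataFrame(rows_w).T
    weighted = pd.DataFrame(rows_wd).T
    r = rmse(dg_calc, dg_exp) if dg_exp is not None else float("nan")
    return Evaluation(dg_calc=dg_calc, weights=weights, weighted=weighted,
                      rmse=r, dg_exp=dg_exp)


def fit_given_weights(weighted: pd.DataFrame, dg_exp: pd.Series,
                      variant: str) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares coefficients with the Boltzmann weights frozen.

    ``weighted`` holds per-ligand weight-averaged differences (wd_el,
    wd_vdw).  The alpha/beta variant regresses dG_exp on (wd_el, wd_vdw)
    without intercept and returns ([beta, alpha], their standard errors);
    the alpha/gamma variant regresses on (wd_vdw, 1) and returns
    ([alpha, gamma], SEs).
    """
    y = dg_exp.loc[weighted.index].to_numpy(float)
    if variant == "alpha_beta":
        X = weighted[["wd_el", "wd_vdw"]].to_numpy(float)
        names = ["wd_el (electrostatic)", "wd_vdw (van der Waals)"]
    elif variant == "alpha_gamma":
        X = np.column_stack([weighted["wd_vdw"].to_numpy(float),
                             np.ones(len(weighted))])
        names = ["wd_vdw (van der Waals)", "intercept (gamma)"]
    else:
        raise ValueError(f"unknown variant {variant!r}")
    n, p = X.shape
    if n < p:
        raise DegenerateDesignError(
            f"{n} ligands cannot determine {p} coefficients")
    # scale-invariant rank test; a constant-zero or repeated column has no
    # information once the other column is fixed
    sv = np.linalg.svd(X, compute_uv=False)
    if sv[0] == 0 or sv[-1] / sv[0] < 1e-10:
        norms = np.linalg.norm(X, axis=0)
        bad = [names[j] for j in range(p)
               if norms[j] == 0 or np.ptp(X[:, j]) / max(norms[j], 1e-300)
               < 1e-12]
        raise DegenerateDesignError(
            "rank-deficient design; offending column(s): "
            + (", ".join(bad) if bad else ", ".join(names)))
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    dof = max(n - p, 1)
    sigma2 = float(resid @ resid) / dof
    cov = sigma2 * np.linalg.inv(X.T @ X)
    se = np.sqrt(np.diag(cov))
    return coef, se


def _run_fixed_point(deltas: pd.DataFrame, dg_exp: pd.Series,
                     init: LIEParams, tol_params: float, tol_rmse: float,
                     max_iter: int) -> dict:
    params = init
    ev = evaluate(deltas, params, dg_exp)
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        old_vec = params.coefficient_vector()
        new_vec, _ = fit_given_weights(ev.weighted, dg_exp, params.variant)
        cand = params.with_coefficients(new_vec)
        ev_new = evaluate(deltas, cand, dg_exp)
        # the self-consistent fixed point need not sit exactly at the
        # minimum of the re-weighted RMSE, so tiny relative increases are
        # fixed-point noise, not oscillation; only damp real ones
        rise = ev.rmse * 1e-4 + tol_rmse
        halvings = 0
        while ev_new.rmse > ev.rmse + rise and halvings < 10:
            halvings += 1
            new_vec = old_vec + (cand.coefficient_vector() - old_vec) / 2
            cand = params.with_coefficients(new_vec)
            ev_new = evaluate(deltas, cand, dg_exp)
        if ev_new.rmse > ev.rmse + rise:
            break  # damping failed: oscillating restart
        dparams = float(np.max(np.abs(cand.coefficient_vector() - old_vec)))
        drmse = abs(ev_new.rmse - ev.rmse)
        params, ev = cand, ev_new
        if dparams < tol_params and drmse < tol_rmse:
            converged = True
            break
    return {"init": init, "params": params, "evaluation": ev,
            "rmse": ev.rmse, "converged": converged, "n_iter": n_iter}


def calibrate(dataset: LIEDataset, spec: ModelSpec,
              init: LIEParams | None = None, kT: float = KT_300K,
              tol_params: float = 1e-6, tol_rmse: float = 1e-8,
              max_iter: int = 500, restarts: Iterable[LIEParams] | None = None,
              outlier_threshold: float = OUTLIER_THRESHOLD
              ) -> CalibrationResult:
    """Fit LIE coefficients self-consistently for one model specification.

    Runs the fixed-point iteration from ``init`` (if given) and from every
    restart (default: a small coefficient grid), and returns the converged
    solution with the lowest RMSE.  ``max_iter=0`` evaluates ``init``
    without fitting (converged=False), as a baseline/control.
    """
    deltas = prepare_deltas(dataset, spec)
    dg_exp = dataset.dg_exp()
    if len(dg_exp) < 2:
        raise ValueError("need at least 2 ligands to calibrate")

    starts: list[LIEParams] = []
    if init is not None:
        if init.variant != spec.variant:
            raise ValueError(
                f"init is {init.variant} but model wants {spec.variant}")
        starts.append(init)
    if max_iter == 0:
        if init is None:
            raise ValueError("max_iter=0 requires an explicit init")
        ev = evaluate(deltas, init, dg_exp)
        return _assemble(init, ev, spec, deltas, dg_exp, converged=False,
                         n_iter=0, restart_log=[], threshold=outlier_threshold)
    if restarts is not None:
        starts.extend(restarts)
    else:
        starts.extend(spec.initial_params(kT))

    log: list[dict] = []
    best = None
    for start in starts:
        run = _run_fixed_point(deltas, dg_exp, start, tol_params, tol_rmse,
                               max_iter)
        log.append({"init": _params_tuple(start),
                    "final": _params_tuple(run["params"]),
                    "rmse": run["rmse"], "converged": run["converged"],
                    "n_iter": run["n_iter"]})
        if run["converged"] and (best is None or run["rmse"] < best["rmse"]):
            best = run
    if best is None:
        raise ConvergenceError(
            f"model {spec.name!r}: no restart converged in {max_iter} "
            "iterations", log)
    return _assemble(best["params"], best["evaluation"], spec, deltas,
                     dg_exp, converged=True, n_iter=best["n_iter"],
                     restart_log=log, threshold=outlier_threshold)


def _params_tuple(p: LIEParams) -> dict:
    return {"alpha": p.alpha, "beta": p.beta, "gamma": p.gamma}


def _assemble(params: LIEParams, ev: Evaluation, spec: ModelSpec,
              deltas: pd.DataFrame, dg_exp: pd.Series, converged: bool,
              n_iter: int, restart_log: list, threshold: float
              ) -> CalibrationResult:
    _, se = fit_given_weights(ev.weighted, dg_exp, params.variant)
    se_names = (["beta", "alpha"] if params.variant == "alpha_beta"
                else ["alpha", "gamma"])
    per_ligand = pd.DataFrame({"dg_calc": ev.dg_calc,
                               "dg_exp": dg_exp.loc[ev.dg_calc.index],
                               "residual": ev.residuals})
    return CalibrationResult(
        params=params, param_se=dict(zip(se_names, map(float, se))),
        per_ligand=per_ligand, weights=ev.weights, rmse=ev.rmse,
        outliers=find_outliers(ev.residuals, threshold), converged=converged,
        n_iter=n_iter, restart_log=restart_log, spec=spec)


def predict(dataset: LIEDataset, spec: ModelSpec, params: LIEParams
            ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Deterministic per-ligand predictions at fixed coefficients.

    Returns ``(per_ligand, weights)``: dg_calc (plus dg_exp/residual when
    experimental data exist) and the weight table in the rows-=-ligands,
    columns-=-simulations layout.
    """
    deltas = prepare_deltas(dataset, spec)
    has_exp = not dataset.experimental.empty
    dg_exp = dataset.dg_exp() if has_exp else None
    ev = evaluate(deltas, params, dg_exp)
    per_ligand = pd.DataFrame({"dg_calc": ev.dg_calc})
    if dg_exp is not None:
        per_ligand["dg_exp"] = dg_exp.loc[ev.dg_calc.index]
        per_ligand["residual"] = ev.residuals
    return per_ligand, ev.weights


@dataclass
class SurfaceResult:
    alpha_grid: np.ndarray
    beta_grid: np.ndarray
    rmse: np.ndarray              # shape (len(alpha_grid), len(beta_grid))
    ceiling: float
    above_ceiling: np.ndarray     # boolean mask, same shape

    def to_frame(self) -> pd.DataFrame:
        a, b = np.meshgrid(self.alpha_grid, self.beta_grid, indexing="ij")
        return pd.DataFrame({"alpha": a.ravel(), "beta": b.ravel(),
                             "rmse": self.rmse.ravel(),
                             "above_ceiling": self.above_ceiling.ravel()})

    def minimum(self) -> tuple[float, float, float]:
        i, j = np.unravel_index(np.argmin(self.rmse), self.rmse.shape)
        return (float(self.alpha_grid[i]), float(self.beta_grid[j]),
                float(self.rmse[i, j]))


def rmse_surface(dataset: LIEDataset, spec: ModelSpec,
                 alpha_grid: Sequence[float], beta_grid: Sequence[float],
                 kT: float = KT_300K, ceiling: float = 5.0,
                 freeze_weights_at: LIEParams | None = None
                 ) -> SurfaceResult:
    """RMSE of the alpha/beta model over a coefficient grid.

    By default the Boltzmann weights are re-evaluated at every grid point
    (no refitting inside a cell); ``freeze_weights_at`` instead freezes the
    weights at one coefficient pair for the whole surface.  Values above
    ``ceiling`` (a display convention for contour plots) are returned
    unclamped but flagged.
    """
    if spec.variant != "alpha_beta":
        raise ValueError("RMSE surfaces are defined for the alpha/beta model")
    alpha_grid = np.asarray(alpha_grid, float)
    beta_grid = np.asarray(beta_grid, float)
    if alpha_grid.size == 0 or beta_grid.size == 0:
        raise ValueError("coefficient grids must be non-empty")
    for g, name in ((alpha_grid, "alpha"), (beta_grid, "beta")):
        if g.size > 1 and np.any(np.diff(g) <= 0):
            raise ValueError(f"{name} grid must be strictly increasing")
    deltas = prepare_deltas(dataset, spec)
    dg_exp = dataset.dg_exp()
    frozen = (evaluate(deltas, freeze_weights_at, dg_exp).weighted
              if freeze_weights_at is not None else None)
    out = np.empty((alpha_grid.size, beta_grid.size))
    for i, a in enumerate(alpha_grid):
        for j, b in enumerate(beta_grid):
            params = LIEParams(alpha=float(a), beta=float(b), kT=kT)
            if frozen is not None:
                dg_calc = pd.Series(
                    pose_free_energy(params, frozen["wd_el"].to_numpy(),
                                     frozen["wd_vdw"].to_numpy()),
                    index=frozen.index)
                out[i, j] = rmse(dg_calc, dg_exp)
            else:
                out[i, j] = evaluate(deltas, params, dg_exp).rmse
    return SurfaceResult(alpha_grid=alpha_grid, beta_grid=beta_grid,
                         rmse=out, ceiling=ceiling,
                         above_ceiling=out > ceiling)
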