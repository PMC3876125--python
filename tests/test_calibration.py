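"""Self-consistent calibration: oracles, recovery, surfaces, outliers."""

import numpy as np
import pandas as pd
import pytest

import boltzlie as bl
from boltzlie.calibrate import (ConvergenceError, DegenerateDesignError,
                                fit_given_weights, prepare_deltas)
from boltzlie.core import KT_300K


def normal_equations(X, y):
    """Independent closed-form least-squares oracle."""
    return np.linalg.solve(X.T @ X, X.T @ y)


def single_sim_spec(**kw):
    return bl.ModelSpec(name="P70-M1", protein_confs={"P70"}, poses={"M1"},
                        replicates={"S1"}, **kw)


# ------------------------------------------------------------------ rmse

def test_rmse_values():
    idx = ["L1", "L2"]
    calc = pd.Series([-20.0, -25.0], index=idx)
    assert bl.rmse(calc, calc) == 0.0
    exp = pd.Series([-23.0, -21.0], index=idx)  # residuals +3, -4
    assert bl.rmse(calc, exp) == pytest.approx(np.sqrt(12.5))
    one = pd.Series([-20.0], index=["L1"])
    assert bl.rmse(one, pd.Series([-17.5], index=["L1"])) == 2.5


def test_rmse_mismatched_ligands():
    with pytest.raises(ValueError, match="differ"):
        bl.rmse(pd.Series([1.0], index=["L1"]),
                pd.Series([1.0], index=["L2"]))


# -------------------------------------------------------------- outliers

def test_outlier_rule_is_strict_one_kcal():
    resid = pd.Series({"L1": 5.01, "L2": 1.0, "L3": 4.184})
    assert bl.find_outliers(resid) == [("L1", 5.01)]
    assert bl.find_outliers(pd.Series({"L1": 0.5, "L2": -1.0})) == []
    # sign does not matter, values rounded to 2 decimals, sorted by ligand
    resid2 = pd.Series({"L9": -6.781, "L2": 5.456})
    assert bl.find_outliers(resid2) == [("L2", 5.46), ("L9", 6.78)]


# ----------------------------------------------------- fit_given_weights

def test_fit_recovers_exact_linear_model():
    rng = np.random.default_rng(0)
    wd = pd.DataFrame({"wd_el": rng.uniform(-60, 0, 5),
                       "wd_vdw": rng.uniform(-120, -20, 5)},
                      index=[f"L{i}" for i in range(5)])
    y = 0.2 * wd["wd_el"] + 0.4 * wd["wd_vdw"]
    coef, _ = fit_given_weights(wd, y, "alpha_beta")
    oracle = normal_equations(wd[["wd_el", "wd_vdw"]].to_numpy(),
                              y.to_numpy())
    np.testing.assert_allclose(coef, [0.2, 0.4], atol=1e-10)
    np.testing.assert_allclose(coef, oracle, atol=1e-10)


def test_fit_alpha_gamma_variant():
    wd = pd.DataFrame({"wd_el": np.zeros(6),
                       "wd_vdw": np.linspace(-100, -40, 6)},
                      index=[f"L{i}" for i in range(6)])
    y = 0.3 * wd["wd_vdw"] - 2.0
    coef, _ = fit_given_weights(wd, y, "alpha_gamma")
    X = np.column_stack([wd["wd_vdw"], np.ones(6)])
    np.testing.assert_allclose(coef, normal_equations(X, y.to_numpy()),
                               atol=1e-10)
    np.testing.assert_allclose(coef, [0.3, -2.0], atol=1e-10)


def test_degenerate_design_named():
    wd = pd.DataFrame({"wd_el": [-10.0, -20.0, -30.0],
                       "wd_vdw": [-50.0, -50.0, -50.0]},
                      index=["L1", "L2", "L3"])
    y = pd.Series([-20.0, -22.0, -24.0], index=wd.index)
    # constant columns are fine for alpha/beta as long as rank is 2;
    # make it truly rank deficient: vdw proportional to el
    wd2 = pd.DataFrame({"wd_el": [-10.0, -20.0, -30.0],
                        "wd_vdw": [-20.0, -40.0, -60.0]}, index=wd.index)
    with pytest.raises(DegenerateDesignError):
        fit_given_weights(wd2, y, "alpha_beta")
    # alpha/gamma with constant vdw: collinear with the intercept
    with pytest.raises(DegenerateDesignError, match="van der Waals"):
        fit_given_weights(wd, y, "alpha_gamma")


# -------------------------------------------------------------- calibrate

def test_single_simulation_model_equals_least_squares(noisy_dataset):
    """With one simulation per ligand all weights are 1 and the iterative
    fit must coincide with plain two-parameter least squares."""
    ds, _ = noisy_dataset
    spec = single_sim_spec()
    res = bl.calibrate(ds, spec)
    deltas = prepare_deltas(ds, spec)
    X = deltas.set_index("ligand_id")[["d_el", "d_vdw"]].to_numpy()
    y = ds.dg_exp().to_numpy()
    beta, alpha = normal_equations(X, y)
    assert res.params.beta == pytest.approx(beta, abs=1e-8)
    assert res.params.alpha == pytest.approx(alpha, abs=1e-8)
    assert (res.weights.to_numpy() == 1.0).all()


@pytest.mark.parametrize("scheme", ["separate", "replicate_averaged"])
def test_noise_free_parameter_recovery(noise_free_dataset, scheme):
    ds, truth = noise_free_dataset
    res = bl.calibrate(ds, bl.ModelSpec(scheme=scheme))
    assert res.converged
    assert res.params.alpha == pytest.approx(truth["alpha"], abs=1e-4)
    assert res.params.beta == pytest.approx(truth["beta"], abs=1e-4)
    assert res.rmse <= 1e-8


def test_recovery_bias_shrinks_with_ligand_count():
    """With observation noise the coefficient error contracts as the
    training set grows (fixed seeds, sigma = 1 kJ/mol)."""
    errs = {}
    for n in (10, 50, 200):
        data = bl.generate(bl.GeneratorSpec(n_ligands=n, seed=123,
                                            obs_noise_sd=1.0))
        ds = bl.assemble_dataset(data.bound, data.free, data.experimental)
        res = bl.calibrate(ds, bl.ModelSpec())
        errs[n] = abs(res.params.alpha - 0.42) + abs(res.params.beta - 0.22)
    assert errs[200] < errs[10]


def test_max_iter_zero_returns_init(noise_free_dataset):
    ds, _ = noise_free_dataset
    init = bl.LIEParams(alpha=0.3, beta=0.3)
    res = bl.calibrate(ds, bl.ModelSpec(), init=init, max_iter=0)
    assert not res.converged and res.n_iter == 0
    assert res.params == init
    per, _ = bl.predict(ds, bl.ModelSpec(), init)
    assert res.rmse == pytest.approx(
        float(np.sqrt(np.mean(per["residual"] ** 2))))


def test_fixed_point_self_consistency(noisy_dataset):
    """At the returned coefficients one extra weight update + refit moves
    the RMSE by less than the convergence tolerance."""
    ds, _ = noisy_dataset
    spec = bl.ModelSpec()
    res = bl.calibrate(ds, spec)
    deltas = prepare_deltas(ds, spec)
    ev = bl.evaluate(deltas, res.params, ds.dg_exp())
    coef, _ = fit_given_weights(ev.weighted, ds.dg_exp(), "alpha_beta")
    refit = res.params.with_coefficients(coef)
    ev2 = bl.evaluate(deltas, refit, ds.dg_exp())
    assert abs(ev2.rmse - res.rmse) < 1e-6


def test_restart_log_records_all_starts(noisy_dataset):
    ds, _ = noisy_dataset
    res = bl.calibrate(ds, bl.ModelSpec())
    assert len(res.restart_log) == 10  # 3x3 grid + theoretical point
    assert all({"init", "final", "rmse", "converged"} <= set(r)
               for r in res.restart_log)


def test_alpha_gamma_variant_calibrates(noisy_dataset):
    ds, _ = noisy_dataset
    res = bl.calibrate(ds, bl.ModelSpec(variant="alpha_gamma"))
    assert res.converged
    assert res.params.beta is None and res.params.gamma is not None


def test_nonconvergence_carries_log(noise_free_dataset):
    ds, _ = noise_free_dataset
    with pytest.raises(ConvergenceError) as exc:
        bl.calibrate(ds, bl.ModelSpec(), max_iter=1,
                     tol_params=1e-15, tol_rmse=1e-16)
    assert exc.value.restart_log


def test_duplicate_simulation_is_not_deduplicated(noise_free_dataset):
    """A duplicated simulation row changes the weight distribution (the
    duplicate pose is counted twice) and must not be silently dropped."""
    ds, _ = noise_free_dataset
    params = bl.LIEParams(alpha=0.42, beta=0.22)
    spec = bl.ModelSpec()
    per0, w0 = bl.predict(ds, spec, params)
    dup = ds.bound.iloc[[0]].assign(replicate="S3")
    ds2 = bl.LIEDataset(pd.concat([ds.bound, dup], ignore_index=True),
                        ds.free, ds.experimental)
    per2, w2 = bl.predict(ds2, spec, params)
    lig = dup.iloc[0]["ligand_id"]
    assert w2.shape[1] == w0.shape[1] + 1
    assert per2.loc[lig, "dg_calc"] != per0.loc[lig, "dg_calc"]


# ------------------------------------------------------------- prediction

def test_predict_matches_calibration_output(noisy_dataset):
    ds, _ = noisy_dataset
    res = bl.calibrate(ds, bl.ModelSpec())
    per, w = bl.predict(ds, bl.ModelSpec(), res.params)
    pd.testing.assert_series_equal(per["dg_calc"],
                                   res.per_ligand["dg_calc"])
    np.testing.assert_allclose(w.to_numpy(), res.weights.to_numpy())


def test_predict_weights_normalised(noisy_dataset):
    ds, _ = noisy_dataset
    _, w = bl.predict(ds, bl.ModelSpec(), bl.LIEParams(alpha=0.4, beta=0.2))
    np.testing.assert_allclose(w.sum(axis=1), 1.0, atol=1e-12)


def test_dominant_pose_gets_dominant_weight():
    """A configuration at least 5 kT below the rest takes > 0.85 weight."""
    kT = KT_300K
    p = bl.LIEParams(alpha=1.0, beta=0.0, kT=kT)
    d_vdw = np.array([-30.0 - 5 * kT, -30.0, -30.0, -30.0])
    _, w = bl.combined_free_energy(p, np.zeros(4), d_vdw)
    assert w[0] > 0.85


def test_scheme_equivalence_when_replicates_identical():
    """If S1 and S2 averages coincide exactly, weighting replicates
    separately or pooling them first gives the same prediction."""
    data = bl.generate(bl.GeneratorSpec(seed=21, replicate_noise_sd=0.0,
                                        obs_noise_sd=0.0))
    ds = bl.assemble_dataset(data.bound, data.free, data.experimental)
    params = bl.LIEParams(alpha=0.42, beta=0.22)
    per_sep, _ = bl.predict(ds, bl.ModelSpec(scheme="separate"), params)
    per_avg, _ = bl.predict(ds, bl.ModelSpec(scheme="replicate_averaged"),
                            params)
    np.testing.assert_allclose(per_sep["dg_calc"], per_avg["dg_calc"],
                               atol=1e-10)


# ---------------------------------------------------------------- surface

def test_surface_minimum_consistent_with_calibration(noisy_dataset):
    ds, _ = noisy_dataset
    res = bl.calibrate(ds, bl.ModelSpec())
    a0, b0 = res.params.alpha, res.params.beta
    alpha_grid = np.linspace(a0 - 0.05, a0 + 0.05, 11)
    beta_grid = np.linspace(b0 - 0.05, b0 + 0.05, 11)
    surf = bl.rmse_surface(ds, bl.ModelSpec(), alpha_grid, beta_grid)
    amin, bmin, rmin = surf.minimum()
    step = 0.01
    assert abs(amin - a0) <= step + 1e-12
    assert abs(bmin - b0) <= step + 1e-12
    assert rmin >= res.rmse - 1e-10

    # noise-free surface bottoms out at ~0 on the truth
    data = bl.generate(bl.GeneratorSpec(seed=11, replicate_noise_sd=0.0,
                                        obs_noise_sd=0.0))
    ds0 = bl.assemble_dataset(data.bound, data.free, data.experimental)
    surf0 = bl.rmse_surface(ds0, bl.ModelSpec(), [0.40, 0.42, 0.44],
                            [0.20, 0.22, 0.24])
    amin0, bmin0, rmin0 = surf0.minimum()
    assert (amin0, bmin0) == (0.42, 0.22)
    assert rmin0 == pytest.approx(0.0, abs=1e-8)


def test_surface_single_cell_and_flags(noisy_dataset):
    ds, _ = noisy_dataset
    params = bl.LIEParams(alpha=0.42, beta=0.22)
    surf = bl.rmse_surface(ds, bl.ModelSpec(), [0.42], [0.22], ceiling=5.0)
    per, _ = bl.predict(ds, bl.ModelSpec(), params)
    direct = float(np.sqrt(np.mean(per["residual"] ** 2)))
    assert surf.rmse[0, 0] == pytest.approx(direct, abs=1e-12)
    # far-off coefficients exceed the display ceiling but stay unclamped
    far = bl.rmse_surface(ds, bl.ModelSpec(), [5.0], [5.0])
    assert far.above_ceiling[0, 0]
    assert far.rmse[0, 0] > 5.0


def test_surface_input_validation(noisy_dataset):
    ds, _ = noisy_dataset
    with pytest.raises(ValueError, match="non-empty"):
        bl.rmse_surface(ds, bl.ModelSpec(), [], [0.2])
    with pytest.raises(ValueError, match="increasing"):
        bl.rmse_surface(ds, bl.ModelSpec(), [0.4, 0.3], [0.2])


def test_surface_frozen_weights_option(noisy_dataset):
    ds, _ = noisy_dataset
    freeze = bl.LIEParams(alpha=0.42, beta=0.22)
    surf = bl.rmse_surface(ds, bl.ModelSpec(), [0.3, 0.42], [0.1, 0.22],
                           freeze_weights_at=freeze)
    live = bl.rmse_surface(ds, bl.ModelSpec(), [0.3, 0.42], [0.1, 0.22])
    # identical at the freezing point, generally different elsewhere
    assert surf.rmse[1, 1] == pytest.approx(live.rmse[1, 1], abs=1e-12)
    assert not np.allclose(surf.rmse, live.rmse)
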