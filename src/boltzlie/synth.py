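"""Synthetic datasets with known ground-truth LIE coefficients.

MD interaction-energy averages for real CYP-ligand systems are expensive to
produce, so the calibration machinery is exercised on generated data that
mimic their statistical structure: per ligand, several starting
configurations (protein conformation x binding pose) with distinct energy
averages, replicate runs scattered around each configuration mean
(emulating finite-sampling non-convergence of short MD), and experimental
affinities constructed from the Boltzmann-weighted model at known
coefficients plus observation noise.  With all noise at zero the generated
experimental values satisfy the weighted LIE model exactly, so calibration
must recover the ground-truth coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from importlib import resources
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .core import KT_300K, LIEParams, boltzmann_weights, pose_free_energy


@dataclass(frozen=True)
class GeneratorSpec:
    """Parameters of the synthetic-data generator.

    Defaults emulate the benchmark layout used throughout: 10 ligands, two
    protein conformations x two poses x two replicates, ground-truth
    coefficients near typical fitted values for CYP binders, energy
    differences in ranges plausible for drug-like compounds (kJ/mol), a
    per-configuration spread of a few kT so poses receive genuinely
    different weights, and ~1 kJ/mol replicate scatter.
    """

    n_ligands: int = 10
    protein_confs: Sequence[str] = ("P70", "P170")
    poses: Sequence[str] = ("M1", "M2")
    replicates: Sequence[str] = ("S1", "S2")
    true_alpha: float = 0.42
    true_beta: float = 0.22
    kT: float = KT_300K
    d_el_range: tuple[float, float] = (-60.0, 0.0)
    d_vdw_range: tuple[float, float] = (-120.0, -20.0)
    pose_offset_scale: float = 5.0
    replicate_noise_sd: float = 1.0
    obs_noise_sd: float = 0.0
    v_el_free_range: tuple[float, float] = (-200.0, -100.0)
    v_vdw_free_range: tuple[float, float] = (-80.0, -30.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_ligands < 2:
            raise ValueError("need at least 2 ligands")
        for sd in (self.pose_offset_scale, self.replicate_noise_sd,
                   self.obs_noise_sd):
            if sd < 0:
                raise ValueError("scale/noise parameters must be >= 0")
        for lo, hi in (self.d_el_range, self.d_vdw_range,
                       self.v_el_free_range, self.v_vdw_free_range):
            if not lo < hi:
                raise ValueError(f"degenerate range ({lo}, {hi})")


class SyntheticDataset(NamedTuple):
    bound: pd.DataFrame
    free: pd.DataFrame
    experimental: pd.DataFrame
    ground_truth: dict


def generate(spec: GeneratorSpec) -> SyntheticDataset:
    """Generate bound/free/experimental tables from a known model.

    Per ligand a base (d_el, d_vdw) pair is drawn uniformly in the spec
    ranges; every starting configuration adds Gaussian offsets of scale
    ``pose_offset_scale`` (distinct pose contributions), and each replicate
    scatters around the configuration mean with ``replicate_noise_sd``.
    dG_exp is the Boltzmann-weighted LIE value at the ground-truth
    coefficients over all individual replicate simulations, plus
    observation noise.  Bound-state energies are the free-state draws plus
    the intended deltas, so the differences hold exactly.  Fully
    reproducible from the seed.
    """
    rng = np.random.default_rng(spec.seed)
    params = LIEParams(alpha=spec.true_alpha, beta=spec.true_beta, kT=spec.kT)
    ligands = [f"L{i + 1}" for i in range(spec.n_ligands)]

    free_rows, bound_rows = [], []
    dg_exp_rows = []
    for lig in ligands:
        v_el_free = rng.uniform(*spec.v_el_free_range)
        v_vdw_free = rng.uniform(*spec.v_vdw_free_range)
        free_rows.append({"ligand_id": lig, "v_el_free": v_el_free,
                          "v_vdw_free": v_vdw_free})
        base_el = rng.uniform(*spec.d_el_range)
        base_vdw = rng.uniform(*spec.d_vdw_range)
        d_el_all, d_vdw_all = [], []
        for conf in spec.protein_confs:
            for pose in spec.poses:
                cfg_el = base_el + rng.normal(0.0, spec.pose_offset_scale)
                cfg_vdw = base_vdw + rng.normal(0.0, spec.pose_offset_scale)
                for rep in spec.replicates:
                    d_el = cfg_el + rng.normal(0.0, spec.replicate_noise_sd)
                    d_vdw = cfg_vdw + rng.normal(0.0,
                                                 spec.replicate_noise_sd)
                    bound_rows.append({
                        "ligand_id": lig, "protein_conf": conf,
                        "pose": pose, "replicate": rep,
                        "v_el_bound": v_el_free + d_el,
                        "v_vdw_bound": v_vdw_free + d_vdw})
                    d_el_all.append(d_el)
                    d_vdw_all.append(d_vdw)
        dg_i = pose_free_energy(params, np.array(d_el_all),
                                np.array(d_vdw_all))
        w = boltzmann_weights(dg_i, spec.kT)
        dg_true = float(pose_free_energy(
            params, float(w @ np.array(d_el_all)),
            float(w @ np.array(d_vdw_all))))
        dg_exp_rows.append({
            "ligand_id": lig,
            "dg_exp": dg_true + rng.normal(0.0, spec.obs_noise_sd)})

    truth = {"alpha": spec.true_alpha, "beta": spec.true_beta,
             "kT": spec.kT, "spec": asdict(spec)}
    return SyntheticDataset(
        bound=pd.DataFrame(bound_rows),
        free=pd.DataFrame(free_rows),
        experimental=pd.DataFrame(dg_exp_rows),
        ground_truth=truth)


def ar1_timeseries(n_frames: int, mean_el: float, mean_vdw: float,
                   sd: float = 5.0, phi: float = 0.8, dt_ps: float = 0.02,
                   seed: int = 0) -> pd.DataFrame:
    """Serially correlated (AR(1)) interaction-energy time series.

    A minimal stand-in for stored per-frame MD energies, used to exercise
    time-series averaging; ``phi`` is the lag-one autocorrelation.
    """
    rng = np.random.default_rng(seed)
    innov_sd = sd * np.sqrt(1 - phi ** 2)
    el = np.empty(n_frames)
    vdw = np.empty(n_frames)
    el[0] = rng.normal(0, sd)
    vdw[0] = rng.normal(0, sd)
    for k in range(1, n_frames):
        el[k] = phi * el[k - 1] + rng.normal(0, innov_sd)
        vdw[k] = phi * vdw[k - 1] + rng.normal(0, innov_sd)
    return pd.DataFrame({"time_ps": dt_ps * np.arange(1, n_frames + 1),
                         "v_el": mean_el + el, "v_vdw": mean_vdw + vdw})


def table1_fixture() -> pd.DataFrame:
    """The packaged thiourea benchmark: IC50 +/- sigma from a CYP 2D6
    inhibition assay for ligands L1-L10, with the published dG_exp values.
    """
    path = resources.files("boltzlie.data") / "table1_ic50.tsv"
    with resources.as_file(path) as p:
        return pd.read_csv(p, sep="\t")
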