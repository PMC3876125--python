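"""Calibrate a Boltzmann-weighted LIE model on synthetic multi-pose data.

Generates a benchmark with known coefficients (alpha=0.42, beta=0.22),
1 kJ/mol replicate scatter and 0.5 kJ/mol observation noise, then fits the
coefficients self-consistently under both replicate-combination schemes.
"""

import boltzlie as bl

data = bl.generate(bl.GeneratorSpec(seed=7, obs_noise_sd=0.5))
dataset = bl.assemble_dataset(data.bound, data.free, data.experimental)

for scheme in ("separate", "replicate_averaged"):
    result = bl.calibrate(dataset, bl.ModelSpec(scheme=scheme))
    p = result.params
    print(f"{scheme:>20}: beta={p.beta:+.3f} (SE {result.param_se['beta']:.3f})"
          f"  alpha={p.alpha:+.3f} (SE {result.param_se['alpha']:.3f})"
          f"  RMSE={result.rmse:.3f} kJ/mol"
          f"  [{result.n_iter} iterations, outliers: "
          f"{result.outliers or 'none'}]")

print("\nGround truth is alpha=0.42, beta=0.22; both schemes should land "
      "within a few standard errors, with RMSE near the injected noise "
      "level. 'separate' weights every replicate run individually; "
      "'replicate_averaged' pools replicate energy averages per starting "
      "configuration before weighting.")
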