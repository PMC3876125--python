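"""Per-simulation Boltzmann weights behind each ligand's prediction.

After calibration, every ligand's predicted dG is a Boltzmann-weighted
blend of its simulations; the weight table shows which starting
configuration (protein conformation x pose x replicate) dominates.
"""

import boltzlie as bl

data = bl.generate(bl.GeneratorSpec(seed=7, obs_noise_sd=0.5))
dataset = bl.assemble_dataset(data.bound, data.free, data.experimental)
result = bl.calibrate(dataset, bl.ModelSpec(scheme="replicate_averaged"))

cols = list(result.weights.columns)
print("ligand  " + "  ".join(f"{c:>10}" for c in cols))
for lig, row in result.weights.iterrows():
    cells = []
    top = row.idxmax()
    for c in cols:
        mark = "*" if c == top else " "
        cells.append(f"{row[c]:>9.3f}{mark}")
    print(f"{lig:<8}" + "  ".join(cells))

print("\nEach row sums to 1; '*' marks the dominant configuration. "
      "Distinct ligands are dominated by different poses/conformations — "
      "the point of combining multiple starting structures instead of "
      "trusting a single docked geometry.")
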