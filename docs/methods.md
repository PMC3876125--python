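# Methods

## Model

The package implements the linear interaction energy (LIE) estimate of a
binding free energy from ensemble-averaged ligand–surrounding interaction
energies, extended to several independent simulations per ligand. For a
simulation *i* (one protein conformation × docked pose × replicate),

ΔG_i = β·ΔV^EL_i + α·ΔV^VdW_i,

where ΔV^EL_i and ΔV^VdW_i are the differences of mean electrostatic and
van der Waals interaction energies between the protein-bound simulation
and the ligand free in water (kJ/mol). The combined prediction for the
ligand Boltzmann-weights the simulations,

W_i = exp(−ΔG_i/k_B T) / Σ_j exp(−ΔG_j/k_B T),
ΔG_calc = β Σ W_i ΔV^EL_i + α Σ W_i ΔV^VdW_i = Σ W_i ΔG_i.

Assumptions worth keeping in mind:

- linear response: the free energy is linear in the two mean interaction
  energies; α and β absorb everything else and are transferable only
  within a congeneric training series;
- the independent simulations cover *different* regions of configuration
  space (in the source MD protocol this is enforced by restraining the
  discriminating side-chain dihedral), otherwise Boltzmann-weighting
  double-counts a basin;
- weights act on simulation-level averages, never on individual frames;
- experimental values are *relative* binding free energies from one assay
  (R·T·ln IC50 with a 1 M reference); no Cheng–Prusoff correction is
  applied, so only differences across the series are meaningful.

A variant fixes β = 0 and fits a constant offset γ (kJ/mol) together with
α; it is useful when the electrostatic term carries no signal and is the
form some CYP affinity models prefer.

## Calibration

Since W_i depends on (α, β), fitting is a fixed-point problem. The
iteration alternates (block coordinate descent):

1. evaluate ΔG_i and W_i at the current coefficients;
2. refit the coefficients by unweighted least squares of ΔG_exp on the
   per-ligand weight-averaged differences (weights frozen; no intercept in
   the α/β variant, intercept = γ in the α/γ variant);
3. stop when the largest coefficient change is below `tol_params` (1e−6)
   and the RMSE change is below `tol_rmse` (1e−8), far below the 3-decimal
   reporting precision of such models.

Restarts: a 3×3 grid of (α, β) ∈ {0.1, 0.4, 0.7}² plus the
linear-response point (0.5, 0.5); multiple fixed points are possible
because the weights deform with the coefficients, so all restarts are
logged and the lowest-RMSE converged solution returned. For the α/γ
variant γ shifts every ΔG_i equally and hence never changes the weights;
restarts therefore vary α only.

Numerical choices:

- weights are computed after subtracting the per-ligand minimum ΔG_i
  (softmax shift invariance), so arbitrarily negative energies cannot
  overflow;
- the self-consistent fixed point need not coincide exactly with the
  minimum of the fully re-weighted RMSE, so sub-tolerance RMSE increases
  (< RMSE·1e−4 + tol_rmse) between iterations are treated as fixed-point
  noise; larger increases trigger step-halving damping (up to 10 halvings)
  before a restart is declared oscillating;
- ties in the minimum-energy pose as k_B T → 0 share weight equally (the
  softmax limit);
- the regression design is rejected as degenerate when its singular-value
  ratio falls below 1e−10, naming the offending column;
- RMSE uses 1/n, not 1/(n−p): it is the calibration objective, not an
  unbiased variance estimate (configurable downstream if needed).

Parameter standard errors are the conditional OLS standard errors from the
inner linear step at the converged weights (σ̂² = RSS/(n−p)). They ignore
the dependence of the weights on the coefficients and are therefore mildly
optimistic; for the synthetic benchmarks this bias is negligible because
observation noise enters only the response, not the weights.

The thermal energy defaults to k_B·T at 300 K (0.0083145 × 300 ≈ 2.494
kJ/mol), matching the simulation temperature of the source data; it is a
parameter everywhere because the appropriate weighting temperature is a
modelling choice, not a law.

Outliers are ligands whose |ΔG_calc − ΔG_exp| strictly exceeds 1 kcal/mol
(4.184 kJ/mol), reported to 2 decimals — the conventional reporting rule
for these models.

### Replicate combination

Replicate runs from one starting configuration probe convergence, not new
conformational space, so two schemes exist: `separate` (every replicate
keeps its own weight) and `replicate_averaged` (replicate energy means are
pooled per configuration before weighting). In the limit of converged
sampling the replicate averages coincide and the schemes agree exactly;
the package verifies this identity on constructed data. Configurations
with a single replicate are allowed in both schemes, with a logged
warning.

### RMSE surfaces

`rmse_surface` evaluates the α/β model over a coefficient grid,
re-computing the weights at every grid point and never refitting inside a
cell; a flag records cells above a display ceiling (default 5 kJ/mol, the
usual upper bound of published contour windows) without clamping the
values. Freezing the weights at one coefficient pair is available as an
option for sensitivity checks.

## IC50 conversion

ΔG_exp = R·T·ln(IC50/1 M) with R = 0.0083145 kJ mol⁻¹ K⁻¹ and T = 300 K
by default; the uncertainty is the asymmetric log-interval half-width
R·T·ln(IC50/(IC50−σ)), which reproduces the published benchmark error
bars to 0.01 kJ/mol. This propagation formula was identified numerically
— it is the unique simple form matching all ten published uncertainties —
rather than taken from a stated derivation; it diverges as σ → IC50 and
such rows are rejected.

## Time-series averaging

Mean interaction energies from raw per-frame series are plain arithmetic
means over retained frames (default: no initial discard, since stored
production data are assumed post-equilibration; a discard fraction is
available). Standard errors use block averaging with 10 equal blocks
(SE = stdev of block means / √blocks), the standard estimator for serially
correlated MD data; the SEs are reported only, never used as regression
weights. Frame weighting is uniform.

## Synthetic benchmark generator

The generator emulates the statistical structure of multi-configuration
LIE input data without any MD: per ligand a base (ΔV^EL, ΔV^VdW) pair is
drawn uniformly (defaults ΔV^EL ∈ [−60, 0], ΔV^VdW ∈ [−120, −20] kJ/mol —
magnitudes plausible for drug-like binders of buried heme-protein sites;
conventions, not claims about any particular system); each starting
configuration adds Gaussian offsets (default scale 5 kJ/mol, i.e. a few
k_B T, so poses get genuinely distinct weights); replicates scatter around
the configuration mean (default 1 kJ/mol, emulating finite-sampling
non-convergence of short runs); ΔG_exp is the Boltzmann-combined value at
the ground-truth coefficients (defaults α=0.42, β=0.22, typical fitted
magnitudes for CYP series) over the individual replicate simulations,
plus optional Gaussian observation noise. Free-state energies are drawn
independently and bound-state values constructed as free + delta, so the
differences hold exactly. Everything is reproducible from one seed.

What the generator does *not* emulate: correlated errors between the
electrostatic and van der Waals averages, non-Gaussian tails, systematic
force-field bias shared across ligands, and any relation between ligand
chemistry and its energies. Passing recovery tests therefore demonstrates
the correctness of the estimator and its implementation under the model's
own assumptions — not that the model is accurate for real proteins.

Problem sizes used in the shipped tests and the acceptance script — 10–50
ligands, 2×2×2 simulations each, 20 seeds per stochastic check, 11×11
surface grids — were chosen as the smallest sizes at which the checked
identities and statistical bounds are sharply testable.

## Known limitations

- No cross-validation or bootstrap model selection; the RMSE reported is
  a fit RMSE on the training set.
- Experimental error bars are carried through reporting but not used as
  regression weights (uniform ligand weighting).
- The fixed-point iteration is not guaranteed to find the global RMSE
  minimum when several self-consistent solutions exist; the restart log
  exposes all solutions found.
- Native MD-engine energy formats are out of scope; inputs are columnar
  text exports.
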