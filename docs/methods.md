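# Methods

## Model

The package treats solvation as two thermodynamic steps: the solute opens a
cavity and reorganizes the solvent (ΔG_reo), then couples to it
(ΔG_int), so ΔG_sol = ΔG_int + ΔG_reo. The interaction step is an
end-point quantity: it needs only frames of the solvated system, no
alchemical intermediates.

### Interaction free energy

For each frame the solute–solvent energy is the unrestricted double sum of
Coulomb and 12-6 Lennard-Jones terms over (solute atom, solvent atom)
pairs. Parameters follow AMBER conventions throughout: charges in
elementary-charge units, Lennard-Jones in Rmin/2–ε form combined by
R_ij = Rmin/2_i + Rmin/2_j and ε_ij = √(ε_i ε_j), Coulomb constant
332.0522173 kcal·Å/(mol·e²), distances in Å, energies in kcal/mol. Solute
and solvent are distinct molecules, so no exclusion or 1–4 scaling applies.

Over the trajectory,

- ΔH_int = ⟨E⟩ (arithmetic mean of per-frame totals),
- −TΔS_int = kT·ln⟨exp(βΔE)⟩ with ΔE = E − ⟨E⟩ and β = 1/(k_B T),
  k_B = 0.0019872041 kcal/(mol·K),
- ΔG_int = ΔH_int + (−TΔS_int).

The entropy term is non-negative by Jensen's inequality and measures how
much the interaction-energy distribution's width penalizes the free
energy; for Gaussian fluctuations it converges to βσ²/2, which the tests
use as a closed-form check. It is invariant under any constant shift of
the energies.

Assumptions worth keeping in mind: a single solution-ensemble trajectory
supplies the average (no separate gas-phase ensemble), and the exponential
average converges slowly when βσ is large — the block-convergence
diagnostic (`block_convergence`, `--blocks`) exists to expose exactly
that. Equilibration trimming is deliberately manual (`--skip-frames`); the
package never guesses where equilibrium starts.

### Numerical treatment of the exponential average

The average is computed two-pass (mean first, then fluctuations) and
through log-sum-exp: max(βΔE) is subtracted before exponentiating, so
values of βΔE up to ~10⁴ remain finite. A genuinely constant series
short-circuits to exactly 0 before any arithmetic, because subtracting a
mean that is not exactly representable would otherwise leave ~1e-16
residue. Results are clamped at 0 against roundoff; any true signal is
orders of magnitude above the clamp.

### Cavity descriptors

SASA uses the Shrake–Rupley construction (each solute atom inflated by the
probe, covered with a deterministic Fibonacci point lattice, area
proportional to the unburied fraction), computed through
`biotite.structure.sasa` with per-atom radii taken from the topology's
`sasa_radius` field. Defaults: probe 1.4 Å (water), 960 points per atom,
Bondi-type radii in the bundled fixtures. The deterministic lattice means
identical inputs give identical areas with no seed; at 960 points the
quadrature noise under rigid rotation of a ~10-atom cluster is about 0.5%,
dropping below 0.1% by 3840 points.

The solvent-accessible volume (SAV) is the volume of the union of
probe-inflated spheres, estimated by counting regular voxel centers inside
the union (0.25 Å default edge — about 1% accuracy on single spheres at
negligible cost; 0.1 Å for tighter checks). Only solute atoms enter either
descriptor: both describe the cavity the solute carves.

The fitted γ absorbs any scale offset introduced by the probe radius or
radii set, so these choices shift coefficients, not predictions, as long
as they are held fixed between training and prediction. γ has different
units in SAS (per Å²) and SAV (per Å³) mode; values are not comparable
across modes.

### Regression family

ΔG_reo ≈ Σ_k c_k·ΔG_int^{p_k} + γ·SASA + b, with power sets
IRS1 {1}, IRS2 {1,2}, IRS3 {1,2,3}, IRS4 {1,2,3,4}, IRS(3/2) {1, 3/2}.
Each expansion contains all lower powers; the family is capped at the
fourth power because the magnitude gap between interaction and solvation
energies otherwise invites fitting small numbers with huge cancelling
terms. IRS(3/2) is the default: on held-out data the quartic (and often
the cubic) model overfits, which the test suite reproduces on synthetic
second-order truth.

Design choices that were genuinely open:

- The leading ΔG_int in ΔG_sol = ΔG_int + ΔG_reo is fixed at coefficient
  1 so the decomposition keeps its meaning; the expansion's own linear
  term still leaves the total linear response free.
- Fractional powers of negative ΔG_int use sign(x)·|x|^p (hydration
  ΔG_int is usually negative; a plain real power would be undefined). An
  absolute-value convention is selectable per `ModelSpec` for sensitivity
  checks.
- Fitting is plain OLS through statsmodels — no regularization, centering
  or scaling — with a rank check that names collinear columns and a
  warning when the design's condition number exceeds 1e8 (the quartic
  column is the usual culprit). Response is y = ΔG_exp − ΔG_int, so the
  coefficients model ΔG_reo directly.
- Train/test splitting is a seeded shuffle with test size round(n·f);
  f = 73/353 reproduces the canonical 280/73 protocol for a 353-solute
  benchmark.
- `evaluate` returns MAE/RMSE always; when either input has zero variance
  the Pearson correlation is undefined and reported as NaN with a warning
  rather than an exception, so pipelines keep the error metrics.

## Synthetic data

The fixture generators define the conditions every test and the acceptance
script run under.

`generate_water_shell` packs rigid TIP3P waters (O: q = −0.834 e,
Rmin/2 = 1.7683 Å, ε = 0.152 kcal/mol; H: q = +0.417 e; O–H 0.9572 Å,
∠HOH 104.52°) uniformly into a sphere around the solute, enforcing a
2.6 Å minimum O–O distance and 2.8 Å clearance from the solute, each
water randomly oriented; frames add i.i.d. Gaussian jitter (0.05 Å
default) to the base packing. Hydrogen ε is set to 1e-6 instead of 0 so
the geometric combination rule needs no special case; the resulting LJ
contribution is below every test tolerance. What this emulates: correct
bookkeeping over realistic parameter magnitudes and molecule counts. What
it does not: water structure, Boltzmann sampling, periodic boundaries or
long-range electrostatics — so passing tests certify the estimator
machinery, not agreement with experiment on real trajectories.

`generate_gaussian_series` draws i.i.d. normal energies, giving the
entropy estimator a case with a known closed form. `generate_regression_dataset`
draws ΔG_int ~ N(−8, 6) kcal/mol and SASA ~ N(300, 80) Å² (clipped at
1 Å²) — magnitudes typical of neutral small-molecule hydration — and
builds ΔG_exp from chosen coefficients plus N(0, σ) noise, recording the
exact truth for recovery tests. Default truth (c₁ = 0.45, c_{3/2} = 0.012,
γ = 0.008, b = 1.5, σ = 1 kcal/mol) keeps the reorganization term a
realistic fraction of the total.

## Problem sizes

The shipped tests and the acceptance script use: 10⁴ randomized series for
positivity, 2·10⁵ samples for the Gaussian closed form (5% band), twenty
100-atom systems against the double-loop oracle (1e-10 band), 10-atom
clusters against a 10⁶-sample Monte-Carlo volume oracle (2% band), 280-row
training sets with 100 replicates for confidence-interval coverage and for
the overfitting comparison, and six 20-water/50-frame shells for the
end-to-end pipeline. These sizes make every stochastic band comfortably
wide relative to its estimator's sampling error.

## Known limitations

- Pairwise direct sums, not Ewald/PME: energies from periodic MD engines
  will differ; the minimum-image option is a convenience, not a PME
  substitute.
- No LCPO/Molsurf surface variants; SAS and SAV only.
- Published benchmark coefficients cannot be refit here — that requires
  the experimental database and hundreds of solute trajectories; the
  regression stage is validated by ground-truth recovery instead.
- The PDB writer emits fixed-column records (3 decimal places); use XYZ
  when full double precision must round-trip.
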