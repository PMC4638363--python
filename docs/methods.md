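# Methods

## The LIE model and its calibration

`cyplie.lie` implements the multi-pose linear interaction energy estimator

    ΔG_bind = α·Σ_i W_i ΔV_i^VdW + β·Σ_i W_i ΔV_i^Ele + γ,
    W_i ∝ exp(−ΔG_i / RT),   ΔG_i = α·ΔV_i^VdW + β·ΔV_i^Ele + γ,

where ΔV^VdW and ΔV^Ele are differences in MD-ensemble-averaged
ligand–surroundings van der Waals and electrostatic energies between the
protein-bound and free (water) simulations of one docked pose. All
energies are molar (kJ·mol⁻¹), so the thermal energy in the Boltzmann
factor is R·T, not k_B·T — the only dimensionally consistent reading when
the ΔG_i are molar. The exponent is shifted by the minimum ΔG_i before
exponentiation; the weights are invariant under that shift.

Calibration is a self-consistent iteration, since the weights depend on
the coefficients being fitted:

1. First fit: uniform weights over *all* poses of each ligand; each ligand
   contributes one least-squares equation built from its weighted energy
   sums.
2. Each subsequent iteration: recompute per-pose ΔG_i with the current
   (α, β), re-rank, retain the `max_poses` lowest-ΔG simulations per
   ligand (ties broken by input pose order for determinism), recompute
   Boltzmann weights over the retained set, refit.
3. Stop when the L1 change in the coefficients falls below `tol`
   (default 1e-6) or after `max_iter` (default 1000) iterations. If the
   trajectory revisits a previously seen coefficient state within `tol`
   without converging, the iteration is oscillating: it stops and the
   result carries `converged=False` rather than being silently accepted.

Pose re-ranking happens inside every iteration (which poses are "lowest
ΔG" is itself parameter-dependent). The offset γ is 0 by default and can
be co-fitted with `fit_gamma=True`. The least-squares fit is unweighted
across ligands. A rank-deficient design (e.g. all ΔV^Ele zero, or ΔV^VdW
proportional to ΔV^Ele) raises `SingularFitError` instead of returning an
arbitrary solution.

The retained-pose count is selected by calibrating one model per candidate
count and picking the lowest leave-one-out SDEP (ties favour the smaller
count). LOO-CV refits the entire model — coefficients *and* weights — in
every fold; this is the stricter of the two possible protocols and the one
implemented throughout. `r²` is reported as 1 − SS_res/SS_tot about the
mean of the observations (the definition that reproduces the reference
tables); the squared Pearson correlation is available separately as
`pearson_r2` because the two differ for biased predictions.

Unit conversions (`cyplie.affinity`) use the competitive-inhibition
Cheng–Prusoff equation and ΔG = RT ln Ki with R = 8.3145 J·mol⁻¹·K⁻¹. The
default temperature is 300 K — the temperature of the MD ensembles the
model consumes, and the value under which the embedded affinity table is
internally consistent (e.g. phenacetin: IC50 24 μM at substrate = Km →
Ki 12 μM → −28.26 ≈ −28.3 kJ·mol⁻¹); it is configurable everywhere. When
no substrate concentration is supplied the substrate-at-Km convention
Ki = IC50/2 is applied, matching the usual CYP assay design.

## Pose clustering and the binder filter

`cyplie.poses` reduces a ligand's docked poses to representative binding
modes. Poses are assumed pre-aligned in the protein frame (docking outputs
share it), so no superposition is performed. PCA runs on the flattened
heavy-atom coordinates; components are retained while each addition
explains at least 5 percentage points of the total coordinate variance.
k-means (seeded, 10 restarts) runs on the retained scores, and the cluster
count grows while each added cluster raises the between-cluster share of
the *total coordinate* variance by at least the same 5 points. Measuring
the gain against total variance — rather than the variance of the
truncated score space — is what keeps a single unstructured Gaussian pose
cloud in one cluster: splitting within-mode scatter along the top
component gains only a small fraction of the total and never clears the
threshold, while genuine multi-modal structure does. Each cluster is
represented by its medoid (the member closest to the centroid in score
space; ties resolved by input order), never a synthetic average
conformation.

Active-site geometry is anchored on the heme: the site center lies 0.78 nm
from the iron along the Cys-thiolate→Fe axis (the proximal cysteine
coordinates the iron, so this direction points into the distal pocket),
with a 1.2 nm site radius.

The binder filter combines structural alerts with geometry: a compound is
labelled mechanism-based or quasi-irreversible only if a rule's SMARTS
pattern matches *and* a matched reactive atom lies within 0.6 nm of the
iron in at least one representative pose; mechanism-based takes precedence
when both kinds of rule trigger. The built-in rule file covers the
documented CYP alert motifs (terminal alkene/alkyne, furan, thiophene,
methylenedioxyphenyl, aromatic primary amine, hydrazine, dihydropyridine
as mechanism-based; accessible heteroaromatic nitrogen as a
quasi-irreversible heme coordinator). It is a curated approximation of the
alert catalogues in the CYP-inactivation literature, deliberately small,
and fully user-replaceable via `--rules`/`load_rules`.

## Reliability estimation

`cyplie.reliability` scores each prediction with four binary analyses:

- **A, chemical similarity.** 166-key MACCS fingerprints, Tanimoto
  similarity. The cutoff is the weakest best-match similarity *within* the
  training set; a query whose best match falls strictly below it is
  flagged. The strict inequality means a query exactly at the cutoff is
  not an outlier.
- **B, energy distribution.** Sample mean and covariance of the training
  (ΔV^Ele, ΔV^VdW) pairs — taken over the simulations actually retained in
  the calibrated model — and the squared Mahalanobis distance of every
  query simulation (all of them, not only retained ones). The threshold is
  the 95% χ² quantile with 1 degree of freedom (3.841), treating a
  deviation along either single energy axis as the reference; a 2-dof
  option (5.991) is provided since the distance is measured in a
  2-dimensional space, and the choice is a documented flag. The flag is
  invariant under any invertible linear map applied consistently to
  training and query energies.
- **C/D, per-residue profiles.** Each ligand's per-residue interaction
  decomposition is weight-averaged over its simulations with the model's
  Boltzmann weights, giving one electrostatic and one van der Waals
  profile vector per compound; water in the site is aggregated as a single
  pseudo-residue. Independent PCA models (mean-centered, unscaled) are fit
  per channel on the training profiles, retaining components that each
  explain more than 5% of the variance. A query is a *score* outlier when
  SD = √(Σ t_k²/λ_k) exceeds SD_crit = √(χ²_{a,0.95}) (normalizing scores
  by the training variances makes the χ² cutoff dimensionally coherent),
  and an *orthogonal* outlier when its residual norm off the subspace
  exceeds OD_crit = (median(OD^{2/3}) + MAD(OD^{2/3})·z_{0.95})^{3/2}.
  The cutoff formula is ambiguous as usually printed — median(OD^{2/3})
  versus median(OD)^{2/3}; the transformed-median reading is the default
  (it matches the robust-cutoff literature the construction comes from,
  where OD^{2/3} is the approximately normal quantity), with the
  alternative behind `transformed_median=False`. The MAD is unscaled by
  default; `mad_scale=1.4826` applies the normal-consistency factor.
  Because the location term is a median and the MAD term non-negative, at
  least half of the training compounds always satisfy OD ≤ OD_crit.

The reliability category is the number of flags raised (0–4), and
per-category SDEPs satisfy the pooling identity
Σ n_c·SDEP_c² = n·(overall mean squared residual) exactly.

## The synthetic generator

`cyplie.synthetic` emulates the statistical structure the workflow
assumes, not force-field physics. Defaults are the study conditions of the
CYP 1A2 model: 35 ligands, 4–7 poses each, ΔV^VdW ~ U(−60, −10) and
ΔV^Ele ~ U(−45, +5) kJ·mol⁻¹, true coefficients α = 0.587 / β = 0.267 /
γ = 0, T = 300 K, and Gaussian observation noise of σ = 3.3 kJ·mol⁻¹ (the
estimated experimental uncertainty of the affinity data; Gaussian because
that uncertainty is summarized as an RMSD). Free-state energies are drawn
separately so the four stored energy fields are individually plausible;
observations are the Boltzmann-weighted model value over *all* of a
ligand's poses at the true coefficients, plus noise. Per-residue
decompositions are Dirichlet convex splits of each pose's ΔV per channel
across 15 site-residue labels (water first), so rows sum exactly to the
pose totals — adequate for exercising the profile machinery, though a
physical decomposition would split the bound-state energy and include
cancellation structure that the splits do not model.

The pose-geometry generator places cluster base conformations along
mutually orthogonal directions in flattened-coordinate space (pairwise
center distance ≥ the requested separation) around a shared scaffold and
adds isotropic per-atom Gaussian scatter. Defaults (80 poses per cluster,
20 heavy atoms) mirror the few-hundred-pose docking regime; with many
fewer poses than coordinate dimensions, sampling noise alone can mimic
cluster structure under the 5% rule, so small-n fixtures should not be
read as statements about the clustering of real pose sets.

What passing synthetic tests shows — and does not. Parameter recovery,
weight normalization, cross-validation accounting, outlier-flag geometry
and cluster recovery are all exercised under the generator's assumptions
(linear truth, independent uniform energies, Gaussian noise, exchangeable
residue splits). Real MD energies are autocorrelated, pose energies within
a ligand are correlated, and residue decompositions are far from
exchangeable; the tests validate the machinery, not the physical accuracy
of LIE for any particular target.

## Numerical choices and problem sizes

- Calibration tolerance 1e-6 (L1 on coefficients), max 1000 iterations;
  parameter-recovery tests tighten to 1e-10–1e-12.
- Boltzmann weights: min-ΔG shift before exponentiation; no clipping.
- Covariance fits reject near-singular matrices (relative eigenvalue floor
  1e-10) rather than regularizing silently.
- k-means: `n_init=10` with a caller-supplied `random_state`; re-running
  with the same seed is bit-reproducible.
- Test-suite and acceptance-script simulation sizes (20–35 ligands, ≤ 20
  cross-validation seeds, ≤ 500 poses per clustering problem) keep the
  full run in the tens of seconds while leaving the sampling bands
  comfortably resolvable.

## Known limitations

- The package consumes *tabulated* MD averages; it does not parse
  trajectories or energy time series, and does not implement MM/PBSA, FEP
  or QM corrections for covalent inhibition.
- The structural-alert catalogue is intentionally minimal; production use
  should supply a curated rule file.
- The four reliability analyses are exactly the four described here;
  the broader ADAN-style criterion families are out of scope.
- Per-residue analyses require identical residue label sets across all
  simulations of the compounds being compared.
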