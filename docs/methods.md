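# Methods

This note documents the models, conventions, and numerical choices behind
`tesplan`, and what the synthetic fixtures do and do not establish.

## Volume conduction model

Current flow in the head is quasi-static: the potential obeys
∇·(σ∇φ) = −s with isotropic, piecewise-constant conductivity σ and
insulating boundaries against air.  Tissue conductivities (S/m) are fixed
literature values — eyeball 1.5, scalp 0.44, skull 0.018, CSF 1.79, gray
matter 0.25, white matter 0.35, air 0 — stored in a validated table; any
label volume mapped through the table yields a voxel conductivity volume.

The reference phantom is a 4-shell concentric sphere (gray matter to
78 mm, CSF to 80 mm, skull to 85 mm, scalp to 92 mm).  Voxel membership is
decided by the voxel center (no partial-volume weighting), which matches
the finite-difference stencil's one-conductivity-per-voxel assumption.
The eyeball tissue is supported in label volumes but deliberately absent
from the concentric phantom, which has no anatomical place for it.

Grid spacing is a free parameter.  The underlying MRI protocols this
emulates acquire ~1 mm voxels, but no solver resolution is prescribed
anywhere authoritative, so the package treats it as a quality dial:
phantoms default to 2 mm; the forward-modeling test fixtures and the
pipeline default to 4 mm, which keeps a full 64-electrode lead field under
half a minute on one CPU.  The convergence study (below) quantifies what
each spacing costs in accuracy.

## Finite-difference solver

The 7-point stencil couples face-adjacent voxels with conductance
`g = harmonic_mean(sigma_i, sigma_j) * h` (SI units; h the spacing).  The
harmonic mean represents series resistance across the shared face and
makes any face touching air (σ = 0) naturally insulating — the Neumann
boundary needs no special casing.  The operator is symmetric with zero row
sums (discrete charge conservation).

The pure-Neumann system is singular; one node is grounded during the
conjugate-gradient solve (Jacobi preconditioner, relative tolerance 1e-8
by default) and the solution is then re-referenced to a zero mean over
conducting voxels.  Electrodes are point electrodes: each maps to its
nearest conducting voxel; the nominal 1 cm² contact area is carried only
for current-density reporting, since no contact-impedance model is in
scope.

## Analytic oracle

For concentric spheres the potential separates into Legendre harmonics;
per degree, continuity of potential and radial current at each interface
plus the outer boundary condition give a small linear system for the
radial coefficients.  Basis functions are rescaled per shell
(`(r/r_outer)^n`, `(r_inner/r)^(n+1)`) so the system stays conditioned to
degree several thousand.  Three sources are supported: an ideal dipole in
the innermost shell; zero-sum interior monopoles in any single shell
(degree 0 handled in closed form as Σ I/(4πσ·max(r, b)) ), which can be
placed exactly at the discrete source voxels of an FDM solve; and on-surface
injection via the boundary-flux expansion.  Truncation is adaptive with a
relative tail tolerance (1e-8 default).  On-surface point sources make the
series only conditionally convergent at other surface points, so the
FDM-vs-series comparison uses interior monopoles one half-voxel below the
surface — exactly where the discrete solver actually injects.

The comparison in the acceptance script drives a ±1 mA pair through
scalp-surface voxels 45° either side of the vertex and compares scalp
potentials (average-referenced, observation points more than 25° from the
sources) over 8 → 4 → 2 mm grids.  Scalp potentials from *cortical dipole*
sources converge more slowly: their error is dominated by the voxelized
representation of the 2 mm CSF and 5 mm skull layers, which under-resolves
trans-skull attenuation at coarse spacing.  That error is a property of
the voxel-center labeling rule, not of the solver, and is the main reason
sub-2 mm grids are worth their cost when absolute cortical dose matters.

## Lead fields and reciprocity

The lead-field matrix **L** maps a unit dipole at patch p (oriented along
the patch's averaged outward normal) to average-referenced electrode
voltages.  It is built by reciprocity: one forward solve per electrode
(unit current against a fixed reference electrode), with
`L[e, p] = ∇φ_e(centroid_p) · n_p / I` evaluated by central differences,
then row-referenced to the electrode average (which also furnishes the
reference electrode's row).  The dual-route check solves the dipole
directly — as opposite monopole pairs one spacing apart per axis, the
adjoint of the same central-difference stencil — and verifies the entries
agree; since both routes sample the same symmetric discrete operator, the
agreement is limited only by solver tolerance, and the check validates
operator symmetry, the solver, and the bookkeeping at once.

## Targeting rule and sign conventions

Montage construction follows the ranked-weighting heuristic exactly as
specified in the worked example of the README: rank by projected voltage,
cap-weight both sides, re-balance the larger side, rescale to
min(requested, 2 mA).  Ranking ties break toward the lower electrode
index; "largest sink voltage" means largest absolute value among negative
voltages; "total current" means the one-sided (anodal) sum.

Polarity is defined at the cortex, not the scalp:
*cortical-surface-anodal* drives current **along** the patch's outward
normal at the target (n·J > 0 with J = −σ∇φ), cathodal is its exact
negation.  Because maximizing n·J requires injecting in proportion to the
*negated* scalp projection of the along-normal dipole (reciprocity gives
V_e = p·∇φ_e/I, so currents ∝ +column maximize +∇φ·n, i.e. −n·J), the
anodal projection returned by `project_target_to_scalp` is the negated
lead-field column.  The polarity antisymmetry holds exactly; with unequal
source/sink counts the roles of N and M swap under polarity reversal.

The sham montage keeps one local pair inside each active cluster: the
lowest-current source paired with its Euclidean nearest neighbor (next
nearest if the neighbor carries opposite-side current), likewise for the
sink cluster, 100 µA per pair and 200 µA total, so scalp sensation is
mimicked while the deep current path largely cancels.  Array-topology
neighborhoods are not modeled; Euclidean distance stands in for them.

Montage evaluation decomposes J at each patch centroid into the signed
normal component and the tangential magnitude.  `MontageEvaluator` caches
the per-electrode solves and evaluates any montage on the same array by
superposition — identical to a dedicated forward solve by linearity, which
a test verifies — making the Monte-Carlo comparison against
constraint-matched random montages cheap.

## Dosimetry conventions

Injection time: continuous waveforms (tDCS, conditioning, so-tDCS) flow
for the whole session; pulsed waveforms flow for the duty-cycle fraction
`pulse/(pulse + IPI)` (period `1/frequency` when the interval is not
given); sham flows for `n_pulses × pulse`.  Charge is current × injection
time.  For slow-oscillatory DC the package adopts a half-amplitude
convention — a 0-to-peak sinusoid has time-average peak/2 — which is a
documented convention of this package (it reproduces the published charge
figures for the 0.75/1.5 mA oscillatory protocols), not a claim from any
single source.  Published pulse frequencies like "1.8 Hz" are treated as
rounded; presets carry pulse + inter-pulse interval as ground truth.
Mean current density uses decimal half-up rounding to two places, matching
how such dose levels are conventionally quoted.

## MEP statistics and the synthetic cohort

Post-stimulation blocks of 12 trials are summarized by a trimmed mean that
removes exactly one minimum and one maximum; 10-trial baseline blocks are
averaged untrimmed.  Ratios are per-interval means over the baseline mean;
the overall session ratio averages the nine post intervals (0–30 min in
5-min steps, 60, 90), and grouped analyses use the 0–30 and 60–90
groupings.  A participant-exclusion flag supports sensitivity re-analyses
without hard-coding any exclusion.  Condition contrasts are classical
one-tailed paired t-tests (condition < placebo); zero-variance differences
are flagged degenerate rather than silently propagated.  Responder
proportions are compared with exact binomial tail sums; the reference
proportions are kept as exact fractions (22/53) or published decimals
(0.26), with the tail evaluated by direct summation.

The cohort generator draws, per participant: a baseline amplitude from
Normal(0.97, 0.35) mV truncated above 0.1 mV; a true after-effect ratio
per condition from Normal(0.79, 0.21) (cathodal), Normal(0.93, 0.08)
(anodal), Normal(1.10, 0.36) (placebo), floored at 0.05; and multiplicative
lognormal trial noise with log-SD 0.15 (mean-one).  The log-SD is a design
choice: real MEP series are often more variable, but 15% keeps the
min/max-trimmed mean essentially unbiased so the generator's condition
means are recoverable, which is what the recovery tests check.  The
generator emulates only the statistical structure of the crossover — no
TMS recruitment physics, no serial correlation between trials or sessions,
no motor-threshold staircase (those enter only as the baseline amplitude
parameters).  Passing tests therefore establish the correctness of the
analysis chain and the internal consistency of the published effect sizes,
not anything about new experimental data.

## Numerical and degenerate-case choices

* CG tolerance 1e-8 relative (sufficient: the dual-route reciprocity check
  agrees to ~1e-8 at 1e-10).
* Patch normals are area-weighted vertex-normal means (plain mean by
  flag); patches whose normals cancel below 1e-6 are flagged degenerate
  and fall back to the largest member triangle's face normal.
* Parcellation: k = round(area/target) seeds by farthest-point sampling
  (started from the largest triangle for determinism), nearest-seed
  assignment, two Lloyd recentering passes, one boundary rebalancing pass,
  then a connectivity cleanup that merges stranded fragments into their
  best neighbor.
* Nearest-patch and ranking ties break toward the lowest id/index.
* Electrode rays that never cross a scalp voxel (possible at 8 mm, where
  the 7 mm scalp shell voxelizes with gaps) raise a resolution error
  rather than silently snapping.
* Geodesic layouts cover a 120° polar cap by default, mimicking sensor-net
  coverage that spares the lower head.

## Known limitations

* Isotropic conductivity only; no white-matter anisotropy, no
  electrode-skin impedance dynamics, no finite-element variant.
* Point electrodes; contact area is bookkeeping, not physics.
* Voxel-center labeling under-resolves thin CSF/skull layers at ≥4 mm;
  absolute cortical current densities at those spacings should be read as
  order-of-magnitude.
* The ranked-weighting heuristic is the only targeting rule implemented —
  no constrained-optimization (least-squares/LCMV) variants.
* Synthetic cohorts cannot validate any claim about real after-effects;
  they validate the pipeline.
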