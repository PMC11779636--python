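# Methods

This note documents the models implemented in `saxsemble`, the choices made
where the design was genuinely open, and what the synthetic-data tests do
and do not demonstrate about real data.

## Coordinate model

Structures are coarse-grained to one bead per residue (default: the
phosphorus atom of each nucleotide; configurable to C4′ or CA).  Residue
numbers are taken verbatim from the PDB file and must increase strictly;
all vector and matrix outputs are ordered by the ensemble's shared residue
index.  Files with insertion codes are rejected — coarse-grained models do
not use them — and only the first altloc of an atom is kept.  The writer
emits minimal wwPDB v3.3 ATOM records (occupancy 1.00, stored B-factor),
which bounds round-trip coordinate precision at the format's 0.001 Å.

Superposition uses the Kabsch algorithm via quaternion-based alignment with
the proper-rotation (determinant +1) guarantee, so reflections can never
masquerade as fits.  The returned r.m.s.d. is the minimum over the
superposition subset; the transform is applied to the whole conformer.
Subsets with fewer than 3 non-collinear points are rejected because the
rotation is underdetermined.  A brute-force quaternion minimization serves
as the independent oracle in the test suite.

## Debye scattering

Theoretical curves use the Debye equation with unit point form factors:

    I(q) = Σ_i Σ_j sin(q·d_ij)/(q·d_ij),   sinc(0) = 1,  I(0) = N².

This deliberately omits the hydration shell and excluded-volume terms of
atomistic predictors such as CRYSOL; absolute χ² values against curves
computed with those models will differ, which is why all χ²-based claims in
this package are made on internally consistent synthetic data.  An optional
single-Gaussian residue form factor exp(−(q·w)²/2) is available behind a
flag.  The default q grid is 101 linear points over 0.006–0.45 Å⁻¹,
matching a typical bench-instrument range.  Because a discrete bead model's
intensity floors at N·f(q)² rather than decaying at high q, shape
diagnostics (Kratky) are informative only to qRg ≈ 4–5.

Guinier analysis fits ln I vs q² by weighted regression (weights from σ via
var(ln I) = (σ/I)²; absent σ defaults to 1% of I), iterating the window
until q·Rg ≤ 1.3 is self-consistent; nonnegative slopes are reported as
non-Guinier behaviour.  Note the residual systematic bias of the Guinier
approximation itself (≈1% for a homogeneous sphere fitted to qRg ≤ 0.9).
P(r) is the normalized pair-distance histogram with dmax the largest pair
distance; its second moment reproduces Rg within bin-width error.

## Volume-fraction deconvolution

The experimental curve is modelled as c·Σ ν_i·I_i(q) with ν on the unit
simplex and a single global scale c absorbing units; no per-conformer scale
is allowed.  Internally the solver minimizes ‖(I_exp − Σ w_i I_i)/σ‖² over
w_i ≥ 0 with scipy's trust-region reflective bounded least squares, then
reports ν_i = w_i/Σw_i and c = Σw_i — the same model space as a bounded
simplex fit, with a deterministic closed pipeline.  χ² is the reduced form,
Σ[(I_exp − I_fit)/σ]²/(K−1).  Rank deficiency of the candidate matrix
(e.g. duplicate profiles) is detected and the fit flagged non-identifiable:
sums of fractions over a degenerate group remain meaningful, their split
does not.  Missing experimental σ falls back to max(0.01·I, ε), the ~1%
noise regime of bench SAXS, keeping χ² scale-free.

Cosine classification computes 1 − cosine similarity between raw intensity
vectors on the reference grid — scale-invariant by construction, matching
the use of relative intensity variation with q.  Candidates farther than
the threshold (default 0.1) from every reference are left unassigned; ties
break in reference order.

The combination study draws k members per class uniformly **without**
replacement (a class smaller than k contributes all its members — real
classes can be as small as a handful of conformers), refits the drawn
subset, and summarizes χ² per k by mean, s.d. and minimum over the rounds.
With k equal to the class sizes every round reduces to the all-members fit.

The genetic algorithm is a compact stand-in for EOM/GAJOE-style subensemble
selection: membership bitmask chromosomes, fitness = fit χ², tournament
selection of size 2, single-point crossover, per-gene mutation at rate 1/L,
elitism, and all singletons seeded into the initial population so the
result can never be worse than the best single candidate.  Defaults mirror
common EOM settings (50 ensembles per generation, ≤50 members, ≥1).

## Invariant core and ensemble decomposition

Each pruning round superposes all members on the current residue set,
computes each residue's 3×3 positional covariance across members, converts
its eigenvalues to an ellipsoid volume v = (4/3)π√(λ₁λ₂λ₃) (semi-axes of
one standard deviation), and removes the residue with the largest volume.
With a numeric cutoff, pruning stops once max v ≤ cutoff; with the
automatic rule, pruning runs to the floor and the stopping point is the
valley of the derivative of total volume with respect to remaining-residue
count — operationally, the first removal whose 3-point-smoothed volume shed
falls below 1% of the largest shed.  The numeric default (150 Å³) suits
isotropic fluctuations of several Å; near-one-dimensional motions (a pure
hinge arc) produce thin ellipsoids with deceptively small volumes, for
which the automatic rule is the safer choice.  The full pruning trajectory
is reported so either criterion can be audited.

r.m.s.f., PCA and the AMSM all operate on members superposed on the
invariant core by default (configurable).  PCA is the eigendecomposition of
the 3N-coordinate covariance across members, computed by SVD of the
centred coordinate matrix with population (1/M) normalization; eigenvector
signs follow the convention that the largest-magnitude coefficient is
positive, for reproducible reports.  Per-residue amplitudes are
√eigenvalue times the norm of the residue's three eigenvector coefficients,
so squared amplitudes sum to the eigenvalue.  Trajectories interpolate the
mean structure along one component between the minimum and maximum observed
projections.

The AMSM is implemented as the standard dynamic cross-correlation of
positional deviations, ⟨Δr_i·Δr_j⟩/√(⟨|Δr_i|²⟩⟨|Δr_j|²⟩) ∈ [−1, 1] —
the published figure does not state a formula, so this interpretation is an
explicit design choice.  Residues with numerically zero fluctuation are
flagged and given 0 off-diagonal, 1 on the diagonal.  Clustering in PC
space uses average-linkage hierarchical clustering on the truncated
projections (deterministic; default 7 components, 3 clusters).

## Conservation scores

SCS substitutes a transparent information score for ConSurf's Bayesian
framework: per mapped column, 1 − H/log₂4 over {A, C, G, U} frequencies
(gaps excluded from H), multiplied by the column's non-gap occupancy, then
min-max rescaled to [0, 1] across residues.  The ordering semantics —
conserved columns high, variable columns low, gappy columns penalized —
match the original; absolute values do not.  Secondary-structure consensus
and covariation terms are documented extension points, not scored.

3DCS is 1 − min-max-normalized r.m.s.f.; it is invariant to affine
rescaling of the r.m.s.f. vector, and a constant vector is degenerate (all
scores 1, flagged).  Anticorrelated residues are flagged by quartile rule
(upper quartile of one score, lower quartile of the other; no numeric
cutoffs exist to inherit, so quartiles are the default and configurable).
Pearson correlations are reported overall and excluding the flagged sets;
a squared-score correlation is reported alongside on request, since the
published "scaling exponent of 2" is ambiguous between a fit exponent and
axis scaling — both raw and squared correlations are exposed rather than
guessing.

## Synthetic data: what it emulates and what it does not

`generate_hinge_ensemble` builds a 400-residue two-domain bead model at
5.9 Å spacing: a helical rigid core (residues 131–270, identical across
members) and two helical arms hinged at their attachment residues.  Three
classes differ in the mean hinge opening of the first arm (0°, −65°, −140°,
s.d. 4°, arm jitter 1 Å), calibrated once so class Rg spans ≈ 46–58 Å — the
compact-to-extended range of a large two-domain RNA — with class counts
32/118/8 for the 158-member study-scale default.  `synthesize_mixture_profile`
inverts the volume-fraction model with multiplicative Gaussian noise
(default 1%, the bench-SAXS regime) and an honest σ column.
`generate_mode_ensemble` produces rank-controlled ensembles for PCA tests.
`generate_coupled_msa` draws a consensus sequence and mutates each column
with probability coupled to per-residue flexibility; `coupling` is the
induced correlation between conservation and flexibility (−1: flexible
residues are the most variable, so SCS correlates positively with 3DCS),
with optional planted fully-conserved columns at flexible residues as
ground-truth anticorrelated outliers.

What passing these tests shows: the estimators invert their own generating
models correctly at realistic scale, noise and class imbalance, and the
classification/core/PCA machinery recovers planted structure.  What it
does not show: performance under model mismatch that real data carries —
CRYSOL-grade form factors, inter-particle interference, AFM-reconstruction
error correlated across residues, phylogenetic correlation between
alignment rows (rows here are i.i.d. given the column profile), or RNA
backbone realism.  Absolute χ² parity with atomistic predictors is out of
scope by design.

## Numerical choices and degeneracies

- Fractions are validated to sum to 1 within 1e-9; P(r) must integrate to
  1 within 1e-6 (trapezoid).
- Model curves are linearly interpolated onto the experimental grid; only
  the overlapping q range is compared, extrapolation is forbidden.
- Eigenvalues of per-residue covariances are clipped at 0 before the
  square root; PCA orthonormality is asserted to 1e-8 in tests.
- All stochastic components (generators, combination study, GA) take an
  explicit integer seed and are bitwise reproducible from it; the pipeline
  records the config hash, seed and package version in every artifact.
- Desk-scale problem sizes used throughout the suite and the acceptance
  script — 158-member × 400-residue ensembles, 101-point curves,
  100-seed fraction-recovery repeats, 200–500 combination rounds — keep the
  full run in the minutes range while exercising the study-scale geometry;
  the published default of 10,000 rounds remains the library default.
- The pipeline treats every stage as isolated: a failing stage is recorded
  with its error and downstream stages that need its output are skipped,
  never crashed.
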