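# saxsemble

Conformer-ensemble characterization for large, flexible two-domain RNA
molecules — the analysis layer that sits between a set of experimentally
derived 3D conformers (e.g. coarse-grained models of a ~400-nt RNase P RNA)
and the questions a structural biologist asks of them:

- **Which mixture of conformers explains the solution SAXS curve?**
  The experimental intensity is modelled as a linear combination of
  per-conformer profiles, *I*<sub>Total</sub>(*q*) = Σ<sub>*i*</sub>
  *ν*<sub>*i*</sub>·*I*<sub>*i*</sub>(*q*) with volume fractions
  0 ≤ *ν*<sub>*i*</sub> ≤ 1, Σ*ν*<sub>*i*</sub> = 1, fitted by bounded
  (trust-region reflective) least squares against the error-weighted curve
  and scored by reduced χ².  Per-conformer curves come from the Debye
  equation over one-bead-per-residue models; conformers are grouped into
  classes by cosine distance between profiles (default threshold 0.1), and
  a randomized combination study maps how χ² behaves when *k* random
  members per class are refitted over many rounds.  A compact genetic
  algorithm selects minimal subensembles; a titration series is deconvolved
  into per-condition class populations.
- **Which residues form the rigid core, and how does the rest move?**
  An iterative superposition prunes, one residue at a time, the residue
  whose positional covariance ellipsoid volume
  *v* = (4/3)π√(λ₁λ₂λ₃) is largest, until the volume trajectory reaches a
  cutoff (e.g. 150 Å³) or its automatic valley.  The ensemble is then
  superposed on that invariant core and decomposed: per-residue r.m.s.f.,
  PCA of the 3N-coordinate covariance (variance fractions, per-residue
  amplitudes, min-to-max trajectories along each component), the atomic
  movement similarity matrix (AMSM, a dynamic cross-correlation in
  [−1, 1]), clustering in PC space, and correlation of r.m.s.f. against
  crystallographic B-factors.
- **Does sequence conservation track conformational conservation?**
  A per-residue sequence conservation score (SCS: entropy-based column
  information, occupancy-weighted, min-max scaled to [0, 1]) from a
  multiple alignment is correlated with the 3D conformation conservation
  score (3DCS = 1 − min-max-normalized r.m.s.f.).  Residues conserved in
  sequence but conformationally mobile (or vice versa) are flagged as
  anticorrelated, and the correlation is recomputed without them.

A first-class synthetic-data module generates every input with known ground
truth — multi-class hinge ensembles with a rigid core and flexible arms
(class Rg spread ≈ 46–58 Å), noisy mixture curves with known fractions, and
alignments whose conservation is coupled to flexibility — so every recovery
claim in the test suite is checked against a planted truth.

## Worked example

`examples/02_volume_fractions.py` generates the study-scale ensemble
(158 conformers in three classes), mixes one representative per class at
18% / 76% / 6% with 1% noise, and inverts the mixture:

```
true fractions    :  18.0%  76.0%   6.0%
recovered         :  19.2%   73.4%    7.4%
reduced χ² of fit : 0.72 (≈ 1 when residuals match the noise)
class sizes       : {'S001': 32, 'S033': 118, 'S151': 8} (generator used 32 / 118 / 8)
```

Each recovered fraction lands within ~3 percentage points of the planted
truth at this noise level, and cosine classification at threshold 0.1
reassigns every conformer to its generating class.  The other examples
cover SAXS analytics (`01`), invariant core + PCA + AMSM (`03`),
conservation (`04`) and the file-based end-to-end pipeline (`05`); each
prints the numbers it computes and a line on what they mean.

A thin CLI mirrors the library (`saxsemble synth | profiles | fit-ensemble |
classify | combi-study | core | pca | amsm | conserve | run-all`); all
analysis logic lives in the importable API.

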