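# Methods

## Model and assumptions

`cspmatch` treats assignment transfer between two 2D heteronuclear spectra as
a one-to-one matching problem between two point sets in (δ_H, δ_het) space.
The distance between reference peak *i* and target peak *j* is the weighted
chemical shift perturbation

    d_ij = sqrt( Δδ_H² + (Δδ_het / HetScale)² )    [ppm]

The implementation assumes one set of peaks per spectrum, i.e. fast exchange
between free and bound protein, or slow exchange recorded at ligand
saturation; it does not attempt to distinguish the two regimes, track peak
trajectories across a titration series, or resolve overlapped peaks.  Peak
picking is upstream of the package.

No global normalization constant is applied to the distance.  Some CSP
conventions include a prefactor such as 1/√2; all four matching algorithms
are provably invariant under a global positive rescaling of the distance
matrix (greedy order, assignment optima, and both Smart refinements are
preserved — this is asserted by property tests), so the choice affects only
the absolute scale of reported CSPs, never a pairing, a classification
(mean and SD rescale together), or an accuracy.

The same weighting factor is used for every residue type.  Per-residue
weights (e.g. a different factor for glycine) are a known refinement but an
uncommon practice; using one factor keeps reported CSPs comparable across
the sequence.

## Parameters

| parameter        | default | units | role |
|------------------|---------|-------|------|
| `het_scale`      | 5.0     | —     | divisor for the heteronuclear shift difference; ¹³C spectra use the same form with Δδ_C |
| `window_k`       | 7       | residues | width of the centered sequence window for the neighborhood CSP average (the residue ±3) |
| `max_iterations` | 50      | —     | cap on SDS passes / RAS refinement rounds |
| `epsilon`        | 1e-6    | ppm   | floor for neighborhood averages used as RAS divisors |

## Algorithmic choices

**Tie-breaking.**  Wherever a smallest element is selected, exact ties are
broken by lowest reference row index, then lowest target column index; the
SDS score additionally prefers the smaller raw distance before falling back
to indices.  This makes every algorithm deterministic and permutation
handling reproducible.  For the greedy selection this is simply the
row-major first occurrence of the minimum.

**SD.**  Greedy selection of the globally smallest remaining matrix entry,
deleting the matched row and column, until the shorter list is exhausted.

**SDS.**  The greedy score for candidate pair (i, j) is
`|d_ij − avg_csp(i, k)|`, where `avg_csp` averages the current CSP profile
over the window centered at residue i, *excluding* residue i itself — a
candidate must resemble its neighbors, not vote for itself.  Within a pass
the profile entry of residue i is overwritten the moment a pair for i is
accepted, so later selections in the same pass see a mixture of fresh values
and values inherited from the previous pass.  Passes repeat, each seeded
with the previous pass's final profile (the first pass with an all-zero
profile, which makes its first selection identical to SD's), until two
consecutive passes produce the identical pairing or `max_iterations` is hit;
the `converged` flag records which.

**RA.**  Minimum-total-cost bipartite assignment, solved with
`scipy.optimize.linear_sum_assignment`; rectangular matrices are handled
natively, leaving |n − m| peaks of the longer list unmatched (they are
reported, never dropped silently).

**RAS.**  Round 1 is plain RA.  Each subsequent round computes the CSP
profile of the current solution, rescales row i of the distance matrix by
`1 / max(avg_csp(i, k), epsilon)`, and re-solves.  The epsilon floor keeps
the first rescaled matrix finite when a neighborhood average is zero (for
instance every average in the round after a self-match).  Because rescaling
is per-row and positive, it never changes a row's internal preference
order; it changes which rows win conflicts — rows sitting in low-CSP
neighborhoods are amplified, so their nearest-candidate preference dominates,
which is exactly the mechanism that undoes swaps involving one background
residue.  The loop stops when the pairing is stable between rounds.
Reported CSPs are always taken from the unscaled distances: the rescaled
matrix is a search heuristic, not a physical quantity.

**Smart preconditions.**  SDS and RAS require residue assignments on the
reference list; unassigned reference peaks are neglected (dropped before
matching and reported as unmatched).  A reference without any assignment
raises an error rather than degrading silently.

**Brute-force oracle.**  An exhaustive enumeration over all injections of
the shorter list into the longer, capped at 8 peaks on the shorter side,
with the same tie rule.  It exists purely as an independent optimality
check for RA in the test suite and acceptance script.

## Classification protocol

Mean and population standard deviation (divide by N — a descriptive
statistic over the full residue set, not a sample estimate) are computed
once over all residues in the profile.  Categories:

* outlier: CSP > mean + 4·SD (likely artifacts, e.g. a mis-transfer at the
  site; excluded from highlighting),
* high: mean + 2·SD < CSP ≤ mean + 4·SD,
* moderate: mean + 1·SD ≤ CSP ≤ mean + 2·SD,
* background: the rest.

Boundary conventions follow the wording of the protocol: "exceeding by
twice the SD" is strict, "at least one SD" is inclusive.  A numerically
flat profile (SD = 0 up to rounding) maps everything to background so an
unperturbed protein is never flagged.  Whether mean/SD should be recomputed
after outlier removal is genuinely ambiguous (the protocol lists the
computation before the removal and never mentions recomputation); the
single-pass reading is the default and the recomputing variant is available
behind `recompute_after_outliers=True` — in borderline cases, typically
small-CSP systems, the variant admits more residues past the 1σ cut.

The generated viewer script (PyMOL command syntax) shows high residues as
red spheres (sphere scale 1.0) and moderate residues as pink spheres
(scale 0.7) on all heavy atoms, the backbone as a gray cartoon, and the
user-supplied ligand selection in green (sticks for small molecules, cartoon
for peptide ligands).  Residue selections enumerate indices explicitly — no
range fill-in — so the script is an exact transcription of the
classification.  The contract is the script text; rendering is up to the
viewer.

## Accuracy metric

Accuracy is the percentage of predicted pairs whose target peak carries the
same curated residue assignment as its matched reference peak.  Pairs whose
target (or reference) peak is uncurated are excluded from the denominator —
the algorithm is not penalized for peaks no human assigned — and counted
separately.  Percentages are reported at full precision and as half-up
integers for comparison with published tables.

## Synthetic data generator

The generator emulates a well-resolved ¹H–¹⁵N HSQC titration endpoint for a
single-site binder:

* Reference peaks: one per residue, uniform over ¹H 6–11 ppm × ¹⁵N 100–135
  ppm, rejection-sampled so every pair is at least `min_separation = 0.30`
  ppm apart in combined (weighted-distance) units.  That floor is what makes
  planted-truth recovery provable; real crowded spectra violate it, which is
  precisely when matching gets hard.
* Displacements: isotropic directions in the (Δδ_H, Δδ_N/HetScale) plane so
  planted CSP magnitudes are controlled directly in weighted-distance units.
  Magnitudes are `site_csp_scale = 0.10` ppm inside the binding site
  (residues 40–48 of 100 by default — a typical fragment-screening response),
  taper linearly over 2 residues at each site edge, and floor at
  `noise_csp_scale = 0.01` ppm elsewhere; a 5% multiplicative jitter keeps
  magnitudes from being perfectly deterministic.  The taper realizes the
  sequence-clustering of CSPs that the Smart algorithms exploit.
* Optionally a fraction of target peaks is dropped (peaks lost to exchange
  broadening); the planted truth then covers only surviving peaks.
* Everything is deterministic for a fixed seed; target peaks carry the
  curated assignment so accuracy scoring works end-to-end, but matching
  never reads it.

Because every displacement (≤ 0.105 ppm) is below half the separation floor
(0.15 ppm), each target peak is strictly closer to its own reference peak
than to any other, in both directions.  This makes the planted matching the
unique optimum for RA (elementwise dominance), the inevitable result of SD's
greedy order, and a fixed point of both Smart refinements — so 100% recovery
under default conditions is a construction-level guarantee, which the test
suite and acceptance script confirm empirically over 20 seeds.  Passing
these tests therefore validates the machinery, not performance on hard
data: real spectra with overlap, missing peaks, and displacements beyond
the half-separation bound will show the 79–100% accuracy range typical of
experimental benchmarks, not 100%.

The generator does not model exchange-regime line shapes, peak overlap,
intensities, or slow-exchange doubled peak sets.

## Numerical choices and degenerate inputs

* Shifts are stored as read; no referencing correction is applied.
* csv shift values are written to 4 decimals (0.1 ppb, below experimental
  precision); exported per-residue CSPs are written at full float precision
  and re-parsed with exact round-trip.
* Empty peak lists, nucleus mismatches, non-finite shifts, duplicate residue
  assignments, and malformed csv rows raise typed errors early; the CLI maps
  them to exit code 1 (internal faults exit 2).
* Profiles with fewer than 2 residues cannot define an SD and are rejected.
* The problem sizes used by the test suite and acceptance script (100-residue
  simulations, 20 seeds, 500–1000 random oracle instances up to n = 7) were
  chosen to exercise every code path at realistic scale while keeping a full
  run within seconds.

## Known limitations

* One peak list per spectrum: systems in intermediate exchange, or slow
  exchange away from saturation, are outside the model.
* Assignment transfer assumes comparable peak counts in both spectra; large
  asymmetries simply leave the surplus unmatched.
* The Smart algorithms presume sequence-clustered CSPs; for binders with
  genuinely isolated single-residue responses they can be counterproductive
  (that is what the penalty is for).
* The classification is a display convention, not a statistical test; no
  significance is attached to category boundaries.
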