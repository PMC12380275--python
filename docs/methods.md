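# Methods

`chrombench` benchmarks coarse-grained 3D chromatin models against each
other and against chromosome-conformation-capture contact maps.  This note
records the models and procedures it implements, the defaults and why they
were chosen, and what the synthetic generator does and does not emulate.

## The comparison problem

Chromatin modeling packages emit bead-chain polymers for a genomic region,
but at different resolutions (e.g. 1 kb vs 5 kb per bead), in different
units, orientations and overall sizes, and either as single structures or
as ensembles.  Direct coordinate comparison (RMSD after superposition) is
therefore fragile.  The pipeline instead:

1. resamples every model to a common bead count with a basis spline,
2. reduces each model/ensemble to one pairwise Euclidean distance matrix,
3. compares matrices with rank-based and divergence-based statistics that
   are invariant to the nuisances above.

### Coordinates and binning

Region strings are parsed as 1-based inclusive (browser convention) and
stored 0-based half-open (BED convention); both give the same bin count,
so the worked example — the ~1 Mb TAD `chr1:178,421,513-179,491,193` at
5 kb/bead → 214 beads — is stable under either convention.  Bin counts use
ceiling division so the last (possibly partial) bin keeps full region
coverage.  Beads are assumed to tile the region uniformly from its start;
structure formats carry no genomic metadata, so anchoring is supplied by
the caller.

### Spline standardization

Each chain is treated as a discrete space curve.  Beads receive a
chord-length parameter t ∈ [0, 1] (cumulative inter-bead distance,
normalized); three independent univariate B-splines x(t), y(t), z(t) are
fitted over the shared parameter and evaluated at n_out uniform parameter
values including both endpoints.  Per-axis fitting over a common parameter
is equivalent to a parametric curve fit and is easy to verify axis by
axis.

Defaults: cubic splines (`degree=3`), `smoothing=0` (interpolating — the
curve passes through every input bead).  Cubic + chord length is the
standard stable choice for space curves; smoothing is exposed for noisy
inputs but not used by default.  Uniform *parameter* sampling is not exact
arc-length sampling; for the smooth curves produced by chromatin models
the difference is far below the bead scale (the semicircle test bounds the
deviation at 1% of the radius).  Resampling necessarily loses information;
`spline_resample(..., report_loss=True)` reports the max/mean distance
from the original beads to the resampled polyline so users can quantify
it.  Degenerate inputs: coincident consecutive beads are merged for the
fit (they carry no extra curve information); a fully collapsed chain is
rejected.

### Matrices, ensembles and masks

`SquareMatrix` carries values, a kind (`distance`, `contact`,
`pseudodistance`), region, bin size and a per-bin validity mask.  The
diagonal is forced to zero in every kind and excluded from all statistics:
the dominant near-diagonal signal of contact maps otherwise inflates
correlations.  All statistics use only strictly-upper-triangle entries
whose two bins are both unmasked, avoiding double counting.

Ensemble → matrix reduction rules:

- `final` — distance matrix of the last structure; for simulated-annealing
  trajectories where only the final state is physically meaningful.
- `mean` — entrywise mean of the per-structure distance matrices; for
  equilibrium ensembles.  Note this averages heatmaps, never coordinates
  (coordinate averaging collapses mirror-image conformations; a unit test
  asserts the two disagree).
- `medoid` — the structure minimizing summed Frobenius distance to the
  other structures' matrices; a deterministic "single representative"
  rule for when one model must be kept and no trajectory order exists.

Experimental maps are aligned to the model resolution by integer-factor
coarsening: contact matrices are block-summed (counts conserved between
coarse bins; within-block pairs land on the excluded diagonal), distance
matrices block-averaged; a trailing partial block is kept, consistent with
ceiling binning.  Bins whose off-diagonal nonzero fraction falls below a
configurable threshold can be masked (`mask_sparse_bins`), since
near-empty rows of sparse assays yield unreliable ranks.

### Contact ↔ distance mapping

Contact frequency and spatial distance are linked by the power-law decay
s ~ (1/d)^a.  `PowerLawMap(a, eps)` implements d = (s + eps)^(−1/a) and
s = d^(−a).  Defaults: `a = 1` (plain inversion of the contact map — the
baseline validation transform) with `eps` set per matrix to half the
smallest positive off-diagonal contact, which keeps the ordering of all
observed counts while mapping zeros to a finite, largest pseudodistance.
The exponent is not assumed universal: `fit_exponent` estimates a as minus
the slope of the least-squares fit of ln s on ln d over usable pairs, and
recovers a known exponent within 0.1 under 5% lognormal noise at N = 100.
Whether raw or normalized counts should be inverted is left to the user;
the transform parameters used are echoed in output metadata.

### Metrics

- **Spearman** (primary): rank correlation with average ranks for ties.
  Invariant under any strictly increasing entrywise transform — in
  particular under the power-law maps, so model-vs-experiment values do
  not depend on the (unknown) exponent, and under rigid motion or uniform
  scaling of either model's coordinates.
- **Pearson** on raw values, as the common linear alternative.
- **KL divergence** (nats): both matrices are taken to contact space
  (distance-like inputs mapped through the power law, since KL needs
  non-negative mass that decays with distance), restricted to the shared
  unmasked upper triangle, smoothed by an additive constant and normalized
  to probability vectors.  Default direction is model→experiment;
  `jensen_shannon` gives the symmetric, ln 2-bounded variant.
- **Stratified Spearman**: Spearman within windows of genomic separation
  |i−j|, removing distance-decay dominance.  Default strata are dyadic
  (1, 2, 4, … up to N), spanning scales evenly in log separation; strata
  with fewer than `min_pairs` (default 10) usable pairs or constant values
  are reported as *undefined*, never coerced to 0.

Pairwise tables score all unordered pairs; per-pair failures become
undefined cells with reasons rather than aborting the table.  The
upper-triangle/no-diagonal convention is recorded in output metadata so
the numbers are interpretable.

## Synthetic ground truth

The generator is a Gaussian phantom network: beads joined by harmonic
springs — a backbone chain (κ_b, default 1) plus loop springs between
anchor pairs (the spring analogue of CTCF/cohesin loops).  Its Boltzmann
distribution is an exact zero-mean Gaussian whose per-axis precision
matrix is the weighted graph Laplacian, so structures are sampled exactly
(eigendecomposition, no dynamics, no equilibration) in the subspace
orthogonal to the all-ones vector, which also centers every structure and
removes the free translation mode.  Closed forms make the sampler
testable: per-axis covariance is the Laplacian pseudoinverse, and
E‖r_i − r_j‖² = 3 R_ij with R_ij the effective resistance (R_ij = |i−j|
for a unit chain); adding a loop strictly lowers the anchor resistance.
This was chosen over Monte-Carlo polymer simulation precisely because the
oracles are analytic at desk scale.

Contact maps are emitted from an ensemble by either a capture radius
(count structures with d_ij < r_c — ligation-like, loop-enriched) or the
power law (mean of d_ij^(−a)); optional multinomial downsampling to a
target read depth produces finite-depth sparsity.  The packaged benchmark
scene uses 214 beads (matching the 5 kb TAD example), 3 loop springs
(κ = 8), 200 structures, a dense a = 1 power-law map as the Hi-C-like
input, and a capture-radius map (r_c ≈ the median bond length) downsampled
to 20 reads/bead as the ChIA-PET-like input.  Those sizes keep the full
scene under ~10 s on one CPU while leaving Monte-Carlo error well inside
the tolerances above.

What the generator does **not** emulate: excluded volume and chain
topology, loop extrusion dynamics, compartment-scale block copolymer
structure, genomic-distance-dependent ligation bias, balancing artifacts,
or inter-cell heterogeneity beyond Gaussian fluctuation.  Passing tests
therefore demonstrate that the pipeline's transformations and statistics
are correct and self-consistent — not that any particular modeling package
reproduces real chromatin.

## Numerical choices

- Symmetry is enforced at 1e−9; matrices are symmetrized after transforms
  to absorb floating-point drift.
- Correlations on fewer than 3 pairs or constant input raise/report
  *undefined* rather than returning a number.
- The medoid tie-break is `argmin` (first minimizer wins), deterministic.
- All randomness flows through explicit integer seeds
  (`numpy.random.default_rng`); scene metadata records every derived seed.
- Structure round-trip precision: 1e−3 for fixed-width PDB, 1e−6 for XYZ
  (6-decimal output) and mmCIF.

## Known limitations

- Bead→coordinate anchoring assumes uniform tiling from the region start;
  models with irregular per-bead coverage are not representable.
- Coarsening only by integer factors; incompatible bin counts raise with
  the nearest achievable alternatives rather than silently interpolating.
- The cooler-style reader handles single-resolution containers with raw
  counts; balancing weights are ignored.
- KL in contact space depends on the chosen exponent (unlike Spearman);
  the default a = 1 is a convention, not an estimate.
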