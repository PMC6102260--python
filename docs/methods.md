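# Methods

This note documents the models, numerical choices and deliberate
simplifications behind each analysis stage, in the order a typical domain
comparison runs them.

## Coordinate model and I/O

Structures are parsed (gemmi) into a minimal hierarchy — models → chains →
residues → atoms — keyed by author (PDB) numbering; all residue ranges in
the package are 1-based and inclusive. Three policies are fixed at read
time so that downstream geometry is comparable across inputs:

- **Altlocs** resolve to the highest-occupancy conformer, ties broken by
  file order. This is deterministic and needs no user input.
- **Hydrogens, waters and heteroatoms** are excluded by default.
  Crystallographic entries rarely contain hydrogens, and including them
  only where present would make SASA and r.m.s.d. values incommensurable.
- **"Backbone"** means the four heavy atoms N, CA, C, O.

Writing always emits ATOM records; per-residue annotations (conservation,
scores) are stamped into the B-factor column (`%6.2f`, so values must lie
in [-99.99, 999.99]) — the standard trick for surface colouring in
molecular viewers.

## Superposition and r.m.s.d.

Optimal rigid superposition uses the SVD form of the Kabsch algorithm with
the determinant correction, so reflections are never returned. Pairwise
r.m.s.d. is computed only over corresponded residues that carry the full
atom set on both sides; incomplete pairs are dropped with a warning and
fewer than three usable pairs is an error.

**Ensemble precision** is defined as mean ± sample sd of per-model
r.m.s.d. to a mean structure refined iteratively (superpose all models on
the current mean, recompute the mean, repeat until the mean shifts by
< 1e-6 Å r.m.s.). This is the standard NMR-ensemble convention; the
alternative (average over all model pairs) differs by a factor close to
√2 for Gaussian ensembles. For a crystal form with several copies in the
asymmetric unit the analogous statistic is mean ± sd over the pairwise
chain superpositions.

**Structure-based alignment** pairs residues of two single-chain domains
by spatial proximity rather than sequence: starting from a global sequence
alignment as seed, superpose chain B onto A on the CA atoms of the current
pairs, then re-pair with an order-preserving (monotone) dynamic programme
that maximises the number of CA pairs within 4.5 Å and, among those,
minimises the total CA–CA distance; iterate until the pairing is stable
(at most 20 rounds). 4.5 Å is the conventional cutoff for structural
equivalence of CA positions; monotonicity keeps the correspondence
biologically sequential, so insertions (e.g. a two-residue loop extension)
are left unpaired rather than crossed over. The procedure is idempotent
once converged. Ties in the DP traceback prefer matching earlier (lower
residue numbers).

## Solvent accessibility

Shrake–Rupley SASA places a deterministic golden-angle spiral lattice
(default 960 points) on each probe-expanded sphere (probe 1.4 Å) and
counts points not occluded by any neighbour. Because the lattice is fixed
in the laboratory frame, repeated runs are bit-identical, translations
leave areas exactly unchanged, and rotations reproduce totals to the
angular resolution of the lattice (≲ 0.5 % at 960 points; doubling the
point count roughly halves the discretisation error). Neighbour search
uses a k-d tree with radius r_i + r_max + 2·probe.

Van der Waals radii are the Bondi (1964) set, bundled and named in every
profile so provenance travels with results (absolute SASA shifts with the
radii choice). Relative accessibility divides residue SASA by the
theoretical Gly-X-Gly maxima of Tien et al. (2013); values above 1 can
legitimately occur at termini and are not clipped. The exposed/buried call
thresholds relative accessibility at 0.25, with the boundary value
classified exposed — a deliberate, documented convention since no single
threshold is canonical in the field.

## Interface detection and occurrence score

For a binary complex, each reference-chain residue's buried SASA is
`sasa_alone − sasa_complex`, with `sasa_alone` computed on the reference
chain extracted *at its complex coordinates* and both passes using
identical SASA parameters. The buried fraction divides by `sasa_alone`
and is defined as 0 where `sasa_alone` is 0: a residue with no accessible
surface in the monomer cannot be an interface residue, and this avoids a
division by zero.

Across a panel of complexes sharing a reference protein, a residue's
occurrence count increments once per complex in which its buried fraction
is strictly greater than 10 % (strict, matching the defining convention of
such scores). The score divides by the number of complexes, giving a
bounded, directly interpretable interface propensity; dividing by the
maximum count instead is available as an option. Residue-level (not
atom-level) aggregation is used before thresholding. Complexes with
several copies of the reference protein are handled by the caller naming
the reference chain explicitly; chain choice is recorded in the record.

## Sequence identity and conservation

Pairwise identity uses Biopython's global aligner with BLOSUM62 and affine
gaps (open 10, extend 0.5). The denominator is the number of alignment
columns that are not double gaps; columns gapped on exactly one side count
as non-identical. This pinning matters: with it, the bundled human FAT10
domain sequences give 27 % (N-domain) and 35 % (C-domain) identity to
ubiquitin and 18 % to each other. Domain boundaries follow the expression
constructs used in the structural work (N: residues 5–86, C: 85–165);
identity values move by a point or two under other defensible boundary
choices, which is why a ±3-point band is the right way to read them.

Column conservation is deliberately simple and fully reproducible: the
modal-residue frequency among non-gap symbols, or 1 − H/ln 20 with H the
Shannon entropy of the non-gap frequencies. Phylogeny-aware rate
estimation (ConSurf-style) is out of scope — the scores here serve
qualitative surface colouring, and the method name is recorded in every
profile. All-gap columns yield a missing value; columns with > 50 % gaps
are flagged low-coverage. Note that duplicating an arbitrary sequence can
*lower* a column's modal frequency (k/(n+1) < k/n when the duplicate does
not carry the modal residue); only duplicating the per-column consensus is
guaranteed never to decrease it, and that is the invariant the tests pin.

Mapping a conservation profile onto a structure transfers column scores
through the gap pattern of the named MSA record onto author residue
numbers; the record's ungapped sequence must match the chain sequence
(> 10 % mismatch is an error, anything less a warning with a per-site
report).

## NMR observables

CSP combines proton and nitrogen shift changes as
√(Δδ_H² + (w·Δδ_N)²) with w = 0.154, the conventional nitrogen scaling
reflecting the relative shift dispersions; w is a parameter and is
recorded in the profile. Peaks are matched across spectra strictly by
assignment (residue number) — no nearest-peak matching — because the
analysis targets assigned spectra; residues present in only one list are
reported, never imputed.

Steady-state het-NOE is the per-residue intensity ratio
saturated/reference, averaged over replicate experiment pairs with the
sample (n−1) standard deviation. A zero reference intensity makes the
ratio undefined: the residue is excluded and reported. Negative ratios
are physical (fast motion, exchange) and pass through. The flexibility
flag selects residues with mean NOE strictly below 0.2, the conventional
boundary for fast backbone disorder.

## Melt curves

Melting temperature is read from the first derivative of the smoothed
signal: Savitzky–Golay smoothing (second-order polynomial, default window
25 points ≈ 0.9 °C on a 0.036 °C grid), derivative of the fitted
polynomial, then the global maximum. Sub-grid precision comes from a
quadratic fit of the derivative over a window of ±1.5× the smoothing
window around the maximum, which averages point noise far more effectively
than three-point parabolic interpolation (on synthetic curves with 1 %
amplitude noise, mean recovery error drops from ~0.17 °C to ~0.02 °C). A
derivative maximum within half a smoothing window of either grid boundary
— the signature of a flat or truncated transition — is flagged unreliable
and no Tm is reported. Tm is invariant under affine rescaling of the
signal axis. Replicate inputs yield per-replicate Tm plus mean ± sd. The
temperature grid must be uniform (within 0.1 %); thermodynamic two-state
ΔG fitting is out of scope.

## Trajectory metrics

RMSF superposes all frames onto an iteratively refined mean structure —
optionally fitting only a rigid core selection, so genuine local motion is
not absorbed by the fit — and reports per-atom √⟨|x − ⟨x⟩|²⟩. Rigid-body
motion alone gives RMSF ≡ 0 after fitting, and a residue jittered with an
isotropic per-coordinate σ recovers σ√3.

RMSD clustering is the GROMOS neighbour-counting algorithm: from the
all-pairs fitted-RMSD matrix, repeatedly take the frame with the most
unassigned neighbours within the cutoff (ties: lowest frame index) as a
cluster center, assign its neighbours, remove them, and continue. The
partition is disjoint and exhaustive, ordered by decreasing size.

Group distances are per-frame Euclidean distances between unweighted (or
mass-weighted, as an option) centroids of two atom selections. Trajectory
input is multi-model PDB or a plain frame/x/y/z table; compressed MD
formats are intentionally not core dependencies.

## Synthetic data

Generators are pure functions of (seed, parameters) and return the planted
truth alongside the fixture:

- **Backbones** are built from ideal bond lengths/angles with per-class
  dihedrals (helix −57/−47, strand −139/135, coil drawn from a small
  allowed set); a helix fixture shows ~3.8 Å CA spacing and ~1.5 Å rise.
- **Complexes** plant interface residues by placing single occluding atoms
  along the carbonyl direction made perpendicular to the local chain axis,
  ~3 Å from the residue surface — a footprint small enough to push one
  residue above the 10 % buried threshold without dragging neighbours
  along. Every fixture is *self-certifying*: it is verified with the
  package's own buried-SASA scorer (same parameters the analysis uses)
  before being returned, so planted truth and downstream scoring agree
  exactly; placement retries with jitter and fails loudly if the requested
  set cannot be certified.
- **MSAs** plant exact per-column modal counts (round(p·n) carriers), so
  identity-conservation recovers the planted frequency exactly.
- **Melt curves** are two-state sigmoids (inflection = planted Tm) on the
  0.036 °C nanoDSF grid, with optional Gaussian noise as a fraction of the
  amplitude.
- **Ensembles** add isotropic per-residue Gaussian jitter to a base
  structure; a disordered-tail range receives a large σ to emulate a
  flexible terminus.

What the generators do *not* emulate: real side-chain packing, correlated
(collective) motions, aligner-induced MSA artefacts, or instrument
baselines with slopes and drift. Passing recovery tests therefore
demonstrates correctness of the estimators under their stated models, not
robustness to every artefact of experimental data.

## Problem sizes and tolerances

The test and acceptance workloads are sized for quick desk runs: 16
synthetic complexes of a 20-residue chain for interface scoring, 100
random instances for the Kabsch-vs-optimizer comparison (oracle:
Nelder–Mead over rotation vectors, six starts), 100 seeded melt curves at
1 % noise, 1000-frame ensembles for RMSF recovery (5 % tolerance on σ√3,
the sampling error at that depth), and 30-frame instances for clustering
against an exhaustive reference. The SASA lattice default of 960 points
keeps single-atom areas within 0.5 % of analytic values; two-sphere
configurations agree with the spherical-cap closed form within 1 %.

## Known limitations

- The deposited FAT10/ubiquitin entries are not redistributed; the tests
  that reproduce published r.m.s.d./precision values require the user to
  supply those files (see README) and fail with an explicit message
  otherwise.
- SASA totals are rotation-invariant only to lattice resolution (see
  above); treat sub-0.5 % SASA differences at default settings as noise.
- The conservation scores are frequency-based, not evolutionary rates.
- `make_complex` certifies plants only for the SASA parameters it is given;
  rescoring a fixture with different probe/lattice settings may move
  residues across the 10 % threshold.
- Experimental melting temperatures from unreleased raw curves cannot be
  recomputed; synthetic recovery is the test surface for the Tm estimator.
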