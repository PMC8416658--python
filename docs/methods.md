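# Methods

This note documents the models implemented in `silicomap`, the parameter
choices that matter, what the synthetic data do and do not emulate, and the
numerical conventions a user relying on the outputs should know.

## Cells, alleles and nuclear placement

An in silico cell is a pair of conformations drawn independently and
uniformly (with replacement) from the ensemble — the two alleles of the
locus. For all three protocols the alleles are placed in a shared spherical
nucleus: each is centered, given a uniform random rotation, and its
centroid is placed uniformly in the sub-sphere that guarantees full
containment. Inter-allele crosslinks are therefore *possible* but rare, as
for homologous loci in a real nucleus; a `placement="native"` option keeps
the conformations in their original coordinate frames instead (there the
two alleles overlap spatially and trans-allele contacts are common). All
intra-allele proximity relations are rigid-motion invariant, so the
implementation caches per-conformation proximity edges and only computes
explicit placed coordinates when the two alleles' bounding spheres approach
within the crosslink range.

## The three protocols

**Crosslinking (Hi-C and SPRITE).** Beads of the same binding-site color
closer than the interaction range *d* (default 1.3 σ, the models'
interaction range for regular colors) are joined; each bead enters the
crosslinked material independently with probability *p*<sub>c</sub>.
Clusters are the connected components of this proximity graph
(single-linkage); singletons are discarded because a lone fragment cannot
produce a contact.

**Hi-C.** Digestion splits the chain into individual beads, so clusters are
the only surviving structure. Each cluster bead survives biotinylation with
*p*<sub>b</sub> and is ligation-eligible with *p*<sub>l</sub>. Ligation
repeatedly selects a uniform random pair among the still-unused eligible
pairs within *d* until none remains. This sequential-uniform rule is
realized as a greedy pass over a uniformly permuted edge list, which
induces exactly the same distribution (the first feasible element of a
uniform permutation is uniform over the feasible set at every step). Each
ligated pair is counted into its (symmetric) bin-pair entry with
probability *p*<sub>d</sub>. For an isolated two-bead cluster the expected
count is *p*<sub>c</sub>²*p*<sub>b</sub>²*p*<sub>l</sub>²*p*<sub>d</sub>,
which the tests verify by Monte Carlo.

**SPRITE.** Crosslinking and digestion are identical to Hi-C (shared code).
Split-pool barcoding is not simulated explicitly — cluster identity is
already known — but tag loss is: each cluster bead keeps its tag with
*p*<sub>s</sub> and is sequenced with *p*<sub>d</sub>. For each cluster
with *n* detected fragments covering at least two distinct bins, every
unordered pair of those bins receives weight 2/*n*. By default *n* counts
*detected* fragments, mirroring the experimental weighting applied to
sequenced cluster reads; `weight_basis="cluster"` counts all crosslinked
fragments instead. The total weight a cluster can contribute is *n* − 1,
attained exactly when all detected fragments fall in distinct bins.

**GAM.** One randomly oriented slab of thickness *h* is cut per cell: the
slab normal is uniform on the sphere, the slab-center offset uniform in
(−*R*, *R*) along it. In-slab beads are detected with *p*<sub>d</sub>; a
bin is positive when at least one of its beads (alleles pooled) is
detected. Slices that miss the locus are legitimate, frequent, and remain
in the normalizing slice count, as in the experiment. Cosegregation
frequencies are co-occurrence counts divided by the number of slices; the
matrix diagonal equals the per-bin detection frequency *p*(*i*). NPMI
= −PMI / log *p*(*i*,*j*) with natural logs (the ratio is base-invariant);
pairs with *p*(*i*,*j*) = 0 or *p*(*i*)·*p*(*j*) = 0 are undefined and
emitted as NaN, and *p*(*i*,*j*) = 1 (perfect co-occurrence) maps to 1.

## Efficiency semantics

The overall efficiency ε is the product of the per-step probabilities and
is interpreted as the probability that a *bead* survives the full
protocol. A single ε supplied to the convenience constructors or the CLI
is loaded onto one **per-bead** step:

* Hi-C → biotinylation *p*<sub>b</sub>. Any of *p*<sub>c</sub>,
  *p*<sub>b</sub>, *p*<sub>l</sub> would do — per-bead thinning before or
  after clustering yields identical pair-eligibility laws, because a
  within-*d* pair whose endpoints both survive is always in one cluster.
  The detection step *p*<sub>d</sub> is intentionally *not* used: it acts
  per ligated pair, so loading ε there would make single-cell signal scale
  as ε rather than ε², breaking the per-bead interpretation that underlies
  the ε⁻² cell-number law.
* SPRITE → crosslink inclusion *p*<sub>c</sub>. Incomplete crosslinking
  fragments complexes *before* clustering, keeping simulated cluster sizes
  at working efficiencies comparable to the small sequenced clusters of
  real SPRITE. Loading the loss onto tag retention instead leaves intact
  locus-spanning complexes whose co-occurrence signal is far more
  reproducible than observed single-cell data.
* GAM → detection *p*<sub>d</sub> (the only step).

Bulk map *shape* is insensitive to how a given ε is decomposed across
per-bead steps (Pearson ≥ 0.99 between decompositions at *N* = 5,000 in the
acceptance suite), though the absolute count scale is not — a per-pair
*p*<sub>d</sub> thins counts linearly while per-bead steps thin
quadratically.

The bead-level GAM efficiency maps onto the window-level (experimental)
efficiency through
ε<sub>GAM</sub> = 1 − ((1−ε)/ε)(1−(1−ε)^{2n})/(2n),
obtained by averaging the window detection probability 1 − (1−ε)^k over
the number k of in-slab window beads, taken uniform on 1..2n (n beads per
bin, two alleles). The closed form is singular at ε = 0, where the limit 0
is returned; it is verified against direct Monte-Carlo sampling of k over
an (ε, n) grid in the tests.

## Synthetic ensembles

**Domain (TAD-like) generator.** Each conformation is built from one
continuous fractional Brownian chain with Hurst exponent H = 0.30 (near
the crumpled-globule value 1/3 characteristic of interphase chromatin), so
mean pair distance grows as s^H with genomic separation s and pairwise
contact probability decays as a power of s. Each domain segment is scaled
by (1 − compaction)·BASE_STEP — algebraically identical to pulling every
bead toward its domain centroid with strength `compaction` (compaction 1
collapses a domain to a point) — and consecutive domains receive a
cumulative random rigid offset with mean step CENTROID_STEP, producing
distance-map blocks whose mutual distances grow with genomic separation
and fluctuate from cell to cell. Optional long-range bead pairs are
bridged within 1 σ in a configurable fraction of conformations by rigidly
translating the partner's domain, mimicking a block copolymer whose
isolated bridge beads of a third color form a long-range contact.

Constants, with rationale:

| constant | value | meaning |
| --- | --- | --- |
| `FBM_HURST` | 0.30 | distance scaling exponent; near-crumpled-globule folding |
| `BASE_STEP` | 2.4 σ | chain amplitude; at the default compaction 0.6 the mean adjacent-bead spacing is ~1.5 σ. A bead stands for ~13 kb of chromatin whose contour (~5 σ at 70 bp/nm and σ = 38 nm) far exceeds its diameter, so sub-2 σ center spacing is physically comfortable. |
| `CENTROID_STEP` | 4.0 σ | rigid inter-domain offset, deliberately *below* the chain scale: domains are adjacent compartments of one fold. Offsets much larger than the chain scale make inter-domain contact probability grow with chain separation (a variance effect) while mean distance grows too, inverting the contact-distance relation. |
| compaction | 0.6 | default per-domain pull |

At this density the 1.3 σ proximity graph has moderate connected
components (typical clusters of 2–30 beads, occasional ~100+), comparable
in character to sequenced SPRITE clusters, without percolating the whole
chain — the property that lets all three protocols resolve structure on
the same ensemble.

The default benchmark ensemble (`default_test_ensemble`) has 210 beads,
two equal domains, 3 beads per 40-kb bin (70 bins), uniform bead color (so
any proximal pair can crosslink) and 200 conformations — a toy-model scale
chosen so the whole benchmark runs on a desk machine.

What the generator does *not* emulate: excluded volume within and between
domains (conformations are Gaussian-process chains), binder-mediated
folding dynamics, color-specific interaction energies, loop extrusion, or
locus-specific patterns beyond blocks, decay and optional bridges.
Benchmarks passing on these ensembles show that the protocol simulators
and statistics behave correctly on polymers with realistic distance decay
and domain structure; they do not certify performance numbers for any real
locus.

**SAW control.** Self-avoiding chains grown with unit steps and a hard
core of one bead diameter, by per-step retry with whole-chain restarts
(the growth bias of retry-based sampling is acceptable for a structure
control). If a target gyration radius is set, one *global* rescale makes
the ensemble-mean R_g match it exactly, mirroring controls matched in size
to imaged conformations. SAW mean distance maps are featureless: their
distance-corrected correlation r′ with domain-ensemble maps stays below
0.15 (the residual nonzero value comes from chain-end effects present in
any linear polymer).

## Nuclear geometry

Defaults R = 120 σ, h = 6 σ correspond to a ~4.6 µm nuclear radius and
~220 nm cryosections at σ = 38 nm — the scale of a full-size ~6-Mb locus
model of ~2,000 beads. The protocol's principle is that geometry is set in
σ units to match the system under study, so for other ensembles
`gam.scaled_geometry` reproduces the same locus-to-nucleus occupancy
(mean R_g / R ≈ 0.11; R ≈ 40 σ for the 210-bead toy ensemble). The
benchmark's M(ε) study uses the scaled geometry: with the full-size
nucleus around the toy polymer, fewer than 7% of slices intersect the
locus at all and GAM cell numbers inflate ~5-fold for purely geometric
reasons. Criteria that do not involve cell-number searches (noise floors,
bulk fidelity) use the default geometry, where they are insensitive to
this choice.

## Benchmark machinery

**Replicate correlation.** k independent replicates (cells redrawn per
replicate), mean Pearson over all k(k−1)/2 pairs of maps, computed over
the off-diagonal upper triangle. All-zero (constant) replicate maps are
excluded with a warning; fewer than two usable maps is an error.

**Minimal cell number M.** The smallest N on a log-spaced integer
candidate grid where the mean replicate correlation reaches r_t = 0.9,
bracketed by geometric (half-decade) milestones and located by bisection
on grid indices. The replicates are maintained as k cumulative cell
streams with snapshots at every grid point, so every r(N) evaluation is a
prefix lookup and the whole search costs k × (bracket upper end) simulated
cells; each r(N) remains the exact statistic defined above (estimates at
different N share cells, which is harmless for a threshold search on a
monotone curve). The acceptance suite uses k = 15 replicates and a
32-point-per-decade grid: the Hi-C exponent of M(ε) sits close to the edge
of its tolerance band, and coarser grids add ±0.06 of pure quantization
error to the fitted exponent.

**Noise-to-signal.** Per-entry mean μ and sample standard deviation σ
(ddof = 1) across replicate maps, accumulated streamingly. Aggregates at a
genomic separation average σ/μ over entries with μ > 0 (entries never
observed are excluded — the ratio is undefined there). GAM maps are
frequency-normalized before aggregation; σ/μ is scale-invariant, so this
only affects readability.

**CLT diagnostics.** ρ(ε) = ⟨μ²/σ²⟩ over upper-triangle single-cell
entries with σ > 0; L(ε) = δ⁻²/ρ(ε); linear fit of M against L and log-log
power-law fits of M and ρ⁻¹ against ε. For Bernoulli single-cell entries
with success probability ε²c_ij the small-ε limit is ρ ≈ ε²·c̄, which the
tests verify with an injected closed-form simulator; this is the origin of
the approximate M ∝ ε⁻² law. On the default ensemble the measured Hi-C
exponent is ≈ −1.6 rather than −2: Hi-C has an intrinsic reproducibility
floor (M ≈ 40 at ε = 1, from single-molecule conformational variability)
and its ligation matching saturates at high efficiency (once most eligible
beads find partners, counts grow ~linearly rather than quadratically in
ε), both flattening the fit at the ε = 0.4 end. SPRITE (~−1.95) and GAM
(~−1.9) sit closer to the Bernoulli ideal.

## Map-statistic conventions

* Default mask: off-diagonal upper triangle. The main diagonal is excluded
  from every correlation (it is trivially self-similar for distance maps
  and cosegregation).
* Undefined entries (NaN, e.g. NPMI of never-cosegregating pairs) are
  dropped pairwise. Constant inputs raise an explicit
  degenerate-correlation error rather than returning NaN.
* r′: the mean of every diagonal (fixed |i−j|) is subtracted from each
  matrix independently before the Pearson correlation; this removes the
  average distance-decay trend shared by all chromatin maps. A map plus
  any pure function of |i−j| therefore correlates at exactly 1 with the
  original.
* scc: both maps are smoothed with a (2h+1)² mean filter (h = 1 by
  default; edges and missing values average over available entries),
  entries are stratified by |i−j| from 1 up to half the matrix size
  (longer strata are too sparse to be stable), and scc
  = Σ w_k ρ_k / Σ w_k with ρ_k the per-stratum Pearson and
  w_k = N_k·s_Ak·s_Bk using population standard deviations. Zero-variance
  strata are skipped; scc(A, A) = 1 whenever any stratum is
  non-degenerate.
* scc bootstrap null: each diagonal of each matrix is resampled with
  replacement within itself, independently for the two maps — positional
  structure is destroyed, the distance-decay profile preserved. The 90th
  percentile of the null is the reference threshold.
* Mann-Whitney U: exact enumeration when both samples have n < 20 and no
  ties, normal approximation (with tie correction) otherwise.
* Percentiles (e.g. the first tertile in structural matching) use linear
  interpolation between order statistics.
* Structural matching: Kabsch superposition restricted to proper rotations
  (reflections excluded to preserve chirality). The default one-to-one
  assignment is greedy — repeatedly take the global minimum RMSD among
  unassigned pairs — with an optimal bipartite (Hungarian) alternative
  available; the greedy rule is the default because the assignment is
  defined operationally, pair by pair, and is cheaper on large ensembles.

## Determinism and seeds

Every public entry point takes either an integer seed or a numpy
`Generator`. Cells within one run are drawn from a single sequential
stream; replicates and benchmark repetitions use independent spawned
streams, so any replicate can be replayed in isolation. All CLI outputs
are byte-reproducible under a fixed `--seed` and carry a provenance
comment block (method, efficiency decomposition, N, geometry, seed).

## Problem sizes used by the shipped benchmarks

The test and acceptance runs use the 210-bead / 70-bin / 200-conformation
ensemble throughout; 50 replicates per point for the N-scaling of σ/μ over
N ∈ {10, 50, 100, 500, 1000}; 5,000 replicates for the N = 1 noise floor;
N = 5,000 cells (or slices) for bulk-fidelity checks; and k = 15
replicates with n_max = 10⁶ for the M(ε) searches over
ε ∈ {0.05, 0.1, 0.2, 0.4}. These sizes keep the full suite within minutes
on a single CPU while leaving the statistical margins comfortably wider
than the assertion tolerances.

## Known limitations

* The domain generator has no excluded volume and no binder dynamics; it
  emulates the *statistics* of folded chromatin ensembles, not their
  physics.
* Hi-C detection acts per ligated pair (not per bead), so the absolute
  count scale — not the map shape — depends on where a given ε is
  decomposed; cross-method comparisons here always load ε on per-bead
  steps.
* SPRITE barcode collisions, multi-slice GAM variants (several nuclear
  profiles per sequencing tube), restriction-site sequence effects,
  read-level simulation and matrix balancing/ICE are all out of scope.
* The slab geometry treats the nucleus as a sphere with uniformly
  positioned, independently folded alleles; nuclear landmarks (lamina,
  nucleoli) and allele-allele correlations are not modelled.
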