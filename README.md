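# silicomap

**In silico Hi-C, SPRITE and GAM on known chromatin 3D structures.**

Hi-C, SPRITE and GAM all measure genome-wide DNA contacts, but through very
different physical protocols: proximity ligation of crosslinked fragments
(Hi-C), split-pool barcoding of whole crosslinked complexes (SPRITE), and
sequencing of thin random nuclear cryosections (GAM). Because no experiment
ever observes the underlying 3D structures directly, their relative
performance — how faithful their maps are to real 3D distances, how many
cells each needs for reproducible output, how noise grows with genomic
distance and shrinks with detection efficiency — cannot be measured from
experimental data alone.

`silicomap` answers those questions by *simulating all three protocols on
ensembles of single-molecule polymer conformations whose 3D structure is
known exactly*, and benchmarking the resulting contact maps against that
ground truth. It is aimed at computational genomicists designing or
comparing 3D-genome experiments, and at modellers validating polymer
ensembles against contact data.

## What it simulates

One *in silico cell* is a pair of independently drawn conformations (the
two alleles), placed at random in a spherical nucleus. Per cell:

* **Hi-C** — same-color beads closer than the interaction range *d* are
  crosslinked into clusters (single-linkage; each bead enters with
  probability *p*<sub>c</sub>); cluster beads survive biotinylation
  (*p*<sub>b</sub>) and are eligible for ligation (*p*<sub>l</sub>);
  eligible mutually-proximal pairs are ligated by a uniform random maximal
  matching; each ligated pair is detected with *p*<sub>d</sub> and counted
  into its bin pair. Overall efficiency
  ε = *p*<sub>c</sub>·*p*<sub>b</sub>·*p*<sub>l</sub>·*p*<sub>d</sub>.
* **SPRITE** — same crosslinking; each cluster bead keeps its tag
  (*p*<sub>s</sub>) and is sequenced (*p*<sub>d</sub>); every pair of
  distinct bins touched by a cluster's *n* detected fragments receives
  weight 2/*n*.
* **GAM** — one randomly oriented slab of thickness *h* is cut through the
  nucleus (radius *R*) per cell; in-slab beads are detected with
  *p*<sub>d</sub>; a bin is "positive" if any of its beads is detected;
  cosegregation frequencies *p*(*i*,*j*) are co-occurrence counts over
  slices, optionally normalized to NPMI
  = −PMI / log *p*(*i*,*j*), PMI = log[*p*(*i*,*j*) / (*p*(*i*)*p*(*j*))].

On top of the protocols sit the benchmark statistics: Pearson/Spearman
correlations, the genomic-distance-corrected Pearson *r*′, a HiCRep-style
stratum-adjusted correlation (scc) with a distance-preserving bootstrap
null, Kabsch-RMSD structural matching against reference conformations,
replicate-reproducibility curves, the minimal cell number
*M*(ε) (smallest *N* with mean replicate Pearson ≥ 0.9, found by bisection),
per-entry noise-to-signal ratios σ/μ across replicates, and the
central-limit diagnostics ρ(ε) = ⟨μ²/σ²⟩ and *L*(ε) = δ⁻²ρ⁻¹(ε). The GAM
bead efficiency maps to the window-level efficiency via
ε<sub>GAM</sub> = 1 − ((1−ε)/ε)·(1−(1−ε)<sup>2n</sup>)/(2*n*)
(ε = 0.5, *n* = 15 gives ε<sub>GAM</sub> = 0.97).

No external data is needed: a seeded synthetic module generates TAD-like
domain ensembles (fractal chains with compacted domain blocks) and
size-matched self-avoiding-walk (SAW) controls.

## Worked example

```bash
cat > toy.json <<'EOF'
{"kind": "domain", "n_beads": 210, "beads_per_bin": 3,
 "domain_boundaries": [0, 105, 210], "n_structures": 200, "seed": 0}
EOF
silicomap synthesize --config toy.json --out toy
silicomap hic --ensemble toy --cells 5000 --efficiency 1.0 --seed 1 --out hic.tsv
silicomap gam --ensemble toy --slices 5000 --seed 1 --out gam
silicomap compare hic.tsv gam.coseg.tsv
```

prints

```
wrote 200 conformations, 210 beads, 70 bins -> toy.*
hic: 794082 contacts -> hic.tsv
gam: 5000 slices, mean p(i) = 0.0602 -> gam.*
{
 "pearson_r": 0.6703684481008625,
 "spearman_r_s": 0.8752011234548179,
 "distance_corrected_r_prime": 0.2660676112277111,
 "scc": 0.40020793850394143
}
```

The first three lines build a two-domain 210-bead ensemble (70 bins at
40 kb) and run 5,000-cell Hi-C and GAM experiments at full efficiency. The
comparison shows what the benchmark quantifies: the two technologies' bulk
maps agree strongly in rank (Spearman 0.88) because both reflect the same
underlying 3D distances, while the distance-corrected *r*′ (0.27) and scc
(0.40) are lower because, once the shared distance-decay trend is removed,
each protocol retains its own characteristic signal — GAM's slab geometry
emphasises longer-range structure than ligation does. `silicomap find-m`
and `silicomap noise` expose the cell-number and noise benchmarks the same
way; the Python API (`silicomap.*`) gives access to everything, including
replicate streams and CLT diagnostics.

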