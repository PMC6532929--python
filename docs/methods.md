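# Methods

This note documents the models, statistics, defaults and numerical choices
implemented in `rdnafoot`, and what the synthetic-data tests do and do not
demonstrate about real sequencing data.

## Coordinates and landmarks

Internally everything is 0-based half-open (BED convention); configuration
files, serialized matrices and axis labels are 1-based inclusive
(genome-browser convention). The shipped landmark file places one 9.1 kb
repeat unit on sacCer3 chromosome XII with the rARS at printed position
458,991, the c-pro initiation site 200 bp upstream, the 25 bp Reb1 site
immediately upstream of c-pro, the 5S gene at the right edge of the 1.25 kb
analysis window, and a 400 bp downstream window starting at the rARS. The
downstream extent is a tunable: displaced pre-RC signal lies within a few
hundred bp right of the origin but has no sharp boundary, so 400 bp is a
choice, not a measurement. Landmark validation enforces ordering
(c-pro < rARS, rARS inside the window, downstream window anchored at the
rARS, everything inside the repeat unit) and rejects violations by name.

The genome-fraction bookkeeping uses the sacCer3 assembly length
(12,157,105 bp including the mitochondrion) with the reference's two
collapsed rDNA copies replaced by the canonical 150-copy array; 150 × 9.1 kb
over that expanded genome gives 10.1%, i.e. 10% at integer precision.

## Fragments

A fragment is the outer span of a properly paired template (leftmost mate
start to start + TLEN), emitted once per template. Defaults keep multi-mapped
reads (`min_mapq = 0`) and do not deduplicate: rDNA repeats are
near-identical, so composite per-repeat footprints *require* pooling repeat
copies, and at rDNA depth identical fragments are expected biologically.
Both behaviours are flags, not assumptions baked in. The default length
gate is 50–250 bp; 50 bp is the smallest protected footprint the library
protocol retains. Multi-unit alignments collapse onto the canonical unit by
reducing the start modulo the 9.1 kb unit length, preserving length.

## The fragment matrix

`build_matrix` bins fragments jointly by position and length over a window,
by default 1 bp × 1 bp over lengths 40–250 (locus-scale windows make full
resolution cheap). Two assignment modes exist because "plot each fragment
at its location" is ambiguous:

* **span** (default): a fragment increments every position bin it overlaps,
  in its length row. This is read-depth semantics and preserves footprint
  edges; all occupancy and displacement statistics use it.
* **midpoint**: one count at the fragment midpoint — the dot-plot
  rendering. Mass conservation (matrix total = contributing fragments) is
  asserted on every midpoint build.

Size classes are closed intervals: factor 50–100 bp, nucleosome 150–200 bp.
Normalization is either per-million-fragments (invariant under dataset
replication; used for cross-sample display) or unit-max (for rendering).
Correctness is pinned by an independent nested-loop per-base oracle, which
the builder must match exactly (both modes) on thousands of random and
simulated fragments.

## Occupancy statistics

`reb1_normalized_occupancy` integrates factor-class coverage over a target
region and divides by the same quantity at the Reb1 site. The Reb1 footprint
is a stable internal standard, and the ratio cancels sequencing depth and
global composition shifts; the class used at the Reb1 site mirrors the
Mcm2-7 class (50–100 bp). The default target region runs from the c-pro
initiation site to the end of the downstream window: it encompasses both
the loading-site and displaced pre-RC signal while *excluding* the Reb1
site itself — including Reb1 would add a constant factor-class term to the
numerator of both strains and attenuate any true difference (with the
shipped landmarks the attenuation would turn a 37% reduction into ~20%).

Strain effects are percent changes of the normalized occupancy, with CIs
propagated from fragment-level bootstrap resampling (resampling counts via
multinomial weights; 200 replicates by default, percentile intervals).
The experiments this models report point estimates only; the bootstrap is
this package's addition. Calibration is tested: across 200 simulation
replicates the nominal 95% CI covers the generating truth 90–99% of the
time.

`chec_rdna_fraction` counts all fragment lengths by default ("all cleavage
fragments"); a length-restricted variant is available by filtering
upstream. Two strains are compared as a fraction ratio with binomial
bootstrap CIs. `nucleosome_occupancies` integrates the nucleosome class in
±73 bp windows (canonical core half-width) around supplied dyads and
normalizes to the first; dyad calling is out of scope — positions come from
configuration or generator truth.

## Displacement statistics

Displacement is measured on span-mode factor-class signal within the Mcm
quantification region, boundary at the rARS. `downstream_fraction` is the
share of class mass at or right of the boundary; `displacement_test`
reports the between-condition difference (delta) with a within-condition
bootstrap CI, the center-of-mass shift (per-fragment exact, equal to the
matrix computation at 1 bp bins), and a two-sided permutation p-value from
shuffling condition labels at the fragment level (999 permutations by
default; the +1 correction keeps p valid). Under a true null the rejection
rate at α = 0.05 is verified to sit within exact binomial bounds over 200
replicates. No mechanistic inference (polymerase kinetics) is attempted.

## S/G1 replication index

The index is the rDNA read fraction in S-phase cells over the same fraction
in G1 cells, computed from count fractions (not per-base depth); a per-bin
depth-ratio profile exists for plotting only. The CI uses a normal
approximation on the log ratio with binomial variances (`1/k − 1/n` per
phase) — accurate for the large counts any realistic input has. The
generative model treats a region replicated in fraction `f` of S-phase
cells as present at `1 + f` copies, giving the closed-form expectation
`(1 + f_rdna) / (1 + f_gen·(1 − s) + f_rdna·s)` for G1 rDNA share `s`,
against which sampled indices are tested.

## The generative chromatin model

`ChromatinModel` is a particle map: Reb1, six nucleosomes at 165 bp spacing
starting at the c-pro initiation site, and the pre-RC adjacent to the rARS.
Key defaults and their rationale:

* **Occupancies** (0.9, 0.3, 0.6, 0.1, 0.1, 0.1) left to right: first
  nucleosome highest, third next, last three averaging ~11% of the first —
  the documented organization of the locus. Reb1 0.9; pre-RC 0.9 in G1,
  0 in G2 (loading is G1-specific).
* **Protection lengths**: nucleosome 160 ± 8 bp (observed nucleosomal
  fragment sizes peak near 160 bp, core particle plus protected linker
  ends); pre-RC 60 ± 10 bp (graphically bounded to the 50–100 bp band;
  60 is a modeling choice); Reb1 70 ± 8 bp over its 25 bp site (Reb1's
  protected fragments run 50–100 bp even though the bound motif is short —
  a 25 bp protection length would fall below the factor class and make the
  normalization undefined).
* **Competition**: the origin nucleosome and the pre-RC are mutually
  exclusive per repeat copy; the nucleosome's effective occupancy is
  `occ_nuc · (1 − occ_prerc_eff)`. Fragment sources are drawn
  proportionally to effective occupancies, so assignment frequencies are
  the testable marginal of the exclusion rule.
* **sir2 scenario**: loading factor 0.63 (a 37% reduction in loaded
  pre-RC) and push probability 0.6; displaced complexes land uniformly in
  a push window 30–350 bp right of the rARS (inside the downstream window,
  with room for the footprint). The true displacement distribution is not
  known; uniform is the maximum-ignorance choice. The terminator scenario
  keeps sir2 loading but sets the push probability to 0.
* **Digestion noise**: independent Gaussian jitter (sd 3 bp) per fragment
  end; background fragments from unprotected DNA at rate 0.05 with
  log-normal lengths (mean 200, sd 100 bp — a partial-digestion smear).
  None of this is experimentally specified; values were chosen once to be
  realistic for MNase data.
* **ChEC mode**: cleavage flanks only MNase-tagged particles; a 250 bp cap
  emulates library-prep amplification of short fragments; non-rDNA
  fragments (share `1 − rdna_share`) form a background pool on a decoy
  chromosome with shorter log-normal lengths (mean 100, sd 40 bp) so the
  cap removes almost nothing from either pool — otherwise the cap would
  distort the rDNA-fraction ratio away from the share ratio it is meant to
  estimate. WT rDNA share 0.10 (matching the array's genomic share at
  uniform efficiency); sir2 share 0.053, encoding a 47% abundance drop.

Truth records store every latent choice (source particle, displacement
flag, pre-jitter center and length) so parameter-recovery tests never
re-derive latent state. All simulators are deterministic given their seed.

## What the synthetic data does not capture

The generator emulates the *statistical* structure of footprinting data,
not its genomics: there is no sequence, no mappability structure, no
MNase sequence bias, no digestion-titration dependence, no chromatin
heterogeneity beyond independent per-fragment sampling, and no
extrachromosomal rDNA circles (fragments are assumed to derive from
chromosomal repeats). Passing recovery tests therefore demonstrates that
the statistics are implemented correctly and are unbiased under the model's
assumptions — not that those assumptions hold in any particular experiment.
Real-data caveats (alignment quality inside a repeat array, copy-number
differences between strains, digestion-depth differences) must be handled
at experiment design and interpretation time.

## Problem sizes and numerics

Default analysis sizes — 50,000 fragments per MNase condition, 100,000 per
ChEC condition, 30,000 per displacement condition, 10⁶ reads per S-seq
phase, 200–999 bootstrap/permutation replicates — were chosen so that
Monte-Carlo error is small against the effects of interest while a full
run of the suite and the acceptance script completes in minutes on one
core. Degenerate inputs fail loudly: zero Reb1 signal, zero class signal,
empty fragment sets, and all-zero matrices raise typed errors rather than
dividing by zero. Ratio bootstraps drop degenerate resamples as NaN;
percentile CIs use the 2.5/97.5 points. Fragment ends are rounded with
banker's rounding (`np.rint`), and `end ≥ start + 1` is enforced after
jitter.
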