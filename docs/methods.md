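# Methods

This note documents the models and estimators implemented in ecdnakit, the
parameters that matter, and what the synthetic-data generators do and do
not emulate.

## Synthetic nuclei and the hub model

`simulate_nuclei` draws, per cell, an ecDNA count N ~ Poisson(`mean_ecdna`)
and a hub count H ~ 1 + Poisson(`hub_rate`), places hub centres uniformly
in a sphere of radius `nucleus_radius` (default 4 µm, the average cell
radius used for the spatial null), assigns each ecDNA to a uniformly chosen
hub at hub centre + N(0, `hub_sigma`²I), and detects each labelled locus on
each ecDNA with probability `detect_prob` at the ecDNA position
+ N(0, `locus_sigma`²I). Points falling outside the sphere are **resampled,
never projected**, so uniform placements remain exactly uniform.

Defaults: `mean_ecdna = 29` (the observed mean oncogene copy number per
cell; the three imaged loci averaged 29/31/22 copies), `hub_rate = 3`,
`hub_sigma = 0.1` µm, `locus_sigma = 0.05` µm, `detect_prob = 0.85`. Hub
count and spread are not measured quantities; the hub-Poisson construction
is a stand-in generative model chosen to produce tunable short-range
clustering, and its parameters are not claimed to match any cell line.

Because detection is an independent thinning of the shared Poisson ecDNA
count, the per-cell spot-count Pearson correlation between two loci equals
`detect_prob` in closed form — the oracle used to test `copy_correlation`.

**CSR mode.** `hub_rate=None` disables hub structure: every ecDNA is placed
i.i.d. uniform in the sphere. This is the calibration condition for the
spatial statistics. The alternative "hub limit" (`hub_rate` ≫ `mean_ecdna`
with `hub_sigma = 0`) is *not* a usable CSR surrogate: ecDNAs that land in
the same hub are exactly co-located, and a handful of zero-distance pairs
dominates the smallest K shell (whose uniform share is ~(Δr/cutoff)³).

**Randomness.** One root seed per config; each generator derives an
independent, platform-stable numpy PCG64 stream via
`SeedSequence(seed, spawn_key=(crc32(component_name),))`, so adding a
component never perturbs another's draws and fixed seeds give
byte-identical outputs.

## Spatial statistics

Distances are 3D Euclidean, computed per cell; same-locus mode excludes
self-pairs (cells with fewer than two spots contribute nothing). The null
matches each cell's per-locus spot counts exactly with uniform points in a
4-µm sphere; one replicate per cell by default (`n_sims` averages
replicates). Observed and null distances are pooled across cells before
medians and the two-tailed Wilcoxon rank-sum test (normal approximation
with tie and continuity correction, via `scipy.stats.mannwhitneyu`);
per-cell values are also available. The regulatory-range fraction uses a
0.3-µm (300-nm) threshold on the observed distances.

**Shell-corrected K.** Per cell, over cross-pair distances d ≤ `cutoff`
(default 2 µm, grid 0.01:0.01:2 µm):
K_i = p_obs(shell_i)/p_unif(shell_i) with
p_unif(shell_i) = ((r_i+Δr)³ − r_i³)/cutoff³. The uniform reference is
**uniform in volume** within the cutoff sphere (pair-distance density
∝ r²), which makes the volume-shell correction exact and gives K = 1 in
expectation under CSR; a uniform-in-*r* reference would not. Cells are
weighted equally (not by pair count), and shells are reported with
across-cell mean and s.e.m.

Two caveats are deliberate properties of the estimator, not bugs:

* **No edge correction** is applied. Within a cutoff ≤ R/4 of the nucleus
  radius the boundary deficit changes the across-shell mean by ≲ +0.05;
  CSR calibration checks are therefore run at cutoff 1 µm in the 4-µm
  sphere, where the residual bias sits well inside the ±0.1 test band.
* **Narrow shells are noisy**: with p_unif ~ (Δr/cutoff)³, a 0.01-µm shell
  near r = 0 has expected pair counts ≪ 1 per study, and the per-cell ratio
  estimator has a heavy upper tail there. Calibration checks use 0.25-µm
  shells; the default fine grid remains appropriate for plotting K(r)
  profiles with many cells.

## CRISPRi screen scoring

Raw counts → CPM per sample → QC: a guide is kept iff CPM ≥ `cpm_min`
(20) in **every** sample (each replicate separately — the stricter reading)
and its specificity score exceeds 0.2 unless it is a non-targeting control
(NTC); targeting elements then need ≥ 2 surviving guides. Replicate CPMs
are averaged per timepoint; ratio = guide CPM / median NTC CPM;
Z standardizes log₂ ratios against the NTC population (mean 0 by
construction). Element score = unweighted mean of its guides' Z; hits at
Z < −1 (negative) or Z > +1 (positive).

Choices made where the convention was open, all switchable in
`FitnessConfig`: NTC aggregation by median (robust); Z reference population
NTC-only (`zscore_population="all"` for the all-guide alternative) — the
NTC reference keeps the null centred when many elements carry true effects;
log₂ before Z (`log_ratios=False` for raw ratios) because ratios are
right-skewed. No pseudocount is needed after filtering (CPM ≥ 20 > 0).

Two interactions worth knowing:

* The abundance filter couples timepoints: a guide with a strong negative
  growth effect can fall below 20 CPM at late timepoints and be excluded
  outright. In the planted-effect recovery experiments (−0.3 log₂/day) the
  screens therefore run through day 14, the endpoint being scored; a
  day-30 sample would filter out exactly the guides carrying the signal.
* Scoring has no cross-element talk (the NTC reference ignores targeting
  guides), but CPM normalization couples sample totals, so removing guides
  from the *raw* table can flip borderline QC decisions elsewhere. The
  no-cross-talk invariant holds exactly downstream of QC.

## Stripe calling

For each trans bin (a bin on a chromosome carrying no amplicon bin):
coverage = share of amplicon bins contacted with ≥ `min_contact` counts;
enrichment = (mean amplicon contact + 1)/(chromosome background + 1), where
the background is the **median** mean-amplicon-contact over that
chromosome's bins — median rather than mean so the stripes themselves do
not inflate the background — computed over bins with nonzero contact, so
results are invariant to whether all-zero bins are stored. Bins passing
both thresholds merge along runs of adjacent bins into one record anchored
at the maximal-coverage bin (ties toward the lower coordinate).

Defaults `min_contact=1`, `min_coverage_fraction=0.5`, `min_enrichment=3`
were calibrated on the planted-truth synthetic suite (the original
annotation of real data was manual, so no numeric thresholds exist to
inherit); all three are CLI-exposed. Coordinates are 0-based half-open
throughout; repeat classes come from the annotation label prefix before
"/" (RepeatMasker convention).

## Toy genome and contact generator

Repeat intervals are placed left-to-right with exponential gaps, the class
of each interval chosen by largest remaining deficit against its target
genome fraction; classes are mutually disjoint and each stops within one
interval of its target (±2 % guaranteed at the defaults). The contact map
covers amplicon-anchored pairs only — Poisson(background) per
amplicon–trans pair, Poisson(stripe rate) where the trans bin is a planted
EIE, Poisson(cis rate) inside the amplicon block — because those rows are
all the trans-stripe caller consumes; a full genome×genome background would
add quadratic cost and no information. Long-read tables give each planted
EIE `n_reads_per_eie` reads, a configurable fraction of which carry a
second block on the amplicon (the ecDNA-linking signal).

## Probe design

Candidates are every `tiling_step` window of `probe_len` (40 nt). GC is
counted directly; Tm uses unified nearest-neighbour thermodynamics
(Biopython `Tm_NN`, Allawi & SantaLucia parameter set) at 50 mM Na⁺ and
250 nM oligo — the original design software's exact model and salt are
unstated, so the parameter set is pinned in `ProbeConfig.tm_model` for
reproducibility; the wide 65–90 °C band makes pass/fail largely insensitive
to this choice. Homology screening checks all k-mers of length exactly
`unique_k` (17) against the genome outside the target region and
`repeat_k` (14) against a repeat library, both strands; any shared
substring of length ≥ k contains a shared k-mer, so exact-k checking
implements the "k or longer" rule. "Outside the target region" masks the
region's footprint (windows overlapping it contribute nothing), i.e.
uniqueness is screened per region rather than against the whole target
set. All passing candidates are emitted; a greedy leftmost-first
non-overlapping selection is available separately since the original
selection rule is unstated. Ambiguity codes flag a candidate rather than
raising.

## Problem sizes and test design

The simulation-based checks run at: 4000 cells for CSR K calibration
(across-shell mean of across-cell mean K, 0.25-µm shells, cutoff 1 µm);
400 cells for clustering detection; 500 draws for rank-sum p uniformity
and null-screen Z calibration (12 elements × 5 guides + 125 NTCs each);
100 seeded screens at depth 10⁷ for effect recovery; and a 1.4-Mb toy
genome (200 amplicon bins × 1000 trans bins) for stripe recovery. These
sizes put Monte-Carlo error comfortably inside each test band while keeping
the whole suite fast on one CPU.

## What passing tests do and do not show

The generators reproduce the statistical *structure* each stage assumes —
matched-count nulls, NTC-anchored count matrices, planted stripes at known
bins — not the messiness of real data: no segmentation or spot-fitting
errors, no chromatic offsets, no uneven Hi-C coverage or restriction-site
bias, no guide-specific efficacy variation, no repeat-family sequence
structure (repeat intervals label random sequence; probe repeat screening
against a real RepBase-style library is supported but not emulated).
Passing therefore demonstrates correctness of the estimators and callers
under their stated models, and calibrated behaviour under the null — not
performance on any particular cell line. Hub membership of ecDNA has no
measured generative model; conclusions about absolute hub statistics
should not be read off the simulator.
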