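# ecdnakit

Analysis tooling for **ecDNA-interacting elements (EIEs)** — small (~1-kb),
typically retrotransposon-bearing genomic elements that become physically
inserted on extrachromosomal DNA (ecDNA) in cancer cells. Because ecDNA is
present at tens of copies per nucleus and each copy juxtaposes the element
with a different part of the amplicon, an inserted element contacts the
*entire* megabase-scale amplified region in a Hi-C map — a trans "stripe" —
and its FISH signal clusters with the oncogene locus in 3D. The package is
aimed at researchers analysing ecDNA amplicon biology who need the
computational half of that workflow: stripe calling, repeat-content and
long-read co-amplification scoring, 3D spatial statistics, growth-screen
fitness scoring, and oligo probe design.

## What it computes

* **`eie_discovery`** — calls EIE candidates as trans stripes from a binned
  contact matrix. For a trans bin *b* against amplicon bins *a*:
  coverage(b) = |{a : C[a,b] ≥ m}| / n_amp and
  enrichment(b) = (mean_a C[a,b] + 1) / (median chromosome background + 1);
  passing bins merge into anchored records. Also: per-element overlap
  fractions with LINE/SINE/LTR annotations (merged, per-base), the
  genome-wide class fractions they are compared against, and counts of long
  reads whose alignment blocks link an element to an ecDNA cycle interval,
  reported as log10(1 + x).
* **`spatial_stats`** — per-cell 3D distance statistics for labelled FISH
  spots: shortest cross-locus distances, a matched random-points-in-a-sphere
  null (r = 4 µm), two-tailed Wilcoxon rank-sum comparison, the fraction of
  distances within the ≤300-nm regulatory range, per-cell copy-number
  correlation, and a shell-corrected Ripley's-K statistic
  K_i = p_obs(shell_i) / p_unif(shell_i) with
  p_unif(shell_i) = ((r_i+Δr)³ − r_i³)/cutoff³, so K ≈ 1 under complete
  spatial randomness and K > 1 indicates clustering at that scale.
* **`crispri_fitness`** — CRISPRi growth-screen scoring: CPM normalization,
  QC (CPM ≥ 20 in every sample, specificity > 0.2 with NTCs exempt, ≥ 2
  guides per element), per-guide ratio to the NTC median,
  Z = (log₂ratio − μ_NTC)/σ_NTC, element scores as unweighted guide means,
  and hit calls at Z < −1 / Z > +1.
* **`probe_design`** — 40-mer tiling FISH/ORCA probes filtered on GC
  (20–80 %), nearest-neighbour Tm (65–90 °C), genome uniqueness (no shared
  17-mer outside the target, both strands) and repeat homology (no shared
  14-mer with a repeat library), plus per-region 20-mer readout barcodes.
* **`synthetic_data`** — seeded generators for every input above: spherical
  nuclei with hub-clustered ecDNA and per-locus detection, NTC-anchored
  negative-binomial guide-count screens with planted growth effects, and toy
  genomes with repeat classes, an amplicon, planted stripes and linking
  long reads.

## Worked example

```python
from ecdnakit import synthetic_data as sd, spatial_stats as ss

cfg = sd.NucleusSimConfig(n_cells=400, hub_sigma=0.1, seed=1)
spots = sd.simulate_nuclei(cfg)

obs = ss.shortest_cross_distances(spots, "MYC", "EIE14")["distance_um"]
null_spots = ss.sphere_null(spots, ["MYC", "EIE14"], ss.NullConfig(seed=1))
null = ss.shortest_cross_distances(null_spots, "MYC", "EIE14")["distance_um"]
s = ss.compare_obs_exp(obs, null)
print(f"observed median: {s.median_observed:.3f} um")
print(f"null median:     {s.median_null:.3f} um")
print(f"rank-sum p:      {s.pvalue:.3g}")
print(f"within 300 nm:   {100*s.fraction_within_threshold:.1f}%")
```

prints

```
observed median: 0.092 um
null median:     1.306 um
rank-sum p:      0
within 300 nm:   99.4%
```

Each MYC spot's nearest EIE14 spot sits at ~92 nm (the loci ride the same
ecDNA molecules, scattered by the 0.1-µm hub and locus spreads), whereas
matched random points in the same 4-µm sphere sit ~1.3 µm apart; the
rank-sum p-value underflows to 0, i.e. far below any significance level,
and nearly all observed pairs fall within the 300-nm regulatory range.

The same stages are exposed on the command line (`ecdnakit simulate`,
`call-eies`, `repeat-overlap`, `ecdna-support`, `spatial`, `fitness`,
`probes`, `convert`) and `ecdnakit demo --out DIR` chains them end to end
on synthetic data; every run writes a JSON manifest with the config hash,
seed and input checksums.

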