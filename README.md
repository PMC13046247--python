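# calchip

Spike-in calibrated meiotic ChIP-seq analysis: calibration, coverage tracks,
local-Poisson peak calling, feature-overlap classification, and the
comparative statistics used to characterise where a meiotic protein binds —
plus a seeded synthetic-data generator that emulates the experiment's
statistical structure so the whole pipeline is testable without sequencing
data.

## The problem

During budding-yeast meiosis, proteins of the recombination machinery bind
chromatin at DSB hotspots (sites of Spo11-catalysed double-strand breaks),
chromosome-axis sites (Red1 domains) and centromeres. Quantitative ChIP-seq
comparisons between time points, strains and mutants require *calibration*:
cells of a related species (e.g. *S. mikatae*) are mixed with the target
cells at a fixed 1:10 ratio before immunoprecipitation, so that reads mapping
uniquely to the spike-in genome measure the nonspecific pulldown and place
every library on a common scale. `calchip` implements this analysis chain for
users who work downstream of alignment: its inputs are mapped-read records
(position + mapping-uniqueness status), feature maps (BED), SNP positions and
tetrad crossover tables.

## The model

**Calibration.** For each library, with `T` uniquely mapped target-genome
reads, `S` uniquely mapped spike-genome reads and mean raw coverage `c̄`
(reads per 10-bp bin),

    SF1 = T / S            # IP yield per unit of nonspecific background
    SF2 = SF1 / c̄          # additionally removes sequencing depth

The calibrated signal in bin *b* is `chip[b]·SF2_chip − untagged[b]·SF2_unt`
(negative values retained), averaged across replicates, then smoothed with a
Gaussian Nadaraya–Watson kernel whose quartiles sit at ±0.25× the bandwidth
(1 kb default) — the convention of R's `ksmooth`.

**Peak calling.** A self-contained local-Poisson caller on raw 10-bp binned
counts: per bin, λ_local = depth-scaled max of the control mean over 1/5/10-kb
windows and the genome-wide mean; bin p = P(X ≥ obs | Poisson(λ_local));
bins with p ≤ 10⁻⁵ are merged across gaps ≤ 100 bp and extended over
contiguous enriched bins; q-values by Benjamini–Hochberg.

**Classification and statistics.** Peaks are classified Venn-style by ≥ 1 bp
overlap with Spo11/Red1/centromere maps ("Nil" = none). Comparative analyses:
chromosome-level binding density in RPM/kb (with rDNA-style exclusions) vs
chromosome size by Pearson correlation; hotspot-strength comparison of two
proteins' specific hotspots by Wilcoxon rank-sum (exact enumeration for small
tie-free samples, tie- and continuity-corrected normal approximation
otherwise — implemented in-package and tested against full enumeration); SNP
density inside peaks vs genome background; crossover-site co-occupancy; and
input/coldspot/untagged-normalized qPCR fold enrichment.

## Worked example

`examples/` contains one short script per capability. For instance,
`python examples/03_call_and_annotate_peaks.py` simulates a 1.2-Mb genome
with 120 hotspots, 40 axis sites, 4 centromeres and 25 coldspots, two ChIP
replicates and an untagged control at a 1:10 spike-in mixture, then calls
and classifies peaks:

```
called 164 peaks; median width 630 bp, mean 573 bp
Venn classification (each peak counted once):
  Spo11                 120  (73.2%)
  Red1                   40  (24.4%)
  Centromere              4  (2.4%)

metaprofile (+/-0.5 kb): hotspot centre signal 15.54 reads/bin vs coldspot 1.94 (8.0x)
```

Every planted hotspot, axis site and centromere is recovered as a labelled
peak, and the ±0.5-kb metaprofile shows ~8-fold hotspot-over-coldspot signal,
matching the planted enrichment. `examples/04_comparative_statistics.py`
simulates two proteins with opposite coupling between occupancy and hotspot
strength (A ∝ strength⁻⁰·⁵, B ∝ strength⁺⁰·⁵) and runs the comparisons:

```
hotspot binding classes: {'both': 119, 'A_only': 43, 'B_only': 38}
median strength A-only 28 vs B-only 653; rank-sum p = 1.10e-14
chromosome size vs RPM/kb: Pearson r = -0.83, p = 8.2e-05
SNP density: peaks mean 4.04/kb vs genome mean 3.94/kb (rank-sum p = 0.59)
```

A-specific hotspots are two orders of magnitude weaker than B-specific ones
(the planted direction), chromosome-level density is negatively correlated
with chromosome size when hotspot counts per chromosome are equal, and SNP
density at SNP-independent peaks is indistinguishable from the genome
background.

The full staged pipeline (simulate → calibrate → callpeaks → annotate →
stats) runs from a YAML config, from Python (`examples/05_full_pipeline.py`)
or from the shell:

```
calchip run-all --config config.yaml --seed 5
```

All reports are standard text formats (BED, bedGraph, TSV) with a provenance
header; reruns with the same config and seed are byte-identical.

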