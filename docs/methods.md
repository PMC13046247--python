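# Methods

This note documents the models, conventions and design choices behind
`calchip`, in the package's own terms. It states no empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Coordinates and data model

All coordinates are 0-based, half-open (BED semantics). Printed genomics
coordinates (1-based inclusive, e.g. the rDNA repeat locus chrXII
451418–489465) are converted on ingestion (`one_based=True` readers); the
rDNA exclusion is stored as `(chrXII, 451417, 489465)`.

The pipeline starts downstream of read alignment. A `MappedReadSet` holds
per-read records of (chromosome, 5′ position, strand, status), where status
∈ {`target_unique`, `spike_unique`, `ambiguous`, `unmapped`}. Spike-unique
and unmapped reads carry no target coordinate. Only `target_unique` reads
enter coverage tracks; `spike_unique` counts enter only the scaling factors.

## Spike-in calibration

The experiment mixes spike-in cells of a related species with target cells
at 1:10 before immunoprecipitation. The spike genome carries no tagged
protein, so its reads measure nonspecific pulldown. Per library:

* `SF1 = T / S` — uniquely mapped target reads over uniquely mapped spike
  reads. Depth-independent; grows linearly with specific occupancy.
* `SF2 = SF1 / c̄` — SF1 divided by the library's genome-wide mean raw reads
  per bin, so that multiplying the binned counts by SF2 removes the
  library's own sequencing depth.

Calibrated track: `chip·SF2_chip − untagged·SF2_unt` per 10-bp bin,
replicate-averaged after calibration, smoothed last. Two consequences, both
enforced by tests: (i) calibrated genome-wide sums are invariant to
sequencing depth; (ii) the untagged subtraction removes the nonspecific
component exactly in expectation, so calibrated sums scale linearly with
true specific occupancy.

On the "coverage" divisor: the protocol's verbal description of SF2 is
ambiguous about whose coverage divides SF1. Dividing every library's SF1 by
the *untagged* library's coverage leaves each ChIP library's own depth in
its calibrated track, which defeats the purpose of spike-in calibration
(3× more sequencing would triple the "calibrated" signal). `calchip`
therefore divides each library's SF1 by that library's own mean per-bin
coverage — equivalently, depth-normalising each track before applying SF1.
The untagged-coverage constant would anyway cancel in within-sample
comparisons but not across samples; the own-coverage reading restores depth
invariance everywhere.

Negative calibrated values are retained. Clamping at zero would bias
genome-wide means; peak calling does not consume calibrated tracks (below),
so negativity affects only visualisation and summary statistics.

## Smoothing

Genome-wide smoothing is a Nadaraya–Watson estimate at every bin centre with
a Gaussian kernel whose quartiles sit at ±0.25× the bandwidth
(sd = 0.25·bandwidth / 0.6745), the documented convention of the classical
normal-kernel smoother, with weights renormalised over available bins at
chromosome edges — constant tracks are exact fixed points. The default
bandwidth is 1 kb. The implementation truncates the kernel at 8 sd
(excluded mass ~1e−15) and evaluates the last, possibly partial, bin at its
true centre; tests hold it to 1e−9 against full direct summation, and a
cross-check against R's `ksmooth` confirms the bandwidth convention
(agreement there is ~1e−5 because R truncates its kernel at ~4 sd).

## Peak calling

Peaks are called from raw replicate-pooled 10-bp counts with the untagged
library as control — the Poisson model needs counts, not calibrated values.
Before binning, each read's 5′ position is shifted 3′-ward by half the mean
fragment length (175 bp default). Without the shift, plus- and minus-strand
reads pile up on opposite flanks of a binding site (the 5′ ends sit a
half-fragment away from the fragment midpoint), splitting each site into two
half-height shoulders; the shift reunites them over the fragment midpoints.
This is the classical read-shift of model-based callers. `bin_reads` itself
defaults to no shift (binning raw 5′ positions); the pipeline's peak-calling
stage applies 175 bp.

Scoring: per bin, λ_local is the maximum of the depth-scaled control mean
over centred 1/5/10-kb windows and the genome-wide mean (with no control, a
uniform background at the ChIP mean). The bin p-value is the Poisson upper
tail P(X ≥ obs | λ_local); q-values are Benjamini–Hochberg over all bins.
Bins with p ≤ p_max (default 10⁻⁵, the retention rule of the original
analysis) are merged across gaps ≤ merge_gap (100 bp); each merged core is
extended outward over contiguous bins whose count exceeds λ_local, so the
reported span delimits the whole enriched region; candidate spans that meet
after extension are merged into one peak. Peaks narrower than min_width
(50 bp) are dropped. Peak p/q = minimum over core bins; summit = maximum
count bin in the span.

These defaults are not expected to reproduce any particular published peak
count from real data exactly — the original analysis used an external caller
whose exact options are not part of this package's contract. The caller's
*operating characteristics* are the tested contract: false positives on null
data within 2× the nominal `bins × p_max` expectation, and ≥95% recovery
(with span containment) of 10×/500-bp planted regions at ≥2 reads/bin
background.

## Annotation and overlap

A peak is labelled with every feature class (Spo11 = DSB hotspot,
Red1 = axis, Centromere) it overlaps by ≥ 1 bp; the label is the exact
combination, "Nil" if none, so category counts partition the peak set
Venn-style. Overlap queries run on the sorted union of each class's
intervals via binary search; an all-pairs brute-force oracle in the test
suite checks equality on random instances. A peak overlapping two hotspots
counts the hotspot class once; a peak spanning two hotspots marks both
hotspots bound in hotspot-level classification.

## Comparative statistics

* **Chromosome-size density** — per-chromosome reads per million mapped per
  kb (RPM/kb); reads inside layout exclusions (rDNA) are discarded and the
  excluded bp removed from the usable length; Pearson correlation (two-sided
  t-test, n−2 df) against chromosome size, optionally excluding the three
  smallest chromosomes.
* **Wilcoxon rank-sum** — implemented in-package because every headline
  comparison routes through it. Exact path: the null rank-sum distribution
  is built by dynamic programming (equivalent to full enumeration) when
  n₁+n₂ ≤ 12 and there are no ties; two-sided p = 2·min(CDF, SF) capped at
  1. Otherwise a normal approximation with tie correction and a 0.5
  continuity correction toward the mean. Tests check the exact path against
  literal enumeration of all rank assignments for every pattern with
  n₁+n₂ ≤ 10, the approximation within |Δp| ≤ 0.01 of exact at 12 vs 12,
  agreement with an independent library implementation, and a null
  rejection rate within [0.03, 0.07] at α = 0.05.
* **Hotspot binding classification** — hotspots are partitioned into
  both/A-only/B-only/neither by ≥ 1 bp overlap with two proteins' peak
  sets; A-only vs B-only Spo11-oligo strengths are compared by rank-sum.
  The comparison is reported as undefined if either specific class is
  empty.
* **SNP density** — per-peak SNPs/kb. Genome-wide mean and median are
  reported over 1-kb non-overlapping tiles (full tiles only; tiles touching
  exclusions dropped), matching the per-kb unit of the usual summary
  numbers. The rank-sum comparison, however, uses *width-matched* random
  background windows (widths cycled from the peak widths themselves, random
  positions avoiding exclusions, seeded). Rationale: the SNP count of a
  sub-kilobase window divided by its width is a mean-preserving spread of
  the 1-kb tile density, so ranking ~0.6-kb peaks directly against 1-kb
  tiles is median-biased low even when SNPs are uniform (theoretical
  AUC ≈ 0.48–0.49 at 4 SNPs/kb), producing spurious "depletion"; the
  width-matched null is exact by construction.
* **Crossover co-occupancy** — a crossover site is its midpoint ± half the
  site window (2 kb default; tetrad-derived crossover resolution is not
  sharper than this, and the parameter is exposed); sites are classified by
  ≥ 1 bp overlap with each protein's peaks into both/A-only/B-only/neither,
  fractions summing to 1.
* **qPCR fold enrichment** — consumes standard-curve quantities (not raw
  Ct): ratio = IP/input per locus and strain;
  FE(l) = [ratio(l,tag)/ratio(cold,tag)] / [ratio(l,untag)/ratio(cold,untag)].
  The coldspot's FE is exactly 1 by construction.
* **Centromere distance** — |feature midpoint − centromere midpoint| per
  chromosome (exactly one centromere record required), groups compared by
  rank-sum.

Display-only transforms (×2 on 100-bp SNP counts, ÷n_tetrads·×200 on
crossover counts) exist solely as bedGraph writer options and never enter
statistics.

## Synthetic-data generator

The generator emulates, at mapped-coordinate level, the statistical
structure the analysis assumes. What it models: a 1:10 spike:target mixture
(each library's spike-read fraction can be derived from the physical mixture,
shrinking as specific occupancy grows); truncated-normal sonication
fragments (mean 350 bp, sd 25, truncated to [100, 1000] by rejection
sampling); read 5′ ends placed a half-fragment from feature-centred or
uniform-background fragment midpoints, strand Bernoulli(½); mapping
ambiguity and unmapped reads as labelled statuses (5% and 2% defaults);
feature-class enrichment multipliers over a uniform background
(hotspot 8×, axis 6×, centromere 6×, coldspot 1× defaults — a coldspot is
background by definition); hotspot multipliers coupled to Spo11-oligo-proxy
strength via `strength_coupling` (normalised by the geometric-mean strength
so coupling reallocates signal across hotspots without changing the class
total; the true biological coupling is not asserted — it is a free
parameter) and to local SNP density via `snp_coupling`; heavy-tailed
hotspot strengths (log-normal, μ=5, σ=1.2); hotspot/coldspot widths of
600 bp and axis widths of 400 bp, chosen so called peaks come out at the
~0.6-kb scale reported for this protein class; features of all classes
mutually non-overlapping with a minimum gap, centromeres one per chromosome;
Poisson-planted SNPs at 4/kb (constant or per-region); tetrad crossovers
(66 tetrads default, ~90 crossovers per tetrad scaled to genome size)
placed at hotspots with probability ∝ strength^weighting plus a uniform
component.

What it does **not** model: sequences, base-calling error, aligner
behaviour beyond status labels, duplicate reads, GC or chromatin-state
coverage biases, fragment-length dependence on locus, or correlated
replicate noise. Passing tests therefore demonstrate that the *computation*
recovers planted structure under the stated statistical assumptions, not
that those assumptions exhaust real ChIP-seq data.

Ground truth (expected and realized reads per mixture component and status,
per sample) is retained in a sidecar table; recovery tests check realized
counts within 4σ of expectations.

## Determinism and problem sizes

All randomness flows from `numpy.random.default_rng` seeded explicitly;
per-stage and per-sample seeds are derived by stable hashing (CRC32 of the
stage tag mixed with the global seed, kept below 2³¹). Pipeline reports
carry a provenance header (version, config hash over analysis-relevant
fields, seed) and are byte-identical across reruns.

Validation experiments run at desk scale by choice: a 1.2-Mb
four-chromosome genome with ~170 features/Mb and 2–2.5×10⁵ reads per
library for the recovery experiments; a 10-Mb genome for the peak-caller
null (where the false-positive bound is the point); and the 16 real yeast
chromosome sizes for the size–density regression. The calibration-recovery
experiment uses a strong-IP model (hotspot 40×, axis 15×) so that the
specific signal mass is comparable to background — with a weak IP the
spike-read Poisson noise (S ≈ 10⁴ at 2×10⁵ reads) would dominate the
subtracted sums and no calibration scheme could meet a 5% agreement bound
at that depth.

## Known limitations

* The caller has no fragment-model estimation; the read shift is a fixed
  parameter, appropriate when the fragment distribution is known (as in the
  generator) but approximate for real libraries.
* Exact Wilcoxon is limited to tie-free samples (midranks + normal
  approximation otherwise); no permutation fallback for small tied samples.
* `density_by_chromosome` on a binned track excludes only bins fully inside
  an exclusion interval; read-level input is exact.
* qPCR standard-curve conversion from Ct values is upstream of this
  package.
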