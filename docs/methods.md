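# Methods

This note documents the models, defaults and numerical choices behind
`spikequant`, and what the simulation-backed validation does and does not
establish about real data.

## The spike-in quantitation model

A synthetic spike for an amplicon family is a chimeric DNA molecule:
forward primer binding site (PBS) + random stuffer + reverse complement of
the reverse PBS, delivered on a larger construct (typically a plasmid).
Because the spike carries the same PBSs, and a stuffer matched in length
and GC content to the natural amplicon, it is assumed to be isolated,
amplified and sequenced with the same efficiency as environmental
templates. Under that proportionality assumption, sequencing is modelled
as a multinomial draw over molecule pools, giving two identities the whole
package rests on:

* expected spike share of the output: `SR1000 = 1000·NS/(NS+ENV)`, with
  NS spike copies and ENV environmental gene copies per unit sample;
* the ratio estimator: `ENV̂ = NS·m/s` for m microbial-origin and s
  synthetic-origin reads. "Microbial-origin" excludes both synthetic and
  unassigned reads; unassigned reads are excluded from numerator and
  denominator alike.

The estimator is the ratio of two multinomial counts scaled by a known
constant; it is consistent as depth grows and its relative sampling error
at depth N and spike share p is approximately `sqrt(1/(N·p(1−p)))`, which
is the quantitative reason for the dose window below.

### Dose planning

The dosing rule is applied on the read-fraction scale: a dose is accepted
when its expected SR1000 lies strictly inside (200, 800), equivalently a
spike molecule share in (0.2, 0.8). The literature states the same rule
both this way and as "spike at >20% of the expected environmental
abundance"; the two differ algebraically (20% of total vs 20% of ENV), and
the read-fraction form is primary here because the window selections it
produces match the published level choices. Both predicates are reported
(`in_window`, `dose_ok`). Window boundaries are strict by default and
configurable, since sources disagree on inclusivity at exactly 200/800.

When planning against a pilot estimate, the environmental abundance is the
all-level mean of the pilot run by default; restricting the average to
in-window levels is a caller decision (pass that mean instead).

## Spike design

* Amplicon length targets default to 253 bp (16S V4), 211 bp (18S) and
  272 bp (ITS) — the centres of the default read-length windows
  (252–254, 210–212, 250–300) and the modal ITS product size. The ITS
  figure of 272 is read as the full amplicon length; callers who prefer a
  272 bp stuffer plus primers can set the target accordingly.
* Stuffer GC targets 0.50 ± 0.02. The generator draws the GC count
  uniformly from the integer band allowed by the tolerance and shuffles
  bases, so composition holds by construction; motif and homopolymer
  constraints are enforced by rejection with a 10,000-attempt budget
  (exhaustion signals over-constrained inputs and raises).
* Stuffers are screened against every PBS in the experiment, both
  orientations, at Hamming distance ≤ 2 over sliding windows; homopolymer
  runs are capped at 8 bp to avoid synthesis and sequencing artefacts.
  Both stringencies are configurable and deliberately conservative; no
  database (BLAST-style) screening is attempted.
* `in_silico_pcr` treats IUPAC codes on either side as base sets (mismatch
  = disjoint sets) and reports every forward/reverse-site pairing within a
  5 kb product cap, so a correctly designed spike yields exactly one
  product with its own pair and none with the other families'.
* The default construct length (2504 bp) is the plasmid-plus-insert size
  consistent with the measured stock calibrations near 3.7e8 copies/ng;
  it only matters for first-principles mass conversion.

## Mass/copy conversions

Defaults: 650 Da per double-stranded base pair, 1 Da = 1.66054e-24 g.
A measured stock calibration (copies/ng) always takes precedence over the
length-derived conversion because dose tables are internally calibrated to
the stock values. Reporting rounds to 2 significant figures (the
convention of published dose tables); full precision is kept internally.
Two published-arithmetic caveats are implemented as stated and documented
rather than "fixed": the genome-based copies/ng formula with a 4e9 Da
genome and 3 operons gives ≈4.52e5/ng, not the 377,155 sometimes quoted
(that constant is not recoverable with standard unit conversions); and the
culture-control recovery recomputed from the three rounded per-level
estimates is 99.4%, one decimal off the published 99.3% (full-precision
inputs unavailable).

## Read processing

Reads are merged single-end amplicons; paired-end merging is an upstream
requirement, not re-implemented. Layout: forward barcode + 12 bp pad +
amplicon + revcomp(pad) + revcomp(reverse barcode). Defaults: barcode
matching exact (0 mismatches), primer matching ≤ 1 mismatch,
classification ≤ 2 substitutions. Length windows apply to the
PBS-inclusive amplicon, because instrument read-length filters see the
sequenced product, not the trimmed insert.

Classification is nearest-neighbour Hamming distance against spike
stuffers plus labelled reference inserts — deliberately not a denoiser.
The reference set plays the role a denoised zOTU table plays in a real
study; real studies can skip FASTA classification entirely and supply a
count table TSV. Ties break to the lexicographically first label,
ambiguous multi-family primer matches to fewest total mismatches then
lexicographic family name; both rules are deterministic. Reads are
conserved at every stage (every input read ends in exactly one count cell
or one unassigned-report row), and the per-read pipeline is memoised on
the raw sequence, so error-free runs cost one classification per unique
read. Taxonomic rank is whatever the reference lineages encode; the
package imposes none. Singleton categories are dropped only on request
(`drop_singletons`), never silently.

## QC filters

* Low depth: total reads < 40% of the (group, family) mean, the sample
  itself included in the mean (a single-sample group is thus never
  flagged); a leave-one-out variant is available.
* Spike ratio: synthetic/microbial ≥ 2.5× the group mean ratio; zero
  microbial reads flags unconditionally.
* Magnitude outlier: "an order of magnitude off" is formalised as
  |log10(x) − median(log10 of the other replicates)| ≥ 1; no published
  formula exists, and the median makes the reference robust at n = 3.
* Window: observed SR1000 strictly inside (200, 800).
* Contamination is a manifest annotation passed through, never detected.

Per-1000 normalisation is computed on the post-length-filter read universe
(the universe every other analysis uses); filters are independent and
idempotent, and removing flagged samples never rescales survivors.

## Statistics

Per-taxon comparisons use Welch's t-test by default (Student's by flag —
sources typically say only "t test"), Bonferroni correction over the
testable taxa (`min(1, p·m)`), and star tiers at adjusted p < 0.05 / 0.01
/ 0.001. Taxa with zero variance in both groups and equal means are
reported untestable rather than raising, so batch runs survive degenerate
columns; zero variance with unequal means reports p = 0. Tests run on
per-sample values, not level means.

Bray-Curtis follows the standard community pre-treatment: per-sample
standardisation to proportions, square-root transform, then
`Σ|x−y|/Σ(x+y)`. Standardisation makes the distance invariant to
per-sample rescaling, which is exactly why removing a constant synthetic
share upstream cannot distort the ordination. All-zero samples have no
defined distance and are excluded with a report. Ordination defaults to
classical (metric) MDS via principal coordinates for determinism and exact
Euclidean round-trips; non-metric MDS is available and seed-controlled.

## The simulator

The generator emulates the reference study conditions: lognormal taxon
abundances (natural-log SD 1.5, a realistic soil-like skew; 0 gives equal
abundances) scaled to family totals of 1e9 (16S), 1e8 (18S) and 1e7 (ITS)
copies per gram; spike doses taken from the default eight-level table via
the planner; optional isolation loss applied to the taxon pool and — only
for spike-before-isolation samples — the spike pool, reproducing the
cancellation contrast; multinomial sequencing at configurable depth; and
optional FASTQ emission with realised (ambiguity-free) primer sites,
dual barcodes, pads, fixed quality 'I', i.i.d. substitution errors
(default 0 for oracle tests) and optional planted off-length reads. PCR
efficiency multipliers default to 1.0 — length/GC matching of the spikes
is the design rationale for that neutral default.

What passing simulation tests shows: the arithmetic, bookkeeping and
statistical machinery are correct under the stated sampling model. What it
does not show: robustness to real-world violations of proportionality —
PCR bias between spike and environmental templates, chimera formation,
soil-dependent spike retention or degradation, DNA isolation bias, or
denoising artefacts. Those must be controlled experimentally (dose
gradients, replication) rather than in software.

## Validation problem sizes and tolerances

The bundled acceptance checks use problem sizes chosen to make sampling
error comfortably smaller than the asserted tolerances: estimator recovery
at depth 1e5 with 100 independent communities per dose level (median
relative error < 2% at the top level, RMSE < 5% per in-window level); the
exact round trip on 3 families × 6 samples × 20,000 error-free reads; the
sign-flip scenario at n = 10 per group, depth 1e5 and 5% replicate CV; and
a 500-replicate Gaussian null for the familywise error of the Bonferroni
comparison. The null check asserts consistency with the nominal 0.05 level
under a one-sided 95% Monte Carlo bound (0.05 + 1.645·SE ≈ 0.066 at 500
reps), since the observed rate of a correctly calibrated procedure
fluctuates around 0.05 by ±0.01 at that replicate count.

## Known limitations

* Gene copies are never converted to cell counts: rRNA operon copy number
  varies across taxa, so copies per gram is the honest unit.
* Hamming-based classification requires equal-length comparison; indel
  errors make reads unassigned rather than misassigned.
* The qPCR helper assumes a single amplification efficiency per run
  (default 2.0) rather than per-assay calibration curves.
* The dose table's published picogram values are rounded; regenerated
  copies agree with printed values at 2 significant figures only for
  mutually consistent cells, and the package treats the stock calibration
  (copies/ng) as the source of truth.
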