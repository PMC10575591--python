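# Methods

This note records the models, conventions and numerical choices behind
`readthru`, and what the synthetic-data validation does and does not
demonstrate.

## Coordinates and coverage

All internal coordinates are 0-based half-open; GTF (1-based closed) is
converted on ingestion and regenerated on output, so GTF → internal → GTF
is the identity. The TSS of a `+` gene is `start`, of a `-` gene `end − 1`;
the TES is the opposite terminus, and "downstream" always means the
direction of transcription.

Coverage is binned with **midpoint attribution**: each read increments the
single bin containing its midpoint. This conserves read counts exactly
(bin sums equal attributed reads), which makes CPM arithmetic and the
round-trip tests exact; per-base fractional attribution is available behind
a flag for smoother tracks. CPM of a bin is `count × 10⁶ / library_size ×
scale_factor` with the library size being the number of target-genome
reads. Region sums weight boundary bins by overlap fraction.

Spike-in reads are recognized by chromosome-name prefix in a merged
coordinate space, which sidesteps dual-genome alignment. Two normalizations
are distinguished on purpose:

- **Cross-sample scale factors** (`chiprx_scale_factor`): factor_i =
  min_j(spike_j) / spike_i, inversely proportional to spike-in counts with
  the constant fixed so the smallest-spike sample gets factor 1 and all
  factors lie in (0, 1].
- **Per-sample spike-in CPM** (`spikein_cpm_track`): target coverage per
  million *spike-in* reads. Because numerator and denominator scale
  together, this track is invariant to multiplying one sample's material
  (target and spike-in reads alike) by any constant — the property the
  quantitative-normalization test asserts to machine precision. Per-target
  CPM with an external factor does not have this property and is not used
  for that purpose.

## Synthetic-data model

The generator produces the observable consequences of elongation
inhibition, not the mechanism. Each condition is a set of effect dials
(`ConditionEffect`):

| dial | meaning | defaults (DMSO / JQ1 / SN38 / SN38+JQ1) |
|---|---|---|
| `elongation_block` b | linear 5′ tilt of within-gene density, f(u) = 1 + b(1 − 2u) | 0 / 0 / 0.5 / 0.5 |
| `dog_gain` | readthrough emission multiplier | 0 / 0.1 / 0.5 / 1.0 |
| `depth_factor` | library depth multiplier | 1 / 0.7 / 1 / 0.9 |
| `repli_factor` | Repli-seq depth (replication suppression) | 1 / 1 / 0.5 / 0.5 |
| `late_rescue` | late-domain L-coverage multiplier | 1 / 1 / 1 / 1.5 |

The panel encodes the study design: the BET inhibitor alone mostly lowers
output without tilting the profile, the TOP1 poison blocks elongation and
induces readthrough, and the combination maximizes readthrough and
partially rescues late replication (dormant-origin firing).

Geometry and expression: gene lengths and FPKM are log-normal (length
median 15 kb, σ_log 0.8; FPKM median 10, σ_log 0.8), genes are placed
non-overlapping with log-normal intergenic gaps (median 80 kb) on
25-Mb chromosomes; exons of ~250 bp are spaced every ~4 kb. A
`dog_fraction` (default 0.2) of genes is planted as readthrough-prone;
their downstream reads have exponential offsets with scale
`dog_decay_length` (50 kb), matching the monotone decline of observed
downstream profiles and giving closed-form checks (mean offset = decay
length). Planted readthrough is truncated at the next same-strand gene
body, where a real readthrough polymerase would be indistinguishable from
that gene's transcription. Sampling the tilt uses the inverse CDF of
(1+b)u − bu², so b = 0 is exactly uniform.

Depth defaults to 2,000 reads per gene (read length 100 bp), a scaled-down
genome that preserves per-gene statistics of a full-size library
(~10⁳ reads/gene at 2×10⁷ reads over 2×10⁴ genes). Background noise is
0.2% of reads, uniform. A `nascent_fraction` (0.4) of gene-derived reads is
labeled; labeled reads carry 1 + Poisson(tc_rate × (L−1) × U-content)
conversions — per read, not per site, i.e. counts are conditioned on
detection so the labeled fraction is exactly recoverable at the 1-conversion
threshold. Replication domains alternate early/late with lengths uniform in
0.8–2 Mb; E (L) coverage is Poisson with mean 20/bin in matching and 4/bin
in opposite domains (10-kb bins). The optional `dog_near_boundary` mode
plants DoG status on the early-region genes closest (in transcription
direction) to an early→late border, for boundary-geometry validation.

All streams derive from one master seed via CRC-keyed child generators, so
any condition can be regenerated independently and the full fixture set is
byte-reproducible.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: sequence content and alignment artifacts
(mappability, multimappers, PCR duplicates), isoform diversity and
alternative TES usage, copy-number variation, overlapping/nested genes,
antisense transcription, chromatin-dependent conversion-rate variation, and
sub-S-phase Repli-seq structure. Recovery rates measured here are upper
bounds relative to real libraries.

## Analysis definitions and numerical choices

**Metagene.** Gene bodies are rescaled to 100 bins by linear interpolation
of bin midpoints on the scaled axis; ±5-kb flanks stay at native
resolution; `-` genes are flipped so the TSS is on the left. Raw CPM is
averaged across genes (no per-gene normalization, matching common metagene
tooling defaults; a flag enables it). Genes whose maximum body bin exceeds
50× the cross-gene median bin are excluded as pileup outliers (the rule is
configurable; some exclusion rule is needed because single hotspots
otherwise dominate the mean). Optional lowess smoothing (span 0.1, degree 1)
is presentation-only and never feeds the index.

**Elongation index.** OLS of body-bin values on positions
`linspace(0, 1, n_bins)` (endpoints included, so a profile falling 10 units
over the body has slope −10). Constant profiles return slope 0 with r² = 0
rather than an undefined fit. Condition comparisons use slope differences;
the slope scales linearly with the profile, so depth normalization matters
only across conditions, not within.

**DoG calling.** Window-by-window extension from the TES (2-kb windows,
12-kb minimum call, threshold 0.1 CPM per window by default — the window
total, not density). Extension stops at chromosome ends and at the body of
the next expressed same-strand gene; opposite-strand genes do not stop it.
With stranded libraries each gene is scored on its own strand's coverage
(per-strand tracks share the total library size so CPM is comparable);
unstranded tracks are accepted with the caveat that convergent neighbors
can inflate calls. Annotations are reduced to the longest isoform per gene
before calling. The high-stringency rule is the mean over windows 7–9
(30–45 kb) strictly greater than 1.5 CPM; a per-window variant is
available. Calls whose 30–45 kb windows run off the chromosome are excluded
rather than padded.

**Control matching.** Features (log₁₀ length, log₁₀ FPKM) are z-scored on
the pooled DoG + pool distribution; DoG genes are processed in a seeded
random order and each takes its nearest unused pool gene (greedy, without
replacement). Greedy matching is order-dependent, hence the seeded order
and the determinism test.

**Replication timing.** ε = 0.5 CPM pseudocount, 50-kb mean smoothing,
segmentation by sign of smoothed RT (≥ 0 → early), minimum segment 100 kb:
short runs are merged into the longer neighbor (tie → the earlier segment),
then equal labels coalesce, leaving alternating segments that tile the
territory with boundaries on bin edges. These scales sit comfortably below
the 0.8–2 Mb domain size and above single-bin noise; they are configurable.
This transparent segmentation stands in for wavelet-based tooling: the
downstream analyses consume only labels and boundaries, and equivalence to
any external segmenter on real data is not claimed. Segments are called on
the untreated condition and held fixed across treatments so treatment
coverage is compared within fixed regions. Boundary distances are measured
from the TES in the direction of transcription to the first early→late
switch and are reported only for genes whose TES lies in an early segment;
chromosomes with known artifacts (e.g. copy-number variation) can be
excluded by name.

**Pausing index.** TSS window −50/+300 bp around the TSS, body from +300 bp
to the TES — conventional promoter-proximal windows, configurable since
published pipelines rarely print them. Densities are CPM/bp; the ratio
cancels library size. Isoform rule: length > 1 kb, nonzero average signal
in both windows, highest TSS *density* wins (density rather than raw counts
keeps the rule invariant to window length). Genes with zero body density
are excluded, never zero-filled.

**Fold change vs length.** Genes below 1 CPM in both conditions are
dropped; log₂ FC uses a 0.5 pseudocount; genes are ordered by length and
smoothed with a centered 501-gene window (250 each side) that shrinks at
the ends; a window larger than the gene list degrades to the global mean
with a warning.

**Bliss.** Effects are 1 − relative viability, clipped to [0, 1] for the
prediction only; Δ = predicted − observed so synergy is negative. The
checkerboard requires explicit zero-dose rows/columns and viability 1 at
(0, 0), failing loudly on unnormalized plates.

## Validation scale

Recovery tests and the acceptance script run the default study at 300
genes × ~600k reads per condition on two 25-Mb chromosomes, three seeds;
segmentation recovery uses ~20 domains per seed; the end-to-end golden run
uses 80 genes on one 12-Mb chromosome at reduced depth. These sizes were
chosen to preserve per-gene and per-domain statistics of full-size data
while keeping the whole suite fast enough to run on every change.

## Known limitations

- The DoG caller is a minimum-length/threshold scanner, not a segmentation
  model; very weakly expressed DoG genes (bottom percentiles of the
  expression distribution) fall below per-window detectability and bound
  recall below 1.
- Per-read conversion counts carry no positions, so SNP masking is a
  pass-through unless positional conversion data are supplied.
- The moving-average fold-change analysis is descriptive; no
  differential-expression model or significance calling is included.
- Greedy matching does not minimize the global matching cost; with small
  control pools late-matched genes can take distant controls (the per-pair
  distances are reported for auditing).
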