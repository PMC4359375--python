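# Methods

This note documents the models, conventions, and parameter choices behind
`polyribo`, and what the simulator does and does not emulate.

## Coordinates and ORF discovery

All coordinates are 0-based, half-open, in sense-strand transcript space;
the GTF importer converts (1-based closed, strand-aware) at the boundary.
ORF intervals include the stop codon, so a peptide of *a* amino acids
spans 3(*a*+1) nt.

Discovery is AUG-anchored: an ORF is an ATG followed by the first in-frame
stop. "Longer than 10 aa" is read as peptide ≥11 aa (`min_aa=11`,
configurable). Codons containing N never match a start or stop
(conservative). When several ATGs share a stop, the default
`longest_per_stop` mode reports the 5′-most qualifying ATG, mirroring
classic ORF-finder output; `all_starts` retains every ATG for sensitivity
studies. uORFs must lie entirely inside the 5′-UTR, stop codon included —
ORFs reading into the CDS are excluded so uORF metrics stay independent of
CDS signal. The smORF/canonical boundary is inclusive at 100 aa
(303 nt with stop).

## Counting versus coverage

Two placement rules coexist deliberately:

- **Counting** anchors each read at one point — the P-site for footprint
  lengths with calibrated offsets (28–29 nt: +12, 30–31: +13, 32: +14),
  the midpoint for other lengths and for mRNA fragments — so adjacent
  features never double-count a read. Anchors use half-open boundaries
  (an anchor at `feature.end` is outside).
- **Coverage** uses full read extents, reproducing the convention under
  which one internal 32-nt footprint covers 32/57 ≈ 0.56 of a 57-nt ORF.

Metrics (RPKM, coverage) consume footprint lengths 28–34; framing consumes
only 28–32, the lengths with calibrated offsets. The RPKM denominator is
the total retained transcript-aligned read count of the library.

## Expression significance

TE is unstable at low mRNA signal, so it is computed only for features
whose mRNA expression is significant against a randomised background. The
test scatters the library's read anchors uniformly over the concatenated
transcript space (one seeded randomisation), places `n_samples` (default
1000) length-matched intervals uniformly over that space, and reports the
add-one empirical p-value — the fraction of null intervals whose
randomised-read count reaches the observed count. Identical interval
lengths make count and RPKM comparisons equivalent. An alternative null
that samples intervals over the *observed* read field was rejected: under
it a feature's p-value approximates the quantile of its transcript's
density within the transcript space, so when abundances are comparable
every feature sits near p = 0.5 and the significance gate passes nothing.

## Thresholds and calls

The background set is the 3′-UTRs of transcribed canonical (>100 aa)
mRNAs from the small-polysome fraction; "transcribed" uses the same gate
as TE (mRNA RPKM > 0 and expression p < α = 0.01). Cut-offs are the 90th
percentiles of background footprint RPKM and coverage; the coverage
cut-off is floored at 0.57 (one footprint on a dwarf ORF reaches 0.56),
generalising the published "raise to 0.57" correction as
`max(percentile, floor)`. All quantiles in the package — here and for the
conservation cut-off — use linear interpolation between order statistics
through one shared implementation. A feature is translated iff footprint
RPKM ≥ cut-off AND coverage ≥ cut-off AND raw count ≥ 5, all boundaries
inclusive ("at least"). Per-experiment call sets combine by union with
provenance. Report tallies are restricted to transcribed features, so
translated + untranslated = transcribed per category; median TEs exclude
undefined TEs rather than coding them as 0.

## Conservation and composition

A feature's conservation is the overlap-length-weighted mean of block
scores over its bases; bases under no block score 0 by default (an
`exclude` mode averages covered bases only). Overlapping blocks are
rejected. The conserved flag is inclusive at the 90th percentile of
intergenic feature scores. Composition pools residues across peptides
(not per-peptide averages); the random expectation multiplies base
frequencies per codon, sums synonymous codons, and renormalises over the
61 sense codons — stop codons are excluded, a choice the source
convention leaves open.

## The simulator

The generator's defaults are the package's standard study conditions:
300 canonical genes (150–600 aa), 150 smORF genes (11–100 aa), 50 ncRNAs
seeded with 1–3 AUG-ORFs, 40% of 5′-UTRs carrying an embedded uORF
(11–30 aa), footprint libraries of 2×10⁵ reads per fraction, mRNA library
2×10⁵ fragments of 50–80 nt, frame fidelity φ = 0.85. Embedded ORFs are
preceded by an in-frame TAA so AUG-anchored discovery recovers exactly
the embedded interval.

**Truth.** 60% of transcripts are transcribed (many annotated genes are
silent in any one cell line); transcribed abundance is lognormal
(median 20 copies, σ_log = 0.75), spanning roughly two orders of
magnitude as real expression does. Among transcribed genes, 81% of
canonical CDSs and 83% of smORF CDSs are translated (the proportions the
method reports on real data), and 30% of uORFs and ncORFs. Translated
ORFs draw an occupancy *u* ~ U(0.3, 0.9).

**Loading and fractionation.** Ribosome capacity is 1 + ⌈L/80⌉ — one
ribosome at the start codon plus one per (possibly partial) 80-nt
interval, the convention that puts five ribosomes on a 303-nt smORF. A
strict positional-packing mode, 1 + ⌊(L−footprint)/80⌋ (which gives
four), is available for sensitivity analysis of tighter packing. Each
copy of a transcript with a translated ORF draws
min(capacity, 1 + Poisson(u·capacity)) ribosomes using its
highest-capacity translated ORF; untranslated copies carry 0–1
sporadically bound ribosomes. Copies with ≤1 ribosome are sub-polysomal,
2–6 small-polysome, ≥7 large-polysome. Poisson loading is a modelling
choice; no loading distribution is prescribed by the design. Transcripts
whose only translated ORFs are smORF-sized (capacity ≤6) therefore never
reach large polysomes — the enrichment the fractionation exploits.

**Footprints.** Reads are emitted only from copies in the requested
fraction, in proportion to ribosome load, split between co-translated
ORFs by rate × length. P-sites sit at sense-codon starts (frame 0) with
probability φ, else ±1 nt — jitter rather than uniform noise, mimicking
empirical phasing leakage. The stop codon is not an emission site, so
counting anchors stay inside the ORF; full read extents still overhang
the stop by a few nt, as real footprints do. Read 5′ ends are P-site
minus the length-specific offset; lengths draw from a 28–34 nt
distribution peaked at 29–30.

**Background.** UTRs and untranslated stretches of fraction-resident
transcripts emit unphased background at 3×10⁻⁴ per nt per copy — chosen
so CDS-to-3′-UTR footprint density ratios land near the ~5–10× the
method's TE tables report — with 5′-UTRs scaled 2.5× (scanning
ribosomes/leaky initiation, matching the reported 5′- vs 3′-UTR TE ratio
of ~2.2). Background is clustered around sparse sticky sites (~1 per
100 nt, ±10 nt): sporadic single-ribosome binding gives low per-feature
coverage even at appreciable density, which is why the empirical 3′-UTR
coverage percentile stays below the 0.57 floor, as on real data. Under
base-uniform background the same RPKM density would give 3′-UTR coverages
near 0.9 and an absurd coverage cut-off.

**mRNA fragments** place uniformly with counts proportional to
abundance × length (fragmentation yield), so per-base mRNA coverage is
flat away from the ~80-nt edge ramps. **Conservation** tiles translated
ORFs with Beta(6.6, 3.4) block scores (mean 0.66) and everything else
with a low distribution scaled so its theoretical 90th percentile sits at
0.55; the intergenic sample comes from the same low distribution.

**What the simulator does not emulate** — and what passing tests
therefore do not show about real data: sequencing error and quality,
rRNA contamination, mapping ambiguity (reads are placed, not aligned),
isoform structure and spliced coordinates, non-AUG initiation,
transcript-level mixing of ribosome loads across co-translated ORFs
(loading follows the dominant ORF only), and any dependence between
translation level and mRNA abundance. Recovery rates measured here
characterise the calling logic under the stated noise model, not the
wet-lab assay.

## Numerical conventions and edge cases

Empty 3′-UTR background raises an error that points to the published
default thresholds rather than silently substituting them. Zero included
reads in a framing query returns a defined-false result, not an error.
Zero-length features, overlapping conservation blocks, and invalid
fraction ranges raise immediately. Multiplicity-k reads behave exactly as
k unit reads in every metric. All simulation randomness flows from one
integer seed; identical configs give bitwise-identical text outputs. The
analysis seed (expression-null randomisation) is independent of the
generator seed and recorded in run logs and table headers.

## Problem sizes

Defaults were sized for a laptop-class single core: the full simulate +
analyse cycle (500 transcripts, ~2000 features, 6×10⁵ reads, 1000-sample
expression null) runs in well under a minute, and the acceptance script's
five-seed recovery sweep in about one minute.
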