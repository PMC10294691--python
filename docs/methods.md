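# Methods

This note documents the models, conventions, and numerical choices behind
regulonkit, and what its synthetic-data tests do and do not establish.

## Coordinates and domain model

All in-memory coordinates are 0-based, half-open, forward-strand. File
dialects are converted once, at the I/O boundary: peak tables and gene
TSV/GFF3 are 1-based inclusive on disk, BED/bedGraph are 0-based half-open.
A ChIP peak is a single center coordinate with a positive enrichment score —
windows are always built symmetrically around it. Expression values of ND
(not determined) load as missing and are excluded from every statistic; the
genes they belong to are reported alongside results rather than silently
dropped.

The packaged binding-region table (`data/table1.tsv`) transcribes a
published set of 65 PhoB-bound regions mapped by ChIP-seq: 59 of the
regions carry an 18-bp pho-box site call, 18 carry a nucleoid-silencer
(H-NS) co-occupancy flag, and parenthesized gene links mark intragenic
placements (36 of 65).

## Context classification

A peak center is **intragenic** when `start <= center < end` for at least
one gene body, upgraded to **intragenic-and-upstream** when it additionally
lies within 200 bp 5′ of some gene's annotated start on that gene's own
strand (strict inequality), and **intergenic** otherwise. Strand-awareness
matters: "upstream" of a minus-strand gene is to the right of its body.
When two overlapping genes contain a peak, the container whose start is
nearest is reported, ties broken by leftmost start — an arbitrary but
deterministic rule, since annotations rarely make the choice meaningful.
Peak-set matching between experiments uses strict distance inequality
(`|Δcenter| < max_dist`) with the nearest partner reported.

## Motif model

PWMs use per-position counts, probabilities `(count + α) / (n + 4α)` with
pseudocount `α` (default 0.5, i.e. Jeffreys-like smoothing — small enough
not to blur a 59-site alignment, large enough to keep log-odds finite), and
base-2 log-odds against a background distribution (uniform by default,
genome-estimated where a genome is supplied). Scores are in bits and
additive over positions; the expected score of background-distributed
sequence equals the negative KL divergence and is therefore ≤ 0, which the
suite checks empirically.

Genome scanning scores every window on both strands; reverse-strand windows
are scored with the reverse-complemented matrix and reported at the forward
coordinate of the window's leftmost base. Hits are sorted by descending
score with ties broken by (position, strand) ascending; scores are rounded
to 9 decimals for ordering only, so floating-point summation order cannot
scramble ties. Overlapping hits are not masked — the top-k list is the k
best-scoring windows, full stop. A hit "falls inside" a region set when its window midpoint
(`position + width // 2`) lies in the interval union; the choice of midpoint
over start or any-overlap shifts the overlap fraction by at most a window
width at region edges and did not change any qualitative result on
synthetic data.

The scrambled-site null permutes each site's letters independently
(mononucleotide-preserving, not dinucleotide-preserving — the simplest
composition-preserving null, and the one that isolates the A/T-content
argument), rebuilds the PWM from the scrambled set, rescans, and reports
the in-region fraction of top-k hits.

## Occupancy

Tracks are dense per-position coverage, normalized to a fixed total
(reads-per-million-equivalent) so replicate depth cancels; normalization is
linear, so windowed means scale with it. Window occupancy is the arithmetic
mean over `[center − w/2, center + w/2)` (mean rather than sum so values are
comparable across widths; ratios are identical either way); windows
clipped by a contig edge are averaged over the available positions with a
warning. Stranded tracks should be strand-summed before windowing — the
factor-proximal signal of interest is not strand-specific at window scale.
Fold changes are `(mean_A + floor) / (mean_B + floor)` with a default floor
of 1 RPM unit guarding near-zero denominators; with the floor at 0 the fold
is exactly antisymmetric under condition swap. Genome fractions use interval
unions (split/merge invariant).

## Statistics

* **Binomial enrichment** is one-sided upper-tail by default
  (`P(X ≥ k)`), since the hypothesis — sites are *enriched* in a region
  class — is directional; a two-sided alternative is available. On the
  packaged table, k=18, n=65, p0=0.17 gives p = 0.0211.
* **Mann-Whitney** reports U for both samples, the two-sided p, and both
  one-sided p-values. Tie-free samples with n·m ≤ 2000 use the exact null
  distribution; otherwise midranks with tie-corrected variance and the
  normal approximation (with continuity correction). The ChIP-score
  comparison in the packaged table (36 intragenic vs 29 intergenic, heavy
  ties) gives a one-sided p of 0.0047 for "intragenic lower" — reported as
  the directional test, with the two-sided value (0.0095) available in the
  same result object.
* **Roadblock test**: occupancy quadruples (up/downstream × wild-type/
  deletion) are drawn from normal distributions parameterized by the qPCR
  mean/SD — the only published parameters — truncated below at 10⁻⁶
  occupancy units to keep ratios defined. Per repeat (default 1,000 draws ×
  10 repeats), the per-draw comparison is whether down/up is higher in the
  deletion strain; the reported p is the fraction of draws where it is not,
  averaged over repeats, with the orientation ("relief") carried explicitly
  on the result to avoid 1−p ambiguity. The comparison is pairwise per draw
  (a frequency over joint draws), not a comparison of distribution
  summaries. Under the
  null all four summaries are exchangeable and p ≈ 0.5; at zero variance p
  is exactly 0 or 1.
* **qPCR arithmetic**: occupancy units are background-subtracted fold
  enrichment over a silent control region,
  `2^(ΔCT_control − ΔCT_target) − 1`; relative expression is
  `2^(CT_reference − CT_target)`.

## Conservation

The conservation score of a (site, species) cell is the maximum PWM score
over all windows, both strands, of the homologous region; regions shorter
than the motif (or absent) give masked cells rather than errors. Extraction
of homologous regions is upstream of this package — regions arrive as FASTA
with `species|site_id` headers. Scores are reported in raw bits; a per-matrix
min-max normalization to [0, 1] is provided for plotting only, since no
principled absolute color scale exists for cross-matrix comparison.

## Regulon calls

Membership-eligible binding is promoter-proximal evidence only: an
intergenic peak with the gene as nearest downstream neighbor, or an
intragenic-and-upstream peak within 200 bp of the gene's start. A gene is a
**direct member** when it has such binding and responds (significance flag
from the upstream DE analysis AND fold ≥ threshold, default 2.0, computed
with the same floor convention as occupancy). A responding gene without
membership-eligible binding is an **indirect target** — deliberately
including genes whose only evidence is a promoter-distal intragenic site,
because windowed-occupancy and roadblock analyses of exactly such cases show
the response is not mediated by the site. Bound non-responders are
**binding-only inert**; the rest **unaffected**. The four classes partition
the gene universe, and raising the fold threshold can only demote direct
members. Operon structure is not inferred; an optional operon table
propagates eligible binding across members.

## Synthetic data

The generator's defaults mirror the study conditions the package models:
65 peaks with 36/65 intragenic, silencer domains covering 17% of the genome
(2-kb domains, realized coverage within 2% of target by construction),
silencer GC 0.30 vs genome 0.50, an AT-rich 18-bp direct-repeat consensus
with 10% per-position mutation on planted instances, 20× base coverage with
Poisson noise, 2 replicates per genotype, log2 effect 2.0 on planted DE
genes with log-normal (σ = 0.05) inter-condition jitter, and qPCR CV 0.2.
Each peak gets a distinct gene so planted signals never stack; factor-
dependent promoters elevate a full 400-bp window so the windowed fold equals
the planted strength exactly in expectation. Coverage noise is Poisson
(count data), expression noise log-normal, qPCR noise normal on the
occupancy scale. Everything is reproducible to the byte under a fixed seed
and emits a truth table that the recovery tests consume.

Passing recovery tests show the pipeline's logic is correct under its own
generative assumptions — they do not certify robustness to mapping bias,
operonic read-through, overlapping genes, or peak-calling artifacts, none of
which the generator models.

## Problem sizes and defaults in the test suite

Tests run the generator at 120-kb genomes with 70 genes — large enough to
hold 65 non-interacting peaks with realistic spacing, small enough that the
whole suite (including a 10⁶-draw Monte-Carlo oracle and brute-force
scanning oracles) completes in a few seconds. Exhaustive oracles are used
wherever feasible: all-window rescoring for scans and conservation,
outcome enumeration for the binomial (n ≤ 12), rank-split enumeration for
Mann-Whitney (n·m ≤ 64 in tests).

## Known limitations

* The classifier consumes whatever features the annotation provides as
  "genes"; whether non-coding RNA genes are included is the caller's choice
  and shifts intragenic counts accordingly.
* The H-NS co-occupancy flags in the packaged table are taken as printed;
  the underlying coverage data (and hence t-values that depend on rescanning
  the real genome) are not redistributed with the package.
* The Mann-Whitney exact path requires tie-free data; heavily tied score
  tables always use the asymptotic approximation.
* The roadblock test assumes normal qPCR errors; with CVs above ~0.5 the
  truncation at the floor becomes material and the test conservative.
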