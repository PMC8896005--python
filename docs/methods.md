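# Methods

`temotif` quantifies how much of a genome's transcription-factor (TF)
binding-motif repertoire is supplied by transposable elements (TEs), and
whether those TE-resident motifs sit in accessible, TF-bound chromatin and
in promoters conserved between species. This note documents the models,
the numerical choices, and what the synthetic test conditions do and do
not establish.

## Coordinate conventions and interval algebra

All coordinates are 0-based half-open (BED convention); the GFF-lite gene
reader converts from 1-based inclusive on ingest. `merge` unions
overlapping *and* book-ended intervals, matching `bedtools merge`
defaults. "A motif resides within a TE" means subset containment of the
motif interval in a single *un-merged* TE record, so the covering record's
type and family are unambiguous; when overlapping TE records both contain
a hit, the longest covering record wins, ties broken by lexicographic type
name, and the hit is flagged ambiguous. Promoters are the 2.5-kb window
upstream of a gene or operon start (strand-aware, clipped at chromosome
ends, never dropped). Two promoter variants exist because the analyses
need both: the *exclusive* variant (coverage partition) subtracts coding
exons, UTRs and introns of any gene and replaces operon members with a
single operon promoter; the *inclusive* variant (gene counting) keeps every
gene's raw window. Distal intergenic space is the genome minus every other
class; the other classes may overlap one another, so class totals can
exceed the genome size.

## Motif scanning

A PWM is scored against a zero-order (mononucleotide) background estimated
from the scanned genome with both strands pooled (freq(A)=freq(T),
freq(C)=freq(G)) and add-one smoothing; a `--no-rc`-style flag disables
the pooling. Log-odds scores are

    score(i, b) = log2( ((p_ib + c * bg_b) / (1 + c)) / bg_b )

with pseudocount `c = 0.1` distributed proportionally to the background
(exposed as a parameter). With `c = 0`, zero-probability cells score −inf
and are clamped onto the lowest bin of the integer grid.

Exact p-values come from discretizing each position's scores to integers
(default 1000 bins spanning the largest per-position score range) and
convolving the per-position score distributions under the background by
dynamic programming. The scanner computes each window's integer score
directly from the integer matrix, so reported p-values are *exact* tail
probabilities of the integer score — the only approximation is the
per-position rounding, bounded by half a bin per position. Mapping an
externally supplied real score onto the grid rounds once per matrix.
Both strands are scanned (reverse strand = position-reversed,
base-complemented matrix, sharing the forward tail table, which is exact
whenever the background is strand-symmetric); windows containing N are
skipped; with max-strand collapsing, only the better strand at a start is
kept, ties keeping `+`. The default significance threshold is p ≤ 1e-4.

Because the integer score distribution is discrete, the largest attainable
p-value not exceeding the threshold (the "attained tail") varies by motif
and can sit anywhere below the nominal threshold; the expected chance-hit
count in a scan is exactly `attained_tail x windows x 2 strands`, a fact
both the false-positive test and the synthetic generator use.

## Enrichment statistics

Per feature class, coverage reports the percent of the class covered by
TEs, the class's share of all TE bases versus all non-TE bases, and their
ratio; ratios below 1 are also reported as the reciprocal depletion. Report
tables round percentages and folds to one decimal, and fold changes are
taken over the share percentages as printed (so a 27.8%-vs-1.0% pair reads
as a 27.8-fold depletion).

Per (motif, TE type), fold enrichment is the proportion of the motif's
genomic instances fully inside that TE type divided by the type's genome
share (merged per-type bp, so overlapping fragments count once). The null
treats each instance as an independent Bernoulli trial with success
probability equal to the genome share; significance is the one-sided upper
binomial tail (scipy's regularized incomplete beta; agreement with direct
rational summation is tested to 1e-10 for n ≤ 30 and to 1e-9 against
log-space summation for n up to 1e4). Instance dependence from overlapping
windows is ignored, and full containment makes the true success
probability marginally smaller than the genome share for short TEs — both
effects are conservative. The filter cascade keeps types covering
**more than 20 kb**, folds **strictly above 20**, and p **strictly below
1e-12**. Gene counting attributes a TE-contained hit to every gene whose
inclusive promoter window fully contains it (genes are counted, not hits).

Hypergeometric tails (ortholog sharing) and two-sided Fisher tests
(binding-accessibility association) are computed with exact Python-integer
arithmetic: the two-sided Fisher p sums outcome probabilities no larger
than the observed one with exact integer weight comparisons, so ties are
handled without a float fudge factor. Degenerate margins return p = 1 with
a flag.

## Chromatin association

Summits become 101-bp regions (±50 bp, clipped at chromosome bounds) and
are merged across developmental stages before any fraction is computed.
"Accessible motif" means the motif interval is fully contained in a merged
accessible region — the same containment convention as TE residence (the
looser overlap reading is a defensible alternative; containment was chosen
for internal consistency). Accessible fractions gate on more than 3,000
accessible instances and more than 10% in TEs; bound fractions count a
TF's merged bound regions containing at least one cognate hit (a region
with several hits counts once, and is TE-derived if any contained hit is
TE-contained), gating on more than 500 bound regions and more than 5%.
The accessibility association builds, per TF, a 2x2 table of bound regions
classified by (contains a TE-provided cognate motif) x (overlaps a merged
accessible region) and reports the two-sided Fisher p; the construction is
recorded in the output because the unit of the original analysis is not
printed. Top contributors rank TE types by count, ties lexicographic.

## Cross-species sharing

Both genomes are scanned with the same PWMs against their own backgrounds.
For each motif, the genes with a TE-contained hit in their inclusive
promoter window are collected per species and restricted to a one-to-one
ortholog map; the shared count k is tested against the upper-tail
hypergeometric distribution with population N = all mapped orthologs
(an option restricts N to orthologs with any promoter TE). Shared pairs
are "family-similar" when any normalized family label of the A-side
promoter TEs equals any on the B side; the normalization table (superfamily
synonyms onto one key, e.g. all Tc1/mariner spellings) ships as an editable
mapping, and unknown labels fall back to raw string equality with a
warning. Significance stars follow the 0.05 / 0.01 / 1e-05 convention.

## Synthetic data: what it emulates and what it does not

The generator emits, per species, a random multi-chromosome genome at 64%
AT (worm-like), non-overlapping TE intervals from a typed/familied library
(~9% of the genome under the default plan), gene models with UTRs, exons,
introns and operons, planted motif occurrences, multi-stage ATAC/ChIP
summit sets covering a chosen fraction of planted sites plus noise summits
kept ≥ 120 bp away from any site, and a second species with an ortholog
map and promoter-TE sharing plan. One integer seed drives named substreams
so editing one plan section leaves the other draws untouched; output is
byte-identical per seed.

Planted words are rejection-sampled from the PWM's own distribution until
their scan p-value is at most 1e-6 (floored at the best word's attainable
p-value for short motifs), guaranteeing recovery at the 1e-4 scan
threshold. Target-fold plans derive the in/out split from the realized TE
coverage *and* the expected chance-match count (attained tail x windows),
so the expected pipeline-estimated fold equals the target; the
fold-recovery study condition plants a 22-fold excess — a 10% margin above
the strictly-greater-than-20 gate so replicate noise cannot straddle it —
in a TE type covering ~24 kb of a 1.2 Mb genome, with a width-14
high-information motif (600 planted instances per replicate). The null
(calibration) bundle places motifs uniformly, irrespective of TEs, over
long (2–2.5 kb) TE copies with ~30 expected in-TE counts per pair and
permits placement collisions: rejection-sampled non-overlapping placement
underdisperses counts and makes the binomial test read conservative, which
is a property of the placement process, not of the statistic under its
stated null.

What passing these conditions shows: the scanner's p-values are exact for
its score model, interval accounting matches per-base truth, the
enrichment statistic recovers a designed excess through the full
file-format round trip, and the exact tests are correctly calibrated.
What they do not show: behaviour on decayed TE copies (the library plants
clean intervals over random sequence, with no consensus decay, indels or
nested insertions), motif clustering or dependence between instances,
realistic ChIP/ATAC noise structure, or assembly/annotation error — on
real data the binomial independence assumption and the containment
convention are approximations.

## Problem sizes and defaults

Default bundle: 2 x 400 kb, 6 TE types (~9%), 10 motifs of widths 8–12
(dominant base probability 0.95), 400 genes with a 15% operon fraction,
150 orthologs; the full pipeline runs in a few seconds. Fold-recovery
replicates use 2 x 600 kb; calibration bundles 2 x 250 kb with 10 motifs x
1,000 placements. These sizes were chosen so a complete closed-loop run of
every stage, including 20-replicate recovery and 2,000-pair calibration,
finishes in minutes on a single CPU while keeping expected counts large
enough for the statistics to be in their intended regime.

## Known limitations

- First-order or higher Markov backgrounds, gapped motifs and q-value/FDR
  control over scan hits are out of scope (raw-p thresholding only).
- The Fisher-table construction and the bound-fraction denominator
  (regions, not instances; an instance-mode flag exists) are one
  defensible reading of an under-specified analysis and are labelled in
  outputs.
- Overlapping same-motif hits are counted post max-strand collapsing;
  collapsing shifted overlapping occurrences is not attempted.
- The hypergeometric population defaults to all mapped orthologs; whether
  orthologs lacking promoter TEs belong in the population is a judgement
  call exposed as an option.
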