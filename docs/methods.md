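# Methods

This note records the models, conventions and deliberate choices behind
exofold, in the spirit of a methods appendix: what each stage assumes,
which knobs matter, and what the synthetic benchmarks do and do not show.

## Coordinates and data model

All internal coordinates are 0-based, half-open. The 5′ position of a
minus-strand read is its rightmost aligned base. Conversion to 1-based
happens only at serialization boundaries: wiggle tracks, the TSS table on
disk, and the peak analysis CSV. A pair is modelled by the fields that
matter downstream — chromosome, read_1 strand, the two 5′ positions, and
the pair mapping quality (the minimum of the two mates, a conservative
reading of a per-read threshold). Discordant or half-mapped pairs are never
constructed; the reader drops and tallies them.

## PCR-duplicate definition

Duplicates are pairs identical in (chromosome, read_1 strand, read_1 5′,
read_2 5′). Because read_1 is pinned by the exonuclease while read_2 comes
from sonication, identical read_2 positions essentially only arise by PCR
amplification. The first pair in input order represents each group — the
surviving coordinates are identical, so the choice is downstream-invisible.
Opposite-strand pairs at mirrored coordinates are distinct events: the key
includes the strand.

## Footprint formula

`footprint = round(3 × 0.066 × (L/3 × 110)^(1/3) × 3.03)` with L in
nucleotides. Constants: 110 Da mean residue mass; 0.066 nm·Da^(−1/3) for a
sphere of average protein density; 3.03 bp/nm B-DNA rise; the factor 3
models a dimer whose subunits overlap for half their size (an expert flag
exposes this multiplier; 2 ≈ monomer, 4 ≈ non-overlapping dimer). Rounding
is half-up; the mode only matters on exact .5 boundaries. Input may include
or exclude the stop codon — for Ino2 (912 vs 915 nt) both give 19 bp. A
convenience entry point accepts amino-acid counts.

## Trimming and the strand-overlap profile

Each read_1 is replaced by a fixed-length interval growing from its 5′ end:
`[p, p+L)` on the plus strand, `[p−L+1, p+1)` on the minus strand. Spans
crossing a chromosome end are clipped, not dropped, so signal near
telomeric genes survives. Strand coverages are accumulated by difference
arrays (O(reads + genome)). The profile keeps a position only where both
strands are covered; the kept value is the **sum** of the two strand
coverages. "Combined" admits several operators — sum preserves total read
support and keeps enrichment magnitudes comparable with the read-count QC;
`combine_strands` is the single place to change if min or mean is wanted.

Normalization divides by the genome-wide mean over *all* positions,
including zeros: parameter-free, robust, and it makes profile units read
directly as fold-over-background (mean 1). Whether peak regions should be
excluded from the background is a judgement call; the all-positions mean is
used deliberately, and with sparse binding the difference is small.
Replicates are averaged per base after normalization. An all-zero profile
normalizes to itself with a warning rather than failing.

Because the overlap profile is flat across a binding site, the profile
argmax breaks ties at the **median maximizing position** (plateau center);
the conventional leftmost-index tie-break would bias site localization left
by about half the footprint.

## QC statistics

*Sample correlation*: read_1 5′ positions are point-assigned to 1-kb bins
(no double counting at edges), bins that are zero in every sample are
dropped, survivors are transformed log₂(count + 1) — the pseudocount keeps
bins that are zero in only some samples finite — and Pearson correlation is
computed pairwise. Binning uses deduplicated, untrimmed reads so the QC is
independent of the chosen trim length.

*TSS meta-profile*: the normalized profile is averaged over ±1000 bp
windows around each TSS, minus-strand windows flipped so upstream is always
left. Windows truncated at chromosome ends contribute only the positions
they cover (per-position anchor counts). "Promoter enrichment" is the mean
over the upstream half [−1000, 0).

*Peak shape*: read_1 5′ ends are counted per strand in ±30 bp (default)
around each peak center; the per-peak matrix is the individual-peak plot,
its column means the averaged border profile. With trimming matched to the
footprint the averaged maxima sit at ∓footprint/2.

Every figure writer has a TSV twin carrying the plotted numbers, so no test
or user ever needs to parse an image.

## Peak post-processing

GEM's events file is parsed tolerantly: the `Position` column
(`chrom:coordinate`, 1-based) is converted to 0-based; the expected
strength is taken from GEM's `Expectd` column (its own header spelling),
falling back to `Expected`/`Control`, and to 0 with a warning when absent.
SNR = IP / expected with a pseudocount of 1 when the expected strength is
zero. Boundary semantics are strict and deliberate: peaks with SNR ≤ 2 are
removed (exactly 2.0 is removed), and a peak is assigned to a gene iff
|center − TSS| < 1000 bp (999 in, 1000 out), upstream or downstream, to
*every* qualifying gene. Assignment distances are signed negative upstream
in gene orientation. The gene-target table covers every gene in the TSS
annotation so absence of binding is explicit. Peak discovery itself (GEM)
and motif search (MEME) are external tools; exofold consumes the former's
events file and prepares the latter's 60-bp input sequences.

## Synthetic data generator

The generator emulates the exonuclease border model: for a site at center
c with footprint f, plus-strand read_1 5′ ends are drawn at c − f//2 +
N(0, jitter) and minus-strand ends at c + f//2 + N(0, jitter), rounded to
integers; read_2 is placed at a sonication-like insert distance
N(225, 75) bp outward (75-bp reads), floored at the read length and clamped
to the chromosome. Defaults: jitter sd 1.5 bp, matching the few-bp smear
seen in real averaged border profiles; background fraction 0.05 of reads
placed uniformly, reflecting that exonuclease digestion leaves a
high-quality library dominated by border reads; reads split evenly between
the two borders. PCR duplicates are injected by copying existing pairs at a
configurable rate; base pairs are guaranteed distinct under the duplicate
key (colliding read_2 positions are re-drawn, which is the biological
rationale for the key in the first place), so the truth table's duplicate
flags are exactly what deduplication removes. Every dataset is a pure
function of its seed.

What the generator does **not** emulate: sequencing errors and quality
scores, mappability and copy-number structure, chromatin-accessibility
background biases, site-strength heterogeneity, and motif-dependent
binding. Passing benchmarks therefore demonstrate the pipeline's
correctness and noise response under the border model, not performance on
any particular real library.

## Graded-noise validation design

A shared signal pool is generated once — replicates subsample it without
replacement, as pseudo-replicates drawn from one merged library do. Noise
reads are generated fresh per replicate from its own seed: a genome-wide
artificial read set is far deeper than a 100,000-read subsample, so two
subsamples share a negligible fraction of reads, and independent draws
model that limit exactly (subsampling a noise pool only ~1.2× the sample
would leave the two "replicates" sharing most of their reads and thus
spuriously correlated). Mixtures follow the five-grade design exactly:
100k/0, 75k/25k, 50k/50k, 25k/75k, 0/100k at 100,000 total reads.

Study conditions used by the tests and the acceptance script, chosen once
as a yeast-scale benchmark: 12 chromosomes × 1 Mb (12 Mb); 3000 genes with
evenly spaced TSSs on alternating strands; 600 of them bound, each with a
site planted 200 bp upstream of its TSS; 250 reads per site plus 5 %
background (signal pool ≈ 158k pairs); footprint/trim 19 bp. Under these
conditions replicate correlation runs ≈ 0.95 / 0.74 / 0.69 / 0.56 / ≈ 0
across the five grades, decreasing monotonically, and promoter enrichment
falls from ≈ 4 to ≈ 1. Smaller configurations (2 × 200 kb, tens of sites)
are used for unit-level checks.

## Numerical and degenerate-input conventions

Correlation requires ≥ 2 samples and ≥ 3 surviving bins. Wiggle output
serializes with 8 significant digits (round-trips within 1e-6 relative).
Trim length must be ≥ 1; a trim that leaves no on-chromosome span drops the
read with a warning. Footprint inputs not divisible by 3 warn and proceed.
Peak windows and TSS windows clip at chromosome bounds with per-position
averaging. The pipeline writes data files through `.incomplete` temp names
renamed on completion, so an aborted run is distinguishable from a finished
one.

## Known limitations

GEM's internal noise model is not reproduced — the expected strength is
whatever its events file reports. The SNR denominator choice (control
channel) is an interpretation; an alternative would be GEM's noise
estimate. Footprint estimation assumes a globular dimer; elongated factors
or large complexes will be under- or over-estimated, and the method offers
no per-domain modelling. The uniform-background simulator makes replicate
correlations at low noise slightly optimistic relative to real libraries
with structured background.
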