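# Methods

This note documents the models, conventions and design choices behind
`tecensus`, in the order the pipeline runs.

## Annotation summarization

RepeatMasker `.out` reports (15-column whitespace layout, 1-based inclusive
query coordinates) are converted at the boundary to 0-based half-open
intervals; all interval arithmetic in the package uses that convention.
Records are kept if their Smith-Waterman score reaches the cutoff (default
250, the conventional value for TE censuses) and their class is a
transposable element: simple repeats, low-complexity runs, satellites and
structural RNAs are excluded at parse time, mirroring a TE-only masking run.

Classification is a total function. A family or `class/family` string is
resolved through an editable taxonomy TSV (family → superfamily → order)
covering the standard superfamilies of the LTR, LINE, TIR, Helitron and
Maverick orders; the string is tried as an exact name, then by its
`order/superfamily` parts (both sides, since superfamily-first strings occur
in the wild), then by the RepeatMasker class token alone (`DNA` → TIR,
`RC` → Helitron, `SINE` → Others). A recognisable order with an unlisted
superfamily resolves to (order, Unknown); anything else to
(Unknown, Unknown). Which families belong in the residual "TIR other" and
"Others" buckets is not standardised; the shipped taxonomy places a small
set of minor TIR superfamilies (Sola, Academ, Kolobok, …) under "TIR other"
and Penelope/SINE/DIRS under "Others", and users can replace the TSV.

**Overlap policy.** Annotators may report overlapping hits, and whether to
deduplicate them before summing nucleotides is a genuinely open choice. The
default resolves overlaps explicitly: each base is assigned to the covering
hit with the highest score, ties broken by earlier start and then by
lexicographic family name, which makes totals per scaffold bounded by the
scaffold length and makes the policy testable against a per-base oracle.
Records flagged `*` (overlapped by a better hit) are parsed, not
pre-dropped, so the policy is applied in one visible place. A `union`
counting mode (raw hit lengths, no deduplication) is available as a
sensitivity check.

## Windowed chromosomal density

Mapped scaffolds are abutted in their reported order, without gap padding,
to form one concatenated coordinate per chromosome starting at the
telomere; reverse-oriented scaffolds are flipped in place. Windows are
non-overlapping, 50 kb by default. Partial trailing windows are used for
plotting only, never for statistics. TE bp per window is the exact
intersection of overlap-resolved annotations with the window; an annotation
spanning a boundary is split at the boundary, so total windowed TE bp is
conserved.

The proximal region of a chromosome is the 3 Mb (configurable) at the
*highest* coordinates — the end nearest the centromere under the
telomere-first plotting convention. If a per-chromosome map disagrees with
that orientation, the scaffold orientations in the map are the place to
express it. The dot chromosome (label "6") is a single undivided region: it
is short, recombination-poor and uniformly TE-dense, so a proximal/distal
split is not meaningful. Chromosomes shorter than the proximal span are
treated as entirely proximal with a warning.

Region statistics report mean density in percent with the sample (n−1)
standard deviation. Distributions are compared with the two-sided
two-sample Kolmogorov-Smirnov test (scipy); the pairwise comparison matrix
reports raw p-values as the primary surface and Holm-adjusted p-values as
an extra column, since multiple-testing policy differs between audiences.

## Coverage-based correction

Depth is the number of aligned read bases covering a position, accumulated
from mapped primary alignments only; insertions and soft/hard clips
contribute nothing and deletions add no read base. No MAPQ filter is
applied by default and duplicates are not removed: multi-mapped placement
over repeat loci *is* the collapse signal, and filtering it away would
defeat the correction. A MAPQ knob exists for sensitivity analyses. A plain
depth TSV dialect (`scaffold  pos  depth`, 0-based) is accepted
interchangeably with SAM/BAM for alignment-free testing.

The reference coverage C̄ comes either from gene intervals (mean depth over
the interval set, length-weighted) or from an external scalar such as an
assembler's estimate; the source is recorded. Genes are assumed single-copy
and collapse-free — the central assumption of the method. Corrected mass
divides the summed depth over a category's annotated positions by C̄; the
correction factor divides corrected by annotated mass. The correction says
nothing about *where* the missing copies are: the delta is attributed to
gaps or unassembled sequence without placement, which is reflected in the
two genome-fraction conventions (`gaps`: genome size = assembly size;
`inflate`: genome size grows by the delta). Reported kb are rounded to two
decimals only at the reporting boundary; internal arithmetic is unrounded.

## Sequencing-technology comparison

Group means of assembly TE percentages are arithmetic means reported at two
decimals. The two-group comparison uses the two-sided Mann-Whitney U test
with the exact null distribution whenever both groups have ≤ 25
observations and the pooled sample is tie-free (the regime of genus-scale
assembly surveys), falling back to the normal approximation with continuity
correction otherwise; the method used is recorded in the result. On the
bundled 27-assembly survey the exact p is 0.001421. Phylogenetic
non-independence of species-level records is acknowledged, not modelled:
subgroups sequenced with both technologies are emitted as a descriptive
paired table with no test attached.

Nx statistics sort scaffold lengths descending; the index is the count of
scaffolds whose cumulative length first reaches the given fraction of the
total, the length is that scaffold's length.

## Synthetic collapse worlds

The generator emulates the one assembly artifact the correction targets:
near-identical repeat copies merged into a consensus locus whose read depth
is inflated by the number of source copies. A world is built from a seed, a
scaffold plan and per-family plans (unit length, copy number n, retained
copies m ≤ n, within-family identity). Copies are mutated from a family
consensus by substitutions only — no indels — so true mass (n × unit) and
assembled mass (m × unit) are exact integers and recovery assertions can be
exact. The first m copies survive; dropped copies are excised from the
assembly and absorbed round-robin by the survivors (any deterministic
assignment would do: the correction only sees aggregate depth). Annotations
describe the collapsed assembly only, i.e. what an annotator would see.
Gene intervals are placed in background sequence untouched by TEs or the
collapse, so their mean depth equals the nominal coverage by construction.

Simulated alignments place reads from the true genome onto the assembly
segment by segment (constant expected depth per segment: C over background,
C × multiplicity over a retained copy). Noiseless mode tiles each segment
with exactly-covering reads, giving exact depths; Poisson mode draws
per-segment read counts at the expected depth. Both emission paths — SAM
records and the depth TSV — serialize the same read list, so they agree by
construction and the SAM path exercises the pysam-based depth accumulation.

The stock world (five 200-kb scaffolds; Gypsy, Copia, Jockey, R1, hAT and
Helitron families with collapse factors between 2 and 4; coverage 50×; read
length 100) runs in about a second. At these sizes the Poisson relative
error of a ≥ 10-kb category is ~1–3 % (thousands of reads per category), so
the 5 % recovery tolerance tests a real property rather than luck. A
separate interval-only generator produces multi-megabase chromosomes with
proximal TE enrichment and a dense dot chromosome for the window-density
statistics, without generating sequence.

What the worlds do *not* emulate: read errors, paired-end structure,
nested/fragmented TE copies, indel divergence, heterochromatin
under-assembly, or a real assembler. Passing tests therefore show that the
implementation computes its model correctly and that the correction inverts
the modelled collapse; they do not validate the collapse-free-gene
assumption or mapper behaviour on real reads.

## Numerical and reporting choices

All randomness flows from explicit integer seeds through
`numpy.random.default_rng`; same seed, byte-identical outputs. Degenerate
inputs fail loudly: empty annotation files are distinguished from
header-only files, zero-length feature sets and zero reference coverage are
refused, samples too small for a test are rejected with a message. Every
table written by the pipeline carries a header with the tool version, a
hash of the run manifest and the seed, and a re-run from the same manifest
is byte-identical for deterministic stages.

## Known limitations

* The correction redistributes read mass but cannot place missing copies;
  per-locus copy number is out of scope.
* Window counts near scaffold junctions depend on the abutting convention;
  windows spanning junctions are counted as ordinary windows.
* The exact Mann-Whitney path requires tie-free data; heavily tied surveys
  silently use the asymptotic method (recorded in the result).
* Real-assembly window densities and published N50/N90 indices require the
  full assemblies and are out of desk-scale reach; the corresponding
  operations are validated on synthetic worlds and structural properties.
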