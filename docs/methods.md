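# Methods

## Data model

The unit of computation is the *pileup column*: every aligned read base
overlapping one genomic position, split across up to three sample roles
(normal DNA, tumor DNA, tumor RNA). Each observation carries the per-read
quantities the filters consume — base quality (assumed already
alignment-adjusted, e.g. BAQ from an upstream pileup engine; no
recomputation is done here), mapping quality, strand, the base's 0-based
offset within the read, read length, pairing flag, the read's genome-wide
mismatch count (excluding inserted/deleted bases), an indel-in-alignment
flag, and the qualities of up to five flanking bases on each side.

Columns come either from coordinate-sorted indexed BAMs via pysam pileup
traversal, or from a one-observation-per-row TSV dialect meant for small,
fully inspectable datasets. Internal coordinates are 0-based; VCF output is
1-based; BED input is 0-based half-open; position-list input (dbSNP/COSMIC
style) is 1-based, as those exports print it.

Per-role summaries count only observations at or above the base- and
mapping-quality cuts; `N` bases never count toward depth or any fraction.
The alternative allele is the non-reference base with the highest surviving
count, ties broken lexicographically (A<C<G<T) for deterministic output.
Overlapping mate pairs are not deduplicated: every observation counts once
(a documented simplification; deduplication belongs to upstream duplicate
marking). Unpaired reads satisfy the proper-pair criterion by default
because single-end RNA-seq libraries are common; `--no-single-end-proper`
disables this.

## Calling procedure

Detection is deliberately lenient — quality-filtered depth ≥ 4 and alt
depth ≥ 2 at base/mapping quality ≥ 10 — so that the typed filter chains,
not the scan, decide every call.

**DNA-only path.** The normal is tested against the reference first
(germline profile: depth ≥ 10, alt depth ≥ 4, VAF ≥ 10%, average alt base
quality ≥ 20, strand skew ≤ 90%, third-allele fraction ≤ 2%). A passing
germline call pre-empts any somatic test at that column. Otherwise the
somatic test requires the tumor to pass the same support profile and the
normal to be deep enough to have revealed a germline variant (depth ≥ 10)
while carrying ≤ 2% of the candidate allele.

**Triple-sample path.** The candidate allele is taken from the RNA; the
tumor DNA and normal are then summarized *for that same allele* (the
published description does not state cross-sample allele matching
explicitly, but the read-support schematic implies it; we enforce it).
Support profiles: RNA depth ≥ 10, alt ≥ 4, VAF ≥ 10%, average alt base
quality ≥ 15; tumor DNA ≥ 1 alt read with average alt base quality ≥ 15
(this is what distinguishes a low-VAF somatic mutation from a candidate
RNA-editing event); normal depth ≥ 10 with ≤ 10% of the allele. Then, in a
fixed order chosen for deterministic rejection attribution: common and
retired known-polymorphism position lists, accessible-genome blacklist,
pseudogene intervals, gene-family intervals, positional bias, remap check.
Known-polymorphism filtering applies to the triple-sample path only (that
is where the published pipeline places it); `--apply-dbsnp-to-dom` extends
it to the DNA-only path.

The strand-bias rule — with ≥ 4 alt reads, fail when more than 90% of them
lie on one strand — is implemented once, inside the threshold profiles, so
it is not double-counted between the table row and a standalone pass. The
guard resolves an ambiguity between the rule text and the table rows in
favor of the rule text; without it, a single-alt-read tumor-DNA column
(which the triple path must accept) would always be strand-biased.

Positional bias: fail when ≥ 95% of alt reads place the allele at relative
position < 1/3 or ≥ 2/3 of the read; computed real-valued so the rule is
read-length independent.

Remap check: each variant-supporting read (sequence required) is re-aligned
by a pluggable `RemapAligner`; a read whose best placement is strictly
better elsewhere is dropped, after which ≥ 4 surviving reads and ≥ 10% of
total depth are required. The default aligner does exhaustive local
alignment (match +1, mismatch −1, gap open −2, extend −1) against a
user-supplied FASTA of candidate regions — the locus neighborhood plus
declared homologs — so tests run with no external binary; an adapter can
shell out to a genome-wide aligner instead. The pipeline skips this stage
when no candidate-region FASTA is configured.

**Merging and final support.** Same-site same-allele calls from the two
paths merge to `RNA_Confirmation`; path-exclusive calls become `DNA_only`
or `RNA_Rescue`; same-site different-allele pairs are kept separately and
logged. Each merged somatic call must be supported by ≥ 4 *perfect* reads:
mapping quality ≥ 10, alt base quality ≥ 10, all flanking qualities ≥ 10,
properly paired, fewer than 4 mismatches, no indel in the alignment. The
strand rule is then re-applied over all perfect reads (reference- and
alt-supporting — a deliberately different denominator from the alt-only
strand filter, following the rule's wording). The inspected sample follows
the evidence source: tumor DNA for `DNA_only`, tumor RNA for `RNA_Rescue`;
`RNA_Confirmation` passes if either sample passes (the published rule names
no sample; this choice matches each path's evidence).

VCF 4.2 output is rendered deterministically (no timestamps); rejected
candidates are emitted as records whose FILTER column lists their failed
filters, which is also how the rejection report is rebuilt from a VCF.
MAF-style VAF percentages round half away from zero (`31/34 → 91`); the
published table this convention reproduces contains two cells (1/7 printed
as 13%, 1/13 as 7%) inconsistent with any single rounding rule, which we
do not attempt to reproduce.

## Spike-in simulator

Mutations are written into the reads of existing pileups rather than
simulated from a reference, preserving the depth/quality/strand structure
of the source data. Eligible loci need tumor-DNA and tumor-RNA depth ≥ 10
(defaults) and reference homozygosity in all samples. Per locus one
alternative allele is drawn and used in *both* DNA and RNA (the natural
model of one somatic event), with independent target VAFs from
configurable distributions (`constant:x`, `uniform:lo-hi`). The edited
read count is `round(VAF × depth)` half away from zero, so
|achieved − target| ≤ 1/(2·depth); a target that rounds to zero reads is
skipped and reported. Editing happens at the column level without
re-mapping (the re-mapping of an alignment-level tool is out of scope at
this scale; a re-mapper can be hooked in when operating on real BAMs). All
choices flow from one seed.

## Validation classifier

The deep-resequencing decision grid is implemented literally from its
printed boundaries: either validation depth < 10 → Ambiguous; normal VAF
≥ 3% → Germline/LOH; tumor VAF = 0 (zero alt reads) → Not Validated;
otherwise Somatic Low (< 8%), Med (≥ 8%, < 20%) or High (≥ 20%), except
that a tumor VAF in (0, 8%) with a non-zero normal VAF below 3% is
Ambiguous. A Not-Validated RNA-rescued call at a catalogued somatic
mutation position is accepted as validated (lowest tier). Precision is
validated / (validated + not-validated + germline/LOH), with Ambiguous
excluded from the denominator; the not-validated and germline/LOH failure
classes are reported separately and combined.

## Synthetic generator and the independent oracle

The generator emulates the *structure* the filters consume — exact alt
counts (`round(VAF × depth)`), normal base/mapping/flank qualities,
Bernoulli strands, optional positional clustering of alt alleles, clipped
exponential mismatch loads, pairing and third-allele contamination. It
does not model platform error profiles, alignment context, overlapping
mates or correlated errors, so green tests demonstrate the decision logic
is faithful to its rules, not performance on real sequencing data.

The truth side of the generator re-implements both calling decisions as
straight-line translations of the threshold tables over raw observation
lists, sharing no code with the filter/calling modules. The acceptance
suite requires exact agreement between caller and oracle on 10,000 random
columns spanning the depth/VAF/quality/strand grids (~10 s), and the
rescue property — on 500 clean columns with DNA VAF strictly below 10%
(≥ 1 alt read) and RNA VAF in 10–50%, every site meeting the triple-sample
tables plus the perfect-read criteria is emitted as `RNA_Rescue` and none
by the DNA-only path (433 of 500 sites meet the criteria at the default
seed). Problem sizes throughout the suite (tens of observations per
column, 10⁴ columns for the equivalence sweep) were chosen as the smallest
that exercise every threshold from both sides.

## Known limitations

Single alternative allele per site (the top allele by count); no INDEL,
LOH or RNA-editing calling; no BAQ recomputation (qualities are trusted as
given); no duplicate marking or re-alignment around INDELs; the default
remap aligner checks only declared candidate regions, not the whole
genome; validation and catalogue inputs are position-based, not
allele-aware.
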