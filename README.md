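# triplecall

Somatic single-nucleotide-variant calling from patient-matched **normal
DNA**, **tumor DNA** and **tumor RNA**.

Traditional somatic callers compare only the tumor and normal genomes, and
their precision collapses at low variant allele frequencies (VAF), where a
real subclonal mutation is hard to tell from noise. When the tumor
transcriptome has also been sequenced — routine in modern cancer profiling —
the RNA provides an independent read-out of the same allele. `triplecall`
exploits this with two calling paths run in parallel over every pileup
column:

* the **DNA-only path (DOM)** — a germline test of the normal against the
  reference, then a tumor-vs-normal somatic test with conventional support
  thresholds (tumor depth ≥ 10, ≥ 4 alt reads, VAF ≥ 10%, average alt base
  quality ≥ 20, normal depth ≥ 10 with ≤ 2% of the allele);
* the **triple-sample path (TBM)** — the variant allele is read from the
  tumor RNA (≥ 4 alt reads, VAF ≥ 10%), the tumor DNA must carry **at least
  one** read with the same allele (separating true mutations from candidate
  RNA-editing events), and the normal DNA must be deep and clean.

Merged calls are classified as **RNA_Confirmation** (both paths),
**RNA_Rescue** (triple-sample only: very low DNA VAF, strong RNA support —
the calls a DNA-only caller misses) or **DNA_only**, passed through a final
*perfect-read* support filter, and written as VCF 4.2. False positives are
suppressed by strand-bias, positional-bias and re-alignment (remap) checks
plus user-supplied accessible-genome blacklist, known-polymorphism,
pseudogene and gene-family annotations.

The package also includes:

* a **read-level mutation spike-in simulator** (edit real reads to a target
  VAF with a recorded truth set) for sensitivity benchmarking;
* a **validation-status classifier** implementing the standard
  deep-resequencing decision grid (Somatic Low/Med/High, Germline/LOH,
  Not Validated, Ambiguous) with a catalogue-rescue rule and per-group
  precision accounting;
* a **synthetic triplet generator** so every stage is testable with no
  external data.

## Worked example

Generate a small synthetic triplet dataset, call it, and summarize the
rejections:

```bash
triplecall synth --n-columns 60 --seed 1 \
    --out-pileup pileup.tsv --out-truth truth.tsv
triplecall call --pileup pileup.tsv --out calls.vcf --report report.tsv
```

The log reports per-stage counts (the generator deliberately produces
mostly noisy, sub-threshold columns so the filters have work to do):

```
INFO triplecall.pipeline: processed 60 columns: 42 DNA-only candidates,
32 triple-sample candidates, 4 final calls (2 somatic, 2 germline), 70 rejected
```

`calls.vcf` then contains one record per candidate; passing somatic records
carry the classification in INFO, for example

```
chr1  38  .  T  A  .  PASS  SS=somatic;ORIGIN=DOM;LABEL=DNA_only  GT:DP:AD:AF:BQ:MQ  0/0:16:16,0:0.0000:.:30.1  0/1:20:14,6:0.3000:35.5:30.0  ./.:...
```

meaning: at position 38 a T→A somatic mutation was called by the DNA-only
path — 6 of 20 tumor-DNA reads carry the allele (30% VAF, average alt base
quality 35.5) against a clean 16-read normal — with per-sample depth
(`DP`), ref/alt allele depths (`AD`), allele fraction (`AF`) and average
base/mapping qualities (`BQ`/`MQ`) for the normal DNA, tumor DNA and tumor
RNA columns. Rejected
candidates appear with their failed filters in the FILTER column (pass
`--pass-only` to suppress them), which is what `triplecall report`
tabulates.

A library-level example of the reporting convention used in MAF-style
summaries — the integer VAF percentage for a mutation supported by 31 of
34 RNA reads:

```pycon
>>> from triplecall import format_vaf_percent
>>> format_vaf_percent(31, 34)
91
```

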