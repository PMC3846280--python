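# ple-scout

Structural annotation of *Penelope*-like retroelements (PLEs), for people
who study transposable elements in assembled genomes and need the unusual
anatomy of these elements called automatically rather than by eye.

PLEs are retroelements related to telomerase reverse transcriptases. An
EN+ element carries a single ORF (reverse transcriptase plus a GIY-YIG
endonuclease) bounded by **pseudo-LTRs** (pLTRs) — terminal repeats that,
unlike true LTRs, occur in direct *and* inverted arrangements, may overlap
the ORF start, and optionally carry a short 3′ "tail" extension. Insertion
duplicates 8–10 bp of target sequence (a TSD); decayed copies instead show
microhomology-mediated junctions and deletions. Some families carry long
in-frame inserts of several hundred residues with 25–30% asparagine, and
elements can mobilise intron-containing host genes *in trans* when a
cassette is framed by pLTRs — an event proven by finding the allelic
"empty site" with the would-be TSD present exactly once.

`ple-scout` implements detectors for each of these signatures:

| module | what it does |
| --- | --- |
| `locus_forge` | seeded synthetic PLE loci, allelic pairs, capture loci and small-RNA libraries with exact ground truth |
| `repeat_annotator` | terminal-repeat pairs by seed-and-extend; arrangement, overlap, truncation, tail |
| `junction_annotator` | TSDs, junction microhomology, (near-)palindromes, TATA/Inr promoter motifs |
| `orf_annotator` | six-frame ORFs, defect calls vs a family reference, GIY-YIG and Cys-motif scans, N-rich segments, (AAY)ₙ bias |
| `capture_detector` | pLTR-framed cassettes, empty-site verification, solo-pLTR labels, anchored p-distance |
| `family_classifier` | 1/3-coverage inclusion rule, distance matrices, nested single-linkage families, neighbor-joining trees |
| `smallrna_profiler` | read mapping with fractional multi-mapper weights, windowed sense/antisense polarity, polarity switches, counts per kb |
| `pipeline_io` | FASTA/GFF3/TSV/JSON, config, the end-to-end `annotate` pipeline and the `ple-scout` CLI |

Key quantities, in the field's notation: per-window polarity index
`(sense − antisense) / (sense + antisense)`; anchored p-distance
(mismatches over aligned columns between chained unique k-mer anchors);
pLTR ORF codon coverage `⌊(ORF bases in unit + tail)/3⌋`.

## Worked example

Forge a canonical Pen2a-type locus — an 842-aa ORF bounded by two 218-bp
direct pLTRs plus a truncated 5′ inverted pLTR, a 31-bp tail and a 9-bp
TSD — then annotate it back:

```python
from plescout import LocusSpec, forge_locus, annotate

seq, truth = forge_locus(LocusSpec(seed=1), "pen2a")
bundle = annotate(seq, "pen2a")
print(bundle.pltr.arrangement_label,
      [u.unit_len for u in bundle.pltr.units],
      bundle.pltr.overlap_5p, bundle.pltr.truncation_5p,
      bundle.pltr.tail_len, bundle.junction.tsd.length)
```

prints

```
DD_plus_inverted5p [181, 218, 218] 15 37 31 9
```

that is: the direct-direct-plus-inverted-5′ arrangement with full 218-bp
units, a 181-bp inverted unit (37 bp shorter) overlapping the adjacent
direct unit by 15 bp, a 31-bp tail, and a 9-bp target-site duplication —
the annotation recovers every planted structural parameter exactly.

The same from the shell:

```bash
ple-scout forge --spec demo.yaml --out forged/ --seed 1
ple-scout annotate forged/loci.fasta --out annotated/
ple-scout smallrna element.fasta --n-reads 10000 --seed 1 --out srna/
```

`annotate` writes per-locus GFF3 plus TSV/JSON reports; `smallrna` writes
the windowed sense/antisense coverage table and plot and prints the
antisense fraction, counts per kb and any polarity switches. Every
threshold lives in one config file (`docs/example_config.yaml`,
`ple-scout config`).

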