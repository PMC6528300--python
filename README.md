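# plastann

Reference-based batch annotation of plastid genomes (plastomes).

Plastomes of photosynthetic seed plants are highly conserved: ~120–160 kb,
usually circular, with a quadripartite layout — a large and a small
single-copy region separated by two identical inverted repeats (IRa/IRb) —
and a near-fixed set of 101–118 genes. High-throughput sequencing produces
plastome assemblies far faster than they can be annotated by hand, and
mis-placed start codons, intron boundaries and unflagged pseudogenes are the
typical residue of automated transfer. `plastann` is for researchers who
have new plastome assemblies (FASTA) and at least one well-annotated
relative (GenBank) and want accurate, checkable annotations in batch.

## Method

The core idea is a **reverse query–subject search**: the annotated
*reference* genes are the query and the unannotated *target* plastome is the
subject, so the program searches for a fixed, known gene set instead of
asking what an anonymous contig contains.

1. **Reference database** — gene/CDS/tRNA/rRNA features are extracted from
   the reference GenBank files into four components: RNA nucleotides, PCG
   (protein-coding gene) nucleotides, CDS amino acids without introns, and
   CDS amino acids with introns. CDS are translated with the plastid /
   bacterial genetic code (table 11).
2. **Search** — nucleotide search locates rRNA/tRNA genes; translated
   (six-frame) protein search locates PCGs. With several references, the
   entry with the highest percent identity wins per gene; PCGs below a
   configurable identity threshold (default 40%) are skipped and logged.
   HSPs are clustered per gene copy, so IR-duplicated genes are annotated
   twice, independently.
3. **Gene boundaries (GBDA)** — the stop codon is the first in-frame stop
   scanning from the HSP; the start codon comes from a four-step cascade:
   (a) the HSP begins with methionine; (b) the in-frame ATG closest to the
   first upstream stop; (c) a sliding 4-residue probe from the reference
   N-terminus, which also recovers non-ATG starts (ACG, GTG, ...); (d) the
   HSP 5′ end, flagged for manual checking. rRNA and intron-free tRNA
   termini are anchored by sliding 9-nt probes from the reference gene ends.
4. **Intron boundaries (IBDA)** — the inter-HSP region is an intron if it
   contains an in-frame stop or its length is not a multiple of three;
   otherwise the intron has been lost and the joined exons become a single
   CDS (logged). Exon–intron boundaries are placed by the same sliding-probe
   machinery plus split-codon arithmetic: the exon-2 boundary moves left of
   the first located codon by `len(reference exon 2) mod 3` nucleotides.
   The short first exons of *rpl16*, *petB* and *petD* (6–9 nt, invisible to
   any similarity search) are recovered by an exact probe search upstream of
   exon 2.
5. **IR detection** — a self-search of the target against its own reverse
   complement; the longest non-overlapping reverse pair of at least
   `--ir-minlen` (default 1000) becomes IRa/IRb.
6. **QC and output** — query coverage (annotated length / reference length)
   outside (0.5, 2) flags putative pseudogenes. Output is one GenBank file
   per target plus a consolidated `warning.log` with per-target statistics:
   total reference genes, total annotated, and every reference gene not
   annotated.

Two search backends implement one contract: a deterministic in-process
seed-and-extend aligner (default) and an adapter for NCBI BLAST+
(`--backend external`, requires `blastn`/`tblastn` on PATH).

## Worked example

Generate a synthetic reference/target pair and annotate it:

```sh
plastann simulate --seed 1 -o demo/fx
mkdir -p demo/refs demo/targets
cp demo/fx/reference.gb demo/refs/
cp demo/fx/target.fasta demo/targets/
plastann annotate -r demo/refs -t demo/targets -o demo/out
tail -n 5 demo/out/warning.log
```

which prints (for this seed):

```
=== target: target_fixture_1 ===
inverted repeat: IRa 9398..12397, IRb 13092..16091 (3000 nt, 100.0% identity)
total number of genes in the reference plastome(s): 18
total number of genes annotated: 21
genes not annotated: none
```

18 unique reference genes produced 21 annotated gene copies — the three
genes inside the 3 kb inverted repeat (two rRNAs and a tRNA) are each
annotated once per IR copy. An empty "genes not annotated" line plus no
warnings means every gene transferred cleanly; intron losses, non-ATG
starts, low-identity skips and coverage flags would each appear as a
`warning [...]` line above the statistics block.

The same works on real data: put annotated GenBank relatives in `-r`,
FASTA assemblies (one sequence per file) in `-t`. Every feature in a
reference must carry a `/gene` qualifier; `plastann.validate_reference`
reports features that do not. For highly incomplete plastomes or plastome
fragments, align the fragment to a reference first (e.g. with
progressiveMauve) and annotate against the homologous reference block —
searching a complete reference against a fragment invites spurious hits for
genes that were never sequenced.

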