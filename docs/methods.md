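# Methods

This note documents the models, algorithms and numerical choices behind
`plastann`, and what the synthetic test surface does and does not show.

## The annotation model

Annotation is treated as homology transfer under three assumptions that hold
broadly for photosynthetic-seed-plant plastomes: (i) gene content is nearly
fixed, so searching for the reference's gene set is sound; (ii) gene order
and orientation may differ, so every gene is located independently; (iii)
coding sequences keep their reading frame, so codon-level arithmetic
(start/stop scanning, split codons) can refine alignment-level coordinates.

The search is reverse query–subject: reference genes (query) against the
target (subject). This inverts the usual orientation and is what makes a
fixed gene inventory — and the "genes not annotated" accounting in the log —
possible.

All coordinates are 0-based half-open internally; conversion to GenBank's
1-based inclusive convention happens only at file boundaries. Boundary
algorithms operate on the coding-strand-oriented sequence; results are
mapped back to the forward axis when annotations are assembled.

## Search layer

Two backends satisfy one contract (`search_nucleotide`, `search_protein`
returning HSPs):

* **builtin** (default): exact k-mer seeds (11 nt; 4 aa on the six-frame
  translation), grouped per diagonal and strand/frame, ungapped X-drop
  extension, identity measured over the full clustered span. Scoring is
  match +1 / mismatch −2 with X-drop 6: the steep penalty stops extensions
  from drifting into introns or spacers on chance matches. Seed runs are
  split at query gaps above 60 units, and gaps above 30 nt / 25 aa are
  bridged only if the intervening diagonal keeps ≥ 40% identity — an
  isolated chance seed then forms its own sub-threshold run instead of
  stretching a real alignment. The aligner is substitution-aware but
  gap-free; it is intended for targets within a few percent divergence of a
  reference and for fully deterministic tests.
* **external**: NCBI BLAST+ (`blastn -task blastn`, `tblastn -db_gencode
  11`), tabular output mapped onto the internal convention. Use it for
  distant references, where gapped alignment matters.

Best-hit selection keeps, per gene, the reference entry whose best HSP has
the highest percent identity (ties: longer alignment, then input order).
Surviving HSPs are pruned (≥ 60% of the best identity), clustered by strand
and proximity (≤ 10 kb for intron genes; about twice the gene length for
intron-free genes), chained into the best collinear subset per cluster, and
clusters scoring < 50% of the gene's best cluster are dropped. IR-duplicated
genes yield two equal clusters and are annotated per copy. A cluster must
cover ≥ 25% of its query (or ≥ 30 aligned units) to count as found — a
lone spurious seed match is not a gene. The PCG threshold decision uses
the aligned-length-weighted identity of the best cluster, so a short frayed
fragment cannot outvote the alignment body.

The builtin defaults (k-mer sizes, scoring, gap and pruning fractions) are
internal to the aligner, chosen for the ~0–5% divergence regime, and are
deliberately not part of the public configuration surface.

## Boundary detection

**Stop codon**: first in-frame stop scanning downstream; for intron genes
the scan starts at the annotated first codon of the last exon rather than
the raw HSP end, which is equivalent on clean input but robust to a few
residues of alignment fray. A premature in-frame stop is returned as found
(the rule as specified), with a warning when it falls inside the HSP.

**Start codon** (cascade; first applicable wins): (a) HSP begins with M;
(b) in-frame ATGs between the first upstream in-frame stop and the 20th HSP
residue — closest to the stop wins (smallest coordinate; in-frame ties are
impossible); (c) 4-residue probes `ref_aa[k:k+4]`, k = 0..16, scanned
right-to-left over the translated region; the first matching probe's
position shifted left by k codons is the start, candidates landing before
the upstream stop are rejected, and among candidates the one closest to the
stop wins. Non-ATG codons are annotated verbatim (ACG, GTG, ...) and
flagged; (d) the HSP 5′ end, flagged. Strategies (c) and (d) always add a
manual-verification warning to the log.

**RNA termini**: 9-nt probes cut from the terminal 30 nt of the reference
gene, sliding inward (offsets 0..21), searched in the 30 nt of the HSP end
plus a 30 nt outside flank; the boundary is the match shifted outward by the
probe offset, the candidate closest to the HSP end winning. No match keeps
the HSP end with a warning.

**Introns**: between two consecutive HSPs of one gene copy, the intron is
present iff the strictly-between region has an in-frame stop (frame
continued from HSP1) or a length ≢ 0 (mod 3); an empty or clean in-frame
region means intron loss, and the exons are joined into a single CDS with a
log entry. Exon-2 starts are found by the strategy-(c) probe machinery
against the reference exon-2 peptide, then moved left by the split-codon
count `len(ref exon 2) mod 3`. The exon-1/intron boundary uses the mirrored
construction: probes from the exon-1 C-terminus sliding upstream, region
from 20 residues inside HSP1 to the first downstream in-frame stop, scanned
left-to-right, candidate closest to that stop, then moved right by
`len(ref exon 1) mod 3`. The mirror is this package's symmetric reading of
"the same process"; the identity `(len e1 + len e2) ≡ 0 (mod 3)` is checked
and warned on violation. Genes with more than two exons are handled by
applying the two-HSP procedure to consecutive HSP pairs. Overlapping HSPs
(possible with gapped hits) are trimmed in codon steps, not rejected.

Intron tRNAs use the 9-nt probe variant on all four exon ends (terminal
30 nt of each reference exon, HSP end ± 30 nt), and a frame-free loss rule:
subject gap < 10 nt with abutting query coordinates, or a single HSP
covering at least 10 nt on both sides of the exon junction.

**Short first exons** (rpl16/petB/petD-like): any reference intron CDS whose
first exon is ≤ 12 nt triggers the rescue — these exons are too short for
any seeded search, but are nearly invariant across angiosperms, so the
reference exon-1 sequence is matched exactly (optionally with 1 mismatch)
within 2,000 nt upstream of the located exon 2 on the coding strand; the
match closest to exon 2 wins; absence is logged and the gene is annotated
exon-2-only. The combined frame (exon 1 + exon 2 through the stop) is
checked and warned on violation. The 2,000 nt window is a configurable
default covering the intron lengths seen in these genes.

## IR detection and coverage QC

The IR pair comes from an in-process self-search of the sequence against its
reverse complement (17-nt seeds, X-drop 20, so near-identical IRs are
tolerated): the longest non-overlapping pair of reverse-strand self-matches
of length ≥ `min_ir_length` (default 1000, the single adjustable parameter)
is reported as IRa/IRb; ties go to higher identity, then leftmost.
Palindromic self-overlapping hits are discarded. The two inter-IR regions
become LSC (larger) and SSC (smaller). With the circular flag the search
runs on the doubled sequence and intervals are normalized modulo the length,
making detection rotation-invariant. Boundaries of near-identical (not
exact) IRs are taken from the self-hit endpoints without polishing.

Query coverage = annotated length / reference length (exon sums on both
sides). Coverages strictly below 0.5 or strictly above 2 are flagged
(boundary-equal values pass); both thresholds are user-adjustable, because
pseudogene decay varies enormously between lineages and a poorly chosen
band simply misses them.

## The log contract

Per target the log records: typed warnings (low-identity skips with the
identity value, non-ATG starts, strategy-(c)/(d) starts, intron losses,
probe fallbacks, runaway ORFs, missing short first exons, coverage flags),
the IR coordinates, and three statistics lines — total unique gene names in
the reference(s), total annotated gene copies (IR duplicates count
separately; the convention is printed in the log header), and the names of
reference genes not annotated. Gene accounting is closed: annotated ∪
skipped ∪ missing covers every reference gene name. The annotation path is
randomness-free; reruns are byte-identical.

## Synthetic fixtures

The generator (`plastann.simulate`) builds a miniature plastome with the
quadripartite layout: ~36% GC, single-copy regions with protein-coding
genes (300–660 nt; intron genes 450–780 nt with 80–300 nt introns), tRNAs
(70–90 nt; intron tRNAs with 40–60 nt exons), and rRNAs (400–700 nt)
duplicated inside an exactly-mirrored IR (default 3 kb). Sizes are scaled
roughly 10× below real plastomes so a full pipeline run takes tens of
milliseconds; the gene-structure grammar (frames, split codons, strand
mixture, IR duplication) is real-scale. Introns are stop-rich in the exon
frame by default, so intron detection exercises the stop-codon criterion;
the `frame_shift` style generates stop-free introns with length ≢ 0 (mod 3)
to exercise the mod-3 criterion alone. Internal ATGs are excluded from the
first 20 codons of generated CDS so the start-cascade fixtures stay
unambiguous under every perturbation.

The target is the reference mutated at a per-site substitution rate plus at
most one structured perturbation per gene (intron loss, ACG start, start
shifted to a planted upstream ATG, 70% truncation, full deletion, codon
scramble to ~27% amino-acid identity, or an rpl16-like short-exon-1 gene
whose 9 nt exon is divergence-protected, mirroring its real conservation).
Each gene copy carries a truth record (coordinates, strand, intron status,
expected outcome class), and `score_against_truth` computes the
missing/wrong/wrong-boundary/correct counts at gene level (single-exon
genes: MG/WG/WGB/CG) and exon level (intron genes: ME/WE/WEB/CE).

What passing these tests shows: coordinate-exact transfer under the
plastome grammar, correct split-codon arithmetic, correct classification of
the perturbation classes at ~2% divergence — the within-genus regime the
tool targets. What they do not show: behaviour with indels (the fixtures
are substitution-only; use the external backend for real diverged data),
RNA editing, trans-splicing (rps12), assembly errors, or origin-spanning
genes on circular assemblies (unsupported; rotate the assembly so no gene
crosses the origin).

## Problem sizes and determinism

The shipped test suite and the acceptance script use 20 divergence-free
fixtures for the self-annotation property, 60 single-perturbation fixtures
at 2% divergence for recovery rates, and 50+ intron genes for the
split-codon oracle — sizes chosen so the whole surface re-runs in seconds
while every algorithm branch is exercised. All randomness lives in the
fixture generator and derives from explicit seeds; the annotation path
itself is deterministic.

## Known limitations

* The builtin aligner is ungapped; indel-rich divergence degrades HSP ends
  (boundary probes absorb small errors, but use BLAST+ beyond a few percent
  divergence).
* The mirrored exon-1 boundary rule can, rarely (< 0.5% of intron genes in
  the sweeps), pick a one-codon-shifted boundary when the exon's C-terminal
  residues are periodic and the flanking intron codon coincides; the
  annotation then carries a boundary warning.
* The stop-scan rule returns premature stops for pseudogene-like inputs by
  design; the coverage QC is the intended safety net.
* One sequence per target file; plastome fragments should be annotated
  against the homologous reference block only.
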