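# homeolocus

Isolate subgenome-specific (locus-specific) sequences from allopolyploid
genomes and design genome-specific PCR assays.

## The problem

In an allopolyploid such as bread wheat (subgenomes A, B and D), every
gene typically exists as two or more *homoeologs* — highly similar
copies on different subgenomes.  A PCR primer designed naively against
one copy amplifies all of them, which defeats locus-specific marker
development, chromosome assignment and homoeolog-specific expression
assays.  The copies do, however, carry *diagnostic* polymorphisms:
alignment positions where one subgenome differs from all the others
(which agree).  Primers anchored on two or more such positions — with at
least one diagnostic base in the 3′-terminal 3 nt of each primer —
amplify a single subgenome's copy only.

`homeolocus` implements the complete computational workflow:

1. **Homology search** — query CDS (e.g. from a diploid relative)
   against polyploid genome contigs; either a built-in seed-and-extend
   local aligner (exact 11-mer seeds, X-drop/gapped Smith–Waterman
   extension, Karlin–Altschul E-values `E = K·m·n·e^(−λS)`) or imported
   BLAST `outfmt 6` tables.  Hits are filtered to the top 10 subjects
   per query at `E ≤ 10⁻⁵`.
2. **Locus building** — HSPs are chained into gene loci by dynamic
   programming under gene-structure constraints: per-HSP subject length
   ≥ 200 bp (minimum exon), subject gap between consecutive blocks
   ≤ 5,000 bp (maximum intron), strand-aware colinearity.  Each locus is
   extracted as genomic sequence (introns retained) with 300 bp of 5′
   and 3′ flank, clipped at contig ends.
3. **Homoeolog alignment** — per-query progressive multiple alignment
   (k-mer distances → UPGMA guide tree → affine-gap Gotoh profile
   merging), plus Gblocks-style conserved-block trimming for
   conserved-region discovery.  Alignments are written as aligned FASTA
   and as browser-readable `.htm` reports with diagnostic bases
   highlighted.
4. **Assay design** — diagnostic SNP/indel calling, genome-specific
   primer pairs (Tm 50–70 °C, GC 0.3–0.7, length 18–27 nt, product
   80–1,500 bp, ≥ 2 diagnostic columns per pair, 3′-anchored), fully
   conserved regions for RT-qPCR, and CAPS marker discovery (restriction
   sites created/destroyed by SNPs, with predicted digest patterns).
5. **In-silico validation** — predicted PCR products on all homoeologous
   templates (≤ 2 mismatches, 3′-terminal 3 nt exact), the computational
   analog of scoring marker presence/absence across nulli-tetrasomic
   aneuploid lines.

A synthetic-data module generates allopolyploid fixtures with full
ground truth (ancestral exon/intron structures, independently diverged
subgenome copies, planted diagnostic mutations), so the whole pipeline
is testable without any genome download.

## Worked example

```python
from homeolocus.synthetic import SimConfig, simulate
from homeolocus.pipeline import run_pipeline
from homeolocus.polymorphism import insilico_pcr

queries, contigs, truth = simulate(SimConfig(n_genes=3, seed=11))
results, manifest = run_pipeline(queries, contigs)
print(manifest.counts)

r = results[0]
row = r.msa.row_ids[0]          # one homoeolog row, e.g. the D copy
pair = r.primer_pairs[row][0]   # top-ranked genome-specific pair
print(pair.forward.seq, pair.reverse.seq, pair.product_len)
templates = [c for c in contigs if c.id.startswith("gene000")]
print(insilico_pcr(pair, templates))
```

prints

```
{'queries': 3, 'with_hits': 3, 'with_alignments': 3, 'with_primers': 3}
GTCAGCGTCTACTAGCGTTGC AATTCTGTTAGGCGGCCGCCA 464
[('gene000_D', (517, 981), 464)]
```

All three simulated genes pass every stage of the funnel; the top pair
for the D-subgenome copy of `gene000` (forward/reverse primers with
balanced Tm ≈ 56 °C, covering 4 diagnostic columns) amplifies a single
464 bp product from the D contig and nothing from the homoeologous A and
B contigs — a genome-specific assay.

The same workflow is available from the shell:

```bash
homeolocus simulate --out-dir fix/ --seed 11 --n-genes 3
homeolocus pipeline --query fix/queries.fa --genome fix/genome.fa --out-dir run/
homeolocus caps --allele-a a.fa --allele-b b.fa --out caps.tsv
```

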