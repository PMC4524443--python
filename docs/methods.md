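# Methods

This note documents the models, algorithms and numerical choices behind
`homeolocus`, and what the synthetic experiments do and do not show.

## Homology search

The built-in search is a seed-and-extend local aligner in the blastn
mould, made deliberately pluggable: users with real BLAST output import
12-column tabular hits instead, and everything downstream is identical.

* **Seeding.** Exact shared 11-mers (the blastn default word size), no
  low-complexity masking.  The subject set is indexed once
  (`SubjectIndex`) so thousands of queries can be searched against one
  genome.  Both query strands are searched; minus-strand hits keep the
  subject interval on the plus strand with a strand flag, so downstream
  chaining always sees sortable intervals.
* **Extension.** Seeds are greedily clustered by subject proximity
  (≤ 60 bp gaps) and diagonal drift (≤ 25 bp, allowing short indels);
  each cluster is refined by a full affine-gap Smith–Waterman on a
  padded window.  If the local optimum touches a window edge the window
  is grown (×4, up to three times) and the alignment recomputed, so
  mutation clusters that leave a seedless stretch at an exon end cannot
  truncate the HSP.  Overlapping extensions on one subject region keep
  the highest raw score.
* **Scoring.** match +2, mismatch −3, gap existence 5, gap extension 2
  per base (a gap of length L costs 5 + 2L).  Ambiguity codes (N etc.)
  mismatch everything, including themselves.  Bit scores use fixed
  Karlin–Altschul parameters λ = 0.625, K = 0.41, and
  `E = K·m·n·e^(−λS)` with m the query length and n the total subject
  length.  These constants approximate ungapped blastn defaults; they
  are configurable and only the *ordering* of hits matters downstream.
* **Filtering.** E ≤ 10⁻⁵; subjects ranked by best bit score; top 10
  subject sequences kept (the `num_alignments` semantics — 10 subject
  sequences, not 10 HSPs).

## Locus building

HSPs of one (query, subject, strand) group are chained by an O(n²)
dynamic program maximizing summed raw score subject to:

* per-HSP subject length ≥ `min_exon` (200 bp), applied before chaining;
* subject gap between consecutive blocks in (0, `max_intron` = 5,000 bp];
* colinearity: query order matches subject order (reversed for minus
  strand), with up to 30 bp of query overlap tolerated between
  consecutive blocks — gapped extension routinely overruns an exon
  boundary by a few bases and would otherwise split true chains.
  Colinearity can be disabled (`colinear=False`) to merge all nearby
  HSPs regardless of query order.

Ties break toward fewer blocks, then leftmost subject start, so output
is deterministic.  The best chain is extracted, its members removed,
and the process repeats; secondary chains whose span overlaps an
accepted locus by more than 30% of their own span are discarded as
alternative alignments of the same region, so only span-disjoint chains
are reported as additional loci (paralogs).  The same span-disjointness
rule is applied across strands of one contig at the pipeline level.

Extraction is span-based — introns are retained, because primers are
designed on genomic sequence and intronic polymorphism is the richest
source of diagnostic sites.  Up to 300 bp of flank is added on each
side, clipped at contig boundaries; minus-strand loci are
reverse-complemented so every extracted record reads 5′→3′ of the gene.

## Multiple alignment

ClustalW-style progressive alignment: pairwise distances are k-mer set
distances (k = 6, `1 − |shared| / |smaller|`), adequate for the
near-identical homoeolog regime and avoiding quadratic DP at the tree
stage; the guide tree is UPGMA with deterministic tie-breaking by row
index; profiles are merged post-order.

Profile columns are frequency vectors over {A, C, G, T, N, −}; the
column-pair score is the sum-of-pairs average `fᵀ·S·g`, where S scores
base pairs match/mismatch, N mismatches everything, and the gap symbol
contributes zero (gap placement is priced only by the affine
penalties).  With single-sequence profiles this reduces exactly to
pairwise global Gotoh, which is what `pairwise_align_global` exposes
and what the brute-force oracle tests check.  "Once a gap, always a
gap" holds by construction.

The DP kernels are numba-compiled with rolling rows (only the uint8
traceback matrix is quadratic in memory).  Profile merges of sequences
longer than 1,500 columns use a diagonal band of ±120 columns plus the
length difference: at ≤ 2% divergence and ≤ 10 bp indels the optimal
path drifts far less than that, and small instances always run the full
matrix, so the oracle-equivalence tests are unaffected by banding.

### Conserved-block selection

A Gblocks-like model with four knobs: a column is conserved when its
most frequent residue exceeds `conserved_frac` (default 0.5, strict
majority); gap columns always break a block (`allow_gap_cols="none"`,
default) or only majority-gap columns do (`"with_half"`); non-conserved
runs longer than `max_nonconserved_run` (8) break a block; flanks are
trimmed to conserved columns and blocks shorter than `min_block_len`
(10) are dropped.  Exact Gblocks IS/FS thresholds are not reproduced.

Block filtering is used for conserved-region (qPCR) discovery only.
Diagnostic-site scanning runs on the *untrimmed* alignment: trimming
would delete exactly the subgenome-specific indels the pipeline exists
to find.

## Diagnostic sites and assay design

A column is diagnostic for a target row iff the target's state differs
from every other row *and* the other rows agree (strict background; a
relaxed mode requiring only target-vs-each is available).  Columns with
N/ambiguity anywhere are skipped.  Columns under any row's leading or
trailing gap run are also skipped: extracted loci differ by a few bases
at their ends, and a terminal overhang is missing data, not
polymorphism.  Contiguous diagnostic gap columns collapse into a single
indel site — one mutational event, one discriminating feature.

Genome-specific primer pairs require:

* each primer to carry ≥ 1 diagnostic base within its 3′-terminal 3 nt
  (the standard allele-specific anchoring mechanism — single internal
  SNPs do not reliably block extension on the wrong template);
* ≥ 2 distinct diagnostic columns per pair in total;
* length 18–27 nt, GC 0.3–0.7, Tm 50–70 °C with ≤ 5 °C between the two
  primers, product 80–1,500 bp.

Tm is the Wallace rule `2(A+T) + 4(G+C)` below 14 nt and the GC formula
`64.9 + 41·(G+C − 16.4)/N` at ≥ 14 nt — closed-form and
dependency-free; nearest-neighbour thermodynamics, secondary-structure
screening and dCAPS mismatch-primer engineering are out of scope.
Pairs are ranked by diagnostic coverage, then Tm balance, then product
length; ordering is fully deterministic.

In-silico PCR reports a product wherever two binding sites face each
other convergently within 5,000 bp; binding tolerates ≤ 2 mismatches
overall and none in the 3′-terminal 3 nt, emulating
stringent-but-realistic annealing.  Either primer may play either role
and both template strands are enumerated.  Specificity of a designed
pair is judged by amplifying its own gene's homoeologous contigs: a
specific pair yields products from the target subgenome's contig only —
the desk version of typing nulli-tetrasomic lines, where absence of a
product from the line lacking chromosome X assigns the marker to X.

## CAPS markers

Two allele sequences are globally aligned; for every SNP column and
catalog enzyme, a candidate is reported when a recognition-site match
overlapping the SNP exists in exactly one allele.  Site matching is
IUPAC-aware on both strands; palindromic sites are single recognition
events cut at the top-strand offset, non-palindromic sites are also
scanned as their reverse complement with the mirrored offset.
Candidates whose differential fragments fall below `min_frag` (default
50 bp — a proxy for 3% agarose resolution) or whose digest patterns do
not differ are dropped; the rest are ranked by separability, the
worst-case gel distance between a differential fragment and its nearest
neighbour in the other allele's pattern (a heuristic of ours; no
standard exists).  A curated catalog of 25 common enzymes ships with
the package and can be replaced by a `name<TAB>site<TAB>offset` file.

## The synthetic model

Each gene is an ancestral structure of 1–5 exons (200–600 bp) separated
by introns of 60–4,800 bp, embedded in an ancestral region with 500 bp
of flanking sequence on each side.  The whole region diverges
independently into k subgenome copies (star phylogeny): substitutions
at 2%/base, indels at 0.1%/base of 1–10 bp.  Flanks mutate with the
gene, as real homoeologous flanks do — unrelated random flanks would
make flank alignment meaningless.  Each copy lands in its own contig on
a random strand.  The query set is the ancestral CDS (the
diploid-relative proxy).  Defaults keep every simulated exon above the
200 bp filter and every intron below the 5,000 bp limit, so true gene
structures are chainable — the estimation problem is parameter
recovery, not model mismatch.

Four diagnostic substitutions per subgenome per gene are *planted* in
exons, ≥ 30 bp apart, with the other subgenomes pinned to the ancestral
base, guaranteeing primer design is well-posed for every gene; the
count-based knob replaces a fraction for clarity.  Ground-truth
diagnostic sites are derived from the true alignment induced by the
event logs — every column where exactly one copy differs and the rest
agree, planted or not — and mapped exactly onto contig coordinates.
Truth sites outside the extractable window (locus span ± 300 bp flank,
with a 50 bp margin for end trimming) are marked unobservable: recall
is scored over observable sites only, while calls are matched against
all sites, so the window choice cannot manufacture precision.

Scoring tolerances: SNP calls must match truth positions exactly; indel
calls match within ± 6 bp, because equivalent gap placements inside
repeats legitimately shift the reported coordinate.

What the simulator does **not** model: repeat content and transposons,
homoeologous exchange and gene conversion, tree-shaped (A,B)–D
divergence, sequencing error, and assembly fragmentation.  Passing
tests therefore demonstrate correctness of the algorithms under clean
homoeology, not robustness to wheat-scale repeat structure; on real
data the search stage is expected to be driven by actual BLAST output
via the tabular import path.

## Problem sizes

The survey-scale experiment used by the test suite and by
`scripts/acceptance.py` is 50 genes × 3 subgenomes (≈ 150 contigs,
≈ 1 Mb of genome) — large enough for stable rate estimates
(≈ 19,000 truth sites, ≈ 140 designed pairs) while a full run completes
in about a minute on one CPU.  Oracle-equivalence tests run exhaustive
enumeration at the sizes where it is exact and affordable: ≤ 8 HSPs per
chaining instance, sequence pairs ≤ 8 nt for global alignment, ≤ 2 kb
for the Smith–Waterman bound.

## Known limitations

* Karlin–Altschul parameters are fixed approximations, not fitted to
  the gapped scoring scheme; E-values are comparable within a run, not
  calibrated probabilities.
* The guide tree is k-mer/UPGMA only; no iterative refinement or
  consistency objective.  For ≤ 10 near-identical homoeologs this is
  immaterial.
* Raw scores for imported tabular hits are back-computed from bit
  scores under the default scheme, so chains over imported and internal
  hits are comparable only under that scheme.
* CAPS ranking and the `.htm` report layout are package conventions;
  no external standard defines them.
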