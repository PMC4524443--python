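"""Chaining HSPs into putative homoeologous gene loci and extracting
their genomic sequences with flanking regions.

The chaining rules mirror the original pipeline's coordinate-limiting
step: HSPs shorter than the minimum exon length (200 bp) are discarded,
and consecutive blocks of a chain may be separated by at most the
maximum intron length (5,000 bp) on the subject.  Chains are colinear
(query and subject order agree, strand-aware) and subject-disjoint.
Extraction is span-based — introns are retained — and adds up to 300 bp
of 5' and 3' flank, clipped at contig boundaries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

from .homology import Hsp
from .seqio import SeqRecord

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """Tunable parameters of the locus-isolation pipeline (defaults are
    the original search settings: 5,000/200/300 bp and 1e-5/10 hits)."""

    max_intron: int = 5000
    min_exon: int = 200
    flank: int = 300
    evalue_max: float = 1e-5
    max_hits: int = 10
    colinear: bool = True
    #: Adjacent exon HSPs may over-extend a few bases into the intron and
    #: re-match the start of the next exon on the query; chains tolerate
    #: this much query overlap between consecutive blocks.
    q_overlap_tol: int = 30

    def __post_init__(self) -> None:
        if min(self.max_intron, self.min_exon, self.flank, self.max_hits) <= 0:
            raise ValueError("pipeline parameters must be positive")
        if self.evalue_max <= 0:
            raise ValueError("evalue_max must be positive")


@dataclass(frozen=True)
class LocusModel:
    """A chained set of HSP blocks on one contig: one putative gene copy."""

    query_id: str
    subject_id: str
    strand: str
    blocks: tuple[tuple[int, int], ...]
    chain_score: int

    def __post_init__(self) -> None:
        if not self.blocks:
            raise ValueError("locus must contain >= 1 block")
        for (a0, a1), (b0, b1) in zip(self.blocks, self.blocks[1:]):
            if b0 < a1:
                raise ValueError("blocks must be sorted and non-overlapping")

    @property
    def span(self) -> tuple[int, int]:
        return (self.blocks[0][0], self.blocks[-1][1])


@dataclass(frozen=True)
class ExtractedLocus:
    """A locus' genomic sequence with flanks, oriented 5'->3' of the gene."""

    record: SeqRecord
    source_subject: str
    source_span: tuple[int, int]
    strand: str
    left_flank_len: int
    right_flank_len: int


def _compatible(prev: Hsp, nxt: Hsp, cfg: PipelineConfig) -> bool:
    """May ``nxt`` follow ``prev`` in a chain?  ``nxt`` starts after
    ``prev`` ends on the subject, within the intron limit, and — in
    colinear mode — the query intervals are disjoint and ordered
    consistently with the strand."""
    gap = nxt.s_interval[0] - prev.s_interval[1]
    if gap < 0 or gap > cfg.max_intron:
        return False
    if not cfg.colinear:
        return True
    tol = cfg.q_overlap_tol
    if prev.strand == "+":
        return prev.q_interval[1] - tol <= nxt.q_interval[0] and \
            prev.q_interval[0] < nxt.q_interval[0]
    return nxt.q_interval[1] - tol <= prev.q_interval[0] and \
        nxt.q_interval[0] < prev.q_interval[0]


def _best_chain(hsps: list[Hsp], cfg: PipelineConfig) -> list[int]:
    """Highest-scoring chain over ``hsps`` (already sorted by subject
    start).  Ties broken toward fewer blocks, then leftmost subject
    start.  Returns member indices in subject order."""
    n = len(hsps)
    # dp value: (score, -n_blocks); predecessor for traceback
    score = [h.raw_score for h in hsps]
    nblk = [1] * n
    pred = [-1] * n
    for i in range(n):
        for j in range(i):
            if hsps[j].s_interval[1] <= hsps[i].s_interval[0] and \
                    _compatible(hsps[j], hsps[i], cfg):
                cand = score[j] + hsps[i].raw_score
                if cand > score[i] or (
                    cand == score[i] and nblk[j] + 1 < nblk[i]
                ):
                    score[i] = cand
                    nblk[i] = nblk[j] + 1
                    pred[i] = j
    best = max(
        range(n),
        key=lambda i: (score[i], -nblk[i], -hsps[i].s_interval[0]),
    )
    chain = []
    while best != -1:
        chain.append(best)
        best = pred[best]
    return chain[::-1]


def chain_hsps(hsps: Sequence[Hsp], cfg: PipelineConfig | None = None) -> list[LocusModel]:
    """Chain the HSPs of one (query, subject, strand) group into loci.

    HSPs whose subject interval is shorter than ``cfg.min_exon`` are
    discarded first.  The best chain (dynamic programming, maximizing
    summed raw score under the intron/colinearity constraints) is
    extracted, its members removed, and the process repeats, so one
    contig can yield several loci (paralogs).
    """
    cfg = cfg or PipelineConfig()
    if not hsps:
        return []
    keys = {(h.query_id, h.subject_id, h.strand) for h in hsps}
    if len(keys) > 1:
        raise ValueError(
            "chain requires one query/subject/strand group, got "
            f"{sorted(keys)}"
        )
    pool = [h for h in hsps if h.s_len >= cfg.min_exon]
    pool.sort(key=lambda h: h.s_interval)
    loci: list[LocusModel] = []
    while pool:
        idx = _best_chain(pool, cfg)
        members = [pool[i] for i in idx]
        locus = LocusModel(
            query_id=members[0].query_id,
            subject_id=members[0].subject_id,
            strand=members[0].strand,
            blocks=tuple(h.s_interval for h in members),
            chain_score=sum(h.raw_score for h in members),
        )
        # Secondary chains whose span largely overlaps an accepted locus
        # are alternative alignments of the same region, not paralogs;
        # only span-disjoint chains are reported as further loci.
        if not any(_span_overlap(locus.span, l.span) > 0.3 * (locus.span[1] - locus.span[0])
                   for l in loci):
            loci.append(locus)
        chosen = set(idx)
        pool = [h for i, h in enumerate(pool) if i not in chosen]
    loci.sort(key=lambda l: (-l.chain_score, l.span))
    return loci


def _span_overlap(a: tuple[int, int], b: tuple[int, int]) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def extract_locus(
    locus: LocusModel, contig: SeqRecord, cfg: PipelineConfig | None = None
) -> ExtractedLocus:
    """Slice the locus span plus up to ``cfg.flank`` bp on each side from
    its contig; minus-strand loci are reverse-complemented so the record
    reads 5'->3' of the gene (flank labels swap accordingly)."""
    cfg = cfg or PipelineConfig()
    if locus.subject_id != contig.id:
        raise ValueError(
            f"locus/contig mismatch: {locus.subject_id!r} vs {contig.id!r}"
        )
    start, end = locus.span
    if start < 0 or end > len(contig):
        raise ValueError(
            f"locus/contig mismatch: span [{start},{end}) outside "
            f"contig of length {len(contig)}"
        )
    lo = max(0, start - cfg.flank)
    hi = min(len(contig), end + cfg.flank)
    left = start - lo
    right = hi - end
    seq = contig.seq[lo:hi]
    if locus.strand == "-":
        from .seqio import revcomp

        seq = revcomp(seq)
        left, right = right, left
    rec_id = f"{contig.id}:{lo}-{hi}({locus.strand})"
    return ExtractedLocus(
        record=SeqRecord(rec_id, seq, description=f"query={locus.query_id}"),
        source_subject=contig.id,
        source_span=(lo, hi),
        strand=locus.strand,
        left_flank_len=left,
        right_flank_len=right,
    )


def collect_homeolog_set(
    query: SeqRecord,
    loci: Sequence[ExtractedLocus],
    include_query: bool = False,
) -> list[SeqRecord]:
    """Assemble the per-query homoeolog set (one multi-FASTA per query).

    Record ids encode subject and span for provenance; duplicate
    (subject, span) loci are dropped with a warning.  The query CDS can
    optionally be prepended as a reference row.
    """
    if not loci:
        raise ValueError(f"no homoeologs retrieved for query {query.id!r}")
    out: list[SeqRecord] = []
    seen: set[tuple[str, tuple[int, int], str]] = set()
    if include_query:
        out.append(SeqRecord(query.id, query.seq, "query CDS"))
    for ex in loci:
        key = (ex.source_subject, ex.source_span, ex.strand)
        if key in seen:
            logger.warning(
                "duplicate locus %s:%s dropped for query %s",
                ex.source_subject, ex.source_span, query.id,
            )
            continue
        seen.add(key)
        out.append(ex.record)
    return out
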