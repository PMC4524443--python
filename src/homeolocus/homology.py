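"""Homology search: produce HSPs between query CDS and genome contigs.

The search stage is pluggable, matching how the original pipeline used an
external blastn run: hits can be imported from 12-column tabular files
(:func:`homeolocus.seqio.read_tabular_hits`), or computed by the built-in
seed-and-extend local aligner (:func:`find_hsps`) — exact shared k-mer
seeds, ungapped X-drop extension, then gapped Smith–Waterman refinement
of each seed cluster.  Either way the same hit-count and E-value filters
(:func:`filter_hits`) apply: at most 10 subject sequences per query and
E <= 1e-5 by default.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import _align
from .seqio import SeqRecord, revcomp


@dataclass(frozen=True)
class ScoringScheme:
    """blastn-like nucleotide scoring with fixed Karlin–Altschul parameters.

    A gap run of length L costs ``|gap_open| + |gap_extend| * L``
    (existence/extension convention).
    """

    match: int = 2
    mismatch: int = -3
    gap_open: int = -5
    gap_extend: int = -2
    karlin_lambda: float = 0.625
    karlin_k: float = 0.41

    def __post_init__(self) -> None:
        if self.match <= 0 or self.mismatch >= 0:
            raise ValueError("match must be > 0 and mismatch < 0")
        if self.gap_open >= 0 or self.gap_extend >= 0:
            raise ValueError("gap penalties must be negative")
        if self.karlin_lambda <= 0 or self.karlin_k <= 0:
            raise ValueError("Karlin parameters must be positive")

    def bitscore(self, raw_score: float) -> float:
        return (self.karlin_lambda * raw_score - math.log(self.karlin_k)) / math.log(2)

    def raw_from_bitscore(self, bits: float) -> int:
        return int(round((bits * math.log(2) + math.log(self.karlin_k))
                         / self.karlin_lambda))


DEFAULT_SCHEME = ScoringScheme()


@dataclass(frozen=True)
class Hsp:
    """One local-alignment hit (high-scoring segment pair).

    Intervals are 0-based half-open; ``s_interval`` is always on the
    subject plus strand with start < end.  ``strand == '-'`` means the
    query aligns to the reverse complement of that subject interval.
    """

    query_id: str
    subject_id: str
    q_interval: tuple[int, int]
    s_interval: tuple[int, int]
    strand: str
    identity: float
    aln_length: int
    raw_score: int
    bitscore: float
    evalue: float
    raw_score_known: bool = True

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"invalid strand {self.strand!r}")
        for lo, hi in (self.q_interval, self.s_interval):
            if not lo < hi:
                raise ValueError(f"empty or inverted interval [{lo},{hi})")
        if not 0.0 <= self.identity <= 1.0:
            raise ValueError("identity must be in [0,1]")
        if self.evalue < 0:
            raise ValueError("evalue must be >= 0")

    @property
    def q_len(self) -> int:
        return self.q_interval[1] - self.q_interval[0]

    @property
    def s_len(self) -> int:
        return self.s_interval[1] - self.s_interval[0]


def evalue(raw_score: int, m: int, n: int,
           scheme: ScoringScheme = DEFAULT_SCHEME) -> float:
    """Karlin–Altschul expectation ``E = K * m * n * exp(-lambda * S)``."""
    if m < 1 or n < 1:
        raise ValueError("search-space dimensions must be >= 1")
    return scheme.karlin_k * m * n * math.exp(-scheme.karlin_lambda * raw_score)


class SubjectIndex:
    """Exact k-mer index over a set of subject sequences.

    Built once per genome so that many queries can be searched without
    re-scanning the contigs (the paper's pipeline searched ~30k queries
    against one fixed CSS database).
    """

    def __init__(self, subjects: Sequence[SeqRecord], k: int = 11):
        if not subjects:
            raise ValueError("subjects must be nonempty")
        self.k = k
        self.subjects = list(subjects)
        self.total_length = sum(len(s) for s in subjects)
        self._index: dict[str, list[tuple[int, int]]] = defaultdict(list)
        for si, rec in enumerate(self.subjects):
            seq = rec.seq
            for p in range(len(seq) - k + 1):
                kmer = seq[p:p + k]
                if "N" not in kmer:
                    self._index[kmer].append((si, p))

    def seeds(self, query_seq: str):
        """Yield (subject_idx, q_pos, s_pos) for every shared exact k-mer."""
        k = self.k
        for qp in range(len(query_seq) - k + 1):
            hits = self._index.get(query_seq[qp:qp + k])
            if hits:
                for si, sp in hits:
                    yield si, qp, sp


def _cluster_seeds(seeds, max_gap: int = 60, max_diag_drift: int = 25):
    """Greedy grouping of (q,s) seeds into candidate exon-scale regions.

    Seeds are sorted by subject position; a seed joins the current cluster
    when it is nearby on the subject and on a similar diagonal (small
    drift allows for short indels).
    """
    seeds = sorted(seeds, key=lambda t: (t[1], t[0]))  # by s_pos then q_pos
    clusters: list[list[tuple[int, int]]] = []
    for qp, sp in seeds:
        placed = False
        for cl in reversed(clusters):
            lq, ls = cl[-1]
            if sp - ls > max_gap:
                break
            if abs((sp - qp) - (ls - lq)) <= max_diag_drift:
                cl.append((qp, sp))
                placed = True
                break
        if not placed:
            clusters.append([(qp, sp)])
    return clusters


def _extend_cluster(qcodes, scodes, cluster, k, scheme, pad: int = 48):
    """Gapped Smith–Waterman refinement of one seed cluster's window.

    The window is grown and the alignment recomputed whenever the local
    optimum touches a window edge (mutation clusters can leave a long
    seedless stretch at an exon end that the first window misses).
    """
    qlo = min(q for q, _ in cluster)
    qhi = max(q for q, _ in cluster) + k
    slo = min(s for _, s in cluster)
    shi = max(s for _, s in cluster) + k
    for _ in range(4):
        q0, q1 = max(0, qlo - pad), min(len(qcodes), qhi + pad)
        s0, s1 = max(0, slo - pad), min(len(scodes), shi + pad)
        score, a0, a1, b0, b1, n_ident, aln_len = _align.sw_local(
            qcodes[q0:q1], scodes[s0:s1],
            scheme.match, scheme.mismatch, -scheme.gap_open, -scheme.gap_extend,
        )
        if score <= 0 or aln_len == 0:
            return None
        at_edge = (
            (a0 == 0 and q0 > 0) or (q0 + a1 == q1 and q1 < len(qcodes))
            or (b0 == 0 and s0 > 0) or (s0 + b1 == s1 and s1 < len(scodes))
        )
        if not at_edge:
            break
        pad *= 4
    return score, (q0 + a0, q0 + a1), (s0 + b0, s0 + b1), n_ident, aln_len


def find_hsps(
    query: SeqRecord,
    subjects: Sequence[SeqRecord] | SubjectIndex,
    scheme: ScoringScheme = DEFAULT_SCHEME,
    seed_k: int = 11,
    min_raw_score: int = 30,
) -> list[Hsp]:
    """Seed-and-extend local search of one query against subject contigs.

    Both query strands are searched (the reverse complement of the query
    is scanned against the plus-strand index; its hits are reported with
    ``strand='-'`` and query coordinates mapped back to the input
    orientation).  Overlapping extensions on the same subject region and
    strand are deduplicated keeping the highest raw score.
    """
    if len(query) < seed_k:
        raise ValueError(
            f"query too short: {len(query)} < seed length {seed_k}"
        )
    if isinstance(subjects, SubjectIndex):
        index = subjects
        if index.k != seed_k:
            raise ValueError("index built with a different seed length")
    else:
        index = SubjectIndex(subjects, k=seed_k)

    m = len(query)
    n_total = index.total_length
    subject_codes = [_align.encode(rec.seq) for rec in index.subjects]
    hsps: list[Hsp] = []

    for strand in "+-":
        qseq = query.seq if strand == "+" else revcomp(query.seq)
        qcodes = _align.encode(qseq)
        per_subject: dict[int, list[tuple[int, int]]] = defaultdict(list)
        for si, qp, sp in index.seeds(qseq):
            per_subject[si].append((qp, sp))
        for si, seeds in per_subject.items():
            rec = index.subjects[si]
            covered: list[tuple[int, int, int]] = []  # (s0, s1, score)
            for cluster in _cluster_seeds(seeds):
                ext = _extend_cluster(qcodes, subject_codes[si], cluster,
                                      index.k, scheme)
                if ext is None:
                    continue
                score, (qa, qb), (sa, sb), n_ident, aln_len = ext
                if score < min_raw_score:
                    continue
                # dedupe: skip if an equal-or-better HSP already covers this
                # subject region
                dominated = False
                for cs0, cs1, csc in covered:
                    ov = min(sb, cs1) - max(sa, cs0)
                    if ov > 0.8 * (sb - sa) and csc >= score:
                        dominated = True
                        break
                if dominated:
                    continue
                covered.append((sa, sb, score))
                if strand == "+":
                    q_int = (qa, qb)
                else:
                    q_int = (m - qb, m - qa)
                ev = evalue(score, m, n_total, scheme)
                hsps.append(
                    Hsp(
                        query_id=query.id,
                        subject_id=rec.id,
                        q_interval=q_int,
                        s_interval=(sa, sb),
                        strand=strand,
                        identity=n_ident / aln_len,
                        aln_length=aln_len,
                        raw_score=int(score),
                        bitscore=scheme.bitscore(score),
                        evalue=ev,
                    )
                )
    hsps.sort(key=lambda h: (h.subject_id, h.s_interval, h.strand, -h.raw_score))
    # cross-cluster dedup: identical subject intervals from both strands of a
    # palindromic repeat keep only the best
    out: list[Hsp] = []
    for h in hsps:
        if out and out[-1].subject_id == h.subject_id \
                and out[-1].s_interval == h.s_interval \
                and out[-1].raw_score >= h.raw_score:
            continue
        out.append(h)
    out.sort(key=lambda h: h.evalue)
    return out


def filter_hits(
    hsps: Sequence[Hsp],
    max_hits: int = 10,
    evalue_max: float = 1e-5,
) -> list[Hsp]:
    """Apply the hit-count and E-value thresholds of the original search.

    HSPs above ``evalue_max`` are removed; the remaining HSPs are grouped
    by subject, subjects ranked by their best bitscore, and only the top
    ``max_hits`` subjects retained (all surviving HSPs of a retained
    subject are kept, in stable input order).
    """
    if not hsps:
        return []
    qids = {h.query_id for h in hsps}
    if len(qids) > 1:
        raise ValueError(f"filter requires a single query, got {sorted(qids)}")
    passing = [h for h in hsps if h.evalue <= evalue_max]
    best: dict[str, float] = {}
    order: dict[str, int] = {}
    for i, h in enumerate(passing):
        if h.subject_id not in best or h.bitscore > best[h.subject_id]:
            best[h.subject_id] = h.bitscore
        order.setdefault(h.subject_id, i)
    ranked = sorted(best, key=lambda s: (-best[s], order[s]))
    keep = set(ranked[:max_hits])
    return [h for h in passing if h.subject_id in keep]
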