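"""Progressive multiple alignment of homoeolog sets and conserved-block
selection.

The strategy is ClustalW-like: a k-mer distance matrix feeds a UPGMA
guide tree; profiles are merged post-order with an affine-gap Gotoh
aligner ("once a gap, always a gap").  Conserved-block filtering follows
the Gblocks model — gap-free, majority-conserved runs above a minimum
length, with short non-conserved stretches tolerated inside a block —
and is used for conserved-region (qPCR) discovery, not for
diagnostic-site scanning, which must keep subgenome-specific indels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import _align
from .homology import DEFAULT_SCHEME, ScoringScheme
from .loci import ExtractedLocus
from .seqio import AlignedSet, SeqRecord

# ---------------------------------------------------------------------------
# Guide tree
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TreeNode:
    """Node of a rooted UPGMA guide tree; leaves carry a record index."""

    height: float
    leaf: int | None = None
    children: tuple["TreeNode", ...] = ()

    def leaves(self) -> list[int]:
        if self.leaf is not None:
            return [self.leaf]
        out: list[int] = []
        for c in self.children:
            out.extend(c.leaves())
        return out


def kmer_distance_matrix(records: Sequence[SeqRecord], k: int = 6) -> np.ndarray:
    """Pairwise k-mer distance ``1 - |shared| / |smaller set|`` in [0, 1]."""
    if len(records) < 2:
        raise ValueError("need >= 2 records for a distance matrix")
    sets = []
    for rec in records:
        if len(rec) < k:
            raise ValueError(
                f"sequence too short for k-mer distance: {rec.id!r} "
                f"({len(rec)} < {k})"
            )
        sets.append({rec.seq[i:i + k] for i in range(len(rec) - k + 1)})
    n = len(records)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            shared = len(sets[i] & sets[j])
            smaller = min(len(sets[i]), len(sets[j]))
            d[i, j] = d[j, i] = 1.0 - shared / smaller
    return d


def build_guide_tree(dist: np.ndarray) -> TreeNode:
    """UPGMA agglomeration with deterministic tie-breaking by row index."""
    dist = np.asarray(dist, dtype=float)
    n = dist.shape[0]
    if dist.ndim != 2 or dist.shape[0] != dist.shape[1] or n < 2 \
            or not np.allclose(dist, dist.T) or np.any(np.diag(dist) != 0):
        raise ValueError("invalid distance matrix")
    nodes: dict[int, TreeNode] = {i: TreeNode(0.0, leaf=i) for i in range(n)}
    sizes = {i: 1 for i in range(n)}
    d = {(i, j): dist[i, j] for i in range(n) for j in range(i + 1, n)}
    active = list(range(n))
    next_id = n
    while len(active) > 1:
        best = min(
            ((d[(min(i, j), max(i, j))], i, j)
             for ai, i in enumerate(active) for j in active[ai + 1:]),
            key=lambda t: (t[0], t[1], t[2]),
        )
        dij, i, j = best
        merged = TreeNode(dij / 2.0, children=(nodes[i], nodes[j]))
        nodes[next_id] = merged
        sizes[next_id] = sizes[i] + sizes[j]
        for m in active:
            if m in (i, j):
                continue
            dm = (
                sizes[i] * d[(min(i, m), max(i, m))]
                + sizes[j] * d[(min(j, m), max(j, m))]
            ) / (sizes[i] + sizes[j])
            d[(min(m, next_id), max(m, next_id))] = dm
        active = [m for m in active if m not in (i, j)] + [next_id]
        next_id += 1
    return nodes[active[0]]


# ---------------------------------------------------------------------------
# Profile alignment
# ---------------------------------------------------------------------------


def _profile_freq(rows: list[str]) -> np.ndarray:
    """(L, 6) per-column symbol frequencies over A,C,G,T,N,-."""
    codes = np.stack([_align.encode(r) for r in rows])
    L = codes.shape[1]
    freq = np.zeros((L, _align.N_SYMBOLS), dtype=np.float64)
    for s in range(_align.N_SYMBOLS):
        freq[:, s] = (codes == s).sum(axis=0)
    return freq / len(rows)


def _merge_rows(rows_a: list[str], rows_b: list[str], ops: np.ndarray
                ) -> tuple[list[str], list[str]]:
    """Apply a traceback op path (1=pair, 2=gap-in-A, 3=gap-in-B) to the
    raw row strings of both profiles."""
    out_a = [[] for _ in rows_a]
    out_b = [[] for _ in rows_b]
    ia = ib = 0
    for op in ops:
        if op == 1:
            for r, buf in zip(rows_a, out_a):
                buf.append(r[ia])
            for r, buf in zip(rows_b, out_b):
                buf.append(r[ib])
            ia += 1
            ib += 1
        elif op == 2:
            for buf in out_a:
                buf.append("-")
            for r, buf in zip(rows_b, out_b):
                buf.append(r[ib])
            ib += 1
        else:
            for r, buf in zip(rows_a, out_a):
                buf.append(r[ia])
            for buf in out_b:
                buf.append("-")
            ia += 1
    return ["".join(b) for b in out_a], ["".join(b) for b in out_b]


def _align_profiles(
    rows_a: list[str],
    rows_b: list[str],
    scheme: ScoringScheme,
    band: int | None = None,
) -> tuple[float, list[str], list[str]]:
    S = _align.substitution_matrix(scheme.match, scheme.mismatch)
    fa = _profile_freq(rows_a)
    fb = _profile_freq(rows_b)
    la, lb = fa.shape[0], fb.shape[0]
    if band is None:
        # full DP for small problems; a generous diagonal band for the
        # long near-identical homoeolog case (drift from short indels is
        # far below 120 columns)
        band_val = -1 if max(la, lb) < 1500 else 120
    else:
        band_val = band
    score, ops = _align.nw_profile(
        fa @ S, fb, -scheme.gap_open, -scheme.gap_extend, band_val
    )
    merged_a, merged_b = _merge_rows(rows_a, rows_b, ops)
    return float(score), merged_a, merged_b


def pairwise_align_global(
    a: str | SeqRecord,
    b: str | SeqRecord,
    scheme: ScoringScheme = DEFAULT_SCHEME,
) -> tuple[str, str, float]:
    """Optimal global alignment of two (possibly gapped) sequences.

    Returns the two aligned strings and the score.  This is the exact
    n=2 case of :func:`progressive_align`: single-sequence profiles.
    """
    sa = a.seq if isinstance(a, SeqRecord) else a.upper()
    sb = b.seq if isinstance(b, SeqRecord) else b.upper()
    if not sa or not sb:
        raise ValueError("cannot align empty sequences")
    score, ra, rb = _align_profiles([sa], [sb], scheme, band=None)
    return ra[0], rb[0], score


# ---------------------------------------------------------------------------
# Msa container and progressive alignment
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RowInfo:
    """Provenance of one MSA row: which contig region it came from."""

    row_id: str
    subject_id: str
    source_span: tuple[int, int]
    strand: str


@dataclass
class Msa:
    """The per-query multiple alignment of extracted homoeolog sequences."""

    aln: AlignedSet
    query_id: str
    provenance: dict[str, RowInfo] = field(default_factory=dict)

    @property
    def length(self) -> int:
        return self.aln.length

    @property
    def row_ids(self) -> list[str]:
        return self.aln.ids

    def row(self, row_id: str) -> str:
        for rid, rseq in self.aln.rows:
            if rid == row_id:
                return rseq
        raise KeyError(f"row not in alignment: {row_id!r}")


def progressive_align(
    records: Sequence[SeqRecord],
    tree: TreeNode | None = None,
    scheme: ScoringScheme = DEFAULT_SCHEME,
    query_id: str = "",
    provenance: dict[str, RowInfo] | None = None,
) -> Msa:
    """Progressive profile alignment guided by a UPGMA tree.

    ``tree`` defaults to UPGMA over k-mer distances of ``records``.
    Profile merging is post-order; gaps introduced at a merge are
    propagated to every member row and never removed.
    """
    if len(records) < 2:
        raise ValueError("progressive alignment needs >= 2 records")
    if tree is None:
        tree = build_guide_tree(kmer_distance_matrix(records))
    leaves = sorted(tree.leaves())
    if leaves != list(range(len(records))):
        raise ValueError("tree does not cover records")

    def merge(node: TreeNode) -> tuple[list[int], list[str]]:
        if node.leaf is not None:
            return [node.leaf], [records[node.leaf].seq]
        (ia, rows_a), (ib, rows_b) = (merge(c) for c in node.children)
        _, ma, mb = _align_profiles(rows_a, rows_b, scheme)
        return ia + ib, ma + mb

    idx, rows = merge(tree)
    by_input = sorted(zip(idx, rows))
    aligned = AlignedSet([(records[i].id, r) for i, r in by_input])
    return Msa(aligned, query_id=query_id, provenance=provenance or {})


def msa_from_loci(
    query: SeqRecord,
    loci: Sequence[ExtractedLocus],
    scheme: ScoringScheme = DEFAULT_SCHEME,
) -> Msa:
    """Align the extracted homoeolog set of one query, keeping provenance."""
    records = [ex.record for ex in loci]
    prov = {
        ex.record.id: RowInfo(ex.record.id, ex.source_subject,
                              ex.source_span, ex.strand)
        for ex in loci
    }
    return progressive_align(records, scheme=scheme, query_id=query.id,
                             provenance=prov)


# ---------------------------------------------------------------------------
# Conserved-block selection (Gblocks-style)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BlockFilterParams:
    """Knobs of the conserved-block model (relaxed Gblocks-like defaults)."""

    min_block_len: int = 10
    max_nonconserved_run: int = 8
    conserved_frac: float = 0.5
    allow_gap_cols: str = "none"  # or "with_half"

    def __post_init__(self) -> None:
        if self.min_block_len <= 0 or self.max_nonconserved_run <= 0:
            raise ValueError("block parameters must be positive")
        if not 0 < self.conserved_frac <= 1:
            raise ValueError("conserved_frac must be in (0, 1]")
        if self.allow_gap_cols not in ("none", "with_half"):
            raise ValueError("allow_gap_cols must be 'none' or 'with_half'")


@dataclass(frozen=True)
class ConservedBlock:
    col_interval: tuple[int, int]

    def __len__(self) -> int:
        return self.col_interval[1] - self.col_interval[0]


def _classify_columns(msa: Msa, p: BlockFilterParams) -> list[str]:
    """Per-column label: 'gap' (hard break), 'cons', or 'non'."""
    labels = []
    n = len(msa.aln.rows)
    for c in range(msa.length):
        col = msa.aln.column(c)
        n_gap = col.count("-")
        if n_gap and p.allow_gap_cols == "none":
            labels.append("gap")
            continue
        if p.allow_gap_cols == "with_half" and n_gap > n // 2:
            labels.append("gap")
            continue
        residues = [b for b in col if b != "-"]
        top = max(residues.count(b) for b in set(residues))
        labels.append("cons" if top / n > p.conserved_frac else "non")
    return labels


def select_conserved_blocks(
    msa: Msa, p: BlockFilterParams | None = None
) -> list[ConservedBlock]:
    """Maximal conserved runs of the alignment, Gblocks-style.

    Gap columns always break a block; non-conserved runs longer than
    ``max_nonconserved_run`` break a block; block flanks are trimmed to
    conserved columns; blocks shorter than ``min_block_len`` are dropped.
    """
    p = p or BlockFilterParams()
    labels = _classify_columns(msa, p)
    blocks: list[ConservedBlock] = []
    start = None
    run_non = 0
    last_cons = -1

    def flush(start: int | None, last_cons: int) -> None:
        if start is not None and last_cons >= start \
                and last_cons - start + 1 >= p.min_block_len:
            blocks.append(ConservedBlock((start, last_cons + 1)))

    for c, lab in enumerate(labels):
        if lab == "gap":
            flush(start, last_cons)
            start, run_non = None, 0
        elif lab == "non":
            run_non += 1
            if run_non > p.max_nonconserved_run:
                flush(start, last_cons)
                start, run_non = None, 0
        else:
            if start is None:
                start = c
            last_cons = c
            run_non = 0
    flush(start, last_cons)
    return blocks
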