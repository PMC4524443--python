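"""Synthetic allopolyploid fixtures with full ground truth.

The generator emulates the pipeline's real inputs — a diploid relative's
CDS queries and a polyploid's genomic contigs — without any download:
each gene is an ancestral exon/intron structure whose genomic region
(including flanking sequence) diverges independently into k subgenome
copies (star phylogeny), each embedded in its own contig on a random
strand.  Substitutions and short indels are applied at configurable
rates; a set of *planted* diagnostic substitutions (one subgenome
altered, the others ancestral, >= 30 bp apart, inside exons) guarantees
that primer design is well-posed for every gene.

Ground truth records, for every gene: the true locus span, strand and
exon intervals on each contig, and every truly diagnostic site — derived
from the true multiple alignment that the known mutation events induce,
so recall/precision of the inference pipeline can be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .seqio import SeqRecord, revcomp

_BASES = "ACGT"

# wheat-style subgenome letters (A, B, D for a hexaploid)
_SUBGENOME_LETTERS = "ABDEFGHIJK"


@dataclass(frozen=True)
class SimConfig:
    """Study conditions of a simulated allopolyploid experiment."""

    n_genes: int = 10
    n_subgenomes: int = 3
    exons_per_gene: tuple[int, int] = (1, 5)
    exon_len: tuple[int, int] = (200, 600)
    intron_len: tuple[int, int] = (60, 4800)
    divergence: float = 0.02
    indel_rate: float = 0.001
    indel_len: tuple[int, int] = (1, 10)
    contig_pad: int = 500
    planted_per_subgenome: int = 4
    planted_spacing: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_subgenomes < 2:
            raise ValueError("invalid simulation config: need >=1 gene, >=2 subgenomes")
        for rate in (self.divergence, self.indel_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("invalid simulation config: rates must be in [0,1]")
        for lo, hi in (self.exons_per_gene, self.exon_len,
                       self.intron_len, self.indel_len):
            if lo > hi or lo < 1:
                raise ValueError("invalid simulation config: bad range")
        if self.contig_pad < 400:
            raise ValueError("invalid simulation config: contig_pad must be >= 400")


@dataclass(frozen=True)
class MutationEvent:
    """One mutation, with positions in both coordinate systems."""

    kind: str  # sub | ins | del
    src_pos: int  # position on the source (ancestral region) sequence
    dst_pos: int  # position on the mutated sequence
    ref: str
    alt: str


@dataclass(frozen=True)
class TruthSite:
    """A truly diagnostic site, from the true (event-induced) alignment."""

    gene_id: str
    subgenome: str
    kind: str  # SNP | indel
    region_pos: int  # ancestral region coordinate
    contig_id: str
    contig_pos: int
    length: int = 1
    #: Whether the site lies inside the window the pipeline can extract
    #: (locus span plus 300 bp flanks, with a small margin for end
    #: trimming).  Recall is scored over observable sites only; calls
    #: are matched against all sites.
    observable: bool = True


@dataclass(frozen=True)
class CopyTruth:
    """One subgenome copy of a gene, as embedded in its contig."""

    subgenome: str
    contig_id: str
    strand: str
    locus_span: tuple[int, int]  # gene (exon..exon) span on the contig
    exon_intervals: tuple[tuple[int, int], ...]  # on the contig
    region_seq: str  # mutated region (pad+gene+pad), region orientation


@dataclass(frozen=True)
class GeneTruth:
    gene_id: str
    cds: SeqRecord
    region_len: int
    gene_interval: tuple[int, int]  # gene within the ancestral region
    copies: tuple[CopyTruth, ...]
    sites: tuple[TruthSite, ...]


@dataclass(frozen=True)
class SimTruth:
    config: SimConfig
    genes: tuple[GeneTruth, ...]


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[i] for i in rng.integers(0, 4, size=n))


def mutate(
    seq: str | SeqRecord,
    sub_rate: float,
    indel_rate: float,
    rng: np.random.Generator,
    indel_len: tuple[int, int] = (1, 10),
    frozen: Sequence[tuple[int, str]] = (),
) -> tuple[str, list[MutationEvent]]:
    """Mutate a sequence, logging every event in both coordinate systems.

    Substitutions are never silent.  ``frozen`` pins (position, base)
    assignments applied before random mutation (used for planted
    diagnostic sites); frozen positions are shielded from further
    mutation and from indels starting there.
    """
    if not 0.0 <= sub_rate <= 1.0 or not 0.0 <= indel_rate <= 1.0:
        raise ValueError("mutation rates must be in [0,1]")
    s = seq.seq if isinstance(seq, SeqRecord) else seq
    content: list[str] = list(s)
    events: list[MutationEvent] = []
    frozen_map = dict(frozen)
    L = len(s)

    for p, alt in frozen_map.items():
        if alt == s[p]:
            raise ValueError("frozen substitution must change the base")
        content[p] = alt
        events.append(MutationEvent("sub", p, -1, s[p], alt))

    # substitutions
    sub_mask = rng.random(L) < sub_rate
    for p in np.nonzero(sub_mask)[0]:
        p = int(p)
        if p in frozen_map:
            continue
        ref = s[p]
        alt = _BASES[(("ACGT".index(ref)) + int(rng.integers(1, 4))) % 4]
        content[p] = alt
        events.append(MutationEvent("sub", p, -1, ref, alt))

    # indels (never at frozen positions; deletions may not cross them)
    indel_mask = rng.random(L) < indel_rate
    deleted = [False] * L
    for p in np.nonzero(indel_mask)[0]:
        p = int(p)
        if p in frozen_map or deleted[p]:
            continue
        length = int(rng.integers(indel_len[0], indel_len[1] + 1))
        if rng.random() < 0.5:  # deletion of [p, p+length)
            stop = min(L, p + length)
            span = range(p, stop)
            if any(deleted[q] or q in frozen_map for q in span):
                continue
            for q in span:
                content[q] = ""
                deleted[q] = True
            events.append(
                MutationEvent("del", p, -1, s[p:stop], "")
            )
        else:  # insertion after p
            ins = _random_seq(rng, length)
            content[p] = content[p] + ins
            events.append(MutationEvent("ins", p, -1, "", ins))

    mutated = "".join(content)
    # fill destination coordinates; substitutions wiped by a later
    # deletion are dropped (the deletion alone describes the outcome)
    starts = np.zeros(L + 1, dtype=int)
    for p in range(L):
        starts[p + 1] = starts[p] + len(content[p])
    events = [
        MutationEvent(e.kind, e.src_pos, int(starts[e.src_pos]), e.ref, e.alt)
        for e in sorted(events, key=lambda e: (e.src_pos, e.kind))
        if not (e.kind == "sub" and deleted[e.src_pos])
    ]
    return mutated, events


def _apply_content(
    s: str, events: Sequence[MutationEvent]
) -> tuple[list[str], np.ndarray]:
    """Reconstruct the per-source-position content strings and the
    cumulative destination offsets from an event log.

    Replay order is substitutions, then insertions, then deletions —
    the generator's order: a deletion wipes any substitution inside its
    span (and deletions never overlap an insertion point).
    """
    content = list(s)
    _PRIORITY = {"sub": 0, "ins": 1, "del": 2}
    for e in sorted(events, key=lambda e: (_PRIORITY[e.kind], e.src_pos)):
        if e.kind == "sub":
            content[e.src_pos] = e.alt + content[e.src_pos][1:]
        elif e.kind == "del":
            for q in range(e.src_pos, e.src_pos + len(e.ref)):
                content[q] = ""
        else:
            content[e.src_pos] = content[e.src_pos] + e.alt
    starts = np.zeros(len(s) + 1, dtype=int)
    for p in range(len(s)):
        starts[p + 1] = starts[p] + len(content[p])
    return content, starts


def _true_sites(
    gene_id: str,
    region: str,
    contents: list[list[str]],
    starts: list[np.ndarray],
    subgenomes: Sequence[str],
    contig_ids: Sequence[str],
    strands: Sequence[str],
    contig_lens: Sequence[int],
) -> list[TruthSite]:
    """Diagnostic sites of the *true* alignment induced by the event logs.

    The true multiple alignment is built on the ancestral coordinate
    frame: each region position contributes one base column (possibly
    substituted or deleted per copy) plus insertion columns.  A column is
    diagnostic for a copy when that copy's state differs from all others
    and the others agree; contiguous indel columns collapse into one
    event, mirroring the caller's convention.
    """
    k = len(contents)
    sites: list[TruthSite] = []

    def contig_pos(ci: int, dpos: int) -> int:
        if strands[ci] == "+":
            return dpos
        return contig_lens[ci] - 1 - dpos

    pending: dict[int, list] = {}

    def emit(ci: int, kind: str, region_pos: int, dpos: int) -> None:
        if kind == "indel" and ci in pending and \
                pending[ci][1] + pending[ci][3] >= region_pos:
            pending[ci][3] += 1
            return
        flush(ci)
        pending[ci] = [kind, region_pos, dpos, 1]

    def flush(ci: int | None = None) -> None:
        targets = [ci] if ci is not None else list(pending)
        for t in targets:
            if t in pending:
                kind, rpos, dpos, length = pending.pop(t)
                sites.append(
                    TruthSite(gene_id, subgenomes[t], kind, rpos,
                              contig_ids[t], contig_pos(t, dpos), length)
                )

    for p in range(len(region)):
        # base column
        states = []
        for ci in range(k):
            c = contents[ci][p]
            states.append(c[0] if c else "-")
        distinct = set(states)
        if len(distinct) > 1:
            for ci in range(k):
                others = [states[x] for x in range(k) if x != ci]
                if states[ci] not in others and len(set(others)) == 1:
                    kind = "indel" if "-" in distinct else "SNP"
                    dpos = int(starts[ci][p])
                    if kind == "SNP":
                        flush(ci)
                        sites.append(
                            TruthSite(gene_id, subgenomes[ci], "SNP", p,
                                      contig_ids[ci], contig_pos(ci, dpos))
                        )
                    else:
                        emit(ci, "indel", p, dpos)
                else:
                    flush(ci)
        else:
            flush()
        # insertion columns after the base at p
        max_ins = max(len(contents[ci][p]) for ci in range(k)) - 1
        for t in range(max_ins):
            ins_states = []
            for ci in range(k):
                c = contents[ci][p]
                ins_states.append(c[1 + t] if len(c) > 1 + t else "-")
            for ci in range(k):
                others = [ins_states[x] for x in range(k) if x != ci]
                if ins_states[ci] not in others and len(set(others)) == 1:
                    dpos = int(starts[ci][p]) + min(
                        1 + t, max(len(contents[ci][p]) - 1, 0)
                    )
                    emit(ci, "indel", p, dpos)
                else:
                    flush(ci)
    flush()
    return sites


def simulate(cfg: SimConfig) -> tuple[list[SeqRecord], list[SeqRecord], SimTruth]:
    """Generate (queries, genome contigs, truth) for one experiment.

    Deterministic for a fixed ``cfg.seed``: running twice yields
    byte-identical FASTA content.
    """
    rng = np.random.default_rng(cfg.seed)
    subgenomes = [_SUBGENOME_LETTERS[i] for i in range(cfg.n_subgenomes)]
    queries: list[SeqRecord] = []
    contigs: list[SeqRecord] = []
    gene_truths: list[GeneTruth] = []

    for g in range(cfg.n_genes):
        gene_id = f"gene{g:03d}"
        n_ex = int(rng.integers(cfg.exons_per_gene[0], cfg.exons_per_gene[1] + 1))
        exon_lens = [int(rng.integers(cfg.exon_len[0], cfg.exon_len[1] + 1))
                     for _ in range(n_ex)]
        intron_lens = [int(rng.integers(cfg.intron_len[0], cfg.intron_len[1] + 1))
                       for _ in range(max(0, n_ex - 1))]
        exons = [_random_seq(rng, n) for n in exon_lens]
        introns = [_random_seq(rng, n) for n in intron_lens]
        gene_parts = []
        exon_region_ivs = []  # exon intervals in region coordinates
        pos = cfg.contig_pad
        for i, ex in enumerate(exons):
            exon_region_ivs.append((pos, pos + len(ex)))
            gene_parts.append(ex)
            pos += len(ex)
            if i < len(introns):
                gene_parts.append(introns[i])
                pos += len(introns[i])
        gene_seq = "".join(gene_parts)
        pad_l = _random_seq(rng, cfg.contig_pad)
        pad_r = _random_seq(rng, cfg.contig_pad)
        region = pad_l + gene_seq + pad_r
        gene_iv = (cfg.contig_pad, cfg.contig_pad + len(gene_seq))
        cds = SeqRecord(gene_id, "".join(exons), "ancestral CDS")
        queries.append(cds)

        # planted diagnostic substitutions: exonic, spaced, round-robin
        planted: dict[str, list[tuple[int, str]]] = {s: [] for s in subgenomes}
        n_wanted = cfg.planted_per_subgenome * cfg.n_subgenomes
        exon_positions = [p for lo, hi in exon_region_ivs for p in range(lo, hi)]
        chosen: list[int] = []
        order = rng.permutation(len(exon_positions))
        for idx in order:
            if len(chosen) >= n_wanted:
                break
            p = exon_positions[int(idx)]
            if all(abs(p - q) >= cfg.planted_spacing for q in chosen):
                chosen.append(p)
        chosen.sort()
        for i, p in enumerate(chosen):
            sg = subgenomes[i % cfg.n_subgenomes]
            ref = region[p]
            alt = _BASES[("ACGT".index(ref) + int(rng.integers(1, 4))) % 4]
            planted[sg].append((p, alt))
        all_planted = {p for ps in planted.values() for p, _ in ps}

        contents = []
        starts_list = []
        copy_meta = []
        for si, sg in enumerate(subgenomes):
            shield = [
                (p, region[p]) for p in all_planted
                if p not in {q for q, _ in planted[sg]}
            ]
            # shielded positions keep the ancestral base so the planted
            # site stays diagnostic; they are pinned via the frozen
            # mechanism without an event
            mutated, events = _mutate_with_shield(
                region, cfg, rng, planted[sg], [p for p, _ in shield]
            )
            contents_i, starts = _apply_content(region, events)
            contig_id = f"{gene_id}_{sg}"
            strand = "+" if rng.random() < 0.5 else "-"
            contig_seq = mutated if strand == "+" else revcomp(mutated)
            contigs.append(SeqRecord(contig_id, contig_seq,
                                     f"subgenome {sg} copy of {gene_id}"))
            d_gene = (int(starts[gene_iv[0]]), int(starts[gene_iv[1]]))
            d_exons = [(int(starts[a]), int(starts[b]))
                       for a, b in exon_region_ivs]
            clen = len(mutated)
            if strand == "+":
                span = d_gene
                exon_ivs = tuple(d_exons)
            else:
                span = (clen - d_gene[1], clen - d_gene[0])
                exon_ivs = tuple(
                    sorted((clen - b, clen - a) for a, b in d_exons)
                )
            copy_meta.append(
                CopyTruth(sg, contig_id, strand, span, exon_ivs, mutated)
            )
            contents.append(contents_i)
            starts_list.append(starts)

        sites = _true_sites(
            gene_id, region, contents, starts_list, subgenomes,
            [c.contig_id for c in copy_meta],
            [c.strand for c in copy_meta],
            [len(c.region_seq) for c in copy_meta],
        )
        window = (gene_iv[0] - 250, gene_iv[1] + 250)
        sites = [
            TruthSite(
                s.gene_id, s.subgenome, s.kind, s.region_pos, s.contig_id,
                s.contig_pos, s.length,
                observable=window[0] <= s.region_pos < window[1],
            )
            for s in sites
        ]
        gene_truths.append(
            GeneTruth(gene_id, cds, len(region), gene_iv,
                      tuple(copy_meta), tuple(sites))
        )

    return queries, contigs, SimTruth(cfg, tuple(gene_truths))


def _mutate_with_shield(
    region: str,
    cfg: SimConfig,
    rng: np.random.Generator,
    planted: list[tuple[int, str]],
    shielded: list[int],
) -> tuple[str, list[MutationEvent]]:
    """Planted substitutions applied as frozen changes; shielded
    positions (other subgenomes' planted sites) excluded from mutation
    so the ancestral state is preserved there."""
    s = region
    content = list(s)
    events: list[MutationEvent] = []
    pinned = {p for p, _ in planted} | set(shielded)
    for p, alt in planted:
        content[p] = alt
        events.append(MutationEvent("sub", p, -1, s[p], alt))

    L = len(s)
    sub_mask = rng.random(L) < cfg.divergence
    for p in np.nonzero(sub_mask)[0]:
        p = int(p)
        if p in pinned:
            continue
        ref = s[p]
        alt = _BASES[("ACGT".index(ref) + int(rng.integers(1, 4))) % 4]
        content[p] = alt
        events.append(MutationEvent("sub", p, -1, ref, alt))

    deleted = [False] * L
    indel_mask = rng.random(L) < cfg.indel_rate
    for p in np.nonzero(indel_mask)[0]:
        p = int(p)
        if p in pinned or deleted[p]:
            continue
        length = int(rng.integers(cfg.indel_len[0], cfg.indel_len[1] + 1))
        if rng.random() < 0.5:
            stop = min(L, p + length)
            span = range(p, stop)
            if any(deleted[q] or q in pinned for q in span):
                continue
            for q in span:
                content[q] = ""
                deleted[q] = True
            events.append(MutationEvent("del", p, -1, s[p:stop], ""))
        else:
            ins = _random_seq(rng, length)
            content[p] = content[p] + ins
            events.append(MutationEvent("ins", p, -1, "", ins))

    mutated = "".join(content)
    starts = np.zeros(L + 1, dtype=int)
    for p in range(L):
        starts[p + 1] = starts[p] + len(content[p])
    events = [
        MutationEvent(e.kind, e.src_pos, int(starts[e.src_pos]), e.ref, e.alt)
        for e in sorted(events, key=lambda e: (e.src_pos, e.kind))
        if not (e.kind == "sub" and deleted[e.src_pos])
    ]
    return mutated, events


# ---------------------------------------------------------------------------
# Scoring inferred sites against truth
# ---------------------------------------------------------------------------


def score_sites(
    truth_sites: Sequence[TruthSite],
    called: Sequence[tuple[str, str, int, str]],
    indel_tolerance: int = 6,
) -> tuple[int, int, int]:
    """Compare called sites with truth.

    ``called`` entries are (contig_id, kind, contig_pos, subgenome).
    SNPs match exactly by position; indels match within
    ``indel_tolerance`` (equivalent gap placements inside repeats shift
    the reported position).  Recall counts observable truth sites only;
    calls are matched against all truth sites.  Returns (tp, fp, fn).
    """
    truth_by_key: dict[tuple[str, str], list[TruthSite]] = {}
    for t in truth_sites:
        truth_by_key.setdefault((t.contig_id, t.kind), []).append(t)
    used: set[int] = set()
    tp = fp = 0
    for contig_id, kind, pos, _sg in called:
        entries = truth_by_key.get((contig_id, kind), [])
        tol = 0 if kind == "SNP" else indel_tolerance
        hit = None
        for t in entries:
            if id(t) in used:
                continue
            tpos, tlen = t.contig_pos, t.length
            if min(abs(pos - tpos), abs(pos - (tpos + tlen - 1))) <= tol \
                    or tpos <= pos < tpos + tlen:
                hit = t
                break
        if hit is None:
            fp += 1
        else:
            used.add(id(hit))
            if hit.observable:
                tp += 1
    fn = sum(1 for t in truth_sites if t.observable) - tp
    return tp, fp, fn
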