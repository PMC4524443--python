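"""Subgenome-diagnostic polymorphism detection and genome-specific assay
design on homoeolog alignments.

A column is *diagnostic* for a target row when the target's state
differs from every other row and the other rows agree with each other —
the asterisked bases of a homoeolog alignment.  Primer pairs are
anchored on such columns (>=1 diagnostic base within the 3'-terminal
3 nt of each primer, >=2 distinct diagnostic columns per pair, because
single-SNP primers do not reliably discriminate homoeologs) and
validated by in-silico PCR, the computational analog of scoring
presence/absence of products across nulli-tetrasomic lines.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from . import _align
from .msa import Msa
from .seqio import SeqRecord, revcomp


class NoPrimerPairError(ValueError):
    """No genome-specific primer pair exists under the given constraints."""


# ---------------------------------------------------------------------------
# Diagnostic sites and conserved regions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DiagnosticSite:
    """An alignment column discriminating one homoeolog from all others."""

    column: int
    target_row: str
    target_state: str
    background_state: str
    kind: str  # "SNP" | "indel"
    length: int = 1  # collapsed run length for indel events

    def __post_init__(self) -> None:
        if self.kind not in ("SNP", "indel"):
            raise ValueError(f"invalid site kind {self.kind!r}")
        if self.target_state == self.background_state:
            raise ValueError("target and background states must differ")


@dataclass(frozen=True)
class ConservedRegion:
    """A gap-free alignment interval with zero inter-row differences."""

    col_interval: tuple[int, int]

    def __len__(self) -> int:
        return self.col_interval[1] - self.col_interval[0]


def _terminal_gap_mask(msa: Msa) -> np.ndarray:
    """True for columns inside any row's leading/trailing gap run.

    Extracted loci differ by a few bases at their ends, so alignment
    termini contain overhangs; terminal gaps are missing data, not
    polymorphism, and are excluded from site scanning.
    """
    mask = np.zeros(msa.length, dtype=bool)
    for _, rseq in msa.aln.rows:
        lead = len(rseq) - len(rseq.lstrip("-"))
        trail = len(rseq) - len(rseq.rstrip("-"))
        if lead:
            mask[:lead] = True
        if trail:
            mask[msa.length - trail:] = True
    return mask


def diagnostic_sites(
    msa: Msa, target_row: str, strict_background: bool = True
) -> list[DiagnosticSite]:
    """Call columns diagnostic for ``target_row``.

    Strict mode (default) requires all non-target rows to share one
    state; relaxed mode only requires the target to differ from each of
    them.  Columns containing N/ambiguity in any row are skipped, as are
    columns under a terminal-gap overhang.  Contiguous diagnostic gap
    columns are collapsed into a single indel site (one mutational
    event, one discriminating feature).
    """
    rows = dict(msa.aln.rows)
    if target_row not in rows:
        raise ValueError(f"row not in alignment: {target_row!r}")
    if len(rows) < 2:
        raise ValueError("need >= 2 rows to call diagnostic sites")
    target = rows[target_row]
    background = [rseq for rid, rseq in msa.aln.rows if rid != target_row]
    skip = _terminal_gap_mask(msa)

    raw: list[DiagnosticSite] = []
    for c in range(msa.length):
        if skip[c]:
            continue
        t = target[c]
        bg = [r[c] for r in background]
        states = set(bg) | {t}
        if any(s not in "ACGT-" for s in states):
            continue
        if t in bg:
            continue
        if strict_background and len(set(bg)) != 1:
            continue
        bstate = bg[0] if len(set(bg)) == 1 else "".join(sorted(set(bg)))
        kind = "indel" if "-" in states else "SNP"
        raw.append(DiagnosticSite(c, target_row, t, bstate, kind))

    # collapse contiguous indel columns belonging to one gap run
    out: list[DiagnosticSite] = []
    for site in raw:
        prev = out[-1] if out else None
        if (
            prev is not None
            and site.kind == "indel"
            and prev.kind == "indel"
            and site.column == prev.column + prev.length
            and (site.target_state == "-") == (prev.target_state == "-")
        ):
            out[-1] = DiagnosticSite(
                prev.column, prev.target_row, prev.target_state,
                prev.background_state, "indel", prev.length + 1,
            )
        else:
            out.append(site)
    return out


def conserved_regions(msa: Msa, min_len: int = 18) -> list[ConservedRegion]:
    """Maximal runs of gap-free columns identical across all rows.

    These are the intervals where one primer pair amplifies every
    homoeolog alike — the substrate for RT-qPCR primer design.
    """
    regions: list[ConservedRegion] = []
    start = None
    for c in range(msa.length):
        col = msa.aln.column(c)
        uniform = len(set(col)) == 1 and col[0] in "ACGT"
        if uniform and start is None:
            start = c
        elif not uniform and start is not None:
            if c - start >= min_len:
                regions.append(ConservedRegion((start, c)))
            start = None
    if start is not None and msa.length - start >= min_len:
        regions.append(ConservedRegion((start, msa.length)))
    return regions


# ---------------------------------------------------------------------------
# Coordinate mapping helpers
# ---------------------------------------------------------------------------


def row_base_index(row_seq: str, column: int) -> int:
    """Ungapped base index of ``column`` in a gapped row (a gap column
    maps to the index of the next base — the junction)."""
    return column - row_seq[:column].count("-")


def base_to_column(row_seq: str) -> list[int]:
    """Alignment column of each ungapped base of a row."""
    return [c for c, ch in enumerate(row_seq) if ch != "-"]


def site_to_subject_coord(msa: Msa, site: DiagnosticSite) -> tuple[str, int]:
    """Map a diagnostic site to (contig id, contig position) using the
    MSA's row provenance."""
    info = msa.provenance[site.target_row]
    row = msa.row(site.target_row)
    b = row_base_index(row, site.column)
    lo, hi = info.source_span
    if info.strand == "+":
        return info.subject_id, lo + b
    return info.subject_id, hi - 1 - b


# ---------------------------------------------------------------------------
# Melting temperature
# ---------------------------------------------------------------------------


def melting_temp(seq: str) -> float:
    """Primer melting temperature in deg C.

    Wallace rule ``2*(A+T) + 4*(G+C)`` below 14 nt; the GC-fraction
    formula ``64.9 + 41*(G+C - 16.4)/N`` at 14 nt and above.
    """
    seq = seq.upper()
    if len(seq) < 8:
        raise ValueError("primer too short for Tm estimate")
    if set(seq) - set("ACGT"):
        raise ValueError(f"cannot compute Tm for ambiguous primer {seq!r}")
    gc = seq.count("G") + seq.count("C")
    n = len(seq)
    if n < 14:
        return float(2 * (n - gc) + 4 * gc)
    return 64.9 + 41.0 * (gc - 16.4) / n


def gc_fraction(seq: str) -> float:
    return (seq.count("G") + seq.count("C")) / len(seq)


# ---------------------------------------------------------------------------
# Primer windows and pair design
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PrimerWindow:
    """A primer-feasible interval on the target row (base coordinates).

    ``strand`` 'F' primers read the row 5'->3' with the 3' end at
    ``end - 1``; 'R' primers are the reverse complement with the 3' end
    at ``start``.
    """

    start: int
    end: int
    strand: str
    diag_positions: tuple[int, ...]
    three_prime_diags: tuple[int, ...]

    @property
    def length(self) -> int:
        return self.end - self.start


def _covered(start: int, end: int, pos: int, junction: bool) -> bool:
    if junction:
        return start < pos < end  # must span the event boundary
    return start <= pos < end


def _site_row_positions(
    sites: Sequence[DiagnosticSite], msa: Msa, target_row: str
) -> list[tuple[int, bool, DiagnosticSite]]:
    row = msa.row(target_row)
    out = []
    for s in sites:
        junction = s.target_state == "-"
        out.append((row_base_index(row, s.column), junction, s))
    return out


def primer_windows(
    sites: Sequence[DiagnosticSite],
    msa: Msa,
    target_row: str,
    win_len: tuple[int, int] = (18, 27),
) -> list[PrimerWindow]:
    """All primer-length windows with >=1 diagnostic position in the
    3'-terminal 3 bases, ranked by diagnostic coverage then 3' proximity.
    """
    row = msa.row(target_row)
    row_len = len(row) - row.count("-")
    positions = _site_row_positions(sites, msa, target_row)
    lo, hi = win_len
    wins: dict[tuple[int, int, str], PrimerWindow] = {}
    for p, junction, _ in positions:
        for length in range(lo, hi + 1):
            for off in range(3):
                # forward: 3' end at column e = p + off
                e = p + off
                start, end = e - length + 1, e + 1
                if start >= 0 and end <= row_len and \
                        _covered(start, end, p, junction) and p >= end - 3:
                    wins.setdefault((start, end, "F"), None)
                # reverse: 3' end at b = p - off
                b = p - off
                start, end = b, b + length
                if start >= 0 and end <= row_len and \
                        _covered(start, end, p, junction) and p < start + 3:
                    wins.setdefault((start, end, "R"), None)
    out = []
    for (start, end, strand) in wins:
        cov = tuple(
            p for p, junction, _ in positions
            if _covered(start, end, p, junction)
        )
        if strand == "F":
            tp = tuple(p for p in cov if p >= end - 3)
            tp_dist = min(end - 1 - p for p in tp) if tp else 99
        else:
            tp = tuple(p for p in cov if p < start + 3)
            tp_dist = min(p - start for p in tp) if tp else 99
        if not tp:
            continue
        out.append(PrimerWindow(start, end, strand, cov, tp))
    out.sort(
        key=lambda w: (
            -len(w.diag_positions),
            min(
                (w.end - 1 - p) if w.strand == "F" else (p - w.start)
                for p in w.three_prime_diags
            ),
            w.length,
            w.start,
            w.strand,
        )
    )
    return out


@dataclass(frozen=True)
class Primer:
    """A designed genome-specific primer on one MSA row."""

    seq: str
    target_row: str
    row_interval: tuple[int, int]
    aln_cols: tuple[int, int]
    strand: str  # F | R
    tm: float
    gc: float
    diag_cols: tuple[int, ...]

    def __post_init__(self) -> None:
        if "-" in self.seq:
            raise ValueError("primer sequence must be gap-free")


@dataclass(frozen=True)
class PrimerPair:
    forward: Primer
    reverse: Primer
    product_len: int
    total_diag: int

    def __post_init__(self) -> None:
        if self.total_diag < 2:
            raise ValueError("pair must cover >= 2 diagnostic columns")


@dataclass(frozen=True)
class PrimerConstraints:
    tm_range: tuple[float, float] = (50.0, 70.0)
    gc_range: tuple[float, float] = (0.3, 0.7)
    len_range: tuple[int, int] = (18, 27)
    product_range: tuple[int, int] = (80, 1500)
    max_tm_gap: float = 5.0


def _window_to_primer(
    w: PrimerWindow, msa: Msa, target_row: str,
    cons: PrimerConstraints, site_cols: dict[int, int],
) -> Primer | None:
    row = msa.row(target_row)
    bases = row.replace("-", "")
    seq = bases[w.start:w.end]
    if set(seq) - set("ACGT"):
        return None
    gc = gc_fraction(seq)
    if not cons.gc_range[0] <= gc <= cons.gc_range[1]:
        return None
    tm = melting_temp(seq)
    if not cons.tm_range[0] <= tm <= cons.tm_range[1]:
        return None
    cols = base_to_column(row)
    aln_cols = (cols[w.start], cols[w.end - 1] + 1)
    if w.strand == "R":
        seq = revcomp(seq)
    return Primer(
        seq=seq,
        target_row=target_row,
        row_interval=(w.start, w.end),
        aln_cols=aln_cols,
        strand=w.strand,
        tm=tm,
        gc=gc,
        diag_cols=tuple(sorted(site_cols[p] for p in w.diag_positions)),
    )


def design_primer_pairs(
    msa: Msa,
    target_row: str,
    constraints: PrimerConstraints | None = None,
    sites: Sequence[DiagnosticSite] | None = None,
    max_candidates_per_strand: int = 50,
    max_pairs: int = 10,
) -> list[PrimerPair]:
    """Design genome-specific primer pairs for one homoeolog row.

    Each primer carries >=1 diagnostic base in its 3'-terminal 3 nt; the
    pair covers >=2 distinct diagnostic columns in total, satisfies the
    Tm/GC/length/product constraints, and the list is ranked by total
    diagnostic coverage, then Tm balance, then product length.

    Raises :class:`NoPrimerPairError` when no pair is feasible (reported
    per query by the pipeline, never fatal).
    """
    cons = constraints or PrimerConstraints()
    if sites is None:
        sites = diagnostic_sites(msa, target_row)
    if not sites:
        raise NoPrimerPairError(
            f"no genome-specific pair under constraints for {target_row!r}: "
            "no diagnostic sites"
        )
    positions = _site_row_positions(sites, msa, target_row)
    site_cols = {p: s.column for p, _, s in positions}
    wins = primer_windows(sites, msa, target_row, cons.len_range)
    fwd: list[tuple[PrimerWindow, Primer]] = []
    rev: list[tuple[PrimerWindow, Primer]] = []
    for w in wins:
        bucket = fwd if w.strand == "F" else rev
        if len(bucket) >= max_candidates_per_strand:
            continue
        primer = _window_to_primer(w, msa, target_row, cons, site_cols)
        if primer is not None:
            bucket.append((w, primer))
    pairs: list[PrimerPair] = []
    for wf, pf in fwd:
        for wr, pr in rev:
            if wf.end > wr.start:
                continue
            product = wr.end - wf.start
            if not cons.product_range[0] <= product <= cons.product_range[1]:
                continue
            if abs(pf.tm - pr.tm) > cons.max_tm_gap:
                continue
            total = len(set(pf.diag_cols) | set(pr.diag_cols))
            if total < 2:
                continue
            pairs.append(PrimerPair(pf, pr, product, total))
    pairs.sort(
        key=lambda p: (
            -p.total_diag,
            abs(p.forward.tm - p.reverse.tm),
            p.product_len,
            p.forward.row_interval,
            p.reverse.row_interval,
        )
    )
    if not pairs:
        raise NoPrimerPairError(
            f"no genome-specific pair under constraints for {target_row!r}"
        )
    return pairs[:max_pairs]


# ---------------------------------------------------------------------------
# In-silico PCR
# ---------------------------------------------------------------------------


def _binding_sites(
    primer: str, tmpl_codes: np.ndarray, max_mismatch: int, tp_exact: int,
    sense: str,
) -> np.ndarray:
    """Start positions where ``primer`` anneals to the template.

    ``sense='+'`` means the primer matches the plus strand and extends
    rightward; ``sense='-'`` means its reverse complement matches the
    plus strand (primer anneals to the minus strand, extending leftward;
    its 3' end sits at the match start).
    """
    pc = _align.encode(primer if sense == "+" else revcomp(primer))
    L = pc.shape[0]
    if tmpl_codes.shape[0] < L:
        return np.empty(0, dtype=int)
    win = sliding_window_view(tmpl_codes, L)
    mism = win != pc
    ok = mism.sum(axis=1) <= max_mismatch
    if sense == "+":
        ok &= mism[:, L - tp_exact:].sum(axis=1) == 0
    else:
        ok &= mism[:, :tp_exact].sum(axis=1) == 0
    return np.nonzero(ok)[0]


def insilico_pcr(
    pair: PrimerPair,
    templates: Sequence[SeqRecord],
    max_mismatch: int = 2,
    three_prime_exact: int = 3,
    max_product: int = 5000,
) -> list[tuple[str, tuple[int, int], int]]:
    """Predict amplification products of a primer pair on templates.

    A product is reported wherever two primer binding sites face each
    other convergently within ``max_product``; annealing tolerates at
    most ``max_mismatch`` mismatches overall and none in the 3'-terminal
    ``three_prime_exact`` bases.  Both template strands are enumerated
    (either primer may play the forward or the reverse role).
    """
    if not templates:
        raise ValueError("templates must be nonempty")
    products: list[tuple[str, tuple[int, int], int]] = []
    primers = (pair.forward.seq, pair.reverse.seq)
    for tmpl in templates:
        codes = _align.encode(tmpl.seq)
        plus = {
            p: _binding_sites(p, codes, max_mismatch, three_prime_exact, "+")
            for p in primers
        }
        minus = {
            p: _binding_sites(p, codes, max_mismatch, three_prime_exact, "-")
            for p in primers
        }
        seen: set[tuple[int, int]] = set()
        for pa in primers:
            for pb in primers:
                for i in plus[pa]:
                    for j in minus[pb]:
                        lo, hi = int(i), int(j) + len(pb)
                        plen = hi - lo
                        if i <= j and len(pa) < plen <= max_product:
                            if (lo, hi) not in seen:
                                seen.add((lo, hi))
                                products.append((tmpl.id, (lo, hi), plen))
    products.sort()
    return products
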