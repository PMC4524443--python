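"""Reading and writing of every external format the pipeline touches.

FASTA in/out (via Biopython, with strict validation), 12-column tabular
homology hits (BLAST ``outfmt 6`` convention), aligned FASTA, and the
browser-readable per-gene ``.htm`` alignment report.

Internal coordinates are 0-based half-open on the plus strand everywhere;
the tabular hit format is the single place where the 1-based inclusive
BLAST convention appears, and the conversion happens at parse/write time.
"""

from __future__ import annotations

import html
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO as _BioSeqIO
from Bio.Seq import Seq as _BioSeq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

#: IUPAC nucleotide one-letter codes (no gap).
IUPAC_NT = frozenset("ACGTUNRYSWKMBDHV")

_COMPLEMENT = str.maketrans(
    "ACGTUNRYSWKMBDHV-", "TGCAANYRSWMKVHDB-"
)


def revcomp(seq: str) -> str:
    """Reverse complement of an IUPAC nucleotide string (gap-preserving)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SeqRecord:
    """An identified nucleotide sequence (query CDS or genome contig)."""

    id: str
    seq: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise ValueError(f"invalid sequence id {self.id!r}")
        object.__setattr__(self, "seq", self.seq.upper())
        if not self.seq:
            raise ValueError(f"empty sequence for id {self.id!r}")
        bad = set(self.seq) - IUPAC_NT
        if bad:
            pos = next(i for i, c in enumerate(self.seq) if c in bad)
            raise ValueError(
                f"non-IUPAC character {self.seq[pos]!r} at record "
                f"{self.id!r} position {pos}"
            )

    def __len__(self) -> int:
        return len(self.seq)

    def reverse_complement(self) -> "SeqRecord":
        return SeqRecord(self.id, revcomp(self.seq), self.description)


@dataclass
class AlignedSet:
    """An alignment: ordered rows of (id, gapped sequence) of equal length."""

    rows: list[tuple[str, str]]

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError("alignment has no rows")
        n = len(self.rows[0][1])
        for rid, rseq in self.rows:
            if len(rseq) != n:
                raise ValueError(
                    f"row {rid!r} length {len(rseq)} != alignment length {n}"
                )

    @property
    def length(self) -> int:
        return len(self.rows[0][1])

    @property
    def ids(self) -> list[str]:
        return [rid for rid, _ in self.rows]

    def dealign(self) -> list[SeqRecord]:
        """Strip gaps from every row, recovering the input sequences."""
        return [SeqRecord(rid, rseq.replace("-", "")) for rid, rseq in self.rows]

    def column(self, i: int) -> list[str]:
        return [rseq[i] for _, rseq in self.rows]


def read_fasta(path: str | Path) -> list[SeqRecord]:
    """Read a multi-FASTA file into validated :class:`SeqRecord` objects.

    Lowercase is folded to uppercase; gaps are rejected (unaligned input).
    """
    path = Path(path)
    if path.stat().st_size == 0:
        raise ValueError(f"empty input: {path}")
    records: list[SeqRecord] = []
    seen: set[str] = set()
    for rec in _BioSeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        desc = rec.description
        if desc.startswith(rec.id):
            desc = desc[len(rec.id):].strip()
        records.append(SeqRecord(rec.id, str(rec.seq), desc))
    if not records:
        raise ValueError(f"empty input: no FASTA records in {path}")
    return records


def write_fasta(
    records: Sequence[SeqRecord], path: str | Path, wrap: int = 60
) -> Path:
    """Write records as multi-FASTA, wrapping sequence lines at ``wrap``."""
    if not records:
        raise ValueError("nothing to write")
    if wrap < 1:
        raise ValueError("wrap must be >= 1")
    path = Path(path)
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id if not rec.description else f"{rec.id} {rec.description}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.seq), wrap):
                fh.write(rec.seq[i:i + wrap] + "\n")
    return path


def read_aligned_fasta(path: str | Path) -> AlignedSet:
    """Read an aligned FASTA file (gaps allowed) into an :class:`AlignedSet`."""
    rows: list[tuple[str, str]] = []
    for rec in _BioSeqIO.parse(str(path), "fasta"):
        rows.append((rec.id, str(rec.seq).upper()))
    if not rows:
        raise ValueError(f"empty input: no FASTA records in {path}")
    return AlignedSet(rows)


def write_aligned_fasta(aln: AlignedSet, path: str | Path, wrap: int = 60) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for rid, rseq in aln.rows:
            fh.write(f">{rid}\n")
            for i in range(0, len(rseq), wrap):
                fh.write(rseq[i:i + wrap] + "\n")
    return path


# ---------------------------------------------------------------------------
# 12-column tabular hits (BLAST outfmt 6 convention)
# ---------------------------------------------------------------------------

TABULAR_COLUMNS = (
    "qseqid sseqid pident length mismatch gapopen "
    "qstart qend sstart send evalue bitscore"
).split()


def read_tabular_hits(path: str | Path):
    """Parse 12-column tab-separated hits into :class:`~.homology.Hsp` objects.

    Input coordinates are 1-based inclusive; minus-strand hits have
    ``sstart > send``.  On return all intervals are 0-based half-open with
    start < end, and the strand flag records the original orientation.
    """
    from .homology import DEFAULT_SCHEME, Hsp  # local import to avoid a cycle

    hsps = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise ValueError(
                    f"malformed hit line {lineno}: expected 12 columns, "
                    f"got {len(fields)}"
                )
            try:
                qid, sid = fields[0], fields[1]
                pident = float(fields[2])
                length = int(fields[3])
                qstart, qend = int(fields[6]), int(fields[7])
                sstart, send = int(fields[8]), int(fields[9])
                evalue = float(fields[10])
                bitscore = float(fields[11])
            except ValueError as exc:
                raise ValueError(f"parse error line {lineno}: {exc}") from None
            strand = "+"
            if sstart > send:
                strand = "-"
                sstart, send = send, sstart
            hsps.append(
                Hsp(
                    query_id=qid,
                    subject_id=sid,
                    q_interval=(qstart - 1, qend),
                    s_interval=(sstart - 1, send),
                    strand=strand,
                    identity=pident / 100.0,
                    aln_length=length,
                    # raw score back-computed from the bit score so that
                    # imported and internal hits chain on the same scale
                    raw_score=DEFAULT_SCHEME.raw_from_bitscore(bitscore),
                    bitscore=bitscore,
                    evalue=evalue,
                    raw_score_known=False,
                )
            )
    return hsps


def write_tabular_hits(hsps, path: str | Path) -> Path:
    """Write Hsps in the 12-column convention (inverse of the reader)."""
    path = Path(path)
    with open(path, "w") as fh:
        for h in hsps:
            qs, qe = h.q_interval
            ss, se = h.s_interval
            if h.strand == "-":
                sstart, send = se, ss + 1
            else:
                sstart, send = ss + 1, se
            n_ident = int(round(h.identity * h.aln_length))
            fh.write(
                "\t".join(
                    [
                        h.query_id,
                        h.subject_id,
                        f"{h.identity * 100.0:.2f}",
                        str(h.aln_length),
                        str(h.aln_length - n_ident),
                        "0",
                        str(qs + 1),
                        str(qe),
                        str(sstart),
                        str(send),
                        f"{h.evalue:.2e}",
                        f"{h.bitscore:.1f}",
                    ]
                )
                + "\n"
            )
    return path


# ---------------------------------------------------------------------------
# Browser-readable alignment report
# ---------------------------------------------------------------------------

_REPORT_CSS = """
body { font-family: sans-serif; margin: 1.5em; }
pre.aln { font-family: monospace; font-size: 13px; line-height: 1.35; }
span.diag { background: #ffd54d; font-weight: bold; }
p.note { color: #555; }
"""


def write_alignment_report(
    aln: AlignedSet,
    annotations: Iterable,
    path: str | Path,
    title: str = "Homoeolog alignment",
    block_width: int = 60,
) -> Path:
    """Write a self-contained ``.htm`` report of an alignment.

    Diagnostic columns are highlighted and marked with an asterisk rail
    beneath each sequence block, so subgenome-discriminating bases can be
    spotted in any web browser without extra software.
    """
    path = Path(path)
    if path.suffix != ".htm":
        path = path.with_suffix(".htm")
    marked: set[int] = set()
    for ann in annotations:
        col = getattr(ann, "column", ann)
        if not 0 <= int(col) < aln.length:
            raise ValueError(f"annotation column {col} outside alignment")
        marked.add(int(col))

    id_w = max(len(rid) for rid in aln.ids) + 2
    out = io.StringIO()
    out.write("<!DOCTYPE html>\n<html><head><meta charset='utf-8'>")
    out.write(f"<title>{html.escape(title)}</title>")
    out.write(f"<style>{_REPORT_CSS}</style></head><body>\n")
    out.write(f"<h1>{html.escape(title)}</h1>\n")
    out.write(
        f"<p class='note'>{len(aln.rows)} sequences, {aln.length} columns; "
        f"{len(marked)} diagnostic columns highlighted "
        "(asterisks mark polymorphic bases).</p>\n<pre class='aln'>"
    )
    for start in range(0, aln.length, block_width):
        stop = min(start + block_width, aln.length)
        for rid, rseq in aln.rows:
            out.write(html.escape(rid.ljust(id_w)))
            for c in range(start, stop):
                ch = html.escape(rseq[c])
                if c in marked:
                    out.write(f"<span class='diag'>{ch}</span>")
                else:
                    out.write(ch)
            out.write("\n")
        rail = "".join("*" if c in marked else " " for c in range(start, stop))
        out.write(" " * id_w + rail.rstrip() + "\n\n")
    out.write("</pre></body></html>\n")
    path.write_text(out.getvalue())
    return path
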