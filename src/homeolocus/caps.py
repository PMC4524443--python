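"""CAPS (cleaved amplified polymorphic sequence) marker discovery.

Given two allele sequences of one locus — e.g. the two parents of a
mapping population — find restriction enzymes whose recognition site is
created or destroyed by a SNP, and predict the digestion fragment
patterns that would separate on a gel.  Only natural CAPS is handled
(no mismatch-primer dCAPS engineering).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Sequence

from .msa import pairwise_align_global
from .seqio import SeqRecord, revcomp

_IUPAC_CLASS = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "[AG]", "Y": "[CT]", "S": "[CG]", "W": "[AT]",
    "K": "[GT]", "M": "[AC]", "B": "[CGT]", "D": "[AGT]",
    "H": "[ACT]", "V": "[ACG]", "N": "[ACGT]",
}


def _pattern_regex(site: str) -> re.Pattern:
    return re.compile("".join(_IUPAC_CLASS[c] for c in site))


@dataclass(frozen=True)
class Enzyme:
    """A restriction enzyme: IUPAC recognition site and top-strand cut
    offset (cut occurs before ``site_start + cut_offset_top``)."""

    name: str
    site: str
    cut_offset_top: int

    def __post_init__(self) -> None:
        if len(self.site) < 4:
            raise ValueError(f"{self.name}: site must be >= 4 bp")
        if not 0 <= self.cut_offset_top <= len(self.site):
            raise ValueError(f"{self.name}: cut offset outside site")
        if set(self.site) - set(_IUPAC_CLASS):
            raise ValueError(f"{self.name}: non-IUPAC site {self.site!r}")

    @property
    def palindromic(self) -> bool:
        return revcomp(self.site) == self.site


def load_catalog(path: str | Path | None = None) -> list[Enzyme]:
    """Load an enzyme catalog (name<TAB>site<TAB>cut_offset); defaults to
    the built-in set of common enzymes."""
    if path is None:
        text = (
            resources.files("homeolocus") / "data" / "enzymes.tsv"
        ).read_text()
    else:
        text = Path(path).read_text()
    enzymes = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 3:
            raise ValueError(f"malformed enzyme line: {line!r}")
        enzymes.append(Enzyme(fields[0], fields[1].upper(), int(fields[2])))
    return enzymes


def find_sites(seq: SeqRecord | str, enzyme: Enzyme) -> list[int]:
    """All cut positions of an enzyme on a sequence (both strands).

    Top-strand matches cut at ``start + cut_offset_top``; matches of the
    reverse-complement pattern (relevant for non-palindromic enzymes)
    cut at the mirrored offset.  Positions are sorted and deduplicated.
    """
    s = seq.seq if isinstance(seq, SeqRecord) else seq.upper()
    cuts: set[int] = set()
    pat = _pattern_regex(enzyme.site)
    for m in _finditer_overlapping(pat, s):
        cuts.add(m + enzyme.cut_offset_top)
    if not enzyme.palindromic:
        rc = revcomp(enzyme.site)
        pat_rc = _pattern_regex(rc)
        L = len(enzyme.site)
        for m in _finditer_overlapping(pat_rc, s):
            cuts.add(m + L - enzyme.cut_offset_top)
    return sorted(c for c in cuts if 0 <= c <= len(s))


def _finditer_overlapping(pat: re.Pattern, s: str) -> list[int]:
    out = []
    pos = 0
    while True:
        m = pat.search(s, pos)
        if m is None:
            return out
        out.append(m.start())
        pos = m.start() + 1


def digest(seq: SeqRecord | str, enzyme: Enzyme) -> list[int]:
    """Sorted fragment lengths after cutting at all sites (fragments sum
    to the sequence length; an uncut sequence yields one fragment)."""
    s = seq.seq if isinstance(seq, SeqRecord) else seq.upper()
    cuts = [c for c in find_sites(s, enzyme) if 0 < c < len(s)]
    bounds = [0] + cuts + [len(s)]
    return sorted(b - a for a, b in zip(bounds, bounds[1:]))


@dataclass(frozen=True)
class CapsCandidate:
    """An enzyme/SNP combination producing allele-distinguishable digests."""

    enzyme: Enzyme
    snp_pos: int  # column in the pairwise allele alignment
    cut_alleles: str  # "a" or "b": which allele is cut at the SNP site
    fragments_a: tuple[int, ...]
    fragments_b: tuple[int, ...]
    separability: int  # worst-case gel distance of a differential fragment


def _differential_fragments(fa: Sequence[int], fb: Sequence[int]):
    """Multiset differences between two fragment patterns."""
    from collections import Counter

    ca, cb = Counter(fa), Counter(fb)
    only_a = list((ca - cb).elements())
    only_b = list((cb - ca).elements())
    return only_a, only_b


def _separability(fa: Sequence[int], fb: Sequence[int]) -> int:
    only_a, only_b = _differential_fragments(fa, fb)
    sep = None
    for frag, other in ((f, fb) for f in only_a):
        d = min(abs(frag - o) for o in other)
        sep = d if sep is None else min(sep, d)
    for frag, other in ((f, fa) for f in only_b):
        d = min(abs(frag - o) for o in other)
        sep = d if sep is None else min(sep, d)
    return 0 if sep is None else sep


def find_caps(
    allele_a: SeqRecord,
    allele_b: SeqRecord,
    catalog: Sequence[Enzyme] | None = None,
    min_frag: int = 50,
) -> list[CapsCandidate]:
    """Screen a SNP-bearing allele pair against an enzyme catalog.

    The alleles are globally aligned; for every SNP column and enzyme, a
    candidate is reported when a recognition site overlapping the SNP
    exists in exactly one allele.  Candidates whose differential
    fragments are below ``min_frag`` (unresolvable on a 3% agarose gel)
    or whose patterns do not differ are dropped; the rest are ranked by
    fragment-size separability.
    """
    catalog = list(catalog) if catalog is not None else load_catalog()
    ra, rb, _ = pairwise_align_global(allele_a.seq, allele_b.seq)
    snps = [
        c for c, (x, y) in enumerate(zip(ra, rb))
        if x != y and x in "ACGT" and y in "ACGT"
    ]
    if not snps and allele_a.seq == allele_b.seq:
        raise ValueError("no polymorphism between alleles")
    candidates: list[CapsCandidate] = []
    pos_a = _column_to_pos(ra)
    pos_b = _column_to_pos(rb)
    for enz in catalog:
        L = len(enz.site)
        match_a = _match_intervals(allele_a.seq, enz)
        match_b = _match_intervals(allele_b.seq, enz)
        frags_a = tuple(digest(allele_a.seq, enz))
        frags_b = tuple(digest(allele_b.seq, enz))
        for c in snps:
            a_hit = _overlaps(match_a, pos_a[c])
            b_hit = _overlaps(match_b, pos_b[c])
            if a_hit == b_hit:
                continue
            if frags_a == frags_b:
                continue
            only_a, only_b = _differential_fragments(frags_a, frags_b)
            if any(f < min_frag for f in only_a + only_b):
                continue
            candidates.append(
                CapsCandidate(
                    enzyme=enz,
                    snp_pos=c,
                    cut_alleles="a" if a_hit else "b",
                    fragments_a=frags_a,
                    fragments_b=frags_b,
                    separability=_separability(frags_a, frags_b),
                )
            )
    candidates.sort(
        key=lambda c: (-c.separability, c.enzyme.name, c.snp_pos)
    )
    return candidates


def _column_to_pos(gapped: str) -> list[int]:
    """Ungapped position of each alignment column (gap -> next base)."""
    out = []
    p = 0
    for ch in gapped:
        out.append(p)
        if ch != "-":
            p += 1
    return out


def _match_intervals(seq: str, enzyme: Enzyme) -> list[tuple[int, int]]:
    """Recognition-site match intervals on both strands of ``seq``."""
    pats = [_pattern_regex(enzyme.site)]
    if not enzyme.palindromic:
        pats.append(_pattern_regex(revcomp(enzyme.site)))
    L = len(enzyme.site)
    out = []
    for pat in pats:
        for m in _finditer_overlapping(pat, seq):
            out.append((m, m + L))
    return sorted(set(out))


def _overlaps(intervals: Sequence[tuple[int, int]], pos: int) -> bool:
    return any(lo <= pos < hi for lo, hi in intervals)
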