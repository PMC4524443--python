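"""Diagnostic-site calling, Tm, primer design, in-silico PCR."""

import random

import pytest
from Bio.SeqUtils import MeltingTemp as BioTm

from homeolocus.msa import Msa, RowInfo
from homeolocus.polymorphism import (
    DiagnosticSite,
    NoPrimerPairError,
    PrimerConstraints,
    conserved_regions,
    design_primer_pairs,
    diagnostic_sites,
    gc_fraction,
    insilico_pcr,
    melting_temp,
    primer_windows,
    row_base_index,
    site_to_subject_coord,
)
from homeolocus.seqio import AlignedSet, SeqRecord, revcomp


def _mk_msa(rows, provenance=None):
    return Msa(AlignedSet(rows), query_id="q", provenance=provenance or {})


def _random_seq(rng, n):
    return "".join(rng.choice("ACGT") for _ in range(n))


class TestDiagnosticSites:
    def test_single_snp(self):
        msa = _mk_msa([("A", "ACGT"), ("B", "ACGT"), ("C", "ACAT")])
        sites = diagnostic_sites(msa, "C")
        assert len(sites) == 1
        s = sites[0]
        assert (s.column, s.target_state, s.background_state, s.kind) == \
            (2, "A", "G", "SNP")

    def test_identical_rows_empty(self):
        msa = _mk_msa([("A", "ACGT"), ("B", "ACGT"), ("C", "ACGT")])
        assert diagnostic_sites(msa, "C") == []

    def test_background_disagreement_not_diagnostic(self):
        msa = _mk_msa([("A", "AAAA"), ("B", "ACAA"), ("C", "AGAA")])
        for row in "ABC":
            assert diagnostic_sites(msa, row) == []

    def test_relaxed_mode_allows_varied_background(self):
        msa = _mk_msa([("A", "AAAA"), ("B", "ACAA"), ("C", "AGAA")])
        sites = diagnostic_sites(msa, "C", strict_background=False)
        assert [s.column for s in sites] == [1]

    def test_indel_run_collapsed(self):
        msa = _mk_msa([
            ("A", "ACGTACGTAC"),
            ("B", "ACGTACGTAC"),
            ("C", "ACG---GTAC"),
        ])
        sites = diagnostic_sites(msa, "C")
        assert len(sites) == 1
        assert sites[0].kind == "indel" and sites[0].length == 3

    def test_ambiguity_column_skipped(self):
        msa = _mk_msa([("A", "ANGT"), ("B", "ANGT"), ("C", "ACAT")])
        sites = diagnostic_sites(msa, "C")
        assert [s.column for s in sites] == [2]

    def test_terminal_overhang_not_called(self):
        msa = _mk_msa([
            ("A", "CCGTACGTAC"),
            ("B", "CCGTACGTAC"),
            ("C", "--GTACGTAC"),
        ])
        assert diagnostic_sites(msa, "C") == []

    def test_unknown_row(self):
        msa = _mk_msa([("A", "ACGT"), ("B", "ACGT")])
        with pytest.raises(ValueError, match="row not in alignment"):
            diagnostic_sites(msa, "Z")


class TestConservedRegions:
    def test_fully_identical(self):
        msa = _mk_msa([("A", "ACGT" * 25), ("B", "ACGT" * 25)])
        assert [r.col_interval for r in conserved_regions(msa)] == [(0, 100)]

    def test_central_snp_splits(self):
        left = "ACGTACGTACGTACGTACG"  # 19
        right = "TGCATGCATGCATGCATGCA"  # 20
        msa = _mk_msa([("A", left + "A" + right), ("B", left + "C" + right)])
        assert [r.col_interval for r in conserved_regions(msa, min_len=18)] == \
            [(0, 19), (20, 40)]

    def test_disjoint_from_diagnostic_columns(self):
        rng = random.Random(17)
        base = _random_seq(rng, 150)
        rows = [("A", base), ("B", base)]
        mutated = list(base)
        for p in (30, 70, 110):
            mutated[p] = rng.choice("ACGT".replace(mutated[p], ""))
        rows.append(("C", "".join(mutated)))
        msa = _mk_msa(rows)
        diag_cols = {s.column for s in diagnostic_sites(msa, "C")}
        for region in conserved_regions(msa, min_len=10):
            lo, hi = region.col_interval
            assert diag_cols.isdisjoint(range(lo, hi))


class TestMeltingTemp:
    @pytest.mark.parametrize(
        "seq,expected",
        [
            ("AAAATTTT", 16.0),
            ("GGGGCCCC", 32.0),
            ("GGGGGCCCCCATATATATAT", 64.9 + 41 * (10 - 16.4) / 20),
        ],
    )
    def test_closed_form(self, seq, expected):
        assert melting_temp(seq) == pytest.approx(expected)

    def test_wallace_rule_matches_biopython(self):
        for short in ("AATTGGCC", "ACGTACGTAC", "GGGGGGGGG"):
            assert melting_temp(short) == pytest.approx(BioTm.Tm_Wallace(short))

    def test_monotone_in_gc(self):
        tms = [
            melting_temp("G" * gc + "A" * (20 - gc)) for gc in range(0, 21)
        ]
        assert all(b - a == pytest.approx(41 / 20) for a, b in zip(tms, tms[1:]))

    def test_ambiguous_rejected(self):
        with pytest.raises(ValueError, match="ambiguous"):
            melting_temp("ACGTNACGTACG")


def _site(col, target="C", t="A", b="G", kind="SNP"):
    return DiagnosticSite(col, target, t, b, kind)


class TestPrimerWindows:
    def _two_site_msa(self, rng=None, n=200, positions=(60, 70)):
        rng = rng or random.Random(23)
        base = _random_seq(rng, n)
        mutated = list(base)
        for p in positions:
            mutated[p] = rng.choice("ACGT".replace(mutated[p], ""))
        msa = _mk_msa([("A", base), ("B", base), ("C", "".join(mutated))])
        return msa, diagnostic_sites(msa, "C")

    def test_window_covering_two_sites_outranks(self):
        msa, sites = self._two_site_msa()
        wins = primer_windows(sites, msa, "C")
        assert len(wins[0].diag_positions) == 2
        assert all(len(w.diag_positions) <= 2 for w in wins)

    def test_no_sites_no_windows(self):
        msa = _mk_msa([("A", "ACGT" * 30), ("B", "ACGT" * 30), ("C", "ACGT" * 30)])
        assert primer_windows([], msa, "C") == []

    def test_matches_exhaustive_window_scan(self):
        msa, sites = self._two_site_msa()
        got = {(w.start, w.end, w.strand)
               for w in primer_windows(sites, msa, "C")}
        row = msa.row("C")
        positions = [row_base_index(row, s.column) for s in sites]
        expected = set()
        L = len(row.replace("-", ""))
        for start in range(L):
            for length in range(18, 28):
                end = start + length
                if end > L:
                    continue
                if any(end - 3 <= p < end for p in positions):
                    expected.add((start, end, "F"))
                if any(start <= p < start + 3 for p in positions):
                    expected.add((start, end, "R"))
        assert got == expected


class TestDesignPrimerPairs:
    def test_identical_rows_error(self):
        msa = _mk_msa([("A", "ACGT" * 60), ("B", "ACGT" * 60), ("C", "ACGT" * 60)])
        with pytest.raises(NoPrimerPairError, match="no genome-specific pair"):
            design_primer_pairs(msa, "C")

    def test_single_site_cannot_reach_two(self):
        rng = random.Random(29)
        base = _random_seq(rng, 400)
        mutated = list(base)
        mutated[200] = rng.choice("ACGT".replace(mutated[200], ""))
        msa = _mk_msa([("A", base), ("B", base), ("C", "".join(mutated))])
        with pytest.raises(NoPrimerPairError):
            design_primer_pairs(msa, "C")

    def test_two_planted_sites_top_pair_covers_both(self):
        rng = random.Random(37)
        base = _random_seq(rng, 500)
        mutated = list(base)
        for p in (150, 330):
            mutated[p] = rng.choice("ACGT".replace(mutated[p], ""))
        msa = _mk_msa([("A", base), ("B", base), ("C", "".join(mutated))])
        pairs = design_primer_pairs(msa, "C")
        top = pairs[0]
        assert top.total_diag == 2
        # each primer anchors one site in its 3'-terminal 3 bases
        f0, f1 = top.forward.row_interval
        r0, r1 = top.reverse.row_interval
        assert f1 - 3 <= 150 < f1
        assert r0 <= 330 < r0 + 3
        cons = PrimerConstraints()
        for p in (top.forward, top.reverse):
            assert cons.tm_range[0] <= p.tm <= cons.tm_range[1]
            assert cons.gc_range[0] <= p.gc <= cons.gc_range[1]
            assert cons.len_range[0] <= len(p.seq) <= cons.len_range[1]
        assert cons.product_range[0] <= top.product_len <= cons.product_range[1]

    def test_primer_sequences_come_from_target_row(self):
        rng = random.Random(38)
        base = _random_seq(rng, 500)
        mutated = list(base)
        for p in (150, 330):
            mutated[p] = rng.choice("ACGT".replace(mutated[p], ""))
        target_seq = "".join(mutated)
        msa = _mk_msa([("A", base), ("B", base), ("C", target_seq)])
        for pair in design_primer_pairs(msa, "C"):
            f0, f1 = pair.forward.row_interval
            assert pair.forward.seq == target_seq[f0:f1]
            r0, r1 = pair.reverse.row_interval
            assert pair.reverse.seq == revcomp(target_seq[r0:r1])


class TestInsilicoPcr:
    def _pair_for(self, template, f_start=50, r_end=350, length=20):
        rng = random.Random(2)
        fwd_seq = template[f_start:f_start + length]
        rev_seq = revcomp(template[r_end - length:r_end])
        from homeolocus.polymorphism import Primer, PrimerPair

        fwd = Primer(fwd_seq, "C", (f_start, f_start + length),
                     (f_start, f_start + length), "F", 60.0,
                     gc_fraction(fwd_seq), (1, 2))
        rev = Primer(rev_seq, "C", (r_end - length, r_end),
                     (r_end - length, r_end), "R", 60.0,
                     gc_fraction(rev_seq), (3, 4))
        return PrimerPair(fwd, rev, r_end - f_start, 2)

    def test_perfect_match_product(self):
        rng = random.Random(51)
        template = _random_seq(rng, 600)
        pair = self._pair_for(template)
        products = insilico_pcr(pair, [SeqRecord("t", template)])
        assert products == [("t", (50, 350), 300)]

    def test_product_found_on_either_template_strand(self):
        rng = random.Random(52)
        template = _random_seq(rng, 600)
        pair = self._pair_for(template)
        products = insilico_pcr(pair, [SeqRecord("rc", revcomp(template))])
        assert len(products) == 1
        assert products[0][2] == 300

    def test_three_prime_mismatch_blocks_amplification(self):
        rng = random.Random(53)
        template = _random_seq(rng, 600)
        pair = self._pair_for(template)
        # mutate the base under the forward primer's 3' terminus
        t = list(template)
        t[69] = "A" if t[69] != "A" else "C"
        products = insilico_pcr(pair, [SeqRecord("t", "".join(t))])
        assert products == []

    def test_internal_mismatches_tolerated(self):
        rng = random.Random(54)
        template = _random_seq(rng, 600)
        pair = self._pair_for(template)
        t = list(template)
        t[55] = "A" if t[55] != "A" else "C"
        t[58] = "A" if t[58] != "A" else "C"
        products = insilico_pcr(pair, [SeqRecord("t", "".join(t))])
        assert len(products) == 1

    def test_template_without_sites(self):
        rng = random.Random(55)
        template = _random_seq(rng, 600)
        other = _random_seq(random.Random(99), 600)
        pair = self._pair_for(template)
        assert insilico_pcr(pair, [SeqRecord("o", other)]) == []

    def test_empty_templates_rejected(self):
        rng = random.Random(56)
        template = _random_seq(rng, 600)
        with pytest.raises(ValueError, match="nonempty"):
            insilico_pcr(self._pair_for(template), [])


class TestCoordinateMapping:
    def test_site_maps_to_contig_position(self):
        contig = SeqRecord("ctg", "AAAACCCCGGGGTTTTACGTAAAA")
        # extracted [4:20) on plus strand
        row_seq = contig.seq[4:20]
        prov = {"r": RowInfo("r", "ctg", (4, 20), "+")}
        msa = _mk_msa([("r", row_seq), ("x", row_seq)], provenance=prov)
        site = _site(5, target="r", t="C", b="G")
        cid, pos = site_to_subject_coord(msa, site)
        assert (cid, pos) == ("ctg", 9)

    def test_minus_strand_mapping(self):
        contig = SeqRecord("ctg", "AAAACCCCGGGGTTTTACGTAAAA")
        row_seq = revcomp(contig.seq[4:20])
        prov = {"r": RowInfo("r", "ctg", (4, 20), "-")}
        msa = _mk_msa([("r", row_seq), ("x", row_seq)], provenance=prov)
        site = _site(0, target="r")
        cid, pos = site_to_subject_coord(msa, site)
        assert (cid, pos) == ("ctg", 19)
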