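"""End-to-end orchestration: search -> chain -> extract -> align ->
report -> diagnostic sites -> primers, with per-query failure isolation.

Queries flow through a monotone funnel — every query either progresses
or is recorded with the stage it stopped at (no hits, no alignment, no
primers) — so a run over thousands of queries never aborts on one bad
gene, and the manifest reproduces the per-stage tallies of a survey run.
"""

from __future__ import annotations

import json
import logging
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from . import __version__
from .homology import DEFAULT_SCHEME, Hsp, ScoringScheme, SubjectIndex, \
    filter_hits, find_hsps
from .loci import ExtractedLocus, LocusModel, PipelineConfig, chain_hsps, \
    collect_homeolog_set, extract_locus
from .msa import Msa, msa_from_loci
from .polymorphism import DiagnosticSite, NoPrimerPairError, PrimerPair, \
    diagnostic_sites, design_primer_pairs, insilico_pcr
from .seqio import SeqRecord, write_aligned_fasta, write_alignment_report, \
    write_fasta, write_tabular_hits

logger = logging.getLogger(__name__)


@dataclass
class QueryResult:
    """Everything the pipeline derived for one query."""

    query: SeqRecord
    status: str  # ok | no_hits | no_alignment | no_primers
    hsps: list[Hsp] = field(default_factory=list)
    loci: list[LocusModel] = field(default_factory=list)
    extracted: list[ExtractedLocus] = field(default_factory=list)
    msa: Msa | None = None
    sites: dict[str, list[DiagnosticSite]] = field(default_factory=dict)
    primer_pairs: dict[str, list[PrimerPair]] = field(default_factory=dict)


@dataclass
class RunManifest:
    """Machine-readable per-run summary (the funnel tallies)."""

    version: str
    seed: int | None
    config: dict
    statuses: dict[str, str]
    counts: dict[str, int]

    def to_json(self) -> str:
        return json.dumps(
            {
                "version": self.version,
                "seed": self.seed,
                "config": self.config,
                "statuses": self.statuses,
                "counts": self.counts,
            },
            indent=2,
            sort_keys=True,
        )

    def to_tsv(self) -> str:
        lines = ["query\tstatus"]
        for qid in sorted(self.statuses):
            lines.append(f"{qid}\t{self.statuses[qid]}")
        return "\n".join(lines) + "\n"


def process_query(
    query: SeqRecord,
    index: SubjectIndex,
    contigs_by_id: dict[str, SeqRecord],
    cfg: PipelineConfig,
    scheme: ScoringScheme = DEFAULT_SCHEME,
    design_primers: bool = True,
) -> QueryResult:
    """Run every stage for one query; never raises for per-query failure."""
    res = QueryResult(query=query, status="ok")
    hsps = find_hsps(query, index, scheme=scheme)
    hsps = filter_hits(hsps, max_hits=cfg.max_hits, evalue_max=cfg.evalue_max)
    res.hsps = hsps
    if not hsps:
        res.status = "no_hits"
        return res

    groups: dict[tuple[str, str], list[Hsp]] = defaultdict(list)
    for h in hsps:
        groups[(h.subject_id, h.strand)].append(h)
    loci: list[LocusModel] = []
    for key in sorted(groups):
        loci.extend(chain_hsps(groups[key], cfg))
    # keep only span-disjoint loci per subject (best chain first): an
    # overlapping lower-scoring chain, e.g. from the opposite strand of a
    # near-palindromic stretch, is the same region, not a paralog
    loci.sort(key=lambda l: (-l.chain_score, l.subject_id, l.span))
    accepted: list[LocusModel] = []
    for locus in loci:
        lo, hi = locus.span
        clash = any(
            a.subject_id == locus.subject_id
            and min(hi, a.span[1]) - max(lo, a.span[0]) > 0.3 * (hi - lo)
            for a in accepted
        )
        if not clash:
            accepted.append(locus)
    loci = accepted
    res.loci = loci
    if not loci:
        res.status = "no_hits"
        return res

    extracted = [
        extract_locus(l, contigs_by_id[l.subject_id], cfg) for l in loci
    ]
    # drop exact duplicates, keep deterministic order
    records = collect_homeolog_set(query, extracted)
    rec_ids = {r.id for r in records}
    extracted = [e for e in extracted if e.record.id in rec_ids]
    res.extracted = extracted
    if len(extracted) < 2:
        res.status = "no_alignment"
        return res

    res.msa = msa_from_loci(query, extracted)
    if design_primers:
        any_pair = False
        for row_id in res.msa.row_ids:
            sites = diagnostic_sites(res.msa, row_id)
            res.sites[row_id] = sites
            try:
                res.primer_pairs[row_id] = design_primer_pairs(
                    res.msa, row_id, sites=sites
                )
                any_pair = True
            except NoPrimerPairError as exc:
                logger.info("%s/%s: %s", query.id, row_id, exc)
                res.primer_pairs[row_id] = []
        if not any_pair:
            res.status = "no_primers"
    return res


def run_pipeline(
    queries: Sequence[SeqRecord],
    contigs: Sequence[SeqRecord],
    cfg: PipelineConfig | None = None,
    out_dir: str | Path | None = None,
    scheme: ScoringScheme = DEFAULT_SCHEME,
    seed: int | None = None,
    write_reports: bool = False,
    design_primers: bool = True,
) -> tuple[list[QueryResult], RunManifest]:
    """Run the full locus-isolation pipeline over a query set.

    Per-query failures are recorded in the manifest and skipped; only
    unreadable/empty inputs are fatal.  When ``out_dir`` is given, the
    per-query homoeolog FASTA, aligned FASTA, optional ``.htm`` reports,
    primer tables, hit tables and the manifest are written there.
    """
    if not queries:
        raise ValueError("empty input: no queries")
    if not contigs:
        raise ValueError("empty input: no genome contigs")
    cfg = cfg or PipelineConfig()
    index = SubjectIndex(contigs)
    contigs_by_id = {c.id: c for c in contigs}

    results: list[QueryResult] = []
    for query in queries:
        logger.info("query %s: searching", query.id)
        try:
            res = process_query(query, index, contigs_by_id, cfg,
                                scheme=scheme, design_primers=design_primers)
        except Exception:  # per-query isolation
            logger.exception("query %s failed", query.id)
            res = QueryResult(query=query, status="no_hits")
        logger.info("query %s: status=%s loci=%d", query.id, res.status,
                    len(res.loci))
        results.append(res)

    counts = {
        "queries": len(results),
        "with_hits": sum(1 for r in results if r.hsps),
        "with_alignments": sum(1 for r in results if r.msa is not None),
        "with_primers": sum(
            1 for r in results if any(r.primer_pairs.values())
        ),
    }
    manifest = RunManifest(
        version=__version__,
        seed=seed,
        config={
            "max_intron": cfg.max_intron,
            "min_exon": cfg.min_exon,
            "flank": cfg.flank,
            "evalue_max": cfg.evalue_max,
            "max_hits": cfg.max_hits,
        },
        statuses={r.query.id: r.status for r in results},
        counts=counts,
    )

    if out_dir is not None:
        _write_outputs(results, manifest, Path(out_dir), write_reports)
    return results, manifest


def _write_outputs(
    results: Sequence[QueryResult],
    manifest: RunManifest,
    out_dir: Path,
    write_reports: bool,
) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "loci").mkdir(exist_ok=True)
    (out_dir / "aln").mkdir(exist_ok=True)
    all_hsps = []
    for res in results:
        all_hsps.extend(res.hsps)
        if res.extracted:
            write_fasta(
                [e.record for e in res.extracted],
                out_dir / "loci" / f"{res.query.id}.fa",
            )
        if res.msa is not None:
            write_aligned_fasta(res.msa.aln, out_dir / "aln" / f"{res.query.id}.fa")
            if write_reports:
                marked = sorted(
                    {s.column for sites in res.sites.values() for s in sites}
                )
                write_alignment_report(
                    res.msa.aln, marked,
                    out_dir / "aln" / f"{res.query.id}.htm",
                    title=f"Homoeolog alignment — {res.query.id}",
                )
    if all_hsps:
        write_tabular_hits(all_hsps, out_dir / "hits.tsv")
    _write_primer_table(results, out_dir / "primers.tsv")
    (out_dir / "manifest.json").write_text(manifest.to_json())
    (out_dir / "manifest.tsv").write_text(manifest.to_tsv())


def _write_primer_table(results: Sequence[QueryResult], path: Path) -> None:
    header = (
        "query\ttarget_row\trank\tstrand\tseq\trow_start\trow_end\t"
        "tm\tgc\tdiag_cols\tproduct_len\ttotal_diag"
    )
    lines = [header]
    for res in results:
        for row_id in sorted(res.primer_pairs):
            for rank, pair in enumerate(res.primer_pairs[row_id], 1):
                for primer in (pair.forward, pair.reverse):
                    lines.append(
                        "\t".join(
                            [
                                res.query.id,
                                row_id,
                                str(rank),
                                primer.strand,
                                primer.seq,
                                str(primer.row_interval[0]),
                                str(primer.row_interval[1]),
                                f"{primer.tm:.2f}",
                                f"{primer.gc:.3f}",
                                ",".join(map(str, primer.diag_cols)),
                                str(pair.product_len),
                                str(pair.total_diag),
                            ]
                        )
                    )
    path.write_text("\n".join(lines) + "\n")
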