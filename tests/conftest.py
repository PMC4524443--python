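"""Shared fixtures: simulated allopolyploid runs at two scales.

The large run (50 genes, 3 subgenomes, 2% divergence, 0.1% indels) is
the survey-scale experiment used by the end-to-end tests; it is built
once per session.
"""

from __future__ import annotations

import pytest

from homeolocus.pipeline import run_pipeline
from homeolocus.polymorphism import site_to_subject_coord
from homeolocus.synthetic import SimConfig, simulate


@pytest.fixture(scope="session")
def small_run():
    """5-gene hexaploid-style simulation plus a full pipeline run."""
    cfg = SimConfig(n_genes=5, seed=1)
    queries, contigs, truth = simulate(cfg)
    results, manifest = run_pipeline(queries, contigs, seed=1)
    return cfg, queries, contigs, truth, results, manifest


@pytest.fixture(scope="session")
def survey_run():
    """50-gene, 3-subgenome run at 2% divergence / 0.1% indels (seed 7)."""
    cfg = SimConfig(n_genes=50, seed=7)
    queries, contigs, truth = simulate(cfg)
    results, manifest = run_pipeline(queries, contigs, seed=7)
    return cfg, queries, contigs, truth, results, manifest


@pytest.fixture(scope="session")
def null_run():
    """Zero-divergence control: all subgenome copies identical."""
    cfg = SimConfig(
        n_genes=5, divergence=0.0, indel_rate=0.0,
        planted_per_subgenome=0, seed=3,
    )
    queries, contigs, truth = simulate(cfg)
    results, manifest = run_pipeline(queries, contigs, seed=3)
    return cfg, queries, contigs, truth, results, manifest


def called_sites_of(result):
    """Flatten one query's diagnostic calls to (contig, kind, pos, subgenome)."""
    called = []
    for row_id, sites in result.sites.items():
        for s in sites:
            cid, pos = site_to_subject_coord(result.msa, s)
            called.append((cid, s.kind, pos, cid.rsplit("_", 1)[1]))
    return called
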