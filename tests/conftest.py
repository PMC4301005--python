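"""Shared fixtures: all test data is generated programmatically and seeded.

The heavyweight objects — the full study-condition fixture, its scanned
gene hits, the end-to-end pipeline run, and the twenty-seed fixture bank —
are session-scoped so their cost is paid once.
"""

from __future__ import annotations

import pytest

from rdnafinish.pipeline import run_finishing_plan
from rdnafinish.rdna import scan_contigs
from rdnafinish.seqio import Contig
from rdnafinish.simulate import (
    DraftProfile,
    corrupt_to_draft,
    cr1_like_fixture,
    generate_genome,
)

FIXTURE_SEED = 7
TWENTY_SEEDS = list(range(20))


@pytest.fixture(scope="session")
def cr1():
    """Full study-condition fixture: (GenomeTruth, DraftTruth)."""
    return cr1_like_fixture(seed=FIXTURE_SEED)


@pytest.fixture(scope="session")
def cr1_genes(cr1):
    return cr1[0].consensus_genes()


@pytest.fixture(scope="session")
def genome_hits(cr1, cr1_genes):
    """Consensus-gene hits on the full synthetic genome."""
    truth, _draft = cr1
    return scan_contigs([Contig("genome", truth.seq)], cr1_genes)


@pytest.fixture(scope="session")
def pipeline_report(cr1, cr1_genes, tmp_path_factory):
    """One full end-to-end finishing run on the study-condition fixture."""
    truth, draft = cr1
    outdir = tmp_path_factory.mktemp("finishing_run")
    return run_finishing_plan(
        draft.contigs,
        reference=Contig("reference", truth.seq),
        genes=cr1_genes,
        pcr_template=draft.relocated_genome,
        final_assembly=truth.seq,
        outdir=outdir,
    )


@pytest.fixture(scope="session")
def twenty_fixtures():
    """Twenty independently seeded study-condition fixtures."""
    return [cr1_like_fixture(seed=s) for s in TWENTY_SEEDS]


MINI_PROFILE = DraftProfile(
    contig_count=13,
    rrna_only_count=4,
    n_run_count=40,
    placeable_count=3,
    relocation_bp=60_000,
    non_rdna_gap_range=(6_000, 9_000),
)


@pytest.fixture(scope="session")
def mini():
    """A small (1.2 Mb, 4-operon) fixture for cheaper integration tests."""
    truth = generate_genome(size=1_200_000, operon_count=4, seed=11, margin=40_000)
    draft = corrupt_to_draft(truth, MINI_PROFILE, seed=11)
    return truth, draft
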