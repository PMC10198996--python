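"""Shared fixtures: one synthetic multi-species dataset per session.

The fixture uses the default planted design (the study layout at toy
scale) with reduced sequencing depth so the whole suite stays fast; tests
that need specific depths or configurations build their own.
"""

import json

import pytest

from novostart import io as nio
from novostart.pipeline import RunConfig, run_all
from novostart.synthetic_data import FixtureConfig, make_fixture

FIXTURE_SEED = 7


@pytest.fixture(scope="session")
def fixture(tmp_path_factory):
    outdir = tmp_path_factory.mktemp("fixture")
    cfg = FixtureConfig(
        seed=FIXTURE_SEED, reads_per_human_sample=8000, reads_per_chimp_sample=6000
    )
    paths, truth = make_fixture(cfg, str(outdir))
    return {"config": cfg, "paths": paths, "truth": truth, "dir": str(outdir)}


@pytest.fixture(scope="session")
def human_genome(fixture):
    return nio.read_genome(fixture["paths"]["fasta_human"], "human")


@pytest.fixture(scope="session")
def human_transcripts(fixture, human_genome):
    return nio.read_gff3(fixture["paths"]["gff_human"], human_genome)


@pytest.fixture(scope="session")
def snvs(fixture):
    return nio.read_vcf(fixture["paths"]["vcf"])


@pytest.fixture(scope="session")
def pipeline_run(fixture, tmp_path_factory):
    out = tmp_path_factory.mktemp("pipeline_out")
    cfg = RunConfig.from_fixture(fixture["paths"], fixture["truth"], str(out), seed=11)
    summary = run_all(cfg)
    return {"summary": summary, "out": str(out), "config": cfg}
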