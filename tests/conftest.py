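"""Shared fixtures: one seed-17 synthetic transcriptome per session."""

from __future__ import annotations

import pytest

from prepromine import fixtures as fx
from prepromine.pipeline import RunConfig, run_pipeline

FIXTURE_SEED = 17
N_DECOYS = 100


@pytest.fixture(scope="session")
def fixture_bundle(tmp_path_factory):
    """Synthetic transcriptome (7 precursors + 100 decoys) and manifest."""
    d = tmp_path_factory.mktemp("transcriptome")
    fasta = d / "transcriptome.fasta"
    manifest_path = d / "manifest.json"
    records, manifest = fx.build_transcriptome(
        n_decoys=N_DECOYS,
        seed=FIXTURE_SEED,
        out_fasta=fasta,
        out_manifest=manifest_path,
    )
    return {
        "fasta": fasta,
        "manifest_path": manifest_path,
        "manifest": manifest,
        "records": records,
    }


@pytest.fixture(scope="session")
def pipeline_result(fixture_bundle, tmp_path_factory):
    """Full pipeline run over the session transcriptome."""
    out = tmp_path_factory.mktemp("run")
    config = RunConfig(
        input_fasta=str(fixture_bundle["fasta"]),
        aminopeptidase_l_rule=True,
        seed=FIXTURE_SEED,
        out_dir=str(out),
    )
    return run_pipeline(config)
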