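import json
from pathlib import Path

import pytest
from hypothesis import settings

import hccnet as h

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def dataset(tmp_path_factory):
    """Full demo dataset at the study conditions (19 studies, support 10,
    27 high-degree seeds, articulation-vertex hub, n=364 cohort)."""
    d = tmp_path_factory.mktemp("fixture")
    truth = h.generate_dataset(d, seed=11)
    return d, truth


@pytest.fixture(scope="session")
def pipeline_report(dataset, tmp_path_factory):
    d, truth = dataset
    out = tmp_path_factory.mktemp("run")
    cfg = h.PipelineConfig(
        study_dir=str(d / "studies"),
        interactome_path=str(d / "interactome.tsv"),
        tissue_path=str(d / "tissue_genes.txt"),
        gmt_path=str(d / "pathways.gmt"),
        survival_path=str(d / "survival.tsv"),
        out_dir=str(out),
    )
    return h.run_pipeline(cfg), cfg, truth
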