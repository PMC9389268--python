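import numpy as np
import pytest

from triohet import RunConfig, run_pipeline
from triohet.io import CountMatrix, Role, SampleDesign
from triohet.simulate import default_fixture


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    """The pinned 500-gene x 9-sample synthetic trio dataset."""
    outdir = tmp_path_factory.mktemp("fixture")
    paths = default_fixture(outdir)
    return paths


@pytest.fixture(scope="session")
def pipeline_run(fixture_dir, tmp_path_factory):
    """A completed pipeline run on the pinned fixture."""
    outdir = tmp_path_factory.mktemp("run")
    cfg = RunConfig(
        counts=str(fixture_dir["counts"]),
        design=str(fixture_dir["design"]),
        gene_lengths=str(fixture_dir["lengths"]),
        annotation=str(fixture_dir["annotation"]),
        outdir=str(outdir),
    )
    summary = run_pipeline(cfg)
    return cfg, outdir, summary


@pytest.fixture
def small_counts():
    rng = np.random.default_rng(42)
    return CountMatrix(
        gene_ids=tuple(f"g{i}" for i in range(20)),
        sample_ids=tuple(f"s{i}" for i in range(6)),
        counts=rng.integers(0, 500, size=(20, 6)),
    )


@pytest.fixture
def trio_design():
    roles = [Role.FEMALE_PARENT, Role.MALE_PARENT, Role.HYBRID]
    out = []
    for prefix, role in zip("FMH", roles):
        for rep in (1, 2, 3):
            out.append(SampleDesign(f"{prefix}{rep}", role, rep))
    return out
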