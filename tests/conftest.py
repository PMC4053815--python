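import numpy as np
import pytest

from promcage.fixtures import FixtureSpec, make_fixture
from promcage.pipeline import RunConfig, run_pipeline

BENCH_SEED = 0


@pytest.fixture(scope="session")
def bundle(tmp_path_factory):
    """Default synthetic dataset with planted promoters."""
    outdir = tmp_path_factory.mktemp("fixture")
    return make_fixture(FixtureSpec(seed=BENCH_SEED), outdir)


def config_for(bundle, outdir, **overrides):
    base = dict(
        cage={k: str(v) for k, v in bundle["cage"].items()},
        gtf=str(bundle["gtf"]),
        mirna_gff3=str(bundle["gff3"]),
        genome_fasta=str(bundle["genome"]),
        conservation=str(bundle["conservation"]),
        tata_pfm=str(bundle["tata_pfm"]),
        repeats=str(bundle["repeats"]),
        known_promoters=str(bundle["known_promoters"]),
        seed=BENCH_SEED,
        outdir=str(outdir),
    )
    base.update(overrides)
    return RunConfig(**base)


@pytest.fixture(scope="session")
def pipeline_result(bundle, tmp_path_factory):
    """Full pipeline run with the feature-based belief prior."""
    outdir = tmp_path_factory.mktemp("run_informative")
    return run_pipeline(config_for(bundle, outdir))


@pytest.fixture(scope="session")
def flat_result(bundle, tmp_path_factory):
    """Counts-only baseline run (global mixing proportion, no beliefs)."""
    outdir = tmp_path_factory.mktemp("run_flat")
    return run_pipeline(config_for(bundle, outdir, prior_mode="flat"))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
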