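import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def study_dir(tmp_path_factory):
    """One default synthetic study shared across tests (seeded)."""
    from mirsnp.pipeline import simulate_full_study

    d = tmp_path_factory.mktemp("study")
    truth = simulate_full_study(d, seed=11)
    return d, truth


@pytest.fixture(scope="session")
def discovery_run(study_dir, tmp_path_factory):
    """Discovery executed once on the shared study."""
    from mirsnp.pipeline import RunConfig, run_discovery

    d, truth = study_dir
    out = tmp_path_factory.mktemp("discovery_out")
    cfg = RunConfig(
        counts_tsv=str(d / "publication_counts.tsv"),
        utr_fasta=str(d / "utrs.fasta"),
        mirna_fasta=str(d / "mirnas.fasta"),
        vcf=str(d / "variants.vcf"),
        go_tsv=str(d / "go_annotations.tsv"),
        seed=11,
        outdir=str(out),
    )
    return run_discovery(cfg), truth, cfg


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
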