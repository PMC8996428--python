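import pytest

from vqsurvey.report import SurveyConfig, run_pipeline
from vqsurvey.seqio import load_genome
from vqsurvey.synthetic_data import GenConfig, generate


@pytest.fixture(scope="session")
def manifest(tmp_path_factory):
    """Default synthetic hexaploid bundle (seed 42), generated once."""
    out = tmp_path_factory.mktemp("synthetic")
    return generate(GenConfig(seed=42), out)


@pytest.fixture(scope="session")
def bundle(manifest):
    return load_genome(manifest.files["genome"], manifest.files["gff3"])


@pytest.fixture(scope="session")
def survey(manifest, tmp_path_factory):
    """Full pipeline run over the synthetic bundle."""
    out = tmp_path_factory.mktemp("survey_out")
    cfg = SurveyConfig(
        genome=manifest.files["genome"],
        gff3=manifest.files["gff3"],
        groups=manifest.files["groups"],
        cds=manifest.files["cds"],
        proteins=manifest.files["proteins"],
        tpm=manifest.files["tpm"],
        tissues=manifest.files["tissues"],
        qpcr=manifest.files["qpcr"],
        out_dir=str(out),
    )
    return run_pipeline(cfg)
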