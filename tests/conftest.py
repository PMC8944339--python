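import pytest

from barcodeaudit.fixtures import (
    FixtureConfig,
    generate_corpus,
    make_gazetteer,
    make_geometries,
)
from barcodeaudit.report import AuditInputs, run_audit


@pytest.fixture(scope="session")
def gaz():
    return make_gazetteer(4, 3, 2, seed=11)


@pytest.fixture(scope="session")
def geoms(gaz):
    return make_geometries(gaz, seed=11)


@pytest.fixture(scope="session")
def small_config():
    return FixtureConfig(seed=11, n_genbank=150, n_bold=100, n_occurrence=400)


@pytest.fixture(scope="session")
def small_corpus(small_config, gaz, geoms):
    return generate_corpus(small_config, gaz, geoms)


@pytest.fixture(scope="session")
def small_inputs(small_corpus):
    return AuditInputs.from_corpus(small_corpus)


@pytest.fixture(scope="session")
def small_reports(small_inputs):
    return {
        mode: run_audit(small_inputs, mode)
        for mode in ("include_na_country", "exclude_na_country")
    }


# Full-scale study conditions: 2,000 barcode + 5,000 occurrence records with
# the default (mixed) missingness rates, fixed seed.
@pytest.fixture(scope="session")
def study_corpus():
    gaz = make_gazetteer(6, 4, 3, seed=29)
    geoms = make_geometries(gaz, seed=29)
    config = FixtureConfig(seed=29)
    return generate_corpus(config, gaz, geoms)


@pytest.fixture(scope="session")
def study_reports(study_corpus):
    inputs = AuditInputs.from_corpus(study_corpus)
    return {
        mode: run_audit(inputs, mode)
        for mode in ("include_na_country", "exclude_na_country")
    }
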