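import logging

import pytest

from tabfhir import (
    CohortSpec,
    Mapper,
    RunConfig,
    default_profiles,
    default_registry,
    generate_cohort,
    generate_to_dir,
    join_reference,
    register_default_schemas,
)
from tabfhir.pipeline import run_pipeline
from tabfhir.schemas import CORE_EVENT_TABLES
from tabfhir.store import open_store

logging.getLogger("tabfhir").setLevel(logging.WARNING)

SEED = 20260924


@pytest.fixture(scope="session")
def small_spec():
    return CohortSpec(n_patients=6, seed=SEED)


@pytest.fixture(scope="session")
def cohort(small_spec):
    return generate_cohort(small_spec)


@pytest.fixture(scope="session")
def cohort_dir(small_spec, tmp_path_factory):
    out = tmp_path_factory.mktemp("cohort")
    generate_to_dir(small_spec, out)
    return out


@pytest.fixture(scope="session")
def schemas():
    return register_default_schemas()


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def profiles():
    return default_profiles()


@pytest.fixture(scope="session")
def joined_tables(cohort):
    """Event tables merged with their dictionaries, core tables as-is."""
    out = {}
    for name in CORE_EVENT_TABLES:
        tab = cohort.tables[name]
        if tab.schema.reference_join:
            ref = cohort.tables[tab.schema.reference_join.reference_table]
            out[name] = join_reference(tab, ref)
        else:
            out[name] = tab
    return out


@pytest.fixture(scope="session")
def mapped(joined_tables):
    """table name -> list of mapped FhirResource, in table order."""
    mapper = Mapper()
    return {name: mapper.map_table(tab) for name, tab in joined_tables.items()}


@pytest.fixture(scope="session")
def all_resources(mapped):
    out = []
    for name in CORE_EVENT_TABLES:
        out.extend(mapped[name])
    return out


@pytest.fixture(scope="session")
def run_env(cohort_dir, tmp_path_factory):
    """A full pipeline run over the session cohort: (config, report, store)."""
    base = tmp_path_factory.mktemp("run")
    config = RunConfig(input_dir=cohort_dir, store_path=base / "store.db")
    report = run_pipeline(config)
    store = open_store(config.store_path)
    yield config, report, store
    store.close()


DIAGNOSIS_ROW = {
    "subject_id": 10,
    "hadm_id": 20,
    "seq_num": 1,
    "icd_code": "A011",
    "icd_version": 9,
    "long_title": "Paratyphoid fever A",
}


@pytest.fixture()
def diagnosis_row():
    return dict(DIAGNOSIS_ROW)
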