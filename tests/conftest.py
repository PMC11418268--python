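import numpy as np
import pytest

from drugdoctor.ehr_data import (
    Cohort,
    MedicalCodeVocabulary,
    PatientRecord,
    Visit,
)
from drugdoctor.model import DrugDoctorModel, ModelConfig
from drugdoctor.synthetic_cohort import GeneratorConfig, generate_bundle


@pytest.fixture
def small_vocab():
    return MedicalCodeVocabulary(
        ("D0", "D1", "D2", "D3"),
        ("P0", "P1"),
        ("M0", "M1", "M2"),
    )


@pytest.fixture
def small_cohort(small_vocab):
    def visit(pid, t, d, p, m):
        return Visit(pid, t, frozenset(d), frozenset(p), frozenset(m))

    patients = [
        PatientRecord("a", [
            visit("a", 1, {"D0", "D1"}, {"P0"}, {"M0"}),
            visit("a", 2, {"D1"}, set(), {"M0", "M2"}),
        ]),
        PatientRecord("b", [
            visit("b", 1, {"D2"}, {"P1"}, {"M1"}),
        ]),
        PatientRecord("c", [
            visit("c", 1, {"D3"}, set(), {"M2"}),
            visit("c", 2, {"D3", "D0"}, {"P0", "P1"}, {"M2", "M1"}),
            visit("c", 3, {"D0"}, set(), {"M0"}),
        ]),
    ]
    return Cohort(small_vocab, patients, metadata={"source": "fixture"})


@pytest.fixture(scope="session")
def tiny_bundle():
    """A small generated cohort + truth + DDI + fragment library."""
    cfg = GeneratorConfig(
        n_patients=25, n_diagnosis=12, n_procedure=6, n_medication=10,
        fragment_pool_size=8, seed=42,
    )
    return generate_bundle(cfg)


@pytest.fixture(scope="session")
def tiny_model(tiny_bundle):
    cohort, _truth, _ddi, library = tiny_bundle
    config = ModelConfig(dim=8, heads=2, ffn_size=16)
    return DrugDoctorModel(cohort.vocabulary, library, config, seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
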