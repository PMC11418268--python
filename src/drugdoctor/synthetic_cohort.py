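"""Synthetic EHR cohorts with planted structure.

The generator produces cohorts whose statistics mirror what the model
exploits in real claims data: a skewed (truncated-geometric) visit-count
distribution, latent comorbidity topics that make diagnoses co-occur,
planted diagnosis->drug prescription rules, strong persistence of a
patient's prescriptions across visits, a sparse symmetric interaction
network, and a shared pool of per-drug substructure graphs.  The planted
rules are returned alongside the cohort so recovery tests can compare
model behaviour against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .ehr_data import (
    Cohort,
    DDIMatrix,
    MedicalCodeVocabulary,
    PatientRecord,
    Visit,
    filter_visits,
)
from .molecule_substructures import FragmentLibrary, MoleculeGraph


@dataclass
class GeneratorConfig:
    n_patients: int = 100
    n_diagnosis: int = 30
    n_procedure: int = 10
    n_medication: int = 20
    visit_geom_p: float = 0.5          # success prob of the truncated geometric
    max_visits: int = 10
    n_topics: int = 3
    topic_mix: float = 0.1             # prob a diagnosis is drawn off-topic
    diagnoses_per_visit: tuple[int, int] = (1, 4)
    procedures_per_visit: tuple[int, int] = (0, 3)
    rule_drugs_per_diagnosis: int = 1
    rule_strength: float = 0.9         # P(rule drug | its diagnosis present)
    persistence: float = 0.7           # P(drug recurs | prescribed at t-1)
    noise_rate: float = 0.05           # per-drug random prescription prob
    ddi_density: float = 0.1           # fraction of interacting drug pairs
    fragment_pool_size: int = 30
    fragments_per_drug: tuple[int, int] = (1, 4)
    fragment_atom_types: int = 8
    drop_empty_medication_visits: bool = True
    seed: int = 0

    def __post_init__(self):
        for name in ("visit_geom_p", "topic_mix", "rule_strength",
                     "persistence", "noise_rate", "ddi_density"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.visit_geom_p <= 0.0:
            raise ValueError("visit_geom_p must be positive")
        for name in ("n_patients", "n_diagnosis", "n_procedure", "n_medication",
                     "max_visits", "n_topics", "fragment_pool_size",
                     "rule_drugs_per_diagnosis", "fragment_atom_types"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("diagnoses_per_visit", "procedures_per_visit",
                     "fragments_per_drug"):
            lo, hi = getattr(self, name)
            if lo < 0 or hi < lo:
                raise ValueError(f"invalid range for {name}: ({lo}, {hi})")
        if self.diagnoses_per_visit[0] < 1:
            raise ValueError("each visit needs at least one diagnosis")
        if self.fragments_per_drug[0] < 1:
            raise ValueError("each drug needs at least one fragment")


@dataclass
class PlantedTruth:
    """Ground truth of the generative process, for recovery tests."""

    rules: dict[str, list[str]]            # diagnosis code -> rule drug codes
    topic_diagnoses: list[list[str]]       # per-topic diagnosis codes
    topic_procedures: list[list[str]]      # per-topic procedure codes
    drug_fragments: dict[str, list[int]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)


def visit_count_pmf(config: GeneratorConfig) -> np.ndarray:
    """Truncated-geometric visit-count law: ``P(n) ∝ p (1-p)^(n-1)`` for
    ``n = 1..max_visits``, renormalized."""
    p = config.visit_geom_p
    n = np.arange(1, config.max_visits + 1)
    pmf = p * (1.0 - p) ** (n - 1)
    return pmf / pmf.sum()


def make_vocabulary(config: GeneratorConfig) -> MedicalCodeVocabulary:
    return MedicalCodeVocabulary(
        tuple(f"D{i:04d}" for i in range(config.n_diagnosis)),
        tuple(f"P{i:04d}" for i in range(config.n_procedure)),
        tuple(f"M{i:04d}" for i in range(config.n_medication)),
    )


def _plant_structure(config: GeneratorConfig,
                     rng: np.random.Generator) -> PlantedTruth:
    vocab = make_vocabulary(config)
    # round-robin partition of codes into comorbidity topics
    topic_diag = [list(vocab.diagnosis_codes[k::config.n_topics])
                  for k in range(config.n_topics)]
    topic_proc = [list(vocab.procedure_codes[k::config.n_topics])
                  for k in range(config.n_topics)]
    rules = {}
    for d in vocab.diagnosis_codes:
        picks = rng.choice(config.n_medication,
                           size=config.rule_drugs_per_diagnosis, replace=False)
        rules[d] = sorted(vocab.medication_codes[i] for i in picks)
    return PlantedTruth(rules, topic_diag, topic_proc)


def _draw_codes(pool: list[str], global_pool, k: int, mix: float,
                rng: np.random.Generator) -> set[str]:
    out: set[str] = set()
    for _ in range(k):
        source = global_pool if rng.random() < mix else pool
        out.add(source[rng.integers(len(source))])
    return out


def generate_cohort(config: GeneratorConfig) -> tuple[Cohort, PlantedTruth]:
    """Sample a cohort from the planted generative process.

    Per visit: a comorbidity topic is sampled; diagnoses and procedures
    are drawn from topic-conditional pools; the prescription set is the
    union of (a) each drawn diagnosis's rule drugs kept with probability
    ``rule_strength``, (b) the previous visit's drugs each kept with
    probability ``persistence``, and (c) independent per-drug noise.
    Visits left with an empty prescription set are filtered out and
    ordinals renumbered.  Fully reproducible from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    truth = _plant_structure(config, rng)
    vocab = make_vocabulary(config)
    pmf = visit_count_pmf(config)
    d_lo, d_hi = config.diagnoses_per_visit
    p_lo, p_hi = config.procedures_per_visit
    all_diag = list(vocab.diagnosis_codes)
    all_proc = list(vocab.procedure_codes)
    meds = vocab.medication_codes

    patients = []
    for i in range(config.n_patients):
        pid = f"pt{i:05d}"
        n_visits = int(rng.choice(config.max_visits, p=pmf)) + 1
        visits = []
        prev_meds: frozenset[str] = frozenset()
        for t in range(1, n_visits + 1):
            topic = int(rng.integers(config.n_topics))
            diagnoses = _draw_codes(
                truth.topic_diagnoses[topic], all_diag,
                int(rng.integers(d_lo, d_hi + 1)), config.topic_mix, rng)
            k_p = int(rng.integers(p_lo, p_hi + 1))
            procedures = _draw_codes(
                truth.topic_procedures[topic], all_proc, k_p,
                config.topic_mix, rng) if k_p else set()
            prescribed: set[str] = set()
            for d in sorted(diagnoses):
                for m in truth.rules[d]:
                    if rng.random() < config.rule_strength:
                        prescribed.add(m)
            for m in sorted(prev_meds):
                if rng.random() < config.persistence:
                    prescribed.add(m)
            if config.noise_rate > 0:
                noise_mask = rng.random(len(meds)) < config.noise_rate
                prescribed.update(m for m, keep in zip(meds, noise_mask) if keep)
            visits.append(Visit(pid, t, frozenset(diagnoses),
                                frozenset(procedures), frozenset(prescribed)))
            prev_meds = frozenset(prescribed)
        patients.append(PatientRecord(pid, visits))

    cohort = Cohort(vocab, patients, metadata={
        "generator": "synthetic_cohort", "config": asdict(config),
    })
    if config.drop_empty_medication_visits:
        cohort = filter_visits(cohort, require_medications=True,
                               require_diagnoses=True)
    return cohort, truth


def generate_ddi(config: GeneratorConfig, seed: int | None = None) -> DDIMatrix:
    """Each unordered drug pair interacts independently with probability
    ``ddi_density``."""
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    n = config.n_medication
    upper = np.triu(rng.random((n, n)) < config.ddi_density, k=1)
    mat = (upper | upper.T).astype(np.int8)
    return DDIMatrix(mat)


def _random_connected_graph(rng: np.random.Generator, n_nodes: int,
                            feature_dim: int, n_atom_types: int) -> MoleculeGraph:
    """Random spanning tree plus a few chords; connected by construction."""
    feats = np.zeros((n_nodes, feature_dim))
    types = rng.integers(n_atom_types, size=n_nodes)
    edges = []
    for v in range(1, n_nodes):
        edges.append((int(rng.integers(v)), v))
    for u in range(n_nodes):
        for v in range(u + 1, n_nodes):
            if (u, v) not in edges and rng.random() < 0.15:
                edges.append((u, v))
    degree = np.zeros(n_nodes)
    for u, v in edges:
        degree[u] += 1
        degree[v] += 1
    feats[np.arange(n_nodes), types] = 1.0
    feats[:, -1] = degree
    return MoleculeGraph(feats, edges)


def generate_fragment_library(config: GeneratorConfig,
                              seed: int | None = None) -> FragmentLibrary:
    """A fixed pool of small random connected graphs; each drug maps to a
    few pool fragments, so identical fragments are shared across drugs."""
    rng = np.random.default_rng(config.seed + 2 if seed is None else seed)
    feature_dim = config.fragment_atom_types + 1  # type one-hot + degree
    fragments = {
        fid: _random_connected_graph(rng, int(rng.integers(3, 13)),
                                     feature_dim, config.fragment_atom_types)
        for fid in range(config.fragment_pool_size)
    }
    lo, hi = config.fragments_per_drug
    vocab = make_vocabulary(config)
    drug_fragments = {}
    for m in vocab.medication_codes:
        k = int(rng.integers(lo, hi + 1))
        k = min(k, config.fragment_pool_size)
        ids = rng.choice(config.fragment_pool_size, size=k, replace=False)
        drug_fragments[m] = sorted(int(i) for i in ids)
    return FragmentLibrary(fragments, drug_fragments,
                           metadata={"source": "synthetic", "seed": config.seed})


def generate_bundle(config: GeneratorConfig):
    """Cohort + planted truth + interaction matrix + fragment library."""
    cohort, truth = generate_cohort(config)
    ddi = generate_ddi(config)
    library = generate_fragment_library(config)
    truth.drug_fragments = {d: list(ids) for d, ids in library.drug_fragments.items()}
    return cohort, truth, ddi, library
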