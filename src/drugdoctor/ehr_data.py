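"""Data model for EHR cohorts: vocabularies, visits, multi-hot encoding, DDI matrix, I/O.

A cohort is stored as JSONL: a header record carrying the three code
vocabularies and free-form metadata, followed by one patient record per
line.  The schema is versioned via ``schema_version`` in the header.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1

#: valid vocabulary-space names
SPACES = ("diagnosis", "procedure", "medication")


class CohortFormatError(ValueError):
    """Raised for malformed cohort files or out-of-vocabulary codes."""


@dataclass(frozen=True)
class MedicalCodeVocabulary:
    """Ordered code lists for the diagnosis / procedure / medication spaces.

    Index maps are bijections between codes and ``0..size-1`` integers,
    built from the given ordering.
    """

    diagnosis_codes: tuple[str, ...]
    procedure_codes: tuple[str, ...]
    medication_codes: tuple[str, ...]

    def __post_init__(self):
        for space in SPACES:
            codes = self.codes(space)
            if len(codes) == 0:
                raise ValueError(f"{space} vocabulary is empty")
            if len(set(codes)) != len(codes):
                raise ValueError(f"duplicate codes in {space} vocabulary")
        object.__setattr__(self, "_index", {
            space: {c: i for i, c in enumerate(self.codes(space))}
            for space in SPACES
        })

    def codes(self, space: str) -> tuple[str, ...]:
        if space == "diagnosis":
            return self.diagnosis_codes
        if space == "procedure":
            return self.procedure_codes
        if space == "medication":
            return self.medication_codes
        raise ValueError(f"unknown vocabulary space: {space!r}")

    def size(self, space: str) -> int:
        return len(self.codes(space))

    def index(self, code: str, space: str) -> int:
        try:
            return self._index[space][code]
        except KeyError:
            raise CohortFormatError(
                f"unknown {space} code {code!r}"
            ) from None

    def __contains__(self, item: tuple[str, str]) -> bool:
        code, space = item
        return code in self._index[space]

    @property
    def n_diagnosis(self) -> int:
        return len(self.diagnosis_codes)

    @property
    def n_procedure(self) -> int:
        return len(self.procedure_codes)

    @property
    def n_medication(self) -> int:
        return len(self.medication_codes)


@dataclass
class Visit:
    """One hospital visit: three deduplicated code sets with a 1-based ordinal."""

    patient_id: str
    t: int
    diagnoses: frozenset[str]
    procedures: frozenset[str]
    medications: frozenset[str]

    def __post_init__(self):
        if self.t < 1:
            raise ValueError(f"visit ordinal must be >= 1, got {self.t}")
        self.diagnoses = frozenset(self.diagnoses)
        self.procedures = frozenset(self.procedures)
        self.medications = frozenset(self.medications)

    def validate(self, vocab: MedicalCodeVocabulary) -> None:
        for codes, space in (
            (self.diagnoses, "diagnosis"),
            (self.procedures, "procedure"),
            (self.medications, "medication"),
        ):
            for code in codes:
                vocab.index(code, space)


@dataclass
class PatientRecord:
    patient_id: str
    visits: list[Visit]

    def __post_init__(self):
        for i, v in enumerate(self.visits, start=1):
            if v.t != i:
                raise ValueError(
                    f"patient {self.patient_id}: visit ordinals must be "
                    f"consecutive from 1, got {v.t} at position {i}"
                )
            if v.patient_id != self.patient_id:
                raise ValueError(
                    f"visit patient_id {v.patient_id!r} != record "
                    f"{self.patient_id!r}"
                )

    @property
    def n_visits(self) -> int:
        return len(self.visits)


@dataclass
class Cohort:
    vocabulary: MedicalCodeVocabulary
    patients: list[PatientRecord]
    metadata: dict = field(default_factory=dict)

    def validate(self) -> None:
        for p in self.patients:
            for v in p.visits:
                v.validate(self.vocabulary)

    @property
    def n_patients(self) -> int:
        return len(self.patients)

    @property
    def n_visits(self) -> int:
        return sum(p.n_visits for p in self.patients)

    def patient_ids(self) -> list[str]:
        return [p.patient_id for p in self.patients]


@dataclass
class MultiHotVector:
    values: np.ndarray
    space: str

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 1:
            raise ValueError("multi-hot vector must be 1-D")
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("multi-hot entries must be 0 or 1")
        if self.space not in SPACES:
            raise ValueError(f"unknown space {self.space!r}")


@dataclass
class DDIMatrix:
    """Symmetric binary drug-drug interaction prior over the medication space."""

    matrix: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.matrix)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("DDI matrix must be square")
        if not np.isin(m, (0, 1)).all():
            raise ValueError("DDI matrix entries must be binary")
        if not np.array_equal(m, m.T):
            raise ValueError("DDI matrix must be symmetric")
        if np.diagonal(m).any():
            raise ValueError("DDI matrix must have zero diagonal")
        self.matrix = m.astype(np.int8)

    @property
    def n_drugs(self) -> int:
        return self.matrix.shape[0]

    def n_pairs(self) -> int:
        """Number of interacting unordered pairs."""
        return int(self.matrix.sum()) // 2


def encode_multi_hot(
    codes, space: str, vocab: MedicalCodeVocabulary
) -> MultiHotVector:
    """Binary indicator vector with a 1 exactly at the indices of ``codes``."""
    vec = np.zeros(vocab.size(space), dtype=np.int8)
    for code in codes:
        vec[vocab.index(code, space)] = 1
    return MultiHotVector(vec, space)


def decode_multi_hot(
    mh: MultiHotVector, vocab: MedicalCodeVocabulary
) -> frozenset[str]:
    """Inverse of :func:`encode_multi_hot`."""
    codes = vocab.codes(mh.space)
    if len(mh.values) != len(codes):
        raise CohortFormatError(
            f"vector length {len(mh.values)} != |{mh.space}| = {len(codes)}"
        )
    return frozenset(codes[i] for i in np.flatnonzero(mh.values))


def code_indices(codes, space: str, vocab: MedicalCodeVocabulary) -> np.ndarray:
    """Sorted integer indices of a code set (deterministic embedding order)."""
    return np.array(sorted(vocab.index(c, space) for c in codes), dtype=np.intp)


# ---------------------------------------------------------------------------
# cohort JSONL I/O


def _visit_to_json(v: Visit) -> dict:
    return {
        "t": v.t,
        "diagnoses": sorted(v.diagnoses),
        "procedures": sorted(v.procedures),
        "medications": sorted(v.medications),
    }


def write_cohort(cohort: Cohort, path) -> None:
    """Write a cohort as JSONL with deterministic key and code ordering."""
    with open(path, "w") as fh:
        header = {
            "schema_version": SCHEMA_VERSION,
            "kind": "cohort_header",
            "vocabulary": {
                "diagnosis": list(cohort.vocabulary.diagnosis_codes),
                "procedure": list(cohort.vocabulary.procedure_codes),
                "medication": list(cohort.vocabulary.medication_codes),
            },
            "metadata": cohort.metadata,
        }
        fh.write(json.dumps(header, sort_keys=True) + "\n")
        for p in cohort.patients:
            rec = {
                "patient_id": p.patient_id,
                "visits": [_visit_to_json(v) for v in p.visits],
            }
            fh.write(json.dumps(rec, sort_keys=True) + "\n")


def read_cohort(path) -> Cohort:
    """Read a JSONL cohort; raises :class:`CohortFormatError` with line numbers."""
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise CohortFormatError(f"{path}: empty file (missing header)")
    try:
        header = json.loads(lines[0])
    except json.JSONDecodeError as e:
        raise CohortFormatError(f"{path}:1: malformed JSON: {e}") from None
    if header.get("kind") != "cohort_header":
        raise CohortFormatError(f"{path}:1: first record is not a cohort header")
    if header.get("schema_version") != SCHEMA_VERSION:
        raise CohortFormatError(
            f"{path}:1: unsupported schema_version {header.get('schema_version')!r}"
        )
    voc = header["vocabulary"]
    vocab = MedicalCodeVocabulary(
        tuple(voc["diagnosis"]), tuple(voc["procedure"]), tuple(voc["medication"])
    )
    patients = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        try:
            rec = json.loads(line)
            visits = [
                Visit(
                    patient_id=rec["patient_id"],
                    t=v["t"],
                    diagnoses=frozenset(v["diagnoses"]),
                    procedures=frozenset(v["procedures"]),
                    medications=frozenset(v["medications"]),
                )
                for v in rec["visits"]
            ]
            patients.append(PatientRecord(rec["patient_id"], visits))
        except (KeyError, TypeError, ValueError, json.JSONDecodeError) as e:
            raise CohortFormatError(f"{path}:{lineno}: malformed record: {e}") from None
    cohort = Cohort(vocab, patients, metadata=header.get("metadata", {}))
    try:
        cohort.validate()
    except CohortFormatError as e:
        raise CohortFormatError(f"{path}: {e}") from None
    return cohort


# ---------------------------------------------------------------------------
# DDI TSV I/O


def read_ddi(path, vocab: MedicalCodeVocabulary) -> DDIMatrix:
    """Read a two-column TSV edge list into a symmetric binary matrix.

    Unknown medication codes are skipped; the number of skipped edges is
    logged as a warning.  ``#`` lines are comments.
    """
    n = vocab.n_medication
    mat = np.zeros((n, n), dtype=np.int8)
    skipped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise CohortFormatError(
                    f"{path}:{lineno}: expected two tab-separated codes"
                )
            a, b = parts[0], parts[1]
            if (a, "medication") not in vocab or (b, "medication") not in vocab:
                skipped += 1
                continue
            i = vocab.index(a, "medication")
            j = vocab.index(b, "medication")
            if i == j:
                continue
            mat[i, j] = 1
            mat[j, i] = 1
    if skipped:
        logger.warning("read_ddi: skipped %d edges with unknown codes", skipped)
    return DDIMatrix(mat)


def write_ddi(ddi: DDIMatrix, vocab: MedicalCodeVocabulary, path) -> None:
    meds = vocab.medication_codes
    with open(path, "w") as fh:
        fh.write("# drug-drug interaction edge list\n")
        idx_i, idx_j = np.nonzero(np.triu(ddi.matrix, k=1))
        for i, j in zip(idx_i, idx_j):
            fh.write(f"{meds[i]}\t{meds[j]}\n")


# ---------------------------------------------------------------------------
# filtering and splitting


def filter_visits(
    cohort: Cohort,
    require_medications: bool = True,
    require_diagnoses: bool = True,
) -> Cohort:
    """Drop visits with empty medication and/or diagnosis sets.

    Remaining visits are re-numbered so ordinals stay consecutive from 1;
    patients left with zero visits are dropped.
    """
    patients = []
    for p in cohort.patients:
        kept = [
            v for v in p.visits
            if (v.medications or not require_medications)
            and (v.diagnoses or not require_diagnoses)
        ]
        if not kept:
            continue
        renum = [
            Visit(p.patient_id, i, v.diagnoses, v.procedures, v.medications)
            for i, v in enumerate(kept, start=1)
        ]
        patients.append(PatientRecord(p.patient_id, renum))
    return Cohort(cohort.vocabulary, patients, metadata=dict(cohort.metadata))


def split_cohort(
    cohort: Cohort,
    ratios: tuple[float, float, float] = (4, 1, 1),
    seed: int = 0,
) -> tuple[Cohort, Cohort, Cohort]:
    """Partition patients into train/validation/test cohorts by ratio.

    The split is by patient: all of a patient's visits land in exactly one
    part, so held-out patients are fully unseen.  Reproducible per seed.
    """
    n = cohort.n_patients
    if n < len(ratios):
        raise ValueError(f"cannot split {n} patients into {len(ratios)} parts")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    total = float(sum(ratios))
    # largest-remainder apportionment so counts sum exactly to n
    raw = [n * r / total for r in ratios]
    counts = [int(np.floor(x)) for x in raw]
    rem = n - sum(counts)
    by_frac = sorted(range(len(ratios)), key=lambda i: raw[i] - counts[i], reverse=True)
    for i in by_frac[:rem]:
        counts[i] += 1
    parts = []
    start = 0
    for c in counts:
        idx = sorted(order[start:start + c])
        parts.append(
            Cohort(
                cohort.vocabulary,
                [cohort.patients[i] for i in idx],
                metadata=dict(cohort.metadata),
            )
        )
        start += c
    return tuple(parts)
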