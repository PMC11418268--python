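"""Evaluation: per-visit multi-label metrics, the patient-resampling
bootstrap protocol, and visit-count-stratified reports.

Cohort-level numbers average uniformly over all evaluated visits (the
visit-level philosophy); a per-patient-first aggregation is available via
``per_patient=True``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .ehr_data import Cohort, DDIMatrix, code_indices
from .model import DrugDoctorModel
from .training import visit_examples

logger = logging.getLogger(__name__)


@dataclass
class VisitPrediction:
    """Ground truth and prediction for one visit, as index sets plus the
    full probability vector over the medication vocabulary."""

    patient_id: str
    t: int
    truth: frozenset[int]
    predicted: frozenset[int]
    scores: np.ndarray

    def __post_init__(self):
        self.truth = frozenset(self.truth)
        self.predicted = frozenset(self.predicted)
        self.scores = np.asarray(self.scores, dtype=np.float64)


@dataclass
class MetricsReport:
    ddi_rate: float
    jaccard: float
    f1: float
    prauc: float
    avg_n_drugs: float
    n_rounds: int = 1
    std: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        out = {
            "ddi_rate": self.ddi_rate,
            "jaccard": self.jaccard,
            "f1": self.f1,
            "prauc": self.prauc,
            "avg_n_drugs": self.avg_n_drugs,
            "n_rounds": self.n_rounds,
        }
        if self.std:
            out["std"] = dict(self.std)
        return out


# ---------------------------------------------------------------------------
# per-metric functions


def ddi_rate(predictions: list[VisitPrediction], ddi: DDIMatrix) -> float:
    """Mean over visits of the fraction of predicted unordered drug pairs
    that interact; visits with fewer than two predictions contribute 0."""
    if not predictions:
        return 0.0
    mat = ddi.matrix
    vals = []
    for p in predictions:
        idx = sorted(p.predicted)
        k = len(idx)
        if k < 2:
            vals.append(0.0)
            continue
        sub = mat[np.ix_(idx, idx)]
        n_hit = int(np.triu(sub, k=1).sum())
        vals.append(n_hit / (k * (k - 1) / 2))
    return float(np.mean(vals))


def jaccard(predictions: list[VisitPrediction]) -> float:
    """Mean per-visit Jaccard; two empty sets count as identical (1)."""
    if not predictions:
        return 0.0
    vals = []
    for p in predictions:
        union = len(p.truth | p.predicted)
        vals.append(len(p.truth & p.predicted) / union if union else 1.0)
    return float(np.mean(vals))


def f1(predictions: list[VisitPrediction]) -> float:
    """Mean per-visit harmonic mean of precision and recall; an empty
    prediction has precision 0, and P + R = 0 yields F1 = 0."""
    if not predictions:
        return 0.0
    vals = []
    for p in predictions:
        inter = len(p.truth & p.predicted)
        prec = inter / len(p.predicted) if p.predicted else 0.0
        rec = inter / len(p.truth) if p.truth else 0.0
        vals.append(2 * prec * rec / (prec + rec) if prec + rec > 0 else 0.0)
    return float(np.mean(vals))


def prauc(predictions: list[VisitPrediction]) -> float:
    """Mean per-visit step-sum of precision times recall increments over
    the drug list ranked by descending score.

    Visits with no true drugs are skipped (their recall is undefined);
    the skip count is logged.
    """
    vals = []
    skipped = 0
    for p in predictions:
        n_pos = len(p.truth)
        if n_pos == 0:
            skipped += 1
            continue
        order = np.argsort(-p.scores, kind="stable")
        truth_mask = np.zeros(len(p.scores), dtype=bool)
        truth_mask[sorted(p.truth)] = True
        hits = truth_mask[order]
        tp = np.cumsum(hits)
        k = np.arange(1, len(order) + 1)
        precision = tp / k
        recall = tp / n_pos
        delta_recall = np.diff(np.concatenate([[0.0], recall]))
        vals.append(float((precision * delta_recall).sum()))
    if skipped:
        logger.info("prauc: skipped %d visits with no true drugs", skipped)
    return float(np.mean(vals)) if vals else 0.0


def avg_n_drugs(predictions: list[VisitPrediction]) -> float:
    if not predictions:
        return 0.0
    return float(np.mean([len(p.predicted) for p in predictions]))


def evaluate_predictions(predictions: list[VisitPrediction],
                         ddi: DDIMatrix) -> MetricsReport:
    """All metrics over one fixed prediction pool (no resampling)."""
    return MetricsReport(
        ddi_rate=ddi_rate(predictions, ddi),
        jaccard=jaccard(predictions),
        f1=f1(predictions),
        prauc=prauc(predictions),
        avg_n_drugs=avg_n_drugs(predictions),
        n_rounds=1,
    )


# ---------------------------------------------------------------------------
# model -> predictions


def predict_cohort(model: DrugDoctorModel, cohort: Cohort) -> list[VisitPrediction]:
    """Run inference over every visit of a cohort."""
    e_drug = model.substructure_table().matrix.detach()
    out = []
    for ex in visit_examples(cohort):
        bundle = model.predict_visit(ex.visit, ex.history, e_drug)
        truth = code_indices(ex.visit.medications, "medication", model.vocab)
        out.append(VisitPrediction(
            ex.patient_id, ex.t,
            frozenset(int(i) for i in truth),
            frozenset(int(i) for i in np.flatnonzero(bundle.m_hat)),
            bundle.o_hat,
        ))
    return out


# ---------------------------------------------------------------------------
# bootstrap protocol and stratification

_METRICS = ("ddi_rate", "jaccard", "f1", "prauc", "avg_n_drugs")


def bootstrap_evaluate(predictions: list[VisitPrediction], ddi: DDIMatrix,
                       n_rounds: int = 10, frac: float = 0.8,
                       seed: int = 0) -> MetricsReport:
    """Resample a fraction of *patients* without replacement ``n_rounds``
    times; report the per-metric mean and standard deviation over rounds."""
    if not predictions:
        raise ValueError("no predictions to evaluate")
    by_patient: dict[str, list[VisitPrediction]] = {}
    for p in predictions:
        by_patient.setdefault(p.patient_id, []).append(p)
    ids = sorted(by_patient)
    n_sample = max(1, int(round(frac * len(ids))))
    rng = np.random.default_rng(seed)
    rounds = {m: [] for m in _METRICS}
    for _ in range(n_rounds):
        chosen = rng.choice(len(ids), size=n_sample, replace=False)
        pool = [p for i in sorted(chosen) for p in by_patient[ids[i]]]
        rep = evaluate_predictions(pool, ddi)
        for m in _METRICS:
            rounds[m].append(getattr(rep, m))
    means = {m: float(np.mean(rounds[m])) for m in _METRICS}
    stds = {m: float(np.std(rounds[m])) for m in _METRICS}
    return MetricsReport(
        ddi_rate=means["ddi_rate"], jaccard=means["jaccard"], f1=means["f1"],
        prauc=means["prauc"], avg_n_drugs=means["avg_n_drugs"],
        n_rounds=n_rounds, std=stds,
    )


def stratify_by_visit_count(predictions: list[VisitPrediction],
                            ddi: DDIMatrix) -> dict[int, MetricsReport]:
    """Evaluate separately for patients with exactly ``n`` total visits.

    The ``n = 1`` stratum is the cold-start report.  Empty strata are
    simply absent from the map.
    """
    by_patient: dict[str, list[VisitPrediction]] = {}
    for p in predictions:
        by_patient.setdefault(p.patient_id, []).append(p)
    strata: dict[int, list[VisitPrediction]] = {}
    for preds in by_patient.values():
        n = len(preds)
        strata.setdefault(n, []).extend(preds)
    return {
        n: evaluate_predictions(pool, ddi)
        for n, pool in sorted(strata.items())
    }


# ---------------------------------------------------------------------------
# a simple co-occurrence baseline for recovery experiments


class DiagnosisFrequencyBaseline:
    """Predict drugs by per-diagnosis empirical frequency.

    For each (diagnosis, drug) pair, fit estimates P(drug prescribed |
    diagnosis present) over training visits.  A visit's score for a drug
    aggregates that probability over the visit's diagnoses (``mean`` by
    default, ``max`` available), and drugs scoring above the threshold
    are predicted.
    """

    def __init__(self, threshold: float = 0.5, aggregate: str = "mean"):
        if aggregate not in ("mean", "max"):
            raise ValueError(f"unknown aggregate {aggregate!r}")
        self.threshold = threshold
        self.aggregate = aggregate
        self.cond_prob: np.ndarray | None = None

    def fit(self, cohort: Cohort) -> "DiagnosisFrequencyBaseline":
        vocab = cohort.vocabulary
        counts = np.zeros((vocab.n_diagnosis, vocab.n_medication))
        diag_counts = np.zeros(vocab.n_diagnosis)
        for p in cohort.patients:
            for v in p.visits:
                d_idx = code_indices(v.diagnoses, "diagnosis", vocab)
                m_idx = code_indices(v.medications, "medication", vocab)
                diag_counts[d_idx] += 1
                for d in d_idx:
                    counts[d, m_idx] += 1
        with np.errstate(invalid="ignore", divide="ignore"):
            self.cond_prob = np.where(
                diag_counts[:, None] > 0, counts / diag_counts[:, None], 0.0)
        self.vocab = vocab
        return self

    def predict_cohort(self, cohort: Cohort) -> list[VisitPrediction]:
        if self.cond_prob is None:
            raise RuntimeError("baseline not fitted")
        out = []
        for p in cohort.patients:
            for v in p.visits:
                d_idx = code_indices(v.diagnoses, "diagnosis", self.vocab)
                if len(d_idx):
                    agg = np.max if self.aggregate == "max" else np.mean
                    scores = agg(self.cond_prob[d_idx], axis=0)
                else:
                    scores = np.zeros(self.vocab.n_medication)
                truth = code_indices(v.medications, "medication", self.vocab)
                out.append(VisitPrediction(
                    p.patient_id, v.t,
                    frozenset(int(i) for i in truth),
                    frozenset(int(i) for i in np.flatnonzero(
                        scores > self.threshold)),
                    scores,
                ))
        return out
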