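"""Visit-level training: every visit (with its own patient's earlier
visits attached as history) is an independent training example, globally
shuffled while each patient's internal chronology is preserved.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np

from .autodiff import Adam
from .ehr_data import Cohort, DDIMatrix, Visit, encode_multi_hot
from .model import DrugDoctorModel, bce_loss, ddi_loss, total_loss

logger = logging.getLogger(__name__)


@dataclass
class TrainConfig:
    learning_rate: float = 5e-4
    batch_size: int = 16
    epochs: int = 50
    seed: int = 1023
    patience: int = 10           # early stop on validation Jaccard
    min_epochs: int = 1
    log_every: int = 1

    def __post_init__(self):
        for name in ("learning_rate", "batch_size", "epochs", "patience",
                     "min_epochs"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class VisitExample:
    """One training unit: a visit plus that patient's strictly earlier visits."""

    patient_id: str
    t: int
    visit: Visit
    history: list[Visit]

    def __post_init__(self):
        for i, h in enumerate(self.history):
            if h.patient_id != self.patient_id:
                raise ValueError("history contains another patient's visit")
            if h.t >= self.t:
                raise ValueError("history contains a same-or-later visit")
            if i + 1 != h.t:
                raise ValueError("history must be chronologically ordered")


@dataclass
class EpochRecord:
    epoch: int
    train_loss: float
    train_bce: float
    train_ddi: float
    val_jaccard: float


@dataclass
class TrainLog:
    epochs: list[EpochRecord] = field(default_factory=list)
    best_epoch: int = -1
    best_val_jaccard: float = -1.0

    def to_jsonl(self, path) -> None:
        with open(path, "w") as fh:
            for rec in self.epochs:
                fh.write(json.dumps(asdict(rec)) + "\n")


def visit_examples(cohort: Cohort) -> list[VisitExample]:
    """All visits of a cohort as examples, patient by patient."""
    out = []
    for p in cohort.patients:
        for i, v in enumerate(p.visits):
            out.append(VisitExample(p.patient_id, v.t, v, p.visits[:i]))
    return out


def build_visit_sequence(cohort: Cohort, seed) -> list[VisitExample]:
    """Random global order over all visits that preserves, for every
    patient, the chronological order of that patient's own visits.

    Implementation: each visit occupies one slot; slots are assigned to
    patients uniformly at random, then each patient's visits fill that
    patient's slots in chronological order.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    slots: list[int] = []
    for pi, p in enumerate(cohort.patients):
        slots.extend([pi] * p.n_visits)
    rng.shuffle(slots)
    cursor = [0] * cohort.n_patients
    per_patient = [visit_examples_for(p) for p in cohort.patients]
    seq = []
    for pi in slots:
        seq.append(per_patient[pi][cursor[pi]])
        cursor[pi] += 1
    return seq


def visit_examples_for(patient) -> list[VisitExample]:
    return [
        VisitExample(patient.patient_id, v.t, v, patient.visits[:i])
        for i, v in enumerate(patient.visits)
    ]


def _example_loss(model: DrugDoctorModel, example: VisitExample, e_drug,
                  ddi: DDIMatrix):
    m_c, m_h, m_p = model.forward(example.visit, example.history, e_drug)
    o_hat = (m_c + m_h + m_p).sigmoid()
    target = encode_multi_hot(
        example.visit.medications, "medication", model.vocab
    ).values.astype(np.float64)
    return bce_loss(target, o_hat), ddi_loss(o_hat, ddi)


def _quick_jaccard(model: DrugDoctorModel, examples: list[VisitExample]) -> float:
    if not examples:
        return 0.0
    e_drug = model.substructure_table().matrix.detach()
    scores = []
    for ex in examples:
        bundle = model.predict_visit(ex.visit, ex.history, e_drug)
        pred = model.predicted_codes(bundle)
        truth = ex.visit.medications
        union = len(truth | pred)
        scores.append(len(truth & pred) / union if union else 1.0)
    return float(np.mean(scores))


def train(model: DrugDoctorModel, train_cohort: Cohort, val_cohort: Cohort | None,
          ddi: DDIMatrix, config: TrainConfig) -> TrainLog:
    """Adam training over shuffled visit batches with early stopping on
    validation Jaccard; the best-epoch parameters are restored at the end.

    The visit sequence is reshuffled every epoch from a seed-derived
    stream, so runs are reproducible end to end.  Raises on non-finite
    loss.
    """
    if train_cohort.n_visits == 0:
        raise ValueError("training cohort has no visits")
    opt = Adam(model.params, lr=config.learning_rate)
    rng = np.random.default_rng(config.seed)
    val_examples = visit_examples(val_cohort) if val_cohort is not None else []
    log = TrainLog()
    best_state = None
    since_best = 0
    cfg = model.config
    for epoch in range(1, config.epochs + 1):
        seq = build_visit_sequence(train_cohort, rng)
        epoch_bce = epoch_ddi = epoch_total = 0.0
        for start in range(0, len(seq), config.batch_size):
            batch = seq[start:start + config.batch_size]
            opt.zero_grad()
            e_drug = model.substructure_table().matrix
            losses = []
            bce_sum = ddi_sum = 0.0
            for ex in batch:
                bce, ddi_term = _example_loss(model, ex, e_drug, ddi)
                losses.append(total_loss(bce, ddi_term, cfg.alpha, cfg.use_ddi_loss))
                bce_sum += float(bce.data)
                ddi_sum += float(ddi_term.data)
            batch_loss = losses[0]
            for extra in losses[1:]:
                batch_loss = batch_loss + extra
            batch_loss = batch_loss / float(len(batch))
            if not np.isfinite(batch_loss.data):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}: {batch_loss.data}"
                )
            batch_loss.backward()
            opt.step()
            epoch_total += float(batch_loss.data) * len(batch)
            epoch_bce += bce_sum
            epoch_ddi += ddi_sum
        n = len(seq)
        val_j = _quick_jaccard(model, val_examples) if val_examples else float("nan")
        log.epochs.append(EpochRecord(
            epoch, epoch_total / n, epoch_bce / n, epoch_ddi / n, val_j))
        if epoch % config.log_every == 0:
            logger.info("epoch %d: loss=%.4f val_jaccard=%.4f",
                        epoch, epoch_total / n, val_j)
        if val_examples:
            if val_j > log.best_val_jaccard:
                log.best_val_jaccard = val_j
                log.best_epoch = epoch
                best_state = model.state_arrays()
                since_best = 0
            else:
                since_best += 1
                if since_best >= config.patience and epoch >= config.min_epochs:
                    logger.info("early stop at epoch %d (best %d)",
                                epoch, log.best_epoch)
                    break
        else:
            log.best_epoch = epoch
    if best_state is not None:
        model.load_state_arrays(best_state)
    return log
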