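"""The recommendation model: set encoders over visit codes, a
substructure-aware cross-attention block, a prescription-history GRU,
logit fusion, thresholding, and the combined multi-label / interaction
losses.

Three logit vectors are produced per visit and summed before the sigmoid:

* ``m_c`` — from the current visit's diagnoses and procedures, with the
  substructure table as cross-attention query (block 1);
* ``m_h`` — from a GRU over the pooled embeddings of all historical
  prescription sets;
* ``m_p`` — from the previous visit, with its prescription embeddings as
  cross-attention query against that visit's encoded diagnoses and
  procedures (block 2).

At a patient's first visit ``m_h`` and ``m_p`` are zero, so the fused
prediction depends only on current-visit information (cold start).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict

import numpy as np

from .autodiff import Tensor, concat
from .ehr_data import DDIMatrix, MedicalCodeVocabulary, Visit, code_indices
from .molecule_substructures import (
    FragmentLibrary,
    SubstructureTable,
    build_substructure_table,
    gin_params,
)
from . import nn
from .nn import attention, multi_head, pool_set  # re-exported building blocks

__all__ = [
    "ModelConfig", "PredictionBundle", "LossReport", "DrugDoctorModel",
    "ca_mhsa", "fuse_predict", "bce_loss", "ddi_loss", "total_loss",
    "attention", "multi_head", "pool_set",
]


@dataclass
class ModelConfig:
    """Architecture and loss hyper-parameters.

    ``dim`` need not equal the medication vocabulary size: the output
    heads always project to ``|M|``.  The ablation flags disable, in
    order, the substructure cross-attention block, the previous-visit
    cross-attention block, the history GRU, and the interaction loss.
    """

    dim: int = 64
    heads: int = 4
    ffn_size: int = 2048
    delta: float = 0.4
    alpha: float = 0.5
    use_block1: bool = True
    use_block2: bool = True
    use_rnn: bool = True
    use_ddi_loss: bool = True
    share_prev_encoders: bool = False

    def __post_init__(self):
        if self.dim <= 0 or self.dim % self.heads:
            raise ValueError(f"dim {self.dim} must be positive and divisible by "
                             f"heads {self.heads}")
        if not 0.0 < self.delta < 1.0:
            raise ValueError(f"delta must be in (0, 1), got {self.delta}")
        if self.alpha < 0:
            raise ValueError(f"alpha must be >= 0, got {self.alpha}")
        if self.ffn_size <= 0:
            raise ValueError("ffn_size must be positive")


@dataclass
class PredictionBundle:
    """Per-visit outputs: three logit vectors, fused probabilities, and the
    thresholded medication indicator."""

    m_c: np.ndarray
    m_h: np.ndarray
    m_p: np.ndarray
    o_hat: np.ndarray
    m_hat: np.ndarray


@dataclass
class LossReport:
    bce: float
    ddi: float
    total: float


def ca_mhsa(q_rows: Tensor, d_rows: Tensor, p_rows: Tensor,
            params: dict, prefix: str, heads: int) -> Tensor:
    """Cross-attention + multi-head self-attention block.

    The query rows attend separately to the diagnosis rows and the
    procedure rows; the two results are concatenated feature-wise,
    passed through multi-head self-attention over the query rows, and
    mean-pooled to a single double-width vector.
    """
    if d_rows.shape[0] < 1 or p_rows.shape[0] < 1:
        raise ValueError("cross-attention requires non-empty key sets")
    ca = concat([attention(q_rows, d_rows, d_rows),
                 attention(q_rows, p_rows, p_rows)], axis=-1)
    out = multi_head(ca, ca, ca, params, prefix, heads)
    return pool_set(out)


def fuse_predict(m_c, m_h, m_p, delta: float) -> PredictionBundle:
    """Sigmoid of the summed logits, thresholded with strict ``>``."""
    m_c, m_h, m_p = (np.asarray(x, dtype=np.float64) for x in (m_c, m_h, m_p))
    if not (m_c.shape == m_h.shape == m_p.shape):
        raise ValueError("logit vectors must have equal length")
    o_hat = 1.0 / (1.0 + np.exp(-(m_c + m_h + m_p)))
    m_hat = (o_hat > delta).astype(np.int8)
    return PredictionBundle(m_c, m_h, m_p, o_hat, m_hat)


# ---------------------------------------------------------------------------
# losses

_CLIP = 1e-12


def bce_loss(target: np.ndarray, o_hat: Tensor) -> Tensor:
    """Binary cross-entropy summed over the medication vocabulary."""
    t = np.asarray(target, dtype=np.float64)
    if t.shape != o_hat.shape:
        raise ValueError(f"target shape {t.shape} != prediction {o_hat.shape}")
    o = o_hat.clip(_CLIP, 1.0 - _CLIP)
    return -((Tensor(t) * o.log() + Tensor(1.0 - t) * (1.0 - o).log()).sum())


def ddi_loss(o_hat: Tensor, ddi: DDIMatrix) -> Tensor:
    """Full quadratic form over the symmetric interaction matrix: each
    interacting unordered pair contributes twice."""
    n = o_hat.shape[0]
    if ddi.n_drugs != n:
        raise ValueError(f"DDI matrix size {ddi.n_drugs} != |M| = {n}")
    dmat = Tensor(ddi.matrix.astype(np.float64))
    row = o_hat.reshape(1, n)
    return (row @ dmat @ row.T).reshape(())


def total_loss(bce: Tensor, ddi: Tensor, alpha: float,
               use_ddi_loss: bool = True) -> Tensor:
    """Weighted combination ``bce + alpha * ddi`` (just ``bce`` when the
    interaction term is ablated)."""
    for x in (bce, ddi):
        if not np.isfinite(np.asarray(x.data)).all():
            raise FloatingPointError("non-finite loss component")
    if not use_ddi_loss:
        return bce
    return bce + alpha * ddi


def loss_report(bce: Tensor, ddi: Tensor, alpha: float,
                use_ddi_loss: bool = True) -> LossReport:
    total = total_loss(bce, ddi, alpha, use_ddi_loss)
    return LossReport(float(bce.data), float(ddi.data), float(total.data))


# ---------------------------------------------------------------------------
# the model


def vocabulary_hash(vocab: MedicalCodeVocabulary) -> str:
    payload = json.dumps({
        "diagnosis": list(vocab.diagnosis_codes),
        "procedure": list(vocab.procedure_codes),
        "medication": list(vocab.medication_codes),
    }, sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()


class DrugDoctorModel:
    """End-to-end model over a fixed vocabulary and fragment library.

    All learnable parameters (embedding tables, encoders, cross-attention
    blocks, GRU, output heads, and the substructure GIN) live in a single
    flat dict, so one optimizer instance trains everything end-to-end and
    gradients flow into the GIN through the recomputed substructure table.
    """

    def __init__(self, vocab: MedicalCodeVocabulary, library: FragmentLibrary,
                 config: ModelConfig | None = None, seed: int = 0):
        self.vocab = vocab
        self.library = library
        self.config = config or ModelConfig()
        missing = [m for m in vocab.medication_codes
                   if m not in library.drug_fragments]
        if missing:
            raise ValueError(
                f"fragment library missing {len(missing)} medications "
                f"(e.g. {missing[0]!r})"
            )
        rng = np.random.default_rng(seed)
        cfg = self.config
        dim = cfg.dim
        p: dict[str, Tensor] = {}
        p["emb.d"] = Tensor(nn.uniform_init(rng, dim, (vocab.n_diagnosis, dim)),
                            requires_grad=True)
        # extra final row: learned token standing in for an empty procedure set
        p["emb.p"] = Tensor(nn.uniform_init(rng, dim, (vocab.n_procedure + 1, dim)),
                            requires_grad=True)
        p["emb.m"] = Tensor(nn.uniform_init(rng, dim, (vocab.n_medication, dim)),
                            requires_grad=True)
        p.update(nn.encoder_params(rng, dim, cfg.heads, cfg.ffn_size, "enc.d"))
        p.update(nn.encoder_params(rng, dim, cfg.heads, cfg.ffn_size, "enc.p"))
        if not cfg.share_prev_encoders:
            p.update(nn.encoder_params(rng, dim, cfg.heads, cfg.ffn_size, "enc.d_prev"))
            p.update(nn.encoder_params(rng, dim, cfg.heads, cfg.ffn_size, "enc.p_prev"))
        p.update(nn.multi_head_params(rng, 2 * dim, cfg.heads, "block1"))
        p.update(nn.multi_head_params(rng, 2 * dim, cfg.heads, "block2"))
        p.update(nn.linear_params(rng, 4 * dim, vocab.n_medication, "ff1"))
        p.update(nn.linear_params(rng, 3 * dim, vocab.n_medication, "ff2"))
        p.update(nn.gru_params(rng, dim, dim, "gru"))
        p.update(nn.linear_params(rng, dim, vocab.n_medication, "gru_out"))
        p.update(gin_params(rng, library.feature_dim, dim, prefix="gin"))
        self.params = p

    # -- sub-forwards ------------------------------------------------------

    def substructure_table(self) -> SubstructureTable:
        """Encode the fragment library; recomputed per batch so gradients
        reach the GIN parameters."""
        return build_substructure_table(self.library, self.params, prefix="gin")

    def _prev_prefix(self, which: str) -> str:
        if self.config.share_prev_encoders:
            return f"enc.{which}"
        return f"enc.{which}_prev"

    def _encode_codes(self, visit: Visit, enc_d_prefix: str, enc_p_prefix: str):
        cfg = self.config
        d_idx = code_indices(visit.diagnoses, "diagnosis", self.vocab)
        if len(d_idx) == 0:
            raise ValueError(
                f"visit {visit.patient_id}/{visit.t} has no diagnoses"
            )
        p_idx = code_indices(visit.procedures, "procedure", self.vocab)
        if len(p_idx) == 0:
            p_idx = np.array([self.vocab.n_procedure], dtype=np.intp)
        d_rows = nn.encoder(self.params["emb.d"].take_rows(d_idx),
                            self.params, enc_d_prefix, cfg.heads)
        p_rows = nn.encoder(self.params["emb.p"].take_rows(p_idx),
                            self.params, enc_p_prefix, cfg.heads)
        return d_rows, p_rows

    def visit_forward(self, visit: Visit, e_drug: Tensor) -> Tensor:
        """Current-visit logits ``m_c`` from block 1 and the FF1 head."""
        cfg = self.config
        d_rows, p_rows = self._encode_codes(visit, "enc.d", "enc.p")
        if cfg.use_block1:
            e_t = ca_mhsa(e_drug, d_rows, p_rows, self.params, "block1", cfg.heads)
        else:
            e_t = Tensor(np.zeros(2 * cfg.dim))
        feats = concat([e_t, pool_set(d_rows), pool_set(p_rows)], axis=-1)
        return nn.linear(feats, self.params, "ff1")

    def history_rnn_forward(self, history: list[Visit]) -> Tensor:
        """History logits ``m_h`` from the prescription GRU; zero at cold
        start or when the GRU is ablated."""
        n_med = self.vocab.n_medication
        med_visits = [v for v in history if v.medications]
        if not self.config.use_rnn or not med_visits:
            return Tensor(np.zeros(n_med))
        xs = []
        for v in med_visits:
            m_idx = code_indices(v.medications, "medication", self.vocab)
            xs.append(pool_set(self.params["emb.m"].take_rows(m_idx)))
        h_final = nn.gru_sequence(xs, self.config.dim, self.params, "gru")
        return nn.linear(h_final, self.params, "gru_out")

    def effectiveness_forward(self, history: list[Visit]) -> Tensor:
        """Previous-visit logits ``m_p`` from block 2 and the FF2 head."""
        cfg = self.config
        n_med = self.vocab.n_medication
        if not history:
            return Tensor(np.zeros(n_med))
        prev = history[-1]
        if not prev.medications:
            return Tensor(np.zeros(n_med))
        m_idx = code_indices(prev.medications, "medication", self.vocab)
        m_rows = self.params["emb.m"].take_rows(m_idx)
        if cfg.use_block2:
            d_rows, p_rows = self._encode_codes(
                prev, self._prev_prefix("d"), self._prev_prefix("p"))
            e_prev = ca_mhsa(m_rows, d_rows, p_rows, self.params, "block2", cfg.heads)
        else:
            e_prev = Tensor(np.zeros(2 * cfg.dim))
        feats = concat([e_prev, pool_set(m_rows)], axis=-1)
        return nn.linear(feats, self.params, "ff2")

    # -- full forward ------------------------------------------------------

    def forward(self, visit: Visit, history: list[Visit],
                e_drug: Tensor | None = None) -> tuple[Tensor, Tensor, Tensor]:
        """Return the three logit tensors for one visit (graph-building)."""
        if e_drug is None:
            e_drug = self.substructure_table().matrix
        m_c = self.visit_forward(visit, e_drug)
        m_h = self.history_rnn_forward(history)
        m_p = self.effectiveness_forward(history)
        return m_c, m_h, m_p

    def predict_visit(self, visit: Visit, history: list[Visit],
                      e_drug: Tensor | None = None) -> PredictionBundle:
        """Inference: fused probabilities and thresholded set for one visit."""
        m_c, m_h, m_p = self.forward(visit, history, e_drug)
        return fuse_predict(m_c.data, m_h.data, m_p.data, self.config.delta)

    def predicted_codes(self, bundle: PredictionBundle) -> frozenset[str]:
        meds = self.vocab.medication_codes
        return frozenset(meds[i] for i in np.flatnonzero(bundle.m_hat))

    # -- checkpointing -----------------------------------------------------

    def state_arrays(self) -> dict[str, np.ndarray]:
        return {k: p.data.copy() for k, p in self.params.items()}

    def load_state_arrays(self, arrays: dict[str, np.ndarray]) -> None:
        if set(arrays) != set(self.params):
            raise ValueError("checkpoint parameter names do not match model")
        for k, p in self.params.items():
            if arrays[k].shape != p.data.shape:
                raise ValueError(f"shape mismatch for {k}")
            p.data = np.asarray(arrays[k], dtype=np.float64).copy()

    def save(self, path) -> None:
        meta = json.dumps({
            "config": asdict(self.config),
            "vocab_hash": vocabulary_hash(self.vocab),
        })
        np.savez(path, __meta__=np.array(meta), **self.state_arrays())

    @classmethod
    def load(cls, path, vocab: MedicalCodeVocabulary,
             library: FragmentLibrary) -> "DrugDoctorModel":
        with np.load(path, allow_pickle=False) as npz:
            meta = json.loads(str(npz["__meta__"]))
            arrays = {k: npz[k] for k in npz.files if k != "__meta__"}
        if meta["vocab_hash"] != vocabulary_hash(vocab):
            raise ValueError("checkpoint vocabulary hash does not match cohort")
        model = cls(vocab, library, ModelConfig(**meta["config"]))
        model.load_state_arrays(arrays)
        return model
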