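# drugdoctor

Visit-level medication-combination recommendation for EHR data, with a
fully synthetic benchmark path so everything runs offline on a laptop.

A patient's record is an ordered sequence of hospital visits, each a
triple of diagnosis / procedure / medication code sets. The model
recommends the medication set for a visit from:

1. **Current visit** — transformer set encoders over the visit's
   diagnosis and procedure codes, cross-attended against a table of
   drug-substructure embeddings (BRICS fragments encoded by a 3-layer
   graph isomorphism network), through a cross-attention +
   multi-head-self-attention block.
2. **Prescription history** — a GRU over the pooled embeddings of all
   earlier prescription sets.
3. **Previous visit** — the previous prescription's embeddings
   cross-attended against that visit's encoded diagnoses/procedures.

The three logit vectors are summed, passed through a sigmoid, and
thresholded (default 0.4). Training minimizes summed binary
cross-entropy plus a weighted drug–drug-interaction (DDI) penalty
`sum_ij D_ij * o_i * o_j` (default weight 0.5), Adam, batch size 16,
visit-by-visit: all visits are globally shuffled each epoch while each
patient's own visits keep their chronological order, so first visits
(cold start) are first-class training examples.

Everything neural runs on a small numpy reverse-mode autodiff engine
bundled in the package (`drugdoctor.autodiff`) — no deep-learning
framework required. RDKit is optional and only needed for the
real-molecule (SMILES/BRICS) route; the synthetic fragment library
needs nothing beyond numpy.

## Package layout

| module | contents |
|---|---|
| `drugdoctor.ehr_data` | vocabularies, visits, cohorts, multi-hot encoding, JSONL/TSV I/O, patient-level splitting |
| `drugdoctor.synthetic_cohort` | seeded cohort/DDI/fragment generators with planted diagnosis→drug rules and prescription persistence |
| `drugdoctor.molecule_substructures` | BRICS decomposition, molecule graphs, GIN encoder, substructure table |
| `drugdoctor.autodiff`, `drugdoctor.nn` | tensor autograd, attention / transformer encoder / GRU layers, Adam |
| `drugdoctor.model` | the full model, fusion, thresholding, losses |
| `drugdoctor.training` | visit-sequence construction, training loop, checkpoints |
| `drugdoctor.evaluation` | DDI rate / Jaccard / F1 / PRAUC, 80%-patient bootstrap, visit-count strata, frequency baseline |
| `drugdoctor.cli` | `drugdoctor generate / train / evaluate / predict` |

## CLI quick start

```bash
drugdoctor generate --out data --n-patients 200 --seed 7
drugdoctor train --cohort data/cohort.jsonl --ddi data/ddi.tsv \
    --fragments data/fragments.json --epochs 30 --out run
drugdoctor evaluate --cohort data/cohort.jsonl --ddi data/ddi.tsv \
    --fragments data/fragments.json --checkpoint run/checkpoint.npz \
    --strata --out report.json
```

`generate` writes a cohort (JSONL: one header record with the
vocabularies, then one patient per line), a DDI edge list (two
tab-separated medication codes per line, `#` comments allowed), a
fragment library (JSON graphs) and the generator's planted ground
truth. `evaluate` reports mean ± std over 10 bootstrap rounds, each
resampling 80% of test patients, plus optional per-visit-count strata
(the `n = 1` stratum is the cold-start report).

## File formats

- **Cohort JSONL** — line 1: `{"schema_version": 1, "kind":
  "cohort_header", "vocabulary": {"diagnosis": [...], "procedure":
  [...], "medication": [...]}, "metadata": {...}}`; each further line:
  `{"patient_id": "...", "visits": [{"t": 1, "diagnoses": [...],
  "procedures": [...], "medications": [...]}, ...]}` with 1-based
  consecutive visit ordinals.
- **DDI TSV** — `codeA<TAB>codeB` per interacting pair; symmetric and
  deduplicated on read; unknown codes are skipped with a warning.
- **Fragment library JSON** — distinct fragment graphs
  (`node_features`, `edges`) plus a drug → fragment-id map; fragments
  are shared across drugs.
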