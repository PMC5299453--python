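"""Reading and writing EMR snapshots and ground-truth sidecars.

The on-disk layout is five UTF-8 CSV tables with ISO-8601 dates plus an
optional ``truth.json`` sidecar that is never merged into the EMR tables
(the analysis pipeline must not see it). Notes can additionally be written
as JSONL, one object per note.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic_emr import EmrSnapshot, GeneratorTruth

_TABLES = ("patients", "providers", "diagnoses", "prescriptions", "notes")
_DATE_COLS = {"patients": ["birth_date"], "diagnoses": ["date"],
              "prescriptions": ["date"], "notes": ["date"], "providers": []}


def write_snapshot(snapshot: EmrSnapshot, out_dir: str | Path,
                   notes_jsonl: bool = False, write_truth: bool = True) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name in _TABLES:
        df = getattr(snapshot, name).copy()
        for col in _DATE_COLS[name]:
            df[col] = pd.to_datetime(df[col]).dt.strftime("%Y-%m-%d")
        df.to_csv(out / f"{name}.csv", index=False)
    if notes_jsonl:
        with open(out / "notes.jsonl", "w", encoding="utf-8") as fh:
            for rec in snapshot.notes.to_dict("records"):
                rec["date"] = pd.Timestamp(rec["date"]).strftime("%Y-%m-%d")
                fh.write(json.dumps(rec, sort_keys=True) + "\n")
    if write_truth and snapshot.truth is not None:
        write_truth_sidecar(snapshot.truth, out / "truth.json")
    return out


def write_truth_sidecar(truth: GeneratorTruth, path: str | Path) -> None:
    payload = {
        "provider_preference_true": truth.provider_preference_true,
        "topic_word_true": np.asarray(truth.topic_word_true).tolist(),
        "doc_topic_true": {k: np.asarray(v).tolist()
                           for k, v in truth.doc_topic_true.items()},
        "beta_true": list(truth.beta_true),
        "vocabulary": truth.vocabulary,
        "depression_topic": truth.depression_topic,
        "intended_cohort": truth.intended_cohort,
        "decoy_reasons": truth.decoy_reasons,
        "patient_index": json.loads(
            truth.patient_index.assign(
                t0=truth.patient_index["t0"].dt.strftime("%Y-%m-%d")
            ).to_json(orient="records")
        ) if truth.patient_index is not None else None,
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, sort_keys=True)


def read_truth_sidecar(path: str | Path) -> GeneratorTruth:
    with open(path, encoding="utf-8") as fh:
        raw = json.load(fh)
    patient_index = None
    if raw.get("patient_index") is not None:
        patient_index = pd.DataFrame(raw["patient_index"])
        patient_index["t0"] = pd.to_datetime(patient_index["t0"])
    return GeneratorTruth(
        provider_preference_true=raw["provider_preference_true"],
        topic_word_true=np.asarray(raw["topic_word_true"]),
        doc_topic_true={k: np.asarray(v)
                        for k, v in raw["doc_topic_true"].items()},
        beta_true=tuple(raw["beta_true"]),
        vocabulary=list(raw["vocabulary"]),
        depression_topic=int(raw["depression_topic"]),
        intended_cohort=list(raw["intended_cohort"]),
        decoy_reasons=dict(raw["decoy_reasons"]),
        patient_index=patient_index,
    )


def read_snapshot(emr_dir: str | Path, with_truth: bool = False) -> EmrSnapshot:
    emr = Path(emr_dir)
    frames = {}
    for name in _TABLES:
        df = pd.read_csv(emr / f"{name}.csv", dtype={"icd9_code": str})
        for col in _DATE_COLS[name]:
            df[col] = pd.to_datetime(df[col], errors="coerce")
        frames[name] = df
    truth = None
    truth_path = emr / "truth.json"
    if with_truth and truth_path.exists():
        truth = read_truth_sidecar(truth_path)
    return EmrSnapshot(truth=truth, **frames)
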