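"""START-cohort extraction: first sleep-medication prescription phenotype.

A patient enters the cohort when they (1) carry an insomnia indication —
an ICD-9 billing code from the insomnia list, or a clinical note whose text
contains one of the literal sleep-disorder expressions — dated in the
12 months before the index prescription, (2) have no sleep-medication
prescription before that index date t0, and (3) receive a further sleep
medication within the following 12 months (continued use).

Window conventions: the indication window is half-open [t0-365d, t0), the
follow-up window half-open (t0, t0+365d], and the note window closed
[t0-7d, t0+7d]; half-open prior windows prevent the index event from
certifying itself. Expression matching is case-insensitive raw substring
matching after whitespace normalisation — no stemming, no negation
handling.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from datetime import date

import numpy as np
import pandas as pd

from .synthetic_emr import (EmrSnapshot, INSOMNIA_ICD9, SLEEP_DRUGS,
                            SLEEP_EXPRESSIONS, validate_snapshot)


@dataclass
class PhenotypeRules:
    insomnia_icd9_codes: frozenset[str] = INSOMNIA_ICD9
    sleep_expressions: tuple[str, ...] = SLEEP_EXPRESSIONS
    indication_lookback_days: int = 365
    followup_window_days: int = 365
    note_window_days: int = 7
    sleep_medication_names: frozenset[str] = frozenset(SLEEP_DRUGS)


@dataclass
class CohortRecord:
    patient_id: str
    provider_id: str
    t0: pd.Timestamp
    outcome_drug: str
    indication_source: str  # "code" | "note" | "both"
    window_text: str
    age_at_t0: float
    sex: str
    tied_index_date: bool = False


@dataclass
class CohortExtraction:
    """Extraction result: included records plus a per-patient exclusion log."""

    records: list[CohortRecord]
    exclusions: pd.DataFrame = field(repr=False)

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(r) for r in self.records])


def _normalise(text: pd.Series) -> pd.Series:
    return text.fillna("").str.lower().str.replace(r"\s+", " ", regex=True)


def matches_sleep_expression(text: str, expressions=SLEEP_EXPRESSIONS) -> bool:
    norm = re.sub(r"\s+", " ", str(text).lower())
    return any(e in norm for e in expressions)


def extract_cohort(snapshot: EmrSnapshot,
                   rules: PhenotypeRules | None = None) -> CohortExtraction:
    """Apply the inclusion algorithm to a snapshot.

    The index date t0 is the earliest sleep prescription that carries an
    indication in its lookback window; exclusion reasons are reported per
    candidate patient (``no_indication``, ``prior_sleep_medication``,
    ``no_followup``).
    """
    rules = rules or PhenotypeRules()
    validate_snapshot(snapshot)

    meds = {m.lower() for m in rules.sleep_medication_names}
    rx = snapshot.prescriptions
    sleep_rx = rx[rx["drug_name"].str.lower().isin(meds)]

    dx = snapshot.diagnoses
    ind_dx = dx[dx["icd9_code"].astype(str).isin(rules.insomnia_icd9_codes)]

    notes = snapshot.notes
    pattern = "|".join(re.escape(e) for e in rules.sleep_expressions)
    note_match = _normalise(notes["text"]).str.contains(pattern, regex=True)
    ind_notes = notes[note_match.to_numpy()]

    code_dates = {pid: g["date"].to_numpy()
                  for pid, g in ind_dx.groupby("patient_id")}
    note_dates = {pid: g["date"].to_numpy()
                  for pid, g in ind_notes.groupby("patient_id")}
    notes_by_pat = {pid: g for pid, g in notes.groupby("patient_id")}
    pat_info = snapshot.patients.set_index("patient_id")

    lookback = np.timedelta64(rules.indication_lookback_days, "D")
    followup = np.timedelta64(rules.followup_window_days, "D")
    window = np.timedelta64(rules.note_window_days, "D")

    records: list[CohortRecord] = []
    excluded: list[tuple[str, str]] = []

    for pid, g in sleep_rx.groupby("patient_id"):
        g = g.sort_values(["date", "drug_name"], kind="stable")
        dates = g["date"].to_numpy()
        cd = code_dates.get(pid, np.array([], dtype="datetime64[ns]"))
        nd = note_dates.get(pid, np.array([], dtype="datetime64[ns]"))

        t0 = None
        src_code = src_note = False
        for d in np.unique(dates):
            src_code = bool(np.any((cd >= d - lookback) & (cd < d)))
            src_note = bool(np.any((nd >= d - lookback) & (nd < d)))
            if src_code or src_note:
                t0 = d
                break
        if t0 is None:
            excluded.append((pid, "no_indication"))
            continue
        if np.any(dates < t0):
            excluded.append((pid, "prior_sleep_medication"))
            continue
        if not np.any((dates > t0) & (dates <= t0 + followup)):
            excluded.append((pid, "no_followup"))
            continue

        at_t0 = g[g["date"].to_numpy() == t0]
        tied = len(at_t0) > 1 and at_t0["drug_name"].nunique() > 1
        index_row = at_t0.iloc[0]  # already drug-name sorted within date

        pat_notes = notes_by_pat.get(pid)
        if pat_notes is not None:
            in_win = ((pat_notes["date"].to_numpy() >= t0 - window)
                      & (pat_notes["date"].to_numpy() <= t0 + window))
            win = pat_notes[in_win].sort_values(["date", "note_id"], kind="stable")
            window_text = "\n".join(win["text"].tolist())
        else:
            window_text = ""

        info = pat_info.loc[pid]
        age = (pd.Timestamp(t0) - pd.Timestamp(info["birth_date"])).days / 365.25
        source = "both" if (src_code and src_note) else ("code" if src_code else "note")
        records.append(CohortRecord(
            patient_id=pid,
            provider_id=index_row["provider_id"],
            t0=pd.Timestamp(t0),
            outcome_drug=index_row["drug_name"],
            indication_source=source,
            window_text=window_text,
            age_at_t0=float(age),
            sex=str(info["sex"]),
            tied_index_date=tied,
        ))

    records.sort(key=lambda r: r.patient_id)
    exclusions = pd.DataFrame(excluded, columns=["patient_id", "failed_criterion"])
    exclusions.sort_values("patient_id", inplace=True, ignore_index=True)
    return CohortExtraction(records=records, exclusions=exclusions)


def summarize_prescription_distribution(cohort) -> pd.DataFrame:
    """Counts and fractions of the initial medication across the cohort."""
    records = list(cohort)
    if not records:
        raise ValueError("cannot summarise an empty cohort")
    drugs = pd.Series([r.outcome_drug for r in records])
    counts = drugs.value_counts().sort_values(ascending=False)
    out = counts.rename_axis("drug").reset_index(name="count")
    out["fraction"] = out["count"] / len(records)
    return out


def filter_to_binary_outcome(cohort) -> list[CohortRecord]:
    """Restrict to trazodone/zolpidem initial prescriptions, order preserved."""
    return [r for r in cohort
            if r.outcome_drug.lower() in ("trazodone", "zolpidem")]


def outcome_vector(records) -> np.ndarray:
    """1 = trazodone, 0 = zolpidem."""
    bad = {r.outcome_drug for r in records} - {"trazodone", "zolpidem"}
    if bad:
        raise ValueError(f"non-binary outcome drugs present: {sorted(bad)}")
    return np.array([1 if r.outcome_drug == "trazodone" else 0
                     for r in records], dtype=int)


def write_cohort(extraction: CohortExtraction, out_dir) -> None:
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    df = extraction.to_frame()
    if not df.empty:
        df = df.assign(t0=df["t0"].dt.strftime("%Y-%m-%d"))
    df.to_csv(out / "cohort.csv", index=False)
    extraction.exclusions.to_csv(out / "exclusions.csv", index=False)


def read_cohort(path) -> list[CohortRecord]:
    df = pd.read_csv(path, keep_default_na=False)
    records = []
    for row in df.to_dict("records"):
        row["t0"] = pd.Timestamp(row["t0"])
        row["age_at_t0"] = float(row["age_at_t0"])
        row["tied_index_date"] = bool(row["tied_index_date"])
        records.append(CohortRecord(**row))
    return records
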