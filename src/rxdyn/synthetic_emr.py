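"""Synthetic EMR generator with planted prescribing dynamics.

Generates a relational EMR snapshot (patients, providers, diagnoses,
prescriptions, free-text notes) in which the quantities the downstream
analysis estimates are *known by construction*:

* each provider has a latent trazodone-vs-zolpidem preference drawn from a
  Beta mixture with a point mass of exclusive trazodone prescribers;
* clinical notes are drawn from a latent Dirichlet allocation process whose
  first topic carries depression vocabulary on a block of terms disjoint
  from every other topic's support;
* the index prescription (trazodone vs zolpidem) is a Bernoulli draw from a
  logistic model on provider preference and the patient's depression-topic
  proportion.

The generator also plants decoy patients that each violate exactly one
cohort inclusion criterion, so the phenotyping filters can be exercised
end to end without any external data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date, timedelta

import numpy as np
import pandas as pd
from scipy.special import expit

SLEEP_DRUGS = ("trazodone", "zolpidem", "zolpidem ER", "eszopiclone")

INSOMNIA_ICD9 = frozenset(
    {"307.41", "307.42", "327.00", "327.01", "327.02", "327.09", "780.52"}
)

SLEEP_EXPRESSIONS = (
    "poor sleep",
    "has trouble sleep",
    "reduced sleep",
    "increased sleep",
    "decreased sleep",
    "excessive sleep",
    "fragmented sleep",
    "sleeplessness",
    "sleep disruption",
    "sleeps poorly",
)

# Seed words for each planted topic block; the depression block (topic 0) is
# what the decision model is expected to find. Blocks are padded with
# synthetic filler terms up to vocab_size // n_topics.
_TOPIC_SEED_WORDS = (
    ["depression", "mood", "psychiatric", "mental", "suicidal", "substance",
     "anxiety", "depressed", "affect", "psychotherapy"],
    ["glucose", "insulin", "diabetes", "metformin", "hemoglobin", "glycemic",
     "endocrine", "hyperglycemia", "neuropathy", "retinopathy"],
    ["cardiac", "hypertension", "lisinopril", "systolic", "angina",
     "coronary", "statin", "lipid", "ejection", "arrhythmia"],
    ["knee", "pain", "arthritis", "ibuprofen", "joint", "lumbar",
     "physical", "therapy", "osteoarthritis", "gait"],
    ["cough", "asthma", "wheezing", "inhaler", "pulmonary", "dyspnea",
     "bronchitis", "albuterol", "spirometry", "copd"],
)


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic-EMR generative process.

    Defaults mirror the study conditions the analysis is built around:
    504 providers and 1,105 first-prescription patients, a trazodone/
    zolpidem mix near 57%/38%, odds ratios of 3.13 per unit provider
    preference and 1.38 per unit depression-topic proportion, and roughly
    43% of insomnia indications arriving as billing codes (the rest as
    narrative sleep expressions).
    """

    n_providers: int = 504
    n_patients: int = 1105
    exclusive_trazodone_fraction: float = 0.10
    preference_beta_params: tuple[float, float] = (2.0, 2.0)
    n_topics_true: int = 5
    vocab_size: int = 500
    doc_length_mean: float = 100.0
    dirichlet_alpha_true: float = 0.5
    dirichlet_eta_true: float = 0.5
    beta0: float = -0.3
    beta_pref: float = math.log(3.13)
    beta_depr: float = math.log(1.38)
    history_rx_per_provider_mean: float = 100.0
    study_start_date: date = date(2004, 1, 1)
    study_end_date: date = date(2010, 12, 31)
    seed: int = 0
    # knobs below are generator plumbing, not headline effects
    notes_per_patient: tuple[int, int] = (1, 3)
    code_indication_fraction: float = 476 / 1105
    other_drug_fraction: float = 0.05
    decoy_fraction_prior_rx: float = 0.05
    decoy_fraction_no_indication: float = 0.05
    decoy_fraction_no_followup: float = 0.05

    def __post_init__(self) -> None:
        if min(self.n_providers, self.n_patients, self.n_topics_true,
               self.vocab_size) <= 0:
            raise ValueError("all counts must be positive")
        if self.n_topics_true < 2:
            raise ValueError("n_topics_true must be >= 2")
        if not 0.0 <= self.exclusive_trazodone_fraction <= 1.0:
            raise ValueError("exclusive_trazodone_fraction must lie in [0, 1]")
        if min(self.preference_beta_params) <= 0:
            raise ValueError("preference_beta_params must be positive")
        if self.doc_length_mean <= 0 or self.history_rx_per_provider_mean < 0:
            raise ValueError("doc_length_mean must be positive")
        if self.dirichlet_alpha_true <= 0 or self.dirichlet_eta_true <= 0:
            raise ValueError("Dirichlet concentrations must be positive")
        if self.study_start_date >= self.study_end_date:
            raise ValueError("study_start_date must precede study_end_date")
        if self.vocab_size < self.n_topics_true:
            raise ValueError("vocab_size must be >= n_topics_true")
        if (self.study_end_date - self.study_start_date).days < 4 * 365:
            raise ValueError(
                "study window must span at least 4 years (2y provider "
                "history + 1y lookback + 1y follow-up)"
            )


@dataclass
class GeneratorTruth:
    """Ground truth of one generated snapshot, kept out of the EMR tables."""

    provider_preference_true: dict[str, float]
    topic_word_true: np.ndarray  # (K_true, V), rows sum to 1
    doc_topic_true: dict[str, np.ndarray]  # note_id -> (K_true,)
    beta_true: tuple[float, float, float]
    vocabulary: list[str]
    depression_topic: int
    intended_cohort: list[str]
    decoy_reasons: dict[str, str]
    # per intended-cohort-patient covariates the outcome was generated from
    patient_index: pd.DataFrame = field(repr=False, default=None)


@dataclass
class EmrSnapshot:
    """Five linked EMR tables plus optional generator ground truth."""

    patients: pd.DataFrame
    providers: pd.DataFrame
    diagnoses: pd.DataFrame
    prescriptions: pd.DataFrame
    notes: pd.DataFrame
    truth: GeneratorTruth | None = None


def build_vocabulary(config: GeneratorConfig) -> list[str]:
    """Topic-blocked vocabulary: seed words plus synthetic filler terms."""
    k, v = config.n_topics_true, config.vocab_size
    sizes = [v // k + (1 if i < v % k else 0) for i in range(k)]
    vocab: list[str] = []
    for t, size in enumerate(sizes):
        seeds = list(_TOPIC_SEED_WORDS[t % len(_TOPIC_SEED_WORDS)])[:size]
        if t >= len(_TOPIC_SEED_WORDS):
            seeds = []
        fillers = [f"t{t}term{j:03d}" for j in range(size - len(seeds))]
        vocab.extend(seeds + fillers)
    return vocab


def _topic_blocks(config: GeneratorConfig) -> list[np.ndarray]:
    k, v = config.n_topics_true, config.vocab_size
    sizes = [v // k + (1 if i < v % k else 0) for i in range(k)]
    blocks, start = [], 0
    for size in sizes:
        blocks.append(np.arange(start, start + size))
        start += size
    return blocks


def _sample_tokens(rng: np.random.Generator, theta: np.ndarray, length: int,
                   phi_cum: list[np.ndarray], blocks: list[np.ndarray]) -> np.ndarray:
    """Draw `length` word ids from the mixture theta over block topics."""
    topic_counts = rng.multinomial(length, theta)
    words = np.empty(length, dtype=np.int64)
    pos = 0
    for t, c in enumerate(topic_counts):
        if c == 0:
            continue
        u = rng.random(c)
        words[pos:pos + c] = blocks[t][np.searchsorted(phi_cum[t], u, side="right")]
        pos += c
    rng.shuffle(words)
    return words


def generate_snapshot(config: GeneratorConfig) -> EmrSnapshot:
    """Generate a complete synthetic EMR snapshot, reproducible from seed."""
    rng = np.random.default_rng(config.seed)
    n_prov, n_pat = config.n_providers, config.n_patients
    k_true = config.n_topics_true

    expected_cohort = n_pat
    if expected_cohort == 0:
        raise ValueError("configuration yields an expected cohort of size 0")

    provider_ids = [f"P{i:04d}" for i in range(n_prov)]
    a, b = config.preference_beta_params
    pref = rng.beta(a, b, size=n_prov)
    exclusive = rng.random(n_prov) < config.exclusive_trazodone_fraction
    pref[exclusive] = 1.0

    blocks = _topic_blocks(config)
    vocab = build_vocabulary(config)
    vocab_arr = np.array(vocab, dtype=object)
    topic_word = np.zeros((k_true, config.vocab_size))
    for t, block in enumerate(blocks):
        topic_word[t, block] = rng.dirichlet(
            np.full(block.size, config.dirichlet_eta_true)
        )
    phi_cum = [np.cumsum(topic_word[t, block]) for t, block in enumerate(blocks)]
    for c in phi_cum:
        c[-1] = 1.0  # guard against cumulative rounding

    start = pd.Timestamp(config.study_start_date)
    end = pd.Timestamp(config.study_end_date)
    history_end = start + pd.Timedelta(days=730)
    # index dates leave >= 1y of history+lookback behind and 1y follow-up ahead
    t0_lo = history_end + pd.Timedelta(days=366)
    t0_hi = end - pd.Timedelta(days=366)
    t0_span = (t0_hi - t0_lo).days

    # ---- provider prescription history (all before any index date) -------
    hist_counts = rng.poisson(config.history_rx_per_provider_mean, n_prov)
    hist_prov = np.repeat(np.arange(n_prov), hist_counts)
    n_hist = hist_prov.size
    hist_days = rng.integers(0, (history_end - start).days, n_hist)
    hist_traz = rng.random(n_hist) < pref[hist_prov]
    n_hist_pat = max(1, n_hist // 5)
    hist_pat = rng.integers(0, n_hist_pat, n_hist)

    rx_patient: list[str] = [f"H{i:05d}" for i in hist_pat]
    rx_provider: list[str] = [provider_ids[i] for i in hist_prov]
    rx_drug: list[str] = ["trazodone" if t else "zolpidem" for t in hist_traz]
    rx_date: list[pd.Timestamp] = [start + pd.Timedelta(days=int(d)) for d in hist_days]

    dx_rows: list[tuple[str, pd.Timestamp, str]] = []
    note_rows: list[tuple[str, str, str, pd.Timestamp, str]] = []
    doc_topic: dict[str, np.ndarray] = {}
    note_counter = 0

    def add_note(pid: str, prov: str, when: pd.Timestamp, theta: np.ndarray,
                 length: int, prefix: str = "") -> str:
        nonlocal note_counter
        nid = f"N{note_counter:06d}"
        note_counter += 1
        words = _sample_tokens(rng, theta, length, phi_cum, blocks)
        text = " ".join(vocab_arr[words])
        if prefix:
            text = prefix + " " + text
        note_rows.append((nid, pid, prov, when, text))
        doc_topic[nid] = theta
        return nid

    def add_indication(pid: str, prov: str, t0: pd.Timestamp) -> None:
        if rng.random() < config.code_indication_fraction:
            code = sorted(INSOMNIA_ICD9)[rng.integers(0, len(INSOMNIA_ICD9))]
            dx_rows.append((pid, t0 - pd.Timedelta(days=int(rng.integers(1, 366))), code))
        else:
            expr = SLEEP_EXPRESSIONS[rng.integers(0, len(SLEEP_EXPRESSIONS))]
            when = t0 - pd.Timedelta(days=int(rng.integers(8, 301)))
            theta = rng.dirichlet(np.full(k_true, config.dirichlet_alpha_true))
            add_note(pid, prov, when, theta, max(10, int(rng.poisson(30))), prefix=expr)

    def note_len() -> int:
        return max(10, int(rng.poisson(config.doc_length_mean)))

    # ---- intended START-cohort patients ---------------------------------
    pat_ids = [f"S{i:05d}" for i in range(n_pat)]
    pat_prov_idx = rng.integers(0, n_prov, n_pat)
    pat_t0 = [t0_lo + pd.Timedelta(days=int(d))
              for d in rng.integers(0, t0_span + 1, n_pat)]
    pat_theta = rng.dirichlet(np.full(k_true, config.dirichlet_alpha_true), size=n_pat)
    depr = pat_theta[:, 0]
    p_traz = expit(config.beta0 + config.beta_pref * pref[pat_prov_idx]
                   + config.beta_depr * depr)
    is_other = rng.random(n_pat) < config.other_drug_fraction
    u_drug = rng.random(n_pat)
    u_other = rng.random(n_pat)

    index_rows = []
    for i, pid in enumerate(pat_ids):
        prov = provider_ids[pat_prov_idx[i]]
        t0 = pat_t0[i]
        if is_other[i]:
            drug = "eszopiclone" if u_other[i] < 0.5 else "zolpidem ER"
        elif pref[pat_prov_idx[i]] == 1.0:
            # exclusive trazodone prescribers never write zolpidem
            drug = "trazodone"
        else:
            drug = "trazodone" if u_drug[i] < p_traz[i] else "zolpidem"
        add_indication(pid, prov, t0)
        n_notes = int(rng.integers(config.notes_per_patient[0],
                                   config.notes_per_patient[1] + 1))
        for _ in range(n_notes):
            when = t0 + pd.Timedelta(days=int(rng.integers(-7, 8)))
            add_note(pid, prov, when, pat_theta[i], note_len())
        rx_patient.append(pid); rx_provider.append(prov)
        rx_drug.append(drug); rx_date.append(t0)
        # continued use: one more sleep script within the following year
        fu_drug = "trazodone" if rng.random() < pref[pat_prov_idx[i]] else "zolpidem"
        rx_patient.append(pid); rx_provider.append(prov)
        rx_drug.append(fu_drug)
        rx_date.append(t0 + pd.Timedelta(days=int(rng.integers(1, 366))))
        # background non-insomnia diagnosis so code filtering is non-trivial
        dx_rows.append((pid, t0 - pd.Timedelta(days=int(rng.integers(1, 700))), "250.00"))
        index_rows.append((pid, prov, t0, drug, pref[pat_prov_idx[i]], depr[i]))

    # ---- decoys: each violates exactly one inclusion criterion ----------
    decoy_reasons: dict[str, str] = {}
    decoy_specs = [
        ("prior_sleep_medication", config.decoy_fraction_prior_rx),
        ("no_indication", config.decoy_fraction_no_indication),
        ("no_followup", config.decoy_fraction_no_followup),
    ]
    d_counter = 0
    for reason, frac in decoy_specs:
        for _ in range(int(round(frac * n_pat))):
            pid = f"D{d_counter:05d}"
            d_counter += 1
            prov_i = int(rng.integers(0, n_prov))
            prov = provider_ids[prov_i]
            t0 = t0_lo + pd.Timedelta(days=int(rng.integers(0, t0_span + 1)))
            theta = rng.dirichlet(np.full(k_true, config.dirichlet_alpha_true))
            drug = "trazodone" if rng.random() < pref[prov_i] else "zolpidem"
            add_note(pid, prov, t0 + pd.Timedelta(days=int(rng.integers(-7, 8))),
                     theta, note_len())
            rx_patient.append(pid); rx_provider.append(prov)
            rx_drug.append(drug); rx_date.append(t0)
            if reason != "no_indication":
                add_indication(pid, prov, t0)
            if reason != "no_followup":
                fu = "trazodone" if rng.random() < pref[prov_i] else "zolpidem"
                rx_patient.append(pid); rx_provider.append(prov)
                rx_drug.append(fu)
                rx_date.append(t0 + pd.Timedelta(days=int(rng.integers(1, 366))))
            if reason == "prior_sleep_medication":
                # an old sleep script with no indication of its own; drug
                # follows the prescriber's preference so exclusive
                # trazodone providers stay exclusive
                prior_day = int(rng.integers(0, (history_end - start).days))
                prior = "trazodone" if rng.random() < pref[prov_i] else "zolpidem"
                rx_patient.append(pid); rx_provider.append(prov)
                rx_drug.append(prior)
                rx_date.append(start + pd.Timedelta(days=prior_day))
            decoy_reasons[pid] = reason

    # ---- assemble tables -------------------------------------------------
    all_pat = pat_ids + sorted(decoy_reasons) + [f"H{i:05d}" for i in range(n_hist_pat)]
    birth_days = rng.integers(0, 365 * 50, len(all_pat))
    patients = pd.DataFrame({
        "patient_id": all_pat,
        "birth_date": [pd.Timestamp(date(1930, 1, 1)) + pd.Timedelta(days=int(d))
                       for d in birth_days],
        "sex": np.where(rng.random(len(all_pat)) < 0.5, "F", "M"),
    })
    providers = pd.DataFrame({"provider_id": provider_ids})
    diagnoses = pd.DataFrame(dx_rows, columns=["patient_id", "date", "icd9_code"])
    prescriptions = pd.DataFrame({
        "patient_id": rx_patient,
        "provider_id": rx_provider,
        "drug_name": rx_drug,
        "date": rx_date,
    })
    notes = pd.DataFrame(
        note_rows, columns=["note_id", "patient_id", "provider_id", "date", "text"]
    )
    for df in (diagnoses, prescriptions, notes):
        df["date"] = pd.to_datetime(df["date"])
    diagnoses.sort_values(["patient_id", "date", "icd9_code"],
                          inplace=True, kind="stable", ignore_index=True)
    prescriptions.sort_values(["patient_id", "date", "drug_name"],
                              inplace=True, kind="stable", ignore_index=True)

    truth = GeneratorTruth(
        provider_preference_true=dict(zip(provider_ids, pref.tolist())),
        topic_word_true=topic_word,
        doc_topic_true=doc_topic,
        beta_true=(config.beta0, config.beta_pref, config.beta_depr),
        vocabulary=vocab,
        depression_topic=0,
        intended_cohort=list(pat_ids),
        decoy_reasons=decoy_reasons,
        patient_index=pd.DataFrame(
            index_rows,
            columns=["patient_id", "provider_id", "t0", "drug",
                     "preference_true", "depression_proportion"],
        ),
    )
    return EmrSnapshot(patients, providers, diagnoses, prescriptions, notes, truth)


def validate_snapshot(snapshot: EmrSnapshot) -> None:
    """Referential-integrity and date-sanity checks; raises on violation."""
    pat = set(snapshot.patients["patient_id"])
    prov = set(snapshot.providers["provider_id"])
    for name, df in (("diagnoses", snapshot.diagnoses),
                     ("prescriptions", snapshot.prescriptions),
                     ("notes", snapshot.notes)):
        missing = set(df["patient_id"]) - pat
        if missing:
            raise ValueError(f"{name}: unknown patient ids {sorted(missing)[:5]}")
        if "provider_id" in df.columns:
            missing_p = set(df["provider_id"]) - prov
            if missing_p:
                raise ValueError(f"{name}: unknown provider ids {sorted(missing_p)[:5]}")
        dates = pd.to_datetime(df["date"], errors="coerce")
        if dates.isna().any():
            row = int(np.flatnonzero(dates.isna().to_numpy())[0])
            raise ValueError(f"{name}: malformed date in row {row}")
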