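"""Provider trazodone-preference statistic, global and time-specific.

For provider i with t_i lifetime trazodone prescriptions and z_i zolpidem
prescriptions, the preference is p_i = t_i / (t_i + z_i): 0 means an
exclusive zolpidem prescriber, 1 an exclusive trazodone prescriber. The
time-specific variant counts only prescriptions dated strictly before a
given encounter date, so the feature for an index encounter can never see
the encounter itself or anything after it (leakage-free by construction).

Providers with no trazodone/zolpidem history at the as-of date have an
undefined ratio (NaN); the modeling default imputes the uninformative
midpoint 0.5 and flags the row, with a drop-the-encounter policy as the
alternative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

UNDEFINED = float("nan")


@dataclass
class PreferenceValue:
    provider_id: str
    as_of_date: object  # pd.Timestamp or the string "all-time"
    t_count: int
    z_count: int
    p_i: float

    @property
    def defined(self) -> bool:
        return self.t_count + self.z_count > 0


def compute_preference(t_count: int, z_count: int) -> float:
    """p_i = t / (t + z); NaN when the provider has no history."""
    if t_count < 0 or z_count < 0:
        raise ValueError("prescription counts must be non-negative")
    total = t_count + z_count
    if total == 0:
        return UNDEFINED
    return t_count / total


def _traz_zolp(prescriptions: pd.DataFrame) -> pd.DataFrame:
    drug = prescriptions["drug_name"].str.lower()
    return prescriptions[drug.isin(("trazodone", "zolpidem"))]


def time_specific_preference(prescriptions: pd.DataFrame, provider_id: str,
                             as_of_date) -> PreferenceValue:
    """Preference from this provider's scripts strictly before as_of_date."""
    as_of = pd.Timestamp(as_of_date)
    sub = _traz_zolp(prescriptions)
    sub = sub[(sub["provider_id"] == provider_id) & (sub["date"] < as_of)]
    t = int((sub["drug_name"].str.lower() == "trazodone").sum())
    z = len(sub) - t
    return PreferenceValue(provider_id, as_of, t, z, compute_preference(t, z))


def all_time_preferences(prescriptions: pd.DataFrame) -> pd.DataFrame:
    """Per-provider lifetime (t_count, z_count, p_i)."""
    sub = _traz_zolp(prescriptions)
    is_t = sub["drug_name"].str.lower() == "trazodone"
    g = sub.assign(is_t=is_t).groupby("provider_id")["is_t"]
    out = g.agg(t_count="sum", total="count").reset_index()
    out["t_count"] = out["t_count"].astype(int)
    out["z_count"] = (out["total"] - out["t_count"]).astype(int)
    out["p_i"] = out["t_count"] / out["total"]
    return out[["provider_id", "t_count", "z_count", "p_i"]]


def encounter_preferences(prescriptions: pd.DataFrame, cohort,
                          policy: str = "impute",
                          impute_value: float = 0.5) -> pd.DataFrame:
    """Time-specific preference for every cohort index encounter.

    policy="impute" keeps zero-history encounters at `impute_value` with
    imputed_flag set; policy="drop" removes them.
    """
    if policy not in ("impute", "drop"):
        raise ValueError("policy must be 'impute' or 'drop'")
    sub = _traz_zolp(prescriptions)
    by_provider: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for prov, g in sub.groupby("provider_id"):
        g = g.sort_values("date", kind="stable")
        dates = g["date"].to_numpy()
        is_t = (g["drug_name"].str.lower() == "trazodone").to_numpy()
        by_provider[prov] = (dates, np.concatenate([[0], np.cumsum(is_t)]))

    rows = []
    for rec in cohort:
        dates_cum = by_provider.get(rec.provider_id)
        if dates_cum is None:
            t = z = 0
        else:
            dates, cum_t = dates_cum
            n_before = int(np.searchsorted(dates, np.datetime64(rec.t0), side="left"))
            t = int(cum_t[n_before])
            z = n_before - t
        p = compute_preference(t, z)
        imputed = not (t + z > 0)
        if imputed:
            if policy == "drop":
                continue
            p = impute_value
        rows.append((rec.patient_id, rec.provider_id, rec.t0, t, z, p, imputed))
    return pd.DataFrame(
        rows, columns=["patient_id", "provider_id", "t0",
                       "t_count", "z_count", "p_i", "imputed_flag"])


@dataclass
class PreferenceHistogram:
    bin_edges: np.ndarray
    counts: np.ndarray
    spike_count: int  # providers at exactly p_i = 1
    n_defined: int

    @property
    def spike_mass(self) -> float:
        return self.spike_count / self.n_defined if self.n_defined else UNDEFINED


def preference_histogram(prescriptions: pd.DataFrame,
                         n_bins: int = 20) -> PreferenceHistogram:
    """All-time preference histogram with the p_i = 1 spike kept separate."""
    prefs = all_time_preferences(prescriptions)
    if prefs.empty:
        raise ValueError("no provider with a defined preference")
    p = prefs["p_i"].to_numpy()
    spike = int(np.sum(p == 1.0))
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    counts, _ = np.histogram(p[p < 1.0], bins=edges)
    return PreferenceHistogram(edges, counts, spike, len(p))
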