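"""End-to-end pipeline: simulate -> phenotype -> preference -> topics -> model.

One structured config drives every stage; per-stage seeds are derived from
the top-level seed so a rerun with the same config reproduces every CSV and
JSON data output byte for byte. The run manifest records the config, the
derived seeds, file digests of every stage output, and wall-clock
timestamps (the manifest is therefore the one output that differs between
otherwise identical runs).

The pipeline never reads the generator's truth sidecar: ``truth.json`` is
written next to the EMR tables for tests and report comparison only, and
the analysis stages consume only the five EMR tables.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .decision_model import SIGNIFICANCE_LEVEL, sweep_topic_grid
from .phenotyping import (PhenotypeRules, extract_cohort,
                          filter_to_binary_outcome,
                          summarize_prescription_distribution, write_cohort)
from .preference import (encounter_preferences, preference_histogram)
from .synthetic_emr import GeneratorConfig, generate_snapshot
from .topic_model import build_corpus, rank_terms_by_relevance
from . import io as rxio

logger = logging.getLogger(__name__)

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "generator": {},          # GeneratorConfig overrides
    "phenotype": {},          # PhenotypeRules overrides
    "preference": {"policy": "impute", "impute_value": 0.5},
    "lda": {"n_iterations": 2000, "n_burnin": 500, "eta": 0.01},
    "model": {"k_grid": [0, 5, 10, 15, 20], "n_folds": 10, "threshold": 0.5},
    "report": {"top_n_terms": 30, "histogram_bins": 20},
}


def default_config() -> dict:
    return copy.deepcopy(DEFAULT_CONFIG)


def load_config(path: str | Path) -> dict:
    with open(path, encoding="utf-8") as fh:
        user = yaml.safe_load(fh) or {}
    cfg = default_config()
    unknown = set(user) - set(cfg)
    if unknown:
        raise ValueError(f"unknown config sections: {sorted(unknown)}")
    for key, val in user.items():
        if isinstance(cfg[key], dict):
            cfg[key] = {**cfg[key], **(val or {})}
        else:
            cfg[key] = val
    return cfg


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n",
                    encoding="utf-8")


def run_pipeline(config: dict | str | Path, out_dir: str | Path) -> dict:
    """Execute every stage; returns the run manifest (also written to disk)."""
    if not isinstance(config, dict):
        config = load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    manifest: dict = {
        "version": __version__,
        "config": copy.deepcopy(config),
        "seeds": {"generator": seed, "lda_base": seed + 1000, "cv": seed + 2000},
        "stages": {},
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }

    def stage_done(name: str, outputs: list[Path], **info) -> None:
        manifest["stages"][name] = {
            "outputs": {p.name: _digest(p) for p in outputs}, **info}
        logger.info("stage %s done: %s", name, info)

    # ---- simulate -------------------------------------------------------
    gen_cfg = GeneratorConfig(**{**config["generator"], "seed": seed})
    snapshot = generate_snapshot(gen_cfg)
    emr_dir = out / "emr"
    rxio.write_snapshot(snapshot, emr_dir)
    stage_done("simulate", sorted(emr_dir.glob("*.csv")),
               n_patients=len(snapshot.patients),
               n_prescriptions=len(snapshot.prescriptions),
               n_notes=len(snapshot.notes))

    # analysis stages re-read the EMR tables and never touch truth.json
    snapshot = rxio.read_snapshot(emr_dir, with_truth=False)

    # ---- phenotype ------------------------------------------------------
    rules = PhenotypeRules(**config["phenotype"]) if config["phenotype"] \
        else PhenotypeRules()
    extraction = extract_cohort(snapshot, rules)
    write_cohort(extraction, out)
    dist = summarize_prescription_distribution(extraction.records)
    dist.to_csv(out / "prescription_distribution.csv", index=False)
    cohort = filter_to_binary_outcome(extraction.records)
    stage_done("phenotype",
               [out / "cohort.csv", out / "exclusions.csv",
                out / "prescription_distribution.csv"],
               cohort_size=len(extraction.records),
               excluded=len(extraction.exclusions),
               binary_cohort_size=len(cohort))

    # ---- preference -----------------------------------------------------
    pol = config["preference"]
    prefs = encounter_preferences(snapshot.prescriptions, cohort,
                                  policy=pol["policy"],
                                  impute_value=pol["impute_value"])
    prefs.assign(t0=prefs["t0"].dt.strftime("%Y-%m-%d")).to_csv(
        out / "preferences.csv", index=False)
    hist = preference_histogram(snapshot.prescriptions,
                                n_bins=config["report"]["histogram_bins"])
    pd.DataFrame({"bin_left": hist.bin_edges[:-1],
                  "bin_right": hist.bin_edges[1:],
                  "count": hist.counts}).to_csv(
        out / "preference_histogram.csv", index=False)
    _write_json({"spike_count": hist.spike_count,
                 "spike_mass": hist.spike_mass,
                 "n_providers_defined": hist.n_defined},
                out / "preference_spike.json")
    if pol["policy"] == "drop":
        kept = set(prefs["patient_id"])
        cohort = [r for r in cohort if r.patient_id in kept]
    stage_done("preference",
               [out / "preferences.csv", out / "preference_histogram.csv",
                out / "preference_spike.json"],
               n_encounters=len(prefs),
               n_imputed=int(prefs["imputed_flag"].sum()))

    # ---- topics + model -------------------------------------------------
    corpus = build_corpus([r.window_text for r in cohort],
                          doc_ids=[r.patient_id for r in cohort])
    if corpus.excluded_doc_ids:
        kept = set(corpus.doc_ids)
        cohort = [r for r in cohort if r.patient_id in kept]
    aligned = prefs.set_index("patient_id").loc[[r.patient_id for r in cohort]]
    mdl = config["model"]
    report = sweep_topic_grid(
        cohort, aligned["p_i"].to_numpy(), corpus,
        k_grid=tuple(mdl["k_grid"]), n_folds=int(mdl["n_folds"]),
        seed=seed, threshold=float(mdl["threshold"]),
        lda_iterations=int(config["lda"]["n_iterations"]),
        lda_burnin=int(config["lda"]["n_burnin"]),
        lda_eta=float(config["lda"]["eta"]))

    model_dir = out / "model"
    model_dir.mkdir(exist_ok=True)
    report.metrics.to_csv(model_dir / "metrics.csv", index=False,
                          float_format="%.6f")
    report.coefficients.to_csv(model_dir / "coefficients.csv", index=False,
                               float_format="%.10g")
    topic_paths = []
    if report.chosen_k > 0:
        fit = report.topic_fits[report.chosen_k]
        topics_dir = out / "topics"
        topics_dir.mkdir(exist_ok=True)
        pd.DataFrame(fit.phi, columns=fit.vocabulary).to_csv(
            topics_dir / "phi.csv", index=False, float_format="%.10g")
        pd.DataFrame(fit.theta,
                     columns=[f"topic_{t + 1}" for t in range(fit.k)]).assign(
            patient_id=fit.doc_ids).to_csv(
            topics_dir / "theta.csv", index=False, float_format="%.10g")
        rel_rows = []
        for t in range(fit.k):
            for rank, (term, score) in enumerate(rank_terms_by_relevance(
                    fit, t, 0.6, config["report"]["top_n_terms"])):
                rel_rows.append((t + 1, rank + 1, term, score))
        pd.DataFrame(rel_rows, columns=["topic", "rank", "term", "relevance"]
                     ).to_csv(topics_dir / "relevance.csv", index=False,
                              float_format="%.10g")
        topic_paths = [topics_dir / "phi.csv", topics_dir / "theta.csv",
                       topics_dir / "relevance.csv"]
    stage_done("model", [model_dir / "metrics.csv",
                         model_dir / "coefficients.csv"] + topic_paths,
               chosen_k=report.chosen_k,
               cv_auc=float(report.metrics["auc"].max()))

    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    _write_json(manifest, out / "manifest.json")
    return manifest


def report(outputs_dir: str | Path, make_plots: bool = True) -> str:
    """Compose a human-readable markdown summary of a completed run."""
    out = Path(outputs_dir)
    lines = ["# rxdyn run report", ""]
    warnings_: list[str] = []

    dist_path = out / "prescription_distribution.csv"
    if dist_path.exists():
        dist = pd.read_csv(dist_path)
        lines += ["## Initial prescription distribution", "",
                  dist.to_string(index=False), ""]
    else:
        warnings_.append("prescription distribution missing")

    spike_path = out / "preference_spike.json"
    if spike_path.exists():
        spike = json.loads(spike_path.read_text())
        lines += ["## Provider preference", "",
                  f"{spike['n_providers_defined']} providers with a defined "
                  f"preference; {spike['spike_count']} "
                  f"({100 * spike['spike_mass']:.1f}%) prescribe trazodone "
                  "exclusively (p_i = 1).", ""]
    else:
        warnings_.append("preference stage outputs missing")

    metrics_path = out / "model" / "metrics.csv"
    coef_path = out / "model" / "coefficients.csv"
    if metrics_path.exists() and coef_path.exists():
        metrics = pd.read_csv(metrics_path)
        coefs = pd.read_csv(coef_path)
        chosen_k = int(metrics.loc[metrics["auc"].idxmax(), "k"])
        lines += ["## Cross-validated performance by number of topics", "",
                  metrics.to_string(index=False), "",
                  f"Chosen K = {chosen_k} "
                  f"(best mean CV AUC = {metrics['auc'].max():.3f}).", "",
                  "## Final model odds ratios", "",
                  coefs.to_string(index=False), ""]
        sig = coefs[(coefs["p_value"] < SIGNIFICANCE_LEVEL)
                    & coefs["variable"].str.startswith("topic_")]
        rel_path = out / "topics" / "relevance.csv"
        if not sig.empty and rel_path.exists():
            rel = pd.read_csv(rel_path)
            lines.append("## Top relevance-ranked terms of significant topics")
            lines.append("")
            for var in sig["variable"]:
                t = int(var.split("_")[1])
                terms = rel[rel["topic"] == t].nsmallest(15, "rank")["term"]
                lines.append(f"- {var}: " + ", ".join(terms))
            lines.append("")
    else:
        warnings_.append("model stage outputs missing")

    if warnings_:
        lines += ["## Warnings", ""] + [f"- {w} (partial run?)" for w in warnings_] + [""]

    text = "\n".join(lines)
    (out / "report.md").write_text(text, encoding="utf-8")
    if make_plots:
        try:
            _plots(out)
        except Exception as exc:  # plotting is best-effort
            logger.warning("plotting failed: %s", exc)
    return text


def _plots(out: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    dist_path = out / "prescription_distribution.csv"
    if dist_path.exists():
        dist = pd.read_csv(dist_path)
        fig, ax = plt.subplots(figsize=(5, 3.2))
        ax.bar(dist["drug"], dist["fraction"], color="#4878d0")
        ax.set_ylabel("fraction of cohort")
        ax.set_title("Initial sleep medication")
        fig.autofmt_xdate(rotation=20)
        fig.tight_layout()
        fig.savefig(out / "prescription_distribution.png", dpi=120)
        plt.close(fig)
    hist_path = out / "preference_histogram.csv"
    if hist_path.exists():
        hist = pd.read_csv(hist_path)
        fig, ax = plt.subplots(figsize=(5, 3.2))
        width = hist["bin_right"] - hist["bin_left"]
        ax.bar(hist["bin_left"], hist["count"], width=width, align="edge",
               color="#6acc64", edgecolor="white")
        spike = json.loads((out / "preference_spike.json").read_text())
        ax.bar([1.0], [spike["spike_count"]], width=0.02, align="center",
               color="#d65f5f", label="exclusive trazodone (p=1)")
        ax.set_xlabel("provider trazodone preference $p_i$")
        ax.set_ylabel("providers")
        ax.legend(fontsize=8)
        fig.tight_layout()
        fig.savefig(out / "preference_histogram.png", dpi=120)
        plt.close(fig)
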