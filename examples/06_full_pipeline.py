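"""Run the whole pipeline from one config and print the run report.

Equivalent to `rxdyn run --config configs/demo.yaml --out <dir>` followed
by `rxdyn report --in <dir>` (here with a smaller cohort so it finishes in
well under a minute).
"""

import tempfile
from pathlib import Path

from rxdyn.pipeline import default_config, report, run_pipeline

cfg = default_config()
cfg["seed"] = 7
cfg["generator"] = {"n_patients": 500, "n_providers": 100,
                    "doc_length_mean": 60.0}
cfg["lda"] = {"n_iterations": 200, "n_burnin": 60, "eta": 0.01}
cfg["model"] = {"k_grid": [0, 5, 10], "n_folds": 10, "threshold": 0.5}

with tempfile.TemporaryDirectory() as out:
    manifest = run_pipeline(cfg, out)
    for stage, info in manifest["stages"].items():
        extras = {k: v for k, v in info.items() if k != "outputs"}
        print(f"stage {stage}: {extras}")
    print()
    print(report(out, make_plots=False))
# The report shows the prescription mix, the exclusive-prescriber spike,
# CV AUC per K, and the odds-ratio table of the chosen model. Rerunning
# with the same config reproduces every CSV/JSON data output byte for byte.
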