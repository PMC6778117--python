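"""Covariate-adjusted models: CVD risk markers and demographic factors.

Fits the marker battery (Marker ~ Age + Gender + Ethnicity + DailySteps +
TST / SE / both) for every CVD marker, plus the TST-on-demographics and
TST-on-socioeconomic/lifestyle-factor models, and tabulates per-term betas,
Wald 95% CIs and raw p-values.
"""

import importlib
from pathlib import Path

from somnocohort import pipeline

step01 = importlib.import_module("01_simulate_cohort")

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"


def main() -> None:
    bundle_dir = step01.ensure_bundle()
    result = pipeline.run_pipeline(bundle_dir)
    assoc = result.associations
    keep = assoc["model_id"].str.startswith(("marker_", "tst_"))
    table = assoc[keep].reset_index(drop=True)
    RESULTS.mkdir(exist_ok=True)
    table.to_csv(RESULTS / "04_marker_associations.csv", index=False)

    sleepy = table[table["term"].isin(["tst_hours", "se_pct"])]
    n_sig = int(sleepy["significant"].sum())
    print(f"{len(table)} model terms fitted; {n_sig}/{len(sleepy)} sleep-metric "
          "terms significant at raw p<0.05 (markers are null by default in the "
          "simulator, so this approximates the false-positive rate)")
    demo = table[table["model_id"] == "tst_demo"]
    print(demo[["term", "beta", "ci_low", "ci_high", "p"]].to_string(index=False))


if __name__ == "__main__":
    main()
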