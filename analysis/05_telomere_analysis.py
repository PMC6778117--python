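"""Sleep and telomere length: qPCR plate processing and adjusted contrasts.

Runs the raw qPCR plates through the standard-curve / triplicate /
normalization / batch-adjustment workflow, corrects WGS LTL for sequencing
run, and fits the LTL models: continuous TST, TST-stratum contrasts
(insufficient <5 h vs adequate >7 h, and the three-level split with long
sleepers >9 h), and the TST x age / TST x gender interactions.
"""

import importlib
from pathlib import Path

import pandas as pd

from somnocohort import pipeline, telomere

step01 = importlib.import_module("01_simulate_cohort")

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"


def main() -> None:
    bundle_dir = step01.ensure_bundle()

    plates = pd.read_csv(bundle_dir / "plates.csv")
    ts = telomere.process_plates(plates)
    n_repeat = int((ts["flag"] == "repeat").sum())

    result = pipeline.run_pipeline(bundle_dir)
    ltl_models = result.associations[
        result.associations["model_id"].str.startswith("ltl_")
    ].reset_index(drop=True)

    RESULTS.mkdir(exist_ok=True)
    ts.to_csv(RESULTS / "05_qpcr_ts_ratios.csv", index=False)
    ltl_models.to_csv(RESULTS / "05_ltl_associations.csv", index=False)

    print(f"qPCR: {len(ts)} samples quantified, {n_repeat} flagged for repeat")
    grp = ltl_models[ltl_models["model_id"] == "ltl_group_binary:ltl_wgs_bp"]
    row = grp[grp["term"].str.contains("insufficient")].iloc[0]
    print(
        "WGS-LTL, adequate (>7 h) vs insufficient (<5 h) sleep: "
        f"{-row['beta']:.0f} bp longer (95% CI {-row['ci_high']:.0f} to "
        f"{-row['ci_low']:.0f}, p = {row['p']:.3f}, n = {row['n']})"
    )
    cont = ltl_models[(ltl_models["model_id"] == "ltl_tst:ltl_wgs_bp")
                      & (ltl_models["term"] == "tst_hours")].iloc[0]
    print(f"WGS-LTL per hour of TST: {cont['beta']:.0f} bp/h (p = {cont['p']:.3f})")


if __name__ == "__main__":
    main()
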