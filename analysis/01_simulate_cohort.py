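"""Generate the default synthetic cohort and write it as a study export.

Produces, under scratch/bundle, per-volunteer wearable JSON (sleep sessions
and tracker days), PSQI responses, phenotypes, LTL values and raw qPCR
plates, plus the ground-truth table; writes a one-row overview to
results/01_cohort_overview.csv.
"""

from pathlib import Path

import pandas as pd

from somnocohort import simulate

ROOT = Path(__file__).resolve().parents[1]
BUNDLE_DIR = ROOT / "scratch" / "bundle"
RESULTS = ROOT / "results"


def ensure_bundle(seed: int = 0) -> Path:
    if not (BUNDLE_DIR / "ground_truth.csv").exists():
        bundle = simulate.generate_cohort(simulate.SimConfig(seed=seed))
        simulate.write_bundle(bundle, BUNDLE_DIR)
    return BUNDLE_DIR


def main() -> None:
    ensure_bundle()
    truth = pd.read_csv(BUNDLE_DIR / "ground_truth.csv")
    overview = pd.DataFrame([{
        "n_volunteers": len(truth),
        "n_included": int(truth["included"].sum()),
        "mean_nights": truth["n_nights"].mean(),
        "mean_true_tst_minutes": truth["true_tst_minutes"].mean(),
        "mean_true_se_pct": truth["true_se_pct"].mean(),
    }])
    RESULTS.mkdir(exist_ok=True)
    overview.to_csv(RESULTS / "01_cohort_overview.csv", index=False)
    print(overview.to_string(index=False))
    print(f"bundle written to {BUNDLE_DIR}")


if __name__ == "__main__":
    main()
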