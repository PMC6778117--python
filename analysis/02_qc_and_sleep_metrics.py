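"""QC the wearable streams and derive per-volunteer sleep metrics.

Applies the completeness filters (>=20 h heart-rate coverage, nonzero steps,
>=3 complete days per volunteer), gates each night on its start day, and
writes the per-volunteer TST / SE / awakenings / sleep-and-wake-hour table.
"""

import importlib
from pathlib import Path

from somnocohort import pipeline

step01 = importlib.import_module("01_simulate_cohort")

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"


def main() -> None:
    bundle_dir = step01.ensure_bundle()
    result = pipeline.run_pipeline(bundle_dir, run_associations=False)
    RESULTS.mkdir(exist_ok=True)
    result.qc_report.to_csv(RESULTS / "02_qc_report.csv", index=False)
    result.sleep_summary.to_csv(RESULTS / "02_sleep_summary.csv", index=False)
    s = result.sleep_summary
    print(f"{int(result.qc_report['included'].sum())}/{len(result.qc_report)} "
          "volunteers pass QC")
    print(f"mean TST {s['tst_hours'].mean():.2f} h, "
          f"mean SE {s['se_pct'].mean():.3f}% (SD {s['se_pct'].std():.3f}), "
          f"mean awakenings {s['awakenings'].mean():.2f}/night")


if __name__ == "__main__":
    main()
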