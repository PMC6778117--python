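"""End-to-end driver: raw streams -> QC -> sleep metrics -> merged cohort
table -> association battery.

This is the path the analysis scripts and the acceptance checks run.  It
consumes either an in-memory :class:`~somnocohort.simulate.CohortBundle` or
a directory written by :func:`~somnocohort.simulate.write_bundle` (the same
layout a real study export would use).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import association, psqi, qc, sleep, telomere
from .ingest import parse_day_log, parse_sleep_log
from .simulate import CohortBundle

__all__ = ["PipelineResult", "load_streams", "run_pipeline"]


@dataclass
class PipelineResult:
    qc_report: pd.DataFrame
    sleep_summary: pd.DataFrame
    psqi_scores: pd.DataFrame
    cohort: pd.DataFrame  # merged per-volunteer analysis table
    associations: pd.DataFrame


def load_streams(source: CohortBundle | str | Path):
    """Raw JSON text per volunteer plus the questionnaire / phenotype / LTL
    tables, from a bundle or a written directory."""
    if isinstance(source, CohortBundle):
        plates = source.plates
        return (source.sleep_json, source.days_json, source.psqi,
                source.phenotypes, source.ltl, plates)
    root = Path(source)
    sleep_json, days_json = {}, {}
    for path in sorted((root / "wearable").glob("*.sleep.json")):
        vid = path.name.removesuffix(".sleep.json")
        sleep_json[vid] = path.read_text()
    for path in sorted((root / "wearable").glob("*.days.json")):
        vid = path.name.removesuffix(".days.json")
        days_json[vid] = path.read_text()
    plates_path = root / "plates.csv"
    plates = pd.read_csv(plates_path) if plates_path.exists() else None
    return (
        sleep_json,
        days_json,
        pd.read_csv(root / "psqi.csv"),
        pd.read_csv(root / "phenotypes.csv"),
        pd.read_csv(root / "ltl.csv"),
        plates,
    )


def _adjusted_ltl(ltl: pd.DataFrame, plates: pd.DataFrame | None) -> pd.DataFrame:
    """Per-volunteer batch-corrected LTL columns.

    WGS estimates are regression-corrected for sequencing run.  qPCR T/S
    comes from the raw plate data when present (standard curves, triplicate
    averaging, control normalization, batch adjustment); otherwise the
    pre-computed T/S values are batch-corrected directly.
    """
    frames = []
    wgs = ltl[ltl["method"] == "wgs"]
    if not wgs.empty:
        adj = telomere.batch_adjust(wgs["ltl_raw"].to_numpy(), wgs["batch"].to_numpy())
        frames.append(pd.DataFrame(
            {"volunteer_id": wgs["volunteer_id"].to_numpy(), "ltl_wgs_bp": adj}
        ))
    qpcr = ltl[ltl["method"] == "qpcr"]
    if plates is not None and not qpcr.empty:
        ts = telomere.process_plates(plates)
        ts = ts[ts["sample_id"].isin(set(qpcr["volunteer_id"]))]
        frames.append(
            ts.rename(columns={"sample_id": "volunteer_id",
                               "ts_ratio_adjusted": "ltl_qpcr_ts"})
            [["volunteer_id", "ltl_qpcr_ts"]]
        )
    elif not qpcr.empty:
        adj = telomere.batch_adjust(qpcr["ltl_raw"].to_numpy(), qpcr["batch"].to_numpy())
        frames.append(pd.DataFrame(
            {"volunteer_id": qpcr["volunteer_id"].to_numpy(), "ltl_qpcr_ts": adj}
        ))
    if not frames:
        return pd.DataFrame({"volunteer_id": []})
    out = frames[0]
    for f in frames[1:]:
        out = out.merge(f, on="volunteer_id", how="outer")
    return out


def run_pipeline(
    source: CohortBundle | str | Path,
    run_associations: bool = True,
) -> PipelineResult:
    """Full analysis over one study export.

    Steps: parse the wearable JSON streams; apply the day-completeness /
    volunteer-inclusion filters; derive per-volunteer sleep metrics over
    QC-retained nights; score the PSQI; batch-correct LTL; merge everything
    on volunteer id (included volunteers only); and, unless disabled, run
    the full association battery on the merged table.
    """
    sleep_json, days_json, psqi_table, phenotypes, ltl, plates = load_streams(source)

    sessions_by_vol = {vid: list(parse_sleep_log(text, vid))
                       for vid, text in sleep_json.items()}
    days_by_vol = {vid: parse_day_log(text, vid) for vid, text in days_json.items()}

    qc_table = qc.qc_cohort(days_by_vol)
    complete_by_vol = {vid: qc.complete_dates(days) for vid, days in days_by_vol.items()}
    included = set(qc_table.loc[qc_table["included"], "volunteer_id"])

    summary = sleep.derive_cohort_summary(
        {vid: s for vid, s in sessions_by_vol.items() if vid in included},
        complete_by_vol,
    )
    scores = psqi.score_table(psqi_table)

    cohort = (
        summary.merge(scores, on="volunteer_id", how="left")
        .merge(phenotypes, on="volunteer_id", how="left")
        .merge(_adjusted_ltl(ltl, plates), on="volunteer_id", how="left")
        .sort_values("volunteer_id")
        .reset_index(drop=True)
    )

    associations_table = (
        association.run_battery(cohort) if run_associations else pd.DataFrame()
    )
    return PipelineResult(
        qc_report=qc_table,
        sleep_summary=summary,
        psqi_scores=scores,
        cohort=cohort,
        associations=associations_table,
    )
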