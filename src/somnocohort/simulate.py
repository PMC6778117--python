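"""Synthetic cohort generator with planted, configurable effects.

Emulates a single-timezone wearable study: each volunteer contributes a
handful of tracked nights (mean 4, range 3-11), a PSQI questionnaire, a
phenotype record of CVD risk markers, and a telomere-length value (WGS-style
base pairs for a subset, qPCR T/S for the rest, optionally as raw plate
data).  The generator writes the same file dialects the ingest modules read,
so every pipeline stage is testable without any download, and exports a
ground-truth table holding the per-volunteer true sleep metrics and every
planted coefficient.

Default parameters are the study conditions: mean nightly sleep 388 min
(6 h 28 min) with near-ceiling sleep efficiency (mean 92.584%, SD 3.060%);
male volunteers sleep 16 min less, alcohol drinkers 19 min more, Malay
volunteers 41 min less and Indian volunteers 32 min more than the Chinese
majority, manual workers 27 min less, private-residence dwellers 15 min
more; telomeres are 356 bp longer for adequate (>7 h) vs insufficient
(<5 h) sleepers and 259 / 432 bp shorter in the 40-60 / 60-80 age groups
relative to 20-40; self-reported sleep overestimates the tracker by 6 min
and is reported on a coarse half-hour grid with enough recall noise to put
its rank correlation with true sleep in the ~0.3 regime.  Marker-on-sleep
slopes default to zero so the marker battery is null-calibrated out of the
box.

Two layers are exposed:

- :func:`simulate_cohort_table` draws the volunteer-level analysis table
  directly (fast; used for Monte-Carlo calibration and recovery loops);
- :func:`generate_cohort` additionally materializes raw wearable JSON,
  per-day tracker logs, PSQI item responses and qPCR plates, exercising the
  full ingest path.

All randomness flows from one seed through per-volunteer ``SeedSequence``
substreams, so adding a volunteer never perturbs the draws of another.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, datetime, time, timedelta
from pathlib import Path

import numpy as np
import pandas as pd

from .ingest import SleepSession, TrackerDay, serialize_days, serialize_sessions

__all__ = ["SimConfig", "CohortBundle", "simulate_cohort_table", "generate_cohort",
           "export_ground_truth", "write_bundle"]

_ETHNICITIES = ("Chinese", "Indian", "Malay", "Others")


@dataclass
class SimConfig:
    """Study conditions for the synthetic cohort.  Units in field names."""

    n_volunteers: int = 482
    seed: int = 0

    # nights per volunteer: nights_min + Poisson(nights_extra_mean), capped
    nights_min: int = 3
    nights_max: int = 11
    nights_extra_mean: float = 1.0

    # nightly sleep
    tst_mean_minutes: float = 388.0
    tst_between_sd: float = 55.0
    tst_within_sd: float = 45.0
    se_mean_pct: float = 92.584
    se_between_sd: float = 3.060
    se_within_sd: float = 1.0
    awakenings_rate: float = 2.0

    # wearable-stream imperfections
    nap_rate: float = 0.10
    missing_day_rate: float = 0.12
    split_rate: float = 0.15

    # self-report model
    selfreport_bias_minutes: float = 6.0
    selfreport_noise_sd_minutes: float = 180.0
    selfreport_rounding_hours: float = 0.5

    # planted effects on volunteer mean TST, minutes
    gender_tst_minutes: float = -16.0  # male vs female
    alcohol_tst_minutes: float = 19.0
    malay_tst_minutes: float = -41.0
    indian_tst_minutes: float = 32.0
    manual_occupation_tst_minutes: float = -27.0
    private_residence_tst_minutes: float = 15.0
    age_tst_minutes_per_year: float = 0.0

    # planted telomere effects, base pairs
    ltl_base_bp: float = 250.0
    ltl_sleepgroup_bp: float = 356.0  # adequate (>7 h) vs insufficient (<5 h)
    ltl_age_40_60_bp: float = -259.0
    ltl_age_60_80_bp: float = -432.0
    ltl_resid_sd_bp: float = 330.0
    ts_base: float = 1.0  # qPCR T/S corresponding to 0 bp offset
    ts_per_bp: float = 7.1e-4

    # marker ~ TST slopes (per hour); empty = null cohort
    marker_tst_slopes: dict = field(default_factory=dict)
    # False draws every marker from the pooled (female) distribution, making
    # all marker-model terms null — used for type-I calibration
    marker_gender_difference: bool = True

    # demographics
    female_prop: float = 0.5436
    ethnicity_props: tuple = (0.911, 0.035, 0.033, 0.021)  # Chinese/Indian/Malay/Others
    age_range: tuple = (21, 69)
    alcohol_prop: float = 0.33
    manual_occupation_prop: float = 0.15
    private_residence_prop: float = 0.25
    n_wgs: int | None = None  # WGS-LTL subset size; None = 175/482 of cohort
    n_sequencing_runs: int = 3
    wgs_run_shift_bp: float = 150.0  # planted between-run shift, removed downstream
    qpcr_batch_shift: float = 2.0  # planted conc shift on batch 2 sample wells
    make_plates: bool = True

    def __post_init__(self) -> None:
        for name in ("nap_rate", "missing_day_rate", "split_rate", "female_prop",
                     "alcohol_prop", "manual_occupation_prop", "private_residence_prop"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        for name in ("tst_between_sd", "tst_within_sd", "se_between_sd", "se_within_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if abs(sum(self.ethnicity_props) - 1.0) > 1e-9:
            raise ValueError("ethnicity_props must sum to 1")
        if not self.nights_min <= self.nights_max:
            raise ValueError("nights_min must be <= nights_max")


@dataclass
class CohortBundle:
    """In-memory synthetic study: raw streams, tables and ground truth."""

    config: SimConfig
    sleep_json: dict  # volunteer_id -> JSON text
    days_json: dict  # volunteer_id -> JSON text
    psqi: pd.DataFrame
    phenotypes: pd.DataFrame
    ltl: pd.DataFrame
    plates: pd.DataFrame | None
    ground_truth: pd.DataFrame


# ---------------------------------------------------------------------------
# demographics and volunteer-level truth


def _tst_effect_offset(cfg: SimConfig) -> float:
    """Expected planted-effect contribution, subtracted so the cohort mean
    TST stays at ``tst_mean_minutes`` by construction."""
    p_chinese, p_indian, p_malay, _ = cfg.ethnicity_props
    mean_age = (cfg.age_range[0] + cfg.age_range[1]) / 2.0
    return (
        (1 - cfg.female_prop) * cfg.gender_tst_minutes
        + cfg.alcohol_prop * cfg.alcohol_tst_minutes
        + p_malay * cfg.malay_tst_minutes
        + p_indian * cfg.indian_tst_minutes
        + cfg.manual_occupation_prop * cfg.manual_occupation_tst_minutes
        + cfg.private_residence_prop * cfg.private_residence_tst_minutes
        + cfg.age_tst_minutes_per_year * mean_age
    )


def _draw_volunteer(cfg: SimConfig, rng: np.random.Generator) -> dict:
    gender = "Female" if rng.random() < cfg.female_prop else "Male"
    ethnicity = _ETHNICITIES[rng.choice(4, p=np.asarray(cfg.ethnicity_props))]
    age = int(rng.integers(cfg.age_range[0], cfg.age_range[1] + 1))
    alcohol = "Yes" if rng.random() < cfg.alcohol_prop else "No"
    occupation = (
        "Manual-labor"
        if rng.random() < cfg.manual_occupation_prop
        else str(rng.choice(["Service", "Office", "Unemployed-retired"]))
    )
    residence = "Private" if rng.random() < cfg.private_residence_prop else "Public-housing"
    mu_tst = (
        cfg.tst_mean_minutes
        - _tst_effect_offset(cfg)
        + (cfg.gender_tst_minutes if gender == "Male" else 0.0)
        + (cfg.alcohol_tst_minutes if alcohol == "Yes" else 0.0)
        + (cfg.malay_tst_minutes if ethnicity == "Malay" else 0.0)
        + (cfg.indian_tst_minutes if ethnicity == "Indian" else 0.0)
        + (cfg.manual_occupation_tst_minutes if occupation == "Manual-labor" else 0.0)
        + (cfg.private_residence_tst_minutes if residence == "Private" else 0.0)
        + cfg.age_tst_minutes_per_year * age
        + rng.normal(0.0, cfg.tst_between_sd)
    )
    mu_se = float(np.clip(rng.normal(cfg.se_mean_pct, cfg.se_between_sd), 60.0, 99.5))
    n_nights = cfg.nights_min + int(
        min(rng.poisson(cfg.nights_extra_mean), cfg.nights_max - cfg.nights_min)
    )
    return {
        "gender": gender,
        "ethnicity": ethnicity,
        "age": age,
        "alcohol": alcohol,
        "occupation": occupation,
        "residence_type": residence,
        "mu_tst": max(mu_tst, 120.0),
        "mu_se": mu_se,
        "n_nights": n_nights,
    }


def _plant_ltl(cfg: SimConfig, tst_hours: float, age: int,
               rng: np.random.Generator) -> float:
    """True LTL (bp) from the planted age-group and sleep-group effects.

    The sleep effect is 0 for adequate sleepers (>7 h, the reference),
    -ltl_sleepgroup_bp for insufficient (<5 h) and linearly interpolated
    in between, so the insufficient-vs-adequate contrast equals the planted
    magnitude exactly while the excluded 5-7 h middle stays plausible.
    """
    ltl = cfg.ltl_base_bp
    if 40 <= age < 60:
        ltl += cfg.ltl_age_40_60_bp
    elif age >= 60:
        ltl += cfg.ltl_age_60_80_bp
    if tst_hours < 5:
        ltl -= cfg.ltl_sleepgroup_bp
    elif tst_hours <= 7:
        ltl -= cfg.ltl_sleepgroup_bp * (7 - tst_hours) / 2.0
    return float(ltl + rng.normal(0.0, cfg.ltl_resid_sd_bp))


def _selfreport_hours(cfg: SimConfig, true_tst_minutes: float,
                      rng: np.random.Generator) -> float:
    raw = (
        true_tst_minutes
        + cfg.selfreport_bias_minutes
        + rng.normal(0.0, cfg.selfreport_noise_sd_minutes)
    ) / 60.0
    step = cfg.selfreport_rounding_hours
    if step > 0:
        raw = round(raw / step) * step
    # clip limits near-symmetric about the cohort mean so the planted bias
    # survives truncation of the recall-noise tails
    return float(np.clip(raw, 1.0, 12.0))


_MARKER_DISTS = {
    # marker: (female mean, female SD, male mean, male SD) from the cohort
    # summary table
    "bmi": (22.83, 3.80, 24.27, 3.06),
    "wc": (79.01, 11.08, 86.82, 9.36),
    "whtr": (0.50, 0.07, 0.51, 0.05),
    "bfp": (33.16, 7.65, 23.64, 6.48),
    "smp": (35.49, 4.40, 42.57, 4.25),
    "sbp": (122.54, 17.53, 132.06, 15.04),
    "dbp": (73.82, 12.85, 82.40, 10.88),
    "total_chol": (5.38, 0.93, 5.39, 0.97),
    "ldl": (3.34, 0.81, 3.45, 0.91),
    "hdl": (1.58, 0.32, 1.36, 0.32),
    "tg": (1.02, 0.54, 1.33, 0.80),
    "fbg": (5.18, 0.50, 5.39, 0.73),
    "resting_hr": (69.79, 6.37, 68.23, 6.48),
}


def _draw_markers(cfg: SimConfig, gender: str, tst_hours: float,
                  rng: np.random.Generator) -> dict:
    out = {}
    for marker, (f_mean, f_sd, m_mean, m_sd) in _MARKER_DISTS.items():
        use_female = gender == "Female" or not cfg.marker_gender_difference
        mean, sd = (f_mean, f_sd) if use_female else (m_mean, m_sd)
        slope = cfg.marker_tst_slopes.get(marker, 0.0)
        out[marker] = float(
            mean + slope * (tst_hours - cfg.tst_mean_minutes / 60.0)
            + rng.normal(0.0, sd)
        )
    return out


def _draw_steps(gender: str, rng: np.random.Generator) -> float:
    mean, sd = (10349.6, 3466.2) if gender == "Female" else (11061.1, 3818.6)
    return float(max(rng.normal(mean, sd), 500.0))


# ---------------------------------------------------------------------------
# fast volunteer-level table (no raw streams)


def simulate_cohort_table(cfg: SimConfig) -> pd.DataFrame:
    """Volunteer-level analysis table drawn directly (no JSON round trip).

    Observed TST/SE are the volunteer's nightly-mean draws; LTL carries the
    planted age-group and sleep-group effects keyed to the *observed* TST
    stratum, markers the configured TST slopes (default null).  Used for
    Monte-Carlo calibration and coverage experiments where generating raw
    streams would only add runtime.
    """
    streams = np.random.SeedSequence(cfg.seed).spawn(cfg.n_volunteers)
    rows = []
    for i, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        v = _draw_volunteer(cfg, rng)
        n = v["n_nights"]
        tst_minutes = v["mu_tst"] + rng.normal(0.0, cfg.tst_within_sd / np.sqrt(n))
        tst_hours = max(tst_minutes, 60.0) / 60.0
        se_pct = float(
            np.clip(v["mu_se"] + rng.normal(0.0, cfg.se_within_sd / np.sqrt(n)),
                    40.0, 100.0)
        )
        awakenings = float(rng.poisson(cfg.awakenings_rate * n)) / n
        row = {
            "volunteer_id": f"V{i:04d}",
            "age": v["age"],
            "gender": v["gender"],
            "ethnicity": v["ethnicity"],
            "alcohol": v["alcohol"],
            "occupation": v["occupation"],
            "residence_type": v["residence_type"],
            "n_nights": n,
            "tst_hours": tst_hours,
            "se_pct": se_pct,
            "awakenings": awakenings,
            "avg_daily_steps": _draw_steps(v["gender"], rng),
            "selfreport_tst_hours": _selfreport_hours(cfg, tst_minutes, rng),
            "true_tst_minutes": tst_minutes,
        }
        row.update(_draw_markers(cfg, v["gender"], tst_hours, rng))
        ltl_bp = _plant_ltl(cfg, tst_hours, v["age"], rng)
        row["ltl_wgs_bp"] = ltl_bp
        row["ltl_qpcr_ts"] = cfg.ts_base + cfg.ts_per_bp * ltl_bp
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# full bundle with raw streams


def _round_quarter_hour(t: datetime) -> time:
    minutes = (t.hour * 60 + t.minute + 7) // 15 * 15 % 1440
    return time(minutes // 60, minutes % 60)


def _make_night_sessions(
    vid: str,
    night: date,
    tst_min: int,
    se_target: float,
    wakes: int,
    start_offset_min: int,
    split: bool,
    rng: np.random.Generator,
) -> list[SleepSession]:
    """Sessions for one night; total sleep minutes equals ``tst_min``."""
    start = datetime.combine(night, time(20, 0)) + timedelta(minutes=start_offset_min)
    window_close = datetime.combine(night + timedelta(days=1), time(8, 0))

    def bed_minutes(asleep: int) -> int:
        return max(int(round(asleep * 100.0 / se_target)), asleep)

    if split and tst_min >= 120:
        first = int(tst_min * rng.uniform(0.3, 0.7))
        second = tst_min - first
        gap = int(rng.integers(15, 61))
        s1_bed = bed_minutes(first)
        s2_start = start + timedelta(minutes=s1_bed + gap)
        s2_bed = bed_minutes(second)
        # both sessions must start inside the night window and stay plausible
        if s2_start < window_close and first >= 30 and second >= 30:
            w1 = int(rng.integers(0, wakes + 1))
            return [
                SleepSession(vid, start, start + timedelta(minutes=s1_bed),
                             first, s1_bed, w1),
                SleepSession(vid, s2_start, s2_start + timedelta(minutes=s2_bed),
                             second, s2_bed, wakes - w1),
            ]
    bed = bed_minutes(tst_min)
    return [SleepSession(vid, start, start + timedelta(minutes=bed), tst_min, bed, wakes)]


def _make_nap(vid: str, day: date, rng: np.random.Generator) -> SleepSession:
    start = datetime.combine(day, time(13, 0)) + timedelta(
        minutes=int(rng.integers(0, 180))
    )
    asleep = int(rng.integers(20, 91))
    bed = int(round(asleep * 100.0 / 95.0))
    return SleepSession(vid, start, start + timedelta(minutes=bed), asleep, bed, 0)


def _psqi_items(cfg: SimConfig, reported_hours: float, bed_clock: time,
                awakenings: float, rng: np.random.Generator) -> dict:
    tib_hours = min(reported_hours + float(rng.uniform(0.25, 1.5)), 14.0)
    bed_minutes = bed_clock.hour * 60 + bed_clock.minute
    rise_minutes = int(bed_minutes + round(tib_hours * 60)) % 1440
    item5b = int(np.clip(round(awakenings / 1.5 + rng.normal(0, 0.8)), 0, 3))
    skew = [0.55, 0.25, 0.13, 0.07]  # most volunteers report few disturbances
    items = {f"item5{c}": int(rng.choice(4, p=skew)) for c in "acdefghij"}
    return {
        "bed_time": f"{bed_clock.hour:02d}:{bed_clock.minute:02d}",
        "rise_time": f"{rise_minutes // 60:02d}:{rise_minutes % 60:02d}",
        "sleep_latency_minutes": float(round(min(rng.lognormal(2.6, 0.6), 120.0))),
        "sleep_hours": reported_hours,
        "item5b": item5b,
        **items,
        "item6_quality": int(rng.choice(4, p=[0.45, 0.40, 0.12, 0.03])),
        "item7_medication": int(rng.choice(4, p=[0.88, 0.06, 0.04, 0.02])),
        "item8_sleepiness": int(rng.choice(4, p=[0.55, 0.30, 0.10, 0.05])),
        "item9_enthusiasm": int(rng.choice(4, p=[0.60, 0.25, 0.10, 0.05])),
    }


def _simulate_plates(cfg: SimConfig, qpcr_truth: pd.DataFrame,
                     rng: np.random.Generator) -> pd.DataFrame:
    """Raw qPCR wells consistent with the target T/S values.

    One T plate and one S plate per batch, identical well layout: the
    five-point threefold standard series, the inter-plate control and each
    sample in triplicate.  Sample wells of the second batch carry a planted
    additive concentration shift (the effect batch adjustment removes);
    sample+control wells carry a per-plate Cq offset (the effect the control
    normalization removes).
    """
    curves = {"T": (-3.322, 18.0), "S": (-3.322, 24.0)}  # slope, intercept
    cq_sd = 0.05
    input_conc = 35.0  # ng/uL, the normalized DNA input
    rows = []
    batches = sorted(qpcr_truth["batch"].unique())
    for batch_i, batch in enumerate(batches):
        members = qpcr_truth[qpcr_truth["batch"] == batch]
        for assay in ("T", "S"):
            slope, intercept = curves[assay]
            plate_id = f"{assay}-{batch}"
            plate_cq_offset = float(rng.normal(0.0, 0.15))
            shift = cfg.qpcr_batch_shift * batch_i if assay == "T" else \
                cfg.qpcr_batch_shift * batch_i / 2.0

            def cq_of(conc: float, offset: float = 0.0) -> float:
                return slope * np.log10(conc) + intercept + offset + rng.normal(0, cq_sd)

            for conc in (109.0, 36.3, 12.1, 4.0, 1.3):
                for _ in range(3):
                    rows.append(dict(plate_id=plate_id, assay=assay,
                                     sample_id=f"std{conc}", role="standard",
                                     cq=cq_of(conc), conc=conc, batch=batch))
            for _ in range(3):
                rows.append(dict(plate_id=plate_id, assay=assay,
                                 sample_id="control", role="control",
                                 cq=cq_of(input_conc, plate_cq_offset),
                                 conc=np.nan, batch=batch))
            for _, s in members.iterrows():
                conc = input_conc * s["true_ts"] if assay == "T" else input_conc
                conc = max(conc + shift, 0.5)
                for _ in range(3):
                    rows.append(dict(plate_id=plate_id, assay=assay,
                                     sample_id=s["volunteer_id"], role="sample",
                                     cq=cq_of(conc, plate_cq_offset),
                                     conc=np.nan, batch=batch))
    return pd.DataFrame(rows)


def generate_cohort(cfg: SimConfig) -> CohortBundle:
    """Materialize the full synthetic study from one seed.

    Per volunteer: consecutive tracked nights written as wearable-dialect
    sleep JSON (some nights split into two sessions, naps injected at
    ``nap_rate``), a day log whose completeness pattern drives QC (days are
    incomplete at ``missing_day_rate``), PSQI responses derived from the
    biased/rounded self-report model, a phenotype record and an LTL value.
    Ground truth records, per volunteer, the true sleep metrics over
    QC-retained nights and the inclusion status the pipeline should find.
    """
    streams = np.random.SeedSequence(cfg.seed).spawn(cfg.n_volunteers + 1)
    plate_rng = np.random.default_rng(streams[-1])
    sleep_json: dict[str, str] = {}
    days_json: dict[str, str] = {}
    psqi_rows, pheno_rows, truth_rows = [], [], []
    start_monday = date(2016, 1, 4)

    for i, ss in enumerate(streams[: cfg.n_volunteers]):
        rng = np.random.default_rng(ss)
        vid = f"V{i:04d}"
        v = _draw_volunteer(cfg, rng)
        first_night = start_monday + timedelta(days=int(rng.integers(0, 90)))

        sessions: list[SleepSession] = []
        days: list[TrackerDay] = []
        nightly: list[dict] = []
        habitual_offset = int(np.clip(rng.normal(195, 50), 30, 420))  # ~23:15
        for k in range(v["n_nights"]):
            night = first_night + timedelta(days=k)
            tst = int(np.clip(round(v["mu_tst"] + rng.normal(0, cfg.tst_within_sd)),
                              60, 700))
            se_target = float(np.clip(v["mu_se"] + rng.normal(0, cfg.se_within_sd),
                                      50.0, 100.0))
            wakes = int(rng.poisson(cfg.awakenings_rate))
            offset = int(np.clip(habitual_offset + rng.normal(0, 30), 5, 700))
            night_sessions = _make_night_sessions(
                vid, night, tst, se_target, wakes, offset,
                rng.random() < cfg.split_rate, rng,
            )
            sessions.extend(night_sessions)
            complete = rng.random() >= cfg.missing_day_rate
            if complete:
                coverage = float(rng.uniform(20.0, 24.0))
                steps = int(max(rng.normal(10700, 3500), 1000))
            elif rng.random() < 0.5:
                coverage = float(rng.uniform(2.0, 19.9))
                steps = int(max(rng.normal(8000, 3000), 500))
            else:
                coverage = float(rng.uniform(20.0, 24.0))
                steps = 0
            days.append(TrackerDay(vid, night, coverage, steps))
            if rng.random() < cfg.nap_rate:
                sessions.append(_make_nap(vid, night, rng))
            nightly.append(
                {
                    "night": night,
                    "complete": complete,
                    "tst": float(sum(s.minutes_asleep for s in night_sessions)),
                    "se": sum(s.efficiency_pct for s in night_sessions)
                    / len(night_sessions),
                    "awakenings": float(sum(s.wake_count for s in night_sessions)),
                }
            )

        sleep_json[vid] = serialize_sessions(sorted(sessions, key=lambda s: s.start))
        days_json[vid] = serialize_days(days)

        retained = [nt for nt in nightly if nt["complete"]]
        included = len(retained) >= 3
        if retained:
            true_tst = float(np.mean([nt["tst"] for nt in retained]))
            true_se = float(np.mean([nt["se"] for nt in retained]))
            true_awk = float(np.mean([nt["awakenings"] for nt in retained]))
        else:
            true_tst = true_se = true_awk = np.nan

        reported = _selfreport_hours(cfg, true_tst if retained else v["mu_tst"], rng)
        bed_clock = _round_quarter_hour(
            datetime.combine(first_night, time(20, 0))
            + timedelta(minutes=habitual_offset)
        )
        psqi_rows.append(
            {"volunteer_id": vid,
             **_psqi_items(cfg, reported, bed_clock, true_awk if retained else 2.0, rng)}
        )

        tst_hours = (true_tst if retained else v["mu_tst"]) / 60.0
        pheno = {
            "volunteer_id": vid,
            "age": v["age"],
            "gender": v["gender"],
            "ethnicity": v["ethnicity"],
            "alcohol": v["alcohol"],
            "occupation": v["occupation"],
            "residence_type": v["residence_type"],
            "avg_daily_steps": _draw_steps(v["gender"], rng),
        }
        pheno.update(_draw_markers(cfg, v["gender"], tst_hours, rng))
        pheno_rows.append(pheno)

        truth_rows.append(
            {
                "volunteer_id": vid,
                "age": v["age"],
                "gender": v["gender"],
                "ethnicity": v["ethnicity"],
                "alcohol": v["alcohol"],
                "occupation": v["occupation"],
                "residence_type": v["residence_type"],
                "n_nights": v["n_nights"],
                "n_complete_days": len(retained),
                "included": included,
                "true_tst_minutes": true_tst,
                "true_se_pct": true_se,
                "true_awakenings": true_awk,
                "true_ltl_bp": _plant_ltl(cfg, tst_hours, v["age"], rng),
            }
        )

    truth = pd.DataFrame(truth_rows)

    # LTL assay assignment: a WGS subset with sequencing-run labels (and a
    # planted between-run shift), qPCR T/S for the remainder in two batches
    order = np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(
        cfg.n_volunteers + 2)[-1]).permutation(cfg.n_volunteers)
    n_wgs = cfg.n_wgs if cfg.n_wgs is not None else round(cfg.n_volunteers * 175 / 482)
    n_wgs = min(n_wgs, cfg.n_volunteers)
    wgs_ids = set(truth["volunteer_id"].iloc[order[:n_wgs]])
    ltl_rows = []
    qpcr_truth_rows = []
    for _, r in truth.iterrows():
        vid = r["volunteer_id"]
        if vid in wgs_ids:
            run_idx = int(plate_rng.integers(0, cfg.n_sequencing_runs))
            ltl_rows.append(
                {
                    "volunteer_id": vid,
                    "method": "wgs",
                    "ltl_raw": r["true_ltl_bp"] + cfg.wgs_run_shift_bp * run_idx,
                    "batch": f"run{run_idx + 1}",
                }
            )
        else:
            batch = "batch1" if plate_rng.random() < 0.5 else "batch2"
            ts = cfg.ts_base + cfg.ts_per_bp * r["true_ltl_bp"]
            ltl_rows.append(
                {"volunteer_id": vid, "method": "qpcr",
                 "ltl_raw": max(ts, 0.05), "batch": batch}
            )
            qpcr_truth_rows.append(
                {"volunteer_id": vid, "true_ts": max(ts, 0.05), "batch": batch}
            )
    ltl = pd.DataFrame(ltl_rows)
    plates = (
        _simulate_plates(cfg, pd.DataFrame(qpcr_truth_rows), plate_rng)
        if cfg.make_plates and qpcr_truth_rows
        else None
    )

    return CohortBundle(
        config=cfg,
        sleep_json=sleep_json,
        days_json=days_json,
        psqi=pd.DataFrame(psqi_rows),
        phenotypes=pd.DataFrame(pheno_rows),
        ltl=ltl,
        plates=plates,
        ground_truth=truth,
    )


def export_ground_truth(bundle: CohortBundle) -> pd.DataFrame:
    """Ground-truth table plus one row of planted coefficients (echoed from
    the config) appended as frame attrs for machine-readable assertions."""
    truth = bundle.ground_truth.copy()
    cfg = bundle.config
    truth.attrs["planted"] = {
        "gender_tst_minutes": cfg.gender_tst_minutes,
        "alcohol_tst_minutes": cfg.alcohol_tst_minutes,
        "malay_tst_minutes": cfg.malay_tst_minutes,
        "indian_tst_minutes": cfg.indian_tst_minutes,
        "manual_occupation_tst_minutes": cfg.manual_occupation_tst_minutes,
        "ltl_sleepgroup_bp": cfg.ltl_sleepgroup_bp,
        "ltl_age_40_60_bp": cfg.ltl_age_40_60_bp,
        "ltl_age_60_80_bp": cfg.ltl_age_60_80_bp,
        "selfreport_bias_minutes": cfg.selfreport_bias_minutes,
    }
    return truth


def write_bundle(bundle: CohortBundle, out_dir: str | Path) -> Path:
    """Write the bundle in the file dialects the ingest modules read."""
    out = Path(out_dir)
    (out / "wearable").mkdir(parents=True, exist_ok=True)
    for vid, text in bundle.sleep_json.items():
        (out / "wearable" / f"{vid}.sleep.json").write_text(text)
    for vid, text in bundle.days_json.items():
        (out / "wearable" / f"{vid}.days.json").write_text(text)
    bundle.psqi.to_csv(out / "psqi.csv", index=False)
    bundle.phenotypes.to_csv(out / "phenotypes.csv", index=False)
    bundle.ltl.to_csv(out / "ltl.csv", index=False)
    if bundle.plates is not None:
        bundle.plates.to_csv(out / "plates.csv", index=False)
    bundle.ground_truth.to_csv(out / "ground_truth.csv", index=False)
    return out
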