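"""qPCR standard curve, T/S arithmetic, normalization and batch adjustment."""

import numpy as np
import pandas as pd
import pytest

from somnocohort.telomere import (
    DEFAULT_STANDARD_CONCS,
    batch_adjust,
    compute_ts,
    fit_standard_curve,
    process_plates,
)

IDEAL_SLOPE = -1.0 / np.log10(2.0)  # -3.3219: perfect doubling per cycle


def _ideal_curve(intercept=30.0):
    return fit_standard_curve(
        [(c, IDEAL_SLOPE * np.log10(c) + intercept) for c in DEFAULT_STANDARD_CONCS]
    )


class TestStandardCurve:
    def test_ideal_doubling_efficiency_one(self):
        curve = _ideal_curve()
        assert curve.efficiency == pytest.approx(1.0, abs=1e-9)
        assert curve.r_squared == pytest.approx(1.0)

    def test_two_points_rejected(self):
        with pytest.raises(ValueError, match="3 distinct"):
            fit_standard_curve([(10.0, 25.0), (1.0, 28.3)])

    def test_noiseless_interpolation_identity(self):
        curve = _ideal_curve()
        cqs = [IDEAL_SLOPE * np.log10(c) + 30.0 for c in DEFAULT_STANDARD_CONCS]
        np.testing.assert_allclose(
            curve.interpolate(cqs), DEFAULT_STANDARD_CONCS, rtol=1e-9
        )


class TestComputeTS:
    def test_identical_concentrations_give_unit_ratio(self):
        t_curve, s_curve = _ideal_curve(18.0), _ideal_curve(24.0)
        t_cq = IDEAL_SLOPE * np.log10(35.0) + 18.0
        s_cq = IDEAL_SLOPE * np.log10(35.0) + 24.0
        res = compute_ts("s1", [t_cq] * 3, [s_cq] * 3, t_curve, s_curve)
        assert res.ts_ratio == pytest.approx(1.0, rel=1e-9)
        assert res.flag == "ok"

    def test_one_cycle_earlier_doubles_ratio(self):
        """At efficiency 1, shifting every T well one cycle earlier doubles
        the interpolated T concentration, hence the ratio."""
        t_curve, s_curve = _ideal_curve(18.0), _ideal_curve(24.0)
        t_cq = IDEAL_SLOPE * np.log10(35.0) + 18.0
        s_cq = IDEAL_SLOPE * np.log10(35.0) + 24.0
        base = compute_ts("s1", [t_cq] * 3, [s_cq] * 3, t_curve, s_curve)
        shifted = compute_ts("s1", [t_cq - 1] * 3, [s_cq] * 3, t_curve, s_curve)
        assert shifted.ts_ratio == pytest.approx(2.0 * base.ts_ratio, rel=1e-9)

    def test_outlier_well_dropped(self):
        t_curve, s_curve = _ideal_curve(18.0), _ideal_curve(24.0)
        t_cq = IDEAL_SLOPE * np.log10(35.0) + 18.0
        s_cq = IDEAL_SLOPE * np.log10(35.0) + 24.0
        res = compute_ts("s1", [t_cq, t_cq, t_cq + 2.0], [s_cq] * 3, t_curve, s_curve)
        assert res.ts_ratio == pytest.approx(1.0, rel=1e-6)  # outlier removed
        assert res.flag == "ok"


def _wells(ts_by_sample, control_cq_offsets=(0.0, 0.0), batches=None):
    """Two-plate (T, S) well table with ideal chemistry and no noise."""
    rows = []
    curves = {"T": 18.0, "S": 24.0}
    batches = batches or {sid: "b1" for sid in ts_by_sample}
    for assay, intercept in curves.items():
        plate = f"{assay}-plate"
        offset = control_cq_offsets[0] if assay == "T" else control_cq_offsets[1]
        for conc in DEFAULT_STANDARD_CONCS:
            for _ in range(3):
                rows.append(dict(plate_id=plate, assay=assay, sample_id=f"std{conc}",
                                 role="standard",
                                 cq=IDEAL_SLOPE * np.log10(conc) + intercept,
                                 conc=conc, batch="b1"))
        for _ in range(3):
            rows.append(dict(plate_id=plate, assay=assay, sample_id="control",
                             role="control",
                             cq=IDEAL_SLOPE * np.log10(35.0) + intercept + offset,
                             conc=np.nan, batch="b1"))
        for sid, ts in ts_by_sample.items():
            conc = 35.0 * ts if assay == "T" else 35.0
            for _ in range(3):
                rows.append(dict(plate_id=plate, assay=assay, sample_id=sid,
                                 role="sample",
                                 cq=IDEAL_SLOPE * np.log10(conc) + intercept + offset,
                                 conc=np.nan, batch=batches[sid]))
    return pd.DataFrame(rows)


class TestProcessPlates:
    def test_recovers_planted_ratios(self):
        out = process_plates(_wells({"a": 0.8, "b": 1.3}))
        got = out.set_index("sample_id")["ts_ratio"]
        assert got["a"] == pytest.approx(0.8, rel=1e-9)
        assert got["b"] == pytest.approx(1.3, rel=1e-9)

    def test_control_normalization_rescales_plate(self):
        """A plate whose control reads 10% high has its samples scaled back
        by 1/1.1 (here: shifting the T plate's sample+control wells)."""
        shift = IDEAL_SLOPE * np.log10(1.1)  # Cq shift making concs 10% high
        base = process_plates(_wells({"a": 1.0}))
        shifted = process_plates(_wells({"a": 1.0}, control_cq_offsets=(shift, 0.0)))
        assert shifted["ts_ratio"].iloc[0] == pytest.approx(
            base["ts_ratio"].iloc[0], rel=1e-9
        )

    def test_scale_equivariance(self):
        """Multiplying one plate's concentrations by any constant leaves
        every T/S ratio unchanged after normalization."""
        for factor in (0.5, 2.0, 3.7):
            shift = IDEAL_SLOPE * np.log10(factor)
            out = process_plates(
                _wells({"a": 0.9, "b": 1.2}, control_cq_offsets=(0.0, shift))
            )
            got = out.set_index("sample_id")["ts_ratio"]
            assert got["a"] == pytest.approx(0.9, rel=1e-9)
            assert got["b"] == pytest.approx(1.2, rel=1e-9)

    def test_missing_control_rejected(self):
        wells = _wells({"a": 1.0})
        with pytest.raises(ValueError, match="control"):
            process_plates(wells[wells["role"] != "control"])

    def test_unbiased_under_cq_noise(self):
        """Recovered ratios are unbiased: mean relative error < 1% over 200
        simulated samples at Cq noise sigma = 0.1 on the sample wells.

        (Noise on the shared control/standard wells moves a whole plate's
        calibration together, which cannot average out within one plate pair;
        unbiasedness is a property of the per-sample arithmetic.)
        """
        rng = np.random.default_rng(8)
        true_ts = rng.uniform(0.6, 1.6, 200)
        samples = {f"s{i}": ts for i, ts in enumerate(true_ts)}
        noisy = _wells(samples)
        is_sample = noisy["role"] == "sample"
        noisy.loc[is_sample, "cq"] += rng.normal(0, 0.1, int(is_sample.sum()))
        out = process_plates(noisy).set_index("sample_id")
        rel_err = (out.loc[list(samples), "ts_ratio"].to_numpy() - true_ts) / true_ts
        assert abs(rel_err.mean()) < 0.01


class TestBatchAdjust:
    def test_batch_means_map_to_grand_mean(self):
        values = np.array([9.0, 11.0, 11.0, 13.0])  # batch means 10 and 12
        adj = batch_adjust(values, ["a", "a", "b", "b"])
        assert adj[:2].mean() == pytest.approx(11.0)
        assert adj[2:].mean() == pytest.approx(11.0)
        assert adj.mean() == pytest.approx(values.mean())

    def test_single_batch_is_identity_with_warning(self):
        values = np.arange(5.0)
        with pytest.warns(UserWarning, match="single batch"):
            adj = batch_adjust(values, ["a"] * 5)
        np.testing.assert_array_equal(adj, values)

    def test_planted_shift_removed_exactly(self):
        rng = np.random.default_rng(9)
        base = rng.normal(1000.0, 50.0, 120)
        batch = np.repeat(["run1", "run2", "run3"], 40)
        shifted = base + np.where(batch == "run2", 250.0, 0.0)
        adj = batch_adjust(shifted, batch)
        means = pd.Series(adj).groupby(batch).mean()
        assert means.max() - means.min() < 1e-9
        assert adj.mean() == pytest.approx(shifted.mean())
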