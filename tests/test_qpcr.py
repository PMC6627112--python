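"""qPCR processing chain: 2^-dCt, QC filtering, duplicates, calibration."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from crcmark.config import CohortConfig, MarkerSpec
from crcmark.errors import CalibrationError
from crcmark.qpcr import (
    QC_HIGH_CT,
    QC_NO_AMPLIFICATION,
    QC_OK,
    QC_REPEAT_REQUIRED,
    apply_reliability_filter,
    compute_relative_level,
    fit_run_calibration,
    marker_qc_summary,
    process_table,
    reconcile_duplicates,
)
from crcmark.synthetic import generate_cohort, generate_ct_table


@pytest.mark.parametrize(
    "ct_target, ct_norm, expected",
    [(30.0, 30.0, 1.0), (31.0, 30.0, 0.5), (30.0, 33.0, 8.0)],
)
def test_relative_level_examples(ct_target, ct_norm, expected):
    assert compute_relative_level(ct_target, ct_norm) == pytest.approx(expected)


def test_relative_level_absent_ct_signals_no_amplification():
    with pytest.raises(ValueError):
        compute_relative_level(math.nan, 30.0)


@given(
    ct=st.floats(10, 40),
    norm=st.floats(10, 40),
    shift=st.floats(-5, 5),
)
def test_normalization_equivariance_under_constant_shift(ct, norm, shift):
    """Adding a constant to target and normalizer Ct leaves the level unchanged."""
    a = compute_relative_level(ct, norm)
    b = compute_relative_level(ct + shift, norm + shift)
    assert a == pytest.approx(b, rel=1e-9)


@given(ct=st.floats(10, 39), norm=st.floats(10, 40), dq=st.floats(0.01, 5))
def test_level_strictly_decreasing_in_target_ct(ct, norm, dq):
    assert compute_relative_level(ct + dq, norm) < compute_relative_level(ct, norm)


@pytest.mark.parametrize(
    "r1, r2, expected",
    [
        (36.2, 36.5, QC_HIGH_CT),
        (math.nan, math.nan, QC_NO_AMPLIFICATION),
        (28.0, 28.3, QC_OK),
        (35.0, 35.0, QC_OK),  # threshold is strict: Ct == 35 kept
    ],
)
def test_reliability_filter(r1, r2, expected):
    assert apply_reliability_filter(r1, r2) == expected


@pytest.mark.parametrize(
    "r1, r2, tol, ct, flag",
    [
        (30.0, 30.2, 0.5, 30.1, QC_OK),
        (30.0, 31.5, 0.5, math.nan, QC_REPEAT_REQUIRED),
        (30.0, math.nan, 0.5, 30.0, QC_OK),
        (math.nan, math.nan, 0.5, math.nan, QC_NO_AMPLIFICATION),
    ],
)
def test_reconcile_duplicates(r1, r2, tol, ct, flag):
    got_ct, got_flag = reconcile_duplicates(r1, r2, tol)
    assert got_flag == flag
    if math.isnan(ct):
        assert math.isnan(got_ct)
    else:
        assert got_ct == pytest.approx(ct)


def _irc_frame(deviations_by_run):
    """Three calibrator samples; per-run Cts = reference + given deviations."""
    base = [28.0, 31.0, 34.0]
    rows = []
    for run, devs in deviations_by_run.items():
        for i, (ct0, dev) in enumerate(zip(base, devs)):
            rows.append((f"S{i}", "preoperative", -0.14, "miR-21", run, ct0 + dev, ct0 + dev, 26.0))
    return pd.DataFrame(
        rows,
        columns=["patient_id", "phase", "time_weeks", "marker", "run_id", "ct_rep1", "ct_rep2", "spikein_ct"],
    )


def test_calibration_identical_runs_give_zero_offsets():
    irc = _irc_frame({"run01": [0, 0, 0], "run02": [0, 0, 0]})
    calib = fit_run_calibration(irc, "run01")
    assert (calib["ct_offset"] == 0.0).all()


def test_calibration_recovers_constant_shift():
    irc = _irc_frame({"run01": [0, 0, 0], "run02": [0.3, 0.3, 0.3]})
    calib = fit_run_calibration(irc, "run01").set_index("run_id")
    assert calib.loc["run02", "ct_offset"] == pytest.approx(0.3)


def test_calibration_offset_is_mean_of_deviations():
    irc = _irc_frame({"run01": [0, 0, 0], "run02": [0.1, 0.2, 0.3]})
    calib = fit_run_calibration(irc, "run01").set_index("run_id")
    assert calib.loc["run02", "ct_offset"] == pytest.approx(0.2)


def test_calibration_impossible_names_the_run():
    irc = _irc_frame({"run01": [0, 0, 0]})
    # run03 measured different samples: no shared calibrator
    stray = irc.copy()
    stray["patient_id"] = ["X0", "X1", "X2"]
    stray["run_id"] = "run03"
    with pytest.raises(CalibrationError, match="run03"):
        fit_run_calibration(pd.concat([irc, stray]), "run01")


def _zero_noise_config(**overrides):
    defaults = dict(
        seed=3,
        n_patients=30,
        ct_noise_sd=0.0,
        level_noise_sd=0.0,
        spikein_ct_sd=0.0,
        markers=(MarkerSpec("miR-21", 0.05, 1.0), MarkerSpec("miR-20a", -1.4, 1.0)),
    )
    defaults.update(overrides)
    return CohortConfig(**defaults)


def test_zero_noise_round_trip_recovers_levels_exactly():
    cfg = _zero_noise_config()
    _, samples = generate_cohort(cfg)
    raw = generate_ct_table(samples, cfg)
    levels, log = process_table(raw)
    merged = levels.merge(
        samples, on=["patient_id", "phase", "time_weeks", "marker"], suffixes=("_est", "_true")
    )
    ok = merged[merged["qc_flag"] == QC_OK]
    assert len(ok) == len(samples)
    np.testing.assert_allclose(ok["level_est"], ok["level_true"], rtol=1e-9)


def test_round_trip_with_plate_shifts_requires_calibration():
    """Plate shifts corrupt uncalibrated levels; IRC calibration removes them."""
    cfg = _zero_noise_config(run_shift_sd=1.0, n_runs=3)
    _, samples = generate_cohort(cfg)
    raw = generate_ct_table(samples, cfg)
    levels, _ = process_table(raw)
    merged = levels.merge(
        samples, on=["patient_id", "phase", "time_weeks", "marker"], suffixes=("_est", "_true")
    )
    np.testing.assert_allclose(merged["level_est"], merged["level_true"], rtol=1e-9)
    # naive 2^-dCt without calibration does NOT recover levels on shifted runs
    key = ["patient_id", "phase", "time_weeks", "marker"]
    quant = raw.drop_duplicates(subset=key, keep="first")
    naive = 2.0 ** -(quant["ct_rep1"] - quant["spikein_ct"])
    naive_err = np.abs(np.log(naive.to_numpy() / quant.merge(samples, on=key)["level"].to_numpy()))
    assert naive_err.max() > 0.1


def test_process_table_flags_and_counts():
    rows = []
    for i in range(10):
        ct = 36.5 if i < 2 else 28.0  # two rows past the reliability threshold
        rows.append((f"P{i}", "preoperative", -0.14, "miR-21", "run01", ct, ct, 26.0))
    raw = pd.DataFrame(
        rows,
        columns=["patient_id", "phase", "time_weeks", "marker", "run_id", "ct_rep1", "ct_rep2", "spikein_ct"],
    )
    levels, log = process_table(raw)
    assert len(levels) == 10
    assert (levels["qc_flag"] == QC_OK).sum() == 8
    assert (levels["qc_flag"] == QC_HIGH_CT).sum() == 2
    assert levels.loc[levels["qc_flag"] == QC_HIGH_CT, "level"].isna().all()
    assert log["qc_counts"][QC_HIGH_CT] == 2


def test_process_table_unknown_run_errors():
    raw = _irc_frame({"run01": [0, 0, 0], "run02": [0, 0, 0]})
    orphan = pd.DataFrame(
        [("P9", "followup", 10.0, "miR-21", "run07", 30.0, 30.0, 26.0)], columns=raw.columns
    )
    with pytest.raises(CalibrationError, match="run07"):
        process_table(pd.concat([raw, orphan], ignore_index=True))


def test_calibration_idempotent_with_zero_offsets():
    """A single-run table (all offsets zero) is normalized untouched."""
    raw = pd.DataFrame(
        [("P1", "preoperative", -0.14, "miR-21", "run01", 28.0, 28.0, 26.0)],
        columns=["patient_id", "phase", "time_weeks", "marker", "run_id", "ct_rep1", "ct_rep2", "spikein_ct"],
    )
    levels, _ = process_table(raw)
    assert levels["level"].iloc[0] == pytest.approx(2.0 ** -(28.0 - 26.0))


def test_marker_qc_summary_flags_unreliable_assay():
    levels = pd.DataFrame(
        {
            "patient_id": ["P1"] * 4,
            "phase": ["followup"] * 4,
            "time_weeks": [1, 2, 3, 4],
            "marker": ["good", "good", "bad", "bad"],
            "level": [1.0, 1.1, np.nan, np.nan],
            "qc_flag": [QC_OK, QC_OK, QC_HIGH_CT, QC_NO_AMPLIFICATION],
        }
    )
    rep = marker_qc_summary(levels).set_index("marker")
    assert not rep.loc["good", "exclude_panelwide"]
    assert rep.loc["bad", "exclude_panelwide"]
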