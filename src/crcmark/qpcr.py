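"""Relative quantification of miRNA qPCR data (2^-dCt against a spike-in).

The processing chain converts raw duplicate Ct readouts into calibrated
relative levels:

1. **reconcile** technical duplicates (mean if they agree within a tolerance,
   otherwise the sample is flagged for repeat and excluded from analysis);
2. **calibrate** across PCR runs by subtracting per-run, per-marker Ct
   offsets estimated from inter-run calibrators (IRCs) — samples from the
   reference run re-measured on every later run;
3. **filter** unreliable quantification (calibrated Ct above 35 cycles, or
   no amplification in either duplicate);
4. **normalize** against the same sample's exogenous spike-in (cel-miR-39)
   Ct: ``level = 2^-(Ct_target - Ct_spikein)``.

Serum markers (CEA, CA19-9) are immunoassay concentrations and never pass
through this module.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from crcmark.errors import CalibrationError, SchemaError

QC_OK = "ok"
QC_HIGH_CT = "excluded_high_ct"
QC_NO_AMPLIFICATION = "excluded_no_amplification"
QC_REPEAT_REQUIRED = "repeat_required"

#: Reliability threshold (cycles): quantification above this Ct is excluded.
#: Applied with strict inequality (Ct == 35 is kept).
DEFAULT_CT_MAX = 35.0

#: Technical duplicates further apart than this (cycles) are in disagreement.
DEFAULT_TOLERANCE = 0.5

LEVEL_COLUMNS = ["patient_id", "phase", "time_weeks", "marker", "level", "qc_flag"]

_SAMPLE_KEY = ["patient_id", "phase", "time_weeks", "marker"]


@dataclass(frozen=True)
class RunCalibration:
    """Per-run, per-marker Ct offset to subtract before normalization."""

    run_id: str
    marker: str
    ct_offset: float


def compute_relative_level(ct_target: float, ct_normalizer: float) -> float:
    """Relative level as 2^-(Ct_target - Ct_normalizer).

    One cycle difference corresponds to a two-fold level change; the result
    is strictly decreasing in ``ct_target``.  Absent (non-finite) Cts signal
    no amplification and raise ``ValueError``.
    """
    if not (math.isfinite(ct_target) and math.isfinite(ct_normalizer)):
        raise ValueError("absent Ct: no amplification")
    return 2.0 ** -(ct_target - ct_normalizer)


def reconcile_duplicates(
    ct_rep1: float, ct_rep2: float, tolerance: float = DEFAULT_TOLERANCE
) -> tuple[float, str]:
    """Reconcile technical duplicates into a single Ct.

    Agreement within ``tolerance`` cycles yields the arithmetic mean; a
    single present replicate is taken as-is; disagreement flags the sample
    as requiring repeat assessment (such rows are excluded from downstream
    analysis, since the wet-lab repeat cannot happen in a reanalysis).  Both
    replicates absent signals no amplification via the returned flag.
    """
    p1 = ct_rep1 is not None and math.isfinite(ct_rep1)
    p2 = ct_rep2 is not None and math.isfinite(ct_rep2)
    if not p1 and not p2:
        return (math.nan, QC_NO_AMPLIFICATION)
    if p1 and p2:
        if abs(ct_rep1 - ct_rep2) <= tolerance:
            return ((ct_rep1 + ct_rep2) / 2.0, QC_OK)
        return (math.nan, QC_REPEAT_REQUIRED)
    return (ct_rep1 if p1 else ct_rep2, QC_OK)


def apply_reliability_filter(
    ct_rep1: float,
    ct_rep2: float,
    ct_max: float = DEFAULT_CT_MAX,
    tolerance: float = DEFAULT_TOLERANCE,
) -> str:
    """QC decision for one raw duplicate pair.

    ``excluded_no_amplification`` if both replicates are absent,
    ``excluded_high_ct`` if the reconciled Ct exceeds ``ct_max`` (strict
    inequality: Ct equal to the threshold is kept), ``ok`` otherwise.
    """
    ct, flag = reconcile_duplicates(ct_rep1, ct_rep2, tolerance)
    if flag != QC_OK:
        return flag
    return QC_HIGH_CT if ct > ct_max else QC_OK


def fit_run_calibration(
    irc: pd.DataFrame,
    reference_run: str,
    tolerance: float = DEFAULT_TOLERANCE,
) -> pd.DataFrame:
    """Estimate per-run, per-marker Ct offsets from inter-run calibrators.

    ``irc`` holds the calibrator measurements (same sample key measured on
    several runs).  For each run and marker the offset is the mean, over IRC
    samples shared with the reference run, of (Ct in run - Ct in reference);
    the reference run gets offset 0 by construction.

    Returns a DataFrame with columns (run_id, marker, ct_offset).

    Raises
    ------
    CalibrationError
        If a non-reference run shares no calibrator with the reference run
        for some marker.
    """
    if irc.empty:
        return pd.DataFrame(columns=["run_id", "marker", "ct_offset"])
    df = irc.copy()
    df["ct"] = _reconciled_ct(df, tolerance)
    ref = df[df["run_id"] == reference_run]
    if ref.empty:
        raise CalibrationError(f"reference run '{reference_run}' has no calibrator measurements")
    ref = ref.rename(columns={"ct": "ct_ref"})[_SAMPLE_KEY + ["ct_ref"]]
    merged = df.merge(ref, on=_SAMPLE_KEY, how="left")

    rows = []
    for (run, marker), grp in merged.groupby(["run_id", "marker"], sort=True):
        if run == reference_run:
            rows.append((run, marker, 0.0))
            continue
        deltas = (grp["ct"] - grp["ct_ref"]).dropna()
        if deltas.empty:
            raise CalibrationError(
                f"run '{run}' shares no inter-run calibrator with reference run "
                f"'{reference_run}' for marker '{marker}'"
            )
        rows.append((run, marker, float(deltas.mean())))
    return pd.DataFrame(rows, columns=["run_id", "marker", "ct_offset"])


def find_irc_keys(raw: pd.DataFrame) -> pd.DataFrame:
    """Sample keys measured on more than one run (the inter-run calibrators)."""
    counts = raw.groupby(_SAMPLE_KEY)["run_id"].nunique()
    return counts[counts > 1].reset_index()[_SAMPLE_KEY]


def process_table(
    raw: pd.DataFrame,
    tolerance: float = DEFAULT_TOLERANCE,
    ct_max: float = DEFAULT_CT_MAX,
    reference_run: str | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Run the full chain reconcile -> calibrate -> filter -> normalize.

    Inter-run calibrator rows are identified structurally (the same sample
    key appearing under more than one ``run_id``); their re-measurements feed
    the calibration fit and are then dropped, so each input sample yields
    exactly one output record.  The reliability filter is applied to the
    *calibrated* Ct.

    Returns
    -------
    levels : DataFrame
        Columns (patient_id, phase, time_weeks, marker, level, qc_flag); the
        level is NaN for every excluded record.
    log : dict
        Processing log: qc-flag counts, reference run, number of calibrator
        rows consumed, and the fitted offsets.

    Raises
    ------
    SchemaError
        Missing columns, or a run that cannot be calibrated.
    """
    required = set(_SAMPLE_KEY + ["run_id", "ct_rep1", "ct_rep2", "spikein_ct"])
    missing = required - set(raw.columns)
    if missing:
        raise SchemaError(f"raw qPCR table missing column(s): {sorted(missing)}")

    raw = raw.copy()
    runs = sorted(raw["run_id"].astype(str).unique())
    irc_keys = find_irc_keys(raw)
    has_irc = not irc_keys.empty
    if reference_run is None:
        if has_irc:
            # the reference run is the one carrying every calibrator sample
            irc_rows = raw.merge(irc_keys, on=_SAMPLE_KEY)
            uniq = irc_rows.drop_duplicates(subset=_SAMPLE_KEY + ["run_id"])
            per_run = uniq.groupby("run_id").size()
            full = per_run[per_run == len(irc_keys)]
            reference_run = sorted(full.index)[0] if len(full) else sorted(per_run.index)[0]
        elif len(runs) == 1:
            reference_run = runs[0]
        else:
            raise CalibrationError(
                "multiple runs but no shared calibrator samples; cannot calibrate"
            )
    if reference_run not in runs:
        raise CalibrationError(f"reference run '{reference_run}' not present in table")

    if has_irc:
        irc_rows = raw.merge(irc_keys, on=_SAMPLE_KEY)
        calib = fit_run_calibration(irc_rows, reference_run, tolerance)
    else:
        calib = pd.DataFrame(
            [(reference_run, m, 0.0) for m in raw["marker"].unique()],
            columns=["run_id", "marker", "ct_offset"],
        )

    # quantification rows: drop calibrator re-measurements from other runs
    if has_irc:
        flagged = raw.merge(irc_keys.assign(_irc=True), on=_SAMPLE_KEY, how="left")
        is_dup = flagged["_irc"].notna() & (flagged["run_id"] != reference_run)
        quant = raw[~is_dup.to_numpy()].copy()
        n_irc_dropped = int(is_dup.sum())
    else:
        quant = raw
        n_irc_dropped = 0

    quant = quant.merge(calib, on=["run_id", "marker"], how="left", validate="m:1")
    uncalibrated = quant[quant["ct_offset"].isna()]["run_id"].unique()
    if len(uncalibrated):
        raise CalibrationError(
            f"run(s) without calibration: {sorted(map(str, uncalibrated))}"
        )

    r1 = quant["ct_rep1"].to_numpy(dtype=float)
    r2 = quant["ct_rep2"].to_numpy(dtype=float)
    p1, p2 = np.isfinite(r1), np.isfinite(r2)
    with np.errstate(invalid="ignore"):
        disagree = p1 & p2 & (np.abs(r1 - r2) > tolerance)
    ct = np.where(p1 & p2, (r1 + r2) / 2.0, np.where(p1, r1, r2))

    flag = np.full(len(quant), QC_OK, dtype=object)
    flag[disagree] = QC_REPEAT_REQUIRED
    flag[~p1 & ~p2] = QC_NO_AMPLIFICATION

    calibrated = ct - quant["ct_offset"].to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        high = (flag == QC_OK) & (calibrated > ct_max)
    flag[high] = QC_HIGH_CT

    level = np.where(
        flag == QC_OK,
        2.0 ** -(calibrated - quant["spikein_ct"].to_numpy(dtype=float)),
        np.nan,
    )

    levels = quant[["patient_id", "phase", "time_weeks", "marker"]].copy()
    levels["level"] = level
    levels["qc_flag"] = flag
    levels = levels.reset_index(drop=True)

    log = {
        "n_input_rows": int(len(raw)),
        "n_calibrator_rows_dropped": n_irc_dropped,
        "reference_run": reference_run,
        "qc_counts": {k: int(v) for k, v in pd.Series(flag).value_counts().items()},
        "calibration": calib,
    }
    return levels, log


def marker_qc_summary(levels: pd.DataFrame, min_ok_fraction: float = 0.5) -> pd.DataFrame:
    """Panel-level exclusion report: per-marker QC counts and ok fraction.

    Markers whose fraction of reliably quantified samples falls below
    ``min_ok_fraction`` are flagged ``exclude_panelwide`` — the whole-assay
    analogue of the per-sample reliability filter, for panels in which some
    assays amplify too late across the board.
    """
    out = []
    for marker, grp in levels.groupby("marker", sort=True):
        counts = grp["qc_flag"].value_counts()
        n = len(grp)
        ok = int(counts.get(QC_OK, 0))
        out.append(
            {
                "marker": marker,
                "n_samples": n,
                "n_ok": ok,
                "n_high_ct": int(counts.get(QC_HIGH_CT, 0)),
                "n_no_amplification": int(counts.get(QC_NO_AMPLIFICATION, 0)),
                "n_repeat_required": int(counts.get(QC_REPEAT_REQUIRED, 0)),
                "ok_fraction": ok / n if n else np.nan,
                "exclude_panelwide": bool(n and ok / n < min_ok_fraction),
            }
        )
    return pd.DataFrame(out)


def _reconciled_ct(df: pd.DataFrame, tolerance: float) -> pd.Series:
    """Vectorized duplicate reconciliation returning NaN for unusable rows."""
    r1 = df["ct_rep1"].to_numpy(dtype=float)
    r2 = df["ct_rep2"].to_numpy(dtype=float)
    p1, p2 = np.isfinite(r1), np.isfinite(r2)
    ct = np.where(p1 & p2, (r1 + r2) / 2.0, np.where(p1, r1, r2))
    with np.errstate(invalid="ignore"):
        ct = np.where(p1 & p2 & (np.abs(r1 - r2) > tolerance), np.nan, ct)
    return pd.Series(ct, index=df.index)
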