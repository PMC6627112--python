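"""Synthetic surveillance-cohort generator.

Emulates the statistical structure of a longitudinal tumor-marker study of
surgically treated colorectal-cancer patients: paired pre/post-operative
plasma samples plus irregular follow-up samples, lognormal marker levels
whose postoperative drop depends on surgery type, exponential survival times
driven by a shared per-patient burden factor, and clinical recurrences that
elevate all post-recurrence follow-up levels.  A second stage renders the
miRNA levels as raw duplicate Ct measurements (spike-in normalizer, plate
runs with shifts, inter-run calibrator re-measurements) so that the full
qPCR processing chain can be exercised and inverted.

All randomness flows from ``CohortConfig.seed``; a fixed seed yields
bit-identical output tables.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from crcmark.config import CohortConfig
from crcmark.errors import ConfigError

CLINICAL_COLUMNS = [
    "patient_id",
    "surgery_type",
    "t_stage",
    "n_stage",
    "m_stage",
    "grade",
    "clinical_stage",
    "survival_weeks",
    "death_event",
    "recurrence",
    "recurrence_weeks",
]
SAMPLE_COLUMNS = ["patient_id", "phase", "time_weeks", "marker", "level"]
QPCR_COLUMNS = [
    "patient_id",
    "phase",
    "time_weeks",
    "marker",
    "run_id",
    "ct_rep1",
    "ct_rep2",
    "spikein_ct",
]

# Marginal distributions of the clinicopathological covariates in a typical
# mixed radical/palliative resection cohort (counts out of 85).
_STAGE_TABLES = {
    "t_stage": (["T2", "T3", "T4"], [10, 62, 13]),
    "n_stage": (["N0", "N1", "N2"], [28, 40, 17]),
    "m_stage": (["M0", "M1"], [56, 29]),
    "grade": (["1", "2", "3"], [14, 60, 11]),
    "clinical_stage": (["I", "II", "III", "IV"], [4, 17, 35, 29]),
}

#: Instrument detection limit: amplification past this cycle is reported as
#: absent (no Cq call).
CT_DETECTION_LIMIT = 40.0

PREOP_TIME_WEEKS = -1.0 / 7.0  # one day before surgery


def generate_cohort(config: CohortConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw one cohort: a clinical table and a long-format sample-level table.

    Returns
    -------
    clinical : DataFrame
        One row per patient (surgery type, TNM covariates, survival and
        recurrence outcomes).  ``recurrence_weeks`` is NaN unless
        ``recurrence`` is True; palliative patients never carry recurrence
        labels (recurrence evaluation is restricted to radically resected
        patients).
    samples : DataFrame
        One row per sample event x marker with the true underlying level.
        Each patient has exactly one preoperative and one postoperative
        sample and 0-7 follow-ups at strictly increasing times.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 0])
    n = config.n_patients
    n_radical = int(round(n * config.fraction_radical))
    surgery = np.array(["radical"] * n_radical + ["palliative"] * (n - n_radical))
    patient_ids = np.array([f"P{i + 1:04d}" for i in range(n)])

    # shared standardized burden factor; palliative (residual) disease shifts it
    burden = rng.normal(size=n)
    burden[surgery == "palliative"] += config.palliative_burden_shift

    markers = config.markers
    rho = config.marker_correlation
    eps = rng.normal(size=(n, len(markers)))
    z = rho * burden[:, None] + np.sqrt(1.0 - rho**2) * eps
    mu = np.array([m.log_level_mean for m in markers])
    sd = np.array([m.log_level_sd for m in markers])
    pre_levels = np.exp(mu[None, :] + sd[None, :] * z)  # (n, M)

    # survival: exponential with proportional hazards on burden
    hazard = config.hazard_baseline * np.exp(config.log_hazard_per_logunit * burden)
    hazard[surgery == "palliative"] *= config.palliative_hazard_multiplier
    t_death = rng.exponential(1.0 / hazard)
    horizon = config.censor_horizon_weeks
    death_event = t_death <= horizon
    survival_weeks = np.minimum(t_death, horizon)

    # follow-up schedule
    lo, hi = config.followup_samples_range
    wlo, whi = config.followup_window_weeks
    n_followups = rng.integers(lo, hi + 1, size=n)
    followup_times = [np.sort(rng.uniform(wlo, whi, size=k)) for k in n_followups]

    # recurrence: a fixed fraction of radical patients, timed inside the
    # patient's observed sampling window so surveillance can see it
    recurrence = np.zeros(n, dtype=bool)
    recurrence_weeks = np.full(n, np.nan)
    radical_idx = np.flatnonzero(surgery == "radical")
    n_rec = int(round(config.recurrence_fraction * len(radical_idx)))
    if n_rec > 0:
        rec_idx = rng.choice(radical_idx, size=n_rec, replace=False)
        recurrence[rec_idx] = True
        for i in rec_idx:
            upper = followup_times[i][-1] if len(followup_times[i]) else whi
            recurrence_weeks[i] = rng.uniform(wlo, upper)

    clinical = pd.DataFrame({"patient_id": patient_ids, "surgery_type": surgery})
    for col, (cats, counts) in _STAGE_TABLES.items():
        p = np.asarray(counts, dtype=float)
        clinical[col] = rng.choice(cats, size=n, p=p / p.sum())
    clinical["survival_weeks"] = survival_weeks
    clinical["death_event"] = death_event
    clinical["recurrence"] = recurrence
    clinical["recurrence_weeks"] = recurrence_weeks
    clinical = clinical[CLINICAL_COLUMNS]

    # sample events and levels
    drop = np.where(
        surgery == "radical", config.postop_drop_radical, config.postop_drop_palliative
    )
    remission_levels = pre_levels * drop[:, None]  # post-surgery expected level
    post_times = rng.uniform(5.0, 10.0, size=n) / 7.0
    lns = config.level_noise_sd
    marker_names = config.marker_names

    rows: list[tuple] = []
    for i in range(n):
        pid = patient_ids[i]
        for m, name in enumerate(marker_names):
            rows.append((pid, "preoperative", PREOP_TIME_WEEKS, name, pre_levels[i, m]))
        post_noise = np.exp(rng.normal(0.0, lns, size=len(marker_names)))
        for m, name in enumerate(marker_names):
            rows.append(
                (pid, "postoperative", post_times[i], name, remission_levels[i, m] * post_noise[m])
            )
        for t in followup_times[i]:
            fu_noise = np.exp(rng.normal(0.0, lns, size=len(marker_names)))
            signal = (
                config.recurrence_fold_signal
                if recurrence[i] and t >= recurrence_weeks[i]
                else 1.0
            )
            for m, name in enumerate(marker_names):
                rows.append((pid, "followup", t, name, remission_levels[i, m] * fu_noise[m] * signal))

    samples = pd.DataFrame(rows, columns=SAMPLE_COLUMNS)
    return clinical, samples


def generate_ct_table(samples: pd.DataFrame, config: CohortConfig) -> pd.DataFrame:
    """Render miRNA sample levels as raw duplicate Ct measurements.

    Each sample event is assigned to a PCR run in plate-sized blocks; every
    run after the first carries a per-marker Ct shift (expressed relative to
    the first run, which defines the reference scale).  The first three
    sample events of the first run are re-measured on every later run as
    inter-run calibrators, appearing as additional rows with the same sample
    key but a different ``run_id``.  Serum markers (CEA, CA19-9) are not
    qPCR assays and are omitted.

    The generating model per replicate is::

        Ct = ct_baseline + (spikein_ct - spikein_ct_mean) - log2(level)
             + run_shift + N(0, ct_noise_sd)

    so that with the default ``ct_baseline == spikein_ct_mean`` the
    processing chain (reconcile -> calibrate -> 2^-dCt against the spike-in)
    inverts to the generating level exactly at zero noise.  Replicates past
    the detection limit (40 cycles) are reported as absent.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 1])
    mirna_names = [m.name for m in config.mirna_markers]
    if not mirna_names:
        return pd.DataFrame(columns=QPCR_COLUMNS)
    sub = samples[samples["marker"].isin(mirna_names)]
    if (sub["level"] <= 0).any() or not np.isfinite(sub["level"]).all():
        raise ConfigError("marker levels must be strictly positive and finite")

    events = sub[["patient_id", "phase", "time_weeks"]].drop_duplicates().reset_index(drop=True)
    n_events = len(events)
    block = int(np.ceil(n_events / config.n_runs))
    run_ids = [f"run{1 + i // block:02d}" for i in range(n_events)]
    events = events.assign(
        run_id=run_ids,
        spikein_ct=rng.normal(config.spikein_ct_mean, config.spikein_ct_sd, size=n_events),
    )

    all_runs = sorted(set(run_ids))
    reference_run = all_runs[0]
    shifts = {
        (r, m): (0.0 if r == reference_run else rng.normal(0.0, config.run_shift_sd))
        for r in all_runs
        for m in mirna_names
    }

    merged = sub.merge(events, on=["patient_id", "phase", "time_weeks"], how="left")

    def _measure(level, spike, run, marker, k):
        base = (
            config.ct_baseline
            + (spike - config.spikein_ct_mean)
            - np.log2(level)
            + shifts[(run, marker)]
        )
        cts = base + rng.normal(0.0, config.ct_noise_sd, size=k)
        return [ct if ct <= CT_DETECTION_LIMIT else np.nan for ct in cts]

    rows = []
    for rec in merged.itertuples(index=False):
        r1, r2 = _measure(rec.level, rec.spikein_ct, rec.run_id, rec.marker, 2)
        rows.append(
            (rec.patient_id, rec.phase, rec.time_weeks, rec.marker, rec.run_id, r1, r2, rec.spikein_ct)
        )

    # inter-run calibrators: first events of the reference run, re-measured
    # on every other run
    irc_events = events[events["run_id"] == reference_run].head(3)
    irc_keys = irc_events.merge(sub, on=["patient_id", "phase", "time_weeks"])
    for run in all_runs:
        if run == reference_run:
            continue
        for rec in irc_keys.itertuples(index=False):
            r1, r2 = _measure(rec.level, rec.spikein_ct, run, rec.marker, 2)
            rows.append(
                (rec.patient_id, rec.phase, rec.time_weeks, rec.marker, run, r1, r2, rec.spikein_ct)
            )

    return pd.DataFrame(rows, columns=QPCR_COLUMNS)


def write_cohort(
    clinical: pd.DataFrame,
    samples: pd.DataFrame,
    qpcr: pd.DataFrame,
    outdir: str | Path,
) -> dict[str, Path]:
    """Write the three cohort tables as TSV (UTF-8, header row, NaN = empty)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "clinical": outdir / "clinical.tsv",
        "samples": outdir / "samples.tsv",
        "qpcr_raw": outdir / "qpcr_raw.tsv",
    }
    clinical.to_csv(paths["clinical"], sep="\t", index=False, na_rep="")
    samples.to_csv(paths["samples"], sep="\t", index=False, na_rep="")
    qpcr.to_csv(paths["qpcr_raw"], sep="\t", index=False, na_rep="")
    return paths
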