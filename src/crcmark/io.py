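"""TSV readers/writers with schema validation.

All inter-stage tables are tab-delimited UTF-8 text with a header row;
missing values are empty fields.  Readers raise ``SchemaError`` naming the
offending file and column so pipeline failures are diagnosable.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import pandas as pd

from crcmark.errors import SchemaError
from crcmark.config import SERUM_MARKERS

CLINICAL_REQUIRED = ["patient_id", "surgery_type", "survival_weeks", "death_event", "recurrence"]
SAMPLES_REQUIRED = ["patient_id", "phase", "time_weeks", "marker", "level"]
QPCR_REQUIRED = [
    "patient_id",
    "phase",
    "time_weeks",
    "marker",
    "run_id",
    "ct_rep1",
    "ct_rep2",
    "spikein_ct",
]
LEVELS_REQUIRED = ["patient_id", "phase", "time_weeks", "marker", "level", "qc_flag"]


def _read(path: str | Path, required: list[str], dtype_overrides: dict | None = None) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise SchemaError("file not found", str(path))
    df = pd.read_csv(path, sep="\t", dtype=dtype_overrides)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {missing}", str(path))
    return df


def read_clinical(path: str | Path) -> pd.DataFrame:
    df = _read(path, CLINICAL_REQUIRED, {"patient_id": str})
    df["death_event"] = df["death_event"].astype(bool)
    df["recurrence"] = df["recurrence"].astype(bool)
    return df


def read_samples(path: str | Path) -> pd.DataFrame:
    return _read(path, SAMPLES_REQUIRED, {"patient_id": str, "marker": str})


def read_qpcr_raw(path: str | Path) -> pd.DataFrame:
    return _read(path, QPCR_REQUIRED, {"patient_id": str, "marker": str, "run_id": str})


def read_levels(path: str | Path) -> pd.DataFrame:
    return _read(path, LEVELS_REQUIRED, {"patient_id": str, "marker": str})


def write_tsv(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, na_rep="")
    return path


def serum_levels_from_samples(samples: pd.DataFrame, serum_markers=SERUM_MARKERS) -> pd.DataFrame:
    """Serum-marker rows (immunoassay concentrations) as a qc-ok level table.

    CEA/CA19-9 bypass the qPCR chain; their measured concentrations enter
    the level table directly.
    """
    sub = samples[samples["marker"].isin(serum_markers)].copy()
    sub["qc_flag"] = "ok"
    return sub[LEVELS_REQUIRED]


def format_paired_summary(summary: pd.DataFrame, serum_markers=SERUM_MARKERS) -> pd.DataFrame:
    """Round medians for reporting: 3 decimals for miRNA relative values,
    1 decimal for serum concentrations."""
    out = summary.copy()
    serum = out["marker"].isin(serum_markers)
    for col in ("median_pre", "median_post"):
        out.loc[serum, col] = out.loc[serum, col].round(1)
        out.loc[~serum, col] = out.loc[~serum, col].round(3)
    return out


def diagnostics_frame(metrics) -> pd.DataFrame:
    """Tabulate a list of DiagnosticMetrics (percentages to one decimal)."""
    rows = []
    for m in metrics:
        rows.append(
            {
                "marker": m.marker,
                "tp": m.tp,
                "fn": m.fn,
                "tn": m.tn,
                "fp": m.fp,
                "sensitivity": None if m.sensitivity is None else round(m.sensitivity, 1),
                "specificity": None if m.specificity is None else round(m.specificity, 1),
                "ppv": None if m.ppv is None else round(m.ppv, 1),
                "npv": None if m.npv is None else round(m.npv, 1),
            }
        )
    return pd.DataFrame(rows)


def sha256_of(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
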