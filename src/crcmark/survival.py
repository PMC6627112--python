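"""Overall-survival analysis: Kaplan-Meier, logrank, minimal-p cutpoints.

Preoperative marker levels are dichotomized at an "optimal" cutoff — the
candidate split minimizing the two-group logrank p-value — and high/low
groups are compared by Kaplan-Meier estimation.  A multi-marker OR rule
combines per-marker cutoffs into a single risk call: a patient is
*unfavorable* if any panel marker exceeds its cutoff, *favorable* only if
all markers are at or below theirs.

The minimal-p scan performs many correlated tests, so its reported p-value
is optimistic (anti-conservative) unless adjusted; ``optimal_cutoff`` returns
the unadjusted minimum (the conventional presentation) and
``permutation_adjusted_p`` offers an honest label-permutation correction.

By default the analysis is run on the palliative stratum: radically
resected patients rarely die within a three-year follow-up, so overall
survival is informative mainly where residual disease remains.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from crcmark.errors import SchemaError

DEFAULT_PANEL = ("CEA", "CA19-9", "miR-20a", "miR-21", "miR-23a")
DEFAULT_MIN_GROUP_FRACTION = 0.1


@dataclass(frozen=True)
class KMCurve:
    """Product-limit estimate: survival immediately after each event time."""

    times: np.ndarray  # distinct event times, increasing
    survival: np.ndarray  # S(t) just after each event time
    at_risk: np.ndarray  # number at risk just before each event time
    n_subjects: int

    def survival_at(self, t: float) -> float:
        """S(t): right-continuous step function starting at 1."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass(frozen=True)
class CutoffFit:
    marker: str
    cutoff: float
    logrank_chi2: float
    p_value: float
    n_low: int
    n_high: int
    candidate_count: int


@dataclass(frozen=True)
class CombinedRiskCall:
    patient_id: str
    risk: str  # "favorable" | "unfavorable" | "non-evaluable"
    triggering_markers: tuple[str, ...] = field(default_factory=tuple)


def _as_arrays(times, events):
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    if t.ndim != 1 or t.shape != e.shape:
        raise ValueError("times and events must be 1-d arrays of equal length")
    if len(t) == 0:
        raise ValueError("need at least one subject")
    if (t <= 0).any() or not np.isfinite(t).all():
        raise ValueError("survival times must be finite and > 0")
    return t, e


def km_estimate(times, events) -> KMCurve:
    """Kaplan-Meier product-limit estimator.

    ``events`` marks deaths (True) vs right-censoring (False).  Subjects
    censored exactly at an event time are counted at risk at that time
    (the standard convention: censoring happens just after the event).
    """
    t, e = _as_arrays(times, events)
    order = np.argsort(t, kind="stable")
    t, e = t[order], e[order]
    event_times = np.unique(t[e])
    n = len(t)
    surv, at_risk, s = [], [], 1.0
    for et in event_times:
        r = int(np.sum(t >= et))
        d = int(np.sum((t == et) & e))
        s *= 1.0 - d / r
        at_risk.append(r)
        surv.append(s)
    return KMCurve(event_times, np.asarray(surv), np.asarray(at_risk, dtype=int), n)


def km_table(curve: KMCurve) -> pd.DataFrame:
    """Tabular export of a KM curve (time, at-risk, survival)."""
    return pd.DataFrame(
        {"time_weeks": curve.times, "n_at_risk": curve.at_risk, "survival": curve.survival}
    )


def logrank_test(times, events, groups) -> tuple[float, float]:
    """Standard two-group logrank test.

    chi2 = (O1 - E1)^2 / V with the hypergeometric variance summed over
    distinct event times; p from the chi-square distribution with 1 df.
    With no events (or no variance) chi2 = 0 and p = 1.
    """
    t, e = _as_arrays(times, events)
    g = np.asarray(groups)
    labels = np.unique(g)
    if len(labels) != 2:
        raise ValueError(f"logrank requires exactly two groups, got {len(labels)}")
    in1 = g == labels[0]

    event_times = np.unique(t[e])
    o_minus_e = 0.0
    var = 0.0
    for et in event_times:
        at_risk = t >= et
        n_j = int(at_risk.sum())
        n1_j = int((at_risk & in1).sum())
        dying = (t == et) & e
        d_j = int(dying.sum())
        d1_j = int((dying & in1).sum())
        o_minus_e += d1_j - d_j * n1_j / n_j
        if n_j > 1:
            var += d_j * (n1_j / n_j) * (1 - n1_j / n_j) * (n_j - d_j) / (n_j - 1)
    if var <= 0.0:
        return 0.0, 1.0
    chi2 = o_minus_e**2 / var
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


def candidate_cutoffs(values: np.ndarray) -> np.ndarray:
    """Midpoints between consecutive distinct sorted marker values."""
    distinct = np.unique(values)
    return (distinct[:-1] + distinct[1:]) / 2.0


def optimal_cutoff(
    values,
    times,
    events,
    min_group_fraction: float = DEFAULT_MIN_GROUP_FRACTION,
    marker: str = "",
) -> CutoffFit:
    """Minimal-p logrank cutpoint for one marker.

    Candidates are the midpoints between consecutive distinct values;
    candidates leaving either group with fewer than
    ``min_group_fraction * n`` subjects are inadmissible.  The returned
    p-value is the unadjusted minimum over the scan (see module docstring
    for the multiple-look caveat).  Ties on p are broken toward the larger
    chi2, then the smaller cutoff.  The high group is strict: value > cutoff.
    """
    v = np.asarray(values, dtype=float)
    t, e = _as_arrays(times, events)
    if len(v) != len(t):
        raise ValueError("values and times must align")
    if len(np.unique(v)) < 2:
        raise ValueError("need at least 2 distinct marker values to place a cutoff")
    n = len(v)
    floor = min_group_fraction * n
    best = None
    n_admissible = 0
    for c in candidate_cutoffs(v):
        high = v > c
        n_high = int(high.sum())
        n_low = n - n_high
        if n_high < floor or n_low < floor:
            continue
        n_admissible += 1
        chi2, p = logrank_test(t, e, high)
        key = (p, -chi2, c)
        if best is None or key < best[0]:
            best = (key, c, chi2, p, n_low, n_high)
    if best is None:
        raise ValueError(
            f"no admissible cutoff for marker '{marker}' at min_group_fraction={min_group_fraction}"
        )
    _, c, chi2, p, n_low, n_high = best
    return CutoffFit(marker, float(c), chi2, p, n_low, n_high, n_admissible)


def permutation_adjusted_p(
    values,
    times,
    events,
    min_group_fraction: float = DEFAULT_MIN_GROUP_FRACTION,
    n_permutations: int = 1000,
    rng: np.random.Generator | None = None,
) -> float:
    """Permutation correction for the minimal-p cutoff scan.

    Re-runs the full scan on label-permuted marker values and reports the
    fraction of permutations achieving a minimal p at most as small as the
    observed one (add-one estimator).
    """
    rng = np.random.default_rng() if rng is None else rng
    observed = optimal_cutoff(values, times, events, min_group_fraction).p_value
    v = np.asarray(values, dtype=float)
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(v)
        try:
            fit = optimal_cutoff(perm, times, events, min_group_fraction)
        except ValueError:
            continue
        if fit.p_value <= observed:
            hits += 1
    return (hits + 1) / (n_permutations + 1)


def combine_markers_or(
    marker_values: pd.DataFrame, cutoffs: dict[str, float]
) -> list[CombinedRiskCall]:
    """OR-combination risk classifier over a marker panel.

    ``marker_values`` is patients x markers (index = patient_id).  A patient
    is *unfavorable* iff any panel marker exceeds its cutoff (ties at the
    cutoff fall low); the triggering markers are recorded.  Patients missing
    any panel value are non-evaluable.
    """
    missing = set(cutoffs) - set(marker_values.columns)
    if missing:
        raise SchemaError(f"marker value table missing panel marker(s): {sorted(missing)}")
    calls = []
    for pid, row in marker_values.iterrows():
        panel_vals = row[list(cutoffs)]
        if panel_vals.isna().any():
            calls.append(CombinedRiskCall(str(pid), "non-evaluable"))
            continue
        triggers = tuple(m for m in cutoffs if row[m] > cutoffs[m])
        risk = "unfavorable" if triggers else "favorable"
        calls.append(CombinedRiskCall(str(pid), risk, triggers))
    return calls


def preoperative_matrix(levels: pd.DataFrame, markers) -> pd.DataFrame:
    """Patients x markers matrix of qc-ok preoperative levels."""
    pre = levels[(levels["phase"] == "preoperative") & (levels["marker"].isin(markers))]
    if "qc_flag" in pre.columns:
        pre = pre[pre["qc_flag"] == "ok"]
    return pre.pivot_table(index="patient_id", columns="marker", values="level", aggfunc="first")


def fit_panel_cutoffs(
    levels: pd.DataFrame,
    clinical: pd.DataFrame,
    panel=DEFAULT_PANEL,
    stratum: str | None = "palliative",
    min_group_fraction: float = DEFAULT_MIN_GROUP_FRACTION,
) -> tuple[list[CutoffFit], pd.DataFrame, list[CombinedRiskCall], tuple[float, float]]:
    """Fit per-marker optimal cutoffs and the combined OR classifier.

    Restricted to ``stratum`` (None = all patients).  Returns the per-marker
    fits, the marker matrix used, the combined risk calls, and the logrank
    (chi2, p) comparing favorable vs unfavorable patients.
    """
    clin = clinical if stratum is None else clinical[clinical["surgery_type"] == stratum]
    clin = clin.set_index("patient_id")
    matrix = preoperative_matrix(levels, panel).reindex(clin.index)

    fits = []
    for marker in panel:
        if marker not in matrix.columns:
            raise SchemaError(f"no preoperative levels for panel marker '{marker}'")
        sub = pd.DataFrame(
            {
                "v": matrix[marker],
                "t": clin["survival_weeks"],
                "e": clin["death_event"],
            }
        ).dropna()
        fits.append(
            optimal_cutoff(sub["v"], sub["t"], sub["e"], min_group_fraction, marker=marker)
        )

    cutoffs = {f.marker: f.cutoff for f in fits}
    calls = combine_markers_or(matrix, cutoffs)
    risk = pd.Series({c.patient_id: c.risk for c in calls})
    evaluable = risk[risk != "non-evaluable"]
    aligned = clin.loc[evaluable.index]
    if evaluable.nunique() == 2:
        chi2, p = logrank_test(
            aligned["survival_weeks"], aligned["death_event"], evaluable.to_numpy()
        )
    else:  # degenerate: all patients on one side of the rule
        chi2, p = np.nan, np.nan
    return fits, matrix, calls, (chi2, p)
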