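"""Trajectory-based biochemical recurrence detection and its evaluation.

Each radically resected patient contributes, per marker, a postoperative
baseline level and a time-ordered follow-up trajectory.  The individual-
cutoff recurrence rule calls a trajectory positive when

* any follow-up level reaches ``fold`` (default 1.5) times the postoperative
  baseline, or
* ``consecutive_k`` (default 2) consecutive follow-up samples each exceed
  the baseline (strictly).

Calls are compared with the clinical recurrence label to produce confusion
counts and sensitivity / specificity / PPV / NPV; a continuous score (the
maximum follow-up fold change over baseline) yields ROC curves and AUC.
Patients without a usable postoperative baseline or without follow-up
samples are reported as non-evaluable rather than silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

RULE_FOLD = "fold_increase"
RULE_CONSECUTIVE = "consecutive"
RULE_NONE = "none"


@dataclass(frozen=True)
class TrajectorySeries:
    patient_id: str
    marker: str
    postop_baseline: float
    times: np.ndarray  # strictly increasing follow-up times (weeks)
    levels: np.ndarray

    def __post_init__(self):
        if not (np.isfinite(self.postop_baseline) and self.postop_baseline > 0):
            raise ValueError("postop_baseline must be finite and > 0")
        t = np.asarray(self.times, dtype=float)
        if len(t) > 1 and not (np.diff(t) > 0).all():
            raise ValueError("follow-up times must be strictly increasing")


@dataclass(frozen=True)
class RecurrenceCall:
    patient_id: str
    marker: str
    positive: bool
    rule_fired: str  # fold_increase | consecutive | none
    first_trigger_time: float | None = None


@dataclass(frozen=True)
class DiagnosticMetrics:
    """Confusion counts with derived percentages (None when undefined)."""

    marker: str
    tp: int
    fn: int
    tn: int
    fp: int

    def _pct(self, num: int, den: int) -> float | None:
        return None if den == 0 else 100.0 * num / den

    @property
    def sensitivity(self) -> float | None:
        return self._pct(self.tp, self.tp + self.fn)

    @property
    def specificity(self) -> float | None:
        return self._pct(self.tn, self.tn + self.fp)

    @property
    def ppv(self) -> float | None:
        return self._pct(self.tp, self.tp + self.fp)

    @property
    def npv(self) -> float | None:
        return self._pct(self.tn, self.tn + self.fn)

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.tn + self.fp


@dataclass(frozen=True)
class ROCResult:
    marker: str
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def diagnostic_metrics(tp: int, fn: int, tn: int, fp: int, marker: str = "") -> DiagnosticMetrics:
    """Build DiagnosticMetrics from raw confusion counts."""
    for name, v in (("tp", tp), ("fn", fn), ("tn", tn), ("fp", fp)):
        if v < 0 or int(v) != v:
            raise ValueError(f"{name} must be a non-negative integer, got {v}")
    return DiagnosticMetrics(marker, int(tp), int(fn), int(tn), int(fp))


def classify_trajectory(
    traj: TrajectorySeries,
    fold: float = 1.5,
    consecutive_k: int | None = 2,
) -> RecurrenceCall:
    """Apply the individual-cutoff recurrence rule to one trajectory.

    The fold rule fires at the first follow-up whose level reaches
    ``fold x baseline`` (inclusive); the consecutive rule fires at the k-th
    sample of the first run of ``consecutive_k`` samples each strictly above
    baseline.  Whichever fires earlier in time determines ``rule_fired``
    (the fold rule wins a same-time tie); ``consecutive_k=None`` disables
    the consecutive rule.  An empty trajectory yields a negative call.
    """
    if fold <= 0:
        raise ValueError("fold must be > 0")
    t = np.asarray(traj.times, dtype=float)
    lv = np.asarray(traj.levels, dtype=float)
    if len(t) == 0:
        return RecurrenceCall(traj.patient_id, traj.marker, False, RULE_NONE)

    fold_time = None
    hit = np.flatnonzero(lv >= fold * traj.postop_baseline)
    if len(hit):
        fold_time = float(t[hit[0]])

    consec_time = None
    if consecutive_k is not None and consecutive_k >= 1:
        run = 0
        for i in range(len(lv)):
            run = run + 1 if lv[i] > traj.postop_baseline else 0
            if run >= consecutive_k:
                consec_time = float(t[i])
                break

    if fold_time is None and consec_time is None:
        return RecurrenceCall(traj.patient_id, traj.marker, False, RULE_NONE)
    if consec_time is None or (fold_time is not None and fold_time <= consec_time):
        return RecurrenceCall(traj.patient_id, traj.marker, True, RULE_FOLD, fold_time)
    return RecurrenceCall(traj.patient_id, traj.marker, True, RULE_CONSECUTIVE, consec_time)


def trajectory_score(traj: TrajectorySeries) -> float:
    """Continuous recurrence score: max follow-up fold change over baseline."""
    if len(traj.times) == 0:
        return np.nan
    return float(np.max(np.asarray(traj.levels, dtype=float) / traj.postop_baseline))


def build_trajectories(
    levels: pd.DataFrame, markers: list[str] | None = None
) -> tuple[list[TrajectorySeries], pd.DataFrame]:
    """Assemble per-patient, per-marker trajectories from a level table.

    The postoperative baseline is the patient's (qc-ok) postoperative level;
    follow-ups are the qc-ok ``followup`` rows in time order.  Patients
    lacking a baseline for a marker are returned in the non-evaluable table
    with the reason; patients with a baseline but zero follow-ups yield an
    empty trajectory (the rule then calls them negative).
    """
    df = levels
    if "qc_flag" in df.columns:
        df = df[df["qc_flag"] == "ok"]
    if markers is None:
        markers = sorted(df["marker"].unique())
    trajectories = []
    not_evaluable = []
    for marker in markers:
        sub = df[df["marker"] == marker]
        post = sub[sub["phase"] == "postoperative"].set_index("patient_id")["level"]
        fu = sub[sub["phase"] == "followup"].sort_values("time_weeks")
        for pid in sub["patient_id"].unique():
            if pid not in post.index or not np.isfinite(post[pid]) or post[pid] <= 0:
                not_evaluable.append((pid, marker, "no_postoperative_baseline"))
                continue
            pfu = fu[fu["patient_id"] == pid]
            trajectories.append(
                TrajectorySeries(
                    pid,
                    marker,
                    float(post[pid]),
                    pfu["time_weeks"].to_numpy(dtype=float),
                    pfu["level"].to_numpy(dtype=float),
                )
            )
    ne = pd.DataFrame(not_evaluable, columns=["patient_id", "marker", "reason"])
    return trajectories, ne


def evaluate_marker(
    calls: list[RecurrenceCall], truth: dict[str, bool] | pd.Series, marker: str = ""
) -> DiagnosticMetrics:
    """Cross-tabulate recurrence calls against clinical recurrence labels.

    Every call must have a truth label; empty input is an error.  The
    derived percentages recompute exactly from the counts.
    """
    if len(calls) == 0:
        raise ValueError("no calls to evaluate")
    truth = pd.Series(truth)
    tp = fn = tn = fp = 0
    for call in calls:
        if call.patient_id not in truth.index:
            raise ValueError(f"no truth label for patient {call.patient_id}")
        actual = bool(truth[call.patient_id])
        if call.positive and actual:
            tp += 1
        elif call.positive:
            fp += 1
        elif actual:
            fn += 1
        else:
            tn += 1
    return DiagnosticMetrics(marker or (calls[0].marker if calls else ""), tp, fn, tn, fp)


def roc_curve(scores, truth, marker: str = "") -> ROCResult:
    """ROC curve and trapezoidal AUC for a continuous recurrence score.

    Thresholds sweep the distinct observed scores (call positive when
    score >= threshold), anchored at (0,0) and (1,1).  The trapezoidal AUC
    equals the tie-corrected Mann-Whitney probability
    P(score+ > score-) + 0.5 P(score+ = score-).
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(truth, dtype=bool)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and truth must be aligned 1-d arrays")
    keep = np.isfinite(s)
    s, y = s[keep], y[keep]
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC needs at least one positive and one negative truth label")

    thresholds = np.unique(s)[::-1]
    tpr = np.empty(len(thresholds) + 1)
    fpr = np.empty(len(thresholds) + 1)
    tpr[0], fpr[0] = 0.0, 0.0
    for i, thr in enumerate(thresholds, start=1):
        pos = s >= thr
        tpr[i] = np.sum(pos & y) / n_pos
        fpr[i] = np.sum(pos & ~y) / n_neg
    auc = float(np.trapezoid(tpr, fpr))
    return ROCResult(marker, thresholds, fpr, tpr, auc)


def run_recurrence_analysis(
    levels: pd.DataFrame,
    clinical: pd.DataFrame,
    markers: list[str] | None = None,
    fold: float = 1.5,
    consecutive_k: int | None = 2,
) -> dict:
    """Full recurrence-detection evaluation on the radical stratum.

    Builds trajectories, applies the rule, cross-tabulates against clinical
    recurrence, and computes per-marker ROC/AUC from the max-fold-change
    score.  Patients with no follow-up samples are excluded from evaluation
    (their recurrence status cannot be observed biochemically) and reported.

    Returns a dict with keys: calls (DataFrame), diagnostics (list of
    DiagnosticMetrics), roc (dict marker -> ROCResult), non_evaluable
    (DataFrame).
    """
    radical = clinical[clinical["surgery_type"] == "radical"]
    truth = radical.set_index("patient_id")["recurrence"].astype(bool)
    lv = levels[levels["patient_id"].isin(radical["patient_id"])]
    trajectories, non_eval = build_trajectories(lv, markers)

    call_rows = []
    diagnostics = []
    roc_results = {}
    ne_extra = []
    by_marker: dict[str, list[TrajectorySeries]] = {}
    for traj in trajectories:
        by_marker.setdefault(traj.marker, []).append(traj)

    for marker, trajs in sorted(by_marker.items()):
        calls, scores, labels = [], [], []
        for traj in trajs:
            if len(traj.times) == 0:
                ne_extra.append((traj.patient_id, marker, "no_followup_samples"))
                continue
            call = classify_trajectory(traj, fold=fold, consecutive_k=consecutive_k)
            calls.append(call)
            scores.append(trajectory_score(traj))
            labels.append(bool(truth.get(traj.patient_id, False)))
            call_rows.append(
                (
                    call.patient_id,
                    marker,
                    call.positive,
                    call.rule_fired,
                    call.first_trigger_time,
                    labels[-1],
                )
            )
        if not calls:
            continue
        diagnostics.append(evaluate_marker(calls, truth, marker=marker))
        labels_arr = np.asarray(labels, dtype=bool)
        if labels_arr.any() and not labels_arr.all():
            roc_results[marker] = roc_curve(np.asarray(scores), labels_arr, marker=marker)

    calls_df = pd.DataFrame(
        call_rows,
        columns=["patient_id", "marker", "positive", "rule_fired", "first_trigger_time", "recurrence"],
    )
    non_evaluable = pd.concat(
        [non_eval, pd.DataFrame(ne_extra, columns=["patient_id", "marker", "reason"])],
        ignore_index=True,
    )
    return {
        "calls": calls_df,
        "diagnostics": diagnostics,
        "roc": roc_results,
        "non_evaluable": non_evaluable,
    }
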