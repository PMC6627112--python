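"""Paired pre/post-operative change testing (Wilcoxon signed-rank).

Surgical removal of tumor mass should lower circulating tumor-marker levels;
this module tests that per marker within surgery-type strata (all patients,
radical, palliative) and emits a median-summary table.

The signed-rank test here follows the classic construction: zero differences
are dropped, tied absolute differences receive average ranks, and W is the
sum of ranks of positive differences.  For small samples the two-sided
p-value is exact — computed by enumerating the null distribution of W over
all 2^n sign assignments (a convolution over the doubled ranks, so ties are
handled exactly as a shifted lattice distribution).  Larger samples use the
Gaussian approximation with tie correction and a continuity correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

#: Largest n (after zero removal) for which the exact null distribution of W
#: is enumerated; beyond this the normal approximation is used.
EXACT_MAX_N = 25

STRATA = ("all", "radical", "palliative")


@dataclass(frozen=True)
class WilcoxonResult:
    statistic: float  # W = sum of positive-difference ranks
    p_value: float
    n_used: int  # pairs remaining after zero-difference removal
    method: str  # "exact" | "normal" | "degenerate"


def wilcoxon_signed_rank(
    differences, exact_max_n: int = EXACT_MAX_N
) -> WilcoxonResult:
    """Two-sided Wilcoxon signed-rank test on a vector of paired differences.

    Returns the positive-rank sum W and the two-sided p-value.  All-zero
    input (nothing to rank) yields p = 1 with a warning.
    """
    d = np.asarray(differences, dtype=float)
    if d.ndim != 1 or len(d) == 0:
        raise ValueError("differences must be a non-empty 1-d array")
    if not np.isfinite(d).all():
        raise ValueError("differences must be finite")
    d = d[d != 0.0]  # classic zero handling: drop ties with zero
    n = len(d)
    if n == 0:
        warnings.warn("all differences are zero; signed-rank test is degenerate")
        return WilcoxonResult(0.0, 1.0, 0, "degenerate")

    ranks = stats.rankdata(np.abs(d))  # average ranks for ties
    w = float(np.sum(ranks[d > 0]))
    total = float(np.sum(ranks))  # == n(n+1)/2 regardless of ties

    if n <= exact_max_n:
        p = _exact_two_sided_p(ranks, w, total)
        method = "exact"
    else:
        mu = total / 2.0
        sigma = np.sqrt(np.sum(ranks**2) / 4.0)  # tie-corrected null sd of W
        dev = w - mu
        # continuity correction pulls the statistic half a step toward the mean
        z = (dev - 0.5 * np.sign(dev)) / sigma if dev != 0 else 0.0
        p = min(1.0, 2.0 * stats.norm.sf(abs(z)))
        method = "normal"
    return WilcoxonResult(w, p, n, method)


def _exact_two_sided_p(ranks: np.ndarray, w: float, total: float) -> float:
    """Exact two-sided tail P(|W - total/2| >= |w - total/2|) under the null.

    The null distribution of W over the 2^n equiprobable sign assignments is
    built by convolution on the lattice of doubled ranks (average ranks are
    half-integers at worst, so doubling makes them exact integers).  The
    distribution is symmetric about total/2 because flipping every sign maps
    W to total - W.
    """
    r2 = np.rint(2.0 * ranks).astype(np.int64)
    counts = np.zeros(int(r2.sum()) + 1, dtype=float)
    counts[0] = 1.0
    top = 0
    for r in r2:
        nxt = counts.copy()
        nxt[r : top + r + 1] += counts[: top + 1]
        counts = nxt
        top += r
    w2 = int(np.rint(2.0 * w))
    center = r2.sum() / 2.0
    dev = abs(w2 - center)
    support = np.arange(len(counts))
    tail = counts[np.abs(support - center) >= dev - 1e-9].sum()
    return float(min(1.0, tail / counts.sum()))


def extract_paired_levels(
    levels: pd.DataFrame, marker: str
) -> pd.DataFrame:
    """Complete (pre, post) level pairs for one marker, qc-ok rows only.

    Returns a DataFrame indexed by patient_id with columns pre/post;
    patients missing either side are dropped.
    """
    ok = levels[(levels["marker"] == marker)]
    if "qc_flag" in ok.columns:
        ok = ok[ok["qc_flag"] == "ok"]
    pre = ok[ok["phase"] == "preoperative"].set_index("patient_id")["level"]
    post = ok[ok["phase"] == "postoperative"].set_index("patient_id")["level"]
    pairs = pd.DataFrame({"pre": pre, "post": post}).dropna()
    return pairs


def summarize_paired(
    levels: pd.DataFrame,
    clinical: pd.DataFrame,
    markers: list[str] | None = None,
    alpha: float = 0.05,
    log_scale: bool = True,
) -> pd.DataFrame:
    """Per-marker pre/post comparison within each surgery stratum.

    For every marker and stratum in (all, radical, palliative): the number of
    complete pairs, pre/post medians over the analyzed pairs, the signed-rank
    W, the two-sided p, and a significance flag at ``alpha`` (p <= alpha).
    Strata with fewer than two complete pairs get an absent p-value and a
    warning.

    By default the test is applied to log(post) - log(pre): plasma marker
    levels are close to lognormal and the signed-rank test assumes the null
    differences are symmetric, which holds on the log scale (for qPCR data
    this is exactly a test on paired dCt values) but not on the raw level
    scale, where multiplicative noise skews the differences.  Medians are
    always reported on the raw level scale.
    """
    if markers is None:
        markers = sorted(levels["marker"].unique())
    surgery = clinical.set_index("patient_id")["surgery_type"]
    rows = []
    for marker in markers:
        pairs = extract_paired_levels(levels, marker)
        pair_surgery = surgery.reindex(pairs.index)
        for stratum in STRATA:
            sub = pairs if stratum == "all" else pairs[pair_surgery == stratum]
            n = len(sub)
            if n < 2:
                warnings.warn(
                    f"marker {marker}, stratum {stratum}: fewer than 2 complete pairs"
                )
                rows.append((marker, stratum, n, np.nan, np.nan, np.nan, np.nan, False))
                continue
            pre = sub["pre"].to_numpy()
            post = sub["post"].to_numpy()
            diffs = np.log(post) - np.log(pre) if log_scale else post - pre
            res = wilcoxon_signed_rank(diffs)
            rows.append(
                (
                    marker,
                    stratum,
                    n,
                    float(sub["pre"].median()),
                    float(sub["post"].median()),
                    res.statistic,
                    res.p_value,
                    bool(res.p_value <= alpha),
                )
            )
    return pd.DataFrame(
        rows,
        columns=["marker", "stratum", "n", "median_pre", "median_post", "w", "p", "significant"],
    )
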