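"""Paired Rest-vs-Stroop comparisons: Wilcoxon signed-rank with BH-FDR.

The signed-rank p-value is exact (full null distribution of the positive
rank sum, tied ranks included) for n <= 25 pairs after zero-difference
removal, and uses the tie-corrected normal approximation above that.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import median_abs_deviation, rankdata
from statsmodels.stats.multitest import multipletests

from .errors import InsufficientDataError, UndefinedTestError

EXACT_N_MAX = 25


def _exact_signed_rank_cdf(ranks: np.ndarray) -> np.ndarray:
    """Null pmf of W+ = sum of ranks of positive differences.

    ``ranks`` are midranks of |d|; doubling them gives integers even under
    ties, so the distribution is built by exact integer convolution over the
    2^n equiprobable sign assignments.
    """
    r2 = np.round(2 * ranks).astype(int)
    pmf = np.zeros(r2.sum() + 1)
    pmf[0] = 1.0
    top = 0
    for r in r2:
        nxt = pmf.copy()
        nxt[r : top + r + 1] += pmf[: top + 1]
        pmf = nxt / 2.0
        top += r
    return pmf  # index = 2*W+


def wilcoxon_signed_rank(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided paired Wilcoxon signed-rank test; returns (W+, p).

    Zero differences are discarded (classic Wilcoxon treatment); at least 5
    nonzero pairs are required.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape:
        raise ValueError("paired vectors must have equal length")
    d = a - b
    d = d[d != 0]
    if len(d) == 0:
        raise UndefinedTestError("all paired differences are zero")
    if len(d) < 5:
        raise InsufficientDataError("need at least 5 nonzero differences")
    ranks = rankdata(np.abs(d))
    w_pos = float(ranks[d > 0].sum())
    n = len(d)
    if n <= EXACT_N_MAX:
        pmf = _exact_signed_rank_cdf(ranks)
        idx = int(round(2 * w_pos))
        lower = pmf[: idx + 1].sum()
        upper = pmf[idx:].sum()
        p = min(1.0, 2.0 * min(lower, upper))
    else:
        mu = n * (n + 1) / 4.0
        _, counts = np.unique(ranks, return_counts=True)
        tie_term = (counts**3 - counts).sum() / 48.0
        sigma = np.sqrt(n * (n + 1) * (2 * n + 1) / 24.0 - tie_term)
        from scipy.stats import norm

        z = (w_pos - mu) / sigma
        p = float(2.0 * norm.sf(abs(z)))
    return w_pos, float(p)


def bh_fdr(p_values: np.ndarray, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (rejected flags, adjusted p-values)."""
    p = np.asarray(p_values, float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    rejected, p_adj, *_ = multipletests(p, alpha=alpha, method="fdr_bh")
    return rejected, p_adj


@dataclass
class PairedComparisonResult:
    feature: str
    w_statistic: float
    p_value: float
    p_adjusted: float
    rejected: bool
    median_rest: float
    mad_rest: float
    median_stress: float
    mad_stress: float


def compare_sessions(
    table: pd.DataFrame,
    feature_columns: list[str] | None = None,
    alpha: float = 0.05,
) -> list[PairedComparisonResult]:
    """Paired Wilcoxon for every feature, BH-corrected across the family.

    ``table`` must hold exactly one Rest and one Stroop row per subject
    (columns ``subject``, ``session`` plus the features).  Features whose
    differences are all zero are reported with p = NaN and excluded from the
    BH family.
    """
    if feature_columns is None:
        feature_columns = [
            c for c in table.columns if c not in ("subject", "session", "label")
        ]
    counts = table.groupby(["subject", "session"]).size()
    if (counts != 1).any():
        raise ValueError("table must have exactly one row per subject and session")
    if table["subject"].nunique() < 5:
        raise InsufficientDataError("need at least 5 paired subjects")
    by_session = {
        sess: sub.sort_values("subject") for sess, sub in table.groupby("session")
    }
    if set(by_session) != {"Rest", "Stroop"}:
        raise ValueError("table must contain Rest and Stroop sessions")
    subj_rest = by_session["Rest"]["subject"].to_numpy()
    subj_stress = by_session["Stroop"]["subject"].to_numpy()
    if not np.array_equal(subj_rest, subj_stress):
        unpaired = sorted(set(subj_rest) ^ set(subj_stress))
        raise ValueError(f"unpaired subjects: {unpaired}")

    stats_rows = []
    p_raw: list[float] = []
    for feat in feature_columns:
        rest = by_session["Rest"][feat].to_numpy(float)
        stress = by_session["Stroop"][feat].to_numpy(float)
        try:
            w, p = wilcoxon_signed_rank(stress, rest)
        except (UndefinedTestError, InsufficientDataError):
            # degenerate feature (all-zero or too few nonzero differences)
            w, p = np.nan, np.nan
        stats_rows.append(
            (feat, w, p, np.median(rest), median_abs_deviation(rest),
             np.median(stress), median_abs_deviation(stress))
        )
        p_raw.append(p)

    p_arr = np.asarray(p_raw)
    valid = ~np.isnan(p_arr)
    p_adj = np.full_like(p_arr, np.nan)
    rejected = np.zeros(len(p_arr), dtype=bool)
    if valid.any():
        rej_v, adj_v = bh_fdr(p_arr[valid], alpha=alpha)
        p_adj[valid] = adj_v
        rejected[valid] = rej_v

    return [
        PairedComparisonResult(
            feature=feat,
            w_statistic=w,
            p_value=p,
            p_adjusted=p_adj[i],
            rejected=bool(rejected[i]),
            median_rest=mr,
            mad_rest=madr,
            median_stress=ms,
            mad_stress=mads,
        )
        for i, (feat, w, p, mr, madr, ms, mads) in enumerate(stats_rows)
    ]


def results_to_frame(results: list[PairedComparisonResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "feature": [r.feature for r in results],
            "W": [r.w_statistic for r in results],
            "p": [r.p_value for r in results],
            "p_adj": [r.p_adjusted for r in results],
            "rejected": [r.rejected for r in results],
            "median_rest": [r.median_rest for r in results],
            "mad_rest": [r.mad_rest for r in results],
            "median_stroop": [r.median_stress for r in results],
            "mad_stroop": [r.mad_stress for r in results],
        }
    )
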