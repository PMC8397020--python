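"""Nonparametric cohort statistics.

Group comparisons use the Mann-Whitney U test and feature-ABI association
the Spearman rank correlation, both implemented here so the pipeline is
self-contained and each can be checked against independent oracles.

The exact Mann-Whitney p-value is the tie-aware conditional permutation
p: ranks are averaged over ties and the null distribution of the
first-sample rank sum is counted by dynamic programming over subsets,
which equals full enumeration of all group assignments of the observed
pooled values.  Larger samples use the normal approximation with
tie-corrected variance and continuity correction.

Correlation strength is banded on |rho|: 0.10-0.39 weak, 0.40-0.69
moderate, 0.70-0.89 strong, 0.90-1.00 very strong (below 0.10:
negligible).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import InputError, UndefinedCorrelationError

#: Under method="auto" the exact null is used when n1*n2 <= this.
EXACT_MAX_PRODUCT = 400

FEATURES = ("bl", "hpv", "ttp", "overshoot")


@dataclass(frozen=True)
class GroupComparison:
    """Mann-Whitney comparison of one feature between two groups.

    ``u_statistic`` is U of the first sample (x); it lies in
    [0, n1*n2] and swapping the samples maps it to ``n1*n2 - U``.
    """

    feature: str
    n1: int
    n2: int
    mean1: float
    sd1: float
    mean2: float
    sd2: float
    u_statistic: float
    p_two_sided: float
    method: str


@dataclass(frozen=True)
class CorrelationResult:
    """Spearman rank correlation of one feature against ABI."""

    feature: str
    n: int
    rho: float
    p_two_sided: float
    band: str


def average_ranks(values: np.ndarray) -> np.ndarray:
    """Ranks 1..n with ties replaced by their average rank."""
    v = np.asarray(values, dtype=float)
    order = np.argsort(v, kind="stable")
    ranks = np.empty(v.size, dtype=float)
    sv = v[order]
    i = 0
    while i < v.size:
        j = i
        while j + 1 < v.size and sv[j + 1] == sv[i]:
            j += 1
        ranks[order[i:j + 1]] = 0.5 * (i + j) + 1.0  # average of i+1..j+1
        i = j + 1
    return ranks


def _exact_ranksum_pvalue(ranks2: np.ndarray, n1: int, r1_2: int
                          ) -> tuple[float, float]:
    """Tail probabilities of the rank sum of a size-n1 subset.

    ``ranks2`` are the pooled ranks doubled to integers (average ranks are
    multiples of 1/2); ``r1_2`` is the doubled observed first-sample rank
    sum.  Returns ``(P(R <= r1), P(R >= r1))`` under the exact conditional
    permutation null, counting subsets by dynamic programming.
    """
    total = int(ranks2.sum())
    # ways[k, s] = number of size-k subsets with doubled rank sum s
    ways = np.zeros((n1 + 1, total + 1), dtype=float)
    ways[0, 0] = 1.0
    for r in ranks2:
        r = int(r)
        ways[1:, r:] += ways[:-1, :total + 1 - r]
    dist = ways[n1]
    n_total = dist.sum()
    p_le = dist[:r1_2 + 1].sum() / n_total
    p_ge = dist[r1_2:].sum() / n_total
    return float(p_le), float(p_ge)


def mann_whitney_u(x, y, method: str = "auto") -> GroupComparison:
    """Two-sided Mann-Whitney U test of ``x`` versus ``y``.

    ``method`` is "exact", "normal_approx" or "auto" (exact when
    ``n1*n2 <= 400``).  The exact p equals brute-force enumeration of all
    group assignments; the normal approximation uses the tie-corrected
    variance and a 0.5 continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise InputError("both samples must be non-empty")
    if method not in ("exact", "normal_approx", "auto"):
        raise InputError(f"unknown method {method!r}")
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = average_ranks(pooled)
    r1 = float(ranks[:n1].sum())
    u1 = r1 - n1 * (n1 + 1) / 2.0

    if method == "auto":
        method = "exact" if n1 * n2 <= EXACT_MAX_PRODUCT else "normal_approx"

    if method == "exact":
        ranks2 = np.rint(2.0 * ranks).astype(int)
        r1_2 = int(round(2.0 * r1))
        p_le, p_ge = _exact_ranksum_pvalue(ranks2, n1, r1_2)
        p = min(1.0, 2.0 * min(p_le, p_ge))
    else:
        n = n1 + n2
        mu = n1 * n2 / 2.0
        _, tie_counts = np.unique(pooled, return_counts=True)
        tie_term = float(((tie_counts ** 3 - tie_counts)).sum()) / (n * (n - 1))
        var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
        if var <= 0:  # all values identical
            p = 1.0
        else:
            diff = u1 - mu
            z = (diff - 0.5 * np.sign(diff)) / np.sqrt(var)
            p = min(1.0, 2.0 * float(sps.norm.sf(abs(z))))

    return GroupComparison(
        feature="", n1=n1, n2=n2,
        mean1=float(x.mean()), sd1=float(x.std(ddof=1)) if n1 > 1 else 0.0,
        mean2=float(y.mean()), sd2=float(y.std(ddof=1)) if n2 > 1 else 0.0,
        u_statistic=float(u1), p_two_sided=float(p), method=method)


def strength_band(rho: float) -> str:
    """Correlation strength label from |rho| (half-open bands)."""
    a = abs(rho)
    if a < 0.10:
        return "negligible"
    if a < 0.40:
        return "weak"
    if a < 0.70:
        return "moderate"
    if a < 0.90:
        return "strong"
    return "very strong"


def spearman_rho(x, y) -> CorrelationResult:
    """Spearman rank correlation with average ranks for ties.

    rho is the Pearson correlation of the two rank vectors; the two-sided
    p uses the t approximation with n - 2 degrees of freedom (p = 0 at
    |rho| = 1).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise InputError("samples must be paired (equal length)")
    n = x.size
    if n < 3:
        raise InputError("need at least 3 pairs")
    rx = average_ranks(x)
    ry = average_ranks(y)
    if np.all(rx == rx[0]) or np.all(ry == ry[0]):
        raise UndefinedCorrelationError("a rank vector has zero variance")
    rho = float(np.corrcoef(rx, ry)[0, 1])
    rho = min(1.0, max(-1.0, rho))
    if abs(rho) == 1.0:
        p = 0.0
    else:
        t = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
        p = 2.0 * float(sps.t.sf(abs(t), df=n - 2))
    return CorrelationResult(feature="", n=n, rho=rho, p_two_sided=min(1.0, p),
                             band=strength_band(rho))


def summarize_cohort(table: pd.DataFrame, method: str = "auto"
                     ) -> dict[str, pd.DataFrame]:
    """Group comparisons and TTP-ABI correlations over a cohort table.

    ``table`` has one row per subject x ROI with columns subject_id,
    group ("PAOD"/"control"), abi, roi_label, bl, hpv, ttp, overshoot.
    Returns ``{"comparisons": ..., "correlations": ...}``: per ROI and
    feature the group mean +/- SD and Mann-Whitney p, and per ROI the
    Spearman correlation of TTP against ABI.
    """
    required = {"subject_id", "group", "abi", "roi_label", *FEATURES}
    missing = required - set(table.columns)
    if missing:
        raise InputError(f"cohort table lacks columns {sorted(missing)}")
    groups = set(table["group"].unique())
    if groups != {"PAOD", "control"}:
        raise InputError(
            f"cohort table must contain exactly the groups PAOD and control, "
            f"found {sorted(groups)}")

    comparisons = []
    correlations = []
    for roi_label, sub in table.groupby("roi_label", sort=True):
        paod = sub[sub["group"] == "PAOD"]
        ctrl = sub[sub["group"] == "control"]
        for feature in FEATURES:
            gc = mann_whitney_u(paod[feature].to_numpy(),
                                ctrl[feature].to_numpy(), method=method)
            comparisons.append({
                "roi_label": roi_label, "feature": feature,
                "n_paod": gc.n1, "n_control": gc.n2,
                "paod_mean": gc.mean1, "paod_sd": gc.sd1,
                "control_mean": gc.mean2, "control_sd": gc.sd2,
                "u_statistic": gc.u_statistic,
                "p_two_sided": gc.p_two_sided, "method": gc.method})
        cr = spearman_rho(sub["ttp"].to_numpy(), sub["abi"].to_numpy())
        correlations.append({
            "roi_label": roi_label, "feature": "ttp_vs_abi", "n": cr.n,
            "rho": cr.rho, "p_two_sided": cr.p_two_sided, "band": cr.band})
    return {"comparisons": pd.DataFrame(comparisons),
            "correlations": pd.DataFrame(correlations)}
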