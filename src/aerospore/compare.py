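"""Exclusion filters and paired statistical comparison of sampling methods.

Samples are paired within residence x location across the three analysis
groups (combined active, 1-day passive, 7-day passive). Comparisons use a
paired t-test when the paired differences look normal and the two series
homoscedastic, otherwise the exact Wilcoxon signed-rank test; p values are
Holm-adjusted within one family per metric x location. Indoor/outdoor ratios
are computed on untransformed values and compared between groups with the
Mann-Whitney U test after excluding zero/undefined ratios.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GROUPS",
    "ALLERGEN_GENERA",
    "PairedTestResult",
    "IORatioResult",
    "coverage_exclude",
    "prevalence_filter",
    "log10_with_pseudocount",
    "wilcoxon_exact",
    "paired_compare",
    "holm_adjust",
    "io_ratio",
    "mann_whitney",
    "pairwise_group_tests",
]

GROUPS = ("active_combined", "passive_1day", "passive_7day")

#: WHO/IUIS-listed airborne-allergen fungal genera examined in the workflow
ALLERGEN_GENERA = (
    "Alternaria",
    "Aspergillus",
    "Candida",
    "Cladosporium",
    "Curvularia",
    "Fusarium",
    "Penicillium",
    "Schizophyllum",
)

ALPHA = 0.05


@dataclass(frozen=True)
class PairedTestResult:
    metric: str
    location: str
    pair: tuple[str, str]
    test_used: str  # "paired_t" | "wilcoxon_exact"
    statistic: float
    p_raw: float
    p_holm: float
    n_pairs: int
    degenerate: bool = False


@dataclass(frozen=True)
class IORatioResult:
    residence_id: str
    metric: str
    group: str
    ratio: float | None
    invalid_reason: str | None = None  # "zero" | "undefined"

    @property
    def valid(self) -> bool:
        return self.ratio is not None


def coverage_exclude(
    design: pd.DataFrame, coverages: pd.Series, threshold: float = 0.975
) -> tuple[pd.DataFrame, list[str]]:
    """Residence-level exclusion below the coverage threshold.

    Any residence with at least one sample under the threshold is dropped in
    full — both locations, all groups — so that every retained residence
    contributes complete pairs. Returns (retained design, excluded residence
    ids). ``design`` needs columns sample_id, residence_id, location, group;
    ``coverages`` is indexed by sample_id and must cover every design sample.
    """
    missing = design.loc[~design["sample_id"].isin(coverages.index), "sample_id"]
    if len(missing):
        raise ValueError(f"samples without coverage values: {list(missing[:5])}")
    cov = coverages.loc[design["sample_id"]].to_numpy()
    bad = design.loc[cov < threshold, "residence_id"].unique()
    retained = design.loc[~design["residence_id"].isin(bad)].reset_index(drop=True)
    return retained, sorted(str(r) for r in bad)


def prevalence_filter(
    se_table: pd.DataFrame, min_fraction: float = 0.5
) -> list[str]:
    """Genera present (count > 0) in at least ceil(min_fraction * n) samples."""
    if not 0.0 < min_fraction <= 1.0:
        raise ValueError("min_fraction must be in (0, 1]")
    n_samples = se_table.shape[1]
    need = math.ceil(min_fraction * n_samples)
    present = (se_table > 0).sum(axis=1)
    return sorted(present.index[present >= need])


def log10_with_pseudocount(values, pseudocount: float = 1.0) -> np.ndarray:
    """log10(value + pseudocount); values must be non-negative."""
    x = np.asarray(values, dtype=float)
    if (x < 0).any():
        raise ValueError("abundances must be non-negative before log transform")
    return np.log10(x + pseudocount)


def _signed_rank_distribution(ranks: np.ndarray) -> tuple[np.ndarray, int]:
    """Exact null distribution of W+ over all 2^n sign assignments.

    Ranks may be mid-ranks (half-integers); they are doubled to integers and
    the distribution is built by dynamic programming, so the realized rank
    multiset — ties included — is enumerated exactly. Returns (counts over
    doubled-W values 0..sum, scale) where scale = 2.
    """
    doubled = np.rint(ranks * 2).astype(np.int64)
    total = int(doubled.sum())
    dist = np.zeros(total + 1, dtype=float)
    dist[0] = 1.0
    for r in doubled:
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[: total + 1 - r]
        dist = dist + shifted
    return dist, 2


def wilcoxon_exact(x: np.ndarray, y: np.ndarray) -> tuple[float, float, bool]:
    """Exact Wilcoxon signed-rank test on paired data.

    Zero differences are dropped before ranking; ties among |d| receive
    mid-ranks; the exact two-sided p enumerates every sign assignment of the
    realized rank multiset. Returns (W+, p, degenerate) where degenerate
    marks the all-differences-zero case (p = 1 by convention).
    """
    d = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    d = d[d != 0]
    if d.size == 0:
        return 0.0, 1.0, True
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    dist, scale = _signed_rank_distribution(ranks)
    total = dist.sum()
    w2 = int(round(w_plus * scale))
    p_low = dist[: w2 + 1].sum() / total
    p_high = dist[w2:].sum() / total
    p = min(1.0, 2.0 * min(p_low, p_high))
    return w_plus, float(p), False


def _variances_comparable(x: np.ndarray, y: np.ndarray, alpha: float) -> bool:
    """Two-sided F-ratio test of equal variances at level alpha."""
    vx, vy = np.var(x, ddof=1), np.var(y, ddof=1)
    if vx == 0 or vy == 0:
        return False
    f = vx / vy
    df = len(x) - 1
    p = 2.0 * min(stats.f.cdf(f, df, df), stats.f.sf(f, df, df))
    return p > alpha


def paired_compare(
    x,
    y,
    *,
    metric: str = "",
    location: str = "",
    pair: tuple[str, str] = ("", ""),
    alpha: float = ALPHA,
) -> PairedTestResult:
    """Compare two paired series, choosing paired t vs exact Wilcoxon.

    The gate: Shapiro-Wilk on the paired differences and an F-ratio test of
    variance equality between the series, both at ``alpha``; the paired t is
    used only when both pass, mirroring "normal and homoscedastic" as the
    simplest defensible reading. All-zero differences yield p = 1 with a
    degeneracy flag.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired series must have equal length")
    n = len(x)
    if n < 4:
        raise ValueError(f"need >= 4 pairs, got {n}")
    d = x - y
    if np.all(d == 0):
        return PairedTestResult(
            metric, location, pair, "wilcoxon_exact", 0.0, 1.0, 1.0, n, True
        )
    normal = np.std(d, ddof=1) > 0 and stats.shapiro(d).pvalue > alpha
    if normal and _variances_comparable(x, y, alpha):
        res = stats.ttest_rel(x, y)
        return PairedTestResult(
            metric, location, pair, "paired_t",
            float(res.statistic), float(res.pvalue), float(res.pvalue), n,
        )
    w, p, degen = wilcoxon_exact(x, y)
    return PairedTestResult(
        metric, location, pair, "wilcoxon_exact", w, p, p, n, degen
    )


def holm_adjust(p_raw) -> np.ndarray:
    """Holm step-down adjustment, returned in the input order."""
    p = np.asarray(p_raw, dtype=float)
    if p.size == 0:
        return p
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("p values must lie in (0, 1]")
    return multipletests(p, method="holm")[1]


def io_ratio(indoor: float, outdoor: float, **ids) -> IORatioResult:
    """Indoor/outdoor ratio on untransformed values.

    outdoor = 0 gives an undefined ratio; indoor = 0 gives a zero ratio;
    both are flagged invalid and excluded from rank comparisons.
    """
    if indoor < 0 or outdoor < 0:
        raise ValueError("values must be non-negative")
    ids.setdefault("residence_id", "")
    ids.setdefault("metric", "")
    ids.setdefault("group", "")
    if outdoor == 0:
        return IORatioResult(ratio=None, invalid_reason="undefined", **ids)
    if indoor == 0:
        return IORatioResult(ratio=None, invalid_reason="zero", **ids)
    return IORatioResult(ratio=indoor / outdoor, **ids)


_EXACT_MW_MAX_N = 20


def mann_whitney(x, y, method: str = "auto") -> tuple[float, float, str]:
    """Mann-Whitney U test between two independent samples.

    For combined n <= 20 (``method="auto"``) the two-sided p is exact,
    enumerating every split of the pooled mid-rank multiset; larger samples
    use the normal approximation with tie correction and continuity
    correction. ``method`` may force "exact" or "asymptotic". Returns
    (U for the first sample, p, method used).
    """
    if method not in ("auto", "exact", "asymptotic"):
        raise ValueError(f"unknown method {method!r}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be nonempty")
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    u1 = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2)
    if method == "exact" or (method == "auto" and n1 + n2 <= _EXACT_MW_MAX_N):
        lo = hi = 0
        n_splits = 0
        base = n1 * (n1 + 1) / 2
        for combo in itertools.combinations(range(n1 + n2), n1):
            u = ranks[list(combo)].sum() - base
            n_splits += 1
            if u <= u1 + 1e-9:
                lo += 1
            if u >= u1 - 1e-9:
                hi += 1
        p = min(1.0, 2.0 * min(lo, hi) / n_splits)
        return u1, float(p), "exact"
    mu = n1 * n2 / 2
    _, tie_counts = np.unique(pooled, return_counts=True)
    n = n1 + n2
    tie_term = (tie_counts**3 - tie_counts).sum() / (n * (n - 1))
    sigma2 = n1 * n2 / 12 * (n + 1 - tie_term)
    if sigma2 <= 0:
        return u1, 1.0, "asymptotic"
    z = (u1 - mu - math.copysign(0.5, u1 - mu)) / math.sqrt(sigma2) if u1 != mu else 0.0
    p = min(1.0, 2.0 * stats.norm.sf(abs(z)))
    return u1, float(p), "asymptotic"


def pairwise_group_tests(
    df: pd.DataFrame,
    *,
    metric: str,
    value_col: str = "value",
    groups: tuple[str, ...] = GROUPS,
    alpha: float = ALPHA,
) -> list[PairedTestResult]:
    """All pairwise group comparisons for one metric, stratified by location.

    ``df`` holds one row per (residence_id, location, group) with the metric
    value. Within each location the three group pairs form one Holm family;
    families are not pooled across locations or metrics.
    """
    results: list[PairedTestResult] = []
    for location, loc_df in df.groupby("location", sort=True):
        wide = loc_df.pivot(index="residence_id", columns="group", values=value_col)
        family: list[PairedTestResult] = []
        for g1, g2 in itertools.combinations(groups, 2):
            if g1 not in wide.columns or g2 not in wide.columns:
                continue
            both = wide[[g1, g2]].dropna()
            family.append(
                paired_compare(
                    both[g1].to_numpy(),
                    both[g2].to_numpy(),
                    metric=metric,
                    location=str(location),
                    pair=(g1, g2),
                    alpha=alpha,
                )
            )
        adjusted = holm_adjust([r.p_raw for r in family])
        for r, p_h in zip(family, adjusted):
            results.append(
                PairedTestResult(
                    r.metric, r.location, r.pair, r.test_used,
                    r.statistic, r.p_raw, float(p_h), r.n_pairs, r.degenerate,
                )
            )
    return results
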