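"""Sample-coverage estimation and coverage-based rarefaction.

Coverage is the fraction of the community's relative abundance represented by
the taxa detected in a sample, estimated from singleton/doubleton counts for
the reference sample and by hypergeometric interpolation for subsamples.
Standardizing samples to a common coverage (here 97.5%) rather than a common
size makes richness comparable across samples whose totals differ by orders
of magnitude, as active-impactor and passive-trap air samples do.

All binomial-coefficient ratios are evaluated in log-gamma space, so counts
up to several hundred thousand spore equivalents pose no overflow risk.
Extrapolation beyond the reference sample is deliberately not implemented;
samples whose reference coverage falls below the target are an exclusion
signal, not an estimation problem.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

__all__ = [
    "AbundanceVector",
    "CoverageResult",
    "CoverageBelowTargetError",
    "sample_coverage",
    "coverage_at_m",
    "rarefied_richness",
    "m_at_coverage",
    "rarefied_genus_abundance",
    "rarefaction_curve",
    "coverage_table",
]

TARGET_COVERAGE = 0.975


class CoverageBelowTargetError(ValueError):
    """Reference-sample coverage is below the requested target; the sample
    (and, by study rule, its residence) must be excluded rather than
    extrapolated."""


@dataclass(frozen=True)
class AbundanceVector:
    """Positive integer abundances of the genera present in one sample."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=np.int64)
        if c.size == 0:
            raise ValueError("abundance vector is empty")
        if (c <= 0).any():
            raise ValueError("abundance vector must contain positive counts only")
        object.__setattr__(self, "counts", c)

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def s_obs(self) -> int:
        return int(self.counts.size)

    @property
    def f1(self) -> int:
        return int((self.counts == 1).sum())

    @property
    def f2(self) -> int:
        return int((self.counts == 2).sum())


@dataclass(frozen=True)
class CoverageResult:
    """Coverage summary for one sample at a target coverage level."""

    coverage_ref: float
    target: float
    m: int
    richness_rarefied: float
    genus_rarefied: np.ndarray


def sample_coverage(v: AbundanceVector) -> float:
    """Reference-sample coverage from singletons and doubletons.

    C_hat = 1 - (f1/n) * (n-1) f1 / ((n-1) f1 + 2 f2); equals 1 when there
    are no singletons.
    """
    if v.f1 == 0:
        return 1.0
    n, f1, f2 = v.n, v.f1, v.f2
    if n == 1:
        return 0.0
    return 1.0 - (f1 / n) * ((n - 1) * f1) / ((n - 1) * f1 + 2 * f2)


def _log_binom(a: np.ndarray | float, m: int) -> np.ndarray:
    """log C(a, m) for integer a >= m >= 0."""
    a = np.asarray(a, dtype=float)
    return gammaln(a + 1.0) - gammaln(m + 1.0) - gammaln(a - m + 1.0)


def _binom_ratio(a: np.ndarray, b: int, m: int) -> np.ndarray:
    """C(a, m) / C(b, m), with terms where a < m contributing 0."""
    a = np.asarray(a, dtype=np.int64)
    out = np.zeros(a.shape, dtype=float)
    ok = a >= m
    if ok.any():
        out[ok] = np.exp(_log_binom(a[ok], m) - _log_binom(b, m))
    return out


def coverage_at_m(v: AbundanceVector, m: int) -> float:
    """Expected coverage of a size-m subsample (1 <= m <= n-1).

    C_hat(m) = 1 - sum_i (X_i/n) * C(n - X_i, m) / C(n - 1, m).
    """
    n = v.n
    if not 1 <= m <= n - 1:
        raise ValueError(f"m must be in [1, n-1] = [1, {n - 1}], got {m}")
    x = v.counts
    terms = (x / n) * _binom_ratio(n - x, n - 1, m)
    return float(1.0 - terms.sum())


def rarefied_richness(v: AbundanceVector, m: int) -> float:
    """Expected richness of a size-m subsample (Hurlbert interpolation).

    S(m) = S_obs - sum_i C(n - X_i, m) / C(n, m); S(1) = 1 and S(n) = S_obs.
    """
    n = v.n
    if not 1 <= m <= n:
        raise ValueError(f"m must be in [1, n] = [1, {n}], got {m}")
    absent = _binom_ratio(n - v.counts, n, m)
    return float(v.s_obs - absent.sum())


def _coverage_step(v: AbundanceVector, m: int) -> float:
    """Coverage as a function of m with m = n mapped to the reference
    estimator, the monotone function the subsample search runs over."""
    return sample_coverage(v) if m >= v.n else coverage_at_m(v, m)


def m_at_coverage(v: AbundanceVector, target: float = TARGET_COVERAGE) -> int:
    """Smallest integer m whose expected coverage reaches ``target``.

    Binary search over the nondecreasing coverage curve; m = n is allowed and
    maps to the reference-sample coverage. Raises CoverageBelowTargetError
    when even the full sample does not reach the target (extrapolation is out
    of scope by design).
    """
    if not 0.0 <= target <= 1.0:
        raise ValueError("target coverage must be in [0, 1]")
    cov_ref = sample_coverage(v)
    if cov_ref < target:
        raise CoverageBelowTargetError(
            f"reference coverage {cov_ref:.4f} < target {target}; sample must be excluded"
        )
    lo, hi = 1, v.n
    while lo < hi:
        mid = (lo + hi) // 2
        if _coverage_step(v, mid) >= target:
            hi = mid
        else:
            lo = mid + 1
    return lo


def rarefied_genus_abundance(R: np.ndarray, m: int) -> np.ndarray:
    """Per-genus rarefied spore equivalents R_i * m, left unrounded."""
    R = np.asarray(R, dtype=float)
    if m < 1:
        raise ValueError("m must be >= 1")
    if abs(R.sum() - 1.0) > 1e-9:
        raise ValueError("relative abundances must sum to 1")
    return R * float(m)


def rarefaction_curve(
    v: AbundanceVector,
    grid: np.ndarray | list[int],
    target: float = TARGET_COVERAGE,
) -> pd.DataFrame:
    """Rarefaction curve rows (m, richness, coverage) over a grid of sizes.

    The row nearest the subsample size at the target coverage is marked
    ``at_target`` (the cross mark on published curves); no mark is placed
    when the sample does not reach the target.
    """
    grid = np.unique(np.asarray(grid, dtype=np.int64))
    if grid.size and (grid[0] < 1 or grid[-1] > v.n):
        raise ValueError("grid values must lie within [1, n]")
    try:
        m_star: int | None = m_at_coverage(v, target)
    except CoverageBelowTargetError:
        m_star = None
    rows = [
        dict(
            m=int(m),
            richness=rarefied_richness(v, int(m)),
            coverage=_coverage_step(v, int(m)),
            at_target=(m_star is not None and int(m) == m_star),
        )
        for m in grid
    ]
    return pd.DataFrame(rows)


def coverage_table(
    se_table: pd.DataFrame, target: float = TARGET_COVERAGE
) -> pd.DataFrame:
    """Per-sample coverage summary for a genus x sample spore-equivalent table.

    Columns: sample_id, n, s_obs, f1, f2, coverage, m, richness_rarefied;
    m and richness are NaN for samples below the target coverage.
    """
    rows = []
    for sample_id in se_table.columns:
        col = se_table[sample_id]
        v = AbundanceVector(col[col > 0].to_numpy())
        cov = sample_coverage(v)
        try:
            m = m_at_coverage(v, target)
            rich = rarefied_richness(v, m)
        except CoverageBelowTargetError:
            m, rich = np.nan, np.nan
        rows.append(
            dict(
                sample_id=sample_id,
                n=v.n,
                s_obs=v.s_obs,
                f1=v.f1,
                f2=v.f2,
                coverage=cov,
                m=m,
                richness_rarefied=rich,
            )
        )
    return pd.DataFrame(rows)
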