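"""Genus-level aggregation and spore-equivalent integerization.

Amplicon counts give only relative composition; the qPCR total A (spore
equivalents) anchors them to an absolute scale. Multiplying relative
abundances R_i by A gives decimals, and rounding them up (to preserve rare
taxa as singletons, which plain rounding would erase) inflates the total by
up to one spore equivalent per present genus. The adjusted abundance

    A_adj = A - (sum_i ceil(R_i * A) - A)

pre-subtracts that ceiling inflation so that integer per-genus counts
``ceil(R_i * A_adj)`` sum close to A while every present genus keeps at
least one spore equivalent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "MISSING_TAXON",
    "DegenerateSampleError",
    "SporeEquivalentProfile",
    "normalize_taxonomy",
    "filter_and_aggregate",
    "relative_abundance",
    "adjusted_abundance",
    "spore_equivalent_counts",
    "make_profile",
    "combine_profiles",
]

#: canonical sentinel for a missing rank assignment
MISSING_TAXON = "unassigned"

#: input spellings normalized to the sentinel at read time
_MISSING_ALIASES = frozenset({"", "na", "nan", "none", "unidentified", "g__", "k__"})

RANKS = ("kingdom", "phylum", "class", "order", "family", "genus")


class DegenerateSampleError(ValueError):
    """Sample whose qPCR total is too small for its richness (A_adj <= 0)."""


@dataclass(frozen=True)
class SporeEquivalentProfile:
    """Per-sample absolute profile in spore equivalents.

    ``total`` is the qPCR abundance A (real-valued; never pre-rounded),
    ``relative`` the per-genus R_i over present genera, ``adjusted_total``
    A_adj, and ``counts`` the integer spore equivalents ceil(R_i * A_adj).
    """

    genera: tuple[str, ...]
    total: float
    relative: np.ndarray
    adjusted_total: float
    counts: np.ndarray

    @property
    def observed_richness(self) -> int:
        """S: number of genera present in the sample."""
        return len(self.genera)

    @property
    def inflation_pct(self) -> float:
        """Percent by which integer counts exceed the qPCR total A."""
        return (float(self.counts.sum()) - self.total) / self.total * 100.0


def normalize_taxonomy(taxonomy: pd.DataFrame) -> pd.DataFrame:
    """Map every missing-rank spelling to the single canonical sentinel.

    Expects a ``taxon_id`` column plus rank columns (kingdom..genus at
    minimum); extra ranks (species) are tolerated and ignored.
    """
    if "taxon_id" not in taxonomy.columns:
        raise ValueError("taxonomy table must have a taxon_id column")
    for rank in RANKS:
        if rank not in taxonomy.columns:
            raise ValueError(f"taxonomy table missing rank column '{rank}'")
    tax = taxonomy.copy()
    for rank in RANKS:
        col = tax[rank].astype(str).str.strip()
        tax[rank] = col.where(
            ~col.str.lower().isin(_MISSING_ALIASES), MISSING_TAXON
        )
    return tax


def filter_and_aggregate(
    asv_counts: pd.DataFrame, taxonomy: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Collapse an ASV table to genus level.

    Removes ASVs whose kingdom is not Fungi and ASVs with no genus
    assignment, then sums counts of ASVs sharing a genus. Returns the genus
    x sample table and a per-sample provenance frame (reads kept/removed,
    a ``flag`` marking samples left with zero counts — those are excluded
    downstream).

    Every ASV in ``asv_counts.index`` must have a taxonomy record.
    """
    tax = normalize_taxonomy(taxonomy).set_index("taxon_id")
    missing = asv_counts.index.difference(tax.index)
    if len(missing):
        raise ValueError(
            f"{len(missing)} ASVs lack taxonomy records, e.g. {list(missing[:3])}"
        )
    tax = tax.loc[asv_counts.index]
    keep = (tax["kingdom"] == "Fungi") & (tax["genus"] != MISSING_TAXON)

    total_in = asv_counts.sum(axis=0)
    kept_counts = asv_counts.loc[keep]
    genus_table = kept_counts.groupby(tax.loc[keep, "genus"]).sum()
    genus_table.index.name = "genus"
    genus_table = genus_table.sort_index()

    total_kept = genus_table.sum(axis=0).reindex(total_in.index, fill_value=0)
    provenance = pd.DataFrame(
        {
            "reads_in": total_in.astype(int),
            "reads_kept": total_kept.astype(int),
            "reads_removed": (total_in - total_kept).astype(int),
        }
    )
    provenance.index.name = "sample_id"
    provenance["flag"] = np.where(provenance["reads_kept"] == 0, "empty_after_filter", "")
    return genus_table, provenance


def relative_abundance(column: np.ndarray | pd.Series) -> np.ndarray:
    """R_i = X_i / n for one sample column; requires a positive column sum."""
    x = np.asarray(column, dtype=float)
    n = x.sum()
    if n <= 0:
        raise ValueError("cannot compute relative abundance of an all-zero column")
    if (x < 0).any():
        raise ValueError("counts must be non-negative")
    return x / n


def adjusted_abundance(R: np.ndarray, A: float, *, sample_id: str | None = None) -> float:
    """A_adj = A - (sum_i ceil(R_i * A) - A); all R_i must be > 0 and sum to 1."""
    R = np.asarray(R, dtype=float)
    if A <= 0:
        raise ValueError("total abundance A must be positive")
    if (R <= 0).any():
        raise ValueError("zero-abundance genera must be removed before adjustment")
    if abs(R.sum() - 1.0) > 1e-9:
        raise ValueError(f"relative abundances must sum to 1, got {R.sum()!r}")
    a_adj = A - (np.ceil(R * A).sum() - A)
    if a_adj <= 0:
        who = f" in sample {sample_id!r}" if sample_id else ""
        raise DegenerateSampleError(
            f"adjusted abundance {a_adj:.3g} <= 0{who}: qPCR total A={A:.3g} is "
            f"smaller than the observed richness S={len(R)}"
        )
    return float(a_adj)


def spore_equivalent_counts(R: np.ndarray, A_adj: float) -> np.ndarray:
    """Integer per-genus spore equivalents ceil(R_i * A_adj); min 1 per genus."""
    R = np.asarray(R, dtype=float)
    if A_adj <= 0:
        raise ValueError("A_adj must be positive")
    return np.ceil(R * A_adj).astype(np.int64)


def make_profile(
    genus_counts: pd.Series, total: float, *, sample_id: str | None = None
) -> SporeEquivalentProfile:
    """Build the full spore-equivalent profile for one sample column.

    Genera with zero reads in the sample are dropped from R first (S counts
    present genera only), then the adjusted-abundance transform is applied.
    """
    present = genus_counts[genus_counts > 0]
    if present.empty:
        raise ValueError(f"sample {sample_id!r} has no present genera")
    R = relative_abundance(present.to_numpy())
    a_adj = adjusted_abundance(R, total, sample_id=sample_id)
    counts = spore_equivalent_counts(R, a_adj)
    return SporeEquivalentProfile(
        genera=tuple(present.index),
        total=float(total),
        relative=R,
        adjusted_total=a_adj,
        counts=counts,
    )


def combine_profiles(
    p1: SporeEquivalentProfile, p2: SporeEquivalentProfile
) -> SporeEquivalentProfile:
    """Merge two same-site profiles (e.g. day-6 and day-7 active samples).

    Each day is integerized with its own qPCR total first, then the integer
    counts are summed over the union of genera; totals add and relative
    abundances are recomputed from the combined counts. (Summing raw reads
    first and applying a pooled total is a different quantity and is not
    offered.)
    """
    s1 = pd.Series(p1.counts, index=list(p1.genera), dtype=np.int64)
    s2 = pd.Series(p2.counts, index=list(p2.genera), dtype=np.int64)
    combined = s1.add(s2, fill_value=0).astype(np.int64).sort_index()
    combined = combined[combined > 0]
    total = p1.total + p2.total
    counts = combined.to_numpy()
    return SporeEquivalentProfile(
        genera=tuple(combined.index),
        total=float(total),
        relative=counts / counts.sum(),
        adjusted_total=p1.adjusted_total + p2.adjusted_total,
        counts=counts,
    )
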