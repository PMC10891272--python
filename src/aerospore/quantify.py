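"""qPCR standard-curve calibration and spore-equivalent quantification.

A universal fungal qPCR assay (ITS2) is calibrated against a dilution series
built from a counted quantity of conidia, so that a sample's threshold cycle
(C_T) maps to *spore equivalents per reaction*. The module fits the log-linear
standard curve, applies the replicate-SD quality rule, inverts the curve, and
back-calculates total spore equivalents per sample extract from the template
and elution volumes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "StandardPoint",
    "StandardCurve",
    "ReplicateSet",
    "SampleQuantity",
    "CalibrationError",
    "ReplicateQCError",
    "fit_standard_curve",
    "qc_replicates",
    "ct_to_quantity",
    "back_calculate_total",
    "process_plate",
    "read_plate",
]

#: default template volume per reaction, µL
TEMPLATE_VOLUME_UL = 2.0
#: default elution volume per sample extract, µL
ELUTION_VOLUME_UL = 50.0
#: replicate C_T standard-deviation threshold (cycles) triggering drop-one QC
SD_THRESHOLD = 0.2


class CalibrationError(ValueError):
    """Standard curve cannot be fitted (too few points, inverted slope...)."""


class ReplicateQCError(ValueError):
    """Replicate C_T set unusable (fewer than two finite values)."""


@dataclass(frozen=True)
class StandardPoint:
    """One standard well: known log10 quantity and its measured C_T."""

    log10_quantity: float
    ct: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.log10_quantity):
            raise ValueError("log10_quantity must be finite")
        if not (math.isfinite(self.ct) and self.ct > 0):
            raise ValueError("ct must be finite and positive")


@dataclass(frozen=True)
class StandardCurve:
    """Fitted log-linear calibration ``ct = intercept + slope * log10(q)``.

    ``efficiency`` is the per-cycle amplification gain minus one,
    ``10**(-1/slope) - 1``; 1.0 means perfect doubling-equivalent efficiency
    for a slope of -3.32.
    """

    slope: float
    intercept: float
    r_squared: float
    efficiency: float = field(init=False)

    def __post_init__(self) -> None:
        if self.slope >= 0:
            raise CalibrationError(
                f"standard-curve slope must be negative, got {self.slope:.4g} "
                "(check that quantities and C_T were not swapped)"
            )
        if not 0.0 <= self.r_squared <= 1.0 + 1e-12:
            raise CalibrationError(f"r_squared outside [0, 1]: {self.r_squared}")
        object.__setattr__(self, "efficiency", 10.0 ** (-1.0 / self.slope) - 1.0)

    def predict_ct(self, quantity: float) -> float:
        """C_T the curve predicts for a per-reaction quantity (> 0)."""
        if quantity <= 0:
            raise ValueError("quantity must be positive")
        return self.intercept + self.slope * math.log10(quantity)


@dataclass(frozen=True)
class ReplicateSet:
    """Replicate C_T values after the drop-one SD rule."""

    ct_values: tuple[float, ...]
    retained_mask: tuple[bool, ...]
    mean_ct: float
    sd_ct: float

    @property
    def n_retained(self) -> int:
        return sum(self.retained_mask)

    @property
    def dropped(self) -> bool:
        return self.n_retained < len(self.ct_values)


@dataclass(frozen=True)
class SampleQuantity:
    """Spore equivalents per reaction and per sample extract.

    ``total`` is the pre-integerization abundance A used downstream;
    ``per_microliter`` is the extract concentration (total / elution volume).
    """

    per_reaction: float
    total: float
    per_microliter: float
    sub_loq: bool = False


def fit_standard_curve(points: Sequence[StandardPoint]) -> StandardCurve:
    """Ordinary least squares of C_T on log10 quantity.

    Requires at least three standards spanning at least two decades. Standards
    that failed to amplify should be omitted from ``points`` (they carry no
    C_T), not imputed.
    """
    if len(points) < 3:
        raise CalibrationError(f"need >= 3 standard points, got {len(points)}")
    x = np.array([p.log10_quantity for p in points], dtype=float)
    y = np.array([p.ct for p in points], dtype=float)
    if np.ptp(x) < 2.0:
        raise CalibrationError(
            f"standards span only {np.ptp(x):.2f} decades; need >= 2"
        )
    res = stats.linregress(x, y)
    return StandardCurve(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
    )


def qc_replicates(
    ct_values: Sequence[float], sd_threshold: float = SD_THRESHOLD
) -> ReplicateSet:
    """Apply the drop-one rule: if replicate SD >= threshold, exclude the one
    value whose removal yields the lowest SD of the remaining pair.

    SD is the sample standard deviation (ddof=1). Pairs pass through untouched
    (nothing can be dropped while keeping two values). Ties between candidate
    drops are broken by dropping the highest C_T — late amplification is the
    common replicate failure mode — which is deterministic.
    """
    vals = np.asarray(ct_values, dtype=float)
    finite = np.isfinite(vals)
    if finite.sum() < 2:
        raise ReplicateQCError(
            f"need >= 2 finite C_T replicates, got {int(finite.sum())}"
        )
    mask = finite.copy()
    kept = vals[mask]
    sd_all = float(np.std(kept, ddof=1))
    if len(kept) >= 3 and sd_all >= sd_threshold:
        # leave-one-out over the finite replicates; candidates sorted so that
        # among equal SDs the drop of the highest C_T wins
        idx = np.flatnonzero(mask)
        best_sd, best_drop = math.inf, None
        for j in sorted(idx, key=lambda i: -vals[i]):
            loo = np.delete(vals[idx], np.flatnonzero(idx == j))
            sd = float(np.std(loo, ddof=1))
            if sd < best_sd - 1e-12:
                best_sd, best_drop = sd, j
        mask[best_drop] = False
        kept = vals[mask]
    return ReplicateSet(
        ct_values=tuple(float(v) for v in vals),
        retained_mask=tuple(bool(b) for b in mask),
        mean_ct=float(np.mean(kept)),
        sd_ct=float(np.std(kept, ddof=1)),
    )


def ct_to_quantity(mean_ct: float, curve: StandardCurve) -> float:
    """Invert the calibration: quantity = 10**((ct - intercept) / slope)."""
    if curve.slope >= 0:  # defensive; StandardCurve already enforces this
        raise CalibrationError("curve slope must be negative")
    return 10.0 ** ((mean_ct - curve.intercept) / curve.slope)


def back_calculate_total(
    per_reaction: float,
    template_volume: float = TEMPLATE_VOLUME_UL,
    elution_volume: float = ELUTION_VOLUME_UL,
    *,
    loq_per_reaction: float | None = None,
) -> SampleQuantity:
    """Scale a per-reaction quantity to the whole extract.

    total = per_reaction / template_volume * elution_volume. When
    ``loq_per_reaction`` is given (normally the lowest standard, 10**0),
    samples quantifying below it are flagged ``sub_loq`` but retained.
    """
    if template_volume <= 0 or elution_volume <= 0:
        raise ValueError("volumes must be positive")
    if per_reaction < 0:
        raise ValueError("per_reaction quantity must be non-negative")
    total = per_reaction / template_volume * elution_volume
    sub_loq = loq_per_reaction is not None and per_reaction < loq_per_reaction
    return SampleQuantity(
        per_reaction=float(per_reaction),
        total=float(total),
        per_microliter=float(total / elution_volume),
        sub_loq=sub_loq,
    )


def read_plate(path) -> pd.DataFrame:
    """Read a qPCR plate CSV.

    Columns: well_id, sample_id ("STANDARD" for standard wells),
    replicate_index, ct (empty = no amplification), log10_quantity (standards
    only).
    """
    plate = pd.read_csv(path, dtype={"sample_id": str})
    required = {"well_id", "sample_id", "replicate_index", "ct"}
    missing = required - set(plate.columns)
    if missing:
        raise ValueError(f"plate file missing columns: {sorted(missing)}")
    plate["ct"] = pd.to_numeric(plate["ct"], errors="coerce")
    return plate


def process_plate(
    plate: pd.DataFrame,
    template_volume: float = TEMPLATE_VOLUME_UL,
    elution_volume: float = ELUTION_VOLUME_UL,
    sd_threshold: float = SD_THRESHOLD,
) -> tuple[pd.DataFrame, StandardCurve]:
    """Full plate workflow: fit the curve on standard wells, QC sample
    replicates, and back-calculate totals.

    Returns a per-sample frame (sample_id, mean_ct, sd_ct, n_retained,
    per_reaction, total_spore_equivalents, flags) and the fitted curve. The
    curve is re-fitted per plate; there is no inter-plate normalization.
    Standard wells with no amplification are excluded from the fit.
    """
    is_std = plate["sample_id"].str.upper() == "STANDARD"
    std = plate.loc[is_std & plate["ct"].notna()]
    if "log10_quantity" not in plate.columns or std.empty:
        raise CalibrationError("plate has no amplifying STANDARD wells")
    points = [
        StandardPoint(float(r.log10_quantity), float(r.ct))
        for r in std.itertuples()
    ]
    curve = fit_standard_curve(points)
    loq = 10.0 ** float(std["log10_quantity"].min())

    rows = []
    for sample_id, grp in plate.loc[~is_std].groupby("sample_id", sort=True):
        flags: list[str] = []
        try:
            reps = qc_replicates(grp["ct"].tolist(), sd_threshold=sd_threshold)
        except ReplicateQCError:
            rows.append(
                dict(
                    sample_id=sample_id,
                    mean_ct=np.nan,
                    sd_ct=np.nan,
                    n_retained=int(grp["ct"].notna().sum()),
                    per_reaction=np.nan,
                    total_spore_equivalents=np.nan,
                    flags="qc_failed",
                )
            )
            continue
        if reps.dropped:
            flags.append("replicate_dropped")
        per_reaction = ct_to_quantity(reps.mean_ct, curve)
        sq = back_calculate_total(
            per_reaction,
            template_volume=template_volume,
            elution_volume=elution_volume,
            loq_per_reaction=loq,
        )
        if sq.sub_loq:
            flags.append("below_loq")
        rows.append(
            dict(
                sample_id=sample_id,
                mean_ct=reps.mean_ct,
                sd_ct=reps.sd_ct,
                n_retained=reps.n_retained,
                per_reaction=sq.per_reaction,
                total_spore_equivalents=sq.total,
                flags=";".join(flags),
            )
        )
    return pd.DataFrame(rows), curve
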