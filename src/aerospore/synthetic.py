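"""Synthetic bioaerosol studies with known ground truth.

Emulates a paired sampling design — residences sampled indoors and outdoors
with an active impactor (two repeated days, later combined) and with passive
settling traps deployed for one and for seven days — so that every pipeline
stage can be exercised end-to-end without external data and recovery of the
known truth can be measured.

The model: one regional genus pool with lognormal rank abundances; each
residence's outdoor community is a Dirichlet perturbation of the regional
mean, and its indoor community mixes the outdoor community with an
indoor-specific component, with per-genus indoor/outdoor effect factors
applied to designated allergenic genera. Spore capture is Poisson around a
method-and-duration expected load, read counts are multinomial at an
instrument-driven depth drawn independently of the load (this independence
is exactly why qPCR calibration is needed, and the simulator preserves it),
and triplicate C_T values invert the quantification module's calibration
with Gaussian noise plus occasional late-amplification outliers.

All randomness flows from one master seed through named substreams, so the
community, sampling and qPCR layers can be regenerated independently.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .compare import ALLERGEN_GENERA
from .quantify import (
    ELUTION_VOLUME_UL,
    TEMPLATE_VOLUME_UL,
    StandardCurve,
)

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "generate_community",
    "simulate_sample",
    "simulate_qpcr",
    "generate_study",
]

#: substream tags (kept below 2**31 so derived seeds stay in range)
_STREAMS = {"community": 101, "sampling": 202, "qpcr": 303}

#: physical samples collected per residence x location
SAMPLE_KINDS = (
    ("active", 6),
    ("active", 7),
    ("passive", 1),
    ("passive", 7),
)

_LOCATION_CODE = {"indoor": 0, "outdoor": 1}


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-design and noise parameters for one synthetic study.

    Defaults reproduce the magnitudes of a 12-residence indoor/outdoor
    campaign: a 1500-genus regional pool, amplicon depths of roughly
    7,400-35,300 reads per sample, and expected spore loads of about 21,000
    spore equivalents per active sampling day, 41,000 per 1-day passive trap
    and 115,000 per 7-day passive trap.
    """

    seed: int
    n_residences: int = 12
    n_genera_pool: int = 1500
    lognormal_meanlog: float = 0.0
    lognormal_sdlog: float = 2.5
    indoor_outdoor_overlap: float = 0.7
    allergen_io_effects: dict = field(
        default_factory=lambda: {"Aspergillus": 2.0, "Schizophyllum": 1.5}
    )
    method_load: dict = field(
        default_factory=lambda: {
            "active_day": 21_080.0,
            "passive_1day": 41_072.0,
            "passive_7day": 115_392.0,
        }
    )
    read_depth_range: tuple[int, int] = (7_432, 35_338)
    ct_sigma: float = 0.05
    outlier_rate: float = 0.1
    shallow_residences: tuple[int, ...] = ()
    shallow_load_factor: float = 0.03
    dirichlet_concentration: float = 5_000.0
    curve_slope: float = -3.321928
    curve_intercept: float = 40.0
    template_volume: float = TEMPLATE_VOLUME_UL
    elution_volume: float = ELUTION_VOLUME_UL
    n_contaminant_asvs: int = 40
    contaminant_read_fraction: float = 0.05

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if not 0.0 <= self.indoor_outdoor_overlap <= 1.0:
            raise ValueError("indoor_outdoor_overlap must be in [0, 1]")
        if any(v <= 0 for v in self.method_load.values()):
            raise ValueError("method loads must be positive")
        if self.read_depth_range[0] < 1:
            raise ValueError("read depth must be >= 1")

    @property
    def curve(self) -> StandardCurve:
        return StandardCurve(
            slope=self.curve_slope, intercept=self.curve_intercept, r_squared=1.0
        )


@dataclass(frozen=True)
class GroundTruth:
    """True community compositions and per-sample totals.

    ``communities``: rows (residence_id, location, genus, rel_abundance);
    ``samples``: rows (sample_id, true_total, expected_load, read_depth).
    """

    communities: pd.DataFrame
    samples: pd.DataFrame
    genus_pool: tuple[str, ...]


def _rng(cfg: SyntheticConfig, stream: str, *extra: int) -> np.random.Generator:
    """Generator for a named substream, independent of call order."""
    return np.random.default_rng(
        np.random.SeedSequence(cfg.seed, spawn_key=(_STREAMS[stream], *extra))
    )


def _genus_pool(cfg: SyntheticConfig) -> tuple[list[str], np.ndarray]:
    """Regional genus names and mean relative abundances.

    The allergenic genera are seeded into the pool with abundances boosted
    into the common range, so a realistic study detects them in most samples
    (as field studies of airborne allergenic fungi do).
    """
    rng = _rng(cfg, "community", 0)
    names = [f"Genus{i + 1:04d}" for i in range(cfg.n_genera_pool)]
    for i, genus in enumerate(ALLERGEN_GENERA[: cfg.n_genera_pool]):
        names[i] = genus
    weights = rng.lognormal(cfg.lognormal_meanlog, cfg.lognormal_sdlog, cfg.n_genera_pool)
    top = weights.max()
    n_allergen = min(len(ALLERGEN_GENERA), cfg.n_genera_pool)
    weights[:n_allergen] = top * rng.uniform(0.05, 0.5, n_allergen)
    return names, weights / weights.sum()


def generate_community(
    cfg: SyntheticConfig, residence: int, location: str
) -> np.ndarray:
    """True relative-abundance vector for one residence x location.

    The outdoor community is a Dirichlet draw around the regional mean; the
    indoor community mixes it with an indoor-specific Dirichlet draw at
    weight (1 - overlap) and applies the configured indoor/outdoor effect
    factors to allergenic genera before renormalizing.
    """
    if location not in _LOCATION_CODE:
        raise ValueError(f"unknown location {location!r}")
    names, regional = _genus_pool(cfg)
    alpha = regional * cfg.dirichlet_concentration + 1e-9
    out_rng = _rng(cfg, "community", residence + 1, _LOCATION_CODE["outdoor"])
    outdoor = out_rng.dirichlet(alpha)
    if location == "outdoor":
        return outdoor
    ov = cfg.indoor_outdoor_overlap
    if ov == 1.0:
        indoor = outdoor.copy()
    else:
        in_rng = _rng(cfg, "community", residence + 1, _LOCATION_CODE["indoor"])
        indoor = ov * outdoor + (1.0 - ov) * in_rng.dirichlet(alpha)
    touched = False
    for genus, factor in cfg.allergen_io_effects.items():
        if genus in names and factor != 1.0:
            indoor[names.index(genus)] *= factor
            touched = True
    if touched or ov < 1.0:
        indoor = indoor / indoor.sum()
    return indoor


def simulate_sample(
    truth: np.ndarray,
    total_load: float,
    depth: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, int]:
    """One physical sample: Poisson spore capture + multinomial reads.

    Returns (per-genus read counts summing to ``depth``, true total spores).
    """
    if total_load <= 0:
        raise ValueError("total_load must be positive")
    if depth < 1:
        raise ValueError("depth must be >= 1")
    true_total = int(rng.poisson(total_load))
    reads = rng.multinomial(depth, np.asarray(truth, dtype=float))
    return reads, true_total


def simulate_qpcr(
    true_total: float,
    curve: StandardCurve,
    ct_sigma: float,
    outlier_rate: float,
    rng: np.random.Generator,
    template_volume: float = TEMPLATE_VOLUME_UL,
    elution_volume: float = ELUTION_VOLUME_UL,
) -> np.ndarray:
    """Triplicate C_T values for a sample with a known spore total.

    Inverts the quantification arithmetic (per-reaction quantity =
    total x template / elution), predicts C_T from the calibration line,
    adds Gaussian cycle noise, and with probability ``outlier_rate`` shifts
    one replicate by +1.5 cycles to exercise the replicate-SD rule.
    """
    if true_total <= 0:
        raise ValueError("true_total must be positive")
    per_reaction = true_total * template_volume / elution_volume
    ct = curve.predict_ct(per_reaction) + rng.normal(0.0, ct_sigma, 3)
    if outlier_rate > 0 and rng.uniform() < outlier_rate:
        ct[rng.integers(3)] += 1.5
    return ct


def _sample_id(residence: int, location: str, method: str, day: int) -> str:
    loc = "in" if location == "indoor" else "out"
    if method == "active":
        return f"R{residence + 1:02d}_{loc}_act_d{day}"
    return f"R{residence + 1:02d}_{loc}_pas_{day}d"


def _expected_load(cfg: SyntheticConfig, residence: int, method: str, day: int) -> float:
    if method == "active":
        load = cfg.method_load["active_day"]
    elif day == 1:
        load = cfg.method_load["passive_1day"]
    else:
        load = cfg.method_load["passive_7day"]
    if residence in cfg.shallow_residences:
        load *= cfg.shallow_load_factor
    return load


def generate_study(
    cfg: SyntheticConfig, out_dir: str | Path | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Generate a complete study: metadata, ASV counts, taxonomy, qPCR plate.

    Each residence x location yields four physical samples (active day 6,
    active day 7, passive 1-day, passive 7-day). Each present genus is
    represented by one fungal ASV; a block of contaminant ASVs (non-fungal
    or missing a genus assignment) carries a small fraction of extra reads
    to exercise the taxonomy filters. Residences listed in
    ``cfg.shallow_residences`` receive loads scaled by
    ``cfg.shallow_load_factor`` so their samples fall below the coverage
    threshold downstream.

    Returns (metadata, asv_counts, taxonomy, qpcr_plate, ground_truth); when
    ``out_dir`` is given the four input files plus ground-truth CSVs are
    also written in the dialects the pipeline reads.
    """
    names, _ = _genus_pool(cfg)
    curve = cfg.curve
    meta_rows, truth_comm_rows, truth_sample_rows = [], [], []
    read_columns: dict[str, np.ndarray] = {}
    qpcr_rows = []

    # standard wells: 10^5 .. 10^0 spore equivalents per reaction, triplicate
    std_rng = _rng(cfg, "qpcr", 0)
    for log10_q in range(5, -1, -1):
        ct_pred = curve.intercept + curve.slope * log10_q
        for rep in range(3):
            qpcr_rows.append(
                dict(
                    well_id=f"STD{log10_q}_{rep + 1}",
                    sample_id="STANDARD",
                    replicate_index=rep + 1,
                    ct=round(ct_pred + std_rng.normal(0.0, cfg.ct_sigma), 4),
                    log10_quantity=log10_q,
                )
            )

    for residence in range(cfg.n_residences):
        for location in ("indoor", "outdoor"):
            truth = generate_community(cfg, residence, location)
            for genus, rel in zip(names, truth):
                if rel > 0:
                    truth_comm_rows.append(
                        dict(
                            residence_id=f"R{residence + 1:02d}",
                            location=location,
                            genus=genus,
                            rel_abundance=rel,
                        )
                    )
            for kind_idx, (method, day) in enumerate(SAMPLE_KINDS):
                sid = _sample_id(residence, location, method, day)
                s_rng = _rng(
                    cfg, "sampling", residence, _LOCATION_CODE[location], kind_idx
                )
                depth = int(s_rng.integers(*cfg.read_depth_range, endpoint=True))
                load = _expected_load(cfg, residence, method, day)
                reads, true_total = simulate_sample(truth, load, depth, s_rng)
                read_columns[sid] = reads
                q_rng = _rng(
                    cfg, "qpcr", 1 + residence, _LOCATION_CODE[location], kind_idx
                )
                ct = simulate_qpcr(
                    max(true_total, 1),
                    curve,
                    cfg.ct_sigma,
                    cfg.outlier_rate,
                    q_rng,
                    cfg.template_volume,
                    cfg.elution_volume,
                )
                for rep in range(3):
                    qpcr_rows.append(
                        dict(
                            well_id=f"{sid}_{rep + 1}",
                            sample_id=sid,
                            replicate_index=rep + 1,
                            ct=round(float(ct[rep]), 4),
                            log10_quantity=np.nan,
                        )
                    )
                meta_rows.append(
                    dict(
                        sample_id=sid,
                        residence_id=f"R{residence + 1:02d}",
                        location=location,
                        method=method,
                        day=day,
                    )
                )
                truth_sample_rows.append(
                    dict(
                        sample_id=sid,
                        true_total=true_total,
                        expected_load=load,
                        read_depth=depth,
                    )
                )

    # fungal ASVs: one per pool genus; contaminant block exercises filters
    asv_ids = [f"ASV{i + 1:05d}" for i in range(cfg.n_genera_pool)]
    counts = pd.DataFrame(read_columns, index=pd.Index(asv_ids, name="taxon_id"))
    tax_rows = [
        dict(
            taxon_id=asv,
            kingdom="Fungi",
            phylum="Ascomycota",
            **{r: f"{r[:1]}__{genus}" for r in ("class", "order", "family")},
            genus=genus,
            species="unidentified",
        )
        for asv, genus in zip(asv_ids, names)
    ]
    cont_rng = _rng(cfg, "sampling", 10_000)
    cont_ids = [f"ASVX{i + 1:04d}" for i in range(cfg.n_contaminant_asvs)]
    cont_cols = {}
    for sid in counts.columns:
        extra = int(cfg.contaminant_read_fraction * counts[sid].sum())
        cont_cols[sid] = cont_rng.multinomial(
            extra, np.full(cfg.n_contaminant_asvs, 1.0 / cfg.n_contaminant_asvs)
        )
    cont = pd.DataFrame(cont_cols, index=pd.Index(cont_ids, name="taxon_id"))
    for i, asv in enumerate(cont_ids):
        non_fungal = i % 2 == 0
        tax_rows.append(
            dict(
                taxon_id=asv,
                kingdom="Metazoa" if non_fungal else "Fungi",
                phylum="Arthropoda" if non_fungal else "Ascomycota",
                **{r: "unidentified" for r in ("class", "order", "family")},
                genus=f"Insecta{i}" if non_fungal else "",
                species="unidentified",
            )
        )
    counts = pd.concat([counts, cont])

    metadata = pd.DataFrame(meta_rows)
    taxonomy = pd.DataFrame(tax_rows)
    plate = pd.DataFrame(qpcr_rows)
    truth = GroundTruth(
        communities=pd.DataFrame(truth_comm_rows),
        samples=pd.DataFrame(truth_sample_rows),
        genus_pool=tuple(names),
    )

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        metadata.to_csv(out / "metadata.csv", index=False)
        counts.to_csv(out / "asv_counts.tsv", sep="\t")
        taxonomy.to_csv(out / "taxonomy.tsv", sep="\t", index=False)
        plate.to_csv(out / "qpcr_plate.csv", index=False)
        truth.communities.to_csv(out / "ground_truth_communities.csv", index=False)
        truth.samples.to_csv(out / "ground_truth_samples.csv", index=False)
    return metadata, counts, taxonomy, plate, truth


def config_from_dict(d: dict) -> SyntheticConfig:
    """Build a config from a plain dict (YAML-loaded), coercing list fields."""
    d = dict(d)
    for key in ("read_depth_range", "shallow_residences"):
        if key in d and d[key] is not None:
            d[key] = tuple(d[key])
    valid = {f.name for f in dataclasses.fields(SyntheticConfig)}
    unknown = set(d) - valid
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return SyntheticConfig(**d)
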