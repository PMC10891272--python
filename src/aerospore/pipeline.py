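"""End-to-end orchestration: quantify -> transform -> rarefy -> compare.

Given the four input files (ASV counts, taxonomy, qPCR plate, sample
metadata) the runner produces a deterministic results bundle: per-sample
spore-equivalent totals, the integer genus x sample spore-equivalent table,
coverage and rarefaction summaries, paired comparison results, and
indoor/outdoor ratio analyses, together with a manifest that reconciles
sample and genus counts across stages.
"""

from __future__ import annotations

import dataclasses
import hashlib
import itertools
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, abundance, compare, coverage, quantify

__all__ = ["RunConfig", "RunManifest", "ValidationError", "run", "validate_inputs"]

log = logging.getLogger("aerospore")


class ValidationError(ValueError):
    """Input files are inconsistent or malformed."""


@dataclass(frozen=True)
class RunConfig:
    """Paths and parameters for one pipeline run; defaults are the study's
    operating constants."""

    counts_path: str
    taxonomy_path: str
    plate_path: str
    metadata_path: str
    target_coverage: float = 0.975
    sd_threshold: float = 0.2
    template_volume: float = 2.0
    elution_volume: float = 50.0
    pseudocount: float = 1.0
    min_prevalence: float = 0.5
    allergens: tuple[str, ...] = compare.ALLERGEN_GENERA
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.target_coverage < 1.0:
            raise ValueError("target_coverage must be in (0, 1)")
        if self.template_volume <= 0 or self.elution_volume <= 0:
            raise ValueError("volumes must be positive")
        if not 0.0 < self.min_prevalence <= 1.0:
            raise ValueError("min_prevalence must be in (0, 1]")


@dataclass
class RunManifest:
    config_hash: str
    input_checksums: dict[str, str]
    version: str
    stage_counts: dict[str, dict[str, int]] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def _sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _config_hash(config: RunConfig) -> str:
    payload = json.dumps(
        {k: list(v) if isinstance(v, tuple) else v
         for k, v in dataclasses.asdict(config).items()},
        sort_keys=True,
    )
    return hashlib.sha256(payload.encode()).hexdigest()


def _read_inputs(config: RunConfig):
    counts = pd.read_csv(config.counts_path, sep="\t", index_col=0)
    counts.index = counts.index.astype(str)
    taxonomy = pd.read_csv(config.taxonomy_path, sep="\t", dtype=str, keep_default_na=False)
    plate = quantify.read_plate(config.plate_path)
    metadata = pd.read_csv(config.metadata_path, dtype=str)
    metadata["day"] = metadata["day"].astype(int)
    return counts, taxonomy, plate, metadata


def validate_inputs(config: RunConfig) -> list[str]:
    """Cross-file consistency checks; returns human-readable violations.

    Checks integer counts, duplicate ids, taxonomy completeness, standard
    span, metadata factor levels and sample-id agreement across files.
    """
    problems: list[str] = []
    counts, taxonomy, plate, metadata = _read_inputs(config)

    if counts.index.duplicated().any():
        dups = counts.index[counts.index.duplicated()].unique()
        problems.append(f"duplicate taxon ids in count table: {list(dups[:5])}")
    arr = counts.to_numpy()
    bad = np.argwhere((arr < 0) | (arr != np.floor(arr)))
    for r, c in bad[:10]:
        problems.append(
            f"non-integer or negative count at taxon {counts.index[r]!r}, "
            f"sample {counts.columns[c]!r}: {arr[r, c]}"
        )
    uncovered = counts.index.difference(taxonomy["taxon_id"])
    if len(uncovered):
        problems.append(f"taxa without taxonomy records: {list(uncovered[:5])}")
    std = plate.loc[plate["sample_id"].str.upper() == "STANDARD"]
    if std.empty:
        problems.append("qPCR plate has no STANDARD wells")
    elif "log10_quantity" not in plate.columns:
        problems.append("qPCR plate lacks log10_quantity for standards")
    else:
        span = std["log10_quantity"].astype(float)
        if span.max() - span.min() < 3:
            problems.append(
                f"standards span only {span.max() - span.min():.1f} decades (< 3)"
            )
    if metadata["sample_id"].duplicated().any():
        problems.append("duplicate sample ids in metadata")
    bad_loc = set(metadata["location"]) - {"indoor", "outdoor"}
    if bad_loc:
        problems.append(f"illegal location levels: {sorted(bad_loc)}")
    bad_method = set(metadata["method"]) - {"active", "passive"}
    if bad_method:
        problems.append(f"illegal method levels: {sorted(bad_method)}")

    in_counts = set(counts.columns)
    in_meta = set(metadata["sample_id"])
    plate_samples = set(plate.loc[plate["sample_id"].str.upper() != "STANDARD", "sample_id"])
    for name, only in (
        ("counts but not metadata", in_counts - in_meta),
        ("metadata but not counts", in_meta - in_counts),
        ("metadata but not qPCR plate", in_meta - plate_samples),
    ):
        if only:
            problems.append(f"samples in {name}: {sorted(only)[:5]}")
    return problems


def _analysis_group(method: str, day: int) -> str:
    if method == "active":
        return "active_combined"
    return f"passive_{day}day"


def _build_profiles(genus_table, totals, metadata):
    """Per-analysis-sample spore-equivalent profiles.

    Repeated active samples (days 6 and 7) are each integerized with their
    own qPCR total and then combined; passive samples map one-to-one.
    """
    totals_by_sample = totals.set_index("sample_id")["total_spore_equivalents"]
    profiles: dict[str, abundance.SporeEquivalentProfile] = {}
    design_rows = []
    meta = metadata.copy()
    meta["group"] = [
        _analysis_group(m, d) for m, d in zip(meta["method"], meta["day"])
    ]
    for (residence, location, group), grp in meta.groupby(
        ["residence_id", "location", "group"], sort=True
    ):
        loc = "in" if location == "indoor" else "out"
        analysis_id = f"{residence}_{loc}_{group}"
        parts = []
        for sid in sorted(grp["sample_id"]):
            if sid not in genus_table.columns:
                raise ValidationError(f"sample {sid!r} missing from count table")
            total = float(totals_by_sample.loc[sid])
            parts.append(abundance.make_profile(genus_table[sid], total, sample_id=sid))
        profile = parts[0]
        for extra in parts[1:]:
            profile = abundance.combine_profiles(profile, extra)
        profiles[analysis_id] = profile
        design_rows.append(
            dict(
                sample_id=analysis_id,
                residence_id=residence,
                location=location,
                group=group,
                n_source_samples=len(parts),
            )
        )
    return profiles, pd.DataFrame(design_rows)


def _se_table(profiles: dict[str, abundance.SporeEquivalentProfile]) -> pd.DataFrame:
    cols = {
        sid: pd.Series(p.counts, index=list(p.genera))
        for sid, p in profiles.items()
    }
    table = pd.DataFrame(cols).fillna(0).astype(np.int64).sort_index()
    table.index.name = "genus"
    return table


def run(config: RunConfig, out_dir: str | Path) -> RunManifest:
    """Execute the full workflow and write the results bundle.

    Outputs under ``out_dir``: totals.csv, se_table.tsv, coverage.csv,
    rarefied.csv, curves.csv, results/comparisons.csv,
    results/io_ratios.csv, results/io_tests.csv, manifest.json. Deterministic
    for fixed inputs and config. Fails fast (ValidationError) on
    inconsistent ids and names the offending stage on degenerate data.
    """
    problems = validate_inputs(config)
    if problems:
        raise ValidationError("; ".join(problems))
    out = Path(out_dir)
    (out / "results").mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config_hash=_config_hash(config),
        input_checksums={
            name: _sha256(getattr(config, f"{name}_path"))
            for name in ("counts", "taxonomy", "plate", "metadata")
        },
        version=__version__,
    )
    counts, taxonomy, plate, metadata = _read_inputs(config)

    # --- quantify ---------------------------------------------------------
    totals, curve = quantify.process_plate(
        plate,
        template_volume=config.template_volume,
        elution_volume=config.elution_volume,
        sd_threshold=config.sd_threshold,
    )
    totals.to_csv(out / "totals.csv", index=False)
    manifest.stage_counts["quantify"] = {
        "samples_in": int(len(totals)),
        "samples_quantified": int(totals["total_spore_equivalents"].notna().sum()),
    }
    log.info("quantify: %d samples, curve slope %.3f (R2 %.4f)",
             len(totals), curve.slope, curve.r_squared)

    # --- transform --------------------------------------------------------
    genus_table, provenance = abundance.filter_and_aggregate(counts, taxonomy)
    empty = provenance.index[provenance["flag"] == "empty_after_filter"]
    if len(empty):
        manifest.warnings.append(f"samples empty after taxonomy filter: {list(empty)}")
    profiles, design = _build_profiles(genus_table, totals, metadata)
    se_table = _se_table(profiles)
    se_table.to_csv(out / "se_table.tsv", sep="\t")
    summary = pd.DataFrame(
        [
            dict(
                sample_id=sid,
                total=p.total,
                adjusted_total=p.adjusted_total,
                observed_richness=p.observed_richness,
                inflation_pct=p.inflation_pct,
            )
            for sid, p in sorted(profiles.items())
        ]
    )
    summary.to_csv(out / "sample_summary.csv", index=False)
    manifest.stage_counts["transform"] = {
        "asvs_in": int(counts.shape[0]),
        "genera_out": int(se_table.shape[0]),
        "physical_samples_in": int(len(metadata)),
        "analysis_samples_out": int(len(design)),
    }

    # --- rarefy -----------------------------------------------------------
    cov = coverage.coverage_table(se_table, target=config.target_coverage)
    cov.to_csv(out / "coverage.csv", index=False)
    retained_design, excluded = compare.coverage_exclude(
        design, cov.set_index("sample_id")["coverage"], threshold=config.target_coverage
    )
    if excluded:
        manifest.warnings.append(f"residences excluded for low coverage: {excluded}")
    manifest.stage_counts["rarefy"] = {
        "analysis_samples_in": int(len(design)),
        "residences_excluded": int(len(excluded)),
        "analysis_samples_retained": int(len(retained_design)),
    }
    retained_ids = list(retained_design["sample_id"])
    se_retained = se_table[retained_ids]
    cov_retained = cov.set_index("sample_id").loc[retained_ids]

    # rarefied per-genus abundance R_i * m from the spore-equivalent vector
    rarefied_rows = []
    curve_rows = []
    for sid in retained_ids:
        col = se_retained[sid]
        present = col[col > 0]
        m = int(cov_retained.loc[sid, "m"])
        rare = coverage.rarefied_genus_abundance(
            present.to_numpy() / present.sum(), m
        )
        for genus, value in zip(present.index, rare):
            rarefied_rows.append(dict(sample_id=sid, genus=genus, rarefied_abundance=value))
        v = coverage.AbundanceVector(present.to_numpy())
        grid = np.unique(np.geomspace(1, v.n, 25).astype(np.int64))
        cdf = coverage.rarefaction_curve(v, grid, target=config.target_coverage)
        cdf.insert(0, "sample_id", sid)
        curve_rows.append(cdf)
    rarefied = pd.DataFrame(rarefied_rows)
    rarefied.to_csv(out / "rarefied.csv", index=False)
    pd.concat(curve_rows, ignore_index=True).to_csv(out / "curves.csv", index=False)

    # --- compare ----------------------------------------------------------
    genera_prevalent = compare.prevalence_filter(se_retained, config.min_prevalence)
    allergens = [g for g in config.allergens if g in genera_prevalent]
    manifest.stage_counts["compare"] = {
        "genera_prevalent": int(len(genera_prevalent)),
        "allergen_genera": int(len(allergens)),
        "retained_residences": int(retained_design["residence_id"].nunique()),
    }

    meta_cols = retained_design.set_index("sample_id")[
        ["residence_id", "location", "group"]
    ]
    rich = cov_retained["richness_rarefied"].rename("value").to_frame().join(meta_cols)
    results = compare.pairwise_group_tests(
        rich.reset_index(), metric="rarefied_richness", alpha=config.alpha
    )
    rare_wide = rarefied.pivot(index="genus", columns="sample_id", values="rarefied_abundance")
    rare_wide = rare_wide.reindex(columns=retained_ids).fillna(0.0)
    for genus in allergens:
        vals = compare.log10_with_pseudocount(
            rare_wide.loc[genus].to_numpy(), config.pseudocount
        )
        df = pd.DataFrame(
            dict(sample_id=retained_ids, value=vals)
        ).join(meta_cols, on="sample_id")
        results.extend(
            compare.pairwise_group_tests(
                df, metric=f"rarefied_abundance_{genus}", alpha=config.alpha
            )
        )
    results_df = pd.DataFrame(
        [
            dict(
                metric=r.metric,
                location=r.location,
                group_1=r.pair[0],
                group_2=r.pair[1],
                test_used=r.test_used,
                statistic=r.statistic,
                p_raw=r.p_raw,
                p_holm=r.p_holm,
                n_pairs=r.n_pairs,
                degenerate=r.degenerate,
            )
            for r in results
        ]
    )
    results_df.to_csv(out / "results" / "comparisons.csv", index=False)

    # indoor/outdoor ratios on untransformed values
    io_rows = []
    metrics = {"rarefied_richness": cov_retained["richness_rarefied"]}
    for genus in allergens:
        metrics[f"rarefied_abundance_{genus}"] = rare_wide.loc[genus]
    lookup = meta_cols.reset_index().set_index(["residence_id", "location", "group"])["sample_id"]
    for metric_name, series in metrics.items():
        for (residence, group), _ in retained_design.groupby(["residence_id", "group"]):
            try:
                sid_in = lookup.loc[(residence, "indoor", group)]
                sid_out = lookup.loc[(residence, "outdoor", group)]
            except KeyError:
                continue
            r = compare.io_ratio(
                float(series.get(sid_in, 0.0)),
                float(series.get(sid_out, 0.0)),
                residence_id=residence,
                metric=metric_name,
                group=group,
            )
            io_rows.append(
                dict(
                    residence_id=r.residence_id,
                    metric=r.metric,
                    group=r.group,
                    ratio=r.ratio,
                    invalid_reason=r.invalid_reason or "",
                )
            )
    io_df = pd.DataFrame(io_rows)
    io_df.to_csv(out / "results" / "io_ratios.csv", index=False)

    io_test_rows = []
    for metric_name, mdf in io_df.groupby("metric", sort=True):
        valid = mdf[mdf["invalid_reason"] == ""]
        for g1, g2 in itertools.combinations(compare.GROUPS, 2):
            x = valid.loc[valid["group"] == g1, "ratio"].to_numpy(dtype=float)
            y = valid.loc[valid["group"] == g2, "ratio"].to_numpy(dtype=float)
            if x.size == 0 or y.size == 0:
                io_test_rows.append(
                    dict(metric=metric_name, group_1=g1, group_2=g2,
                         u_statistic=np.nan, p=np.nan, method="skipped_empty_group")
                )
                continue
            u, p, method = compare.mann_whitney(x, y)
            io_test_rows.append(
                dict(metric=metric_name, group_1=g1, group_2=g2,
                     u_statistic=u, p=p, method=method)
            )
    pd.DataFrame(io_test_rows).to_csv(out / "results" / "io_tests.csv", index=False)

    (out / "manifest.json").write_text(manifest.to_json() + "\n")
    return manifest
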