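"""Shared fixtures: synthetic studies at two sizes.

The small study keeps unit/pipeline tests fast; the full-design study
(12 residences, two of them shallow) reproduces the complete sampling
scheme and is shared across the tests that need it.
"""

from __future__ import annotations

import pytest

from aerospore import pipeline, synthetic


@pytest.fixture(scope="session")
def small_config() -> synthetic.SyntheticConfig:
    return synthetic.SyntheticConfig(
        seed=7,
        n_residences=4,
        n_genera_pool=300,
        read_depth_range=(4_000, 8_000),
        method_load={
            "active_day": 8_000.0,
            "passive_1day": 15_000.0,
            "passive_7day": 40_000.0,
        },
    )


@pytest.fixture(scope="session")
def small_study(small_config, tmp_path_factory):
    out = tmp_path_factory.mktemp("small_study")
    synthetic.generate_study(small_config, out_dir=out)
    return out


@pytest.fixture(scope="session")
def full_config() -> synthetic.SyntheticConfig:
    # the complete design: 12 residences x 2 locations x 4 physical samples,
    # residences 3 and 7 generated shallow so they fail the coverage filter
    return synthetic.SyntheticConfig(seed=1, shallow_residences=(2, 6))


@pytest.fixture(scope="session")
def full_study(full_config, tmp_path_factory):
    """(input dir, ground truth) for the full 12-residence design."""
    out = tmp_path_factory.mktemp("full_study")
    *_, truth = synthetic.generate_study(full_config, out_dir=out)
    return out, truth


@pytest.fixture(scope="session")
def full_study_run(full_study, tmp_path_factory):
    """Pipeline results bundle for the full-design study."""
    study_dir, _ = full_study
    out = tmp_path_factory.mktemp("full_run")
    config = pipeline.RunConfig(
        counts_path=str(study_dir / "asv_counts.tsv"),
        taxonomy_path=str(study_dir / "taxonomy.tsv"),
        plate_path=str(study_dir / "qpcr_plate.csv"),
        metadata_path=str(study_dir / "metadata.csv"),
    )
    manifest = pipeline.run(config, out)
    return out, manifest
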