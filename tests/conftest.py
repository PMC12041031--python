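"""Shared fixtures: synthetic quarterly-file sets and in-memory cohorts.

Everything is generated at test time from the synthetic-report module;
no data files ship with the package.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pytest

from faersignal.cohort import build_cohort, deduplicate, load_drug_dictionary
from faersignal.faers_io import load_quarters
from faersignal.synth import (SynthConfig, cases_to_reports, generate,
                              generate_cases, make_validation_fixture)

logging.disable(logging.INFO)


@pytest.fixture(scope="session")
def small_config() -> SynthConfig:
    """2,000 cases over 2 quarters with 10% duplicate versions."""
    return SynthConfig(seed=11, n_cases=2000, n_quarters=2)


@pytest.fixture(scope="session")
def small_synth_dir(tmp_path_factory, small_config):
    out = tmp_path_factory.mktemp("synth_small")
    manifest = generate(small_config, out)
    return out, manifest


@pytest.fixture(scope="session")
def small_quarters(small_synth_dir, small_config):
    out, _ = small_synth_dir
    return load_quarters(out, small_config.quarter_labels)


@pytest.fixture(scope="session")
def small_cohort(small_synth_dir, small_quarters):
    out, _ = small_synth_dir
    demo = [r for q in small_quarters for r in q.rows_by_table["DEMO"]]
    dedup_map = deduplicate(demo)
    dictionary = load_drug_dictionary(Path(out) / "target_drugs.txt")
    return build_cohort(small_quarters, dedup_map, dictionary)


@pytest.fixture(scope="session")
def big_cohort():
    """Default-condition cohort (20k cases) via the fast in-memory path."""
    cases, manifest = generate_cases(SynthConfig(seed=5))
    return cases_to_reports(cases), manifest


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    out = tmp_path_factory.mktemp("validation_fixture")
    manifest = make_validation_fixture(out)
    return out, manifest


@pytest.fixture(scope="session")
def fixture_cohort(fixture_dir):
    out, _ = fixture_dir
    quarters = load_quarters(out, ["2022Q1", "2022Q2"])
    demo = [r for q in quarters for r in q.rows_by_table["DEMO"]]
    dictionary = load_drug_dictionary(Path(out) / "target_drugs.txt")
    return build_cohort(quarters, deduplicate(demo), dictionary)
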