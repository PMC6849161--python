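"""Shared fixtures: a cached pipeline config, reference rows, helpers."""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import pytest

from neurolabel import (
    GeneratorSpec,
    PipelineConfig,
    annotate,
    generate,
    run_pipeline,
)

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def config() -> PipelineConfig:
    cfg = PipelineConfig()
    cfg.resources()  # pre-load lexicons once for the whole session
    return cfg


@pytest.fixture(scope="session")
def annotate_fn(config):
    def fn(text: str, report_id: str = "report"):
        return annotate(text, report_id=report_id, config=config)

    return fn


@pytest.fixture(scope="session")
def prf_rows() -> pd.DataFrame:
    return pd.read_csv(DATA_DIR / "prf_reference.csv")


@pytest.fixture(scope="session")
def synth_batch(config):
    """A generated batch with its pipeline annotations (seed fixed)."""
    reports = generate(GeneratorSpec(seed=7, n_reports=30))
    gold = [r.gold for r in reports]
    pred = run_pipeline([(r.report_id, r.text) for r in reports], config)
    return gold, pred
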