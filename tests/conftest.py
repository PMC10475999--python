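"""Shared fixtures: small synthetic cohorts and hand-built tables."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True, database=None)
settings.load_profile("repro")

from vpdpheno.synthetic import (CohortConfig, GroupSpec, NoiseSpec,
                                default_config, generate_cohort)


def make_steady(rows):
    """Build a steady-state table from (plant, accession, level, vpd,
    gs, e, a) tuples."""
    df = pd.DataFrame(rows, columns=["plant", "accession", "level",
                                     "vpd", "gs", "e", "a"])
    df["iwue"] = df["a"] / df["gs"]
    df["missing"] = False
    return df


@pytest.fixture(scope="session")
def noiseless_cohort():
    """One accession per archetype, 3 plants, zero noise, instant
    relaxation: the pipeline should recover truth exactly."""
    cfg = replace(
        CohortConfig(
            groups=(GroupSpec("I", 1, 3), GroupSpec("II", 1, 3),
                    GroupSpec("III", 1, 3)),
            noise=NoiseSpec(0.0, 0.0, 0.0, 0.0, 0.0),
            seed=3,
        ),
        tau_min=1e-9,
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def default_cohort():
    """The standard 9-accession cohort at default noise."""
    return generate_cohort(default_config(seed=5))


@pytest.fixture(scope="session")
def default_results(default_cohort):
    from vpdpheno.pipeline import PipelineConfig, run_pipeline

    return run_pipeline(default_cohort.gas_series,
                        default_cohort.balance_series,
                        default_cohort.leaf_design,
                        default_cohort.chamber_design,
                        PipelineConfig(n_restarts=200))
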