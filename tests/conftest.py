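"""Shared fixtures: a small simulated study and a full pipeline run.

Everything is generated at test time from fixed seeds; nothing is stored on
disk in the repository.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from novelmine import pipeline, simulate

settings.register_profile("derandomized", deadline=None, derandomize=True)
settings.load_profile("derandomized")


def small_config(**overrides) -> simulate.SimulationConfig:
    """A scaled-down study for fast unit tests (300 kb, 4 gaps, 2+2 novel)."""
    base = dict(
        seed=11,
        genome_length=300_000,
        n_gaps=4,
        n_novel_at_gap=2,
        n_novel_nongap=2,
        novel_length_range=(800, 1500),
        coverage=10.0,
        base_error_rate=0.002,
        n_samples=2,
        n_genes=8,
    )
    base.update(overrides)
    return simulate.SimulationConfig(**base)


@pytest.fixture(scope="session")
def small_sim():
    cfg = small_config()
    ref = simulate.build_reference(cfg)
    donor, truth = simulate.build_donor(ref, cfg)
    return cfg, ref, donor, truth


@pytest.fixture(scope="session")
def small_pipeline(tmp_path_factory):
    """A complete pipeline run on the small study; shared across tests."""
    outdir = str(tmp_path_factory.mktemp("small_pipeline"))
    cfg = small_config()
    summary = pipeline.run_all(cfg, outdir)
    return cfg, outdir, summary


@pytest.fixture(scope="session")
def study_pipeline(tmp_path_factory):
    """The standard study conditions (2 Mb, 10 gaps, 5+5 novel, 3 samples).

    This is the expensive end-to-end fixture; it is shared by the
    acceptance-level tests.
    """
    outdir = str(tmp_path_factory.mktemp("study_pipeline"))
    cfg = simulate.SimulationConfig(seed=20260923)
    summary = pipeline.run_all(cfg, outdir)
    return cfg, outdir, summary


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
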