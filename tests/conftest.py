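"""Shared fixtures: one small synthetic study bundle plus its pipeline run.

The bundle is deliberately smaller than the generator defaults so the whole
suite stays fast; tests that need the default study conditions build their
own bundles.
"""

from __future__ import annotations

import numpy as np
import pytest

from mirwood.pipeline import run_pipeline
from mirwood.simulate import SimulationConfig, simulate_dataset

SMALL = dict(
    seed=11,
    genome_length=250_000,
    n_genes=100,
    n_novel_hairpins=5,
    n_known_mirnas=16,
    library_depth=8_000,
    n_de_mirnas=6,
    mrna_library_depth=400_000,
)


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(**SMALL)


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory, small_config):
    outdir = tmp_path_factory.mktemp("bundle")
    paths, truth = simulate_dataset(small_config, outdir)
    return outdir, paths, truth


@pytest.fixture(scope="session")
def small_run(tmp_path_factory, small_bundle):
    bundle_dir, _paths, truth = small_bundle
    outdir = tmp_path_factory.mktemp("results")
    result = run_pipeline(bundle_dir, outdir)
    return result, truth, outdir


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
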