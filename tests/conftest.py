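"""Shared fixtures: small synthetic configurations sized for fast tests.

The "small" genome keeps the default structure (8 somatic chromosomes, 6
germline scaffolds, 20% germline content, same depth model) at 2 Mb with
proportionally fewer genes, so every downstream stage sees the same
statistical regime as the full-size default at a fraction of the cost.
"""

from __future__ import annotations

import numpy as np
import pytest

from germscan.config import RunConfig
from germscan.simulate import FullSimConfig, TruthBundle, generate_bundle


def small_config(**kwargs) -> FullSimConfig:
    cfg = FullSimConfig(**kwargs)
    cfg.genome.total_length = 2_000_000
    cfg.genome.n_somatic_genes = 400
    cfg.genome.n_gsr_families = 10
    cfg.genome.gene_length_range = (1_000, 2_000)
    return cfg


def null_config(**kwargs) -> FullSimConfig:
    """No elimination, sex-symmetric expression."""
    cfg = small_config(**kwargs)
    cfg.depth.lambda_r = cfg.depth.lambda_s
    cfg.expression.sex_symmetric = True
    return cfg


@pytest.fixture(scope="session")
def small_bundle() -> TruthBundle:
    return generate_bundle(small_config(embryo=True), seed=11)


@pytest.fixture(scope="session")
def small_run_config() -> RunConfig:
    return RunConfig(seed=11, simulate=small_config(embryo=True))


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(202609)
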