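from __future__ import annotations

import pytest

from dietmap.io import default_sfq_path, read_sfq_definition
from dietmap.matching import build_mapping_table
from dietmap.simulate import SynthConfig, generate_catalogue, generate_diary, generate_sfq_definition


@pytest.fixture(scope="session")
def sfq_groups():
    return read_sfq_definition(default_sfq_path())


@pytest.fixture(scope="session")
def small_cfg():
    """Scaled-down study: same structure, fewer codes and subjects."""
    return SynthConfig(n_codes=120, n_groups=24, n_subjects=12, n_days=4, seed=11)


@pytest.fixture(scope="session")
def small_world(small_cfg):
    catalogue, truth = generate_catalogue(small_cfg)
    diary = generate_diary(small_cfg, catalogue, truth)
    sfq = generate_sfq_definition(small_cfg)
    return small_cfg, catalogue, truth, diary, sfq


@pytest.fixture(scope="session")
def small_mapping(small_world):
    _, catalogue, _, _, sfq = small_world
    return build_mapping_table(catalogue, sfq)
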