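import numpy as np
import pandas as pd
import pytest

from rigmeth import preprocess, synth
from rigmeth.config import CNVPlant, PipelineConfig, SynthConfig


def small_config(seed: int = 7, **overrides) -> SynthConfig:
    """Desk-scale cohort: three classes, a few thousand probes."""
    kwargs = dict(
        seed=seed,
        n_probes=4000,
        n_negative_controls=30,
        n_normalization_controls=10,
        ref_class_counts={"pedGBM_RTK1": 6, "PXA": 6, "DMG_K27": 6},
        query_class_counts={"pedGBM_RTK1": 4, "PXA": 2},
        signature_size=80,
    )
    kwargs.update(overrides)
    return SynthConfig(**kwargs)


@pytest.fixture(scope="session")
def small_cfg() -> SynthConfig:
    cfg = small_config()
    cfg.cnv_plants = [
        CNVPlant("RIG_01", "4", 3_800_000, 4_600_000, 8),
        CNVPlant("RIG_01", "13", 4_000_000, 10_000_000, 1),
        CNVPlant("RIG_02", "9", 1_000_000, 1_800_000, 0),
    ]
    return cfg


@pytest.fixture(scope="session")
def small_manifest(small_cfg) -> pd.DataFrame:
    return synth.make_manifest(small_cfg)


@pytest.fixture(scope="session")
def small_cohort(small_cfg, small_manifest):
    return synth.simulate_cohort(small_cfg, small_manifest)


@pytest.fixture(scope="session")
def small_norm(small_cfg, small_manifest, small_cohort):
    data, _ = small_cohort
    return preprocess.normalize(data, small_manifest, PipelineConfig())


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260)
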