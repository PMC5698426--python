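import numpy as np
import pandas as pd
import pytest

from gatkcan.estimators import PSOConfig, SearchSpace
from gatkcan.features import build_feature_frame
from gatkcan.simulate import CohortSpec, generate_catalog, simulate_cohort


@pytest.fixture(scope="session")
def small_catalog():
    return generate_catalog(CohortSpec().genome, 500, seed=3)


@pytest.fixture(scope="session")
def small_cohort_frame(small_catalog):
    """Labeled 10-tumor feature frame at reduced per-tumor counts."""
    spec = CohortSpec(n_true_mutations=10, n_artifacts=40, seed=5)
    calls, truth, stages = simulate_cohort(spec, small_catalog)
    return build_feature_frame(calls, small_catalog, truth=truth, stages=stages)


@pytest.fixture()
def fast_cfg():
    return PSOConfig(n_particles=60, n_generations=15, seed=11)


@pytest.fixture()
def tiny_space():
    """Enumerable search space (few segments per statistic)."""
    return SearchSpace(
        {
            "dnm_min": (1.0, 2000.0, 8),
            "fs_max": (0.0, 100.0, 6),
            "mq_min": (0.0, 70.0, 5),
            "mq_rank_sum_min": (-20.0, 10.0, 6),
            "qd_min": (0.0, 4.0, 5),
            "mw_p_min": (0.001, 0.3, 4),
        }
    )


def random_feature_frame(rng: np.random.Generator, n: int, with_labels: bool = False):
    """Random (not class-separated) feature rows for rule-equivalence checks."""
    df = pd.DataFrame(
        {
            "qd": rng.uniform(0, 6, n),
            "fs": rng.uniform(0, 120, n),
            "mq": rng.uniform(20, 70, n),
            "mq_rank_sum": rng.uniform(-20, 5, n),
            "read_pos_rank_sum": rng.uniform(-15, 5, n),
            "dnm": rng.integers(1, 50_000, n).astype(float),
            "mw_p": rng.uniform(0, 1, n),
        }
    )
    for col in ("mq_rank_sum", "read_pos_rank_sum", "mw_p"):
        df.loc[rng.random(n) < 0.1, col] = np.nan
    if with_labels:
        df["label"] = rng.integers(0, 2, n)
    return df
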