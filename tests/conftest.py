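import numpy as np
import pytest

from rankscreen import RankingGroup, SyntheticConfig, gen_benchmark


@pytest.fixture(scope="session")
def small_benchmark():
    """A small synthetic benchmark shared by read-only tests."""
    config = SyntheticConfig(
        n_targets=6,
        n_compounds_per_target=20,
        n_families=3,
        noise_sd=0.5,
        seed=7,
    )
    dataset, family_map, ground_truth = gen_benchmark(config)
    return dataset, family_map, ground_truth


def random_group(rng: np.random.Generator, n=10, dim=4, target_id="T") -> RankingGroup:
    """A random query group with grades guaranteed non-constant for n >= 2."""
    grades = rng.integers(0, 5, size=n)
    if n >= 2 and len(set(grades.tolist())) == 1:
        grades[0] = (grades[0] + 1) % 5
    return RankingGroup(
        target_id=target_id,
        features=rng.normal(size=(n, dim)),
        grades=grades,
        compound_ids=[f"{target_id}_c{i:03d}" for i in range(n)],
    )
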