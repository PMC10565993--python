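import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from imprintkit.io import MethylomeTable
from imprintkit.simulate import SimConfig, generate_annotation

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=30,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_config() -> SimConfig:
    return SimConfig(seed=1)


@pytest.fixture(scope="session")
def annotation(default_config):
    return generate_annotation(default_config)


def make_table(pos, ratios_by_sample, chrom="chr1", denom=1000):
    """Table whose per-sample ratios equal round(r*denom)/denom exactly."""
    counts = {}
    for s, ratios in ratios_by_sample.items():
        m = np.array([int(round(r * denom)) for r in ratios])
        counts[s] = (m, denom - m)
    return MethylomeTable.from_arrays([chrom] * len(pos), pos, counts)


def random_table(rng, n=40, n_per_group=2, denom=1000, block_signal=True):
    """Random two-group table with occasional planted contrast blocks."""
    gaps = rng.choice([40, 80, 150, 299, 300, 600], size=n - 1,
                      p=[0.35, 0.25, 0.2, 0.08, 0.06, 0.06])
    pos = np.concatenate([[100], 100 + np.cumsum(gaps)])
    base = rng.random(n)
    diff = np.zeros(n)
    if block_signal and rng.random() < 0.7:
        i = rng.integers(0, max(1, n - 12))
        j = min(n, i + rng.integers(8, 25))
        diff[i:j] = rng.uniform(-0.6, 0.6)
    ratios = {}
    for g, sign in (("A", 1), ("B", -1)):
        for k in range(n_per_group):
            noise = rng.normal(0, 0.03, n)
            r = np.clip(base + sign * diff / 2 + noise, 0, 1)
            ratios[f"{g}{k + 1}"] = r
    table = make_table(pos, ratios, denom=denom)
    groups = {
        "A": [f"A{k + 1}" for k in range(n_per_group)],
        "B": [f"B{k + 1}" for k in range(n_per_group)],
    }
    return table, groups


def brute_force_regions(pos, mean_a, mean_b, max_gap=300, min_cpgs=11, min_diff=0.2):
    """Independent oracle: all inclusion-maximal qualifying contiguous runs."""
    n = len(pos)
    qualifying = []
    for i in range(n):
        for j in range(i + min_cpgs - 1, n):
            if any(pos[k + 1] - pos[k] >= max_gap for k in range(i, j)):
                continue
            d = sum(mean_a[k] - mean_b[k] for k in range(i, j + 1)) / (j - i + 1)
            if abs(d) > min_diff:
                qualifying.append((i, j))
    maximal = [
        (i, j)
        for (i, j) in qualifying
        if not any(
            i2 <= i and j2 >= j and (i2, j2) != (i, j) for (i2, j2) in qualifying
        )
    ]
    return sorted(maximal)
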