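import numpy as np
import pytest

from chemnuc import synthetic_data as sd
from chemnuc.io_formats import GenomicInterval


@pytest.fixture(scope="session")
def small_landscape():
    """200-kb two-condition landscape with stable/regulatory/barrier regions."""
    lengths = {"chr1": 200_000}
    regions = sd.default_regions(lengths, block=10_000,
                                 regulatory_every=5, barrier_every=5)
    return sd.plant_landscape(lengths, regions, seed=11)


@pytest.fixture(scope="session")
def stable_only_landscape():
    """Landscape with a single large stable region (identical conditions)."""
    lengths = {"chr1": 300_000}
    regions = {"stable": [GenomicInterval("chr1", 1000, 299_000)],
               "regulatory": [], "barrier": []}
    return sd.plant_landscape(lengths, regions, seed=7)


@pytest.fixture(scope="session")
def noise_free_model():
    return sd.CleavageModel(jitter_sd=0.0, background_rate=0.0)


def brute_force_greedy(scores: np.ndarray, min_spacing: int) -> list[int]:
    """Oracle caller: repeatedly take the global maximum (leftmost on ties)
    and delete its +/-(min_spacing-1) neighbourhood."""
    s = scores.astype(float).copy()
    out = []
    while True:
        best = s.max()
        if best <= 0:
            break
        p = int(np.flatnonzero(s == best)[0])
        out.append(p)
        s[max(0, p - (min_spacing - 1)): p + min_spacing] = -np.inf
    return sorted(out)
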