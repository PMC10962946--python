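import numpy as np
import pytest

from admixwave import EvenSignal, GenomeSignal


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def random_genome(rng):
    """Three chromosomes with awkward (non-power-of-two) lengths."""
    return GenomeSignal(
        EvenSignal(f"chr{i + 1}", rng.normal(size=L), 1.0)
        for i, L in enumerate([64, 53, 41])
    )


def paired_genomes(rng, lengths=(64, 53, 41), resolution=1.0):
    xs, ys = [], []
    for i, L in enumerate(lengths):
        xs.append(EvenSignal(f"chr{i + 1}", rng.normal(size=L), resolution))
        ys.append(EvenSignal(f"chr{i + 1}", rng.normal(size=L), resolution))
    return GenomeSignal(xs), GenomeSignal(ys)


def pooled_pearson(gx, gy):
    """Independent oracle: population Pearson correlation over all grid points
    pooled across chromosomes."""
    x = np.concatenate([s.values for s in gx])
    y = np.concatenate([s.values for s in gy])
    xc, yc = x - x.mean(), y - y.mean()
    return float(np.mean(xc * yc) / np.sqrt(np.mean(xc**2) * np.mean(yc**2)))
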