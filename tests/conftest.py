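import numpy as np
import pytest

from haploclust.core import Region, SNPMatrix
from haploclust.simulate import FixtureSpec, generate_matrix


def make_matrix(chrom, positions, samples, rows):
    """Build a small SNPMatrix from per-position symbol strings."""
    return SNPMatrix(
        chromosome=chrom,
        positions=np.asarray(positions, dtype=np.int64),
        samples=tuple(samples),
        calls=np.array([list(r) for r in rows], dtype="<U1"),
    )


@pytest.fixture
def small_matrix():
    # Ref, S1, S2 over three positions on one chromosome.
    return make_matrix(
        "Gm06", [100, 105, 110], ["Ref", "S1", "S2"],
        ["AGG", "CCC", "T-T"],
    )


@pytest.fixture
def clean_two_cluster():
    """Noise- and missing-free planted two-cluster panel with its truth."""
    spec = FixtureSpec(
        n_samples=12, n_sites=200,
        region=Region("Gm06", 1000, 9000),
        founders=2, divergence=0.1, noise=0.0, missing=0.0, seed=11,
    )
    return generate_matrix(spec)
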