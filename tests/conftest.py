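import numpy as np
import pytest

from nlmixup import AugmentedSample, LabelMatrix, MultiChannelImage


@pytest.fixture
def abc_matrix() -> LabelMatrix:
    """Six instances, counts A:6 B:3 C:2 -> IRL {A:1, B:2, C:3}."""
    entries = np.array(
        [
            [1, 0, 0],
            [1, 0, 0],
            [1, 1, 0],
            [1, 1, 0],
            [1, 1, 1],
            [1, 0, 1],
        ]
    )
    return LabelMatrix(entries, ("A", "B", "C"), tuple(f"i{k}" for k in range(6)))


@pytest.fixture
def random_image():
    """Factory for seeded random 4-channel images (values bounded away
    from 1 so rotations with positive sine rarely clip)."""

    def make(seed=0, size=16, high=1.0) -> MultiChannelImage:
        rng = np.random.default_rng(seed)
        return MultiChannelImage(rng.uniform(0.0, high, size=(4, size, size)))

    return make


@pytest.fixture
def sample_pair(random_image):
    a = AugmentedSample(
        image=random_image(1), label_set={"8", "0"}, provenance={"id": "a"}
    )
    b = AugmentedSample(
        image=random_image(2), label_set={"8", "25"}, provenance={"id": "b"}
    )
    return a, b


def random_label_matrix(rng: np.random.Generator, n: int, L: int) -> LabelMatrix:
    """Random binary matrix guaranteed to have no zero-count label and no
    empty instance."""
    entries = (rng.random((n, L)) < 0.25).astype(np.int8)
    for j in range(L):
        if entries[:, j].sum() == 0:
            entries[int(rng.integers(n)), j] = 1
    for i in range(n):
        if entries[i].sum() == 0:
            entries[i, int(rng.integers(L))] = 1
    return LabelMatrix(
        entries,
        tuple(str(j) for j in range(L)),
        tuple(f"s{i}" for i in range(n)),
    )


def scumble_bruteforce(matrix: LabelMatrix) -> tuple[np.ndarray, float]:
    """Literal per-instance oracle: geometric over arithmetic mean of the
    IRL values of each instance's active labels."""
    counts = matrix.entries.sum(axis=0)
    irl = counts.max() / counts
    per = []
    for row in matrix.entries:
        active = [irl[j] for j in range(matrix.n_labels) if row[j]]
        if not active:
            continue
        prod = 1.0
        for v in active:
            prod *= v
        geo = prod ** (1.0 / len(active))
        arith = sum(active) / len(active)
        per.append(1.0 - geo / arith)
    per = np.array(per)
    return per, float(per.mean())
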