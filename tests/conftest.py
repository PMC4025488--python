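import numpy as np
import pytest

from gbsdiv import GenotypeMatrix, GroupAssignment, SyntheticConfig, generate_population


@pytest.fixture
def tiny_matrix() -> GenotypeMatrix:
    """3 lines x 4 markers with one missing cell."""
    codes = np.array(
        [
            [1, 2, 3, 0],
            [1, 3, 3, 1],
            [2, 2, 1, 3],
        ],
        dtype=np.int8,
    )
    return GenotypeMatrix(["l1", "l2", "l3"], ["m1", "m2", "m3", "m4"], codes)


@pytest.fixture
def two_group_assignment() -> GroupAssignment:
    return GroupAssignment({"l1": "a", "l2": "a", "l3": "b"})


@pytest.fixture(scope="session")
def inbred_population():
    """Structured, highly inbred synthetic panel shared by slower tests."""
    cfg = SyntheticConfig(
        n_groups=4, lines_per_group=50, n_markers=2000,
        maf_regime="uniform", fst_target=0.05, f_is=0.98, seed=11,
    )
    return generate_population(cfg)


def random_matrix(rng: np.random.Generator, n: int, p: int, missing: float = 0.0) -> GenotypeMatrix:
    codes = rng.integers(1, 4, size=(n, p)).astype(np.int8)
    if missing > 0:
        mask = rng.random((n, p)) < missing
        codes[mask] = 0
    return GenotypeMatrix([f"l{i}" for i in range(n)], [f"m{j}" for j in range(p)], codes)
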