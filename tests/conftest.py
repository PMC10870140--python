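import numpy as np
import pytest

from hstkit import HaplotypeMatrix, VariantInfo

# six haplotype rows x seven markers at positions 100..700; the worked
# reference cohort used across the tree/comparison tests (start marker idx 3)
F1_ROWS = np.array(
    [
        [0, 1, 0, 1, 0, 1, 1],  # h0
        [0, 1, 0, 1, 0, 1, 0],  # h1
        [1, 1, 0, 1, 0, 1, 1],  # h2
        [0, 0, 1, 1, 0, 0, 1],  # h3
        [0, 1, 0, 1, 1, 1, 1],  # h4
        [0, 1, 0, 0, 0, 1, 1],  # h5
    ],
    dtype=np.uint8,
)

F1_START = 3


def make_matrix(rows: np.ndarray, contig: str = "9", ploidy: int = 2,
                start_pos: int = 100, spacing: int = 100) -> HaplotypeMatrix:
    rows = np.asarray(rows, dtype=np.uint8)
    n_rows, n_markers = rows.shape
    variants = [
        VariantInfo(contig, start_pos + spacing * j, f"m{j}", "A", "C")
        for j in range(n_markers)
    ]
    if ploidy == 2 and n_rows % 2 == 0:
        sample_ids = [f"s{i}" for i in range(n_rows // 2)]
    else:
        ploidy = 1
        sample_ids = [f"s{i}" for i in range(n_rows)]
    return HaplotypeMatrix(
        variants=variants, data=rows, sample_ids=sample_ids, ploidy=ploidy
    )


@pytest.fixture
def f1_matrix() -> HaplotypeMatrix:
    return make_matrix(F1_ROWS)


def random_matrix(rng: np.random.Generator, n_rows: int, n_markers: int) -> HaplotypeMatrix:
    freqs = rng.uniform(0.1, 0.9, size=n_markers)
    rows = (rng.random((n_rows, n_markers)) < freqs[None, :]).astype(np.uint8)
    return make_matrix(rows, ploidy=1)
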