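import numpy as np
import pytest

from forenseq.genotypes import GenotypeMatrix, Locus


@pytest.fixture
def toy_matrix() -> GenotypeMatrix:
    """Three individuals, two loci, one missing call, two populations."""
    calls = {
        "A1": {"L1": (150, 154), "L2": (200, 200)},
        "A2": {"L1": (150, 150), "L2": None},
        "B1": {"L1": (158, 158), "L2": (204, 208)},
    }
    pops = {"A1": "north", "A2": "north", "B1": "south"}
    return GenotypeMatrix.from_calls(calls, pop_labels=pops)


def random_matrix(
    rng: np.random.Generator,
    n_samples: int = 6,
    n_loci: int = 4,
    missing_rate: float = 0.1,
    all_pops_known: bool = True,
) -> GenotypeMatrix:
    """Small random genotype matrix for round-trip/property tests."""
    loci = [Locus(f"L{j}", tuple(range(100 + 4 * j, 140 + 4 * j, 4))) for j in range(n_loci)]
    calls = np.zeros((n_samples, n_loci, 2), dtype=np.int32)
    for i in range(n_samples):
        for j, locus in enumerate(loci):
            if rng.random() < missing_rate:
                calls[i, j] = -1
            else:
                calls[i, j] = sorted(rng.choice(locus.allele_labels, size=2))
    samples = [f"S{i:02d}" for i in range(n_samples)]
    # contiguous population blocks (GenePop files are organised this way)
    pops = [f"pop{1 if i < (n_samples + 1) // 2 else 2}" for i in range(n_samples)]
    if not all_pops_known:
        known = [i % 3 != 0 for i in range(n_samples)]
        pops = [p if k else None for p, k in zip(pops, known)]
        return GenotypeMatrix(samples, loci, calls, pops, known)
    return GenotypeMatrix(samples, loci, calls, pops)
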