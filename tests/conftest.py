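import numpy as np
import pytest

from deplete_bias import CountTable, TaxonProfile


@pytest.fixture
def ten_taxon_counts() -> CountTable:
    """Fixed 10-taxon count table used by the subsampling checks."""
    counts = {
        f"t{i:02d}": c
        for i, c in enumerate([6000, 4500, 3000, 2500, 1500, 1000, 800, 400, 200, 100])
    }
    return CountTable(sample_id="fixed10", taxon_counts=counts)


def random_normalized_profile(
    rng: np.random.Generator,
    taxa: list[str],
    zero_fraction: float = 0.3,
    sample_id: str = "rand",
) -> TaxonProfile:
    """Random percent profile over a taxon pool, with random absences."""
    keep = rng.random(len(taxa)) >= zero_fraction
    if not keep.any():
        keep[rng.integers(len(taxa))] = True
    weights = rng.random(len(taxa)) * keep
    weights = 100.0 * weights / weights.sum()
    return TaxonProfile(
        sample_id=sample_id,
        taxa={t: float(w) for t, w in zip(taxa, weights) if w > 0},
        normalized=True,
    )
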