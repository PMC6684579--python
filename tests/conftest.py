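import numpy as np
import pandas as pd
import pytest

from tritrend.io_tables import AbundanceMatrix, SampleDesign


def make_matrix(values, conditions, replicate_ids=None, channel="intensity",
                protein_ids=None):
    """Small AbundanceMatrix builder for tests."""
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    if replicate_ids is None:
        counts: dict[str, int] = {}
        replicate_ids = []
        for c in conditions:
            counts[c] = counts.get(c, 0) + 1
            replicate_ids.append(f"rep{counts[c]}")
    sample_ids = [f"{c}_{i + 1}" for i, c in enumerate(conditions)]
    design = SampleDesign(
        sample_ids=tuple(sample_ids),
        conditions=tuple(conditions),
        replicate_ids=tuple(replicate_ids),
        channel=channel,
    )
    if protein_ids is None:
        protein_ids = [f"P{i + 1}" for i in range(n)]
    df = pd.DataFrame(values, index=protein_ids, columns=sample_ids)
    df.index.name = "protein_id"
    return AbundanceMatrix(values=df, design=design)


@pytest.fixture
def tiny_matrix():
    """2 proteins x 6 samples (3 H, 3 L)."""
    return make_matrix(
        [[4.0, 4.0, 4.0, 1.0, 1.0, 1.0], [8.0, 8.0, 8.0, 8.0, 8.0, 8.0]],
        ["L", "L", "L", "H", "H", "H"],
        replicate_ids=["rep1", "rep2", "rep3", "rep1", "rep2", "rep3"],
    )
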