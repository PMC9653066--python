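import numpy as np
import pandas as pd
import pytest

from paircomm.containers import CountMatrix


def make_counts(counts, groups=None, pairs=None, taxa=None, samples=None):
    """Build a CountMatrix from a 2-D array with minimal boilerplate."""
    counts = np.asarray(counts)
    n_taxa, n_samples = counts.shape
    taxa = taxa or [f"t{i+1}" for i in range(n_taxa)]
    samples = samples or [f"s{j+1}" for j in range(n_samples)]
    if groups is None:
        half = n_samples // 2
        groups = ["A"] * half + ["B"] * (n_samples - half)
    if pairs is None:
        pairs = [f"p{j % max(1, n_samples // 2) + 1}" for j in range(n_samples)]
    md = pd.DataFrame({"group": groups, "pair": pairs}, index=samples)
    return CountMatrix(taxa, samples, counts, md)


@pytest.fixture
def toy_counts():
    return make_counts(
        [[5, 1, 0, 0], [2, 2, 2, 2], [0, 0, 3, 1], [1, 0, 0, 0]],
    )


# The packaged synthetic study configuration: a paired design with planted
# differential taxa and overlapping correlation blocks, sized so per-group
# networks are identifiable.
PIPELINE_SYNTHETIC = dict(
    n_taxa=150,
    n_pairs=15,
    depth_mean=20000,
    abundance_shape=1.0,
    diff_taxa=[(0, 5.0, "camping"), (1, 4.0, "no_camping")],
    corr_blocks=[
        (list(range(2, 11)), 1.0, "positive"),
        ([10, 11, 12, 13, 14], 0.97, "positive"),
        ([15, 16], 0.9, "negative"),
    ],
)

PIPELINE_KWARGS = dict(
    synthetic=PIPELINE_SYNTHETIC,
    rf_trees=2000,
    n_boot=10000,
    stability_replicates=500,
    robustness_replicates=50,
    niche_permutations=500,
    dnci_permutations=100,
    sem_chains=2,
    sem_iterations=2000,
    sem_burn_in=500,
    seed=42,
)
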