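"""Core in-memory containers for the analysis pipeline.

A :class:`CountMatrix` holds a taxa x samples table of non-negative integer
counts together with per-sample metadata (treatment group and site-pair id,
matching a paired sampling design).  A :class:`FunctionTable` holds predicted
per-sample relative abundances of functional categories.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["CountMatrix", "FunctionTable"]


def _check_unique(ids, what):
    if len(set(ids)) != len(ids):
        dupes = sorted({x for x in ids if list(ids).count(x) > 1})
        raise ValueError(f"duplicate {what} ids: {dupes[:5]}")


@dataclass
class CountMatrix:
    """Taxa x samples count table with paired-design sample metadata.

    Parameters
    ----------
    taxon_ids : list of str
        Row labels (OTU / phylotype ids).
    sample_ids : list of str
        Column labels, order preserved from the source.
    counts : ndarray of shape (n_taxa, n_samples)
        Non-negative integer counts.
    metadata : pandas.DataFrame
        Indexed by sample id, with at least columns ``group`` and ``pair``.
    """

    taxon_ids: list
    sample_ids: list
    counts: np.ndarray
    metadata: pd.DataFrame

    def __post_init__(self):
        self.taxon_ids = list(map(str, self.taxon_ids))
        self.sample_ids = list(map(str, self.sample_ids))
        _check_unique(self.taxon_ids, "taxon")
        _check_unique(self.sample_ids, "sample")
        counts = np.asarray(self.counts)
        if counts.shape != (len(self.taxon_ids), len(self.sample_ids)):
            raise ValueError(
                f"counts shape {counts.shape} does not match "
                f"{len(self.taxon_ids)} taxa x {len(self.sample_ids)} samples"
            )
        if counts.size and not np.issubdtype(counts.dtype, np.integer):
            if not np.allclose(counts, np.round(counts)):
                bad = np.argwhere(~np.isclose(counts, np.round(counts)))[0]
                raise ValueError(
                    f"non-integer count at taxon {self.taxon_ids[bad[0]]!r}, "
                    f"sample {self.sample_ids[bad[1]]!r}"
                )
            counts = np.round(counts).astype(np.int64)
        if counts.size and counts.min() < 0:
            bad = np.argwhere(counts < 0)[0]
            raise ValueError(
                f"negative count at taxon {self.taxon_ids[bad[0]]!r}, "
                f"sample {self.sample_ids[bad[1]]!r}"
            )
        self.counts = counts.astype(np.int64)
        md = self.metadata
        if not isinstance(md, pd.DataFrame):
            raise TypeError("metadata must be a pandas DataFrame")
        missing = [s for s in self.sample_ids if s not in md.index]
        if missing:
            raise ValueError(f"metadata missing samples: {missing[:5]}")
        for col in ("group", "pair"):
            if col not in md.columns:
                raise ValueError(f"metadata missing column {col!r}")
            if md.loc[self.sample_ids, col].isna().any():
                bad = md.loc[self.sample_ids, col].isna()
                raise ValueError(
                    f"metadata column {col!r} missing for sample "
                    f"{bad[bad].index[0]!r}"
                )
        self.metadata = md.loc[self.sample_ids].copy()
        if self.counts.size and self.counts.sum() == 0:
            raise ValueError("count matrix has no positive entries")

    # -- convenience views -------------------------------------------------
    @property
    def n_taxa(self) -> int:
        return len(self.taxon_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def groups(self) -> np.ndarray:
        """Group label per sample, in sample order."""
        return self.metadata["group"].to_numpy()

    @property
    def pairs(self) -> np.ndarray:
        return self.metadata["pair"].to_numpy()

    def sample_sums(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def relative_abundance(self) -> np.ndarray:
        """Within-sample proportions; recomputed from counts, never cached."""
        totals = self.counts.sum(axis=0).astype(float)
        if np.any(totals == 0):
            j = int(np.flatnonzero(totals == 0)[0])
            raise ValueError(f"sample {self.sample_ids[j]!r} has zero total")
        return self.counts / totals

    def select_taxa(self, indices) -> "CountMatrix":
        indices = np.asarray(indices)
        return CountMatrix(
            [self.taxon_ids[i] for i in indices],
            list(self.sample_ids),
            self.counts[indices],
            self.metadata.copy(),
        )

    def select_samples(self, indices) -> "CountMatrix":
        indices = np.asarray(indices)
        ids = [self.sample_ids[i] for i in indices]
        return CountMatrix(
            list(self.taxon_ids), ids, self.counts[:, indices], self.metadata.loc[ids]
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.taxon_ids, columns=self.sample_ids)

    def __eq__(self, other):
        if not isinstance(other, CountMatrix):
            return NotImplemented
        return (
            self.taxon_ids == other.taxon_ids
            and self.sample_ids == other.sample_ids
            and np.array_equal(self.counts, other.counts)
            and self.metadata[["group", "pair"]].equals(
                other.metadata[["group", "pair"]]
            )
        )


@dataclass
class FunctionTable:
    """Functions x samples table of non-negative relative abundances."""

    function_ids: list
    sample_ids: list
    values: np.ndarray = field(repr=False)

    def __post_init__(self):
        self.function_ids = list(map(str, self.function_ids))
        self.sample_ids = list(map(str, self.sample_ids))
        _check_unique(self.function_ids, "function")
        _check_unique(self.sample_ids, "sample")
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.function_ids), len(self.sample_ids)):
            raise ValueError(
                f"values shape {v.shape} does not match "
                f"{len(self.function_ids)} functions x {len(self.sample_ids)} samples"
            )
        if v.size and not np.all(np.isfinite(v)):
            raise ValueError("function table contains non-finite values")
        if v.size and v.min() < 0:
            raise ValueError("function table contains negative values")
        self.values = v

    @property
    def n_functions(self) -> int:
        return len(self.function_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.function_ids, columns=self.sample_ids
        )
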