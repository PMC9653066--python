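"""Rarefaction and alpha-diversity indices for taxa and function tables.

Indices follow the conventions most OTU-table pipelines default to: classic
Chao1 (bias-corrected form only when doubletons are absent, keeping the
estimate finite), ACE with the rare/abundant cutoff at 10 reads, Shannon in
nats so that Pielou evenness is H / ln S, inverse Simpson, Fisher's alpha
solved from S = alpha * ln(1 + N / alpha), Good's coverage 1 - F1 / N, and
rooted Faith's phylogenetic diversity (the path to the root is included).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from skbio.diversity.alpha import ace as _skbio_ace
from skbio.diversity.alpha import faith_pd as _skbio_faith_pd
from skbio.diversity.alpha import fisher_alpha as _skbio_fisher_alpha

from .containers import CountMatrix, FunctionTable

__all__ = ["rarefy", "alpha_diversity", "function_diversity"]


def rarefy(counts: CountMatrix, depth: int, seed: int = 0) -> CountMatrix:
    """Subsample every sample without replacement to a common depth.

    Samples whose total is below ``depth`` are dropped with a warning (they
    cannot be subsampled without replacement).  Deterministic per seed.
    """
    if depth <= 0:
        raise ValueError(f"rarefaction depth must be >= 1, got {depth}")
    rng = np.random.default_rng(seed)
    keep, columns = [], []
    for j, sid in enumerate(counts.sample_ids):
        col = counts.counts[:, j]
        total = int(col.sum())
        if total < depth:
            warnings.warn(
                f"sample {sid!r} total {total} < depth {depth}; dropped",
                stacklevel=2,
            )
            continue
        if total == depth:
            columns.append(col.copy())
        else:
            columns.append(rng.multivariate_hypergeometric(col, depth))
        keep.append(j)
    if not keep:
        warnings.warn("no sample reaches the rarefaction depth", stacklevel=2)
        ids = []
        return CountMatrix(
            list(counts.taxon_ids),
            ids,
            np.zeros((counts.n_taxa, 0), dtype=np.int64),
            counts.metadata.iloc[:0],
        )
    sample_ids = [counts.sample_ids[j] for j in keep]
    mat = np.column_stack(columns)
    return CountMatrix(
        list(counts.taxon_ids), sample_ids, mat, counts.metadata.loc[sample_ids]
    )


def _chao1(col: np.ndarray) -> float:
    s_obs = int((col > 0).sum())
    f1 = int((col == 1).sum())
    f2 = int((col == 2).sum())
    if f2 > 0:
        return s_obs + f1**2 / (2.0 * f2)
    return s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))


def _shannon(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def alpha_diversity(counts: CountMatrix, tree=None) -> pd.DataFrame:
    """Per-sample diversity and coverage indices.

    Returns a DataFrame indexed by sample with columns observed_richness,
    chao1, ace, shannon, invsimpson, pielou, fisher_alpha, goods_coverage and,
    when ``tree`` is given, faith_pd.  Pielou is NaN for single-taxon samples
    (H / ln S is undefined at S = 1).
    """
    if np.any(counts.sample_sums() < 1):
        j = int(np.flatnonzero(counts.sample_sums() < 1)[0])
        raise ValueError(f"sample {counts.sample_ids[j]!r} has zero total")
    if tree is not None:
        leaves = {t.name for t in tree.tips()}
        present_any = np.asarray(counts.counts).sum(axis=1) > 0
        missing = [
            t for t, p in zip(counts.taxon_ids, present_any) if p and t not in leaves
        ]
        if missing:
            raise ValueError(f"tree is missing observed taxa: {missing[:5]}")
    rows = {}
    for j, sid in enumerate(counts.sample_ids):
        col = counts.counts[:, j]
        n_total = int(col.sum())
        s_obs = int((col > 0).sum())
        p = col / n_total
        f1 = int((col == 1).sum())
        try:
            ace_val = float(_skbio_ace(col, rare_threshold=10))
        except (ValueError, ZeroDivisionError):
            ace_val = np.nan  # e.g. every rare taxon a singleton
        try:
            fisher_val = float(_skbio_fisher_alpha(col))
        except (ValueError, RuntimeError):
            fisher_val = np.nan  # S == N has no finite root
        rec = {
            "observed_richness": s_obs,
            "chao1": _chao1(col),
            "ace": ace_val,
            "shannon": _shannon(p),
            "invsimpson": float(1.0 / np.sum(p**2)),
            "pielou": (_shannon(p) / np.log(s_obs)) if s_obs > 1 else np.nan,
            "fisher_alpha": fisher_val,
            "goods_coverage": 1.0 - f1 / n_total,
        }
        if tree is not None:
            rec["faith_pd"] = float(
                _skbio_faith_pd(col, taxa=counts.taxon_ids, tree=tree)
            )
        rows[sid] = rec
    return pd.DataFrame.from_dict(rows, orient="index")


def function_diversity(table: FunctionTable) -> pd.DataFrame:
    """Richness, Shannon, Pielou and inverse Simpson of function profiles.

    Computed on column-normalised function values; raises for all-zero
    samples.
    """
    totals = table.values.sum(axis=0)
    if np.any(totals <= 0):
        j = int(np.flatnonzero(totals <= 0)[0])
        raise ValueError(f"sample {table.sample_ids[j]!r} has zero function total")
    rows = {}
    for j, sid in enumerate(table.sample_ids):
        p = table.values[:, j] / totals[j]
        s = int((p > 0).sum())
        h = _shannon(p)
        rows[sid] = {
            "richness": s,
            "shannon": h,
            "pielou": (h / np.log(s)) if s > 1 else np.nan,
            "invsimpson": float(1.0 / np.sum(p**2)),
        }
    return pd.DataFrame.from_dict(rows, orient="index")
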