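"""Niche metrics and assembly-mechanism inference.

Levins niche breadth treats individual samples as resource states:
B_i = 1 / sum_j P_ij^2 with P_ij the share of taxon i's reads found in sample
j, so B runs from 1 (all reads in one sample) to the number of samples.
Pianka overlap is the cosine-like similarity of two taxa's sample-usage
profiles.  Generalists/specialists are taxa whose breadth falls outside a
two-sided quantile band of a fixed-fixed (both margins preserved) permutation
null.  The dispersal-niche continuum test compares how well three constrained
permutation nulls reproduce the observed ranked SIMPER contribution profile:
the regime whose null fits best (lowest E) is selected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import CountMatrix

__all__ = [
    "DNCIResult",
    "levins_breadth",
    "pianka_overlap",
    "classify_generalists",
    "simper_contributions",
    "dnci_test",
]

NULL_MODELS = ("dispersal_controlled", "niche_controlled", "both_controlled")


@dataclass
class DNCIResult:
    e_values: dict  # null model -> ndarray of E over permutations
    mean_e: dict
    selected_regime: str
    n_permutations: int


def _usage_profiles(counts: CountMatrix) -> np.ndarray:
    totals = counts.counts.sum(axis=1, keepdims=True).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(totals > 0, counts.counts / totals, np.nan)


def levins_breadth(counts: CountMatrix) -> pd.Series:
    """Levins B per taxon; NaN for all-zero taxa."""
    p = _usage_profiles(counts)
    with np.errstate(invalid="ignore"):
        b = 1.0 / np.nansum(p**2, axis=1)
    b[np.isnan(p).all(axis=1)] = np.nan
    zero = counts.counts.sum(axis=1) == 0
    b[zero] = np.nan
    return pd.Series(b, index=counts.taxon_ids, name="levins_breadth")


def pianka_overlap(counts: CountMatrix) -> pd.DataFrame:
    """Pairwise Pianka overlap matrix (symmetric, unit diagonal).

    Rows/columns of zero-total taxa are NaN.
    """
    if counts.n_taxa < 2:
        raise ValueError("pianka_overlap needs >= 2 taxa")
    p = _usage_profiles(counts)
    valid = ~np.isnan(p).all(axis=1)
    o = np.full((counts.n_taxa, counts.n_taxa), np.nan)
    pv = np.nan_to_num(p[valid])
    norms = np.sqrt((pv**2).sum(axis=1))
    dot = pv @ pv.T
    sub = dot / np.outer(norms, norms)
    np.fill_diagonal(sub, 1.0)
    o[np.ix_(valid, valid)] = sub
    return pd.DataFrame(o, index=counts.taxon_ids, columns=counts.taxon_ids)


def classify_generalists(
    counts: CountMatrix, n_perm: int = 1000, alpha: float = 0.05, seed: int = 0
) -> pd.Series:
    """Generalist/specialist classification against a fixed-fixed null.

    Null tables preserve both sample totals and taxon totals (Patefield
    draws); a taxon is a generalist when its observed breadth exceeds the
    1 - alpha/2 null quantile, a specialist when it falls below the alpha/2
    quantile, otherwise non_significant.
    """
    if counts.n_samples < 2:
        raise ValueError("classification needs >= 2 samples")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = np.random.default_rng(seed)
    obs = levins_breadth(counts).to_numpy()
    row_tot = counts.counts.sum(axis=1)
    col_tot = counts.counts.sum(axis=0)
    dist = stats.random_table(row_tot, col_tot)
    tables = dist.rvs(n_perm, random_state=rng)
    with np.errstate(invalid="ignore", divide="ignore"):
        tot = tables.sum(axis=2, keepdims=True).astype(float)
        p = np.where(tot > 0, tables / tot, 0.0)
        null_b = 1.0 / np.maximum((p**2).sum(axis=2), 1e-300)  # (n_perm, n_taxa)
    null_b[tables.sum(axis=2) == 0] = np.nan
    lo = np.nanquantile(null_b, alpha / 2.0, axis=0)
    hi = np.nanquantile(null_b, 1.0 - alpha / 2.0, axis=0)
    labels = np.where(
        obs > hi, "generalist", np.where(obs < lo, "specialist", "non_significant")
    ).astype(object)
    labels[~np.isfinite(obs)] = "non_significant"
    return pd.Series(labels, index=counts.taxon_ids, name="niche_class")


def _simper_profile(matrix: np.ndarray, in_a: np.ndarray) -> np.ndarray:
    """Per-taxon mean between-group Bray-Curtis contribution, from a
    taxa x samples matrix of relative abundances (or presences)."""
    xa = matrix[:, in_a]
    xb = matrix[:, ~in_a]
    contrib = np.zeros(matrix.shape[0])
    n_pairs = 0
    for i in range(xa.shape[1]):
        for j in range(xb.shape[1]):
            x, y = xa[:, i], xb[:, j]
            denom = (x + y).sum()
            if denom > 0:
                contrib += np.abs(x - y) / denom
            n_pairs += 1
    return contrib / n_pairs


def simper_contributions(counts: CountMatrix, groups=None) -> pd.Series:
    """Normalised per-taxon contributions to between-group dissimilarity.

    Contributions are averaged over all between-group sample pairs on
    relative abundances, sorted descending, and normalised to sum to 1.
    """
    labels = np.asarray(groups if groups is not None else counts.groups)
    levels = pd.unique(labels)
    if len(levels) != 2:
        raise ValueError("simper_contributions requires exactly 2 groups")
    if min(int((labels == g).sum()) for g in levels) < 1:
        raise ValueError("each group needs at least one sample")
    rel = counts.relative_abundance()
    contrib = _simper_profile(rel, labels == levels[0])
    total = contrib.sum()
    if total > 0:
        contrib = contrib / total
    else:
        # groups are indistinguishable (e.g. a single taxon): every taxon
        # contributes equally to the zero dissimilarity
        contrib = np.full(len(contrib), 1.0 / len(contrib))
    s = pd.Series(contrib, index=counts.taxon_ids, name="simper_contribution")
    return s.sort_values(ascending=False)


def _permute_rows(mat, rng):
    out = mat.copy()
    for i in range(out.shape[0]):
        rng.shuffle(out[i])
    return out


def _permute_cols(mat, rng):
    out = mat.copy()
    for j in range(out.shape[1]):
        rng.shuffle(out[:, j])
    return out


def _curveball(mat, rng, n_swaps=None):
    """Fixed-fixed presence/absence shuffle via the curveball algorithm."""
    m = mat.copy()
    presence = [set(np.flatnonzero(m[i])) for i in range(m.shape[0])]
    if n_swaps is None:
        n_swaps = 10 * max(1, int(m.sum() / max(1, m.shape[0])))
        n_swaps = max(5 * m.shape[0], n_swaps)
    for _ in range(n_swaps):
        i, j = rng.integers(0, m.shape[0], size=2)
        if i == j:
            continue
        a, b = presence[i], presence[j]
        only_a = list(a - b)
        only_b = list(b - a)
        k = min(len(only_a), len(only_b))
        if k == 0:
            continue
        pool = only_a + only_b
        rng.shuffle(pool)
        new_a = set(pool[: len(only_a)])
        new_b = set(pool[len(only_a):])
        presence[i] = (a & b) | new_a
        presence[j] = (a & b) | new_b
    out = np.zeros_like(m)
    for i, cols in enumerate(presence):
        out[i, list(cols)] = 1
    return out


def _ranked_profile(matrix: np.ndarray, in_a: np.ndarray) -> np.ndarray:
    """Sorted, normalised SIMPER profile with additive smoothing.

    The smoothing constant 1/(10 S) keeps the log10 comparison finite when a
    permutation zeroes a taxon's contribution, bounding that rank's penalty
    instead of letting it dominate E.
    """
    prof = _simper_profile(matrix.astype(float), in_a)
    tot = prof.sum()
    if tot > 0:
        prof = prof / tot
    prof = prof + 1.0 / (10.0 * prof.size)
    prof = prof / prof.sum()
    return np.sort(prof)[::-1]


def _profile_e(obs_sorted: np.ndarray, perm: np.ndarray, in_a: np.ndarray) -> float:
    prof = _ranked_profile(perm, in_a)
    return float(np.sum((np.log10(obs_sorted) - np.log10(prof)) ** 2))


def dnci_test(
    counts: CountMatrix, groups=None, n_perm: int = 100, seed: int = 0
) -> DNCIResult:
    """Dispersal-niche continuum test via constrained-permutation SIMPER fits.

    Works on presence/absence.  Three null models are compared: dispersal
    controlled (each species row shuffled across samples, preserving species
    occurrence totals), niche controlled (each sample column shuffled,
    preserving sample richness) and both controlled (curveball fixed-fixed).
    For each permuted matrix the ranked, normalised SIMPER profile is compared
    with the observed one through E = sum over ranks of squared log10
    deviations; the regime whose null reproduces the profile best (lowest mean
    E) is selected.
    """
    labels = np.asarray(groups if groups is not None else counts.groups)
    levels = pd.unique(labels)
    if len(levels) != 2:
        raise ValueError("dnci_test requires exactly 2 groups")
    if min(int((labels == g).sum()) for g in levels) < 2:
        raise ValueError("each group needs >= 2 samples")
    pa = (counts.counts > 0).astype(np.int8)
    occupancy = pa.sum(axis=1)
    ubiquitous = occupancy == counts.n_samples
    absent = occupancy == 0
    if ubiquitous.any():
        warnings.warn(
            f"{int(ubiquitous.sum())} species present in every sample dropped "
            "(unshuffleable)",
            stacklevel=2,
        )
    pa = pa[~(ubiquitous | absent)]
    if pa.shape[0] < 2 or pa.sum() == 0:
        raise ValueError("presence/absence matrix is degenerate after filtering")
    in_a = labels == levels[0]
    obs_sorted = _ranked_profile(pa, in_a)

    ss = np.random.SeedSequence(seed)
    rngs = {m: np.random.default_rng(s) for m, s in zip(NULL_MODELS, ss.spawn(3))}
    e_values = {m: np.empty(n_perm) for m in NULL_MODELS}
    for k in range(n_perm):
        e_values["dispersal_controlled"][k] = _profile_e(
            obs_sorted, _permute_rows(pa, rngs["dispersal_controlled"]), in_a
        )
        e_values["niche_controlled"][k] = _profile_e(
            obs_sorted, _permute_cols(pa, rngs["niche_controlled"]), in_a
        )
        e_values["both_controlled"][k] = _profile_e(
            obs_sorted, _curveball(pa, rngs["both_controlled"]), in_a
        )
    mean_e = {m: float(v.mean()) for m, v in e_values.items()}
    selected = min(("dispersal_controlled", "niche_controlled"), key=mean_e.get)
    return DNCIResult(
        e_values=e_values,
        mean_e=mean_e,
        selected_regime=selected.replace("_controlled", ""),
        n_permutations=n_perm,
    )
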