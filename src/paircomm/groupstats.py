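"""Group comparison machinery: gated test selection, multiple-testing
correction, distance matrices, PERMANOVA, Venn partitioning of taxa, the
random-forest + Kruskal-Wallis differential screen, and Welch comparisons of
function tables.

Test selection mirrors common microbiome practice: parametric tests (t /
ANOVA) only when every group passes Shapiro-Wilk normality and the groups
pass Levene's homoscedasticity check at alpha = 0.05; otherwise the rank
based Wilcoxon rank-sum / Kruskal-Wallis tests are used.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from statsmodels.stats.multitest import multipletests

from .containers import CountMatrix, FunctionTable

__all__ = [
    "GroupTestResult",
    "PermanovaResult",
    "VennPartition",
    "auto_group_test",
    "bh_adjust",
    "distance_matrix",
    "permanova",
    "venn_partition",
    "rf_screen",
    "welch_compare",
]

GATE_ALPHA = 0.05


@dataclass
class GroupTestResult:
    variable: str
    method_used: str  # anova | t | kruskal_wallis | wilcoxon | welch_t
    statistic: float
    p: float
    p_adjusted: float = np.nan
    normality_p: float = np.nan
    homoscedasticity_p: float = np.nan


@dataclass
class PermanovaResult:
    distance_name: str
    R2: float
    pseudo_F: float
    p: float
    n_permutations: int


@dataclass
class VennPartition:
    unique_to_a: set
    unique_to_b: set
    shared: set
    fraction_a: float  # unique-to-A reads as a share of group A's reads
    fraction_b: float
    group_a: str
    group_b: str


def auto_group_test(values, groups, variable="") -> GroupTestResult:
    """Two-stage test: normality/homoscedasticity gates pick the method.

    Groups with fewer than 3 observations cannot be Shapiro-Wilk tested; the
    gate then fails conservatively and the rank-based branch is used.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    levels = pd.unique(groups)
    if len(levels) < 2:
        raise ValueError("need at least 2 groups")
    by_group = [values[groups == g] for g in levels]
    if any(len(v) < 2 for v in by_group):
        raise ValueError("every group needs at least 2 values")
    if all(np.ptp(v) == 0 for v in by_group) and len({v[0] for v in by_group}) == 1:
        raise ValueError(f"variable {variable!r} is constant in all groups")

    normal_ps = []
    for v in by_group:
        if len(v) < 3 or np.ptp(v) == 0:
            normal_ps.append(0.0)  # gate fails; cannot assert normality
        else:
            normal_ps.append(stats.shapiro(v).pvalue)
    normality_p = float(min(normal_ps))
    try:
        homo_p = float(stats.levene(*by_group).pvalue)
    except ValueError:
        homo_p = 0.0
    parametric = normality_p > GATE_ALPHA and homo_p > GATE_ALPHA

    if parametric:
        if len(levels) == 2:
            res = stats.ttest_ind(by_group[0], by_group[1])
            method = "t"
        else:
            res = stats.f_oneway(*by_group)
            method = "anova"
    else:
        if len(levels) == 2:
            a, b = by_group[0], by_group[1]
            exact = (
                max(len(a), len(b)) <= 10
                and len(np.unique(np.concatenate([a, b]))) == len(a) + len(b)
            )
            res = stats.mannwhitneyu(
                a, b, alternative="two-sided", method="exact" if exact else "asymptotic"
            )
            method = "wilcoxon"
        else:
            res = stats.kruskal(*by_group)
            method = "kruskal_wallis"
    return GroupTestResult(
        variable=str(variable),
        method_used=method,
        statistic=float(res.statistic),
        p=float(res.pvalue),
        normality_p=normality_p,
        homoscedasticity_p=homo_p,
    )


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def distance_matrix(counts: CountMatrix, metric: str = "bray_curtis") -> pd.DataFrame:
    """Pairwise Bray-Curtis (on counts) or Jaccard (on presence/absence)."""
    x = counts.counts.T.astype(float)  # samples x taxa
    if np.any(x.sum(axis=1) == 0):
        j = int(np.flatnonzero(x.sum(axis=1) == 0)[0])
        raise ValueError(f"sample {counts.sample_ids[j]!r} has zero total")
    if counts.n_samples < 2:
        raise ValueError("need at least 2 samples")
    if metric == "bray_curtis":
        from scipy.spatial.distance import pdist, squareform

        d = squareform(pdist(x, metric="braycurtis"))
    elif metric == "jaccard":
        from scipy.spatial.distance import pdist, squareform

        d = squareform(pdist(x > 0, metric="jaccard"))
    else:
        raise ValueError(f"unknown metric {metric!r}")
    return pd.DataFrame(d, index=counts.sample_ids, columns=counts.sample_ids)


def _permanova_f(dist2: np.ndarray, labels: np.ndarray, levels) -> tuple:
    """Anderson's pseudo-F from squared distances; returns (F, R2)."""
    n = dist2.shape[0]
    iu = np.triu_indices(n, k=1)
    ss_total = dist2[iu].sum() / n
    ss_within = 0.0
    for g in levels:
        mask = labels == g
        ng = int(mask.sum())
        sub = dist2[np.ix_(mask, mask)]
        ss_within += sub[np.triu_indices(ng, k=1)].sum() / ng
    ss_among = ss_total - ss_within
    k = len(levels)
    if ss_total <= 0:
        return 0.0, 0.0
    if ss_within <= 0:
        return np.inf, ss_among / ss_total
    f = (ss_among / (k - 1)) / (ss_within / (n - k))
    return f, ss_among / ss_total


def permanova(
    dist, groups, n_permutations: int = 9999, seed: int = 0, distance_name=""
) -> PermanovaResult:
    """Permutational multivariate ANOVA on a distance matrix.

    The p-value uses the (1 + exceedances) / (1 + permutations) rule for
    random shuffles; when the number of distinct label arrangements does not
    exceed ``n_permutations`` the null is enumerated exhaustively and the
    p-value is the exact tail proportion (the observed arrangement included).
    """
    if isinstance(dist, pd.DataFrame):
        dist = dist.to_numpy()
    dist = np.asarray(dist, dtype=float)
    if dist.ndim != 2 or dist.shape[0] != dist.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(dist, dist.T):
        raise ValueError("distance matrix must be symmetric")
    if np.any(dist < 0):
        raise ValueError("distance matrix has negative entries")
    labels = np.asarray(groups)
    levels = pd.unique(labels)
    counts = [int((labels == g).sum()) for g in levels]
    if len(levels) < 2 or min(counts) < 2:
        raise ValueError("need >= 2 groups with >= 2 members each")
    dist2 = dist**2
    f_obs, r2 = _permanova_f(dist2, labels, levels)

    n = len(labels)
    n_arrangements = math.factorial(n)
    for c in counts:
        n_arrangements //= math.factorial(c)
    if n_arrangements <= n_permutations:
        # exhaustive: enumerate distinct assignments of samples to groups
        hits = 0
        total = 0
        idx = np.arange(n)
        for combo in _multiset_assignments(n, counts):
            perm_labels = np.empty(n, dtype=labels.dtype)
            for g, members in zip(levels, combo):
                perm_labels[list(members)] = g
            f_p, _ = _permanova_f(dist2, perm_labels, levels)
            total += 1
            if f_p >= f_obs - 1e-12:
                hits += 1
        p = hits / total
        n_used = total
    else:
        rng = np.random.default_rng(seed)
        hits = 0
        for _ in range(n_permutations):
            perm = rng.permutation(labels)
            f_p, _ = _permanova_f(dist2, perm, levels)
            if f_p >= f_obs - 1e-12:
                hits += 1
        p = (1 + hits) / (1 + n_permutations)
        n_used = n_permutations
    if f_obs == 0.0 and r2 == 0.0:
        p = 1.0  # degenerate: all samples identical
    return PermanovaResult(
        distance_name=str(distance_name),
        R2=float(r2),
        pseudo_F=float(f_obs),
        p=float(p),
        n_permutations=int(n_used),
    )


def _multiset_assignments(n, counts):
    """Yield all distinct partitions of range(n) into blocks of given sizes."""

    def rec(remaining, sizes):
        if not sizes:
            yield ()
            return
        size = sizes[0]
        rest = sizes[1:]
        if not rest:
            yield (tuple(sorted(remaining)),)
            return
        remaining = sorted(remaining)
        for block in combinations(remaining, size):
            left = [x for x in remaining if x not in set(block)]
            for tail in rec(left, rest):
                yield (block,) + tail

    yield from rec(list(range(n)), list(counts))


def venn_partition(counts: CountMatrix) -> VennPartition:
    """Taxa unique to each of two groups, plus the read share they represent.

    A taxon is unique to group G when its total count is positive in G and
    zero in the other group.  The fraction is that set's summed reads divided
    by the group's total reads.
    """
    levels = list(pd.unique(counts.groups))
    if len(levels) != 2:
        raise ValueError(f"venn_partition requires exactly 2 groups, got {levels}")
    ga, gb = levels
    in_a = counts.groups == ga
    tot_a = counts.counts[:, in_a].sum(axis=1)
    tot_b = counts.counts[:, ~in_a].sum(axis=1)
    observed = (tot_a + tot_b) > 0
    uniq_a = observed & (tot_a > 0) & (tot_b == 0)
    uniq_b = observed & (tot_b > 0) & (tot_a == 0)
    shared = observed & (tot_a > 0) & (tot_b > 0)
    names = np.asarray(counts.taxon_ids)
    frac_a = tot_a[uniq_a].sum() / tot_a.sum() if tot_a.sum() else 0.0
    frac_b = tot_b[uniq_b].sum() / tot_b.sum() if tot_b.sum() else 0.0
    return VennPartition(
        unique_to_a=set(names[uniq_a]),
        unique_to_b=set(names[uniq_b]),
        shared=set(names[shared]),
        fraction_a=float(frac_a),
        fraction_b=float(frac_b),
        group_a=str(ga),
        group_b=str(gb),
    )


def rf_screen(
    counts: CountMatrix,
    taxonomy: dict | None = None,
    n_trees: int = 10000,
    seed: int = 0,
) -> pd.DataFrame:
    """Random-forest importance ranking plus per-taxon Kruskal-Wallis p.

    A classifier is trained on within-sample relative abundances (optionally
    aggregated by a taxonomy mapping taxon id -> rank label); taxa are ranked
    by mean decrease in Gini impurity with deterministic index tie-breaking.
    The conventional discriminating set is taxa with kw_p < 0.05.
    """
    labels = counts.groups
    levels = pd.unique(labels)
    if len(levels) < 2:
        raise ValueError("rf_screen needs at least 2 classes")
    if min(int((labels == g).sum()) for g in levels) < 2:
        raise ValueError("rf_screen needs >= 2 samples per group")
    rel = counts.relative_abundance()
    ids = list(counts.taxon_ids)
    if taxonomy is not None:
        agg = pd.DataFrame(rel, index=counts.taxon_ids).groupby(
            [taxonomy.get(t, t) for t in counts.taxon_ids]
        ).sum()
        ids = list(agg.index)
        rel = agg.to_numpy()
    x = rel.T  # samples x features
    clf = RandomForestClassifier(
        n_estimators=n_trees,
        random_state=seed,
        class_weight="balanced",
        n_jobs=1,
    )
    clf.fit(x, labels)
    gini = clf.feature_importances_
    order = np.lexsort((np.arange(len(ids)), -gini))
    rank = np.empty(len(ids), dtype=int)
    rank[order] = np.arange(1, len(ids) + 1)
    kw_p = np.empty(len(ids))
    for i in range(len(ids)):
        vals = [rel[i][labels == g] for g in levels]
        if all(np.ptp(v) == 0 for v in vals) and len({v[0] for v in vals}) == 1:
            kw_p[i] = 1.0
        else:
            kw_p[i] = stats.kruskal(*vals).pvalue
    return pd.DataFrame(
        {"mean_decrease_gini": gini, "rank": rank, "kw_p": kw_p}, index=ids
    ).sort_values("rank")


def welch_compare(table: FunctionTable, groups) -> list:
    """Two-sided Welch's t test per function row between two groups."""
    labels = np.asarray(groups)
    levels = np.unique(labels)  # sorted: statistic sign is label-determined
    if len(levels) != 2:
        raise ValueError("welch_compare requires exactly 2 groups")
    if min(int((labels == g).sum()) for g in levels) < 2:
        raise ValueError("welch_compare needs >= 2 samples per group")
    in_a = labels == levels[0]
    results = []
    for i, fid in enumerate(table.function_ids):
        a = table.values[i, in_a]
        b = table.values[i, ~in_a]
        if np.ptp(a) == 0 and np.ptp(b) == 0:
            results.append(
                GroupTestResult(fid, "welch_t", np.nan, np.nan)
            )
            continue
        res = stats.ttest_ind(a, b, equal_var=False)
        results.append(
            GroupTestResult(fid, "welch_t", float(res.statistic), float(res.pvalue))
        )
    ps = [r.p for r in results]
    finite = np.isfinite(ps)
    adj = np.full(len(ps), np.nan)
    if finite.any():
        adj[finite] = bh_adjust(np.asarray(ps)[finite])
    for r, a in zip(results, adj):
        r.p_adjusted = float(a)
    return results
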