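"""Co-occurrence network construction and stability analysis.

Networks are built from pairwise Pearson correlations of within-sample
relative abundances on a filtered OTU table (present in >= 2 samples and
grand-total read share >= 0.1%), keeping edges with |r| above a threshold
(default 0.8) and Benjamini-Hochberg adjusted p below a cut (default 0.001).
The property suite, bootstrap node-attribute distributions, stochastic
node/edge-removal stability and robustness sweeps, and the high/low-degree
class comparison across two networks follow.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp

from .containers import CountMatrix
from .groupstats import bh_adjust

__all__ = [
    "NetworkProperties",
    "KSResult",
    "RobustnessCurve",
    "DegreeClasses",
    "filter_otus",
    "build_network",
    "natural_connectivity",
    "network_properties",
    "bootstrap_node_attributes",
    "ks_compare",
    "stability_after_removal",
    "robustness_sweep",
    "degree_class_partition",
]


@dataclass
class NetworkProperties:
    n_nodes: int
    n_edges: int
    n_positive: int
    n_negative: int
    positive_fraction: float
    connectance: float
    average_degree: float
    n_clusters: int
    modularity: float
    degree_centralization: float
    central_eigen: float
    vulnerability: float
    natural_connectivity: float

    def to_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class KSResult:
    attribute: str
    D: float
    p: float


@dataclass
class RobustnessCurve:
    removal_mode: str
    fractions: np.ndarray
    mean: pd.DataFrame  # fractions x {average_degree, natural_connectivity}
    sd: pd.DataFrame
    slopes: dict  # property -> (slope, intercept) of the linear decline
    n_replicates: int
    seed: int


@dataclass
class DegreeClasses:
    high_a: set
    low_a: set
    high_b: set
    low_b: set
    shared_nodes: set
    degree_pairs: pd.DataFrame  # shared nodes x (degree_a, degree_b)
    transitions: dict  # node -> 'high->low' | 'low->high'
    summary: pd.DataFrame  # per class: specific/shared counts, percentages, abundance
    # convenience partition per class across the two networks
    class_venn: dict = field(default_factory=dict)


def filter_otus(
    counts: CountMatrix, min_prevalence: int = 2, min_total_share: float = 0.001
) -> CountMatrix:
    """Keep taxa present in >= ``min_prevalence`` samples whose grand-total
    read share is >= ``min_total_share``."""
    prevalence = (counts.counts > 0).sum(axis=1)
    share = counts.counts.sum(axis=1) / counts.counts.sum()
    keep = np.flatnonzero((prevalence >= min_prevalence) & (share >= min_total_share))
    if keep.size == 0:
        warnings.warn("OTU filter removed every taxon", stacklevel=2)
    return counts.select_taxa(keep.astype(int))


def build_network(
    counts: CountMatrix, r_threshold: float = 0.8, p_cut: float = 0.001
) -> nx.Graph:
    """Pearson co-occurrence network on relative abundances.

    All taxon pairs are tested; two-sided p-values come from the t transform
    of r and are BH-adjusted over every pair before thresholding.  An edge is
    kept iff |r| > r_threshold and adjusted p < p_cut.  Isolated nodes are
    retained; constant taxa cannot be correlated and are kept as isolated
    nodes with a logged note.
    """
    if counts.n_samples < 4:
        raise ValueError("network construction needs >= 4 samples")
    if counts.n_taxa < 2:
        raise ValueError("network construction needs >= 2 taxa")
    rel = counts.relative_abundance()
    mean_ra = rel.mean(axis=1)
    variable = np.flatnonzero(rel.std(axis=1) > 0)
    if variable.size < counts.n_taxa:
        dropped = counts.n_taxa - variable.size
        warnings.warn(
            f"{dropped} constant taxa excluded from correlation", stacklevel=2
        )
    g = nx.Graph()
    for i, t in enumerate(counts.taxon_ids):
        g.add_node(t, relative_abundance=float(mean_ra[i]))
    if variable.size >= 2:
        sub = rel[variable]
        r = np.corrcoef(sub)
        n = counts.n_samples
        iu = np.triu_indices(len(variable), k=1)
        rvals = np.clip(r[iu], -1.0, 1.0)
        df = n - 2
        with np.errstate(divide="ignore"):
            tstat = rvals * np.sqrt(df / np.maximum(1e-300, 1.0 - rvals**2))
        p = 2.0 * stats.t.sf(np.abs(tstat), df)
        p[np.isclose(np.abs(rvals), 1.0)] = 0.0
        p_adj = bh_adjust(p)
        keep = (np.abs(rvals) > r_threshold) & (p_adj < p_cut)
        names = [counts.taxon_ids[i] for i in variable]
        for k in np.flatnonzero(keep):
            i, j = iu[0][k], iu[1][k]
            g.add_edge(
                names[i],
                names[j],
                r=float(rvals[k]),
                p_adjusted=float(p_adj[k]),
                sign="positive" if rvals[k] > 0 else "negative",
            )
    return g


def natural_connectivity(network: nx.Graph) -> float:
    """ln of the mean exponentiated adjacency eigenvalue (spectral robustness)."""
    n = network.number_of_nodes()
    if n == 0:
        return 0.0
    a = nx.to_numpy_array(network, weight=None)
    lam = np.linalg.eigvalsh(a)
    return float(logsumexp(lam) - np.log(n))


def _eigenvector_centrality(network: nx.Graph) -> dict:
    """Principal adjacency eigenvector (absolute values, unit Euclidean norm).

    Computed by dense eigendecomposition so disconnected graphs -- the rule
    for sparse co-occurrence networks with isolated nodes -- are handled
    deterministically (the dominant component carries the mass).
    """
    nodes = list(network.nodes)
    a = nx.to_numpy_array(network, weight=None)
    w, v = np.linalg.eigh(a)
    vec = np.abs(v[:, int(np.argmax(w))])
    norm = np.linalg.norm(vec)
    if norm > 0:
        vec = vec / norm
    return dict(zip(nodes, vec))


def _average_degree(network: nx.Graph) -> float:
    n = network.number_of_nodes()
    return 2.0 * network.number_of_edges() / n if n else 0.0


def _global_efficiency(network: nx.Graph) -> float:
    return nx.global_efficiency(network) if network.number_of_nodes() > 1 else 0.0


def _vulnerability(network: nx.Graph) -> float:
    """Largest relative drop in global efficiency over single-node deletions."""
    e0 = _global_efficiency(network)
    if e0 <= 0:
        return np.nan
    worst = -np.inf
    for v in list(network.nodes):
        h = network.copy()
        h.remove_node(v)
        worst = max(worst, (e0 - _global_efficiency(h)) / e0)
    return float(worst)


def network_properties(network: nx.Graph) -> NetworkProperties:
    """Full scalar property suite of an (unweighted, signed-edge) network."""
    n = network.number_of_nodes()
    if n < 1:
        raise ValueError("network has no nodes")
    m = network.number_of_edges()
    signs = [d.get("sign", "positive") for _, _, d in network.edges(data=True)]
    n_pos = sum(1 for s in signs if s == "positive")
    n_neg = m - n_pos
    connectance = 2.0 * m / (n * (n - 1)) if n > 1 else 0.0
    degrees = np.array([d for _, d in network.degree()], dtype=float)
    n_clusters = nx.number_connected_components(network)
    if m > 0:
        comms = nx.algorithms.community.greedy_modularity_communities(network)
        q = nx.algorithms.community.modularity(network, comms)
    else:
        q = np.nan
    if n >= 3:
        centralization = float(
            (degrees.max() - degrees).sum() / ((n - 1) * (n - 2))
        )
    else:
        centralization = np.nan
    if m > 0:
        ec = _eigenvector_centrality(network)
        central_eigen = float(max(ec.values()))
    else:
        central_eigen = np.nan
    return NetworkProperties(
        n_nodes=n,
        n_edges=m,
        n_positive=n_pos,
        n_negative=n_neg,
        positive_fraction=(n_pos / m) if m else np.nan,
        connectance=connectance,
        average_degree=_average_degree(network),
        n_clusters=n_clusters,
        modularity=float(q) if q == q else np.nan,
        degree_centralization=centralization,
        central_eigen=central_eigen,
        vulnerability=_vulnerability(network),
        natural_connectivity=natural_connectivity(network),
    )


def bootstrap_node_attributes(
    network: nx.Graph, n_boot: int = 10000, seed: int = 0
) -> dict:
    """Bootstrap distributions of degree, harmonic closeness, local clustering
    and eigenvector centrality.

    Node attributes are computed once on the intact graph; each bootstrap
    replicate resamples N nodes with replacement and records their values, so
    the returned arrays hold ``n_boot * N`` draws per attribute.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    nodes = list(network.nodes)
    n = len(nodes)
    if n == 0:
        raise ValueError("network has no nodes")
    deg = dict(network.degree())
    harm = nx.harmonic_centrality(network)
    clus = nx.clustering(network)
    if network.number_of_edges() > 0:
        eig = _eigenvector_centrality(network)
    else:
        eig = {v: 0.0 for v in nodes}
    norm = (n - 1) if n > 1 else 1
    base = {
        "degree": np.array([deg[v] for v in nodes], dtype=float),
        "closeness": np.array([harm[v] / norm for v in nodes]),
        "transitivity": np.array([clus[v] for v in nodes]),
        "eigenvector": np.array([abs(eig[v]) for v in nodes]),
    }
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=n_boot * n)
    return {name: vals[idx] for name, vals in base.items()}


def ks_compare(dist_a, dist_b, attribute="") -> KSResult:
    """Two-sided two-sample Kolmogorov-Smirnov test (asymptotic p)."""
    a = np.asarray(dist_a, dtype=float)
    b = np.asarray(dist_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("ks_compare requires non-empty samples")
    res = stats.ks_2samp(a, b, method="asymp")
    return KSResult(attribute=str(attribute), D=float(res.statistic), p=float(res.pvalue))


def _remove_random(network: nx.Graph, fraction: float, mode: str, rng) -> nx.Graph:
    h = network.copy()
    if mode == "nodes":
        nodes = list(h.nodes)
        k = int(np.floor(fraction * len(nodes)))
        if k:
            drop = rng.choice(len(nodes), size=k, replace=False)
            h.remove_nodes_from([nodes[i] for i in drop])
    elif mode == "edges":
        edges = list(h.edges)
        k = int(np.floor(fraction * len(edges)))
        if k:
            drop = rng.choice(len(edges), size=k, replace=False)
            h.remove_edges_from([edges[i] for i in drop])
    else:
        raise ValueError(f"removal mode must be 'nodes' or 'edges', got {mode!r}")
    return h


def stability_after_removal(
    network: nx.Graph,
    fraction: float = 0.5,
    mode: str = "nodes",
    n_replicates: int = 1000,
    seed: int = 0,
) -> dict:
    """Replicate distributions of average degree and natural connectivity
    after stochastically removing a fraction of nodes (or edges)."""
    if not (0 < fraction < 1):
        raise ValueError(f"fraction must be in (0, 1), got {fraction}")
    ss = np.random.SeedSequence(seed)
    streams = [np.random.default_rng(s) for s in ss.spawn(n_replicates)]
    avg = np.empty(n_replicates)
    nc = np.empty(n_replicates)
    for r, rng in enumerate(streams):
        h = _remove_random(network, fraction, mode, rng)
        if h.number_of_nodes() == 0:
            avg[r] = 0.0
            nc[r] = 0.0
        else:
            avg[r] = _average_degree(h)
            nc[r] = natural_connectivity(h)
    return {"average_degree": avg, "natural_connectivity": nc}


def robustness_sweep(
    network: nx.Graph,
    fractions=None,
    mode: str = "nodes",
    n_replicates: int = 100,
    seed: int = 0,
) -> RobustnessCurve:
    """Mean decline of average degree and natural connectivity along a grid of
    removal fractions, with an OLS line fitted to each mean curve."""
    if fractions is None:
        fractions = np.arange(0.0, 1.0, 0.1)
    fractions = np.asarray(fractions, dtype=float)
    if np.any((fractions < 0) | (fractions >= 1)):
        raise ValueError("fractions must lie in [0, 1)")
    ss = np.random.SeedSequence(seed)
    streams = ss.spawn(len(fractions))
    means = {"average_degree": [], "natural_connectivity": []}
    sds = {"average_degree": [], "natural_connectivity": []}
    for f, sub in zip(fractions, streams):
        if f == 0.0:
            avg = np.full(n_replicates, _average_degree(network))
            nc = np.full(n_replicates, natural_connectivity(network))
            dists = {"average_degree": avg, "natural_connectivity": nc}
        else:
            dists = stability_after_removal(
                network, fraction=f, mode=mode, n_replicates=n_replicates,
                seed=sub.generate_state(1)[0] % (2**31),
            )
        for k in means:
            means[k].append(dists[k].mean())
            sds[k].append(dists[k].std(ddof=0))
    mean_df = pd.DataFrame(means, index=fractions)
    sd_df = pd.DataFrame(sds, index=fractions)
    slopes = {}
    for k in means:
        res = stats.linregress(fractions, mean_df[k].to_numpy())
        slopes[k] = (float(res.slope), float(res.intercept))
    return RobustnessCurve(
        removal_mode=mode,
        fractions=fractions,
        mean=mean_df,
        sd=sd_df,
        slopes=slopes,
        n_replicates=n_replicates,
        seed=seed,
    )


def degree_class_partition(
    network_a: nx.Graph,
    network_b: nx.Graph,
    high_q: float = 0.75,
    low_q: float = 0.25,
) -> DegreeClasses:
    """High/low-degree node classes of two networks and their overlap.

    Per network, the high class is nodes with degree at or above the
    ``high_q`` quantile of positive degrees and the low class nodes at or
    below the ``low_q`` quantile; classes must not overlap.  Nodes present in
    both networks are cross-tabulated, and class transitions (high->low,
    low->high) are labelled.  Per-class total relative abundance is summed
    from the nodes' ``relative_abundance`` attribute when present.
    """

    def classes(g):
        deg = dict(g.degree())
        pos = np.array([d for d in deg.values() if d > 0], dtype=float)
        if pos.size == 0:
            return set(), set(deg), deg
        hi_thr = np.quantile(pos, high_q)
        lo_thr = np.quantile(pos, low_q)
        high = {v for v, d in deg.items() if d >= hi_thr}
        low = {v for v, d in deg.items() if d <= lo_thr}
        if high & low:
            raise ValueError(
                "degree quantiles collapse the high and low classes; "
                "choose more separated quantiles"
            )
        return high, low, deg

    high_a, low_a, deg_a = classes(network_a)
    high_b, low_b, deg_b = classes(network_b)
    shared = set(network_a.nodes) & set(network_b.nodes)
    pairs = pd.DataFrame(
        {
            "degree_a": [deg_a[v] for v in sorted(shared)],
            "degree_b": [deg_b[v] for v in sorted(shared)],
        },
        index=sorted(shared),
    )
    transitions = {}
    for v in shared:
        if v in high_a and v in low_b:
            transitions[v] = "high->low"
        elif v in low_a and v in high_b:
            transitions[v] = "low->high"

    def abundance(g, nodes):
        return float(
            sum(g.nodes[v].get("relative_abundance", 0.0) for v in nodes)
        )

    rows = []
    venn = {}
    for label, set_a, set_b, g_a, g_b in (
        ("high", high_a, high_b, network_a, network_b),
        ("low", low_a, low_b, network_a, network_b),
    ):
        spec_a = set_a - set_b
        spec_b = set_b - set_a
        both = set_a & set_b
        total = len(set_a | set_b)
        venn[label] = {"specific_a": spec_a, "specific_b": spec_b, "shared": both}
        rows.append(
            {
                "class": label,
                "n_a": len(set_a),
                "n_b": len(set_b),
                "n_specific_a": len(spec_a),
                "n_specific_b": len(spec_b),
                "n_shared": len(both),
                "pct_specific": 100.0 * (len(spec_a) + len(spec_b)) / total
                if total
                else np.nan,
                "pct_shared": 100.0 * len(both) / total if total else np.nan,
                "abundance_a": abundance(g_a, set_a),
                "abundance_b": abundance(g_b, set_b),
            }
        )
    return DegreeClasses(
        high_a=high_a,
        low_a=low_a,
        high_b=high_b,
        low_b=low_b,
        shared_nodes=shared,
        degree_pairs=pairs,
        transitions=transitions,
        summary=pd.DataFrame(rows).set_index("class"),
        class_venn=venn,
    )
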