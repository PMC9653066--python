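"""Synthetic paired-design microbial community generator with known ground truth.

The study design being emulated is a paired comparison: sites come in pairs,
one site per pair under each treatment, so baseline community composition is
shared within a pair while treatment effects act on top of it.  Counts follow
a lognormal-compositional model: per-taxon baseline log-abundances are drawn
once (heavy-tailed across taxa), a pair-level random intercept induces the
paired structure, planted differential taxa receive a log2 fold-change in one
group, and planted correlation blocks share a latent Gaussian factor so block
members co-vary across samples.  Sample proportions are renormalised and reads
drawn multinomially at Poisson library sizes.

Also provided: random rooted binary trees for phylogenetic diversity, sparse
taxon-to-function maps producing mock predicted-function tables, and two-group
metacommunity scenarios assembled by niche preference or by dispersal
(occupancy frequency) for testing assembly-mechanism inference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import TreeNode

from .containers import CountMatrix, FunctionTable

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "generate_paired_counts",
    "generate_tree",
    "generate_function_table",
    "generate_assembly_scenario",
]


@dataclass
class SyntheticConfig:
    """Parameters of the paired-count generator.

    diff_taxa entries are ``(taxon_index, log2_fold_change, group_label)``:
    the taxon's abundance is multiplied by ``2**log2_fold_change`` in that
    group.  corr_blocks entries are ``(member_indices, loading, sign)`` with
    loading in [0, 1]; members share a latent factor so pairwise log-abundance
    correlation approaches ``loading**2``.  A negative block sign flips the
    loading of every member after the first, planting negative associations.
    """

    n_taxa: int = 1000
    n_pairs: int = 3
    group_labels: tuple = ("no_camping", "camping")
    depth_mean: int = 10432
    abundance_shape: float = 2.0  # lognormal sigma of baseline abundances
    pair_sd: float = 0.4  # pair-level random intercept SD (log scale)
    noise_sd: float = 0.6  # residual log-abundance noise SD
    diff_taxa: list = field(default_factory=list)
    corr_blocks: list = field(default_factory=list)
    assembly_mode: str = "mixed"
    seed: int = 0

    def validate(self) -> None:
        if self.n_taxa < 10:
            raise ValueError(f"n_taxa must be >= 10, got {self.n_taxa}")
        if self.n_pairs < 2:
            raise ValueError(f"n_pairs must be >= 2, got {self.n_pairs}")
        if len(self.group_labels) != 2 or len(set(self.group_labels)) != 2:
            raise ValueError(f"group_labels must be two distinct labels")
        if self.depth_mean < 1:
            raise ValueError(f"depth_mean must be >= 1, got {self.depth_mean}")
        if self.abundance_shape <= 0:
            raise ValueError("abundance_shape must be positive")
        if self.assembly_mode not in {"niche", "dispersal", "mixed"}:
            raise ValueError(f"assembly_mode invalid: {self.assembly_mode!r}")
        seen = set()
        for idx, fc, grp in self.diff_taxa:
            if not (0 <= idx < self.n_taxa):
                raise ValueError(f"diff_taxa index {idx} out of range")
            if idx in seen:
                raise ValueError(f"diff_taxa index {idx} repeated")
            if grp not in self.group_labels:
                raise ValueError(f"diff_taxa group {grp!r} not in group_labels")
            seen.add(idx)
        for members, loading, sign in self.corr_blocks:
            if not (0.0 <= loading <= 1.0):
                raise ValueError(f"corr_blocks loading {loading} outside [0, 1]")
            if sign not in (1, -1, "positive", "negative"):
                raise ValueError(f"corr_blocks sign invalid: {sign!r}")
            for m in members:
                if not (0 <= m < self.n_taxa):
                    raise ValueError(f"corr_blocks member {m} out of range")


@dataclass
class GroundTruth:
    """Planted structure: differential taxa and within-block edges with sign."""

    true_diff_taxa: set
    true_edges: set  # frozenset pairs -> handled as {(i, j, sign)} with i < j
    assembly_mode: str

    def edge_pairs(self) -> set:
        return {(i, j) for i, j, _ in self.true_edges}


def _block_sign(sign) -> int:
    return 1 if sign in (1, "positive") else -1


def generate_paired_counts(config: SyntheticConfig):
    """Draw a paired count table and its ground truth.

    Returns ``(CountMatrix, GroundTruth)``.  Deterministic for a fixed
    ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_taxa
    n_samples = 2 * config.n_pairs
    g0, g1 = config.group_labels

    sample_ids, groups, pairs = [], [], []
    for p in range(config.n_pairs):
        for g in (g0, g1):
            sample_ids.append(f"S{p + 1}_{g}")
            groups.append(g)
            pairs.append(f"P{p + 1}")
    groups = np.array(groups)

    # taxon baseline (heavy-tailed across taxa), shared by all samples
    mu = rng.normal(0.0, config.abundance_shape, size=n)
    # pair-level random intercept, shared by the two samples of a pair
    pair_eff = rng.normal(0.0, config.pair_sd, size=(n, config.n_pairs))
    log_ab = mu[:, None] + np.repeat(pair_eff, 2, axis=1)

    eps = rng.normal(0.0, 1.0, size=(n, n_samples))
    log_ab = log_ab + config.noise_sd * eps

    # block members: the latent factor replaces the member's whole
    # non-baseline variation (pair intercept included), so that pairwise
    # log-abundance correlation within a block approaches loading**2
    sigma_resid = np.hypot(config.pair_sd, config.noise_sd)
    true_edges = set()
    for members, loading, sign in config.corr_blocks:
        z = rng.normal(0.0, 1.0, size=n_samples)
        s = _block_sign(sign)
        members = list(members)
        member_signs = {}
        for k, m in enumerate(members):
            ms = 1 if (k == 0 or s == 1) else -1
            member_signs[m] = ms
            log_ab[m] = mu[m] + sigma_resid * (
                ms * loading * z + np.sqrt(max(0.0, 1.0 - loading**2)) * eps[m]
            )
        for a in range(len(members)):
            for b in range(a + 1, len(members)):
                i, j = sorted((members[a], members[b]))
                true_edges.add((i, j, member_signs[i] * member_signs[j]))

    # planted differential taxa
    for idx, fc, grp in config.diff_taxa:
        log_ab[idx, groups == grp] += fc * np.log(2.0)

    props = np.exp(log_ab - log_ab.max(axis=0))
    props /= props.sum(axis=0)

    counts = np.zeros((n, n_samples), dtype=np.int64)
    for j in range(n_samples):
        depth = max(1, int(rng.poisson(config.depth_mean)))
        counts[:, j] = rng.multinomial(depth, props[:, j])
        if counts[:, j].sum() == 0:  # pragma: no cover - depth >= 1 above
            counts[rng.integers(n), j] = 1

    taxon_ids = [f"OTU_{i + 1}" for i in range(n)]
    md = pd.DataFrame({"group": groups, "pair": pairs}, index=sample_ids)
    cm = CountMatrix(taxon_ids, sample_ids, counts, md)
    gt = GroundTruth(
        true_diff_taxa={idx for idx, _, _ in config.diff_taxa},
        true_edges=true_edges,
        assembly_mode=config.assembly_mode,
    )
    return cm, gt


def generate_tree(taxon_ids, seed: int = 0) -> TreeNode:
    """Random rooted binary tree over ``taxon_ids`` with positive branch lengths.

    Built by successive random coalescence of lineages; with n leaves the tree
    has n - 1 internal nodes.
    """
    taxon_ids = list(taxon_ids)
    if len(taxon_ids) < 2:
        raise ValueError("generate_tree requires at least 2 taxa")
    rng = np.random.default_rng(seed)
    nodes = []
    for name in taxon_ids:
        leaf = TreeNode(name=str(name))
        leaf.length = float(rng.uniform(0.1, 1.0))
        nodes.append(leaf)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        parent = TreeNode(children=[a, b])
        parent.length = float(rng.uniform(0.1, 1.0))
        nodes.append(parent)
    root = nodes[0]
    root.length = 0.0
    return root


def generate_function_table(
    counts: CountMatrix, n_functions: int, map_density: float, seed: int = 0
) -> FunctionTable:
    """Mock predicted-function table from a random sparse taxon-function map.

    Each taxon maps to each function independently with probability
    ``map_density``; a function's abundance in a sample is the summed relative
    abundance of its mapped taxa.
    """
    if counts.n_taxa == 0 or counts.n_samples == 0:
        raise ValueError("empty count matrix")
    if n_functions < 1:
        raise ValueError(f"n_functions must be >= 1, got {n_functions}")
    if not (0 < map_density <= 1):
        raise ValueError(f"map_density must be in (0, 1], got {map_density}")
    rng = np.random.default_rng(seed)
    incidence = rng.random((n_functions, counts.n_taxa)) < map_density
    rel = counts.relative_abundance()
    values = incidence.astype(float) @ rel
    ids = [f"F{k + 1}" for k in range(n_functions)]
    return FunctionTable(ids, list(counts.sample_ids), values)


def generate_assembly_scenario(
    mode: str, n_sites: int, n_species: int, seed: int = 0
) -> CountMatrix:
    """Two-group metacommunity assembled by niche filtering or by dispersal.

    niche mode: the habitat controls occurrence -- sites of one group are
    broadly suitable (per-site occurrence probability drawn from 0.85-0.98)
    while sites of the other group are hostile (0.05-0.25), so every species
    occurs mainly in the suitable group and composition is determined by the
    sample margin (site suitability/richness).  dispersal mode: each species
    has its own prevalence, drawn heterogeneously and applied identically at
    every site, so the species margin (occupancy frequency), not group
    identity, shapes composition.
    """
    if mode not in {"niche", "dispersal"}:
        raise ValueError(f"mode must be 'niche' or 'dispersal', got {mode!r}")
    if n_sites < 4:
        raise ValueError(f"n_sites must be >= 4, got {n_sites}")
    if n_sites % 2:
        raise ValueError("n_sites must be even (two equal groups)")
    if n_species < 10:
        raise ValueError(f"n_species must be >= 10, got {n_species}")
    rng = np.random.default_rng(seed)
    half = n_sites // 2
    group_of_site = np.array(["A"] * half + ["B"] * half)

    if mode == "niche":
        suitability = np.where(
            group_of_site == "A",
            rng.uniform(0.85, 0.98, size=n_sites),
            rng.uniform(0.05, 0.25, size=n_sites),
        )
        p_occ = np.repeat(suitability[None, :], n_species, axis=0)
    else:
        prevalence = rng.uniform(0.1, 0.9, size=n_species)
        p_occ = np.repeat(prevalence[:, None], n_sites, axis=1)

    present = rng.random((n_species, n_sites)) < p_occ
    # guarantee no empty site and no globally absent species
    for j in range(n_sites):
        if not present[:, j].any():
            present[rng.integers(n_species), j] = True
    counts = np.where(present, rng.poisson(50, size=present.shape) + 1, 0)

    species = [f"SP_{i + 1}" for i in range(n_species)]
    sites = [f"site_{j + 1}" for j in range(n_sites)]
    pairs = [f"P{(j % half) + 1}" for j in range(n_sites)]
    md = pd.DataFrame({"group": group_of_site, "pair": pairs}, index=sites)
    return CountMatrix(species, sites, counts, md)
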