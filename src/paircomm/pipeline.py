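"""End-to-end orchestration of the paired-community analysis.

``run_pipeline`` sequences the stages — load or simulate counts, OTU
filtering, rarefaction, alpha diversity and group tests, PERMANOVA, Venn
partitioning, the random-forest screen, function comparisons, per-group
co-occurrence networks with their property/stability/robustness suites,
niche metrics with generalist classification and the dispersal-niche test,
and finally the regressions and the Bayesian path model — writing
machine-readable TSV/JSON results plus a run log.  A single global seed
deterministically spawns one substream per stage, so re-running a config
reproduces byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as pio
from .containers import CountMatrix
from .diversity import alpha_diversity, function_diversity, rarefy
from .groupstats import (
    auto_group_test,
    distance_matrix,
    permanova,
    rf_screen,
    venn_partition,
    welch_compare,
)
from .network import (
    bootstrap_node_attributes,
    build_network,
    degree_class_partition,
    filter_otus,
    ks_compare,
    network_properties,
    robustness_sweep,
    stability_after_removal,
)
from .niche import classify_generalists, dnci_test, levins_breadth, pianka_overlap
from .pathmodel import delta_degree, fit_path_model, fit_regression
from .synthetic import SyntheticConfig, generate_function_table, generate_paired_counts

__all__ = ["PipelineConfig", "run_pipeline"]

STAGES = (
    "input",
    "filter",
    "rarefaction",
    "diversity",
    "group_tests",
    "venn",
    "rf_screen",
    "functions",
    "networks",
    "niche",
    "path_model",
)


@dataclass
class PipelineConfig:
    """Everything a run needs; exactly one of synthetic / counts_path is set."""

    output_dir: str = "paircomm_results"
    seed: int = 0
    synthetic: dict | None = None
    counts_path: str | None = None
    metadata_path: str | None = None
    tree_path: str | None = None
    function_table_path: str | None = None
    n_functions: int = 50
    map_density: float = 0.05
    rarefy_depth: int | None = None  # default: smallest sample total
    r_threshold: float = 0.8
    p_cut: float = 0.001
    permutations: int = 9999
    n_boot: int = 10000
    stability_replicates: int = 1000
    robustness_replicates: int = 100
    removal_fraction: float = 0.5
    rf_trees: int = 10000
    high_quantile: float = 0.75
    low_quantile: float = 0.25
    niche_permutations: int = 1000
    dnci_permutations: int = 100
    alpha: float = 0.05
    sem_chains: int = 4
    sem_iterations: int = 5000
    sem_burn_in: int = 1000

    def validate(self) -> None:
        if (self.synthetic is None) == (self.counts_path is None):
            raise ValueError(
                "config must set exactly one of 'synthetic' or 'counts_path'"
            )
        if self.counts_path is not None and self.metadata_path is None:
            raise ValueError("counts_path requires metadata_path")
        for name in (
            "permutations",
            "n_boot",
            "stability_replicates",
            "robustness_replicates",
            "rf_trees",
            "niche_permutations",
            "dnci_permutations",
            "sem_chains",
            "sem_iterations",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def _json_dump(obj, path):
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (set, frozenset)):
            return sorted(o)
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        raise TypeError(f"not JSON serialisable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True, default=default)


def _stage_seed(ss_children, stage: str) -> int:
    return int(ss_children[stage].generate_state(1)[0] % (2**31))


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write the results bundle; returns a report dict."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "FAILED").unlink(missing_ok=True)
    ss = np.random.SeedSequence(config.seed)
    stage_seeds = dict(zip(STAGES, ss.spawn(len(STAGES))))
    seeds = {s: _stage_seed(stage_seeds, s) for s in STAGES}
    report: dict = {"seed": config.seed, "stage_seeds": seeds, "stages": {}}
    current = "input"
    try:
        # ---- input -------------------------------------------------------
        tree = None
        ground_truth = None
        if config.synthetic is not None:
            syn = SyntheticConfig(**{**config.synthetic, "seed": seeds["input"]})
            counts, ground_truth = generate_paired_counts(syn)
            pio.write_counts(counts, out / "counts.tsv", out / "metadata.tsv")
            _json_dump(
                {
                    "true_diff_taxa": sorted(ground_truth.true_diff_taxa),
                    "true_edges": sorted(ground_truth.true_edges),
                    "assembly_mode": ground_truth.assembly_mode,
                },
                out / "ground_truth.json",
            )
        else:
            counts = pio.read_counts(config.counts_path, config.metadata_path)
        if config.tree_path is not None:
            tree = pio.read_newick(config.tree_path)
        report["stages"]["input"] = {
            "n_taxa": counts.n_taxa,
            "n_samples": counts.n_samples,
        }

        # ---- filter ------------------------------------------------------
        current = "filter"
        filtered = filter_otus(counts)
        pio.write_counts(filtered, out / "filtered_counts.tsv")
        report["stages"]["filter"] = {"n_taxa": filtered.n_taxa}

        # ---- rarefaction + diversity ------------------------------------
        current = "rarefaction"
        depth = config.rarefy_depth or int(counts.sample_sums().min())
        rare = rarefy(counts, depth, seed=seeds["rarefaction"])
        report["stages"]["rarefaction"] = {
            "depth": depth,
            "n_samples_kept": rare.n_samples,
        }

        current = "diversity"
        div = alpha_diversity(rare, tree=tree)
        div.to_csv(out / "alpha_diversity.tsv", sep="\t")
        report["stages"]["diversity"] = {"indices": list(div.columns)}

        # ---- group tests on diversity + PERMANOVA -----------------------
        current = "group_tests"
        groups = rare.groups
        rows = []
        for col in div.columns:
            vals = div[col].to_numpy()
            if np.isnan(vals).any() or np.ptp(vals) == 0:
                continue
            r = auto_group_test(vals, groups, variable=col)
            rows.append(dataclasses.asdict(r))
        pd.DataFrame(rows).to_csv(out / "diversity_tests.tsv", sep="\t", index=False)
        perm_results = {}
        for metric in ("bray_curtis", "jaccard"):
            d = distance_matrix(rare, metric)
            res = permanova(
                d,
                groups,
                n_permutations=config.permutations,
                seed=seeds["group_tests"],
                distance_name=metric,
            )
            perm_results[metric] = dataclasses.asdict(res)
        _json_dump(perm_results, out / "permanova.json")
        report["stages"]["group_tests"] = {
            m: {"R2": r["R2"], "p": r["p"]} for m, r in perm_results.items()
        }

        # ---- venn --------------------------------------------------------
        current = "venn"
        venn = venn_partition(counts)
        _json_dump(dataclasses.asdict(venn), out / "venn.json")
        report["stages"]["venn"] = {
            "n_unique_a": len(venn.unique_to_a),
            "n_unique_b": len(venn.unique_to_b),
            "n_shared": len(venn.shared),
        }

        # ---- random-forest screen ---------------------------------------
        current = "rf_screen"
        imp = rf_screen(filtered, n_trees=config.rf_trees, seed=seeds["rf_screen"])
        imp.to_csv(out / "rf_importance.tsv", sep="\t")
        discriminating = imp.index[imp["kw_p"] < config.alpha].tolist()
        report["stages"]["rf_screen"] = {"n_discriminating": len(discriminating)}

        # ---- function tables --------------------------------------------
        current = "functions"
        if config.function_table_path is not None:
            ftab = pio.read_function_table(config.function_table_path)
        else:
            ftab = generate_function_table(
                counts, config.n_functions, config.map_density, seed=seeds["functions"]
            )
            pio.write_function_table(ftab, out / "function_table.tsv")
        fdiv = function_diversity(ftab)
        fdiv.to_csv(out / "function_diversity.tsv", sep="\t")
        welch = welch_compare(ftab, counts.groups)
        pd.DataFrame([dataclasses.asdict(w) for w in welch]).to_csv(
            out / "function_welch.tsv", sep="\t", index=False
        )
        report["stages"]["functions"] = {
            "n_functions": ftab.n_functions,
            "n_significant": int(
                sum(1 for w in welch if np.isfinite(w.p) and w.p < config.alpha)
            ),
        }

        # ---- per-group networks -----------------------------------------
        current = "networks"
        levels = list(pd.unique(counts.groups))
        nets = {}
        net_report = {}
        min_group_n = min(int((filtered.groups == g).sum()) for g in levels)
        if min_group_n >= 4 and filtered.n_taxa >= 2:
            for g in levels:
                idx = np.flatnonzero(filtered.groups == g)
                sub = filtered.select_samples(idx)
                net = build_network(sub, config.r_threshold, config.p_cut)
                nets[g] = net
                pio.write_graph(net, out / f"network_{g}.graphml")
                pio.write_graph(
                    net, out / f"network_{g}_edges.tsv", format="edgelist_tsv"
                )
                props = network_properties(net)
                net_report[g] = props.to_dict()
            _json_dump(net_report, out / "network_properties.json")

            ga, gb = levels
            boots = {
                g: bootstrap_node_attributes(
                    nets[g], n_boot=config.n_boot, seed=seeds["networks"]
                )
                for g in levels
            }
            ks_rows = [
                dataclasses.asdict(ks_compare(boots[ga][k], boots[gb][k], attribute=k))
                for k in boots[ga]
            ]
            pd.DataFrame(ks_rows).to_csv(
                out / "network_ks.tsv", sep="\t", index=False
            )
            stab = {
                g: stability_after_removal(
                    nets[g],
                    fraction=config.removal_fraction,
                    n_replicates=config.stability_replicates,
                    seed=seeds["networks"],
                )
                for g in levels
            }
            stab_rows = []
            for prop in ("average_degree", "natural_connectivity"):
                ks = ks_compare(stab[ga][prop], stab[gb][prop], attribute=prop)
                stab_rows.append(
                    {
                        "property": prop,
                        f"mean_{ga}": float(stab[ga][prop].mean()),
                        f"mean_{gb}": float(stab[gb][prop].mean()),
                        "ks_D": ks.D,
                        "ks_p": ks.p,
                    }
                )
            pd.DataFrame(stab_rows).to_csv(
                out / "network_stability.tsv", sep="\t", index=False
            )
            for g in levels:
                for mode in ("nodes", "edges"):
                    curve = robustness_sweep(
                        nets[g],
                        mode=mode,
                        n_replicates=config.robustness_replicates,
                        seed=seeds["networks"],
                    )
                    df = curve.mean.add_suffix("_mean").join(
                        curve.sd.add_suffix("_sd")
                    )
                    df.index.name = "fraction"
                    df.to_csv(out / f"robustness_{g}_{mode}.tsv", sep="\t")
            try:
                classes = degree_class_partition(
                    nets[ga], nets[gb], config.high_quantile, config.low_quantile
                )
            except ValueError as err:  # degenerate degree distribution
                classes = None
                (out / "degree_classes.tsv").write_text(f"# skipped: {err}\n")
            if classes is not None:
                classes.summary.to_csv(out / "degree_classes.tsv", sep="\t")
                pd.Series(
                    classes.transitions, name="transition"
                ).sort_index().to_csv(out / "degree_transitions.tsv", sep="\t")
            report["stages"]["networks"] = {
                g: {
                    "n_nodes": net_report[g]["n_nodes"],
                    "n_edges": net_report[g]["n_edges"],
                }
                for g in levels
            }
        else:
            classes = None
            report["stages"]["networks"] = {
                "skipped": f"needs >= 4 samples per group (have {min_group_n})"
            }

        # ---- niche metrics ----------------------------------------------
        current = "niche"
        breadth = levins_breadth(filtered)
        breadth.to_csv(out / "niche_breadth.tsv", sep="\t")
        niche_class = classify_generalists(
            filtered,
            n_perm=config.niche_permutations,
            alpha=config.alpha,
            seed=seeds["niche"],
        )
        niche_class.to_csv(out / "niche_class.tsv", sep="\t")
        # assembly inference sees the whole community: rare taxa carry the
        # presence/absence signal the filter strips out
        dnci = dnci_test(
            counts, n_perm=config.dnci_permutations, seed=seeds["niche"]
        )
        _json_dump(
            {
                "mean_e": dnci.mean_e,
                "selected_regime": dnci.selected_regime,
                "n_permutations": dnci.n_permutations,
            },
            out / "dnci.json",
        )
        share = niche_class.value_counts(normalize=True)
        report["stages"]["niche"] = {
            "selected_regime": dnci.selected_regime,
            "pct_generalist": float(100 * share.get("generalist", 0.0)),
            "pct_specialist": float(100 * share.get("specialist", 0.0)),
        }

        # ---- regressions + path model -----------------------------------
        current = "path_model"
        if nets:
            ga, gb = levels
            records = []
            for g in levels:
                idx = np.flatnonzero(filtered.groups == g)
                sub = filtered.select_samples(idx)
                b = levins_breadth(sub)
                ov = pianka_overlap(sub)
                net = nets[g]
                deg = dict(net.degree())
                mean_ov = ov.mean(axis=1, skipna=True)
                for otu in net.nodes:
                    records.append(
                        {
                            "otu": otu,
                            "group": g,
                            "width": b.get(otu, np.nan),
                            "overlap": mean_ov.get(otu, np.nan),
                            "degree": deg[otu],
                        }
                    )
            rec = pd.DataFrame(records)
            if classes is not None and len(classes.degree_pairs):
                dd = delta_degree(classes)
                rec["delta_degree"] = rec["otu"].map(dd)
            else:
                rec["delta_degree"] = np.nan
            rec.to_csv(out / "path_records.tsv", sep="\t", index=False)

            reg_rows = []
            for g in levels:
                sub = rec[(rec.group == g) & rec.width.notna()]
                if len(sub) >= 3 and sub.width.nunique() > 1:
                    r = fit_regression(sub.width, sub.degree)
                    reg_rows.append({"group": g, "x": "width", "y": "degree",
                                     **dataclasses.asdict(r)})
                sub = rec[(rec.group == g) & rec.overlap.notna()
                          & rec.delta_degree.notna()]
                if len(sub) >= 3 and sub.overlap.nunique() > 1:
                    r = fit_regression(sub.overlap, sub.delta_degree)
                    reg_rows.append({"group": g, "x": "overlap", "y": "delta_degree",
                                     **dataclasses.asdict(r)})
            pd.DataFrame(reg_rows).to_csv(
                out / "regressions.tsv", sep="\t", index=False
            )

            sem_out = {}
            fit_a = rec[rec.width.notna()]
            if (
                fit_a.group.nunique() == 2
                and len(fit_a) >= 6
                and fit_a.width.nunique() > 1
                and fit_a.degree.nunique() > 1
            ):
                res = fit_path_model(
                    fit_a.group.to_numpy(),
                    fit_a.width.to_numpy(),
                    fit_a.degree.to_numpy(),
                    n_chains=config.sem_chains,
                    n_iter=config.sem_iterations,
                    burn_in=config.sem_burn_in,
                    seed=seeds["path_model"],
                )
                sem_out["width_degree"] = {
                    "summary": res.summary.to_dict(orient="index"),
                    "converged": res.converged,
                }
            fit_b = rec[rec.overlap.notna() & rec.delta_degree.notna()]
            if (
                fit_b.group.nunique() == 2
                and len(fit_b) >= 6
                and fit_b.overlap.nunique() > 1
                and fit_b.delta_degree.nunique() > 1
            ):
                res = fit_path_model(
                    fit_b.group.to_numpy(),
                    fit_b.overlap.to_numpy(),
                    fit_b.delta_degree.to_numpy(),
                    n_chains=config.sem_chains,
                    n_iter=config.sem_iterations,
                    burn_in=config.sem_burn_in,
                    seed=seeds["path_model"],
                )
                sem_out["overlap_delta_degree"] = {
                    "summary": res.summary.to_dict(orient="index"),
                    "converged": res.converged,
                }
            _json_dump(sem_out, out / "path_model.json")
            report["stages"]["path_model"] = {
                k: {"a": v["summary"]["a"]["mean"], "b": v["summary"]["b"]["mean"]}
                for k, v in sem_out.items()
            }
        else:
            report["stages"]["path_model"] = {"skipped": "no networks built"}
    except Exception as exc:
        (out / "FAILED").write_text(f"stage {current}: {exc}\n")
        raise RuntimeError(f"pipeline failed at stage {current!r}: {exc}") from exc

    report["status"] = "ok"
    _json_dump(report, out / "run_log.json")
    return report
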