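"""End-to-end orchestration from a single YAML config.

Stage order follows the analysis narrative: catalog assembly -> age
assignment and cross-validation -> age-class composition -> tau tissue
specificity -> interactome (graph, degree partition, subnetworks,
Monte Carlo enrichment, reproductive association) -> MKT rate
decomposition and group comparisons.  Stages whose inputs are absent
from the config are skipped with a recorded reason; any stage error
aborts the run naming the stage.  Re-running with the same config and
seed reproduces every statistic exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from . import catalog as cat
from . import composition as comp
from . import expression as expr
from . import mkt as mktmod
from . import network as net
from .catalog import AGE_CLASSES, UNASSIGNED
from .stats import GroupComparison

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "ReportBundle", "run_pipeline", "default_config_yaml"]


@dataclass
class PipelineConfig:
    """All inputs and thresholds for one pipeline run."""

    # input paths (None disables the dependent stage)
    list_a: str | None = None
    list_b: str | None = None
    ages: str | None = None
    exceptions: str | None = None
    ortholog_ids: str | None = None
    paralog_groups: str | None = None
    expression: str | None = None
    edges: str | None = None
    repro_flags: str | None = None
    mkt_counts: dict[str, str] = field(default_factory=dict)  # population -> JSON path

    # analysis parameters
    background_props: dict[str, float] = field(default_factory=dict)
    tau_threshold: float = 0.9
    target_tissues: list[str] = field(default_factory=list)
    tau_transform: str = "log2"
    network_threshold: float = net.DEFAULT_THRESHOLD
    excluded_channels: list[str] = field(default_factory=lambda: list(net.DEFAULT_EXCLUDED))
    min_subnetwork_size: int = 4
    n_resamples: int = 100_000
    n_assoc_sim: int = 2000
    mkt_cutoff: float = 0.05
    collapse_paralogs: bool = False
    seed: int = 0
    outdir: str = "sfpage_out"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        if not 0.0 <= self.tau_threshold <= 1.0:
            raise ValueError("tau_threshold must lie in [0, 1]")
        if not 0.0 <= self.network_threshold <= 1.0:
            raise ValueError("network_threshold must lie in [0, 1]")
        if self.min_subnetwork_size < 1:
            raise ValueError("min_subnetwork_size must be >= 1")
        if self.n_resamples < 1 or self.n_assoc_sim < 1:
            raise ValueError("simulation counts must be >= 1")
        if not 0.0 <= self.mkt_cutoff < 1.0:
            raise ValueError("mkt_cutoff must lie in [0, 1)")
        if self.list_a is None or self.list_b is None:
            raise ValueError("list_a and list_b are required")
        for name in ("list_a", "list_b", "ages", "exceptions", "ortholog_ids",
                     "paralog_groups", "expression", "edges", "repro_flags"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise ValueError(f"config path {name} does not exist: {p}")
        for pop, p in self.mkt_counts.items():
            if not Path(p).exists():
                raise ValueError(f"mkt_counts[{pop}] does not exist: {p}")


@dataclass
class ReportBundle:
    outdir: Path
    outputs: dict[str, Path]
    summary: dict[str, Any]
    skipped: dict[str, str]


def default_config_yaml() -> str:
    """Commented template for `sfpage config init`."""
    cfg = PipelineConfig()
    data = dataclasses.asdict(cfg)
    return (
        "# sfpage pipeline configuration (all thresholds at their defaults)\n"
        + yaml.safe_dump(data, sort_keys=True)
    )


def _comparison_dict(c: GroupComparison) -> dict:
    return {
        "omnibus": {
            "statistic": c.omnibus.statistic,
            "df": c.omnibus.df,
            "p": c.omnibus.p,
            "method": c.omnibus.method,
        },
        "groups": {k: {"n": n, "median": m} for k, (n, m) in c.groups.items()},
        "pairwise": [
            {"pair": list(r.pair), "statistic": r.statistic, "p_raw": r.p_raw, "p_adj": r.p_adj}
            for r in c.pairwise
        ],
    }


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Execute all configured stages and write the report bundle."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}
    skipped: dict[str, str] = {}
    summary: dict[str, Any] = {}

    def save_json(name: str, payload: Any) -> None:
        p = outdir / f"{name}.json"
        p.write_text(json.dumps(payload, indent=1, default=str))
        outputs[name] = p

    def save_tsv(name: str, df: pd.DataFrame, index: bool = False) -> None:
        p = outdir / f"{name}.tsv"
        df.to_csv(p, sep="\t", index=index)
        outputs[name] = p

    # --- catalog -------------------------------------------------------
    try:
        ids_a = set(cat.read_gene_table(config.list_a)["gene_id"])
        ids_b = set(cat.read_gene_table(config.list_b)["gene_id"])
        catalog = cat.assemble_catalog(ids_a, ids_b)
        if config.ages:
            age_table = cat.read_mapping(config.ages, "gene_id", "age_class")
            exceptions: set[str] = set()
            if config.exceptions:
                exceptions = set(cat.read_gene_table(config.exceptions)["gene_id"])
            catalog = cat.assign_ages(catalog, age_table, exceptions)
        if config.collapse_paralogs and config.paralog_groups:
            groups = cat.read_mapping(config.paralog_groups, "gene_id", "paralog_group")
            catalog = cat.collapse_paralogs(catalog, groups)
        save_tsv("catalog", catalog.to_frame())
        summary["catalog"] = {
            "n_union": len(catalog),
            "n_conservative": len(catalog.conservative_ids),
            "n_unassigned": len(catalog.unassigned_ids),
            "class_counts": catalog.class_counts(),
        }
    except Exception as e:  # noqa: BLE001 - re-raise with stage context
        raise RuntimeError(f"stage 'catalog' failed: {e}") from e

    # --- age validation ------------------------------------------------
    if config.ortholog_ids and config.ages:
        try:
            ortho = list(cat.read_gene_table(config.ortholog_ids)["gene_id"])
            report = cat.cross_validate_ages(catalog, ortho)
            save_json("age_validation", report.to_dict())
            summary["age_validation"] = {
                "n_checked": report.n_checked,
                "n_discrepant": report.n_discrepant,
                "rate_percent": report.rate_percent,
            }
        except Exception as e:
            raise RuntimeError(f"stage 'age_validation' failed: {e}") from e
    else:
        skipped["age_validation"] = "no ortholog_ids/ages configured"

    # --- composition ---------------------------------------------------
    if config.background_props and config.ages:
        try:
            results = {}
            for label, subset in (
                ("all", None),
                ("conservative", catalog.conservative_ids),
            ):
                observed = catalog.class_counts(subset)
                res = comp.composition_test(observed, config.background_props)
                results[label] = res.to_dict()
            save_json("composition", results)
            summary["composition"] = {
                k: {"chi2": v["chi2"], "p": v["p"]} for k, v in results.items()
            }
        except Exception as e:
            raise RuntimeError(f"stage 'composition' failed: {e}") from e
    else:
        skipped["composition"] = "no background_props/ages configured"

    # --- tau -----------------------------------------------------------
    tau_table = None
    if config.expression:
        try:
            matrix = expr.read_expression_matrix(config.expression)
            matrix = matrix.loc[matrix.index.intersection(list(catalog.ids))]
            tau_table = expr.specificity_calls(
                matrix,
                threshold=config.tau_threshold,
                target_tissues=config.target_tissues,
                transform=config.tau_transform,
            )
            save_tsv("tau", tau_table, index=True)
            summary["tau"] = {
                "n_genes": int(len(tau_table)),
                "n_specific": int(tau_table["is_specific"].sum()),
                "n_target_specific": int(tau_table["is_target_specific"].sum()),
            }
            if config.ages:
                comparison = expr.compare_tau_by_age(tau_table, catalog)
                save_json("tau_by_age", _comparison_dict(comparison))
                summary["tau_by_age"] = {
                    "kw_statistic": comparison.omnibus.statistic,
                    "p": comparison.omnibus.p,
                }
        except Exception as e:
            raise RuntimeError(f"stage 'tau' failed: {e}") from e
    else:
        skipped["tau"] = "no expression matrix configured"

    # --- interactome ---------------------------------------------------
    subnetworks: list[net.Subnetwork] = []
    network = None
    if config.edges:
        try:
            edges = net.read_edge_table(config.edges)
            network = net.build_network(
                edges,
                sfp_ids=catalog.ids,
                threshold=config.network_threshold,
                excluded=config.excluded_channels,
            )
            degrees = net.degree_partition(network)
            save_tsv("degree_partition", degrees, index=True)
            subnetworks = net.extract_subnetworks(network, min_size=config.min_subnetwork_size)
            save_tsv(
                "subnetworks",
                pd.DataFrame(
                    [
                        {"subnetwork": s.id, "size": s.size, "is_core": s.is_core,
                         "members": ";".join(sorted(s.members))}
                        for s in subnetworks
                    ]
                ),
            )
            summary["network"] = {
                "n_edges": network.n_edges,
                "n_sfp_with_ppi": len(network.sfps_with_interactions()),
                "n_subnetworks": len(subnetworks),
                "core_size": subnetworks[0].size if subnetworks else 0,
                "n_in_subnetworks": int(sum(s.size for s in subnetworks)),
            }
            age_labels = {
                r.gene_id: r.age_class for r in catalog if r.age_class != UNASSIGNED
            }
            if subnetworks and config.ages:
                networked = set().union(*(s.members for s in subnetworks))
                if networked <= set(age_labels):
                    enrich = net.mc_age_enrichment(
                        subnetworks,
                        age_labels,
                        n_resamples=config.n_resamples,
                        seed=config.seed,
                    )
                    save_tsv("age_enrichment", enrich)
                    summary["age_enrichment"] = {
                        "n_tests": int(len(enrich)),
                        "n_significant_adj": int((enrich["p_adj"] < 0.05).sum()),
                    }
                else:
                    skipped["age_enrichment"] = "subnetwork members without age class"
            if subnetworks and config.repro_flags:
                flags_df = cat.read_gene_table(config.repro_flags)
                flags = {
                    g: str(v).lower() in ("true", "1", "yes")
                    for g, v in zip(flags_df["gene_id"], flags_df["reproductive"])
                }
                omnibus, posthoc = net.reproductive_association(
                    subnetworks, flags, n_sim=config.n_assoc_sim, seed=config.seed
                )
                save_tsv("reproductive_posthoc", posthoc)
                save_json(
                    "reproductive_association",
                    {
                        "chi2": omnibus.statistic,
                        "df": omnibus.df,
                        "p": omnibus.p,
                        "n_sim": omnibus.n_sim,
                    },
                )
                summary["reproductive_association"] = {
                    "chi2": omnibus.statistic,
                    "p": omnibus.p,
                }
            node_attrs: dict[str, Mapping[str, object]] = {"age_class": age_labels}
            net.export_network(network, subnetworks, outdir / "network.graphml",
                               node_attrs=node_attrs)
            outputs["network_graphml"] = outdir / "network.graphml"
        except Exception as e:
            raise RuntimeError(f"stage 'network' failed: {e}") from e
    else:
        skipped["network"] = "no edge table configured"

    # --- MKT -----------------------------------------------------------
    if config.mkt_counts:
        try:
            core_members = subnetworks[0].members if subnetworks else frozenset()
            mkt_summary = {}
            for pop, path in sorted(config.mkt_counts.items()):
                counts = mktmod.read_site_counts(path)
                table = mktmod.mkt_table(counts, cutoff=config.mkt_cutoff)
                save_tsv(f"mkt_{pop}", table, index=True)
                pop_summary: dict[str, Any] = {
                    "n_genes": int(len(table)),
                    "n_usable": int(table["usable"].sum()),
                }
                if config.ages:
                    ages = {
                        r.gene_id: r.age_class
                        for r in catalog
                        if r.age_class != UNASSIGNED
                    }
                    for metric in ("omega", "omega_a", "omega_na"):
                        comparison = mktmod.compare_rates(table, ages, metric=metric)
                        save_json(f"mkt_{pop}_{metric}_by_age", _comparison_dict(comparison))
                        pop_summary[f"{metric}_by_age_p"] = comparison.omnibus.p
                if core_members:
                    strata = {
                        g: ("core" if g in core_members else "other")
                        for g in table.index
                    }
                    comparison = mktmod.compare_rates(table, strata, metric="omega")
                    save_json(f"mkt_{pop}_core_vs_rest", _comparison_dict(comparison))
                    pop_summary["core_vs_rest_p"] = comparison.omnibus.p
                mkt_summary[pop] = pop_summary
            summary["mkt"] = mkt_summary
        except Exception as e:
            raise RuntimeError(f"stage 'mkt' failed: {e}") from e
    else:
        skipped["mkt"] = "no MKT count tables configured"

    # --- manifest ------------------------------------------------------
    cfg_dict = dataclasses.asdict(config)
    cfg_hash = hashlib.sha256(
        json.dumps(cfg_dict, sort_keys=True, default=str).encode()
    ).hexdigest()
    manifest = {
        "config": cfg_dict,
        "config_sha256": cfg_hash,
        "seed": config.seed,
        "skipped": skipped,
        "outputs": {k: str(v) for k, v in outputs.items()},
    }
    save_json("manifest", manifest)
    save_json("summary", summary)
    return ReportBundle(outdir=outdir, outputs=outputs, summary=summary, skipped=skipped)
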