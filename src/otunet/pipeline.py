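"""End-to-end orchestration of the exposure-study analysis.

Stages: OTU filter -> diversity (alpha per sample, Bray-Curtis, NMDS,
ANOSIM / PERMANOVA / envfit, within-group dispersion) -> differential
abundance at OTU level and at each requested phylotype rank (fold changes
and susceptibility calls) -> indicator species (exposed pooled vs
unexposed) -> per-group correlation networks with summaries, pairwise
comparisons and shared-vertex counts. All outputs are TSV/JSON; the exact
config (and seed) is serialized next to them for provenance.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import diversity, indicators, networks
from .differential import test_features
from .filtering import FilterSpec, filter_otus
from .tables_io import (
    OtuTable,
    TaxonomyMap,
    collapse_to_rank,
    write_otu_table,
)

logger = logging.getLogger("otunet.pipeline")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """All thresholds and sizes of a pipeline run.

    Defaults are the study's stated analysis settings: abundance/prevalence
    filter 0.1% / ~10%, richness depth 5,000 on a table rarefied to 10,000,
    5,000 permutations (10,000 for envfit), network thresholds
    |rho| >= 0.5 / p <= 0.05 / q <= 0.2, indicator thresholds
    IV >= 0.4 / p <= 0.05 / q <= 0.2, and a q < 0.2 & p < 0.05
    significance gate for post-hoc testing.
    """

    max_rel_abund_threshold: float = 0.001
    min_prevalence: float = 0.10
    richness_depth: int = 5000
    nperm: int = 5000
    nperm_envfit: int = 10000
    nperm_indval: int = 999
    nmds_restarts: int = 20
    rho_min: float = 0.5
    edge_p_max: float = 0.05
    edge_q_max: float = 0.2
    iv_min: float = 0.4
    indicator_p_max: float = 0.05
    indicator_q_max: float = 0.2
    p_gate: float = 0.05
    q_gate: float = 0.2
    reference_group: str = "unexposed"
    phylotype_ranks: tuple[str, ...] = ("genus", "family")
    make_plots: bool = False
    seed: int = 0

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["phylotype_ranks"] = list(self.phylotype_ranks)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if "phylotype_ranks" in data:
            data["phylotype_ranks"] = tuple(data["phylotype_ranks"])
        return cls(**data)

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def run_pipeline(
    table: OtuTable,
    taxonomy: TaxonomyMap | None,
    config: PipelineConfig,
    out_dir: str | Path,
) -> dict:
    """Run every stage on an already-rarefied table; write the report bundle.

    Returns the report as a dict (also written to ``report.json``). Any
    stage failure aborts with the stage name in the exception message.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    taxonomy = taxonomy or TaxonomyMap()
    seeds = _seeds(config.seed, 6)
    report: dict = {
        "config": dataclasses.asdict(config),
        "config_hash": config.config_hash(),
        "input": {"n_samples": table.n_samples, "n_otus": table.n_otus},
    }

    stage = "filter"
    try:
        spec = FilterSpec(config.max_rel_abund_threshold, config.min_prevalence)
        filtered, removal_log = filter_otus(table, spec)
        removal_log.to_csv(out / "removed_otus.tsv", sep="\t", index=False)
        write_otu_table(filtered, out / "filtered_table.tsv", taxonomy)
        logger.info("filter: %d -> %d OTUs", table.n_otus, filtered.n_otus)
        report["filter"] = {"otus_in": table.n_otus, "otus_kept": filtered.n_otus}

        stage = "diversity"
        report["diversity"], ordination = _diversity_stage(filtered, config, seeds, out)

        stage = "differential"
        report["differential"] = {}
        diff = test_features(
            filtered,
            reference_group=config.reference_group,
            p_gate=config.p_gate,
            q_gate=config.q_gate,
        )
        diff.insert(0, "taxonomy", [taxonomy.lineage_string(o) for o in diff.index])
        diff.to_csv(out / "differential_otu.tsv", sep="\t")
        report["differential"]["otu"] = _differential_summary(diff)
        for rank in config.phylotype_ranks:
            if not taxonomy:
                break
            phylo = collapse_to_rank(filtered, taxonomy, rank)
            pdiff = test_features(
                phylo,
                reference_group=config.reference_group,
                p_gate=config.p_gate,
                q_gate=config.q_gate,
            )
            pdiff.to_csv(out / f"differential_{rank}.tsv", sep="\t")
            report["differential"][rank] = _differential_summary(pdiff)

        stage = "indicators"
        ind_all, ind_kept = indicators.indicator_analysis(
            filtered,
            nperm=config.nperm_indval,
            seed=seeds[4],
            iv_min=config.iv_min,
            p_max=config.indicator_p_max,
            q_max=config.indicator_q_max,
        )
        ind_all.insert(0, "taxonomy", [taxonomy.lineage_string(o) for o in ind_all.index])
        ind_all.to_csv(out / "indicators_all.tsv", sep="\t")
        ind_kept.to_csv(out / "indicators_selected.tsv", sep="\t")
        report["indicators"] = {
            "n_selected": int(len(ind_kept)),
            "by_class": ind_kept["class"].value_counts().to_dict() if len(ind_kept) else {},
        }

        stage = "networks"
        report["networks"], nets = _network_stage(filtered, config, out)

        if config.make_plots:
            stage = "plots"
            from .plots import save_standard_figures

            save_standard_figures(filtered, ordination, ind_kept, nets, out / "figures")
    except Exception as exc:  # noqa: BLE001 - annotate with the failing stage
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    config.to_yaml(out / "config.yaml")
    (out / "report.json").write_text(json.dumps(report, indent=2, default=_jsonable))
    return report


def _jsonable(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, (set, tuple)):
        return list(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


def _diversity_stage(filtered: OtuTable, config: PipelineConfig, seeds: list[int], out: Path) -> dict:
    alpha = pd.DataFrame(
        {
            "shannon": [diversity.shannon(row) for row in filtered.counts.to_numpy()],
            "rarefied_richness": [
                diversity.rarefied_richness(row, config.richness_depth)
                for row in filtered.counts.to_numpy()
            ],
            "group": filtered.groups.to_numpy(),
        },
        index=filtered.counts.index,
    )
    alpha.to_csv(out / "alpha_diversity.tsv", sep="\t")
    shannon_cmp = diversity.compare_group_values(alpha["shannon"], alpha["group"])
    richness_cmp = diversity.compare_group_values(alpha["rarefied_richness"], alpha["group"])

    dm = diversity.bray_curtis(filtered)
    pd.DataFrame(dm.data, index=list(dm.ids), columns=list(dm.ids)).to_csv(
        out / "bray_curtis.tsv", sep="\t"
    )
    ordination = diversity.nmds(dm, n_restarts=config.nmds_restarts, seed=seeds[0])
    with open(out / "nmds_coordinates.tsv", "w") as fh:
        fh.write(f"# stress={ordination.stress:.6f}\n")
        ordination.coordinates.to_csv(fh, sep="\t")

    groups = filtered.groups
    res_anosim = diversity.anosim(dm, groups, nperm=config.nperm, seed=seeds[1])
    res_permanova = diversity.permanova(dm, groups, nperm=config.nperm, seed=seeds[2])
    res_envfit = diversity.envfit_factor(
        ordination, groups, nperm=config.nperm_envfit, seed=seeds[3]
    )
    dispersion = diversity.intragroup_dispersion(dm, groups)
    logger.info(
        "diversity: ANOSIM R=%.3f p=%.4g; PERMANOVA F=%.2f p=%.4g; envfit r2=%.3f p=%.4g",
        res_anosim.statistic, res_anosim.p_value,
        res_permanova.statistic, res_permanova.p_value,
        res_envfit.statistic, res_envfit.p_value,
    )
    return {
        "nmds_stress": ordination.stress,
        "anosim": {"R": res_anosim.statistic, "p": res_anosim.p_value},
        "permanova": {
            "pseudo_F": res_permanova.statistic,
            "R2": res_permanova.extras["R2"],
            "p": res_permanova.p_value,
        },
        "envfit": {"r2": res_envfit.statistic, "p": res_envfit.p_value},
        "shannon_kw": {"H": shannon_cmp.H, "p": shannon_cmp.p},
        "richness_kw": {"H": richness_cmp.H, "p": richness_cmp.p},
        "dispersion_kw": {
            "H": dispersion.comparison.H,
            "p": dispersion.comparison.p,
        },
    }, ordination


def _differential_summary(diff: pd.DataFrame) -> dict:
    return {
        "n_features": int(len(diff)),
        "n_significant": int(diff["gate_passed"].sum()),
        "calls": diff["call"].value_counts().to_dict(),
    }


def _network_stage(filtered: OtuTable, config: PipelineConfig, out: Path) -> dict:
    nets = {}
    for g in pd.unique(filtered.groups):
        sub = filtered.select_group(g)
        records = networks.spearman_matrix(sub)
        records.to_csv(out / f"correlations_{g}.tsv", sep="\t", index=False)
        nets[g] = networks.build_network(
            records,
            rho_min=config.rho_min,
            p_max=config.edge_p_max,
            q_max=config.edge_q_max,
            group_abundances=sub.counts.mean(axis=0),
            group=g,
        )

    summaries = {}
    for g, net in nets.items():
        summ = networks.network_summary(net)
        summaries[g] = summ.to_dict()
        edges = pd.DataFrame(
            [
                {"otu_a": a, "otu_b": b, **d}
                for a, b, d in sorted(net.edges(data=True))
            ],
            columns=["otu_a", "otu_b", "rho", "p", "q", "sign"],
        )
        edges.to_csv(out / f"network_edges_{g}.tsv", sep="\t", index=False)
        bc = networks.betweenness(net)
        comms = networks.greedy_communities(net)
        membership = {v: ci for ci, c in enumerate(comms) for v in c}
        vertices = pd.DataFrame(
            {
                "otu_id": sorted(net.nodes),
                "mean_abundance": [net.nodes[v].get("mean_abundance") for v in sorted(net.nodes)],
                "degree": [net.degree(v) for v in sorted(net.nodes)],
                "betweenness": [bc.get(v, 0.0) for v in sorted(net.nodes)],
                "community": [membership.get(v) for v in sorted(net.nodes)],
            }
        )
        vertices.to_csv(out / f"network_vertices_{g}.tsv", sep="\t", index=False)
        logger.info(
            "network %s: %d vertices, %d edges", g, summ.vertices, summ.total_edges
        )

    comparisons = networks.pairwise_network_comparisons(nets)
    venn = networks.venn_counts(nets)
    (out / "network_summaries.json").write_text(
        json.dumps({"summaries": summaries, "venn": venn}, indent=2, default=_jsonable)
    )
    comparisons.to_csv(out / "network_comparisons.tsv", sep="\t", index=False)
    return {
        "summaries": summaries,
        "venn": venn,
        "comparisons": comparisons.to_dict(orient="records"),
    }, nets
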