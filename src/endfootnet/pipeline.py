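"""End-to-end orchestration: simulate/load -> filter -> network -> modules ->
screen -> associate, with a manifest of per-stage counts and full seeded
determinism.

Stages cache their heavyweight intermediates (TOM, partitions) inside the
run directory so the association stage can be re-run with different
covariates without recomputing the network.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from endfootnet import association_stats as stats_mod
from endfootnet import data_io, module_detection, network, preprocess
from endfootnet import endfoot_screen as screen_mod
from endfootnet import synthetic_data as synth

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""


@dataclass
class RunConfig:
    """Defaults follow the published analysis where a value exists:
    min module size 30, screen threshold r > 0.65 with >= 2 bait genes in
    >= 2 regions, astrocyte fraction >= 0.5, soft power within 4..7,
    alpha 0.05."""

    seed: int
    simulation: synth.SimulationConfig | None = None
    input_dir: str | None = None
    regions: tuple[str, ...] = ("TCX", "HIP", "PCX")
    # network
    power: int | None = None
    candidate_powers: tuple[int, ...] = tuple(range(1, 13))
    scale_free_r2: float = 0.8
    # modules
    min_module_size: int = 30
    cut_height_frac: float = 0.90
    linkage_method: str = "average"
    # screen
    r_threshold: float = 0.65
    min_dac: int = 2
    min_regions: int = 2
    astro_threshold: float = 0.5
    # stats
    covariates: tuple[str, ...] = stats_mod.DEFAULT_COVARIATES
    transform: str = "auto"
    alpha: float = 0.05
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if self.simulation is None and self.input_dir is None:
            self.simulation = synth.SimulationConfig(seed=self.seed, regions=self.regions)


@dataclass
class RegionAnalysis:
    expression: data_io.ExpressionMatrix
    filter_report: preprocess.FilterReport
    net: network.GeneNetwork
    partition: module_detection.ModulePartition


@dataclass
class RunResult:
    regions: dict[str, RegionAnalysis]
    screen_report: pd.DataFrame
    screen_summary: dict
    associations: list[stats_mod.AssociationRecord]
    manifest: dict
    cohort: synth.Cohort | None = None
    astro_fractions: pd.Series | None = None


def analyze_region(
    expr: data_io.ExpressionMatrix, config: RunConfig
) -> RegionAnalysis:
    """Filter -> network -> modules -> eigengenes/kME/kWithin for one region."""
    filtered, report = preprocess.filter_low_expression(expr)
    net = network.build_network(
        filtered,
        power=config.power,
        candidate_powers=config.candidate_powers,
        r2_target=config.scale_free_r2,
    )
    partition = module_detection.cluster_modules(
        net.dissimilarity,
        net.gene_ids,
        min_module_size=config.min_module_size,
        cut_height_frac=config.cut_height_frac,
        linkage_method=config.linkage_method,
    )
    module_detection.compute_eigengenes(filtered, partition)
    module_detection.module_membership(filtered, partition)
    module_detection.intramodular_connectivity(net.adjacency, partition)
    return RegionAnalysis(filtered, report, net, partition)


def run_associations(
    exprs: dict[str, data_io.ExpressionMatrix],
    partitions: dict[str, module_detection.ModulePartition],
    subjects: pd.DataFrame,
    pathology: dict[str, data_io.PathologyPanel],
    genes: list[str],
    config: RunConfig,
    outcomes: tuple[str, ...] | None = None,
    interaction: bool = False,
) -> list[stats_mod.AssociationRecord]:
    """Fit every gene x region model: dementia logistic plus OLS for the
    continuous pathology outcomes (all seven unless ``outcomes`` narrows
    them), and the endfoot-eigengene OLS models; then apply the two-stage
    correction across the whole record set. With ``interaction`` the OLS
    models carry an expression x dementia term and report its contrast."""
    outcome_set = outcomes if outcomes is not None else data_io.PATHOLOGY_OUTCOMES
    records: list[stats_mod.AssociationRecord] = []
    for region, expr in exprs.items():
        panel = pathology[region].with_ratios()
        predictors: dict[str, pd.Series] = {}
        for g in genes:
            if g in expr.values.index:
                predictors[g] = expr.values.loc[g]
        part = partitions.get(region)
        if part is not None and part.eigengenes is not None:
            res = screen_mod.find_endfoot_cluster(part, region=region)
            if res.coherent:
                predictors["ME_endfoot"] = pd.Series(
                    part.eigengenes.loc[res.label].to_numpy(), index=part.sample_ids
                )
        for gid, x in predictors.items():
            records.append(
                stats_mod.dementia_logistic(
                    x, subjects, config.covariates, gene_id=gid, region=region
                )
            )
            for outcome in outcome_set:
                if outcome not in panel.columns:
                    continue
                fit = stats_mod.interaction_contrast if interaction else stats_mod.pathology_ols
                records.append(
                    fit(
                        x,
                        panel[outcome],
                        subjects,
                        config.covariates,
                        transform=config.transform,
                        gene_id=gid,
                        region=region,
                    )
                )
    return stats_mod.adjust_pvalues(records, alpha=config.alpha)


def run_full(config: RunConfig) -> RunResult:
    """Execute the whole pipeline; returns all stage outputs plus a manifest."""
    cohort: synth.Cohort | None = None
    if config.input_dir is not None:
        inputs = load_cohort_dir(config.input_dir, config.regions)
        exprs, subjects_records, pathology, celltype = inputs
    else:
        cohort = synth.generate_cohort(config.simulation)
        exprs = cohort.expressions
        subjects_records = cohort.subjects
        pathology = cohort.pathology
        celltype = cohort.celltype

    regions: dict[str, RegionAnalysis] = {}
    for region, expr in exprs.items():
        try:
            regions[region] = analyze_region(expr, config)
        except Exception as exc:  # noqa: BLE001 - re-raise with stage context
            raise PipelineError(f"stage network/modules failed for region {region}: {exc}") from exc

    partitions = {r: a.partition for r, a in regions.items()}
    coherence = {
        r: screen_mod.find_endfoot_cluster(p, region=r).coherent for r, p in partitions.items()
    }
    if sum(coherence.values()) < 2:
        raise PipelineError(
            "stage screen: incoherent clustering of established endfoot genes in "
            f"{[r for r, ok in coherence.items() if not ok]}; "
            "fewer than 2 coherent regions remain"
        )

    any_expr = next(iter(regions.values())).expression
    astro = preprocess.annotate_astro_fraction(any_expr, celltype)
    # genes filtered out in one region may survive in another: annotate the union
    all_genes = sorted({g for a in regions.values() for g in a.expression.gene_ids})
    astro = celltype.astro_fraction.reindex(all_genes)
    try:
        report, summary = screen_mod.candidate_screen(
            {r: a.expression for r, a in regions.items()},
            partitions,
            astro,
            r_threshold=config.r_threshold,
            min_dac=config.min_dac,
            min_regions=config.min_regions,
            astro_threshold=config.astro_threshold,
        )
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"stage screen failed: {exc}") from exc

    subjects = data_io.subjects_to_frame(subjects_records)
    passing = report.loc[report["pass"], "gene_id"].tolist() if len(report) else []
    genes_for_stats = passing + list(screen_mod.ESTABLISHED_ENDFOOT_GENES.values())
    try:
        associations = run_associations(
            {r: a.expression for r, a in regions.items()},
            partitions,
            subjects,
            pathology,
            genes_for_stats,
            config,
        )
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"stage associate failed: {exc}") from exc

    n_sig = sum(1 for r in associations if np.isfinite(r.p_adj) and r.p_adj < config.alpha)
    manifest = {
        "seed": config.seed,
        "regions": list(regions),
        "genes_after_filter": {r: a.filter_report.n_retained for r, a in regions.items()},
        "soft_power": {r: a.net.soft_power for r, a in regions.items()},
        "n_modules": {r: len(a.partition.module_labels) for r, a in regions.items()},
        "endfoot_cluster_size": {
            r: len(a.partition.members(screen_mod.find_endfoot_cluster(a.partition).label))
            for r, a in regions.items()
            if coherence[r]
        },
        "n_in_cluster_any_region": summary["n_in_cluster_any_region"],
        "n_in_cluster_multiple_regions": summary["n_in_cluster_multiple_regions"],
        "n_candidates_pass": summary["n_candidates_pass"],
        "n_association_models": len(associations),
        "n_significant_after_correction": n_sig,
    }

    result = RunResult(
        regions=regions,
        screen_report=report,
        screen_summary=summary,
        associations=associations,
        manifest=manifest,
        cohort=cohort,
        astro_fractions=astro,
    )
    if config.out_dir is not None:
        write_run(result, config)
    return result


# ---------------------------------------------------------------------------
# disk I/O for runs and cohorts


def write_cohort(cohort: synth.Cohort, out_dir: str | Path) -> None:
    """Write a simulated cohort in the package's input formats + ground truth."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for region, expr in cohort.expressions.items():
        data_io.write_expression(expr, out / f"expression_{region}.tsv")
        panel = cohort.pathology[region]
        panel.quantitative.join(panel.ordinal).to_csv(
            out / f"pathology_{region}.tsv", sep="\t", index_label="sample_id", na_rep="NA"
        )
    data_io.write_subjects(cohort.subjects, out / "subjects.tsv")
    cohort.celltype.values.to_csv(out / "celltype.tsv", sep="\t", index_label="gene_id")
    truth = pd.DataFrame(
        {
            "gene_id": list(cohort.truth.gene_to_module),
            "module": list(cohort.truth.gene_to_module.values()),
        }
    )
    truth["role"] = "member"
    truth.loc[truth["gene_id"].isin(cohort.truth.established_genes), "role"] = "established"
    truth.loc[truth["gene_id"].isin(cohort.truth.planted_candidates), "role"] = "candidate"
    truth.loc[truth["gene_id"].isin(cohort.truth.decoy_genes), "role"] = "decoy"
    truth.loc[truth["module"] == 0, "role"] = "background"
    truth.to_csv(out / "ground_truth.tsv", sep="\t", index=False)


def load_cohort_dir(path: str | Path, regions: tuple[str, ...]):
    """Load a cohort directory written by :func:`write_cohort` (or hand-built
    in the same layout)."""
    path = Path(path)
    exprs = {
        r: data_io.read_expression(path / f"expression_{r}.tsv", region=r, unit="fpkm")
        for r in regions
    }
    subjects = data_io.read_subjects(path / "subjects.tsv")
    pathology = {r: data_io.read_pathology(path / f"pathology_{r}.tsv", region=r) for r in regions}
    celltype = data_io.read_celltype_table(path / "celltype.tsv")
    return exprs, subjects, pathology, celltype


def write_run(result: RunResult, config: RunConfig) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for region, analysis in result.regions.items():
        analysis.partition.to_frame().to_csv(out / f"modules_{region}.tsv", sep="\t", index=False)
        if analysis.partition.eigengenes is not None:
            analysis.partition.eigengenes.to_csv(out / f"eigengenes_{region}.tsv", sep="\t")
        if analysis.partition.kme is not None:
            frame = analysis.partition.kme.copy()
            frame["kwithin"] = analysis.partition.kwithin
            frame.to_csv(out / f"kme_{region}.tsv", sep="\t", index_label="gene_id", na_rep="NA")
        np.save(out / f"tom_{region}.npy", analysis.net.tom)
        with open(out / f"tom_{region}.genes.txt", "w") as fh:
            fh.write("\n".join(analysis.net.gene_ids))
    data_io.write_results(result.screen_report, out / "candidate_report.tsv")
    data_io.write_results(
        stats_mod.records_to_frame(result.associations), out / "associations.tsv"
    )
    with open(out / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=2, sort_keys=True, default=str)
    data_io.write_config_echo(
        {k: v for k, v in dataclasses.asdict(config).items() if k != "simulation"},
        out / "run_config.txt",
    )
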