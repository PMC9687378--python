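"""End-to-end orchestration: normalize, cluster, score, select, report.

The full analysis chain is: log-transform the expression matrix, fit
the pooled Gaussian mixture and check it by chi-square, normalize every
value to the Bayes posterior of the expressed component, Ward-cluster
the leukemia samples and cut the dendrogram at the largest fusion-level
jump, tabulate the posterior-difference statistic and Cohen's D for all
subgroup dichotomies, derive the selection threshold by recursive ABC
analysis of the pooled |pdeg| values, and emit per-dichotomy selected
gene tables plus a JSON run summary.  Every stage's intermediate is
serialized so any reported number can be recomputed.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .abc_select import SelectionThreshold, recursive_abc, select_genes
from .effect_stats import Dichotomy, dichotomies_from_groups, dichotomy_table
from .expression_io import (
    ExpressionMatrix,
    read_annotations,
    read_expression_matrix,
    write_annotations,
    write_expression_matrix,
    write_model,
)
from .gmm_bayes import (
    DecisionBorder,
    GaussianMixtureModel,
    GofResult,
    chi_square_gof,
    decision_border,
    fit_gmm,
    log_transform,
    normalize_to_posteriors,
)
from .subgroup_clustering import (
    Dendrogram,
    SubgroupPartition,
    choose_cut,
    contingency,
    map_clusters_to_labels,
    ward_cluster,
)
from .synthetic_data import GroundTruth, SimulationConfig, simulate

__all__ = ["PipelineConfig", "RunReport", "run", "make_report", "evaluate_selection"]


@dataclass(frozen=True)
class PipelineConfig:
    """Everything a run needs; fully serialized for provenance."""

    simulation: SimulationConfig | None = None
    matrix_path: str | None = None
    annotations_path: str | None = None
    whitelist_path: str | None = None
    samples_in_rows: bool = False
    log_base: float = 10.0
    pseudocount: float = 0.0
    m_candidates: tuple[int, ...] = (1, 2, 3, 4, 5)
    n_restarts: int = 10
    max_gmm_points: int = 20000
    seed: int = 0
    k_max: int = 10
    exclude_labels: tuple[str, ...] = ("normal",)
    abc_iterations: int = 3
    keep: str = "AB"
    display_threshold: float | None = None

    def __post_init__(self) -> None:
        if self.simulation is None and self.matrix_path is None:
            raise ValueError("config needs either a simulation or a matrix path")
        if self.simulation is not None and self.matrix_path is not None:
            raise ValueError("give a simulation or input paths, not both")
        if self.keep not in ("A", "AB"):
            raise ValueError("keep mode must be 'A' or 'AB'")


@dataclass
class RunReport:
    """All fitted objects and tables of one pipeline run."""

    config: PipelineConfig
    matrix: ExpressionMatrix
    annotations: pd.DataFrame
    truth: GroundTruth | None
    model: GaussianMixtureModel
    gof: GofResult
    border: DecisionBorder
    posteriors: pd.DataFrame
    dendrogram: Dendrogram
    partition: SubgroupPartition
    contingency: pd.DataFrame
    tables: dict[str, pd.DataFrame]
    threshold: SelectionThreshold
    selected: dict[str, pd.DataFrame]
    reported: dict[str, pd.DataFrame]

    def summary(self) -> dict:
        """JSON-serializable digest of the run."""
        return {
            "package_version": __version__,
            "seed": self.config.seed,
            "n_genes": self.matrix.n_genes,
            "n_samples": self.matrix.n_samples,
            "gmm": {
                "M": self.model.M,
                "components": [
                    {"w": c.w, "m": c.m, "s": c.s} for c in self.model.components
                ],
                "loglik": self.model.loglik,
                "aic": self.model.aic,
                "n_points": self.model.n_points,
            },
            "gof": {
                "chi2": self.gof.chi2_stat,
                "dof": self.gof.dof,
                "p_value": self.gof.p_value,
            },
            "decision_border": {"x_log": self.border.x_log, "x_raw": self.border.x_raw},
            "clustering": {
                "k": self.partition.k,
                "contingency": {
                    str(r): {str(c): int(v) for c, v in row.items()}
                    for r, row in self.contingency.iterrows()
                },
            },
            "abc": {
                "threshold": self.threshold.threshold,
                "keep": self.threshold.keep,
                "iterations": self.threshold.iterations,
                "completed_iterations": self.threshold.completed_iterations,
            },
            "selected": {
                name: list(table.index) for name, table in self.selected.items()
            },
        }


def _load_inputs(cfg: PipelineConfig):
    if cfg.simulation is not None:
        return simulate(cfg.simulation)
    matrix = read_expression_matrix(cfg.matrix_path, samples_in_rows=cfg.samples_in_rows)
    annotations = read_annotations(cfg.annotations_path)
    if cfg.whitelist_path is not None:
        from .expression_io import filter_genes

        whitelist = [
            line.strip()
            for line in Path(cfg.whitelist_path).read_text().splitlines()
            if line.strip()
        ]
        matrix, missing = filter_genes(matrix, whitelist)
        if missing:
            warnings.warn(f"{len(missing)} whitelist genes absent from the matrix")
    return matrix, annotations, None


def run(cfg: PipelineConfig) -> RunReport:
    """Execute the full analysis; deterministic for a fixed config."""
    matrix, annotations, truth = _load_inputs(cfg)

    log_values = log_transform(matrix.values, cfg.log_base, cfg.pseudocount)
    pooled = log_values.ravel()
    if cfg.max_gmm_points and pooled.size > cfg.max_gmm_points:
        idx = np.random.default_rng(cfg.seed).choice(
            pooled.size, size=cfg.max_gmm_points, replace=False
        )
        pooled = pooled[idx]

    model = fit_gmm(
        pooled,
        m_candidates=cfg.m_candidates,
        seed=cfg.seed,
        n_restarts=cfg.n_restarts,
        log_base=cfg.log_base,
        pseudocount=cfg.pseudocount,
    )
    gof = chi_square_gof(model, pooled)
    border = decision_border(model)
    posteriors = pd.DataFrame(
        normalize_to_posteriors(model, log_values),
        index=matrix.gene_ids,
        columns=matrix.sample_ids,
    )

    label_of = annotations["label"].to_dict()
    cluster_samples = [
        s for s in matrix.sample_ids if label_of.get(s) not in cfg.exclude_labels
    ]
    dendrogram = ward_cluster(posteriors, cluster_samples)
    partition = choose_cut(dendrogram, k_max=cfg.k_max)
    table1 = contingency(partition, annotations)

    groups = partition.group_members()
    for label in cfg.exclude_labels:
        members = [s for s in matrix.sample_ids if label_of.get(s) == label]
        if members:
            groups[label] = members
    cluster_names = sorted(partition.group_members())
    pairs = [
        (cluster_names[i], cluster_names[j])
        for i in range(len(cluster_names))
        for j in range(i + 1, len(cluster_names))
    ]
    pairs += [
        (c, label)
        for c in cluster_names
        for label in cfg.exclude_labels
        if label in groups
    ]
    dichotomies = dichotomies_from_groups(groups, pairs)
    tables = {d.name: dichotomy_table(posteriors, d) for d in dichotomies}

    pooled_pdeg = np.abs(np.concatenate([t["pdeg"].to_numpy() for t in tables.values()]))
    threshold = recursive_abc(pooled_pdeg, iterations=cfg.abc_iterations, keep=cfg.keep)

    selected, reported = {}, {}
    for name, table in tables.items():
        sel, rep = select_genes(
            table, threshold, stat="pdeg", display_threshold=cfg.display_threshold
        )
        selected[name] = sel
        reported[name] = rep

    return RunReport(
        config=cfg,
        matrix=matrix,
        annotations=annotations,
        truth=truth,
        model=model,
        gof=gof,
        border=border,
        posteriors=posteriors,
        dendrogram=dendrogram,
        partition=partition,
        contingency=table1,
        tables=tables,
        threshold=threshold,
        selected=selected,
        reported=reported,
    )


def make_report(report: RunReport, out_dir) -> Path:
    """Write every intermediate and the JSON summary under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_expression_matrix(report.matrix, out / "matrix.tsv")
    write_annotations(report.annotations, out / "annotations.tsv")
    write_model(report.model, out / "model.json", border=report.border)
    report.posteriors.rename_axis("gene").to_csv(out / "posteriors.tsv", sep="\t")
    report.dendrogram.to_frame().to_csv(out / "merges.tsv", sep="\t", index=False)
    report.partition.to_frame().to_csv(out / "partition.tsv", sep="\t")
    report.contingency.to_csv(out / "contingency.tsv", sep="\t")
    (out / "deg").mkdir(exist_ok=True)
    (out / "selected").mkdir(exist_ok=True)
    for name, table in report.tables.items():
        table.to_csv(out / "deg" / f"{name}.tsv", sep="\t")
    for name, table in report.reported.items():
        table.to_csv(out / "deg" / f"{name}_reported.tsv", sep="\t")
    for name, table in report.selected.items():
        table.to_csv(out / "selected" / f"{name}.tsv", sep="\t")
    if report.truth is not None:
        truth_doc = {
            "state_probs": {
                g: {c: float(v) for c, v in row.items()}
                for g, row in report.truth.state_probs.iterrows()
            },
            "de_spec": [dataclasses.asdict(e) for e in report.truth.de_spec],
        }
        (out / "truth.json").write_text(json.dumps(truth_doc, indent=1))
    (out / "report.json").write_text(json.dumps(report.summary(), indent=1))
    return out / "report.json"


def evaluate_selection(
    report: RunReport, truth: GroundTruth | None = None, margin: float = 0.5
) -> dict:
    """Score the pipeline's selections against planted ground truth.

    Clusters are mapped to true group labels by contingency majority;
    for every dichotomy the truth set is the genes whose planted
    high-state frequencies differ by at least ``margin``.  Returns
    pooled sensitivity and false-discovery proportion.
    """
    truth = truth if truth is not None else report.truth
    if truth is None:
        raise ValueError("no ground truth available for this run")
    mapping = map_clusters_to_labels(report.contingency)
    tp = fp = fn = 0
    per_dichotomy = {}
    for name, sel in report.selected.items():
        side_a, side_b = name.split("_vs_")
        label_a = mapping.get(side_a, side_a)
        label_b = mapping.get(side_b, side_b)
        true_set = set(truth.de_genes(label_a, label_b, margin=margin))
        got = set(sel.index)
        per_dichotomy[name] = {
            "labels": (label_a, label_b),
            "tp": len(got & true_set),
            "fp": len(got - true_set),
            "fn": len(true_set - got),
        }
        tp += len(got & true_set)
        fp += len(got - true_set)
        fn += len(true_set - got)
    return {
        "sensitivity": tp / (tp + fn) if tp + fn else float("nan"),
        "fdp": fp / (tp + fp) if tp + fp else 0.0,
        "tp": tp,
        "fp": fp,
        "fn": fn,
        "per_dichotomy": per_dichotomy,
        "cluster_labels": mapping,
    }
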