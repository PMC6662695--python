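"""End-to-end orchestration: run every stage in dependency order from one config."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd
import yaml

from . import __version__
from .abundance_io import (
    CohortMetadata,
    GenusAbundanceTable,
    ValidationError,
    read_abundance_table,
    to_relative,
    write_abundance_table,
)
from .cag import (
    cag_abundance,
    compare_cag_abundance,
    correlation_matrix,
    define_cags,
    select_training_combination,
)
from .cohort_stats import build_contingency, chi_square_test
from .differential import (
    differential_genera,
    filter_by_prevalence,
    results_to_frame,
    transition_analysis,
)
from .diversity import compare_diversity, diversity_table
from .enterotyping import enterotype_cohort, pcoa_ordination
from .network import (
    anchor_correlation_profile,
    find_stable_cag,
    network_to_edgelist,
    pearson_network,
    variable_genera,
)
from .synthetic import SyntheticCohortConfig, default_config, generate_cohort

__all__ = ["RunConfig", "run_full_analysis"]

logger = logging.getLogger(__name__)

ALL_STAGES = (
    "enterotype",
    "diversity",
    "diffabund",
    "transitions",
    "cag",
    "network",
    "cohort_stats",
)


@dataclass
class RunConfig:
    """Declarative description of one full analysis run.

    Exactly one of (``table_path`` + ``metadata_path``) or
    ``synthetic`` must be set; omitted parameters take the documented
    defaults.
    """

    table_path: str | None = None
    metadata_path: str | None = None
    table_format: str = "tsv"
    synthetic: SyntheticCohortConfig | None = None
    stages: tuple[str, ...] = ALL_STAGES
    seed: int = 0
    outdir: str = "enterocag_out"
    alpha: float = 0.01
    distance: str = "bray_curtis"
    pcoa_axes: int = 2
    correlation_method: str = "spearman"
    linkage: str = "average"
    k: int | None = None
    combinations: tuple[tuple[str, ...], ...] = (
        ("normal", "cancer"),
        ("normal", "adenoma"),
        ("adenoma", "cancer"),
        ("normal", "adenoma", "cancer"),
    )
    edge_threshold: float = 0.5
    variability_threshold: float = 0.4
    prevalence_threshold: float = 0.5

    def validate(self) -> None:
        has_paths = self.table_path is not None or self.metadata_path is not None
        if has_paths and self.synthetic is not None:
            raise ValidationError("set either input paths or a synthetic config, not both")
        if has_paths and (self.table_path is None or self.metadata_path is None):
            raise ValidationError("both table_path and metadata_path are required")
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValidationError(f"unknown stages: {sorted(unknown)}")

    def to_json_dict(self) -> dict:
        d = {
            "table_path": self.table_path,
            "metadata_path": self.metadata_path,
            "table_format": self.table_format,
            "synthetic": None if self.synthetic is None else vars(self.synthetic).copy(),
            "stages": list(self.stages),
            "seed": self.seed,
            "outdir": self.outdir,
            "alpha": self.alpha,
            "distance": self.distance,
            "pcoa_axes": self.pcoa_axes,
            "correlation_method": self.correlation_method,
            "linkage": self.linkage,
            "k": self.k,
            "combinations": [list(c) for c in self.combinations],
            "edge_threshold": self.edge_threshold,
            "variability_threshold": self.variability_threshold,
            "prevalence_threshold": self.prevalence_threshold,
        }
        if d["synthetic"] is not None:
            syn = d["synthetic"]
            syn["genus_panel"] = list(syn["genus_panel"])
            syn["blocks"] = {k: list(v) for k, v in syn["blocks"].items()}
        return d

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        syn = doc.pop("synthetic", None)
        if syn is not None:
            if isinstance(syn, dict):
                for key in ("genus_panel",):
                    if key in syn:
                        syn[key] = tuple(syn[key])
                if "blocks" in syn:
                    syn["blocks"] = {k: tuple(v) for k, v in syn["blocks"].items()}
                syn = SyntheticCohortConfig(**syn)
            else:
                syn = default_config()
        if "stages" in doc:
            doc["stages"] = tuple(doc["stages"])
        if "combinations" in doc:
            doc["combinations"] = tuple(tuple(c) for c in doc["combinations"])
        return cls(synthetic=syn, **doc)


def _load_inputs(config: RunConfig):
    if config.synthetic is not None or config.table_path is None:
        syn = config.synthetic or default_config()
        table, meta, truth = generate_cohort(syn, seed=config.seed)
        return table, meta, truth
    table = read_abundance_table(config.table_path, format=config.table_format)
    meta = CohortMetadata.from_tsv(config.metadata_path)
    return table, meta, None


def run_full_analysis(config: RunConfig) -> dict:
    """Execute every enabled stage in dependency order; returns the run
    summary (also written to ``<outdir>/run_summary.json``)."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {
        "version": __version__,
        "seed": config.seed,
        "parameters": config.to_json_dict(),
        "stages": {},
    }
    outputs: dict[str, str] = {}

    def _fail(stage: str, exc: Exception):
        summary["failed_stage"] = stage
        summary["error"] = str(exc)
        (outdir / "run_summary.json").write_text(json.dumps(summary, indent=2, default=str))
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    table, meta, truth = _load_inputs(config)
    rel = to_relative(table)
    if truth is not None:
        write_abundance_table(table, outdir / "synthetic_counts.tsv")
        meta.to_tsv(outdir / "synthetic_metadata.tsv")
        (outdir / "synthetic_truth.json").write_text(
            json.dumps({"seed": config.seed, **truth.to_json_dict()}, indent=2)
        )
        outputs["synthetic"] = str(outdir / "synthetic_counts.tsv")

    labels = None
    if "enterotype" in config.stages:
        try:
            labels, contingency = enterotype_cohort(rel, meta)
            labels.to_csv(outdir / "enterotypes.tsv", sep="\t")
            contingency.to_csv(outdir / "enterotype_contingency.tsv", sep="\t")
            coords, fractions = pcoa_ordination(rel, config.distance, config.pcoa_axes)
            with open(outdir / "pcoa.tsv", "w") as fh:
                fh.write("# eigenvalue fractions: " + ",".join(f"{f:.6g}" for f in fractions[:10]) + "\n")
                coords.to_csv(fh, sep="\t")
            outputs["enterotype"] = str(outdir / "enterotypes.tsv")
        except Exception as exc:  # noqa: BLE001 - abort with stage name
            _fail("enterotype", exc)
    et_series = labels["enterotype"] if labels is not None else None

    if "diversity" in config.stages:
        try:
            div = diversity_table(table)
            div.to_csv(outdir / "diversity.tsv", sep="\t")
            frames = [
                compare_diversity(div, meta, metric=m, alpha=config.alpha)
                for m in ("richness", "shannon")
            ]
            if et_series is not None:
                for et in ("I", "II", "III"):
                    for m in ("richness", "shannon"):
                        frames.append(
                            compare_diversity(
                                div, meta, metric=m, stratum=et,
                                enterotype_labels=et_series, alpha=config.alpha,
                            )
                        )
            pd.concat([f for f in frames if len(f)], ignore_index=True).to_csv(
                outdir / "diversity_comparisons.tsv", sep="\t", index=False
            )
            outputs["diversity"] = str(outdir / "diversity.tsv")
        except Exception as exc:  # noqa: BLE001
            _fail("diversity", exc)

    if "diffabund" in config.stages:
        try:
            results = differential_genera(
                rel, meta, alpha=config.alpha,
                prevalence_threshold=config.prevalence_threshold,
            )
            if et_series is not None:
                for et in ("I", "II", "III"):
                    results += differential_genera(
                        rel, meta, stratum=et, enterotype_labels=et_series,
                        alpha=config.alpha, prevalence_threshold=config.prevalence_threshold,
                    )
            results_to_frame(results).to_csv(
                outdir / "differential_genera.tsv", sep="\t", index=False
            )
            outputs["diffabund"] = str(outdir / "differential_genera.tsv")
        except Exception as exc:  # noqa: BLE001
            _fail("diffabund", exc)

    if "transitions" in config.stages:
        try:
            results = transition_analysis(
                rel, meta, alpha=config.alpha,
                prevalence_threshold=config.prevalence_threshold,
            )
            results_to_frame(results).to_csv(
                outdir / "transitions.tsv", sep="\t", index=False
            )
            outputs["transitions"] = str(outdir / "transitions.tsv")
        except Exception as exc:  # noqa: BLE001
            _fail("transitions", exc)

    winner = None
    if "cag" in config.stages:
        try:
            ranking, winner = select_training_combination(
                rel, meta, list(config.combinations),
                correlation_method=config.correlation_method,
                linkage=config.linkage, k=config.k,
                prevalence_threshold=config.prevalence_threshold,
            )
            ranking.to_csv(outdir / "cag_combinations.tsv", sep="\t", index=False)
            pd.Series(winner.assignments, name="cag_id").rename_axis("genus").to_csv(
                outdir / "cag_partition.tsv", sep="\t"
            )
            profiles = cag_abundance(rel, winner)
            profiles.to_csv(outdir / "cag_profiles.tsv", sep="\t")
            comparisons = compare_cag_abundance(profiles, meta, alpha=config.alpha)
            if et_series is not None:
                for et in ("I", "II", "III"):
                    comparisons += compare_cag_abundance(
                        profiles, meta, stratum=et,
                        enterotype_labels=et_series, alpha=config.alpha,
                    )
            results_to_frame(comparisons).to_csv(
                outdir / "cag_comparisons.tsv", sep="\t", index=False
            )
            outputs["cag"] = str(outdir / "cag_partition.tsv")
        except Exception as exc:  # noqa: BLE001
            _fail("cag", exc)

    if "network" in config.stages:
        try:
            kept = filter_by_prevalence(rel, meta, threshold=config.prevalence_threshold)
            group_partitions = []
            edge_frames = []
            for group in ("normal", "adenoma", "cancer"):
                samples = [s for s in meta.samples_in_group(group) if s in rel.data.index]
                sub = rel.data.loc[samples, kept]
                usable = [g for g in kept if sub[g].nunique() > 1]
                corr = correlation_matrix(
                    rel, samples, usable, method=config.correlation_method
                )
                group_partitions.append(
                    define_cags(corr, linkage=config.linkage, k=config.k,
                                correlation_method=config.correlation_method,
                                source_groups=(group,))
                )
                net = pearson_network(
                    rel, samples, usable,
                    edge_threshold=config.edge_threshold, group=group,
                )
                nx.write_graphml(net, outdir / f"network_{group}.graphml")
                edge_frames.append(network_to_edgelist(net))
            pd.concat(edge_frames, ignore_index=True).to_csv(
                outdir / "network_edges.tsv", sep="\t", index=False
            )
            anchor = find_stable_cag(group_partitions)
            report_rows = {}
            if anchor:
                for genus in kept:
                    if genus in anchor:
                        continue
                    report_rows[genus] = anchor_correlation_profile(
                        rel, meta, anchor, genus
                    )
            profiles_frame = pd.DataFrame(report_rows).T
            flagged = variable_genera(profiles_frame, config.variability_threshold)
            with open(outdir / "anchor_report.tsv", "w") as fh:
                fh.write(f"# anchor: {','.join(anchor) if anchor else '(none)'}\n")
                fh.write(f"# edge_threshold: {config.edge_threshold}\n")
                fh.write(f"# variability_threshold: {config.variability_threshold}\n")
                flagged.to_csv(fh, sep="\t", index=False)
            outputs["network"] = str(outdir / "anchor_report.tsv")
        except Exception as exc:  # noqa: BLE001
            _fail("network", exc)

    if "cohort_stats" in config.stages:
        try:
            rows = []
            covariates = [
                c for c in meta.frame.columns if c not in ("stage6", "group3")
            ]
            for variable in covariates:
                ct = build_contingency(meta, variable)
                try:
                    stat, df, p = chi_square_test(ct)
                except ValidationError as exc:
                    logger.warning("skipping %s: %s", variable, exc)
                    continue
                rows.append(
                    {
                        "variable": variable,
                        "levels": ";".join(map(str, ct.row_labels)),
                        "counts": ";".join(",".join(map(str, r)) for r in ct.counts),
                        "chi2": stat,
                        "df": df,
                        "p_value": p,
                    }
                )
            pd.DataFrame(rows).to_csv(outdir / "cohort_stats.tsv", sep="\t", index=False)
            outputs["cohort_stats"] = str(outdir / "cohort_stats.tsv")
        except Exception as exc:  # noqa: BLE001
            _fail("cohort_stats", exc)

    summary["stages"] = outputs
    (outdir / "run_summary.json").write_text(json.dumps(summary, indent=2, default=str))
    return summary
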