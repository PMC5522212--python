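"""End-to-end orchestration: normalize -> DE per time point -> Venn ->
clustering -> correlation pairs -> target prediction -> enrichment.

Every stage writes plain TSV outputs under the run directory
(``de/``, ``venn/``, ``cluster/``, ``pairs/``, ``targets/``,
``enrichment/``) plus a consolidated ``report.json``; ``run.log`` records
every threshold and every filtered/dropped record class, and ``MANIFEST``
lists the stages that completed (a failing stage aborts with a stage-tagged
error but retains partial outputs). Outputs are deterministic for a fixed
input and configuration: rerunning a seeded synthetic study yields
byte-identical files.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import study_io
from .coexpression import CorrConfig, pair_correlations
from .diffexpr import (
    DEConfig,
    differential_expression,
    scatter_table,
    top_n_table,
    volcano_table,
)
from .preprocess import quantile_normalize
from .targets import TargetPredConfig, predict_targets
from .timecourse import hierarchical_cluster, venn3

log = logging.getLogger(__name__)

_FLOAT_FORMAT = "%.10g"


class PipelineError(RuntimeError):
    """A stage failed; the message is tagged with the stage name."""


@dataclass
class RunConfig:
    expression_path: str
    sample_sheet_path: str
    annotation_path: str
    out_dir: str
    lnc_fasta_path: str | None = None
    utr3_fasta_path: str | None = None
    gene_sets_path: str | None = None
    de: DEConfig = field(default_factory=DEConfig)
    corr: CorrConfig = field(default_factory=CorrConfig)
    targets: TargetPredConfig = field(default_factory=TargetPredConfig)
    run_trans: bool = True
    cluster_distance: str = "correlation"
    cluster_linkage: str = "average"
    enrichment_top_n: int = 30

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        nested = {
            "de": DEConfig(**raw.pop("de", {})),
            "corr": CorrConfig(**raw.pop("corr", {})),
            "targets": TargetPredConfig(**raw.pop("targets", {})),
        }
        return cls(**raw, **nested)

    def validate_paths(self) -> None:
        for name in ("expression_path", "sample_sheet_path", "annotation_path",
                     "lnc_fasta_path", "utr3_fasta_path", "gene_sets_path"):
            value = getattr(self, name)
            if value is not None and not Path(value).exists():
                raise FileNotFoundError(f"{name}: {value}")


def _write_tsv(frame: pd.DataFrame, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FORMAT)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns (and writes) the run report."""
    config.validate_paths()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "MANIFEST"
    manifest_path.write_text("")

    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("lncarray")
    root.addHandler(handler)
    previous_level = root.level
    root.setLevel(logging.INFO)

    completed: list[str] = []

    def _done(stage: str) -> None:
        completed.append(stage)
        manifest_path.write_text("".join(s + "\n" for s in completed))

    report: dict = {"stages": {}, "thresholds": {
        "fc_threshold": config.de.fc_threshold,
        "p_threshold": config.de.p_threshold,
        "r_threshold": config.corr.r_threshold,
        "corr_p_threshold": config.corr.p_threshold,
        "cis_window": config.targets.cis_window,
        "min_align_score": config.targets.min_align_score,
        "min_identity": config.targets.min_identity,
    }}
    stage = "load"
    try:
        matrix = study_io.read_expression_matrix(config.expression_path, scale="linear")
        design = study_io.read_sample_sheet(config.sample_sheet_path)
        annotation = study_io.read_annotation(config.annotation_path)
        sequences: dict[str, str] = {}
        if config.run_trans:
            if not (config.lnc_fasta_path and config.utr3_fasta_path):
                raise FileNotFoundError(
                    "trans prediction enabled but FASTA inputs are missing "
                    "(set run_trans: false to skip)"
                )
            sequences.update(study_io.read_fasta(config.lnc_fasta_path))
            sequences.update(study_io.read_fasta(config.utr3_fasta_path))
        gene_sets = (
            study_io.read_gene_sets(config.gene_sets_path) if config.gene_sets_path else None
        )
        report["stages"]["load"] = {
            "n_probes": matrix.shape[0],
            "n_samples": matrix.shape[1],
            "n_dropped_missing": matrix.load_report.n_dropped_missing,
        }
        log.info("loaded %d probes x %d samples (%d rows dropped for missing values)",
                 matrix.shape[0], matrix.shape[1], matrix.load_report.n_dropped_missing)
        _done(stage)

        stage = "normalize"
        normalized = quantile_normalize(matrix)
        study_io.write_expression_matrix(normalized, out / "normalized.tsv")
        _done(stage)

        stage = "differential_expression"
        time_points = design.time_points
        de_tables: dict[tuple[str, str], pd.DataFrame] = {}
        de_counts: dict[str, dict] = {}
        for tp in time_points:
            full = differential_expression(normalized, design, tp, config.de, annotation)
            de_counts[tp] = {}
            for rna_type in ("lncRNA", "mRNA"):
                sub = full[full["rna_type"] == rna_type].reset_index(drop=True)
                de_tables[(tp, rna_type)] = sub
                _write_tsv(sub, out / "de" / f"{rna_type}_{tp}.tsv")
                _write_tsv(
                    top_n_table(sub, annotation, config.de.top_n, tp),
                    out / "de" / f"top{config.de.top_n}_{rna_type}_{tp}.tsv",
                )
                _write_tsv(volcano_table(sub), out / "de" / f"volcano_{rna_type}_{tp}.tsv")
                _write_tsv(scatter_table(sub), out / "de" / f"scatter_{rna_type}_{tp}.tsv")
                sig = sub[sub["significant"]]
                counts = {
                    "up": int((sig["regulation"] == "up").sum()),
                    "down": int((sig["regulation"] == "down").sum()),
                    "ns": int(len(sub) - len(sig)),
                }
                de_counts[tp][rna_type] = counts
                log.info("%s %s: %d up / %d down / %d ns at FC >= %g & p < %g",
                         tp, rna_type, counts["up"], counts["down"], counts["ns"],
                         config.de.fc_threshold, config.de.p_threshold)
        report["stages"]["differential_expression"] = de_counts
        _done(stage)

        stage = "venn"
        venn_report = {}
        if len(time_points) == 3:
            for rna_type in ("lncRNA", "mRNA"):
                for direction in ("up", "down"):
                    sets = []
                    for tp in time_points:
                        table = de_tables[(tp, rna_type)]
                        mask = table["significant"] & (table["regulation"] == direction)
                        sets.append(set(table.loc[mask, "probe_id"]))
                    result = venn3(*sets, names=tuple(time_points))
                    key = f"{rna_type}_{direction}"
                    venn_report[key] = {
                        "sizes": result.sizes,
                        "common": result.common_size,
                        "union": result.union_size,
                        "common_percentage": round(result.common_percentage, 4),
                    }
                    rows = pd.DataFrame(
                        {
                            "set": list(result.sizes) + ["common", "union", "common_pct"],
                            "value": list(result.sizes.values())
                            + [result.common_size, result.union_size,
                               round(result.common_percentage, 4)],
                        }
                    )
                    _write_tsv(rows, out / "venn" / f"venn_{key}.tsv")
                    _write_tsv(
                        pd.DataFrame({"probe_id": sorted(result.common)}),
                        out / "venn" / f"common_{key}.tsv",
                    )
        report["stages"]["venn"] = venn_report
        _done(stage)

        stage = "cluster"
        from .preprocess import to_log2

        dendrogram = hierarchical_cluster(
            to_log2(normalized), axis="samples",
            distance=config.cluster_distance, linkage=config.cluster_linkage,
        )
        (out / "cluster").mkdir(exist_ok=True)
        (out / "cluster" / "samples.newick").write_text(dendrogram.to_newick() + "\n")
        _write_tsv(
            pd.DataFrame({"leaf_order": dendrogram.leaf_order}),
            out / "cluster" / "leaf_order.tsv",
        )
        report["stages"]["cluster"] = {"n_leaves": len(dendrogram.labels),
                                       "dropped": dendrogram.dropped}
        _done(stage)

        stage = "correlation"
        pair_tables: dict[str, pd.DataFrame] = {}
        for tp in time_points:
            pairs = pair_correlations(
                normalized, design, tp,
                de_tables[(tp, "lncRNA")], de_tables[(tp, "mRNA")], config.corr,
            )
            pairs = pairs.sort_values(
                ["lnc_probe_id", "mrna_probe_id"], kind="stable"
            ).reset_index(drop=True)
            pair_tables[tp] = pairs
            _write_tsv(pairs, out / "pairs" / f"pairs_{tp}.tsv")
        report["stages"]["correlation"] = {tp: len(t) for tp, t in pair_tables.items()}
        _done(stage)

        stage = "targets"
        target_report = {}
        for tp in time_points:
            table, summary = predict_targets(
                pair_tables[tp], annotation, sequences, config.targets
            )
            _write_tsv(table, out / "targets" / f"targets_{tp}.tsv")
            target_report[tp] = summary
        report["stages"]["targets"] = target_report
        _done(stage)

        stage = "enrichment"
        if gene_sets is not None:
            from .enrichment import enrich

            universe = {
                annotation[p].gene_id for p in annotation.probes_of_type("mRNA")
            }
            gene_of = {
                p: annotation[p].gene_id for p in annotation.probes_of_type("mRNA")
            }
            enrichment_report = {}
            for tp in time_points:
                table = de_tables[(tp, "mRNA")]
                de_genes = {
                    gene_of[p]
                    for p in table.loc[table["significant"], "probe_id"]
                    if p in gene_of
                }
                results, top = enrich(de_genes, universe, gene_sets,
                                      config.enrichment_top_n)
                all_table = pd.DataFrame(
                    [dataclasses.asdict(r) for r in results]
                )
                _write_tsv(all_table, out / "enrichment" / f"enrichment_{tp}.tsv")
                _write_tsv(top, out / "enrichment" / f"top{config.enrichment_top_n}_{tp}.tsv")
                enrichment_report[tp] = {
                    "n_sets_tested": len(results),
                    "n_significant_adj": int(sum(r.p_adj < 0.05 for r in results)),
                }
            report["stages"]["enrichment"] = enrichment_report
        else:
            log.info("no gene sets supplied; enrichment skipped")
            report["stages"]["enrichment"] = None
        _done(stage)

        report_path = out / "report.json"
        report_path.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
        _done("report")
        return report
    except Exception as exc:  # noqa: BLE001 - stage-tagged re-raise
        raise PipelineError(f"[{stage}] {exc}") from exc
    finally:
        root.removeHandler(handler)
        handler.close()
        root.setLevel(previous_level)
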