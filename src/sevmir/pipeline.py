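"""End-to-end orchestration: QC -> TPM -> presence -> DE -> (cytokines) ->
cross-cohort overlap -> target enrichment, driven by a structured run config,
with a machine-readable run report.

Every analysis decision that is an assumption rather than a published rule
(CV definition, spike comparator, pseudocount, BH family, harmonization
policy, permutation scheme, enrichment background) is echoed into the run
report so a reader can audit the run without the code.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .assay_stats import analyze_cytokine_panel
from .core_io import (
    ValidationError,
    read_count_matrix,
    read_cytokines,
    read_gmt,
    read_sample_sheet,
    read_signatures,
    read_targets,
)
from .cross_cohort import overlap_matrix, write_overlap_table
from .diffexp import (
    GroupDesign,
    call_differential,
    fold_change,
    housekeeping_normalize,
    permutation_t_test,
    sample_clustergram,
)
from .enrichment import consolidate_targets, hypergeom_enrich, term_graph, top_terms
from .presence import presence_sets, venn_counts
from .qc import QCThresholds, drop_failed_samples, low_expression_filter, sample_qc, tpm_normalize

logger = logging.getLogger("sevmir")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage {stage!r} failed: {cause}")


@dataclass
class RunConfig:
    counts: str
    annotation: str
    sample_sheet: str
    output_dir: str
    cytokines_sev_plus: str | None = None
    cytokines_sev_minus: str | None = None
    cytokine_sample_sheet: str | None = None
    signatures: str | None = None
    targets: str | None = None
    gene_sets: str | None = None
    # thresholds
    min_total_reads: int = 1_000_000
    max_spike_fraction: float = 0.10
    max_cv: float = 0.15
    presence_threshold: float = 1.0
    low_expression_mode: str = "all_samples_below"
    pseudocount: float = 1.0
    alpha: float = 0.01
    fc_min: float = 2.0
    scheme: str = "pooled"
    n_permutations: int = 9999
    harmonization_policy: str = "strict"
    target_score_threshold: float = 0.9
    enrichment_fdr: float = 0.05
    reference_group: str = "control"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as handle:
            raw = yaml.safe_load(handle) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValidationError(f"{path}: unknown config key(s) {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        required = {"counts": self.counts, "annotation": self.annotation, "sample_sheet": self.sample_sheet}
        optional = {
            "cytokines_sev_plus": self.cytokines_sev_plus,
            "cytokines_sev_minus": self.cytokines_sev_minus,
            "cytokine_sample_sheet": self.cytokine_sample_sheet,
            "signatures": self.signatures,
            "targets": self.targets,
            "gene_sets": self.gene_sets,
        }
        for name, path in required.items():
            if path is None or not Path(path).exists():
                raise ValidationError(f"RunConfig: input {name!r} missing or not found: {path}")
        for name, path in optional.items():
            if path is not None and not Path(path).exists():
                raise ValidationError(f"RunConfig: input {name!r} not found: {path}")
        if not (0 < self.alpha < 1) or self.fc_min < 1:
            raise ValidationError("RunConfig: alpha must be in (0,1) and fc_min >= 1")
        if self.scheme not in ("pooled", "exhaustive", "monte_carlo"):
            raise ValidationError(f"RunConfig: unknown permutation scheme {self.scheme!r}")


@dataclass
class RunReport:
    version: str
    seed: int
    decisions: dict = field(default_factory=dict)
    counts: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as handle:
            json.dump(asdict(self), handle, indent=2, default=str)


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except StageError:
                raise
            except Exception as exc:  # noqa: BLE001 - annotate and re-raise
                raise StageError(name, exc) from exc

        return wrapped

    return deco


def expression_workflow(
    cm,
    sheet,
    *,
    thresholds: QCThresholds | None = None,
    presence_threshold: float = 1.0,
    low_expression_mode: str = "all_samples_below",
    pseudocount: float = 1.0,
    scheme: str = "pooled",
    n_permutations: int = 9999,
    alpha: float = 0.01,
    fc_min: float = 2.0,
    reference: str = "control",
    seed: int | None = None,
) -> dict:
    """In-memory counts -> DE workflow (QC, TPM, presence, filter, test, call).

    Returns a dict with the intermediate objects: qc report, kept counts, tpm
    matrix, presence partition, filtered matrix, design, normalized matrix,
    fold changes, permutation p-values and the DE table.
    """
    qc_report = sample_qc(cm, thresholds)
    kept = drop_failed_samples(cm, qc_report, sheet)
    em = tpm_normalize(kept)
    partition = presence_sets(em, sheet, threshold=presence_threshold)
    filtered, removed = low_expression_filter(em, sheet, mode=low_expression_mode)
    design = GroupDesign.from_sample_sheet(sheet, filtered.samples, reference)
    norm = housekeeping_normalize(filtered, pseudocount=pseudocount)
    log_norm = pd.DataFrame(
        np.log2(norm.values), index=norm.values.index, columns=norm.values.columns
    )
    fc = fold_change(norm, design)
    p = permutation_t_test(
        log_norm, design, scheme=scheme, n_permutations=n_permutations, seed=seed
    )
    de = call_differential(fc, p, annotation=norm.annotation, alpha=alpha, fc_min=fc_min)
    return {
        "qc": qc_report,
        "kept": kept,
        "tpm": em,
        "presence": partition,
        "filtered": filtered,
        "low_expression_removed": removed,
        "design": design,
        "norm": norm,
        "log_norm": log_norm,
        "fold_change": fc,
        "p_perm": p,
        "de": de,
    }


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute every configured stage and write all artifacts + report.json."""
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = RunReport(
        version=__version__,
        seed=config.seed,
        decisions={
            "cv_definition": "sd/mean of housekeeping-probe counts per sample",
            "spike_comparator": ">= max_spike_fraction fails",
            "tpm_denominator": "positive-control probes excluded",
            "log_pseudocount": config.pseudocount,
            "low_expression_mode": config.low_expression_mode,
            "fold_change": "ratio of geometric means, housekeeping-relative",
            "permutation_scheme": config.scheme,
            "bh_family_de": "mirna-class probes only",
            "de_called_on": "raw permutation p",
            "bh_family_cytokines": "per fraction",
            "harmonization_policy": config.harmonization_policy,
            "target_score_comparator": f"> {config.target_score_threshold} (strict)",
            "enrichment_background": "union of gene-set and target-table genes",
        },
    )

    # --- QC ---------------------------------------------------------------
    @_stage("qc")
    def qc_stage():
        cm = read_count_matrix(config.counts, config.annotation)
        sheet = read_sample_sheet(config.sample_sheet)
        sheet.require_samples(cm.samples)
        thresholds = QCThresholds(
            min_total_reads=config.min_total_reads,
            max_spike_fraction=config.max_spike_fraction,
            max_cv=config.max_cv,
        )
        qc_report = sample_qc(cm, thresholds)
        qc_report.metrics.to_csv(outdir / "qc_metrics.tsv", sep="\t", index_label="sample_id")
        with open(outdir / "qc_report.json", "w") as handle:
            json.dump(qc_report.to_dict(), handle, indent=2)
        kept = drop_failed_samples(cm, qc_report, sheet)
        return cm, sheet, qc_report, kept

    cm, sheet, qc_report, kept = qc_stage()
    report.counts["samples_total"] = len(cm.samples)
    report.counts["samples_dropped"] = len(qc_report.failed)
    report.counts["dropped_samples"] = qc_report.failed
    report.outputs["qc"] = ["qc_metrics.tsv", "qc_report.json"]

    # --- normalization + presence ------------------------------------------
    @_stage("normalize")
    def norm_stage():
        em = tpm_normalize(kept)
        em.values.to_csv(outdir / "tpm.tsv", sep="\t", index_label="probe_id")
        return em

    em = norm_stage()
    report.outputs["normalize"] = ["tpm.tsv"]

    @_stage("presence")
    def presence_stage():
        partition = presence_sets(em, sheet, threshold=config.presence_threshold)
        common, u1, u2 = venn_counts(partition)
        out = partition.membership.copy()
        out.to_csv(outdir / "presence.tsv", sep="\t", index_label="probe_id")
        with open(outdir / "presence_counts.json", "w") as handle:
            json.dump(partition.counts(), handle, indent=2)
        return partition, (common, u1, u2)

    partition, (common, u1, u2) = presence_stage()
    g1, g2 = partition.groups
    report.counts["presence"] = {
        "common": common,
        f"unique_{g1}": u1,
        f"unique_{g2}": u2,
        "absent_in_all": partition.n_absent_in_all,
    }
    report.outputs["presence"] = ["presence.tsv", "presence_counts.json"]

    # --- differential expression -------------------------------------------
    @_stage("diffexp")
    def de_stage():
        filtered, removed = low_expression_filter(em, sheet, mode=config.low_expression_mode)
        design = GroupDesign.from_sample_sheet(sheet, filtered.samples, config.reference_group)
        norm = housekeeping_normalize(filtered, pseudocount=config.pseudocount)
        log_norm = pd.DataFrame(
            np.log2(norm.values), index=norm.values.index, columns=norm.values.columns
        )
        fc = fold_change(norm, design)
        p = permutation_t_test(
            log_norm, design, scheme=config.scheme,
            n_permutations=config.n_permutations, seed=config.seed,
        )
        de = call_differential(
            fc, p, annotation=norm.annotation, alpha=config.alpha, fc_min=config.fc_min,
            scheme={"scheme": config.scheme, "n_permutations": config.n_permutations,
                    "seed": config.seed},
        )
        de.table.to_csv(outdir / "diffexp.tsv", sep="\t")
        gram = sample_clustergram(log_norm)
        gram.distances.to_csv(outdir / "sample_distances.tsv", sep="\t", index_label="sample_id")
        (outdir / "sample_clustergram.nwk").write_text(gram.newick + "\n")
        return removed, de, gram

    removed, de, gram = de_stage()
    report.counts["low_expression_removed"] = len(removed)
    report.counts["probes_tested"] = int(len(de.table))
    report.counts["de_calls"] = de.n_called
    report.outputs["diffexp"] = ["diffexp.tsv", "sample_distances.tsv", "sample_clustergram.nwk"]

    # --- cytokines (optional) ----------------------------------------------
    if config.cytokines_sev_plus or config.cytokines_sev_minus:

        @_stage("cytokines")
        def cytokine_stage():
            if not config.cytokine_sample_sheet:
                raise ValidationError("cytokine tables given without cytokine_sample_sheet")
            cyt_sheet = read_sample_sheet(config.cytokine_sample_sheet)
            results = {}
            for fraction, path in (
                ("sev_plus", config.cytokines_sev_plus),
                ("sev_minus", config.cytokines_sev_minus),
            ):
                if not path:
                    continue
                table = read_cytokines(path)
                res = analyze_cytokine_panel(table, cyt_sheet, reference=config.reference_group)
                res.to_csv(outdir / f"cytokines_{fraction}.tsv", sep="\t")
                results[fraction] = res
            return results

        cytokines = cytokine_stage()
        report.counts["cytokines"] = {
            fraction: {"n_analytes": int(len(res)), "n_significant": int(res["significant"].sum())}
            for fraction, res in cytokines.items()
        }
        report.outputs["cytokines"] = [f"cytokines_{f}.tsv" for f in cytokines]

    de_mirnas = [
        p for p in de.called.index
        if cm.annotation.at[p, "probe_class"] == "mirna"
    ]

    # --- cross-cohort overlap (optional) -------------------------------------
    if config.signatures:

        @_stage("overlap")
        def overlap_stage():
            references = read_signatures(config.signatures)
            om = overlap_matrix(de_mirnas, references, policy=config.harmonization_policy)
            write_overlap_table(om, outdir / "overlap.tsv")
            with open(outdir / "overlap_counts.json", "w") as handle:
                json.dump(om.counts(), handle, indent=2)
            return om

        om = overlap_stage()
        report.counts["overlap"] = om.counts()
        report.outputs["overlap"] = ["overlap.tsv", "overlap_counts.json"]

    # --- enrichment (optional) ----------------------------------------------
    if config.targets and config.gene_sets:

        @_stage("enrichment")
        def enrichment_stage():
            targets = read_targets(config.targets)
            gsc = read_gmt(config.gene_sets)
            selection = consolidate_targets(
                de_mirnas, targets, targets, threshold=config.target_score_threshold
            )
            # the GMT dialect carries no explicit universe, so the background
            # is the union of annotated genes: gene-set members + target genes
            background = set(gsc.union()) | set(targets.records["gene"])
            records = hypergeom_enrich(
                selection.genes, gsc, background=background, fdr=config.enrichment_fdr
            )
            records.drop(columns=["members"]).to_csv(outdir / "enrichment.tsv", sep="\t")
            graph = term_graph(records[records["significant"]])
            (outdir / "term_dendrogram.nwk").write_text(graph.dendrogram_newick + "\n")
            edges = pd.DataFrame(
                [(a, b, d["weight"]) for a, b, d in graph.graph.edges(data=True)],
                columns=["term_a", "term_b", "shared_genes"],
            )
            edges.to_csv(outdir / "term_graph_edges.tsv", sep="\t", index=False)
            return selection, records, top_terms(records[records["significant"]])

        selection, records, top = enrichment_stage()
        report.counts["enrichment"] = {
            "consolidated_target_genes": len(selection.genes),
            "terms_tested": int(len(records)),
            "significant_terms": int(records["significant"].sum()),
        }
        report.outputs["enrichment"] = [
            "enrichment.tsv", "term_dendrogram.nwk", "term_graph_edges.tsv",
        ]

    report.to_json(outdir / "report.json")
    return report
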