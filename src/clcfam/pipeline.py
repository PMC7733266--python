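"""Config-driven orchestration of the full analysis.

Stages run in dependency order (identify -> properties -> classify ->
block filter / reconcile -> expression / anova / correlate); stages whose
optional inputs are missing are skipped with a logged notice.  All
intermediate artifacts are plain-text standard formats so each stage is
independently re-runnable, and the provenance block records every
parameter, the seed and input checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import __version__
from .expression_anion_stats import (
    correlation_matrix,
    ddct_fold_change,
    panel_stats,
    read_ct_table,
    read_measurement_table,
    write_correlation_matrix,
    write_stat_table,
)
from .family_identification import (
    DEFAULT_E_CUTOFF,
    calibrate_profile,
    collapse_isoforms,
    filter_candidates,
    parse_domtblout,
    read_fasta,
    scan_profile,
    write_candidate_table,
)
from .motif_classification import classify_many, write_classification_table
from .phylo_reconciliation import (
    conserved_block_filter,
    lca_reconcile,
    read_alignment,
    read_newick,
    write_reconciliation_report,
)
from .protein_properties import property_table, write_property_table
from .synthetic_data import default_profiles

logger = logging.getLogger("clcfam")

__all__ = ["PipelineConfig", "PipelineReport", "load_config", "validate_config", "run_pipeline"]

_INPUT_KEYS = (
    "proteome_fasta",
    "domtbl",
    "locus_map",
    "gene_tree",
    "species_tree",
    "leaf_map",
    "alignment",
    "ct_table",
    "measurement_table",
)


@dataclass
class PipelineConfig:
    outdir: str
    inputs: dict[str, str] = field(default_factory=dict)
    e_cutoff: float = DEFAULT_E_CUTOFF
    proton_offset: int = 4
    alpha: float = 0.05
    fold_convention: str = "ratio"
    reference_gene: str = "PgActin"
    calibrator: float = 0.0
    block_filter: dict[str, Any] = field(
        default_factory=lambda: {
            "min_ident_fraction": 0.5,
            "max_gap_fraction": 0.2,
            "min_block_length": 5,
        }
    )
    n_null_shuffles: int = 100
    seed: int = 0
    log_level: str = "INFO"


def load_config(path: str | Path) -> PipelineConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = {f for f in PipelineConfig.__dataclass_fields__}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    return PipelineConfig(**raw)


def validate_config(config: PipelineConfig) -> list[str]:
    """Return all problems found (empty list means runnable)."""
    problems: list[str] = []
    if not config.outdir:
        problems.append("outdir is required")
    if config.e_cutoff <= 0:
        problems.append(f"e_cutoff must be positive, got {config.e_cutoff}")
    if not 0 < config.alpha < 1:
        problems.append(f"alpha must be in (0, 1), got {config.alpha}")
    if config.proton_offset < 1:
        problems.append(f"proton_offset must be >= 1, got {config.proton_offset}")
    if config.fold_convention not in ("ratio", "increment"):
        problems.append(f"fold_convention must be 'ratio' or 'increment', "
                        f"got {config.fold_convention!r}")
    for key in config.inputs:
        if key not in _INPUT_KEYS:
            problems.append(f"unknown input key {key!r}")
    for key, path in config.inputs.items():
        if key in _INPUT_KEYS and not Path(path).exists():
            problems.append(f"input {key}: path {path!r} does not exist")
    bf = config.block_filter
    if not 0 < bf.get("min_ident_fraction", 0.5) <= 1:
        problems.append("block_filter.min_ident_fraction must be in (0, 1]")
    if not 0 <= bf.get("max_gap_fraction", 0.2) < 1:
        problems.append("block_filter.max_gap_fraction must be in [0, 1)")
    if bf.get("min_block_length", 5) < 1:
        problems.append("block_filter.min_block_length must be >= 1")
    return problems


@dataclass
class PipelineReport:
    candidates: list = field(default_factory=list)
    properties: list = field(default_factory=list)
    classifications: list = field(default_factory=list)
    reconciliation: Any = None
    panel_results: dict = field(default_factory=dict)
    fold_changes: list = field(default_factory=list)
    correlations: dict = field(default_factory=dict)
    skipped: list[str] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)


def _sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _expression_sample_table(ct, fold_changes) -> pd.DataFrame:
    """Per-replicate fold changes pivoted to (tissue, treatment, rep) rows."""
    rows = []
    for fc in fold_changes:
        for rep, fold in enumerate(fc.per_replicate_folds, start=1):
            rows.append(
                {
                    "tissue": fc.tissue,
                    "treatment_mM": fc.treatment,
                    "rep": rep,
                    "variable": fc.gene,
                    "value": fold,
                }
            )
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig) -> PipelineReport:
    """Run every stage whose inputs are present; abort on stage errors."""
    problems = validate_config(config)
    if problems:
        raise ValueError("invalid config: " + "; ".join(problems))
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = PipelineReport()
    inputs = config.inputs

    # --- identify -----------------------------------------------------------
    if "proteome_fasta" in inputs:
        records = read_fasta(inputs["proteome_fasta"])
        if "locus_map" in inputs:
            locus_df = pd.read_csv(inputs["locus_map"], sep="\t", header=None,
                                   names=["id", "locus"])
            records = collapse_isoforms(records, dict(zip(locus_df["id"], locus_df["locus"])))
        if "domtbl" in inputs:
            hits = parse_domtblout(inputs["domtbl"])
        else:
            profiles = default_profiles()
            hits = []
            for prof in profiles.values():
                calibrate_profile(prof, seed=config.seed,
                                  n_shuffles=config.n_null_shuffles)
            for rec in records:
                for prof in profiles.values():
                    hits.extend(scan_profile(rec, prof))
        report.candidates = filter_candidates(records, hits, e_cutoff=config.e_cutoff)
        write_candidate_table(report.candidates, outdir / "candidates.tsv")
        passed = [c for c in report.candidates if c.passed_filter]
        logger.info("identify: %d/%d candidates passed", len(passed), len(records))

        # --- properties & classify -----------------------------------------
        report.properties = property_table(passed)
        write_property_table(report.properties, outdir / "properties.tsv")
        spans = {
            c.protein.id: c.voltage_clc_hits[0]
            for c in passed
            if c.voltage_clc_hits
        }
        report.classifications = classify_many(
            [c.protein for c in passed],
            domain_spans=spans,
            proton_offset=config.proton_offset,
        )
        write_classification_table(report.classifications, outdir / "classification.tsv")
    else:
        report.skipped += ["identify", "properties", "classify"]
        logger.info("identify/properties/classify skipped: no proteome_fasta input")

    # --- block filter -------------------------------------------------------
    if "alignment" in inputs:
        aln = read_alignment(inputs["alignment"])
        filtered = conserved_block_filter(aln, **config.block_filter)
        with open(outdir / "alignment.blocks.fasta", "w") as fh:
            for rid, seq in filtered.rows:
                fh.write(f">{rid}\n{seq}\n")
        logger.info("blockfilter: %d -> %d columns", aln.n_columns, filtered.n_columns)
    else:
        report.skipped.append("blockfilter")
        logger.info("blockfilter skipped: no alignment input")

    # --- reconcile ----------------------------------------------------------
    if all(k in inputs for k in ("gene_tree", "species_tree", "leaf_map")):
        gtree = read_newick(inputs["gene_tree"])
        stree = read_newick(inputs["species_tree"])
        lm_df = pd.read_csv(inputs["leaf_map"], sep="\t", header=None,
                            names=["gene", "species"])
        leaf_map = dict(zip(lm_df["gene"], lm_df["species"]))
        report.reconciliation = lca_reconcile(gtree, stree, leaf_map)
        write_reconciliation_report(report.reconciliation, outdir / "reconciliation.tsv")
        logger.info(
            "reconcile: %d duplications, %d losses",
            report.reconciliation.total_duplications,
            report.reconciliation.total_losses,
        )
    else:
        report.skipped.append("reconcile")
        logger.info("reconcile skipped: gene tree / species tree / leaf map incomplete")

    # --- expression ---------------------------------------------------------
    ct = None
    if "ct_table" in inputs:
        ct = read_ct_table(inputs["ct_table"], reference_gene=config.reference_gene,
                           calibrator=config.calibrator)
        genes = sorted(g for g in ct.data["gene"].unique() if g != config.reference_gene)
        tissues = sorted(ct.data["tissue"].unique())
        treatments = sorted(ct.data["treatment_mM"].unique())
        for gene in genes:
            for tissue in tissues:
                for treatment in treatments:
                    report.fold_changes.append(
                        ddct_fold_change(ct, gene, tissue, treatment)
                    )
        with open(outdir / "fold_changes.tsv", "w") as fh:
            fh.write("gene\ttissue\ttreatment_mM\tfold\tse\n")
            for fc in report.fold_changes:
                fh.write(
                    f"{fc.gene}\t{fc.tissue}\t{fc.treatment:g}\t"
                    f"{fc.fold:.6g}\t{fc.se:.6g}\n"
                )
    else:
        report.skipped.append("expression")
        logger.info("expression skipped: no ct_table input")

    # --- anova on measurements ---------------------------------------------
    meas = None
    if "measurement_table" in inputs:
        meas = read_measurement_table(inputs["measurement_table"])
        panels = sorted(
            set(zip(meas.data["variable"], meas.data["tissue"]))
        )
        for variable, tissue in panels:
            report.panel_results[(variable, tissue)] = panel_stats(
                meas, variable, tissue, alpha=config.alpha,
                control=config.calibrator,
            )
        write_stat_table(report.panel_results, outdir / "anova.tsv")
    else:
        report.skipped.append("anova")
        logger.info("anova skipped: no measurement_table input")

    # --- correlate ----------------------------------------------------------
    if ct is not None and meas is not None:
        expr_long = _expression_sample_table(ct, report.fold_changes)
        combined = pd.concat([expr_long, meas.data[expr_long.columns]])
        wide = combined.pivot_table(
            index=["tissue", "treatment_mM", "rep"],
            columns="variable",
            values="value",
        ).dropna()
        if len(wide) >= 3 and wide.shape[1] >= 2:
            corr = correlation_matrix(wide)
            report.correlations["pooled"] = corr
            write_correlation_matrix(corr, outdir / "correlation.pooled.tsv")
        for tissue in sorted(set(wide.index.get_level_values("tissue"))):
            sub = wide.loc[tissue]
            if len(sub) >= 3:
                corr = correlation_matrix(sub)
                report.correlations[tissue] = corr
                write_correlation_matrix(corr, outdir / f"correlation.{tissue}.tsv")
    else:
        report.skipped.append("correlate")
        logger.info("correlate skipped: needs both ct_table and measurement_table")

    # --- provenance ---------------------------------------------------------
    report.provenance = {
        "version": __version__,
        "seed": config.seed,
        "parameters": {
            "e_cutoff": config.e_cutoff,
            "proton_offset": config.proton_offset,
            "alpha": config.alpha,
            "fold_convention": config.fold_convention,
            "reference_gene": config.reference_gene,
            "calibrator": config.calibrator,
            "block_filter": config.block_filter,
            "n_null_shuffles": config.n_null_shuffles,
        },
        "inputs": {k: {"path": v, "sha256": _sha256(v)} for k, v in inputs.items()},
        "skipped": report.skipped,
    }
    (outdir / "provenance.json").write_text(
        json.dumps(report.provenance, indent=2, sort_keys=True) + "\n"
    )
    return report
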