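"""End-to-end driver: assignment → typing → PPSS → diversity → strata.

A run starts either from a read-to-reference assignment table or from
pre-aggregated HLA read counts plus an OTU table, plus a presentation
map (per-allele peptide sets or a precomputed allele-pair Jaccard
table).  It emits the full result bundle — genotype profiles, pairwise
PPSS, alpha and beta diversity, stratified pair tables and KS P-value
heatmaps — together with a manifest logging every parameter and input
digest, so a run is reproducible and auditable.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import io
from .config import PipelineConfig, logger
from .diversity import alpha_diversity, beta_diversity, taxonomy_tree
from .hla_typing import HlaProfile, call_profiles, select_complete_profiles
from .peptidome import PresentationMap, ppss_matrix
from .read_assignment import (
    OtuTable,
    build_otu_table,
    distribute_multimappers,
    extract_hla_counts,
    split_namespaces,
)
from .stratified import (
    bin_by_ppss,
    bin_by_shared_alleles,
    group_by_heterozygosity,
    stratum_pvalue_heatmap,
)


@dataclass
class ResultBundle:
    """In-memory results of one pipeline run."""

    profiles: list[HlaProfile]
    otu_table: OtuTable
    ppss: pd.DataFrame
    alpha: pd.DataFrame
    beta: pd.DataFrame
    strata: dict[str, pd.DataFrame] = field(default_factory=dict)
    heatmaps: dict[str, pd.DataFrame] = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> ResultBundle:
    """Run every stage the inputs allow and write the result bundle.

    ``config.paths`` must name an ``outdir`` plus either an
    ``assignment_table`` (with ``lineages``) or ``hla_counts`` +
    ``otu_table``; a ``presentation`` (allele→peptide TSV) or ``jtable``
    (allele-pair Jaccard TSV) enables the PPSS stages.  Deterministic
    for a fixed config.
    """
    paths = {k: Path(v) for k, v in config.paths.items()}
    for key, p in paths.items():
        if key != "outdir" and not p.exists():
            raise FileNotFoundError(f"input '{key}' not found at {p}")
    outdir = paths.get("outdir", Path("hlabiome_out"))
    outdir.mkdir(parents=True, exist_ok=True)

    manifest: dict = {
        "parameters": config.to_dict(),
        "inputs": {k: _digest(p) for k, p in paths.items() if k != "outdir" and p.is_file()},
        "stages": {},
    }

    # --- stage 1: assignment → counts ---------------------------------
    if "assignment_table" in paths:
        table = io.read_assignment_table(paths["assignment_table"])
        counts = distribute_multimappers(table)
        otu_counts, hla_counts_df = split_namespaces(counts)
        lineages = io.read_lineages(paths["lineages"]) if "lineages" in paths else {}
        otu_table = build_otu_table(otu_counts, lineages, config.min_reads, config.min_rel_abund)
        gene_counts = extract_hla_counts(hla_counts_df)
        manifest["stages"]["assignment"] = {
            "reads": int(table["read_id"].nunique()),
            "otu_samples_kept": len(otu_table.sample_ids),
        }
    else:
        gene_counts = io.read_hla_counts(paths["hla_counts"])
        lineages = io.read_lineages(paths["lineages"]) if "lineages" in paths else {}
        otu_table = io.read_otu_table(paths["otu_table"], None)
        otu_table.lineages.update(lineages)

    # --- stage 2: genotype calling ------------------------------------
    profiles = call_profiles(gene_counts, config.r_min, config.min_top_reads, config.het_fraction)
    io.write_profiles(profiles, outdir / "profiles.tsv")
    complete1 = select_complete_profiles(profiles, 1)
    manifest["stages"]["typing"] = {
        "samples": len(profiles),
        "class1_complete": len(complete1),
        "class2_complete": len(select_complete_profiles(profiles, 2)),
    }

    # --- stage 3: PPSS --------------------------------------------------
    pmap: PresentationMap | None = None
    if "presentation" in paths:
        pmap = io.read_presentation_sets(paths["presentation"])
    elif "jtable" in paths:
        pmap = io.read_jaccard_table(paths["jtable"])
    ppss_df = pd.DataFrame(columns=["sample_i", "sample_j", "ppss"])
    if pmap is not None and len(complete1) >= 2:
        ppss_df = ppss_matrix(complete1, pmap)
        ppss_df.to_csv(outdir / "ppss.tsv", sep="\t", index=False)
        manifest["stages"]["ppss"] = {"pairs": len(ppss_df)}

    # --- stage 4: diversity ---------------------------------------------
    alpha = pd.DataFrame(
        [vars(a) for a in alpha_diversity(otu_table)],
        columns=["sample_id", "S", "N", "margalef", "shannon", "heip"],
    )
    alpha.to_csv(outdir / "alpha.tsv", sep="\t", index=False)
    tree = taxonomy_tree(otu_table.lineages) if otu_table.lineages else None
    beta = beta_diversity(otu_table, tree)
    beta.to_csv(outdir / "beta.tsv", sep="\t", index=False)
    manifest["stages"]["diversity"] = {"samples": len(alpha), "pairs": len(beta)}

    # --- stage 5: stratified comparisons --------------------------------
    strata: dict[str, pd.DataFrame] = {}
    heatmaps: dict[str, pd.DataFrame] = {}
    if len(ppss_df):
        strata["ppss"] = bin_by_ppss(ppss_df, beta, config.ppss_edges)
    if len(complete1) >= 2 and len(beta):
        strata["shared_alleles"] = bin_by_shared_alleles(complete1, beta)
    richness = dict(zip(alpha["sample_id"], alpha["margalef"]))
    het = group_by_heterozygosity(profiles, richness, 1)
    if len(het):
        strata["heterozygosity_richness"] = het
    for name, df in strata.items():
        io.write_strata(df, outdir / f"strata_{name}.tsv")
        counted = df.groupby("stratum", observed=True)["value"].count()
        if (counted >= 2).sum() >= 2:
            heatmaps[name] = stratum_pvalue_heatmap(df, "greater")
            io.write_heatmap(heatmaps[name], outdir / f"heatmap_{name}.tsv")
    manifest["stages"]["strata"] = {k: int(len(v)) for k, v in strata.items()}

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    logger.info("pipeline complete: %s", json.dumps(manifest["stages"]))
    return ResultBundle(profiles, otu_table, ppss_df, alpha, beta, strata, heatmaps, manifest)
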