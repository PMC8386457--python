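"""Readers and writers for the pipeline's file contracts.

Everything tabular is tab-separated UTF-8 with a header row; identifiers
are never quoted and two-digit alleles are serialized as ``GENE*NN``
(e.g. ``B*07``).  Proteins travel as FASTA (lowercase residues are
uppercased on read), taxonomies as newick with unit branch lengths or as
a rank-lineage table, peptidomes as one peptide per line.
"""

from __future__ import annotations

import math
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from skbio import TreeNode

from .config import logger
from .hla_typing import GenotypeCall, HlaProfile
from .peptidome import PresentationMap
from .read_assignment import GeneReadCounts, OtuTable


def _read_tsv(path: str | Path, required: list[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except Exception as exc:
        raise ValueError(f"cannot parse {path}: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    bad = df[required].isna().any(axis=1)
    if bad.any():
        line = int(bad.idxmax()) + 2  # header is line 1
        raise ValueError(f"{path}: malformed row at line {line}")
    return df


# -- assignment tables -------------------------------------------------------

def read_assignment_table(path: str | Path) -> pd.DataFrame:
    df = _read_tsv(path, ["read_id", "target_id", "is_primary"])
    df["is_primary"] = df["is_primary"].astype(int).astype(bool)
    return df


def write_assignment_table(df: pd.DataFrame, path: str | Path) -> None:
    out = df.copy()
    out["is_primary"] = out["is_primary"].astype(int)
    out.to_csv(path, sep="\t", index=False)


# -- OTU tables and lineages -------------------------------------------------

def write_otu_table(table: OtuTable, matrix_path: str | Path, lineage_path: str | Path | None = None) -> None:
    out = table.abundance.copy()
    out.insert(0, "total_ssu_reads", table.sample_totals.reindex(out.index))
    out.to_csv(matrix_path, sep="\t", index_label="sample_id")
    if lineage_path is not None:
        write_lineages(table.lineages, lineage_path)


def read_otu_table(matrix_path: str | Path, lineage_path: str | Path | None = None) -> OtuTable:
    df = pd.read_csv(matrix_path, sep="\t", index_col="sample_id")
    totals = df.pop("total_ssu_reads") if "total_ssu_reads" in df.columns else df.sum(axis=1)
    df.index.name = None
    df.columns.name = None
    totals = totals.rename(None)
    totals.index.name = None
    lineages = read_lineages(lineage_path) if lineage_path else {}
    return OtuTable(df.astype(float), lineages, totals.astype(float))


def write_lineages(lineages: dict[str, list[str]], path: str | Path) -> None:
    depth = max((len(v) for v in lineages.values()), default=0)
    cols = [f"rank{i + 1}" for i in range(depth)]
    rows = [[otu] + list(v) + [""] * (depth - len(v)) for otu, v in sorted(lineages.items())]
    pd.DataFrame(rows, columns=["otu_id"] + cols).to_csv(path, sep="\t", index=False)


def read_lineages(path: str | Path) -> dict[str, list[str]]:
    df = _read_tsv(path, ["otu_id"])
    ranks = [c for c in df.columns if c.startswith("rank")]
    return {
        r["otu_id"]: [r[c] for c in ranks if isinstance(r[c], str) and r[c]]
        for _, r in df.iterrows()
    }


# -- HLA counts and profiles -------------------------------------------------

def write_hla_counts(gene_counts: list[GeneReadCounts], path: str | Path) -> None:
    rows = [
        (gc.sample_id, gc.gene, allele, count)
        for gc in gene_counts
        for allele, count in sorted(gc.counts.items())
    ]
    pd.DataFrame(rows, columns=["sample_id", "gene", "allele", "count"]).to_csv(
        path, sep="\t", index=False
    )


def read_hla_counts(path: str | Path) -> list[GeneReadCounts]:
    df = _read_tsv(path, ["sample_id", "gene", "allele", "count"])
    out: dict[tuple[str, str], GeneReadCounts] = {}
    for rec in df.itertuples(index=False):
        gc = out.setdefault(
            (rec.sample_id, rec.gene), GeneReadCounts(rec.sample_id, rec.gene, {})
        )
        gc.counts[rec.allele] = gc.counts.get(rec.allele, 0.0) + float(rec.count)
    return [out[k] for k in sorted(out)]


def write_profiles(profiles: list[HlaProfile], path: str | Path) -> None:
    rows = []
    for p in profiles:
        for gene in sorted(p.calls):
            c = p.calls[gene]
            rows.append(
                (p.sample_id, gene, c.status, c.allele1 or "", c.allele2 or "", c.zygosity, c.r_score)
            )
    pd.DataFrame(
        rows, columns=["sample_id", "gene", "status", "allele1", "allele2", "zygosity", "r_score"]
    ).to_csv(path, sep="\t", index=False)


def read_profiles(path: str | Path) -> list[HlaProfile]:
    df = _read_tsv(path, ["sample_id", "gene", "status", "zygosity"])
    out: dict[str, HlaProfile] = {}
    for rec in df.itertuples(index=False):
        p = out.setdefault(rec.sample_id, HlaProfile(sample_id=rec.sample_id))
        p.calls[rec.gene] = GenotypeCall(
            gene=rec.gene,
            status=rec.status,
            allele1=rec.allele1 if isinstance(rec.allele1, str) and rec.allele1 else None,
            allele2=rec.allele2 if isinstance(rec.allele2, str) and rec.allele2 else None,
            zygosity=rec.zygosity,
            r_score=float(rec.r_score),
        )
    return [out[k] for k in sorted(out)]


# -- peptidomes and presentation maps ----------------------------------------

def write_peptidome(peptidome: set[str], path: str | Path) -> None:
    Path(path).write_text("\n".join(sorted(peptidome)) + "\n")


def read_peptidome(path: str | Path) -> set[str]:
    return {line.strip().upper() for line in Path(path).read_text().splitlines() if line.strip()}


def write_presentation_sets(pmap: PresentationMap, path: str | Path) -> None:
    rows = [(a, p) for a, peps in sorted(pmap.sets.items()) for p in sorted(peps)]
    pd.DataFrame(rows, columns=["allele", "peptide"]).to_csv(path, sep="\t", index=False)


def read_presentation_sets(path: str | Path) -> PresentationMap:
    df = _read_tsv(path, ["allele", "peptide"])
    sets: dict[str, set[str]] = {}
    for rec in df.itertuples(index=False):
        sets.setdefault(rec.allele, set()).add(rec.peptide)
    return PresentationMap(sets=sets)


def write_jaccard_table(pmap: PresentationMap, path: str | Path) -> None:
    table = pmap.jaccard_table or pmap.to_table().jaccard_table
    rows = [(a, b, j) for (a, b), j in sorted(table.items())]
    pd.DataFrame(rows, columns=["allele_a", "allele_b", "jaccard"]).to_csv(path, sep="\t", index=False)


def read_jaccard_table(path: str | Path) -> PresentationMap:
    df = _read_tsv(path, ["allele_a", "allele_b", "jaccard"])
    table = {
        (rec.allele_a, rec.allele_b): float(rec.jaccard) for rec in df.itertuples(index=False)
    }
    return PresentationMap(jaccard_table=table)


# -- proteins and trees ------------------------------------------------------

def read_proteins(path: str | Path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def write_proteins(proteins: list[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in proteins:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


def read_tree(path: str | Path) -> TreeNode:
    """Read a newick taxonomy tree, warning about non-unit branch lengths."""
    tree = TreeNode.read(str(path))
    n_nonunit = sum(
        1 for node in tree.postorder() if node.length is not None and not math.isclose(node.length, 1.0)
    )
    if n_nonunit:
        logger.warning("tree has %d branches with non-unit length; honoring them as read", n_nonunit)
    return tree


def write_tree(tree: TreeNode, path: str | Path) -> None:
    tree.write(str(path))


# -- strata and heatmaps -----------------------------------------------------

def write_strata(strata: pd.DataFrame, path: str | Path) -> None:
    strata.rename(columns={"pair_id": "unit_id"}).to_csv(path, sep="\t", index=False)


def read_strata(path: str | Path, ordered_labels: list | None = None) -> pd.DataFrame:
    df = _read_tsv(path, ["unit_id", "stratum", "value"])
    df["value"] = df["value"].astype(float)
    cats = ordered_labels if ordered_labels is not None else sorted(df["stratum"].unique())
    df["stratum"] = pd.Categorical(df["stratum"], categories=cats, ordered=True)
    return df


def write_heatmap(mat: pd.DataFrame, path: str | Path, png_path: str | Path | None = None) -> None:
    mat.to_csv(path, sep="\t", index_label="stratum")
    if png_path is not None:
        plot_heatmap(mat, png_path)


def plot_heatmap(mat: pd.DataFrame, png_path: str | Path) -> None:
    """Render a P-value heatmap to PNG (rows tested against columns)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(1.2 * len(mat.columns) + 2, 1.0 * len(mat) + 1.5))
    im = ax.imshow(mat.to_numpy(), vmin=0, vmax=1, cmap="viridis")
    ax.set_xticks(range(len(mat.columns)), mat.columns)
    ax.set_yticks(range(len(mat.index)), mat.index)
    for i in range(len(mat.index)):
        for j in range(len(mat.columns)):
            v = mat.iat[i, j]
            if not math.isnan(v):
                ax.text(j, i, f"{v:.3g}", ha="center", va="center", fontsize=8, color="w")
    fig.colorbar(im, ax=ax, label="KS P value")
    fig.tight_layout()
    fig.savefig(png_path, dpi=120)
    plt.close(fig)
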