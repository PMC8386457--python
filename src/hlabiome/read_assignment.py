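"""From read-to-reference assignment tables to OTU tables and HLA read counts.

Shotgun gut reads are mapped against a composite reference of bacterial
SSU-rRNA sequences and genomic HLA sequences; this module starts from the
resulting per-read assignment table.  Reads that hit a single reference
count fully towards it; multimapping reads are divided across their
targets in proportion to each target's unique (primary) read count, with
an equal split when none of the targets has unique support.  The SSU side
becomes a filtered OTU abundance table (samples below a total-read floor
are dropped, OTUs below a relative-abundance floor within a sample are
dropped); the HLA side is aggregated to per-gene, two-digit-allele read
counts for genotype calling.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import ALL_GENES, logger

_HLA_TARGET_RE = re.compile(r"^(?P<gene>[A-Z0-9]+)\*(?P<group>\d+)")


def parse_hla_target(target_id: str) -> tuple[str, str] | None:
    """Resolve a target id to ``(gene, two-digit allele)`` or ``None``.

    HLA reference ids look like ``B*07``, ``B*07:02`` or ``B*07:02#seq1``;
    everything after the allele group (two-digit) field is collapsed, so
    all reference sequences of one allele group aggregate together.
    Ids whose gene is not a classical HLA locus are treated as OTUs.
    """
    m = _HLA_TARGET_RE.match(target_id)
    if m is None or m.group("gene") not in ALL_GENES:
        return None
    return m.group("gene"), f"{m.group('gene')}*{m.group('group')}"


@dataclass
class GeneReadCounts:
    """Read counts per two-digit allele for one (sample, gene)."""

    sample_id: str
    gene: str
    counts: dict[str, float] = field(default_factory=dict)


@dataclass
class OtuTable:
    """Samples x OTUs abundance matrix plus a rank lineage per OTU.

    ``abundance`` is a DataFrame indexed by sample id with one column per
    OTU; ``lineages`` maps otu_id to an ordered list of rank labels
    (domain through species).
    """

    abundance: pd.DataFrame
    lineages: dict[str, list[str]] = field(default_factory=dict)
    #: total SSU reads per sample before OTU filtering; the relative-abundance
    #: denominator and the N of Margalef richness
    sample_totals: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))

    @property
    def sample_ids(self) -> list[str]:
        return list(self.abundance.index)

    @property
    def otu_ids(self) -> list[str]:
        return list(self.abundance.columns)


def distribute_multimappers(table: pd.DataFrame) -> pd.DataFrame:
    """Apportion reads across targets, returning fractional per-target counts.

    Parameters
    ----------
    table:
        Assignment rows with columns ``read_id``, ``target_id``,
        ``is_primary`` and optionally ``sample_id``.  A read with a single
        row is unique; a read with several rows is a multimapper.

    Returns
    -------
    DataFrame with columns ``sample_id``, ``target_id``, ``count``.  Each
    unique read contributes 1 to its target; each multimapper is split
    across its targets proportionally to the targets' unique-read counts
    (equally when all of them have zero unique reads).  The fractions of
    one read sum to 1, so the grand total equals the number of distinct
    reads.
    """
    if table.empty:
        raise ValueError("assignment table is empty")
    df = table.copy()
    if "sample_id" not in df.columns:
        df["sample_id"] = "S0"
    bad = df["target_id"].isna() | (df["target_id"].astype(str).str.len() == 0)
    if bad.any():
        logger.warning("rejecting %d assignment rows without a target", int(bad.sum()))
        df = df[~bad]
    # drop duplicate (read, target) alignments so a read hits a target once
    df = df.drop_duplicates(subset=["sample_id", "read_id", "target_id"])

    out: list[pd.DataFrame] = []
    for sample_id, sub in df.groupby("sample_id", sort=True):
        n_targets = sub.groupby("read_id")["target_id"].transform("size")
        uniq = sub[n_targets == 1]
        multi = sub[n_targets > 1]
        unique_counts = uniq.groupby("target_id").size().astype(float)
        counts = unique_counts.to_dict()
        for _, grp in multi.groupby("read_id"):
            targets = grp["target_id"].tolist()
            weights = np.array([unique_counts.get(t, 0.0) for t in targets])
            if weights.sum() == 0:
                weights = np.ones(len(targets))
            weights = weights / weights.sum()
            for t, w in zip(targets, weights):
                counts[t] = counts.get(t, 0.0) + w
        out.append(
            pd.DataFrame(
                {"sample_id": sample_id, "target_id": list(counts), "count": list(counts.values())}
            )
        )
    res = pd.concat(out, ignore_index=True)
    return res.sort_values(["sample_id", "target_id"], ignore_index=True)


def split_namespaces(counts: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split fractional counts into the OTU and HLA namespaces."""
    is_hla = counts["target_id"].map(lambda t: parse_hla_target(str(t)) is not None)
    return counts[~is_hla].reset_index(drop=True), counts[is_hla].reset_index(drop=True)


def build_otu_table(
    counts: pd.DataFrame,
    lineages: dict[str, list[str]],
    min_reads: float = 1000,
    min_rel_abund: float = 1e-4,
    sample_totals: pd.Series | None = None,
) -> OtuTable:
    """Build a filtered OTU table from OTU-namespace fractional counts.

    Samples whose total SSU count (before any OTU filtering) is below
    ``min_reads`` are dropped.  Within retained samples, OTUs with
    relative abundance below ``min_rel_abund`` are dropped, the relative
    abundance being computed against the pre-filter sample total so the
    threshold does not depend on filter order.  Both thresholds are
    inclusive: a sample at exactly ``min_reads`` and an OTU at exactly
    ``min_rel_abund`` are retained.  Passing ``sample_totals`` (e.g. the
    totals of a previously built table) pins the pre-filter denominators,
    which makes re-filtering a no-op.
    """
    if counts.empty:
        return OtuTable(pd.DataFrame(dtype=float), dict(lineages))
    mat = counts.pivot_table(
        index="sample_id", columns="target_id", values="count", aggfunc="sum", fill_value=0.0
    )
    totals = mat.sum(axis=1) if sample_totals is None else sample_totals.reindex(mat.index)
    kept = totals[totals >= min_reads].index
    n_dropped = len(mat) - len(kept)
    if n_dropped:
        logger.info("OTU table: dropped %d samples below %g total SSU reads", n_dropped, min_reads)
    mat = mat.loc[kept]
    if mat.empty:
        return OtuTable(pd.DataFrame(dtype=float), dict(lineages))
    rel = mat.div(totals.loc[kept], axis=0)
    mat = mat.where(rel >= min_rel_abund, 0.0)
    mat = mat.loc[:, (mat > 0).any(axis=0)]
    return OtuTable(
        mat,
        {o: lineages[o] for o in mat.columns if o in lineages},
        totals.loc[kept].astype(float),
    )


def extract_hla_counts(counts: pd.DataFrame) -> list[GeneReadCounts]:
    """Aggregate HLA-namespace fractional counts to two-digit alleles.

    One :class:`GeneReadCounts` is returned per (sample, gene) with
    counts summed over all reference sequences of the same allele group.
    Malformed allele names are rejected with a warning.
    """
    acc: dict[tuple[str, str], dict[str, float]] = {}
    n_bad = 0
    for row in counts.itertuples(index=False):
        parsed = parse_hla_target(str(row.target_id))
        if parsed is None:
            n_bad += 1
            continue
        gene, allele = parsed
        d = acc.setdefault((str(row.sample_id), gene), {})
        d[allele] = d.get(allele, 0.0) + float(row.count)
    if n_bad:
        logger.warning("extract_hla_counts: rejected %d malformed HLA targets", n_bad)
    return [
        GeneReadCounts(sample_id=s, gene=g, counts=dict(sorted(d.items())))
        for (s, g), d in sorted(acc.items())
    ]
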