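"""Stratified distribution comparisons with two-sample KS tests.

Sample pairs are stratified by functional HLA similarity (PPSS bins,
shared-allele counts, shared supertypes) and their beta-diversity values
compared across strata; samples are stratified by zygosity (number of
heterozygous genes, identity of the homozygous gene) and their alpha
diversity compared.  All comparisons use the two-sample
Kolmogorov–Smirnov test with two-sided or one-sided alternatives; the
P-value heatmap tests, for each ordered stratum pair, the null
hypothesis that the row stratum is drawn from an equal or smaller
distribution than the column stratum.

Note the pairwise values are not independent observations (pairs share
samples); the KS test is applied to them regardless, which is the
analysis convention this package reproduces, and P values should be
read with that caveat.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .config import CLASS_I_GENES, CLASS_II_GENES
from .hla_typing import HlaProfile
from .peptidome import shared_alleles, supertype_similarity

#: above this product of sample sizes the asymptotic KS P value is used
EXACT_KS_MAX_NM = 10_000


@dataclass
class KsResult:
    """Two-sample KS test result."""

    statistic: float
    p_value: float
    alternative: str
    n1: int
    n2: int


def ks_two_sample(x, y, alternative: str = "two_sided") -> KsResult:
    """Two-sample KS test with a two-sided or one-sided alternative.

    ``alternative`` follows the distribution (not CDF) reading:
    ``greater`` means the alternative that x is stochastically greater
    than y, i.e. its ECDF lies below y's; ``less`` the reverse.  The
    exact P value is used for small samples (n1·n2 ≤ 10,000) and the
    asymptotic form otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be nonempty")
    # scipy's 'less'/'greater' refer to the ECDF of x; a stochastically
    # greater sample has the *smaller* ECDF, hence the swap
    scipy_alt = {"two_sided": "two-sided", "greater": "less", "less": "greater"}[alternative]
    method = "exact" if len(x) * len(y) <= EXACT_KS_MAX_NM else "asymp"
    res = stats.ks_2samp(x, y, alternative=scipy_alt, method=method)
    return KsResult(float(res.statistic), float(res.pvalue), alternative, len(x), len(y))


def _pair_key(a: str, b: str) -> str:
    return f"{a}|{b}" if a <= b else f"{b}|{a}"


def bin_by_ppss(
    ppss_values: pd.DataFrame,
    beta_values: pd.DataFrame,
    edges: tuple[float, ...] = (4.0, 6.0, 8.0),
    value_column: str = "spearman",
) -> pd.DataFrame:
    """Stratify sample pairs by PPSS bins and attach a beta-diversity value.

    Bins are left-closed/right-open: with the default edges they are
    <4, [4,6), [6,8) and ≥8.  Returns a frame (``pair_id``, ``stratum``,
    ``value``) with ``stratum`` an ordered categorical.
    """
    edges = tuple(edges)
    if any(b <= a for a, b in zip(edges, edges[1:])):
        raise ValueError("edges must be strictly increasing")
    labels = [f"<{edges[0]:g}"] + [
        f"{a:g}-{b:g}" for a, b in zip(edges, edges[1:])
    ] + [f">={edges[-1]:g}"]
    beta = beta_values.copy()
    beta["pair_id"] = [
        _pair_key(a, b) for a, b in zip(beta["sample_i"], beta["sample_j"])
    ]
    merged = ppss_values.copy()
    merged["pair_id"] = [
        _pair_key(a, b) for a, b in zip(merged["sample_i"], merged["sample_j"])
    ]
    merged = merged.merge(beta[["pair_id", value_column]], on="pair_id", how="inner")
    idx = np.searchsorted(np.asarray(edges), merged["ppss"].to_numpy(), side="right")
    strata = pd.Categorical(
        [labels[i] for i in idx], categories=labels, ordered=True
    )
    return pd.DataFrame(
        {"pair_id": merged["pair_id"], "stratum": strata, "value": merged[value_column]}
    )


def bin_by_shared_alleles(
    profiles: list[HlaProfile],
    beta_values: pd.DataFrame,
    hla_class: int = 1,
    value_column: str = "spearman",
    supertype_map: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Stratify sample pairs by shared-allele count (or shared supertypes).

    With a ``supertype_map`` the stratum is the number of shared HLA-A/B
    supertypes instead of shared alleles.  Returns (``pair_id``,
    ``stratum``, ``value``) with integer-labelled ordered strata.
    """
    by_id = {p.sample_id: p for p in profiles}
    rows = []
    for rec in beta_values.itertuples(index=False):
        pi, pj = by_id.get(rec.sample_i), by_id.get(rec.sample_j)
        if pi is None or pj is None:
            continue
        if supertype_map is not None:
            n = supertype_similarity(pi, pj, supertype_map)
        else:
            n = shared_alleles(pi, pj, hla_class)
        rows.append((_pair_key(rec.sample_i, rec.sample_j), n, getattr(rec, value_column)))
    df = pd.DataFrame(rows, columns=["pair_id", "stratum", "value"])
    cats = sorted(df["stratum"].unique()) if len(df) else []
    df["stratum"] = pd.Categorical(df["stratum"], categories=cats, ordered=True)
    return df


def stratum_pvalue_heatmap(strata: pd.DataFrame, alternative: str = "greater") -> pd.DataFrame:
    """One-sided KS P values for every ordered stratum pair.

    Cell (row, column) tests the null hypothesis that the row stratum's
    values are drawn from an equal or smaller distribution than the
    column stratum's (for ``alternative='greater'``); a small P value
    therefore flags the row as stochastically greater.  Diagonal cells
    are 1 by definition; strata with fewer than two values give NaN.
    """
    if not isinstance(strata["stratum"].dtype, pd.CategoricalDtype):
        raise ValueError("strata must carry an ordered categorical 'stratum' column")
    labels = list(strata["stratum"].cat.categories)
    groups = {lab: strata.loc[strata["stratum"] == lab, "value"].dropna().to_numpy() for lab in labels}
    nonempty = [lab for lab in labels if len(groups[lab]) > 0]
    if len(nonempty) < 2:
        raise ValueError("need at least two nonempty strata")
    mat = pd.DataFrame(np.nan, index=labels, columns=labels)
    for r in labels:
        for c in labels:
            if r == c:
                mat.loc[r, c] = 1.0
            elif len(groups[r]) >= 2 and len(groups[c]) >= 2:
                mat.loc[r, c] = ks_two_sample(groups[r], groups[c], alternative).p_value
    return mat


def group_by_heterozygosity(
    profiles: list[HlaProfile],
    alpha_values: dict[str, float],
    hla_class: int = 1,
) -> pd.DataFrame:
    """Stratify samples by their number of heterozygous genes (0–3).

    ``alpha_values`` maps sample id to the diversity value to compare
    (richness or evenness).  Samples with an undetermined zygosity at
    any gene of the class are excluded.
    """
    genes = CLASS_I_GENES if hla_class == 1 else CLASS_II_GENES
    rows = []
    n_excluded = 0
    for p in profiles:
        if not p.is_complete(hla_class) or p.sample_id not in alpha_values:
            continue
        zygs = [p.calls[g].zygosity for g in genes]
        if "undetermined" in zygs:
            n_excluded += 1
            continue
        rows.append((p.sample_id, zygs.count("het"), alpha_values[p.sample_id]))
    df = pd.DataFrame(rows, columns=["unit_id", "stratum", "value"])
    df.attrs["n_excluded"] = n_excluded
    df["stratum"] = pd.Categorical(df["stratum"], categories=sorted(df["stratum"].unique()), ordered=True)
    return df


def group_by_homozygous_gene(
    profiles: list[HlaProfile],
    alpha_values: dict[str, float],
    hla_class: int = 1,
) -> pd.DataFrame:
    """Stratify samples by the identity of their homozygous gene(s).

    A sample homozygous at several genes appears in each of those gene
    strata (all samples with at least one homozygous gene are used).
    """
    genes = CLASS_I_GENES if hla_class == 1 else CLASS_II_GENES
    rows = []
    for p in profiles:
        if not p.is_complete(hla_class) or p.sample_id not in alpha_values:
            continue
        for g in genes:
            if p.calls[g].zygosity == "hom":
                rows.append((p.sample_id, g, alpha_values[p.sample_id]))
    df = pd.DataFrame(rows, columns=["unit_id", "stratum", "value"])
    df["stratum"] = pd.Categorical(df["stratum"], categories=list(genes), ordered=True)
    return df
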