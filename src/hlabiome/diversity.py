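"""Alpha and beta diversity of OTU abundance profiles.

Alpha diversity uses two indices chosen to attenuate sampling-size
effects: Margalef's richness D_mg = (S − 1)/ln N, where S is the number
of OTUs observed in a sample and N the number of SSU reads mapped
(before OTU filtering), and Heip's evenness E = (e^H − 1)/(S − 1) with H
the natural-log Shannon–Wiener entropy of the relative abundances.  No
rarefaction is applied.

Beta diversity between two samples is measured two ways: Spearman rank
correlation of the abundances over the union of the pair's observed OTUs
(absences as zero), and raw weighted UniFrac on a taxonomy tree whose
edges all have branch length 1 between adjacent ranks,

    d(x, y) = Σ_branches |A_b − B_b|

where A_b and B_b are the fractions of each community descending from
the branch.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from skbio import TreeNode

from .read_assignment import OtuTable


def margalef(S: int, N: float) -> float:
    """Margalef richness (S − 1)/ln N; undefined (NaN) for N < 2."""
    if N < 2:
        return float("nan")
    return (S - 1) / math.log(N)


def shannon(abundances: np.ndarray) -> float:
    """Natural-log Shannon–Wiener entropy of an abundance vector."""
    a = np.asarray(abundances, dtype=float)
    p = a[a > 0]
    p = p / p.sum()
    return float(-(p * np.log(p)).sum())


def heip(abundances: np.ndarray) -> float:
    """Heip evenness (e^H − 1)/(S − 1); undefined (NaN) for S < 2.

    Invariant under rescaling of the abundance vector; exactly 1 for a
    perfectly even community of any size.
    """
    a = np.asarray(abundances, dtype=float)
    S = int((a > 0).sum())
    if S < 2:
        return float("nan")
    return (math.exp(shannon(a)) - 1) / (S - 1)


@dataclass
class AlphaResult:
    """Per-sample alpha diversity: S, N, Margalef richness, entropy, evenness."""

    sample_id: str
    S: int
    N: float
    margalef: float
    shannon: float
    heip: float


def alpha_diversity(table: OtuTable) -> list[AlphaResult]:
    """Alpha diversity for every sample of a filtered OTU table.

    S counts the OTUs with positive abundance after filtering; N is the
    sample's pre-filter mapped SSU read count carried on the table.
    """
    out = []
    for sample_id in table.sample_ids:
        row = table.abundance.loc[sample_id].to_numpy(dtype=float)
        S = int((row > 0).sum())
        N = float(table.sample_totals.get(sample_id, row.sum()))
        out.append(
            AlphaResult(sample_id, S, N, margalef(S, N), shannon(row), heip(row))
        )
    return out


def spearman_beta(x: pd.Series, y: pd.Series) -> float:
    """Spearman rank correlation of two samples' abundances.

    The vectors are aligned on the union of the OTUs observed in either
    sample, with zeros for absences; ties get average ranks.  Constant
    vectors give an undefined correlation (NaN).
    """
    otus = sorted(set(x.index[x > 0]) | set(y.index[y > 0]))
    if len(otus) < 2:
        return float("nan")
    xv = x.reindex(otus, fill_value=0.0).to_numpy(dtype=float)
    yv = y.reindex(otus, fill_value=0.0).to_numpy(dtype=float)
    if np.ptp(xv) == 0 or np.ptp(yv) == 0:
        return float("nan")
    return float(stats.spearmanr(xv, yv).statistic)


def taxonomy_tree(lineages: dict[str, list[str]]) -> TreeNode:
    """Expand rank lineages into a rooted tree with unit branch lengths.

    Every OTU becomes a leaf under the chain of its rank labels
    (domain → … → species); every edge, including the leaf edge, has
    branch length exactly 1.
    """
    root = TreeNode(name="root")
    index: dict[tuple[str, ...], TreeNode] = {(): root}
    for otu_id, lineage in sorted(lineages.items()):
        parent = root
        path: tuple[str, ...] = ()
        for rank in lineage:
            path = path + (rank,)
            node = index.get(path)
            if node is None:
                node = TreeNode(name=rank, length=1.0)
                parent.append(node)
                index[path] = node
            parent = node
        leaf = TreeNode(name=otu_id, length=1.0)
        parent.append(leaf)
    return root


def weighted_unifrac(x: pd.Series, y: pd.Series, tree: TreeNode) -> float:
    """Raw weighted UniFrac distance between two samples on a unit-branch tree.

    Abundances are normalized to relative abundances over the tree's
    leaves; the distance sums branch length times the absolute difference
    of the community fractions descending from each branch.  A sample
    OTU absent from the tree is an error naming the OTU.
    """
    leaves = {leaf.name for leaf in tree.tips()}
    for s in (x, y):
        missing = set(s.index[np.asarray(s) > 0]) - leaves
        if missing:
            raise KeyError(f"OTU {sorted(missing)[0]} absent from taxonomy tree")
    xs, ys = float(x.sum()), float(y.sum())
    if xs == 0 or ys == 0:
        raise ValueError("cannot compute weighted UniFrac for an empty community")
    dist = 0.0
    # postorder accumulation of the community fraction under every branch
    frac: dict[int, tuple[float, float]] = {}
    for node in tree.postorder(include_self=True):
        if node.is_tip():
            a = float(x.get(node.name, 0.0)) / xs
            b = float(y.get(node.name, 0.0)) / ys
        else:
            a = sum(frac[id(c)][0] for c in node.children)
            b = sum(frac[id(c)][1] for c in node.children)
        frac[id(node)] = (a, b)
        if node.length:
            dist += node.length * abs(a - b)
    return dist


def beta_diversity(
    table: OtuTable, tree: TreeNode | None = None
) -> pd.DataFrame:
    """Spearman and weighted-UniFrac beta diversity for all sample pairs.

    Returns a long-format frame (``sample_i``, ``sample_j``,
    ``spearman``, ``unifrac``); UniFrac columns are NaN when no tree is
    given.
    """
    samples = table.sample_ids
    rows = []
    for i, si in enumerate(samples):
        xi = table.abundance.loc[si]
        for sj in samples[i + 1 :]:
            yj = table.abundance.loc[sj]
            rho = spearman_beta(xi, yj)
            wu = weighted_unifrac(xi, yj, tree) if tree is not None else float("nan")
            rows.append((si, sj, rho, wu))
    return pd.DataFrame(rows, columns=["sample_i", "sample_j", "spearman", "unifrac"])


def pairwise_spearman(table: OtuTable) -> pd.DataFrame:
    """Fast all-pairs Spearman beta diversity.

    Exactly equivalent to calling :func:`spearman_beta` on every pair
    when no OTU is absent from both samples of any pair (zeros present
    in both members of a pair shift the union, in which case the slow
    per-pair path of :func:`beta_diversity` is used for those pairs).
    """
    mat = table.abundance.to_numpy(dtype=float)
    samples = table.sample_ids
    pos = mat > 0
    # exact fast path when no OTU is absent from both members of any pair,
    # i.e. every OTU is present in at least n-1 samples
    fast_ok = bool(np.all(pos.sum(axis=0) >= len(samples) - 1))
    rows = []
    if fast_ok:
        ranks = np.apply_along_axis(stats.rankdata, 1, mat)
        ranks = ranks - ranks.mean(axis=1, keepdims=True)
        denom = np.sqrt((ranks**2).sum(axis=1))
        corr = (ranks @ ranks.T) / np.outer(denom, denom)
        for i, si in enumerate(samples):
            for j in range(i + 1, len(samples)):
                rows.append((si, samples[j], float(corr[i, j])))
    else:
        for i, si in enumerate(samples):
            xi = table.abundance.loc[si]
            for sj in samples[i + 1 :]:
                rows.append((si, sj, spearman_beta(xi, table.abundance.loc[sj])))
    return pd.DataFrame(rows, columns=["sample_i", "sample_j", "spearman"])
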