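"""Pipeline configuration and logging.

All thresholds of the analysis live here with their published defaults:
genotype-calling gates (``r_min``, ``min_top_reads``, ``het_fraction``),
OTU-table filters (``min_reads``, ``min_rel_abund``), peptidome sampling
(``window``, ``sample_rate``), binding-rank cutoff (``rank_cutoff``) and
the PPSS stratification edges (``ppss_edges``).  A config round-trips
losslessly through YAML.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

logger = logging.getLogger("hlabiome")


def setup_logging(level: int = logging.INFO) -> None:
    """Configure stage-granularity logging for the pipeline."""
    handler = logging.StreamHandler()
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    logger.handlers[:] = [handler]
    logger.setLevel(level)


@dataclass
class PipelineConfig:
    """All tunable parameters of the analysis with their standard defaults.

    Attributes
    ----------
    r_min:
        Minimum R score (reads on top-two alleles over reads on all other
        alleles of the gene) for a gene to be considered for typing.
    min_top_reads:
        Minimum read count on the top allele for any genotype call.
    het_fraction:
        A locus is heterozygous when the second allele carries at least
        this fraction of the top allele's reads; below it, homozygous.
    min_reads:
        Minimum total SSU read count for a sample to be retained.
    min_rel_abund:
        Minimum within-sample relative abundance for an OTU to be retained
        (computed on the pre-filter sample total).
    window:
        Peptide length for the sliding-window peptidome (9-mers).
    sample_rate:
        Per-candidate inclusion probability when sampling the peptidome.
    rank_cutoff:
        Percentile-rank threshold below or at which a peptide counts as
        presented by an allele.
    ppss_edges:
        Left-closed bin edges for PPSS stratification; the default yields
        the strata <4, [4,6), [6,8) and >=8.
    """

    r_min: float = 2.0
    min_top_reads: int = 10
    het_fraction: float = 0.15
    min_reads: int = 1000
    min_rel_abund: float = 1e-4
    window: int = 9
    sample_rate: float = 0.001
    rank_cutoff: float = 2.0
    ppss_edges: tuple[float, ...] = (4.0, 6.0, 8.0)
    seed: int = 0
    paths: dict[str, str] = field(default_factory=dict)

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["ppss_edges"] = list(self.ppss_edges)
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PipelineConfig":
        d = dict(d)
        if "ppss_edges" in d:
            d["ppss_edges"] = tuple(float(e) for e in d["ppss_edges"])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


CLASS_I_GENES = ("A", "B", "C")
CLASS_II_GENES = ("DPB1", "DQB1", "DRB1")
ALL_GENES = CLASS_I_GENES + CLASS_II_GENES
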