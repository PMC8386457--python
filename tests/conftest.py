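import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from hlabiome.hla_typing import GenotypeCall, HlaProfile

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow], deadline=None
)
settings.load_profile("ci")


def make_profile(sample_id: str, genotypes: dict[str, tuple[str, str]]) -> HlaProfile:
    """Build a called profile from gene → (allele1, allele2)."""
    profile = HlaProfile(sample_id=sample_id)
    for gene, (a1, a2) in genotypes.items():
        profile.calls[gene] = GenotypeCall(
            gene=gene,
            status="called",
            allele1=a1,
            allele2=a2,
            zygosity="hom" if a1 == a2 else "het",
            r_score=10.0,
        )
    return profile


@pytest.fixture
def assignment_table() -> pd.DataFrame:
    """Three unique reads on T1, one on T2, one multimapper hitting both."""
    rows = [
        ("r1", "T1", 1),
        ("r2", "T1", 1),
        ("r3", "T1", 1),
        ("r4", "T2", 1),
        ("r5", "T1", 1),
        ("r5", "T2", 0),
    ]
    return pd.DataFrame(rows, columns=["read_id", "target_id", "is_primary"])
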