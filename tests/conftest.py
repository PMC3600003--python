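import numpy as np
import pandas as pd
import pytest

from circenrich.io import AnnotationTrack, LdConfig, LdMap, SnpCatalog
from circenrich.overlap import compute_overlap_matrix
from circenrich.simulate import SimConfig, TrackSpec, simulate_study


def make_catalog(rows):
    """rows: (snp_id, chrom, pos, groups, pvalue-or-None)."""
    df = pd.DataFrame(
        {
            "snp_id": [r[0] for r in rows],
            "chrom": [r[1] for r in rows],
            "pos": [r[2] for r in rows],
            "platform_groups": [frozenset(r[3]) for r in rows],
            "pvalue": [r[4] if len(r) > 4 else np.nan for r in rows],
        }
    )
    return SnpCatalog(df)


@pytest.fixture
def tiny_catalog():
    """Five SNPs on two chromosomes, one platform group each."""
    return make_catalog(
        [
            ("s1", "1", 150, {"affy"}),
            ("s2", "1", 500, {"affy", "illumina"}),
            ("s3", "1", 900, {"illumina"}),
            ("s4", "2", 120, {"affy"}),
            ("s5", "2", 300, {"hapmap"}),
        ]
    )


@pytest.fixture
def tiny_track():
    return AnnotationTrack("feat", [("1", 100, 200), ("2", 250, 400)])


@pytest.fixture(scope="session")
def toy_study():
    """A small clustered genome with one planted enrichment (shared, read-only)."""
    cfg = SimConfig(
        n_chromosomes=3,
        snps_per_chromosome=2_000,
        chromosome_length=6_000_000,
        n_assoc=120,
        planted_or={"track03": 3.0},
        seed=11,
    )
    return simulate_study(cfg)
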