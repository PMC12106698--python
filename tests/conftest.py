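import numpy as np
import pandas as pd
import pytest

from cfsomatic.variant_io import EvidenceTable, VariantKey


def make_evidence_df(rows):
    """Build an evidence frame from (key, base, strand, frag, mapq, baseq, dist) tuples."""
    recs = []
    for key, base, strand, frag, mapq, baseq, dist in rows:
        recs.append(
            {
                "contig": key.contig,
                "pos": key.pos,
                "ref": key.ref,
                "alt": key.alt,
                "base": base,
                "strand": strand,
                "fragment_length": frag,
                "mapq": mapq,
                "baseq": baseq,
                "dist_from_end": dist,
                "supports_alt": base == key.alt,
            }
        )
    return pd.DataFrame(recs)


@pytest.fixture
def simple_key():
    return VariantKey("chr1", 100, "A", "T")


@pytest.fixture
def simple_evidence(simple_key):
    """10 reads: 3 alt, 6 ref, 1 other-base."""
    rows = []
    for i in range(3):
        rows.append((simple_key, "T", "forward" if i % 2 else "reverse", 120.0, 60.0, 35.0, 10 + i))
    for i in range(6):
        rows.append((simple_key, "A", "forward" if i % 2 else "reverse", 170.0, 60.0, 35.0, 20))
    rows.append((simple_key, "G", "forward", 170.0, 60.0, 35.0, 20))
    return EvidenceTable(make_evidence_df(rows))


@pytest.fixture(scope="session")
def small_cohort():
    """A reusable small cohort with default (non-null) signal."""
    from cfsomatic.synthetic_fixtures import CohortConfig, simulate_cohort

    return simulate_cohort(
        CohortConfig(n_samples=3, n_variants_per_sample=1200, prevalence=0.02, seed=42)
    )
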