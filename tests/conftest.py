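import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from msrisk.genotypes import GenotypeMatrix
from msrisk.panel_io import AssociationPanel, VariantAssociation

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def hla_variant():
    """The published HLA-DRB1*15 association (OR 3.08, RAF 0.2013)."""
    return VariantAssociation("HLA_DRB1_1501", "DRB1*15", 3.08, 0.2013, 9772, 17376)


@pytest.fixture
def hla_panel(hla_variant):
    return AssociationPanel([hla_variant], "HLA_only")


@pytest.fixture
def two_locus_panel():
    return AssociationPanel(
        [
            VariantAssociation("rs_a", "A", 2.0, 0.30, 2000, 2000),
            VariantAssociation("rs_b", "T", 1.5, 0.50, 2000, 2000),
        ],
        "two_locus_toy",
    )


@pytest.fixture
def null_panel():
    """Three loci with OR = 1: no profile distinguishable from baseline."""
    return AssociationPanel(
        [
            VariantAssociation(f"rs_null_{i}", "A", 1.0, raf, 5000, 5000)
            for i, raf in enumerate((0.2, 0.5, 0.7))
        ],
        "null",
    )


def make_matrix(dosages, labels=None, variant_ids=None) -> GenotypeMatrix:
    """Small GenotypeMatrix from a nested list (None = missing)."""
    arr = np.array(
        [[np.nan if d is None else float(d) for d in row] for row in dosages], dtype=float
    )
    n, p = arr.shape
    return GenotypeMatrix(
        sample_ids=[f"s{i}" for i in range(n)],
        variant_ids=variant_ids or [f"v{j}" for j in range(p)],
        dosages=arr,
        labels=np.array(labels if labels is not None else ["unknown"] * n, dtype=object),
    )
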