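import numpy as np
import pandas as pd
import pytest

from symprof import simulate as sim
from symprof.community import ASVTable
from symprof.coverage import per_base_depth
from symprof.io import AlignmentRecord


@pytest.fixture(scope="session")
def small_bundle():
    """A 30-gene reference with 4 planted lineage-specific genes."""
    reference, genes, truth = sim.simulate_reference(
        n_genes=30, n_specific=4, gene_length=120, intergenic_length=20, seed=11
    )
    return reference, genes, truth


@pytest.fixture
def worked_profile():
    """Two 50M reads at positions 0 and 25 on a 100 bp reference.

    Depth is 1 on [0,25), 2 on [25,50), 1 on [50,75), 0 on [75,100).
    """
    records = [
        AlignmentRecord("r1", "ref", 0, ((50, "M"),)),
        AlignmentRecord("r2", "ref", 25, ((50, "M"),)),
    ]
    return per_base_depth(records, 100)


@pytest.fixture
def tiny_asv_table():
    counts = pd.DataFrame(
        {
            "ASV_a": [50, 10, 0],
            "ASV_b": [30, 0, 999],
            "ASV_c": [20, 990, 1],
        },
        index=["s1", "s2", "s3"],
    )
    taxonomy = pd.Series(
        {
            "ASV_a": "Bacteria;Pseudomonadota;Gammaproteobacteria",
            "ASV_b": "Bacteria;Cyanobacteria;Chloroplast",
            "ASV_c": "unclassified",
        }
    )
    metadata = pd.DataFrame(
        {
            "site": ["x", "x", "y"],
            "date": ["2023-05-10"] * 3,
            "compartment": ["gill"] * 3,
        },
        index=pd.Index(["s1", "s2", "s3"], name="sample_id"),
    )
    return ASVTable(counts=counts, taxonomy=taxonomy, metadata=metadata)
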