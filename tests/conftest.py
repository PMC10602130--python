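import numpy as np
import pandas as pd
import pytest

from feiscan.io import CohortTable, GenotypeMatrix, MutationTable


@pytest.fixture
def small_genotypes() -> GenotypeMatrix:
    """3 subjects x 2 markers, fully typed."""
    markers = pd.DataFrame(
        {
            "id": ["rs1", "rs2"],
            "chrom": ["1", "1"],
            "pos": [100, 200],
            "counted_allele": ["A", "C"],
            "other_allele": ["G", "T"],
            "gene": [pd.NA, pd.NA],
        }
    )
    return GenotypeMatrix(
        subject_ids=np.array(["s1", "s2", "s3"], dtype=object),
        dosages=np.array([[0, 1], [1, 2], [2, 0]], dtype=np.int8),
        markers=markers,
    )


@pytest.fixture
def small_cohort() -> CohortTable:
    return CohortTable(
        pd.DataFrame(
            {
                "subject_id": ["s1", "s2", "s3", "s4"],
                "baseline_status": [1, 0, 0, 1],
                "race": ["BA", "BA", "WE", "WE"],
            }
        )
    )


@pytest.fixture
def small_mutations() -> MutationTable:
    return MutationTable(
        pd.DataFrame(
            {
                "subject_id": ["s1", "s2", "s3", "s4"],
                "category": ["intron22_inv", "intron22_inv", "missense", "not_identified"],
                "allele_id": ["I22INV", "I22INV", "p.R1966Q", "NI_s4"],
            }
        )
    )
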