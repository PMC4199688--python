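import numpy as np
import pandas as pd
import pytest

from tetrasnp import load_pho1a_haplotypes
from tetrasnp.genotyping import DosageMatrix


@pytest.fixture(scope="session")
def pho1a():
    """The bundled 15-SNP x 9-variant PHO1a cDNA haplotype matrix."""
    return load_pho1a_haplotypes()


@pytest.fixture()
def small_matrix():
    """A 6-individual, 3-marker dosage matrix with one missing call."""
    values = pd.DataFrame(
        {
            "GWD-A_3452_G": [0, 1, 2, 0, 0, 1],
            "PWD-T_10547_C": [4, 3, 2, 4, np.nan, 2],
            "BMY1-G_2533_A": [0, 0, 0, 0, 0, 0],
        },
        index=[f"ind{i}" for i in range(1, 7)],
    )
    return DosageMatrix(values)
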