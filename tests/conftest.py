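import numpy as np
import pandas as pd
import pytest

from trnadapt.reference import TRNAGene


@pytest.fixture
def phe_only_pool():
    """A tRNA pool containing only the Phe GAA anticodon."""
    return {"GAA": 100.0}


@pytest.fixture
def toy_counts():
    """6-feature, 2-sample count table with a genuine composition shift."""
    return pd.DataFrame(
        {
            "s1": [100, 200, 300, 50, 1000, 10],
            "s2": [150, 380, 290, 120, 1800, 40],
        },
        index=[f"f{i}" for i in range(6)],
    )


@pytest.fixture
def small_gene_set():
    """Six synthetic tRNA genes, three sharing one mature sequence."""
    seqs = {
        "tRNA-Ser-TGA-1-1": "GCATTGGTGGTTCAGTGGTAGAATTCTCGC",
        "tRNA-Ser-TGA-1-2": "GCATTGGTGGTTCAGTGGTAGAATTCTCGC",
        "tRNA-Ser-TGA-1-3": "GCATTGGTGGTTCAGTGGTAGAATTCTCGC",
        "tRNA-Ser-TGA-2-1": "GCATTGGTGGTTCAGTGGTAGAATTCTCGA",
        "tRNA-Gly-GCC-1-1": "GCGCCGCTGGTGTAGTGGTATCATGCAAGA",
        "tRNA-Gly-CCC-1-1": "GCGTTGGTGGTATAGTGGTGAGCATAGCTG",
    }
    return [
        TRNAGene(
            gene_id=g,
            amino_acid=g.split("-")[1],
            anticodon=g.split("-")[2],
            mature_sequence=s,
        )
        for g, s in seqs.items()
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
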