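import numpy as np
import pandas as pd
import pytest

import breadtrial as bt


@pytest.fixture
def tiny_pheno() -> bt.PhenotypeTable:
    """2 genotypes x 2 years x 2 reps, genotype signal only."""
    rows = []
    for geno, val in (("G1", 1.0), ("G2", 3.0)):
        for year in ("Y1", "Y2"):
            for rep in ("R1", "R2"):
                rows.append((geno, year, rep, "t", val))
    return bt.PhenotypeTable(pd.DataFrame(
        rows, columns=["genotype", "year", "rep", "trait", "value"]))


@pytest.fixture
def toy_genotypes() -> bt.GenotypeMatrix:
    # doses count the major allele (canonical coding assumed by the writers)
    calls = np.array([
        [0, 2, 1, 2],
        [2, 2, 0, 1],
        [1, 0, 2, np.nan],
        [0, 2, 2, 2],
        [2, 0, 0, 0],
    ], dtype=float)
    markers = pd.DataFrame({
        "name": ["S1A_100", "S1A_200", "S2B_50", "S2B_900"],
        "chromosome": ["1A", "1A", "2B", "2B"],
        "position": [100, 200, 50, 900],
    })
    return bt.GenotypeMatrix(
        line_ids=[f"L{i}" for i in range(1, 6)],
        markers=markers, calls=calls,
        counted_allele=[("A", "G"), ("C", "T"), ("G", "A"), ("T", "C")])


@pytest.fixture
def toy_areas() -> bt.FractionAreaTable:
    df = pd.DataFrame(
        {
            "E_F1": [2.0, 3.0], "E_F2": [1.0, 2.0],
            "E_F3": [3.0, 5.0], "E_F4": [2.0, 1.0],
            "U_F1": [2.0, 2.0], "U_F2": [1.0, 1.0],
            "U_F3": [1.0, 1.0], "U_F4": [0.0, 1.0],
        },
        index=pd.Index(["s1", "s2"], name="sample"),
    )
    return bt.FractionAreaTable(df)
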