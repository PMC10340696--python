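"""Reference summary statistics shipped with the package.

``quality_trait_mean_squares`` returns the published per-trait ANOVA
summary of a two-year bread-quality evaluation of 76 genotyped soft red
winter wheat breeding lines (one location, harvest years 2020 and 2021):
entry-mean range and mean plus the year, genotype, genotype-x-year and
error mean squares.  Sensory traits (1-7 scales) were scored by a panel
of evaluators acting as the within-year replications; loaf measurements,
dough extensibility, flour protein and the SE-HPLC composition traits
were unreplicated within year, so their genotype-x-year term is
confounded with error and the corresponding cell is absent (NaN).

These mean squares are the inputs from which the trial's broad-sense
heritabilities are recomputed: the MS-ratio estimator where a
genotype-x-year mean square exists, and the year-as-replicate
variance-component estimator otherwise.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

N_GENOTYPES = 76
N_YEARS = 2

_ROWS = [
    # trait, units, entry min, entry max, entry mean,
    #   MS year, MS genotype, MS gxy, MS error
    ("Aroma", "1-7", 3.10, 5.20, 4.0, 4.72, 1.57, 1.23, 1.24),
    ("Flavor", "1-7", 3.10, 5.20, 4.0, 10.47, 1.75, 1.06, 1.28),
    ("Texture: Crumb", "1-7", 2.70, 5.10, 3.70, 7.04, 2.47, 1.11, 1.17),
    ("Texture: Crust", "1-7", 3.20, 5.10, 4.10, 1.58, 2.17, 1.13, 1.07),
    ("Grain Protein Concentration", "%", 9.12, 14.64, 11.27,
     12.43, 1.67, 1.19, 0.09),
    ("Kernel Hardness", "%", 7.32, 31.12, 19.36, 40.22, 30.20, 24.02, 2.72),
    ("SDS Sedimentation Volume", "cm3", 4.75, 15.25, 9.25,
     1548.39, 5.71, 2.69, 0.17),
    ("Loaf Volume", "cm3", 400, 625, 502, 3517.66, 1875.86, np.nan, 602.08),
    ("Loaf Density", "g/cm3", 0.41, 0.74, 0.53,
     6.15e-7, 0.0021, np.nan, 0.002),
    ("Loaf Height", "cm", 5.4, 8.9, 6.9, 2.73, 0.33, np.nan, 0.20),
    ("Dough extensibility score", "1-7", 1.00, 7.00, 3.30,
     35.03, 3.31, np.nan, 2.15),
    ("Flour Protein Concentration", "%", 8.28, 15.07, 10.87,
     np.nan, 0.93, np.nan, 0.76),
    ("T_HMW-GS", "A%", 21.33, 31.59, 26.46, np.nan, 5.18, np.nan, 0.79),
    ("T_LMW-GS", "A%", 10.21, 16.03, 13.06, np.nan, 0.98, np.nan, 0.18),
    ("T_Gli", "A%", 35.35, 45.14, 39.34, np.nan, 5.85, np.nan, 1.18),
    ("T_HMW:LMW", "-", 1.50, 2.44, 2.04, np.nan, 0.02, np.nan, 0.01),
    ("T_Gli:Glu", "-", 0.79, 1.36, 1.00, np.nan, 0.02, np.nan, 0.002),
    ("UPP:TPP", "-", 0.34, 0.59, 0.47, np.nan, 0.002, np.nan, 0.001),
]

_COLUMNS = ["trait", "units", "entry_min", "entry_max", "entry_mean",
            "ms_year", "ms_genotype", "ms_gxy", "ms_error"]


def quality_trait_mean_squares() -> pd.DataFrame:
    """Published trial summary: one row per quality trait (see module docs)."""
    return pd.DataFrame(_ROWS, columns=_COLUMNS)
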