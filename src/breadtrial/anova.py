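"""Trial ANOVA: sequential decomposition of the genotype-by-year model.

For a trait observed over years i, replications (evaluators) j within
year, and genotypes k, the model is

    y_ijk = mu + year_i + rep_j(i) + genotype_k + (genotype x year)_ik + e_ijk

fitted by least squares with sequential (Type I) sums of squares in that
fixed term order.  For balanced complete data this equals the textbook
two-way decomposition (and Type I = Type III).  When no within-year
replication exists -- one observation per genotype-year, as for loaf
volume -- the model reduces to year + genotype, and the interaction is
confounded with error.

F statistics and p-values for every term are computed against the error
mean square; the genotype and genotype-x-year mean squares feed the
heritability estimators downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import PhenotypeTable

FULL_TERMS = ["year", "rep_within_year", "genotype", "genotype_x_year"]
REDUCED_TERMS = ["year", "genotype"]


@dataclass
class AnovaTable:
    """Per-term df/SS/MS table for one trait.

    ``terms`` has one row per model term plus "error", with columns
    df, ss, ms, F, p (F/p are NaN for the error row).  ``reduced`` flags
    the no-replication model in which genotype-x-year is confounded with
    error.
    """

    trait: str
    terms: pd.DataFrame
    grand_mean: float
    n_obs: int
    reduced: bool
    n_genotypes: int
    n_years: int

    def __getitem__(self, term: str) -> pd.Series:
        return self.terms.loc[term]

    def ms(self, term: str) -> float:
        return float(self.terms.loc[term, "ms"])

    def df(self, term: str) -> int:
        return int(self.terms.loc[term, "df"])

    def to_frame(self) -> pd.DataFrame:
        out = self.terms.reset_index(names="term")
        out.insert(0, "trait", self.trait)
        return out


def _dummies(codes: pd.Series) -> np.ndarray:
    return pd.get_dummies(codes.astype(str)).to_numpy(dtype=float)


def _rss_rank(X: np.ndarray, y: np.ndarray) -> tuple[float, int]:
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r), int(rank)


def fit_anova(pheno: PhenotypeTable, trait: str,
              require_balanced: bool = False) -> AnovaTable:
    """Fit the genotype-by-year model for one trait.

    Genotypes observed in only one year are excluded with a warning (their
    interaction term would be confounded).  With ``require_balanced`` the
    fit refuses unequal replication counts instead of falling back on the
    general least-squares decomposition.
    """
    d = pheno.subset(trait)
    if d["genotype"].nunique() < 2:
        raise ValueError(f"trait {trait!r}: need >= 2 genotypes")
    if d["year"].nunique() < 2:
        raise ValueError(f"trait {trait!r}: need >= 2 years")

    years_per_geno = d.groupby("genotype")["year"].nunique()
    dropped = years_per_geno.index[years_per_geno < 2]
    if len(dropped) > 0:
        warnings.warn(
            f"trait {trait!r}: excluding {len(dropped)} genotype(s) observed "
            f"in a single year: {list(dropped[:5])}")
        d = d[~d["genotype"].isin(dropped)]
        if d["genotype"].nunique() < 2:
            raise ValueError(f"trait {trait!r}: fewer than 2 genotypes left")
    n_years = d["year"].nunique()

    cell_counts = d.groupby(["genotype", "year"])["value"].size()
    replicated = cell_counts.max() > 1
    if require_balanced and cell_counts.nunique() > 1:
        raise ValueError(
            f"trait {trait!r}: unbalanced replication "
            f"({sorted(cell_counts.unique())} observations per cell)")

    y = d["value"].to_numpy(dtype=float)
    n = len(y)
    blocks: dict[str, np.ndarray] = {"year": _dummies(d["year"])}
    if replicated:
        term_names = FULL_TERMS
        blocks["rep_within_year"] = _dummies(d["year"] + "/" + d["rep"])
        blocks["genotype"] = _dummies(d["genotype"])
        blocks["genotype_x_year"] = _dummies(d["genotype"] + "/" + d["year"])
    else:
        term_names = REDUCED_TERMS
        blocks["genotype"] = _dummies(d["genotype"])

    X = np.ones((n, 1))
    rss_prev, rank_prev = _rss_rank(X, y)
    ss_total = rss_prev
    rows = []
    for term in term_names:
        X = np.hstack([X, blocks[term]])
        rss, rank = _rss_rank(X, y)
        rows.append((term, rank - rank_prev, max(rss_prev - rss, 0.0)))
        rss_prev, rank_prev = rss, rank
    df_error = n - rank_prev
    rows.append(("error", df_error, rss_prev))

    terms = pd.DataFrame(rows, columns=["term", "df", "ss"]).set_index("term")
    with np.errstate(invalid="ignore", divide="ignore"):
        terms["ms"] = terms["ss"] / terms["df"]
    ms_error = terms.loc["error", "ms"]
    terms["F"] = np.nan
    terms["p"] = np.nan
    if df_error > 0 and ms_error > 0:
        for term in term_names:
            F = terms.loc[term, "ms"] / ms_error
            terms.loc[term, "F"] = F
            terms.loc[term, "p"] = stats.f.sf(F, terms.loc[term, "df"],
                                              df_error)

    assert abs(terms["ss"].sum() - ss_total) <= 1e-9 * max(ss_total, 1.0), \
        "sequential SS do not add to the corrected total"
    return AnovaTable(
        trait=trait,
        terms=terms,
        grand_mean=float(y.mean()),
        n_obs=n,
        reduced=not replicated,
        n_genotypes=d["genotype"].nunique(),
        n_years=n_years,
    )


def entry_means(pheno: PhenotypeTable, trait: str) -> pd.DataFrame:
    """Per-genotype year means and their across-year average.

    Returns a DataFrame indexed by genotype with one column per year, a
    "mean" column (average of the available year means) and a "complete"
    flag that is False when a genotype is missing a year.
    """
    d = pheno.subset(trait)
    by_year = (d.groupby(["genotype", "year"])["value"].mean()
               .unstack("year"))
    out = by_year.copy()
    out["mean"] = by_year.mean(axis=1)
    out["complete"] = by_year.notna().all(axis=1)
    return out


@dataclass
class BlupTable:
    """Genotype entry means shrunk toward the grand mean.

    Shrinkage factor k = sg2 / (sg2 + se2 / r) with r the number of
    (year-)replicates behind each entry mean; k is clamped to [0, 1].
    """

    trait: str
    k: float
    grand_mean: float
    values: pd.DataFrame  # columns: entry_mean, blup


def compute_blups(pheno: PhenotypeTable, trait: str, vc) -> BlupTable:
    """Shrink entry means toward the grand mean by the heritability ratio.

    ``vc`` is a :class:`~breadtrial.heritability.VarianceComponents`; with
    sg2 + se2/r = 0 every BLUP collapses to the grand mean.
    """
    if vc.r < 1:
        raise ValueError("vc.r must be >= 1")
    em = entry_means(pheno, trait)["mean"]
    mu = float(pheno.subset(trait)["value"].mean())
    denom = vc.sigma_g2 + vc.sigma_e2 / vc.r
    k = 0.0 if denom <= 0 else float(np.clip(vc.sigma_g2 / denom, 0.0, 1.0))
    blup = mu + k * (em - mu)
    values = pd.DataFrame({"entry_mean": em, "blup": blup})
    return BlupTable(trait=trait, k=k, grand_mean=mu, values=values)
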