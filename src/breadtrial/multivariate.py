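"""Trait correlations, PCA on scaled traits, and principal-component
regression (PCR) of a response trait.

Inputs are entry-mean tables: rows are genotypes (or genotype-year
combinations), columns are traits.  Correlations are pairwise-complete
Pearson with t-distribution p-values; significance stars follow the
trial-report convention (* < 0.1, ** < 0.05, *** < 0.001), with no
multiplicity correction.  PCA operates on centered (optionally
unit-scaled) columns via SVD, with a deterministic sign convention; PCR is
ordinary least squares of the response on the first k component scores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

STAR_LEVELS = ((0.001, "***"), (0.05, "**"), (0.1, "*"))


@dataclass
class CorrelationMatrix:
    r: pd.DataFrame
    p: pd.DataFrame
    n: pd.DataFrame

    def stars(self) -> pd.DataFrame:
        """Significance markers mirroring the report legend."""
        def mark(p):
            if np.isnan(p):
                return ""
            for cut, sym in STAR_LEVELS:
                if p < cut:
                    return sym
            return "ns"
        return self.p.map(mark)


def correlation_matrix(entry_means: pd.DataFrame) -> CorrelationMatrix:
    """Pairwise-complete Pearson correlations between trait columns.

    Traits with zero variance on a pair's complete cases get NaN r/p for
    that pair.  Requires >= 3 complete rows per pair.
    """
    traits = list(entry_means.columns)
    k = len(traits)
    r = np.eye(k)
    p = np.zeros((k, k))
    n = np.full((k, k), len(entry_means))
    for i in range(k):
        n[i, i] = entry_means[traits[i]].notna().sum()
        for j in range(i + 1, k):
            sub = entry_means[[traits[i], traits[j]]].dropna()
            n[i, j] = n[j, i] = len(sub)
            if len(sub) < 3:
                raise ValueError(
                    f"fewer than 3 complete rows for pair "
                    f"({traits[i]!r}, {traits[j]!r})")
            x, y = sub.iloc[:, 0], sub.iloc[:, 1]
            if x.std() == 0 or y.std() == 0:
                r[i, j] = r[j, i] = np.nan
                p[i, j] = p[j, i] = np.nan
                continue
            res = stats.pearsonr(x, y)
            r[i, j] = r[j, i] = res.statistic
            p[i, j] = p[j, i] = res.pvalue
    idx = pd.Index(traits)
    return CorrelationMatrix(
        r=pd.DataFrame(r, index=idx, columns=idx),
        p=pd.DataFrame(p, index=idx, columns=idx),
        n=pd.DataFrame(n, index=idx, columns=idx),
    )


@dataclass
class PcaModel:
    loadings: pd.DataFrame          # traits x components
    scores: pd.DataFrame            # rows x components
    explained: pd.Series            # variance fractions, sum to 1
    center: pd.Series
    scale: pd.Series | None


def pca(entry_means: pd.DataFrame, scale: bool = True,
        missing: str = "impute") -> PcaModel:
    """PCA of an entry-means table via SVD of the centered(/scaled) data.

    ``missing``: "impute" replaces sporadic missing cells by the trait
    mean; "drop" removes incomplete rows.  Components are ordered by
    decreasing explained variance; each loading column's
    largest-magnitude entry is made positive so signs are deterministic.
    """
    X = entry_means.astype(float)
    if X.isna().all().any():
        bad = list(X.columns[X.isna().all()])
        raise ValueError(f"all-missing trait columns: {bad}")
    if missing == "impute":
        X = X.fillna(X.mean())
    elif missing == "drop":
        X = X.dropna()
    else:
        raise ValueError("missing must be 'impute' or 'drop'")
    if len(X) < 2:
        raise ValueError("need >= 2 rows for PCA")

    center = X.mean()
    Z = X - center
    if scale:
        sd = X.std(ddof=1).replace(0.0, 1.0)
        Z = Z / sd
    else:
        sd = None
    M = Z.to_numpy()
    U, S, Vt = np.linalg.svd(M, full_matrices=False)
    ncomp = min(len(X) - 1, X.shape[1])
    U, S, Vt = U[:, :ncomp], S[:ncomp], Vt[:ncomp]
    # deterministic sign: largest-|loading| entry of each component positive
    flip = np.sign(Vt[np.arange(ncomp), np.argmax(np.abs(Vt), axis=1)])
    flip[flip == 0] = 1.0
    Vt = Vt * flip[:, None]
    U = U * flip[None, :]
    comp_names = [f"PC{i + 1}" for i in range(ncomp)]
    var = S**2 / (len(X) - 1)
    total_var = (M**2).sum() / (len(X) - 1)
    explained = pd.Series(var / total_var, index=comp_names)
    return PcaModel(
        loadings=pd.DataFrame(Vt.T, index=X.columns, columns=comp_names),
        scores=pd.DataFrame(U * S, index=X.index, columns=comp_names),
        explained=explained,
        center=center,
        scale=sd,
    )


def n_components_for(model: PcaModel, cumvar: float) -> int:
    """Smallest k whose components reach the cumulative-variance target."""
    csum = model.explained.cumsum()
    k = int(np.searchsorted(csum.to_numpy(), cumvar) + 1)
    return min(k, len(csum))


@dataclass
class PcrModel:
    k: int
    intercept: float
    coef: pd.Series
    r2: float
    fitted: pd.Series


def pcr_fit(model: PcaModel, response: pd.Series, k: int = 6) -> PcrModel:
    """OLS of a response on the first k principal-component scores.

    The response must be aligned to the score rows; predictions and R2 are
    invariant to the PCA sign convention.
    """
    if not 1 <= k <= model.scores.shape[1]:
        raise ValueError(
            f"k must be in [1, {model.scores.shape[1]}], got {k}")
    y = response.reindex(model.scores.index)
    if y.isna().any():
        missing = list(y.index[y.isna()])[:5]
        raise ValueError(f"response missing for rows {missing}")
    Xk = model.scores.iloc[:, :k]
    fit = sm.OLS(y.to_numpy(), sm.add_constant(Xk.to_numpy())).fit()
    return PcrModel(
        k=k,
        intercept=float(fit.params[0]),
        coef=pd.Series(fit.params[1:], index=Xk.columns),
        r2=float(fit.rsquared),
        fitted=pd.Series(fit.fittedvalues, index=Xk.index),
    )
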