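"""Single-marker association scan with QC filters, FDR control and a
multi-environment/model consensus rule.

The scan follows the fixed-effect GLM tradition of association tools for
inbred crop panels: for each marker, the trait (an entry-mean or BLUP
vector, one value per line) is regressed on an intercept, the leading
principal components of the filtered genotype matrix (population-structure
covariates) and the allele dose; the two-sided t-test on the dose
coefficient gives the raw p-value.

Markers are first filtered on missingness (<= 50%), minor allele
frequency (>= 5%) and per-marker heterozygosity (<= 10%).  Two
significance gates apply conjunctively by default: raw p at most 1/n
(n = markers scanned) and Benjamini-Hochberg adjusted p below 0.1, plus a
minimum absolute effect size expressed as a percentage of the trait mean.
A marker becomes a consensus hit only when its supporting results span at
least two environments or at least two scan models; result tables from
external tools (e.g. multi-locus models) can join the consensus on equal
terms as long as they share the schema.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import GenotypeMatrix

RESULT_COLUMNS = ["marker", "chromosome", "position", "environment", "model",
                  "n_used", "effect", "effect_pct", "p", "p_adj"]


def marker_qc(genos: GenotypeMatrix) -> pd.DataFrame:
    """Per-marker missing fraction, MAF and heterozygosity.

    MAF and het fraction are computed on non-missing calls; a marker with
    no calls at all gets NaN stats.
    """
    calls = genos.calls
    n = calls.shape[0]
    n_obs = np.sum(~np.isnan(calls), axis=0)
    missing = 1.0 - n_obs / n
    with np.errstate(invalid="ignore"):
        freq = np.nansum(calls, axis=0) / (2 * np.where(n_obs > 0, n_obs, 1))
        freq[n_obs == 0] = np.nan
        maf = np.minimum(freq, 1.0 - freq)
        het = np.nansum(calls == 1.0, axis=0) / np.where(n_obs > 0, n_obs, 1)
        het = np.where(n_obs > 0, het, np.nan)
    return pd.DataFrame({
        "marker": genos.marker_names,
        "missing_frac": missing,
        "maf": maf,
        "het_frac": het,
    })


def filter_markers(genos: GenotypeMatrix,
                   max_missing: float = 0.5,
                   min_maf: float = 0.05,
                   max_het: float = 0.10
                   ) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Apply the three marker QC filters; returns (filtered, report).

    A marker is retained iff missing <= max_missing AND maf >= min_maf
    AND het <= max_het.  The report lists every marker with its stats,
    pass flag and comma-joined failure reasons.
    """
    for name, thr in (("max_missing", max_missing), ("min_maf", min_maf),
                      ("max_het", max_het)):
        if not 0.0 <= thr <= 1.0:
            raise ValueError(f"{name} must be in [0, 1]")
    report = marker_qc(genos)
    reasons = []
    for _, row in report.iterrows():
        why = []
        if not row["missing_frac"] <= max_missing:
            why.append("missing")
        if not row["maf"] >= min_maf:  # NaN maf fails too
            why.append("maf")
        if not row["het_frac"] <= max_het:
            why.append("het")
        reasons.append(",".join(why))
    report["reason"] = reasons
    report["pass"] = report["reason"] == ""
    keep = report["pass"].to_numpy()
    if not keep.any():
        raise ValueError("no markers survive QC filtering")
    return genos.subset_markers(keep), report


def genotype_pcs(genos: GenotypeMatrix, n_pcs: int) -> np.ndarray:
    """Leading PCs of the mean-imputed, centered dose matrix (lines x PCs)."""
    if n_pcs == 0:
        return np.empty((genos.n_lines, 0))
    X = genos.calls.copy()
    col_mean = np.nanmean(X, axis=0)
    nan_r, nan_c = np.where(np.isnan(X))
    X[nan_r, nan_c] = col_mean[nan_c]
    X -= X.mean(axis=0)
    U, S, _ = np.linalg.svd(X, full_matrices=False)
    return U[:, :n_pcs] * S[:n_pcs]


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def glm_scan(genos: GenotypeMatrix,
             trait_values: pd.Series,
             n_pcs: int = 3,
             environment: str = "ENV3",
             model: str = "GLM") -> pd.DataFrame:
    """Per-marker GLM association scan for one environment.

    ``trait_values`` is indexed by line id (one value per line).  Lines
    with a missing trait value or a missing dose at a marker are dropped
    pairwise; a marker with fewer than n_pcs + 3 complete lines is skipped
    (NaN row in the output, counted by the caller via ``p.isna()``).
    Effects are the dose coefficient in trait units; ``effect_pct`` is
    100 * effect / mean(trait).  ``p_adj`` is BH-adjusted within the scan.
    """
    if n_pcs < 0:
        raise ValueError("n_pcs must be >= 0")
    tv = trait_values.reindex(genos.line_ids)
    y_all = tv.to_numpy(dtype=float)
    trait_mean = np.nanmean(y_all)
    pcs = genotype_pcs(genos, n_pcs)
    have_trait = ~np.isnan(y_all)

    n_markers = genos.n_markers
    effect = np.full(n_markers, np.nan)
    pval = np.full(n_markers, np.nan)
    n_used = np.zeros(n_markers, dtype=int)
    min_n = n_pcs + 3
    for j in range(n_markers):
        dose = genos.calls[:, j]
        mask = have_trait & ~np.isnan(dose)
        m = int(mask.sum())
        n_used[j] = m
        if m < min_n:
            continue
        X = np.column_stack([np.ones(m), pcs[mask], dose[mask]])
        yj = y_all[mask]
        beta, _, rank, _ = np.linalg.lstsq(X, yj, rcond=None)
        resid = yj - X @ beta
        df = m - rank
        if df <= 0:
            continue
        sigma2 = resid @ resid / df
        XtX_inv = np.linalg.pinv(X.T @ X)
        se = np.sqrt(sigma2 * XtX_inv[-1, -1])
        if se == 0 or not np.isfinite(se):
            # dose constant after conditioning (or perfect fit): no test
            if np.allclose(resid, 0) and not np.allclose(X[:, -1], X[0, -1]):
                effect[j] = beta[-1]
                pval[j] = 0.0
            continue
        effect[j] = beta[-1]
        t = beta[-1] / se
        pval[j] = 2.0 * stats.t.sf(abs(t), df)

    ok = ~np.isnan(pval)
    p_adj = np.full(n_markers, np.nan)
    if ok.any():
        p_adj[ok] = bh_adjust(pval[ok])
    out = pd.DataFrame({
        "marker": genos.marker_names,
        "chromosome": genos.markers["chromosome"].to_numpy(),
        "position": genos.markers["position"].to_numpy(),
        "environment": environment,
        "model": model,
        "n_used": n_used,
        "effect": effect,
        "effect_pct": 100.0 * effect / trait_mean,
        "p": pval,
        "p_adj": p_adj,
    })
    return out[RESULT_COLUMNS]


def consensus_hits(results: pd.DataFrame,
                   min_support: int = 2,
                   fdr_threshold: float = 0.1,
                   raw_cutoff: float | None = None,
                   effect_min_pct: float = 0.1,
                   gates: str = "both") -> pd.DataFrame:
    """Markers supported by >= 2 environments or >= 2 models.

    ``results`` concatenates scan tables (own scans and/or imported
    external model results) sharing :data:`RESULT_COLUMNS` minus optional
    ones.  A row supports a marker when it passes the significance gates:
    with ``gates="both"`` (default) raw p <= raw_cutoff AND adjusted
    p < fdr_threshold; "raw" or "fdr" applies a single gate.  The default
    raw cutoff is 1/n with n the number of distinct markers scanned.
    Returns the supporting rows of hit markers with per-marker support
    counts attached.
    """
    dup = results.duplicated(subset=["marker", "environment", "model"])
    if dup.any():
        first = results.loc[dup, ["marker", "environment", "model"]].iloc[0]
        raise ValueError(f"duplicate result row: {first.to_dict()}")
    if raw_cutoff is None:
        raw_cutoff = 1.0 / results["marker"].nunique()

    sig = results["effect_pct"].abs() >= effect_min_pct
    if gates in ("both", "raw"):
        sig &= results["p"] <= raw_cutoff
    if gates in ("both", "fdr"):
        sig &= results["p_adj"] < fdr_threshold
    if gates not in ("both", "raw", "fdr"):
        raise ValueError("gates must be 'both', 'raw' or 'fdr'")
    supports = results[sig.fillna(False)].copy()

    def qualifies(grp: pd.DataFrame) -> bool:
        return (grp["environment"].nunique() >= min_support
                or grp["model"].nunique() >= min_support)

    keep = supports.groupby("marker").filter(qualifies)
    counts = keep.groupby("marker").agg(
        n_environments=("environment", "nunique"),
        n_models=("model", "nunique"),
        n_supports=("marker", "size"))
    return keep.merge(counts, on="marker").sort_values(
        ["marker", "environment", "model"]).reset_index(drop=True)


@dataclass
class AlleleGroupTest:
    """Welch t-test between the two homozygote classes at one marker."""

    marker: str
    means: dict[float, float]
    se: dict[float, float]
    n: dict[float, int]
    t: float
    p: float
    letters: dict[float, str]


def allele_group_ttest(genos: GenotypeMatrix,
                       trait_values: pd.Series,
                       marker_id: str,
                       alpha: float = 0.05) -> AlleleGroupTest:
    """Compare trait means of the two homozygote allelic forms.

    Heterozygotes are excluded; each class needs >= 2 lines, otherwise the
    test is refused.  Letter codes are "a"/"b" when the Welch p-value is
    below ``alpha`` and "a"/"a" otherwise.
    """
    j = genos.marker_index(marker_id)
    dose = genos.calls[:, j]
    y = trait_values.reindex(genos.line_ids).to_numpy(dtype=float)
    groups = {}
    for cls in (0.0, 2.0):
        vals = y[(dose == cls) & ~np.isnan(y)]
        if len(vals) < 2:
            raise ValueError(
                f"marker {marker_id!r}: homozygote class {int(cls)} has "
                f"{len(vals)} line(s); need >= 2")
        groups[cls] = vals
    res = stats.ttest_ind(groups[0.0], groups[2.0], equal_var=False)
    sig = res.pvalue < alpha
    return AlleleGroupTest(
        marker=marker_id,
        means={c: float(v.mean()) for c, v in groups.items()},
        se={c: float(v.std(ddof=1) / np.sqrt(len(v)))
            for c, v in groups.items()},
        n={c: len(v) for c, v in groups.items()},
        t=float(res.statistic),
        p=float(res.pvalue),
        letters={0.0: "a", 2.0: "b" if sig else "a"},
    )
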