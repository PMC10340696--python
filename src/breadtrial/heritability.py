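"""Broad-sense heritability from trial mean squares.

Two estimators are used, matching how breeding trials with and without
within-year replication are handled:

Mean-square ratio (replicated traits)
    h2 = 1 - MS_gxy / MS_g, with 90% confidence limits from the F
    distribution (Knapp-Stroup-Ross construction):

        UL = 1 - [ (MS_g / MS_gxy) * F_{1-a/2; df1, df2} ]^-1
        LL = 1 - [ (MS_g / MS_gxy) * F_{a/2;   df1, df2} ]^-1

    with df1 = g - 1 (genotype) and df2 = (g - 1)(y - 1) (interaction).
    Since F_{a/2} < 1 < F_{1-a/2} at matching dfs, the interval always
    brackets the point estimate.

Variance components with year as replicate (unreplicated traits)
    Method-of-moments extraction sg2 = (MS_g - MS_e) / r, se2 = MS_e,
    then h2 = sg2 / (sg2 + se2 / r), r being the number of years.

Point estimates from the ratio path may be negative when MS_gxy exceeds
MS_g; they are reported raw (a clamped display form is available) because
their confidence intervals legitimately cross zero.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy import stats

from .anova import AnovaTable


@dataclass
class MeanSquarePair:
    """Genotype and denominator mean squares with their dfs."""

    ms_genotype: float
    ms_gxy: float
    df1: int  # genotype df, g - 1
    df2: int  # denominator df, (g - 1)(y - 1)

    def __post_init__(self):
        if self.ms_genotype <= 0:
            raise ValueError("ms_genotype must be > 0")
        if self.ms_gxy < 0:
            raise ValueError("ms_gxy must be >= 0")
        if self.df1 < 1 or self.df2 < 1:
            raise ValueError("degrees of freedom must be >= 1")


@dataclass
class VarianceComponents:
    """Genotypic and error variance with the replicate count r."""

    sigma_g2: float
    sigma_e2: float
    r: int
    truncated: bool = False


@dataclass
class HeritabilityEstimate:
    trait: str
    method: str  # "ms_ratio" | "varcomp"
    h2: float
    ll: float | None = None
    ul: float | None = None
    alpha: float = 0.10
    df1: int | None = None
    df2: int | None = None
    truncated: bool = False

    def clamped(self) -> tuple[float, float | None, float | None]:
        """[0, 1]-clamped display form of (h2, LL, UL)."""
        clip = lambda v: None if v is None else min(max(v, 0.0), 1.0)
        return clip(self.h2), clip(self.ll), clip(self.ul)


def h2_ms(pair: MeanSquarePair, clamp: bool = False) -> float:
    """Mean-square-ratio heritability 1 - MS_gxy / MS_g."""
    h2 = 1.0 - pair.ms_gxy / pair.ms_genotype
    return max(h2, 0.0) if clamp else h2


def h2_ci(pair: MeanSquarePair, alpha: float = 0.10) -> tuple[float, float]:
    """F-based confidence limits for the mean-square-ratio estimator."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    ratio = pair.ms_genotype / pair.ms_gxy if pair.ms_gxy > 0 else float("inf")
    f_hi = stats.f.ppf(1.0 - alpha / 2.0, pair.df1, pair.df2)
    f_lo = stats.f.ppf(alpha / 2.0, pair.df1, pair.df2)
    ul = 1.0 - 1.0 / (ratio * f_hi)
    ll = 1.0 - 1.0 / (ratio * f_lo)
    return ll, ul


def varcomp_from_ms(ms_genotype: float, ms_error: float,
                    r: int) -> VarianceComponents:
    """Method-of-moments components: sg2 = (MS_g - MS_e)/r, se2 = MS_e.

    A negative genotypic variance is truncated at zero with the flag set.
    """
    if ms_genotype < 0 or ms_error < 0:
        raise ValueError("mean squares must be >= 0")
    if r < 1:
        raise ValueError("r must be >= 1")
    sigma_g2 = (ms_genotype - ms_error) / r
    truncated = sigma_g2 < 0
    return VarianceComponents(sigma_g2=max(sigma_g2, 0.0),
                              sigma_e2=ms_error, r=r, truncated=truncated)


def h2_vc(vc: VarianceComponents) -> float:
    """Variance-component heritability sg2 / (sg2 + se2 / r); in [0, 1]."""
    denom = vc.sigma_g2 + vc.sigma_e2 / vc.r
    if denom <= 0:
        raise ValueError("sigma_g2 + sigma_e2 / r must be > 0")
    return vc.sigma_g2 / denom


def estimate_from_anova(table: AnovaTable,
                        alpha: float = 0.10) -> HeritabilityEstimate:
    """Pick the estimator the trait's design supports.

    Replicated traits use the MS-ratio path with its F interval; traits
    without within-year replication (reduced model, interaction confounded
    with error) use the variance-component path with year as replicate.
    """
    if table.reduced:
        vc = varcomp_from_ms(table.ms("genotype"), table.ms("error"),
                             r=table.n_years)
        return HeritabilityEstimate(
            trait=table.trait, method="varcomp", h2=h2_vc(vc),
            truncated=vc.truncated)
    pair = MeanSquarePair(
        ms_genotype=table.ms("genotype"),
        ms_gxy=table.ms("genotype_x_year"),
        df1=table.df("genotype"),
        df2=table.df("genotype_x_year"),
    )
    ll, ul = h2_ci(pair, alpha)
    return HeritabilityEstimate(
        trait=table.trait, method="ms_ratio", h2=h2_ms(pair),
        ll=ll, ul=ul, alpha=alpha, df1=pair.df1, df2=pair.df2)
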