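"""Synthetic multi-year breeding-trial generator.

Emulates the data structure of a two-year wheat bread-quality trial: 76-ish
genotypes evaluated in 2 years, sensory traits scored 1-7 by a panel of
evaluators (the within-year replications), bench traits measured once per
genotype-year, and a genotyped panel of biallelic SNP markers with
missingness and residual heterozygosity.

The phenotype model is the random-effects reading of the trial ANOVA:

    y_ijkl = mu + a_i + r_j(i) + g_k + (ag)_ik + e_ijkl

with year (a), evaluator-within-year (r), genotype (g), genotype-x-year
(ag) and residual (e) effects each drawn once per index combination from a
zero-mean normal with the configured variance.  Genotype effects may be
drawn jointly across traits under a target genetic correlation matrix;
year, interaction and residual effects are independent across traits.
Sensory scales are emulated by clipping the latent value to the scale
bounds and rounding to the nearest unit, after effect summation.

Every simulation records its ground truth (variance components, implied
broad-sense heritabilities and planted QTL) in a :class:`TruthRecord` so
that recovery tests can compare estimates against the generating values.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .io import FractionAreaTable, GenotypeMatrix, PhenotypeTable


@dataclass
class TraitSpec:
    """Variance structure for one simulated trait.

    Variances are in squared trait units.  ``scale_bounds`` (lo, hi)
    switches on clip-then-round emulation of a bounded integer scale.
    """

    name: str
    mean: float
    var_genotype: float
    var_gxy: float = 0.0
    var_year: float = 0.0
    var_rep: float = 0.0
    var_error: float = 1.0
    scale_bounds: tuple[float, float] | None = None

    def __post_init__(self):
        for fld in ("var_genotype", "var_gxy", "var_year", "var_rep",
                    "var_error"):
            if getattr(self, fld) < 0:
                raise ValueError(f"{self.name}: {fld} must be >= 0")
        if self.scale_bounds is not None:
            lo, hi = self.scale_bounds
            if not lo < hi:
                raise ValueError(f"{self.name}: scale_bounds must satisfy lo < hi")


@dataclass
class SimConfig:
    """Full trial layout: genotypes x years x replications x traits.

    ``n_reps`` is either a single replication (evaluator) count used in
    every year or a per-year list, e.g. ``[4, 6]``.  ``trait_correlation``
    is the target genetic correlation matrix across traits (order of
    ``trait_specs``); it must be symmetric, unit-diagonal and positive
    semidefinite.
    """

    n_genotypes: int
    n_years: int
    n_reps: int | list[int]
    trait_specs: list[TraitSpec]
    trait_correlation: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self):
        if self.n_genotypes < 2:
            raise ValueError("n_genotypes must be >= 2")
        if self.n_years < 2:
            raise ValueError("n_years must be >= 2")
        if isinstance(self.n_reps, int):
            self.n_reps = [self.n_reps] * self.n_years
        if len(self.n_reps) != self.n_years:
            raise ValueError("n_reps list must have one entry per year")
        if any(r < 1 for r in self.n_reps):
            raise ValueError("replication counts must be >= 1")
        if not self.trait_specs:
            raise ValueError("at least one trait spec required")
        if self.trait_correlation is not None:
            R = np.asarray(self.trait_correlation, dtype=float)
            t = len(self.trait_specs)
            if R.shape != (t, t):
                raise ValueError(f"trait_correlation must be {t}x{t}")
            if not np.allclose(R, R.T, atol=1e-10):
                raise ValueError("trait_correlation must be symmetric")
            if not np.allclose(np.diag(R), 1.0, atol=1e-10):
                raise ValueError("trait_correlation must have unit diagonal")
            if np.linalg.eigvalsh(R).min() < -1e-10:
                raise ValueError("trait_correlation must be positive semidefinite")
            self.trait_correlation = R


@dataclass
class QtlSpec:
    """A planted additive QTL: ``additive_effect`` trait units per copy of
    the counted allele; ``effect_pct`` = 100 * |2 * additive_effect| / trait
    mean (the two-homozygote difference as a percentage of the mean)."""

    marker_id: str
    trait_name: str
    additive_effect: float | None = None
    effect_pct: float | None = None

    def resolve(self, trait_mean: float) -> "QtlSpec":
        """Fill whichever of effect/effect_pct is missing, given the mean."""
        a, pct = self.additive_effect, self.effect_pct
        if a is None and pct is None:
            raise ValueError(f"QTL {self.marker_id}: no effect given")
        if a is None:
            a = pct / 100.0 * trait_mean / 2.0
        if pct is None:
            pct = 100.0 * abs(2.0 * a) / trait_mean
        return QtlSpec(self.marker_id, self.trait_name, a, pct)


@dataclass
class TruthRecord:
    """Generating parameters of a simulated trial.

    ``h2_ms`` is the expectation of the mean-square-ratio estimator,
    r*y*sg2 / (se2 + r*sgy2 + r*y*sg2); ``h2_vc`` is the year-as-replicate
    variance-component heritability sg2 / (sg2 + (sgy2 + se2)/y), the
    applicable truth when there is no within-year replication.
    """

    seed: int
    variance_components: dict[str, dict[str, float]] = field(default_factory=dict)
    h2_ms: dict[str, float] = field(default_factory=dict)
    h2_vc: dict[str, float] = field(default_factory=dict)
    qtls: list[QtlSpec] = field(default_factory=list)

    def to_json(self, path) -> None:
        payload = asdict(self)
        text = json.dumps(payload, indent=2)
        if hasattr(path, "write"):
            path.write(text)
        else:
            with open(path, "w") as fh:
                fh.write(text)


def _truth_h2(spec: TraitSpec, n_years: int, mean_reps: float
              ) -> tuple[float, float]:
    sg, sgy, se = spec.var_genotype, spec.var_gxy, spec.var_error
    denom_ms = se + mean_reps * sgy + mean_reps * n_years * sg
    h2_ms = (mean_reps * n_years * sg / denom_ms) if denom_ms > 0 else 0.0
    denom_vc = sg + (sgy + se) / n_years
    h2_vc = sg / denom_vc if denom_vc > 0 else 0.0
    return h2_ms, h2_vc


def simulate_phenotypes(config: SimConfig) -> tuple[PhenotypeTable, TruthRecord]:
    """Draw one trial realisation under ``config``.

    Returns the long-format phenotype table (one record per genotype x
    year x rep x trait) and the matching truth record.  Deterministic for
    a fixed config and seed.
    """
    rng = np.random.default_rng(config.seed)
    g, y = config.n_genotypes, config.n_years
    t = len(config.trait_specs)
    genos = [f"G{k + 1:03d}" for k in range(g)]
    years = [f"Y{i + 1}" for i in range(y)]

    # genotype effects, jointly across traits on the genetic correlation
    sds = np.array([np.sqrt(s.var_genotype) for s in config.trait_specs])
    if config.trait_correlation is not None:
        cov = np.outer(sds, sds) * config.trait_correlation
        g_eff = rng.multivariate_normal(np.zeros(t), cov, size=g,
                                        method="svd")
    else:
        g_eff = rng.standard_normal((g, t)) * sds

    truth = TruthRecord(seed=config.seed)
    mean_reps = float(np.mean(config.n_reps))
    records = []
    for ti, spec in enumerate(config.trait_specs):
        year_eff = rng.normal(0.0, np.sqrt(spec.var_year), size=y)
        rep_eff = [rng.normal(0.0, np.sqrt(spec.var_rep), size=r)
                   for r in config.n_reps]
        gxy_eff = rng.normal(0.0, np.sqrt(spec.var_gxy), size=(g, y))
        for i in range(y):
            for j in range(config.n_reps[i]):
                resid = rng.normal(0.0, np.sqrt(spec.var_error), size=g)
                vals = (spec.mean + year_eff[i] + rep_eff[i][j]
                        + g_eff[:, ti] + gxy_eff[:, i] + resid)
                if spec.scale_bounds is not None:
                    lo, hi = spec.scale_bounds
                    vals = np.round(np.clip(vals, lo, hi))
                for k in range(g):
                    records.append((genos[k], years[i], f"R{j + 1}",
                                    spec.name, vals[k]))
        truth.variance_components[spec.name] = {
            "var_genotype": spec.var_genotype, "var_gxy": spec.var_gxy,
            "var_year": spec.var_year, "var_rep": spec.var_rep,
            "var_error": spec.var_error, "mean": spec.mean,
        }
        h2m, h2v = _truth_h2(spec, y, mean_reps)
        truth.h2_ms[spec.name] = h2m
        truth.h2_vc[spec.name] = h2v

    table = PhenotypeTable(pd.DataFrame(records, columns=[
        "genotype", "year", "rep", "trait", "value"]))
    return table, truth


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

_ALLELES = np.array(list("ACGT"))


def simulate_genotypes(n_lines: int,
                       n_markers: int,
                       maf_range: tuple[float, float] = (0.05, 0.5),
                       missing_rate: float | np.ndarray = 0.0,
                       het_rate: float | np.ndarray = 0.0,
                       map_spec: dict[str, int] | None = None,
                       seed: int = 0,
                       line_ids: list[str] | None = None) -> GenotypeMatrix:
    """Simulate a biallelic SNP panel with missingness and heterozygosity.

    Per marker, an allele frequency is drawn uniformly from ``maf_range``
    and doses are sampled so that the expected heterozygote fraction equals
    ``het_rate`` and the expected missing fraction equals ``missing_rate``
    (either may be a scalar or a per-marker array).  ``map_spec`` maps
    chromosome names to marker counts (default: all markers on "1A");
    positions are strictly increasing within each chromosome.  Markers are
    unlinked: no LD is simulated.
    """
    if n_markers < 1:
        raise ValueError("n_markers must be >= 1")
    lo, hi = maf_range
    if not (0.0 < lo <= hi <= 0.5):
        raise ValueError("maf_range must lie within (0, 0.5]")
    miss = np.broadcast_to(np.asarray(missing_rate, dtype=float),
                           (n_markers,)).copy()
    het = np.broadcast_to(np.asarray(het_rate, dtype=float), (n_markers,)).copy()
    if ((miss < 0) | (miss >= 1)).any() or ((het < 0) | (het >= 1)).any():
        raise ValueError("missing_rate and het_rate must be in [0, 1)")

    rng = np.random.default_rng(seed)
    if map_spec is None:
        map_spec = {"1A": n_markers}
    if sum(map_spec.values()) != n_markers:
        raise ValueError("map_spec marker counts must sum to n_markers")

    freq = rng.uniform(lo, hi, size=n_markers)
    # dose distribution with exact expected het fraction; requires
    # freq >= het/2 on both alleles, so cap het per marker where needed
    het = np.minimum(het, 2 * np.minimum(freq, 1 - freq))
    p2 = freq - het / 2.0       # P(dose 2)
    p1 = het                     # P(dose 1)
    u = rng.random((n_lines, n_markers))
    calls = np.where(u < p2, 2.0, np.where(u < p2 + p1, 1.0, 0.0))
    calls[rng.random((n_lines, n_markers)) < miss] = np.nan

    names, chroms, positions = [], [], []
    for chrom, count in map_spec.items():
        # strictly increasing positions via positive random gaps
        pos = np.cumsum(rng.integers(1, 200_000, size=count))
        for p in pos:
            names.append(f"S{chrom}_{p}")
            chroms.append(chrom)
            positions.append(int(p))

    pairs = []
    for _ in range(n_markers):
        a, b = rng.choice(4, size=2, replace=False)
        pairs.append((str(_ALLELES[a]), str(_ALLELES[b])))

    if line_ids is None:
        line_ids = [f"G{k + 1:03d}" for k in range(n_lines)]
    markers = pd.DataFrame({"name": names, "chromosome": chroms,
                            "position": positions})
    return GenotypeMatrix(line_ids=line_ids, markers=markers, calls=calls,
                          counted_allele=pairs)


def inject_qtl(genotypes: GenotypeMatrix,
               phenotypes: PhenotypeTable,
               qtls: list[QtlSpec],
               truth: TruthRecord | None = None) -> PhenotypeTable:
    """Add additive marker effects to a phenotype table.

    Each observation of the QTL's trait is incremented by
    ``(dose - mean dose) * additive_effect``; lines with a missing call at
    the marker contribute the population-mean dose (zero increment).  The
    operation is deterministic.  If a ``truth`` record is given, the
    resolved QTL specs are appended to it.
    """
    data = phenotypes.data.copy()
    line_pos = {lid: i for i, lid in enumerate(genotypes.line_ids)}
    for qtl in qtls:
        j = genotypes.marker_index(qtl.marker_id)  # KeyError if unknown
        trait_mask = data["trait"] == qtl.trait_name
        if not trait_mask.any():
            raise KeyError(f"trait {qtl.trait_name!r} not in phenotype table")
        trait_mean = data.loc[trait_mask, "value"].mean()
        resolved = qtl.resolve(trait_mean)
        doses = genotypes.calls[:, j]
        mean_dose = np.nanmean(doses)
        centered = np.where(np.isnan(doses), 0.0, doses - mean_dose)
        incr = data.loc[trait_mask, "genotype"].map(
            lambda gid: centered[line_pos[gid]] if gid in line_pos else 0.0)
        data.loc[trait_mask, "value"] += incr * resolved.additive_effect
        if truth is not None:
            truth.qtls.append(resolved)
    return PhenotypeTable(data)


def simulate_fraction_areas(n_samples: int,
                            seed: int = 0,
                            sample_ids: list[str] | None = None
                            ) -> FractionAreaTable:
    """Synthetic SE-HPLC fraction areas (artifact plumbing, not fit to any
    instrument): per-sample total absorbance with lognormal variation and
    Dirichlet-ish fraction shares typical of wheat flour extracts (gliadin
    the largest extractable fraction, HMW/LMW polymers dominating the
    unextractable one)."""
    rng = np.random.default_rng(seed)
    if sample_ids is None:
        sample_ids = [f"S{k + 1:03d}" for k in range(n_samples)]
    # mean shares of (F1, F2, F3, F4) within each fraction set
    e_share = np.array([0.18, 0.12, 0.45, 0.25])
    u_share = np.array([0.55, 0.30, 0.10, 0.05])
    rows = {}
    e_total = 900.0 * np.exp(rng.normal(0, 0.15, n_samples))
    u_total = 350.0 * np.exp(rng.normal(0, 0.25, n_samples))
    e_w = rng.dirichlet(e_share * 60.0, size=n_samples)
    u_w = rng.dirichlet(u_share * 60.0, size=n_samples)
    for i in range(1, 5):
        rows[f"E_F{i}"] = e_total * e_w[:, i - 1]
        rows[f"U_F{i}"] = u_total * u_w[:, i - 1]
    df = pd.DataFrame(rows, index=pd.Index(sample_ids, name="sample"))
    return FractionAreaTable(df)
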