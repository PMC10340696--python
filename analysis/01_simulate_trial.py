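#!/usr/bin/env python
"""Simulate one realisation of the two-year bread-quality trial.

Generates the three data layers the downstream analyses consume and writes
them under results/:

* sensory traits (aroma, flavor, crumb and crust texture) scored 1-7 by a
  panel of 4 evaluators in year 1 and 6 in year 2;
* a replicated bench trait (SDS sedimentation volume, duplicate
  evaluations per genotype-year) and unreplicated bench traits (loaf
  volume, dough extensibility) measured once per genotype-year;
* a 76-line panel of 2,000 biallelic SNPs spread over six wheat
  chromosomes, with 5% missing calls and 2% heterozygotes, carrying two
  planted loaf-volume QTL on chromosome 1D.

Variance components per trait are derived from the published trial's
mean-squares table by the method of moments, so the simulated trial has
the heritability structure of the real one; genetic correlations among
traits follow its correlation table.  Seeded and fully reproducible.
"""

from pathlib import Path

import numpy as np

import breadtrial as bt
from breadtrial.datasets import quality_trait_mean_squares

SEED = 20230706
RESULTS = Path(__file__).resolve().parents[1] / "results"

#: published-table rows backing each simulated trait (name in this study)
SENSORY = {"aroma": "Aroma", "flavor": "Flavor",
           "crumb": "Texture: Crumb", "crust": "Texture: Crust"}
BENCH = {"loaf_volume": "Loaf Volume",
         "dough_extensibility": "Dough extensibility score"}

#: genetic correlations (from the trial's entry-mean correlation table)
SENSORY_CORR = np.array([
    #  aroma flavor crumb crust
    [1.00, 0.40, 0.43, 0.35],
    [0.40, 1.00, 0.58, 0.40],
    [0.43, 0.58, 1.00, 0.66],
    [0.35, 0.40, 0.66, 1.00],
])
BENCH_CORR = np.array([
    # loaf_volume dough_extensibility sds_sedimentation
    [1.00, 0.54, 0.50],
    [0.54, 1.00, 0.60],
    [0.50, 0.60, 1.00],
])


def components_from_ms(row, r, y=2):
    """Method-of-moments variance components from a mean-squares row."""
    se2 = row["ms_error"]
    if np.isnan(row["ms_gxy"]):
        # unreplicated trait: gxy confounded with error
        return dict(var_genotype=max((row["ms_genotype"] - se2) / y, 0.0),
                    var_gxy=0.0, var_error=se2)
    sgy2 = max((row["ms_gxy"] - se2) / r, 0.0)
    sg2 = max((row["ms_genotype"] - row["ms_gxy"]) / (r * y), 0.0)
    return dict(var_genotype=sg2, var_gxy=sgy2, var_error=se2)


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    ms = quality_trait_mean_squares().set_index("trait")

    # sensory layer: panel of 4 evaluators in year 1, 6 in year 2
    sensory_specs = [
        bt.TraitSpec(name, ms.loc[src, "entry_mean"],
                     **components_from_ms(ms.loc[src], r=5),
                     var_year=0.05, scale_bounds=(1, 7))
        for name, src in SENSORY.items()
    ]
    sens_cfg = bt.SimConfig(76, 2, [4, 6], sensory_specs,
                            trait_correlation=SENSORY_CORR, seed=SEED)
    sens_pheno, sens_truth = bt.simulate_phenotypes(sens_cfg)

    # bench layer: loaf volume / extensibility once per genotype-year,
    # sedimentation volume with its gxy structure collapsed to the same
    # layout (duplicate bench evaluations are averaged before analysis)
    bench_specs = [
        bt.TraitSpec(name, ms.loc[src, "entry_mean"],
                     **components_from_ms(ms.loc[src], r=1), var_year=1.0)
        for name, src in BENCH.items()
    ]
    sds_row = ms.loc["SDS Sedimentation Volume"]
    bench_specs.append(bt.TraitSpec(
        "sds_sedimentation", sds_row["entry_mean"],
        var_genotype=max((sds_row["ms_genotype"] - sds_row["ms_gxy"]) / 4, 0),
        var_gxy=0.0,
        var_error=max((sds_row["ms_gxy"] - sds_row["ms_error"]) / 2, 0)
        + sds_row["ms_error"],
        var_year=2.0))
    bench_cfg = bt.SimConfig(76, 2, 1, bench_specs,
                             trait_correlation=BENCH_CORR, seed=SEED + 1)
    bench_pheno, bench_truth = bt.simulate_phenotypes(bench_cfg)

    # SNP panel with two planted loaf-volume QTL on 1D
    genos = bt.simulate_genotypes(
        76, 2000, maf_range=(0.05, 0.5), missing_rate=0.05, het_rate=0.02,
        map_spec={"1A": 350, "1B": 350, "1D": 300, "2B": 350, "5A": 300,
                  "6A": 350},
        seed=SEED + 2)
    qtl_markers = [m for m in genos.marker_names
                   if m.startswith("S1D_")][100:300:99]
    qtls = [bt.QtlSpec(qtl_markers[0], "loaf_volume", effect_pct=20.0),
            bt.QtlSpec(qtl_markers[1], "loaf_volume", effect_pct=10.0)]
    bench_pheno = bt.inject_qtl(genos, bench_pheno, qtls, bench_truth)

    sens_pheno.to_csv(RESULTS / "phenotypes_sensory.csv")
    bench_pheno.to_csv(RESULTS / "phenotypes_bench.csv")
    genos.to_numeric_csv(RESULTS / "genotypes.csv")
    genos.to_hapmap(RESULTS / "genotypes.hmp.txt")
    with open(RESULTS / "truth_sensory.json", "w") as fh:
        sens_truth.to_json(fh)
    with open(RESULTS / "truth_bench.json", "w") as fh:
        bench_truth.to_json(fh)

    print(f"sensory records : {len(sens_pheno)} "
          f"({len(sens_pheno.genotypes)} genotypes x 2 years x 4+6 evaluators)")
    print(f"bench records   : {len(bench_pheno)}")
    print(f"SNP panel       : {genos.n_lines} lines x {genos.n_markers} markers")
    print("planted QTL     :",
          ", ".join(f"{q.marker_id} ({q.effect_pct:.0f}% of loaf-volume mean)"
                    for q in bench_truth.qtls))
    print("true h2 (sensory, MS-ratio expectation):",
          {t: round(v, 2) for t, v in sens_truth.h2_ms.items()})
    print("true h2 (bench, year-as-replicate):",
          {t: round(v, 2) for t, v in bench_truth.h2_vc.items()})
    print(f"written under {RESULTS}/")


if __name__ == "__main__":
    main()
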