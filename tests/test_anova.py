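"""ANOVA engine checks against hand decompositions and an independent
least-squares oracle (statsmodels sequential anova_lm and an explicit
projection-matrix computation)."""

import numpy as np
import pandas as pd
import pytest
from statsmodels.formula.api import ols
from statsmodels.stats.anova import anova_lm

import breadtrial as bt
from breadtrial.heritability import VarianceComponents


TERM_MAP = {
    "C(year)": "year",
    "C(year):C(rep)": "rep_within_year",
    "C(genotype)": "genotype",
    "C(genotype):C(year)": "genotype_x_year",
    "Residual": "error",
}


def random_balanced_pheno(g, y, r, rng) -> bt.PhenotypeTable:
    rows = []
    for k in range(g):
        for i in range(y):
            for j in range(r):
                rows.append((f"G{k}", f"Y{i}", f"R{j}", "t",
                             rng.normal(10.0, 2.0)))
    return bt.PhenotypeTable(pd.DataFrame(
        rows, columns=["genotype", "year", "rep", "trait", "value"]))


def statsmodels_oracle(pheno: bt.PhenotypeTable) -> pd.DataFrame:
    """Sequential (Type I) ANOVA via statsmodels, renamed to our terms."""
    fit = ols("value ~ C(year) + C(year):C(rep) + C(genotype) "
              "+ C(genotype):C(year)", data=pheno.data).fit()
    tab = anova_lm(fit, typ=1)
    tab.index = [TERM_MAP[t] for t in tab.index]
    return tab


def projection_oracle(pheno: bt.PhenotypeTable) -> dict[str, float]:
    """Brute-force nested least squares via explicit hat matrices."""
    d = pheno.data
    y = d["value"].to_numpy()
    blocks = [
        np.ones((len(d), 1)),
        pd.get_dummies(d["year"]).to_numpy(float),
        pd.get_dummies(d["year"] + d["rep"]).to_numpy(float),
        pd.get_dummies(d["genotype"]).to_numpy(float),
        pd.get_dummies(d["genotype"] + d["year"]).to_numpy(float),
    ]
    names = ["intercept", "year", "rep_within_year", "genotype",
             "genotype_x_year"]
    ss = {}
    prev_rss = None
    for i in range(1, len(blocks) + 1):
        X = np.hstack(blocks[:i])
        H = X @ np.linalg.pinv(X)
        rss = float(y @ (np.eye(len(y)) - H) @ y)
        if prev_rss is not None:
            ss[names[i - 1]] = prev_rss - rss
        prev_rss = rss
    ss["error"] = prev_rss
    return ss


class TestFitAnova:
    def test_constant_data_zero_ss(self):
        rows = [(g, yr, r, "t", 7.0) for g in ("G1", "G2")
                for yr in ("Y1", "Y2") for r in ("R1", "R2")]
        pheno = bt.PhenotypeTable(pd.DataFrame(
            rows, columns=["genotype", "year", "rep", "trait", "value"]))
        at = bt.fit_anova(pheno, "t")
        assert at.grand_mean == 7.0
        assert (at.terms["ss"].abs() < 1e-20).all()

    def test_hand_decomposition_genotype_only_signal(self, tiny_pheno):
        at = bt.fit_anova(tiny_pheno, "t")
        assert at.terms.loc["genotype", "ss"] == pytest.approx(8.0)
        for term in ("year", "rep_within_year", "genotype_x_year", "error"):
            assert at.terms.loc[term, "ss"] == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("g,y,r", [(4, 3, 2), (6, 2, 3), (3, 2, 2)])
    def test_matches_both_oracles(self, g, y, r):
        pheno = random_balanced_pheno(g, y, r, np.random.default_rng(g * 100 + r))
        at = bt.fit_anova(pheno, "t")
        sm_tab = statsmodels_oracle(pheno)
        proj = projection_oracle(pheno)
        for term in at.terms.index:
            assert at.terms.loc[term, "ss"] == pytest.approx(
                sm_tab.loc[term, "sum_sq"], rel=1e-9, abs=1e-9)
            assert at.terms.loc[term, "df"] == sm_tab.loc[term, "df"]
            assert at.terms.loc[term, "ss"] == pytest.approx(
                proj[term], rel=1e-9, abs=1e-9)

    def test_df_and_ss_identities(self):
        pheno = random_balanced_pheno(5, 2, 3, np.random.default_rng(0))
        at = bt.fit_anova(pheno, "t")
        assert at.terms["df"].sum() == len(pheno) - 1
        y = pheno.data["value"]
        total = ((y - y.mean()) ** 2).sum()
        assert at.terms["ss"].sum() == pytest.approx(total, rel=1e-12)

    def test_row_order_invariance(self):
        pheno = random_balanced_pheno(4, 2, 2, np.random.default_rng(5))
        shuffled = bt.PhenotypeTable(
            pheno.data.sample(frac=1.0, random_state=1))
        a1 = bt.fit_anova(pheno, "t")
        a2 = bt.fit_anova(shuffled, "t")
        pd.testing.assert_frame_equal(a1.terms, a2.terms)

    def test_reduced_model_without_replication(self):
        pheno = random_balanced_pheno(6, 2, 1, np.random.default_rng(2))
        at = bt.fit_anova(pheno, "t")
        assert at.reduced
        assert list(at.terms.index) == ["year", "genotype", "error"]
        # interaction df confounded into error: (g-1)(y-1)
        assert at.terms.loc["error", "df"] == 5

    def test_single_year_genotype_excluded_with_warning(self):
        pheno = random_balanced_pheno(4, 2, 2, np.random.default_rng(3))
        extra = pd.DataFrame([("G9", "Y0", "R0", "t", 1.0)],
                             columns=["genotype", "year", "rep", "trait",
                                      "value"])
        pheno2 = bt.PhenotypeTable(pd.concat([pheno.data, extra]))
        with pytest.warns(UserWarning, match="single year"):
            at = bt.fit_anova(pheno2, "t")
        assert at.n_genotypes == 4

    def test_require_balanced_refuses_unequal_cells(self):
        pheno = random_balanced_pheno(4, 2, 2, np.random.default_rng(4))
        dropped = bt.PhenotypeTable(pheno.data.iloc[:-1])
        with pytest.raises(ValueError, match="unbalanced"):
            bt.fit_anova(dropped, "t", require_balanced=True)

    def test_expected_genotype_mean_square(self):
        # E[MS_g] = se2 + r*sgy2 + r*y*sg2 for the balanced random model
        spec = bt.TraitSpec("t", 0.0, var_genotype=1.0, var_gxy=0.5,
                            var_error=1.0)
        ms = []
        for s in range(400):
            cfg = bt.SimConfig(20, 2, 2, [spec], seed=s)
            pheno, _ = bt.simulate_phenotypes(cfg)
            ms.append(bt.fit_anova(pheno, "t").ms("genotype"))
        expected = 1.0 + 2 * 0.5 + 2 * 2 * 1.0
        se = np.std(ms, ddof=1) / np.sqrt(len(ms))
        assert abs(np.mean(ms) - expected) < 3 * se + 1e-9

    def test_absent_trait_rejected(self, tiny_pheno):
        with pytest.raises(KeyError):
            bt.fit_anova(tiny_pheno, "nope")


class TestEntryMeans:
    def test_across_year_mean(self):
        rows = [("G1", "Y1", "R1", "t", 4.0), ("G1", "Y2", "R1", "t", 6.0)]
        pheno = bt.PhenotypeTable(pd.DataFrame(
            rows, columns=["genotype", "year", "rep", "trait", "value"]))
        em = bt.entry_means(pheno, "t")
        assert em.loc["G1", "mean"] == 5.0

    def test_missing_year_flagged(self):
        rows = [("G1", "Y1", "R1", "t", 4.0), ("G1", "Y2", "R1", "t", 6.0),
                ("G2", "Y1", "R1", "t", 3.0)]
        pheno = bt.PhenotypeTable(pd.DataFrame(
            rows, columns=["genotype", "year", "rep", "trait", "value"]))
        em = bt.entry_means(pheno, "t")
        assert not em.loc["G2", "complete"]
        assert em.loc["G2", "mean"] == 3.0

    def test_balanced_equals_raw_mean(self):
        pheno = random_balanced_pheno(5, 3, 2, np.random.default_rng(6))
        em = bt.entry_means(pheno, "t")
        raw = pheno.data.groupby("genotype")["value"].mean()
        pd.testing.assert_series_equal(em["mean"], raw, check_names=False)


class TestBlups:
    @pytest.fixture
    def pheno(self):
        return random_balanced_pheno(6, 2, 1, np.random.default_rng(7))

    def test_no_error_variance_keeps_entry_means(self, pheno):
        vc = VarianceComponents(sigma_g2=1.0, sigma_e2=0.0, r=2)
        b = bt.compute_blups(pheno, "t", vc)
        assert b.k == 1.0
        pd.testing.assert_series_equal(b.values["blup"],
                                       b.values["entry_mean"],
                                       check_names=False)

    def test_no_genetic_variance_collapses_to_grand_mean(self, pheno):
        vc = VarianceComponents(sigma_g2=0.0, sigma_e2=1.0, r=2)
        b = bt.compute_blups(pheno, "t", vc)
        assert (b.values["blup"] == b.grand_mean).all()

    def test_shrinkage_factor_two_thirds(self, pheno):
        # sg2 = se2, r = 2 -> k = 2/3; entry mean mu+3 maps to mu+2
        vc = VarianceComponents(sigma_g2=1.0, sigma_e2=1.0, r=2)
        b = bt.compute_blups(pheno, "t", vc)
        assert b.k == pytest.approx(2 / 3)
        spread_em = b.values["entry_mean"].max() - b.values["entry_mean"].min()
        spread_bl = b.values["blup"].max() - b.values["blup"].min()
        assert spread_bl <= spread_em
        assert spread_bl == pytest.approx(2 / 3 * spread_em)
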