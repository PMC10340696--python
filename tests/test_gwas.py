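import numpy as np
import pandas as pd
import pytest

import breadtrial as bt
from breadtrial.gwas import (allele_group_ttest, bh_adjust, consensus_hits,
                             filter_markers, glm_scan, marker_qc)


def brute_force_bh(p):
    """Step-up definition: p_adj(i) = min_{j >= i} min(m * p(j) / j, 1)."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj_sorted = np.minimum.accumulate(
        (m * p[order] / np.arange(1, m + 1))[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj_sorted, 1.0)
    return out


def matrix_from_calls(calls, names=None):
    calls = np.asarray(calls, float)
    n = calls.shape[1]
    names = names or [f"S1A_{i + 1}" for i in range(n)]
    markers = pd.DataFrame({"name": names, "chromosome": "1A",
                            "position": range(1, n + 1)})
    return bt.GenotypeMatrix(
        line_ids=[f"L{i}" for i in range(calls.shape[0])],
        markers=markers, calls=calls)


class TestFilterMarkers:
    def test_monomorphic_marker_excluded(self):
        g = matrix_from_calls(np.column_stack([np.zeros(20),
                                               np.tile([0.0, 2.0], 10)]))
        kept, report = filter_markers(g)
        assert report.loc[0, "reason"] == "maf"
        assert kept.n_markers == 1

    def test_missing_fraction_enumeration(self):
        # markers with missing fractions 0.0 .. 0.9: exactly 6 pass <= 0.5
        calls = np.tile(np.array([0.0, 2.0] * 5), (10, 1))  # 10 x 10, maf .5
        for j in range(10):
            calls[:j, j] = np.nan
        g = matrix_from_calls(calls)
        kept, report = filter_markers(g, max_missing=0.5, min_maf=0.0,
                                      max_het=1.0)
        assert report["pass"].sum() == 6
        assert kept.n_markers == 6

    def test_het_fraction_threshold(self):
        col = np.array([1.0] * 3 + [0.0] * 9 + [2.0] * 8)  # 3/20 het
        good = np.tile([0.0, 2.0], 10)
        g = matrix_from_calls(np.column_stack([col, good]))
        _, report = filter_markers(g, max_het=0.10)
        assert report.loc[0, "reason"] == "het"
        assert report.loc[1, "pass"]

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        g = bt.simulate_genotypes(50, 100, missing_rate=0.3, het_rate=0.05,
                                  maf_range=(0.02, 0.5), seed=3)
        once, _ = filter_markers(g)
        twice, report = filter_markers(once)
        assert report["pass"].all()
        np.testing.assert_array_equal(once.calls, twice.calls)

    def test_allele_recoding_changes_no_decision(self):
        rng = np.random.default_rng(1)
        g = bt.simulate_genotypes(40, 50, missing_rate=0.2, het_rate=0.08,
                                  maf_range=(0.02, 0.5), seed=5)
        flipped = bt.GenotypeMatrix(line_ids=g.line_ids, markers=g.markers,
                                    calls=2.0 - g.calls)
        _, r1 = filter_markers(g)
        _, r2 = filter_markers(flipped)
        pd.testing.assert_series_equal(r1["pass"], r2["pass"])

    def test_qc_stats_on_nonmissing_calls(self):
        col = np.array([0.0, 1.0, 2.0, np.nan])
        g = matrix_from_calls(col[:, None])
        qc = marker_qc(g)
        assert qc.loc[0, "missing_frac"] == pytest.approx(0.25)
        assert qc.loc[0, "maf"] == pytest.approx(0.5)
        assert qc.loc[0, "het_frac"] == pytest.approx(1 / 3)

    def test_everything_filtered_rejected(self):
        g = matrix_from_calls(np.zeros((10, 3)))
        with pytest.raises(ValueError, match="no markers"):
            filter_markers(g)


class TestGlmScan:
    def test_noise_free_dose_recovered_exactly(self):
        rng = np.random.default_rng(2)
        calls = rng.integers(0, 3, size=(30, 5)).astype(float)
        g = matrix_from_calls(calls)
        trait = pd.Series(10.0 + calls[:, 2], index=g.line_ids)
        res = glm_scan(g, trait, n_pcs=0)
        hit = res.iloc[2]
        assert hit["effect"] == pytest.approx(1.0, abs=1e-8)
        assert hit["p"] < 1e-12

    def test_effect_sign_flips_with_dose_recoding(self):
        rng = np.random.default_rng(6)
        calls = rng.integers(0, 3, size=(40, 4)).astype(float)
        g = matrix_from_calls(calls)
        trait = pd.Series(rng.normal(size=40) + 0.8 * calls[:, 1],
                          index=g.line_ids)
        flipped = bt.GenotypeMatrix(line_ids=g.line_ids, markers=g.markers,
                                    calls=2.0 - calls)
        r1 = glm_scan(g, trait, n_pcs=0)
        r2 = glm_scan(flipped, trait, n_pcs=0)
        np.testing.assert_allclose(r1["effect"], -r2["effect"], atol=1e-9)
        np.testing.assert_allclose(r1["p"], r2["p"], atol=1e-9)

    def test_null_p_values_roughly_uniform(self):
        g = bt.simulate_genotypes(76, 400, maf_range=(0.1, 0.5), seed=7)
        rng = np.random.default_rng(7)
        trait = pd.Series(rng.permutation(rng.normal(500, 30, 76)),
                          index=g.line_ids)
        res = glm_scan(g, trait, n_pcs=3)
        frac = (res["p"] < 0.05).mean()
        assert 0.02 <= frac <= 0.09

    def test_pairwise_deletion_counts(self):
        calls = np.array([[0, 2], [1, np.nan], [2, 0], [0, 2], [2, 0],
                          [1, 1], [0, 2], [2, 0]], dtype=float)
        g = matrix_from_calls(calls)
        trait = pd.Series(np.arange(8.0), index=g.line_ids)
        res = glm_scan(g, trait, n_pcs=0)
        assert res.loc[0, "n_used"] == 8
        assert res.loc[1, "n_used"] == 7

    def test_too_few_lines_marker_skipped(self):
        calls = np.array([[0.0], [2.0], [np.nan], [np.nan], [np.nan]])
        g = matrix_from_calls(calls)
        trait = pd.Series(np.arange(5.0), index=g.line_ids)
        res = glm_scan(g, trait, n_pcs=0)
        assert np.isnan(res.loc[0, "p"])

    def test_effect_pct_scale(self):
        rng = np.random.default_rng(3)
        calls = rng.integers(0, 3, size=(50, 3)).astype(float)
        g = matrix_from_calls(calls)
        trait = pd.Series(500.0 + 50.0 * calls[:, 0], index=g.line_ids)
        res = glm_scan(g, trait, n_pcs=0)
        assert res.loc[0, "effect_pct"] == pytest.approx(
            100 * 50.0 / trait.mean(), rel=1e-6)


class TestBhAdjust:
    def test_hand_computed_example(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_all_ones_and_singleton(self):
        np.testing.assert_allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)
        np.testing.assert_allclose(bh_adjust([0.2]), [0.2])

    def test_matches_brute_force_definition(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            p = rng.random(rng.integers(1, 50))
            np.testing.assert_allclose(bh_adjust(p), brute_force_bh(p),
                                       atol=1e-12)

    def test_adjusted_at_least_raw(self):
        rng = np.random.default_rng(13)
        p = rng.random(100)
        assert (bh_adjust(p) >= p - 1e-15).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])


def result_row(marker, env, model, p=1e-4, p_adj=0.01, effect_pct=5.0):
    return dict(marker=marker, chromosome="1A", position=1,
                environment=env, model=model, n_used=76,
                effect=1.0, effect_pct=effect_pct, p=p, p_adj=p_adj)


class TestConsensus:
    def test_single_environment_single_model_not_a_hit(self):
        res = pd.DataFrame([result_row("m1", "ENV1", "GLM")])
        hits = consensus_hits(res, raw_cutoff=0.01)
        assert hits.empty

    def test_two_models_one_environment_is_a_hit(self):
        res = pd.DataFrame([result_row("m1", "ENV1", "GLM"),
                            result_row("m1", "ENV1", "BLINK")])
        hits = consensus_hits(res, raw_cutoff=0.01)
        assert set(hits["marker"]) == {"m1"}
        assert (hits["n_models"] == 2).all()

    def test_two_environments_one_model_is_a_hit(self):
        res = pd.DataFrame([result_row("m1", "ENV1", "GLM"),
                            result_row("m1", "ENV3", "GLM")])
        assert not consensus_hits(res, raw_cutoff=0.01).empty

    def test_small_effect_support_discarded(self):
        res = pd.DataFrame([
            result_row("m1", "ENV1", "GLM", p_adj=0.05, effect_pct=0.05),
            result_row("m1", "ENV2", "GLM", p_adj=0.05, effect_pct=5.0),
        ])
        assert consensus_hits(res, raw_cutoff=0.01).empty

    def test_fdr_gate(self):
        res = pd.DataFrame([
            result_row("m1", "ENV1", "GLM", p_adj=0.5),
            result_row("m1", "ENV2", "GLM", p_adj=0.5),
        ])
        assert consensus_hits(res, raw_cutoff=0.01).empty
        assert not consensus_hits(res, raw_cutoff=0.01, gates="raw").empty

    def test_external_model_tables_participate(self):
        res = pd.DataFrame([result_row("m1", "ENV1", "GLM"),
                            result_row("m1", "ENV1", "FarmCPU")])
        assert not consensus_hits(res, raw_cutoff=0.01).empty

    def test_duplicate_rows_rejected(self):
        res = pd.DataFrame([result_row("m1", "ENV1", "GLM")] * 2)
        with pytest.raises(ValueError, match="duplicate"):
            consensus_hits(res)


class TestAlleleGroupTtest:
    def test_identical_class_means_letters_match(self):
        calls = np.array([[0.0]] * 10 + [[2.0]] * 10)
        g = matrix_from_calls(calls)
        trait = pd.Series([5.0, 6.0] * 10, index=g.line_ids)
        res = allele_group_ttest(g, trait, "S1A_1")
        assert res.p > 0.5
        assert res.letters == {0.0: "a", 2.0: "a"}

    def test_separated_classes_significant(self):
        rng = np.random.default_rng(21)
        calls = np.array([[0.0]] * 20 + [[2.0]] * 20)
        g = matrix_from_calls(calls)
        trait = pd.Series(np.concatenate([rng.normal(0, 1, 20),
                                          rng.normal(5, 1, 20)]),
                          index=g.line_ids)
        res = allele_group_ttest(g, trait, "S1A_1")
        assert res.p < 1e-3
        assert res.letters == {0.0: "a", 2.0: "b"}
        assert res.n == {0.0: 20, 2.0: 20}

    def test_heterozygotes_excluded(self):
        calls = np.array([[0.0]] * 5 + [[1.0]] * 5 + [[2.0]] * 5)
        g = matrix_from_calls(calls)
        trait = pd.Series(np.arange(15.0), index=g.line_ids)
        res = allele_group_ttest(g, trait, "S1A_1")
        assert res.n == {0.0: 5, 2.0: 5}

    def test_single_line_class_refused(self):
        calls = np.array([[0.0]] * 9 + [[2.0]])
        g = matrix_from_calls(calls)
        trait = pd.Series(np.arange(10.0), index=g.line_ids)
        with pytest.raises(ValueError, match="need >= 2"):
            allele_group_ttest(g, trait, "S1A_1")
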