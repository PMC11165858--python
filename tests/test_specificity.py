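"""Sharing classification, concordance, expression patterns, target linking."""

import numpy as np
import pandas as pd
import pytest

from ernaqtl.intervals import GeneModel, GenomicInterval
from ernaqtl.quantify import ERNARegion, ExpressionMatrix
from ernaqtl.specificity import (
    classify_expression_pattern,
    classify_qtl_sharing,
    correlate_with_fractions,
    effect_concordance,
    link_targets,
    partial_correlation,
)


def _pairs(prefix, n):
    return {(f"{prefix}v{i}", f"{prefix}e{i}") for i in range(n)}


class TestSharing:
    def test_printed_cohort_sizes_reproduce_specific_fractions(self):
        shared = _pairs("s", 11_095)
        tumor = shared | _pairs("t", 25_983 - 11_095)
        normal = shared | _pairs("n", 34_737 - 11_095)
        _, summary = classify_qtl_sharing(tumor, normal)
        assert summary["tumor_specific_pct"] == 57.3
        assert summary["normal_specific_pct"] == 68.1
        assert summary["n_shared"] == 11_095

    def test_disjoint_sets_fully_specific(self):
        _, s = classify_qtl_sharing(_pairs("a", 10), _pairs("b", 5))
        assert s["tumor_specific_pct"] == 100.0
        assert s["normal_specific_pct"] == 100.0
        assert s["n_shared"] == 0

    def test_identical_sets_fully_shared(self):
        p = _pairs("x", 7)
        calls, s = classify_qtl_sharing(p, p)
        assert s["tumor_specific_pct"] == 0.0 and s["n_shared"] == 7
        assert (calls["class"] == "shared").all()

    def test_count_identities(self, rng):
        t = {(f"v{i}", f"e{i}") for i in rng.choice(100, 40, replace=False)}
        n = {(f"v{i}", f"e{i}") for i in rng.choice(100, 50, replace=False)}
        calls, s = classify_qtl_sharing(t, n)
        assert s["n_tumor_specific"] + s["n_shared"] == s["n_tumor"]
        assert s["n_normal_specific"] + s["n_shared"] == s["n_normal"]
        assert len(calls) == len(t | n)


class TestConcordance:
    def test_equal_betas(self):
        df = pd.DataFrame({"beta_tumor": [0.5, -0.2, 1.0], "beta_normal": [0.5, -0.2, 1.0]})
        conc, r = effect_concordance(df)
        assert conc == 1.0 and r == pytest.approx(1.0)

    def test_negated_betas(self):
        df = pd.DataFrame({"beta_tumor": [0.5, -0.2, 1.0], "beta_normal": [-0.5, 0.2, -1.0]})
        conc, r = effect_concordance(df)
        assert conc == 0.0 and r == pytest.approx(-1.0)

    def test_noisy_shared_effects_highly_concordant(self):
        concs = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            bt = 0.8 * np.sign(rng.normal(size=200)) + 0.0
            bt = rng.choice([-0.8, 0.8], size=200)
            df = pd.DataFrame(
                {
                    "beta_tumor": bt + rng.normal(0, 0.1, 200),
                    "beta_normal": bt + rng.normal(0, 0.1, 200),
                }
            )
            concs.append(effect_concordance(df)[0])
        assert min(concs) > 0.95

    def test_zero_beta_flagged_concordant(self):
        df = pd.DataFrame({"beta_tumor": [0.0, 1.0], "beta_normal": [0.4, 1.0]})
        with pytest.warns(UserWarning, match="zero beta"):
            conc, _ = effect_concordance(df)
        assert conc == 1.0

    def test_single_pair_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            effect_concordance(pd.DataFrame({"beta_tumor": [1.0], "beta_normal": [1.0]}))


class TestExpressionPattern:
    def test_printed_split_reproduces_percentages(self, rng):
        n_types = 30
        rows = []
        for _ in range(982):
            rows.append(1)
        rows += list(rng.integers(2, 10, size=1_117))
        rows += list(rng.integers(10, n_types + 1, size=297))
        detect = np.zeros((len(rows), n_types), dtype=bool)
        for i, k in enumerate(rows):
            detect[i, :k] = True
        df = pd.DataFrame(detect, index=[f"e{i}" for i in range(len(rows))])
        _, summary = classify_expression_pattern(df)
        assert summary["denominator"] == 2_396
        assert summary["specific_pct"] == 40.98
        assert summary["intermediate_pct"] == 46.62
        assert summary["ubiquitous_pct"] == 12.40

    def test_all_single_type_is_fully_specific(self):
        df = pd.DataFrame(np.eye(5, dtype=bool))
        _, s = classify_expression_pattern(df)
        assert s["specific_pct"] == 100.0

    def test_nine_vs_ten_type_boundary(self):
        detect = np.zeros((2, 12), dtype=bool)
        detect[0, :9] = True
        detect[1, :10] = True
        patterns, _ = classify_expression_pattern(pd.DataFrame(detect))
        assert patterns["class"].tolist() == ["intermediate", "ubiquitous"]

    def test_undetected_excluded_from_denominator(self):
        detect = np.zeros((3, 4), dtype=bool)
        detect[0, 0] = True
        _, s = classify_expression_pattern(pd.DataFrame(detect))
        assert s["denominator"] == 1 and s["n_undetected"] == 2

    def test_percentages_sum_to_hundred(self, rng):
        detect = rng.random((500, 15)) < 0.25
        _, s = classify_expression_pattern(pd.DataFrame(detect))
        total = s["specific_pct"] + s["intermediate_pct"] + s["ubiquitous_pct"]
        assert total == pytest.approx(100.0, abs=0.02)


class TestPartialCorrelation:
    def test_no_covariates_equals_pearson(self, rng):
        from scipy.stats import pearsonr

        x, y = rng.normal(size=50), rng.normal(size=50)
        r, p = partial_correlation(x, y)
        rw, pw = pearsonr(x, y)
        assert r == pytest.approx(rw, rel=1e-10)
        assert p == pytest.approx(pw, rel=1e-6)

    def test_perfect_confounder_removal(self, rng):
        z = rng.normal(size=200)
        x = 2.0 * z + rng.normal(0, 0.1, 200)
        r, _ = partial_correlation(x, z, z)
        # y's residual on its own confounder is numerical dust; pcor ~ 0
        assert abs(r) < 0.05

    def test_matches_precision_matrix_oracle(self, rng):
        for _ in range(20):
            n, k = 20, 3
            data = rng.normal(size=(n, k + 2))
            x, y, C = data[:, 0], data[:, 1], data[:, 2:]
            r, _ = partial_correlation(x, y, C)
            # oracle: negative scaled off-diagonal of the inverse correlation matrix
            R = np.corrcoef(data, rowvar=False)
            P = np.linalg.inv(R)
            want = -P[0, 1] / np.sqrt(P[0, 0] * P[1, 1])
            assert abs(r - want) < 1e-10

    def test_constant_residuals_error(self):
        x = np.ones(10)
        with pytest.raises(ValueError, match="constant"):
            partial_correlation(x, np.arange(10.0))


def _link_fixture(rng, n=120, purity_effect=0.0, gamma=1.0, noise=0.5):
    """Two eRNA regions, three genes; gene g0 driven by eRNA e0."""
    samples = [f"S{i}" for i in range(n)]
    purity = rng.uniform(0.3, 0.9, size=n)
    e0 = rng.normal(size=n) + purity_effect * purity
    e1 = rng.normal(size=n) + purity_effect * purity
    g0 = gamma * e0 + rng.normal(0, noise, n)
    g1 = purity_effect * purity + rng.normal(0, noise, n)
    g2 = rng.normal(size=n)
    erna = ExpressionMatrix(
        pd.DataFrame([e0 - e0.min() + 0.01, e1 - e1.min() + 0.01],
                     index=["e0", "e1"], columns=samples),
        units="RPKM",
    )
    genes_expr = ExpressionMatrix(
        pd.DataFrame([g0, g1, g2], index=["g0", "g1", "g2"], columns=samples),
        units="normal_scores",
    )
    regions = [
        ERNARegion("e0", GenomicInterval("chrT", 100_000, 106_000), 103_000),
        ERNARegion("e1", GenomicInterval("chrT", 500_000, 506_000), 503_000),
    ]
    genes = [
        GeneModel("g0", GenomicInterval("chrT", 200_000, 210_000, strand="+")),
        GeneModel("g1", GenomicInterval("chrT", 300_000, 310_000, strand="+")),
        GeneModel("g2", GenomicInterval("chrT", 700_000, 710_000, strand="-")),
    ]
    covars = pd.DataFrame({"purity": purity}, index=samples)
    return erna, genes_expr, regions, genes, covars


class TestLinkTargets:
    def test_planted_link_recovered_and_purity_pair_rejected(self, rng):
        erna, gexpr, regions, genes, covars = _link_fixture(
            rng, purity_effect=3.0, gamma=1.0, noise=0.5
        )
        links = link_targets(erna, gexpr, regions, genes, covars=covars)
        linked = set(map(tuple, links.loc[links["linked"], ["erna_id", "gene_id"]].values))
        assert ("e0", "g0") in linked
        assert ("e0", "g1") not in linked  # purity-only association adjusted away
        assert ("e1", "g1") not in linked

    def test_window_zero_keeps_only_tss_inside_region(self, rng):
        erna, gexpr, regions, genes, covars = _link_fixture(rng)
        genes.append(
            GeneModel("g_in", GenomicInterval("chrT", 101_000, 140_000, strand="+"))
        )
        gexpr = ExpressionMatrix(
            pd.concat(
                [gexpr.values,
                 pd.DataFrame([rng.normal(size=len(erna.samples))], index=["g_in"],
                              columns=gexpr.samples)]
            ),
            units="normal_scores",
        )
        links = link_targets(erna, gexpr, regions, genes, covars=covars, window=0)
        assert set(links["gene_id"]) == {"g_in"}

    def test_purity_adjustment_removes_spurious_links_plain_correlation_accepts(self):
        """>= 90% of purity-only links accepted by plain correlation are rejected."""
        spurious_plain, spurious_adjusted = 0, 0
        for seed in range(10):
            rng = np.random.default_rng(1000 + seed)
            erna, gexpr, regions, genes, covars = _link_fixture(
                rng, purity_effect=5.0, gamma=0.0, noise=0.3
            )
            plain = link_targets(erna, gexpr, regions, genes, covars=None)
            adjusted = link_targets(erna, gexpr, regions, genes, covars=covars)
            sp = plain[plain["linked"]]
            spurious_plain += len(sp)
            merged = adjusted.merge(sp[["erna_id", "gene_id"]])
            spurious_adjusted += int(merged["linked"].sum())
        assert spurious_plain >= 10  # plain correlation is indeed fooled
        assert spurious_adjusted <= 0.1 * spurious_plain

    def test_pcor_min_one_passes_only_exact_affine(self, rng):
        erna, gexpr, regions, genes, covars = _link_fixture(rng, gamma=1.0, noise=0.0)
        links = link_targets(erna, gexpr, regions, genes, pcor_min=1.0)
        linked = set(map(tuple, links.loc[links["linked"], ["erna_id", "gene_id"]].values))
        assert linked == {("e0", "g0")}


class TestFractions:
    def test_fraction_equal_to_expression_near_one(self, rng):
        n = 80
        samples = [f"S{i}" for i in range(n)]
        e = rng.normal(size=n)
        purity = pd.Series(rng.uniform(0.3, 0.9, n), index=samples)
        erna = ExpressionMatrix(
            pd.DataFrame([e - e.min() + 0.01], index=["e0"], columns=samples), units="RPKM"
        )
        fr = pd.DataFrame({"T_cell": e + rng.normal(0, 1e-6, n)}, index=samples)
        out = correlate_with_fractions(erna, fr, purity)
        assert out.iloc[0]["pcor"] == pytest.approx(1.0, abs=1e-3)

    def test_purity_driven_pair_adjusted_to_zero(self, rng):
        n = 200
        samples = [f"S{i}" for i in range(n)]
        purity = pd.Series(rng.uniform(0.3, 0.9, n), index=samples)
        e = 3.0 * purity.to_numpy() + rng.normal(0, 0.05, n)
        erna = ExpressionMatrix(
            pd.DataFrame([e - e.min() + 0.01], index=["e0"], columns=samples), units="RPKM"
        )
        fr = pd.DataFrame(
            {"mac": 2.0 * purity.to_numpy() + rng.normal(0, 0.05, n)}, index=samples
        )
        out = correlate_with_fractions(erna, fr, purity)
        assert abs(out.iloc[0]["pcor"]) < 0.2

    def test_independent_fractions_significant_count_near_alpha(self, rng):
        n = 100
        samples = [f"S{i}" for i in range(n)]
        purity = pd.Series(rng.uniform(0.3, 0.9, n), index=samples)
        erna = ExpressionMatrix(
            pd.DataFrame(rng.gamma(2, 1, size=(20, n)),
                         index=[f"e{i}" for i in range(20)], columns=samples),
            units="RPKM",
        )
        fr = pd.DataFrame(rng.normal(size=(n, 5)), index=samples,
                          columns=[f"ct{i}" for i in range(5)])
        out = correlate_with_fractions(erna, fr, purity)
        assert int(out["significant"].sum()) <= 5  # BH on 100 null tests
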