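"""Control matching, Fisher enrichment, GWAS LD blocks, pi1, ratio-vs-FC."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ernaqtl.enrichment import (
    enrichment_ratio_vs_expression,
    fisher_enrichment,
    gwas_ld_block_enrichment,
    ld_proxy_counts,
    match_controls,
    pi1_gwas_enrichment,
    variant_strata,
)


def _annotations(rng, n, prefix="v"):
    return pd.DataFrame(
        {
            "maf": rng.uniform(0.05, 0.5, size=n),
            "ld_proxy_count": rng.integers(0, 80, size=n),
            "variant_type": rng.choice(["SNV", "indel"], size=n, p=[0.9, 0.1]),
        },
        index=[f"{prefix}{i}" for i in range(n)],
    )


class TestMatchControls:
    def test_exact_stratum_copies_match_exactly(self, rng):
        sig = _annotations(rng, 50, prefix="s")
        pool = sig.copy()
        pool.index = [f"p{i}" for i in range(len(pool))]
        annot = pd.concat([sig, pool])
        controls = match_controls(list(sig.index), annot, ratio=1, seed=0)
        assert len(controls) == 50
        sig_strata = variant_strata(annot.loc[sig.index])["stratum"].value_counts()
        ctl_strata = variant_strata(annot.loc[controls])["stratum"].value_counts()
        assert sig_strata.to_dict() == ctl_strata.to_dict()

    def test_ratio_two_with_ample_pool(self, rng):
        sig = _annotations(rng, 100, prefix="s")
        pool = pd.concat(
            [_annotations(rng, 100, prefix=f"p{k}_") for k in range(5)]
            + [sig.set_index(pd.Index([f"c{k}_{i}" for i in range(100)]))
               for k in range(3)]
        )
        annot = pd.concat([sig, pool])
        controls = match_controls(list(sig.index), annot, ratio=2, seed=1)
        assert len(controls) == 200
        assert len(set(controls)) == 200  # without replacement

    def test_stratum_frequency_tables_identical(self, rng):
        sig = _annotations(rng, 80, prefix="s")
        copies = pd.concat(
            [sig.set_index(pd.Index([f"c{k}_{i}" for i in range(80)])) for k in range(2)]
        )
        annot = pd.concat([sig, copies])
        controls = match_controls(list(sig.index), annot, ratio=1, seed=3)
        a = variant_strata(annot.loc[sig.index])["stratum"].value_counts().sort_index()
        b = variant_strata(annot.loc[controls])["stratum"].value_counts().sort_index()
        assert (a == b).all()

    def test_empty_stratum_falls_back_to_nearest_maf_bin(self):
        annot = pd.DataFrame(
            {
                "maf": [0.07, 0.22],
                "ld_proxy_count": [3, 3],
                "variant_type": ["SNV", "SNV"],
            },
            index=["sig1", "poolA"],
        )
        with pytest.warns(UserWarning, match="fallback"):
            controls = match_controls(["sig1"], annot, ratio=1, seed=0)
        assert controls == ["poolA"]

    def test_deterministic_under_seed(self, rng):
        sig = _annotations(rng, 30, prefix="s")
        pool = _annotations(rng, 300, prefix="p")
        annot = pd.concat([sig, pool])
        a = match_controls(list(sig.index), annot, seed=42)
        b = match_controls(list(sig.index), annot, seed=42)
        assert a == b

    def test_overlapping_pool_rejected(self, rng):
        annot = _annotations(rng, 10)
        with pytest.raises(ValueError, match="disjoint"):
            match_controls(["v0"], annot, pool=["v0", "v1"])


class TestFisherEnrichment:
    def test_worked_table_or_and_hypergeometric_p(self):
        signal = [f"s{i}" for i in range(100)]
        controls = [f"c{i}" for i in range(100)]
        members = set(signal[:30]) | set(controls[:10])  # a=30 b=70 c=10 d=90
        out = fisher_enrichment(signal, controls, {"feat": members}, n_tests=1)
        row = out.iloc[0]
        assert row["or_"] == pytest.approx(30 * 90 / (70 * 10), rel=1e-12)
        # independent oracle: two-sided hypergeometric enumeration
        M, n, N = 200, 40, 100  # total, members, signal size
        pmf = [stats.hypergeom.pmf(k, M, n, N) for k in range(0, n + 1)]
        p_obs = pmf[30]
        want = sum(p for p in pmf if p <= p_obs * (1 + 1e-9))
        assert row["p"] == pytest.approx(want, rel=1e-8)

    def test_empty_feature_gets_corrected_or_and_p_one(self):
        out = fisher_enrichment(["s1", "s2"], ["c1", "c2"], {"feat": set()}, n_tests=1)
        row = out.iloc[0]
        assert row["p"] == 1.0
        assert row["or_"] == pytest.approx(1.0)  # 0.5 correction on both zero cells

    def test_random_tables_match_fisher_oracle(self, rng):
        for _ in range(20):
            a, b, c, d = rng.integers(0, 50, size=4) + [1, 1, 1, 1]
            signal = [f"s{i}" for i in range(a + b)]
            controls = [f"c{i}" for i in range(c + d)]
            members = set(signal[:a]) | set(controls[:c])
            out = fisher_enrichment(signal, controls, {"f": members}, n_tests=1)
            want = stats.fisher_exact([[a, b], [c, d]])[1]
            assert out.iloc[0]["p"] == pytest.approx(want, rel=1e-12)

    def test_null_draws_give_or_near_one_and_no_adjusted_hits(self, rng):
        n_hits = 0
        ors = []
        for seed in range(20):
            r = np.random.default_rng(seed)
            signal = [f"s{i}" for i in range(200)]
            controls = [f"c{i}" for i in range(200)]
            members = {
                "f": {v for v in signal + controls if r.random() < 0.3}
            }
            out = fisher_enrichment(signal, controls, members, n_tests=10)
            n_hits += int((out["p_adj"] < 0.05).sum())
            ors.append(out.iloc[0]["or_"])
        assert n_hits <= 1  # expected ~0.1 adjusted hits over 20 null draws
        assert np.median(ors) == pytest.approx(1.0, abs=0.3)

    def test_bonferroni_bounds(self, rng):
        signal = [f"s{i}" for i in range(50)]
        controls = [f"c{i}" for i in range(50)]
        membership = {
            f"f{k}": {v for v in signal + controls if rng.random() < 0.4}
            for k in range(8)
        }
        out = fisher_enrichment(signal, controls, membership)
        assert (out["p_adj"] >= out["p"] - 1e-15).all()
        assert (out["p_adj"] <= 1.0).all()
        assert (out["n_tests"] == 8).all()

    def test_signal_control_overlap_rejected(self):
        with pytest.raises(ValueError, match="disjoint"):
            fisher_enrichment(["x"], ["x"], {"f": set()})


class TestGwasLdBlock:
    LD = pd.DataFrame(
        {"id_a": ["t1", "t1", "v5"], "id_b": ["v2", "v3", "v6"], "r2": [0.9, 0.1, 0.95]}
    )

    def test_no_ld_expansion_membership_is_tags_only(self):
        ld = self.LD.assign(r2=0.0)
        out = gwas_ld_block_enrichment(["t1", "v9"], ["t1"], ld, ["c1", "c2"])
        assert out.iloc[0]["a"] == 1  # only the tag itself

    def test_proxies_above_threshold_join_the_block(self):
        out = gwas_ld_block_enrichment(["v2", "v3"], ["t1"], self.LD, ["c1"])
        assert out.iloc[0]["a"] == 1  # v2 in (r2 .9), v3 out (r2 .1)

    def test_planted_colocalization_detected(self, rng):
        # QTL variants concentrated inside the GWAS block
        tags = [f"t{i}" for i in range(5)]
        block = [f"b{i}" for i in range(45)]
        outside = [f"o{i}" for i in range(500)]
        ld = pd.DataFrame(
            {"id_a": list(np.repeat(tags, 9)), "id_b": block, "r2": 0.8}
        )
        signal = block[:30] + outside[:10]
        controls = outside[100:140]
        out = gwas_ld_block_enrichment(signal, tags, ld, controls)
        assert out.iloc[0]["or_"] > 1
        assert out.iloc[0]["p"] < 0.05

    def test_ld_proxy_counts_both_columns(self):
        counts = ld_proxy_counts(["t1", "v2", "v6"], self.LD, r2_min=0.2)
        assert counts.to_dict() == {"t1": 1, "v2": 1, "v6": 1}


class TestPi1:
    def test_uniform_category_pi1_near_zero(self, rng):
        ids = [f"v{i}" for i in range(5_000)]
        p = pd.Series(rng.uniform(size=5_000), index=ids)
        pi1 = pi1_gwas_enrichment({"cat": ids}, p)["cat"]
        assert pi1 == pytest.approx(0.0, abs=0.05)

    def test_planted_mixture_pi1_recovered(self, rng):
        ids = [f"v{i}" for i in range(5_000)]
        vals = rng.uniform(size=5_000)
        vals[:1_250] = rng.uniform(0, 1e-8, size=1_250)  # 25% signal
        p = pd.Series(vals, index=ids)
        pi1 = pi1_gwas_enrichment({"cat": ids}, p)["cat"]
        assert pi1 == pytest.approx(0.25, abs=0.05)

    def test_all_p_equal_one_gives_zero(self):
        ids = [f"v{i}" for i in range(200)]
        pi1 = pi1_gwas_enrichment({"cat": ids}, pd.Series(1.0, index=ids))["cat"]
        assert pi1 == 0.0

    def test_small_category_warns(self, rng):
        ids = [f"v{i}" for i in range(30)]
        with pytest.warns(UserWarning, match="noisy"):
            pi1_gwas_enrichment({"cat": ids}, pd.Series(rng.uniform(size=30), index=ids))


class TestRatioVsExpression:
    def test_identity_gives_rho_one(self):
        ts = pd.Series([2.0, 3.0, 1.5, 4.0], index=list("abcd"))
        sh = pd.Series([1.0, 1.0, 1.0, 1.0], index=list("abcd"))
        fc = np.log(ts / sh)
        rho, p = enrichment_ratio_vs_expression(ts, sh, fc)
        assert rho == pytest.approx(1.0)

    def test_reversed_ranks_give_minus_one(self):
        ts = pd.Series([2.0, 3.0, 1.5, 4.0], index=list("abcd"))
        sh = pd.Series(1.0, index=list("abcd"))
        fc = -np.log(ts)
        rho, _ = enrichment_ratio_vs_expression(ts, sh, fc)
        assert rho == pytest.approx(-1.0)

    def test_independent_tables_small_rho(self, rng):
        pvals = []
        for seed in range(30):
            r = np.random.default_rng(seed)
            idx = [f"f{i}" for i in range(30)]
            ts = pd.Series(r.lognormal(size=30), index=idx)
            sh = pd.Series(r.lognormal(size=30), index=idx)
            fc = pd.Series(r.normal(size=30), index=idx)
            pvals.append(enrichment_ratio_vs_expression(ts, sh, fc)[1])
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_nonpositive_or_dropped_with_warning(self):
        ts = pd.Series([2.0, 0.0, 1.0], index=list("abc"))
        sh = pd.Series([1.0, 1.0, 1.0], index=list("abc"))
        fc = pd.Series([0.5, 0.1, -0.2], index=list("abc"))
        with pytest.warns(UserWarning, match="non-positive"):
            enrichment_ratio_vs_expression(ts, sh, fc)
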