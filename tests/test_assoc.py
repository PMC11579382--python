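import numpy as np
import pandas as pd
import pytest
from scipy import stats

from growthgwas.assoc import (
    cohort_filters,
    genomic_inflation,
    harmonize,
    ivw_meta,
    post_meta_filters,
    run_gwas,
)


def _variants(n, chrom="1", ea="A", nea="G"):
    return pd.DataFrame(
        {
            "snp": [f"v{i}" for i in range(n)],
            "chrom": chrom,
            "pos": 1000 + 1_000_000 * np.arange(n),
            "ea": ea,
            "nea": nea,
            "eaf": 0.3,
            "info": 0.99,
        }
    )


def _assoc_row(**kw):
    base = dict(
        snp="v0", chrom="1", pos=1000, ea="A", nea="G", eaf=0.3, info=0.99,
        n=1000, beta=0.1, se=0.02, p=1e-4, monomorphic=False,
    )
    base.update(kw)
    return base


class TestRunGwas:
    def test_planted_effect_recovered(self):
        rng = np.random.default_rng(5)
        n = 1500
        ids = pd.Index([f"S{i}" for i in range(n)], name="iid")
        g = rng.binomial(2, 0.3, size=(n, 20)).astype(float)
        dosages = pd.DataFrame(g, index=ids, columns=[f"v{i}" for i in range(20)])
        sex = rng.integers(0, 2, n).astype(float)
        y = 0.1 * g[:, 3] + 0.2 * sex + rng.normal(0, 1.0, n)
        res = run_gwas(
            pd.Series(y, index=ids),
            dosages,
            _variants(20),
            pd.DataFrame({"sex": sex}, index=ids),
        )
        hit = res.set_index("snp").loc["v3"]
        assert abs(hit["beta"] - 0.1) < 2 * hit["se"]
        assert hit["p"] < 0.05

    def test_matches_full_ols_fit(self):
        """Residualised single-variant statistics equal the full regression."""
        import statsmodels.api as sm

        rng = np.random.default_rng(6)
        n = 200
        ids = pd.Index([f"S{i}" for i in range(n)], name="iid")
        g = rng.binomial(2, 0.4, size=(n, 3)).astype(float)
        dosages = pd.DataFrame(g, index=ids, columns=["v0", "v1", "v2"])
        cov = pd.DataFrame(
            {"sex": rng.integers(0, 2, n), "pc1": rng.normal(size=n)}, index=ids
        )
        y = pd.Series(0.05 * g[:, 1] + rng.normal(size=n), index=ids)
        res = run_gwas(y, dosages, _variants(3), cov).set_index("snp")
        X = sm.add_constant(np.column_stack([g[:, 1], cov.values]))
        ref = sm.OLS(y.values, X).fit()
        assert res.loc["v1", "beta"] == pytest.approx(ref.params[1], abs=1e-10)
        assert res.loc["v1", "se"] == pytest.approx(ref.bse[1], abs=1e-10)
        assert res.loc["v1", "p"] == pytest.approx(ref.pvalues[1], rel=1e-8)

    def test_monomorphic_dosage_flagged(self):
        ids = pd.Index([f"S{i}" for i in range(50)], name="iid")
        dosages = pd.DataFrame({"v0": np.zeros(50)}, index=ids)
        y = pd.Series(np.random.default_rng(0).normal(size=50), index=ids)
        res = run_gwas(y, dosages, _variants(1), None)
        assert bool(res.loc[0, "monomorphic"])
        assert np.isnan(res.loc[0, "beta"])


class TestCohortFilters:
    def test_each_rule_trips_exactly_once(self):
        rows = [
            _assoc_row(snp="keep1"),
            _assoc_row(snp="keep2", pos=2000),
            _assoc_row(snp="keep3", pos=3000),
            _assoc_row(snp="keep4", pos=4000),
            _assoc_row(snp="mono", monomorphic=True, beta=np.nan, se=np.nan),
            _assoc_row(snp="indel", ea="AT"),
            _assoc_row(snp="lown", n=19),
            _assoc_row(snp="lowmac", eaf=0.001, n=1000),  # MAC = 2
            _assoc_row(snp="bigse", se=10.0),  # boundary inclusive
            _assoc_row(snp="lowinfo", info=0.39),
        ]
        table = pd.DataFrame(rows)
        kept, ledger = cohort_filters(table)
        assert len(kept) == 4
        assert int(ledger.sum()) == 6
        assert (ledger == 1).sum() == 6 or ledger.max() == 1

    @pytest.mark.parametrize(
        "row, removed",
        [
            (_assoc_row(se=10.0), True),
            (_assoc_row(se=9.99), False),
            (_assoc_row(beta=-10.0), True),
            (_assoc_row(eaf=0.0015, n=1000), True),  # MAC 3 -> removed (<= 3)
            (_assoc_row(eaf=0.002, n=1000), False),  # MAC 4 -> kept
            (_assoc_row(n=20), False),
            (_assoc_row(info=0.4), False),
        ],
    )
    def test_boundary_rules(self, row, removed):
        kept, _ = cohort_filters(pd.DataFrame([row]))
        assert (len(kept) == 0) is removed


class TestHarmonize:
    def test_swapped_alleles_flip_beta_and_eaf(self):
        ref = pd.DataFrame([_assoc_row(ea="A", nea="G", beta=0.05, eaf=0.3)])
        other = pd.DataFrame([_assoc_row(ea="G", nea="A", beta=-0.05, eaf=0.7)])
        out = harmonize({"ref": ref, "other": other})
        row = out["other"].iloc[0]
        assert row["beta"] == pytest.approx(0.05)
        assert row["eaf"] == pytest.approx(0.3)
        assert row["ea"] == "A" and row["nea"] == "G"

    def test_ambiguous_near_half_dropped(self):
        ref = pd.DataFrame([_assoc_row(ea="A", nea="T", eaf=0.49)])
        other = pd.DataFrame([_assoc_row(ea="A", nea="T", eaf=0.49)])
        out = harmonize({"ref": ref, "other": other})
        assert len(out["ref"]) == 0 and len(out["other"]) == 0

    def test_ambiguous_far_from_half_kept(self):
        ref = pd.DataFrame([_assoc_row(ea="A", nea="T", eaf=0.1)])
        out = harmonize({"ref": ref})
        assert len(out["ref"]) == 1

    def test_identical_tables_pass_through(self):
        ref = pd.DataFrame([_assoc_row(), _assoc_row(snp="v1", pos=2000)])
        out = harmonize({"a": ref.copy(), "b": ref.copy()})
        for col in ("snp", "beta", "eaf", "ea", "nea"):
            assert list(out["a"][col]) == list(out["b"][col])

    def test_irreconcilable_alleles_dropped(self):
        ref = pd.DataFrame([_assoc_row(ea="A", nea="G")])
        other = pd.DataFrame([_assoc_row(ea="A", nea="C")])
        out = harmonize({"ref": ref, "other": other})
        assert len(out["other"]) == 0

    def test_eaf_discrepancy_flagged_not_dropped(self):
        ref = pd.DataFrame([_assoc_row(eaf=0.1)])
        other = pd.DataFrame([_assoc_row(eaf=0.45)])
        out = harmonize({"ref": ref, "other": other})
        assert len(out["other"]) == 1
        assert bool(out["other"].iloc[0]["eaf_discrepant"])


class TestIvwMeta:
    def test_single_cohort_is_identity(self):
        t = pd.DataFrame([_assoc_row(beta=0.07, se=0.015)])
        meta = ivw_meta({"a": t})
        assert meta.iloc[0]["beta"] == pytest.approx(0.07)
        assert meta.iloc[0]["se"] == pytest.approx(0.015)
        assert meta.iloc[0]["n_cohorts"] == 1

    def test_equal_se_average_and_q(self):
        se = 0.02
        a = pd.DataFrame([_assoc_row(beta=0.1, se=se)])
        b = pd.DataFrame([_assoc_row(beta=0.3, se=se)])
        meta = ivw_meta({"a": a, "b": b})
        row = meta.iloc[0]
        assert row["beta"] == pytest.approx(0.2)
        expected_q = (0.1 - 0.2) ** 2 / se**2 + (0.3 - 0.2) ** 2 / se**2
        assert row["q_stat"] == pytest.approx(expected_q)
        assert row["q_df"] == 1
        assert row["direction"] == "++"

    def test_self_meta_scales_se_by_sqrt_k(self):
        K = 4
        tables = {f"c{i}": pd.DataFrame([_assoc_row(beta=0.1, se=0.02)]) for i in range(K)}
        meta = ivw_meta(tables)
        assert meta.iloc[0]["se"] == pytest.approx(0.02 / np.sqrt(K), abs=1e-12)
        assert meta.iloc[0]["q_stat"] == pytest.approx(0.0, abs=1e-12)
        assert meta.iloc[0]["i2"] == 0.0

    def test_matches_brute_force_weighted_arithmetic(self):
        betas = [0.12, -0.05, 0.33]
        ses = [0.04, 0.09, 0.11]
        ns = [900, 400, 250]
        tables = {
            f"c{i}": pd.DataFrame([_assoc_row(beta=b, se=s, n=n)])
            for i, (b, s, n) in enumerate(zip(betas, ses, ns))
        }
        meta = ivw_meta(tables).iloc[0]
        w = [1.0 / s**2 for s in ses]
        beta = sum(wi * bi for wi, bi in zip(w, betas)) / sum(w)
        se = (sum(w)) ** -0.5
        q = sum(wi * (bi - beta) ** 2 for wi, bi in zip(w, betas))
        assert meta["beta"] == pytest.approx(beta, abs=1e-12)
        assert meta["se"] == pytest.approx(se, abs=1e-12)
        assert meta["q_stat"] == pytest.approx(q, abs=1e-12)
        assert meta["p"] == pytest.approx(2 * stats.norm.sf(abs(beta / se)), abs=1e-15)
        assert meta["n"] == sum(ns)

    def test_q_mean_near_df_under_common_effect(self):
        """Cochran's Q averages ~ K-1 when all cohorts share one effect."""
        rng = np.random.default_rng(9)
        K, M = 5, 1000
        se = 0.05
        tables = {}
        truth = rng.normal(0, 0.02, M)
        for k in range(K):
            rows = []
            for j in range(M):
                rows.append(
                    _assoc_row(
                        snp=f"v{j}", pos=1000 + j, beta=truth[j] + se * rng.standard_normal(), se=se
                    )
                )
            tables[f"c{k}"] = pd.DataFrame(rows)
        meta = ivw_meta(tables)
        assert meta["q_stat"].mean() == pytest.approx(K - 1, rel=0.1)


class TestPostMetaFilters:
    def _meta_row(self, **kw):
        base = dict(
            snp="v0", chrom="1", pos=1000, ea="A", nea="G", eaf=0.3, info=0.99,
            n=5000, beta=0.1, se=0.01, p=1e-9, n_cohorts=5, direction="+++++",
            q_stat=1.0, q_df=4, q_p=0.9, i2=0.0,
        )
        base.update(kw)
        return base

    def test_half_cohort_rule_with_five_cohorts(self):
        meta = pd.DataFrame(
            [self._meta_row(), self._meta_row(snp="v1", pos=2000, n_cohorts=2)]
        )
        kept, hits, _ = post_meta_filters(meta, total_cohorts=5)
        assert list(kept["snp"]) == ["v0"]

    def test_low_maf_dropped(self):
        meta = pd.DataFrame([self._meta_row(eaf=0.004)])
        kept, _, _ = post_meta_filters(meta, total_cohorts=5)
        assert len(kept) == 0
        meta2 = pd.DataFrame([self._meta_row(eaf=0.996)])  # MAF symmetric
        kept2, _, _ = post_meta_filters(meta2, total_cohorts=5)
        assert len(kept2) == 0

    def test_nearby_hits_form_one_clump(self):
        meta = pd.DataFrame(
            [
                self._meta_row(snp="lead", pos=1_000_000, p=1e-12),
                self._meta_row(snp="shadow", pos=1_100_000, p=1e-9),
                self._meta_row(snp="distant", pos=3_000_000, p=1e-10),
            ]
        )
        kept, hits, leads = post_meta_filters(meta, total_cohorts=5)
        assert len(hits) == 3
        assert sorted(leads["snp"]) == ["distant", "lead"]


def test_genomic_inflation_null_uniform():
    rng = np.random.default_rng(3)
    p = rng.uniform(size=200_000)
    assert genomic_inflation(p) == pytest.approx(1.0, abs=0.02)
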