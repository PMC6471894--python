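"""Imputation-quality metrics and the leave-one-out engine."""

import numpy as np
import pandas as pd
import pytest

from pedimpute.core import MISSING
from pedimpute.evaluate import (
    LOOResult,
    MaskingScheme,
    chance_corrected_prop,
    cor_by_individual,
    loo_cross_validate,
    pearson_or_nan,
    prop_by_individual,
    prop_by_snp,
    prop_match,
    quality_by_individual,
    quality_by_snp,
    select_high_quality_snps,
)
from pedimpute.imputers import FamilyLDImputer, FrequencyFillImputer

from conftest import make_gm


class TestMaskingScheme:
    def test_held_out_must_be_reference(self):
        with pytest.raises(ValueError):
            MaskingScheme(reference_ids=["a", "b"], held_out="c")

    def test_extras_must_be_outside_reference(self):
        with pytest.raises(ValueError):
            MaskingScheme(reference_ids=["a", "b"], held_out="a", extra_ids=["b"])


class TestPropAndCor:
    def test_prop_examples(self):
        truth = np.array([0, 1, 2, 1])
        assert prop_match(truth, np.array([0, 1, 2, 1])) == 1.0
        imp = np.array([0, 1, 1, 1])
        assert prop_match(truth, imp) == 0.75
        assert prop_match(truth, imp, mode="allele") == pytest.approx(7 / 8)

    def test_all_missing_is_nan(self):
        truth = np.full(4, MISSING)
        assert np.isnan(prop_match(truth, np.zeros(4)))

    def test_missing_truth_excluded(self):
        truth = np.array([MISSING, 1, 2, 1])
        assert prop_match(truth, np.array([0, 1, 2, 1])) == 1.0

    def test_correlation_examples(self):
        assert pearson_or_nan(np.array([0, 0, 2, 2]), np.array([0, 0, 2, 2])) == 1.0
        assert pearson_or_nan(np.array([0, 0, 2, 2]), np.array([2, 2, 0, 0])) == -1.0
        assert np.isnan(pearson_or_nan(np.array([0, 1, 2, 1]), np.ones(4)))

    def test_per_chromosome_grain(self):
        chrom = np.array(["c1", "c1", "c2", "c2"])
        truth = np.array([0, 1, 2, 1])
        imp = np.array([0, 1, 1, 0])
        propi = prop_by_individual(truth, imp, chrom=chrom)
        assert propi["c1"] == 1.0 and propi["c2"] == 0.0
        cori = cor_by_individual(truth, imp, chrom=chrom)
        assert set(cori.index) == {"c1", "c2"}

    def test_prop_by_snp(self):
        truth = np.array([0, 1, 2, 1])
        props, ni = prop_by_snp(truth, np.array([0, 1, 2, 0]))
        assert props == 0.75 and ni == 4
        truth[0] = MISSING
        props, ni = prop_by_snp(truth, np.array([9, 1, 2, 1]))
        assert props == 1.0 and ni == 3


class TestChanceCorrection:
    def test_arithmetic(self):
        assert chance_corrected_prop(0.9, (0.5, 0.5, 0), (0.5, 0.5, 0)) == pytest.approx(0.8)

    def test_props_equal_chance_is_zero(self):
        tri = (0.25, 0.5, 0.25)
        chance = sum(p * p for p in tri)
        assert chance_corrected_prop(chance, tri, tri) == pytest.approx(0.0)

    def test_both_fixed_is_nan(self):
        assert np.isnan(chance_corrected_prop(1.0, (1, 0, 0), (1, 0, 0)))

    def test_frequencies_must_sum_to_one(self):
        with pytest.raises(ValueError):
            chance_corrected_prop(0.9, (0.5, 0.2, 0.1), (1, 0, 0))

    def test_not_floored_at_zero(self):
        assert chance_corrected_prop(0.1, (0.25, 0.5, 0.25), (0.25, 0.5, 0.25)) < 0


class TestMetricOracle:
    def _naive_tables(self, truth, imp, ref):
        """Double-loop recomputation of Propi/Cori/Props/cProps."""
        n, m = truth.shape
        propi, cori = [], []
        for j in range(n):
            num = den = 0
            tv, iv = [], []
            for s in range(m):
                if truth[j, s] == MISSING:
                    continue
                den += 1
                num += truth[j, s] == imp[j, s]
                tv.append(truth[j, s])
                iv.append(imp[j, s])
            propi.append(num / den if den else np.nan)
            tv, iv = np.array(tv, float), np.array(iv, float)
            if len(tv) >= 2 and tv.std() > 0 and iv.std() > 0:
                cori.append(np.corrcoef(tv, iv)[0, 1])
            else:
                cori.append(np.nan)
        props, cprops = [], []
        for s in range(m):
            num = den = 0
            for j in range(n):
                if truth[j, s] == MISSING:
                    continue
                den += 1
                num += truth[j, s] == imp[j, s]
            p = num / den if den else np.nan
            props.append(p)
            ref_col = ref[:, s]
            p_ref = [np.mean(ref_col == g) for g in (0, 1, 2)]
            called = truth[:, s] != MISSING
            if called.sum():
                q_val = [np.mean(imp[called, s] == g) for g in (0, 1, 2)]
            else:
                q_val = [1, 0, 0]
            chance = sum(a * b for a, b in zip(p_ref, q_val))
            cprops.append((p - chance) / (1 - chance) if chance < 1 - 1e-12 else np.nan)
        return np.array(propi), np.array(cori), np.array(props), np.array(cprops)

    def test_vectorised_tables_match_double_loop(self):
        rng = np.random.default_rng(123)
        for _ in range(20):
            truth = rng.integers(0, 3, (20, 50)).astype(np.int8)
            truth[rng.random(truth.shape) < 0.1] = MISSING
            imp = rng.integers(0, 3, (20, 50)).astype(np.int8)
            ref = rng.integers(0, 3, (20, 50)).astype(np.int8)
            t_gm = make_gm(truth)
            i_gm = make_gm(imp)
            r_gm = make_gm(ref)
            loo = LOOResult(truth=t_gm, imputed=i_gm, imputed_haps=None,
                            provenance=np.zeros_like(truth, dtype=np.uint8))
            qi = quality_by_individual(loo)
            qs = quality_by_snp(loo, r_gm)
            propi, cori, props, cprops = self._naive_tables(truth, imp, ref)
            np.testing.assert_allclose(qi["Propi"].to_numpy(), propi, atol=1e-12)
            np.testing.assert_allclose(qi["Cori"].to_numpy(), cori, atol=1e-12)
            np.testing.assert_allclose(qs["Props"].to_numpy(), props, atol=1e-12)
            np.testing.assert_allclose(qs["cProps"].to_numpy(), cprops, atol=1e-12)

    def test_total_matches_conserved(self):
        # aggregation identity: summed matches agree between the two grains
        rng = np.random.default_rng(5)
        truth = rng.integers(0, 3, (10, 30)).astype(np.int8)
        imp = rng.integers(0, 3, (10, 30)).astype(np.int8)
        t_gm = make_gm(truth)
        loo = LOOResult(truth=t_gm, imputed=make_gm(imp), imputed_haps=None,
                        provenance=np.zeros_like(truth, dtype=np.uint8))
        qi = quality_by_individual(loo)
        qs = quality_by_snp(loo, t_gm)
        by_ind = (qi["Propi"] * 30).sum()
        by_snp = (qs["Props"] * qs["Ni"]).sum()
        assert by_ind == pytest.approx(by_snp)


class TestLOO:
    def test_fold_count_and_chip_passthrough(self, small_study):
        ref = small_study.haps_ref.take_samples(small_study.reference_ids[:3])
        chip = small_study.chip_truth_all.take_samples(ref.samples)
        calls = []

        class CountingImputer(FrequencyFillImputer):
            def fit(self, reference, pedigree=None):
                calls.append(len(reference.samples))
                return super().fit(reference, pedigree)

        loo = loo_cross_validate(ref, chip, small_study.pedigree,
                                 CountingImputer(), seed=3)
        assert len(calls) == 3  # one imputation run per reference individual
        assert all(c == 2 for c in calls)
        # held-out chip genotypes appear unchanged in the imputed rows
        from pedimpute.imputers import target_site_indices

        idx = target_site_indices(ref, chip)
        observed = chip.dosage != MISSING
        assert np.array_equal(
            loo.imputed.dosage[:, idx][observed], chip.dosage[observed]
        )
        # truth equals the pre-masking sequence matrix
        assert np.array_equal(loo.truth.dosage, ref.dosage())

    def test_extra_targets_imputed_every_fold(self, small_study):
        ref = small_study.haps_ref.take_samples(small_study.reference_ids[:3])
        extra = [small_study.reference_ids[4]]
        chip = small_study.chip_truth_all.take_samples(ref.samples + extra)
        loo = loo_cross_validate(ref, chip, small_study.pedigree,
                                 FrequencyFillImputer(), seed=3, extra_ids=extra)
        assert loo.extra_imputed is not None
        assert loo.extra_imputed.samples == extra
        assert (loo.extra_imputed.dosage != MISSING).all()


class TestSelection:
    def test_strict_thresholds(self):
        qt = pd.DataFrame(
            {
                "chrom": ["c"] * 4,
                "pos": [1, 2, 3, 4],
                "Props": [0.95, 0.95, 0.90, 0.95],
                "cProps": [0.85, 0.80, 0.85, np.nan],
            }
        )
        out = select_high_quality_snps(qt)
        assert list(out["pos"]) == [1]


class TestQualitativeStructure:
    def test_family_ld_dominates_lower_bound(self, study_scale_run):
        qi = study_scale_run["ev"]["individual"]
        merged = qi.dropna(subset=["Propi", "lbPropi"])
        assert (merged["Propi"] - merged["lbPropi"]).mean() > 0
        # strict for progenies of sequenced parents
        prog = merged[merged["class"].str.contains("progenies")]
        assert (prog["Propi"] > prog["lbPropi"]).mean() > 0.95

    def test_relatedness_ordering(self, study_scale_run):
        qi = study_scale_run["ev"]["individual"]
        g = qi.groupby("class")["Propi"].mean()
        prog = (g["Factorial_progenies"] + g["MultiplePair_progenies"]) / 2
        par = (g["Factorial_parents"] + g["MultiplePair_parents"]) / 2
        assert prog > par > g["Unrelated"]

    def test_propi_cori_strongly_correlated(self, study_scale_run):
        qi = study_scale_run["ev"]["individual"].dropna(subset=["Propi", "Cori"])
        assert qi["Propi"].corr(qi["Cori"]) > 0.8
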