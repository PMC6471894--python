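"""Generator behaviour: pedigree structure, founder LD, gene dropping,
chip selection and the error/depth models."""

import numpy as np
import pytest

from pedimpute.core import MISSING
from pedimpute.filtering import mendelian_violations
from pedimpute.ld import dprime
from pedimpute.simulate import (
    Cross,
    DepthSpec,
    SimConfig,
    StudyDesign,
    add_genotype_errors,
    build_pedigree,
    default_design,
    gene_drop,
    reference_individuals,
    select_chip_subset,
    simulate_depth_qual,
    simulate_founder_haplotypes,
    simulate_study,
)


class TestBuildPedigree:
    def test_study_shaped_counts(self):
        design = default_design()
        ped = build_pedigree(design)
        assert len(ped) == 1039
        classes = [ped.klass(i) for i in ped.ids()]
        assert classes.count("Factorial_progenies") == 413
        assert classes.count("MultiplePair_progenies") == 598
        assert classes.count("Unrelated") == 6
        ref = reference_individuals(ped, design)
        assert len(ref) == 43
        # every parent has at least one sequenced offspring
        ref_set = set(ref)
        parents = {p for i in ped.ids() for p in ped.parents_of(i) if p}
        for parent in parents - {"GP1"}:
            assert any(k in ref_set for k in ped.offspring_of(parent)), parent

    def test_minimal_design(self, tiny_design):
        ped = build_pedigree(tiny_design)
        # 2 parents + 4 progenies + 2 unrelated
        assert len(ped) == 8
        assert sum(ped.klass(i) == "Factorial_progenies" for i in ped.ids()) == 4

    def test_unknown_parent_in_cross_errors(self, tiny_design):
        tiny_design.factorial_crosses.append(Cross("F1", "GHOST", 2))
        with pytest.raises(ValueError, match="unknown parent"):
            build_pedigree(tiny_design)


class TestFounderHaplotypes:
    def test_no_ld_when_rho_zero(self):
        cfg = SimConfig(n_chrom=1, n_seq_sites=1000, ld_rho=0.0, seed=1)
        pool = simulate_founder_haplotypes(cfg, n_haplotypes=200)
        h = pool.hap.astype(float)
        poly = (h.mean(axis=0) > 0.05) & (h.mean(axis=0) < 0.95)
        idx = np.flatnonzero(poly)[:200]
        r = [
            abs(np.corrcoef(h[:, i], h[:, j])[0, 1])
            for i, j in zip(idx[:-1], idx[1:])
        ]
        assert np.mean(r) < 0.1

    def test_adjacent_ld_exceeds_distant_when_rho_high(self):
        cfg = SimConfig(n_chrom=1, n_seq_sites=1000, ld_rho=0.9, seed=2)
        pool = simulate_founder_haplotypes(cfg, n_haplotypes=200)
        h = pool.hap
        maf = np.minimum(pool.freq, 1 - pool.freq)
        ok = np.flatnonzero(maf > 0.1)
        adj = [dprime(h[:, i], h[:, i + 1]) for i in ok[:150] if i + 1 < h.shape[1]]
        far = [dprime(h[:, i], h[:, i + 150]) for i in ok[:150] if i + 150 < h.shape[1]]
        assert np.nanmean(adj) > np.nanmean(far)

    def test_seed_reproducibility(self):
        cfg = SimConfig(n_chrom=1, n_seq_sites=500, seed=5)
        a = simulate_founder_haplotypes(cfg, 20)
        b = simulate_founder_haplotypes(cfg, 20)
        assert np.array_equal(a.hap, b.hap)
        assert np.array_equal(a.sites["pos"], b.sites["pos"])

    def test_heterozygosity_matches_frequencies(self):
        # founder-site heterozygosity ~ 2p(1-p) across sites
        cfg = SimConfig(n_chrom=1, n_seq_sites=5000, ld_rho=0.0, seed=9)
        pool = simulate_founder_haplotypes(cfg, n_haplotypes=400)
        h = pool.hap.reshape(200, 2, -1)
        het = (h[:, 0] != h[:, 1]).mean(axis=0)
        p = pool.hap.mean(axis=0)
        expected = 2 * p * (1 - p)
        # aggregate chi-square goodness of fit over frequency bins
        resid = het - expected
        assert abs(resid.mean()) < 0.01


class TestGeneDrop:
    def test_trio_zero_recombination_copies_parent_haplotypes(self, trio_pedigree):
        cfg = SimConfig(n_chrom=1, n_seq_sites=200, recomb_rate=1e-9, seed=3)
        pool = simulate_founder_haplotypes(cfg, n_haplotypes=4)
        hs = gene_drop(trio_pedigree, pool, cfg)
        kid = hs.hap[hs.samples.index("kid1")]
        sire = hs.hap[hs.samples.index("sire1")]
        dam = hs.hap[hs.samples.index("dam1")]
        assert any(np.array_equal(kid[0], sire[k]) for k in (0, 1))
        assert any(np.array_equal(kid[1], dam[k]) for k in (0, 1))

    def test_mendelian_consistent_by_construction(self, small_study):
        gm = small_study.haps_ref.to_genotype_matrix()
        bad = mendelian_violations(gm, small_study.pedigree)
        assert not bad.any()

    def test_poisson_crossover_mean(self):
        # 1 cM/Mb on a 50 Mb chromosome -> 0.5 crossovers per gamete
        from pedimpute.simulate import _gamete

        rng = np.random.default_rng(12)
        pos = np.linspace(1, 50_000_000, 500).astype(np.int64)
        parent = np.zeros((2, 500), dtype=np.uint8)
        parent[1] = 1  # haplotype identity readable from the alleles
        switches = 0
        n = 1000
        for _ in range(n):
            g = _gamete(parent, pos, 50_000_000, 1.0, rng)
            switches += (np.diff(g.astype(int)) != 0).sum()
        assert switches / n == pytest.approx(0.5, abs=0.08)

    def test_pool_too_small_errors(self, trio_pedigree):
        cfg = SimConfig(n_chrom=1, n_seq_sites=50, seed=3)
        pool = simulate_founder_haplotypes(cfg, n_haplotypes=2)
        with pytest.raises(ValueError, match="founder haplotypes"):
            gene_drop(trio_pedigree, pool, cfg)


class TestChipSelection:
    def test_chip_subset_of_seq(self, small_study):
        chip_keys = set(
            zip(small_study.chip_all.sites["chrom"], small_study.chip_all.sites["pos"])
        )
        seq_keys = set(
            zip(small_study.seq_ref.sites["chrom"], small_study.seq_ref.sites["pos"])
        )
        assert chip_keys <= seq_keys

    def test_even_spacing_beats_random_subset(self, small_config):
        cfg = small_config
        cfg.chip_density_alpha = None  # heterogeneity off: even spacing
        study = simulate_study(cfg)
        pos = study.chip_all.sites["pos"].to_numpy()
        gaps = np.diff(pos)
        cv_chip = gaps.std() / gaps.mean()
        rng = np.random.default_rng(0)
        cvs = []
        for _ in range(30):
            sub = np.sort(
                rng.choice(study.seq_ref.sites["pos"].to_numpy(), len(pos), replace=False)
            )
            g = np.diff(sub)
            cvs.append(g.std() / g.mean())
        assert cv_chip < np.mean(cvs)

    def test_maf_floor_too_high_errors(self, small_study, small_config):
        small_config.chip_maf_floor = 0.5
        with pytest.raises(ValueError, match="shortfall|MAF"):
            select_chip_subset(small_study.haps_ref, small_config)


class TestDepthAndErrors:
    def test_fixed_depth_mean(self, small_study, small_config):
        small_config.depth = DepthSpec(mean=13.0, sigma=0.0)
        gm = simulate_depth_qual(small_study.seq_ref, small_config)
        assert gm.sample_depth.mean() == pytest.approx(13.0, rel=0.1)
        assert (gm.sites["qual"] >= 0).all()

    def test_zero_depth_masks_genotype(self, small_study, small_config):
        small_config.depth = DepthSpec(mean=0.5, sigma=0.0, low=0.1)
        gm = simulate_depth_qual(
            small_study.seq_ref, small_config, missing_at_zero_depth=True
        )
        assert ((gm.depth == 0) == (gm.dosage == MISSING)).all()

    def test_error_rate_zero_identity(self, small_study):
        out = add_genotype_errors(small_study.chip_truth_all, 0.0, seed=1)
        assert np.array_equal(out.dosage, small_study.chip_truth_all.dosage)

    def test_missing_rate_binomial_count(self):
        from conftest import make_gm

        gm = make_gm(np.ones((100, 100), dtype=np.int8))
        out = add_genotype_errors(gm, 0.0, missing_rate=0.01, seed=42)
        n_missing = (out.dosage == MISSING).sum()
        assert 60 <= n_missing <= 140  # ~Binomial(10000, 0.01)

    def test_error_rate_half_rejected(self, small_study):
        with pytest.raises(ValueError):
            add_genotype_errors(small_study.chip_truth_all, 0.5)

    def test_errors_change_dosage_to_different_value(self):
        from conftest import make_gm

        gm = make_gm(np.full((50, 50), 1, dtype=np.int8))
        out = add_genotype_errors(gm, 0.3, seed=2)
        changed = out.dosage != 1
        assert changed.any()
        assert set(np.unique(out.dosage[changed])) <= {0, 2}


class TestDeterminism:
    def test_simulate_study_bit_identical(self, small_config):
        a = simulate_study(small_config)
        b = simulate_study(small_config)
        assert np.array_equal(a.haps_ref.hap, b.haps_ref.hap)
        assert np.array_equal(a.chip_all.dosage, b.chip_all.dosage)
        assert np.array_equal(a.seq_ref.depth, b.seq_ref.depth)


class TestRelatednessStructure:
    def test_progenies_share_longer_segments_with_parents(self, small_study):
        # identical-segment sharing: progeny vs its parent exceeds progeny vs
        # an unrelated founder
        hs = small_study.haps_ref
        ped = small_study.pedigree
        ids = hs.samples

        def longest_match(a, b):
            eq = a == b
            best = cur = 0
            for v in eq:
                cur = cur + 1 if v else 0
                best = max(best, cur)
            return best

        rows = []
        for iid in ids:
            sire, dam = ped.parents_of(iid)
            if sire in ids and dam in ids:
                kid_h = hs.hap[ids.index(iid)]
                par_h = hs.hap[ids.index(sire)]
                unrel_h = hs.hap[ids.index("U1")]
                par_best = max(
                    longest_match(kid_h[0], par_h[k]) for k in (0, 1)
                )
                unrel_best = max(
                    longest_match(kid_h[0], unrel_h[k]) for k in (0, 1)
                )
                rows.append((par_best, unrel_best))
        assert rows, "no full trios in reference"
        par, unrel = np.array(rows).T
        assert par.mean() > unrel.mean()
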