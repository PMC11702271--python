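import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import _oracles as oracles
from conftest import make_genotypes
from prsbench.geno_io import RegionSet, SummaryStats, WeightFile
from prsbench.prs_engine import (
    AlignedWeights,
    ClumpParams,
    DEFAULT_PT_GRID,
    clump,
    ct_pipeline,
    external_scores,
    harmonize,
    ld_r2,
    restrict_region,
    score,
    threshold,
)


def sumstats_for(gm, beta=None, p=None, flip=None, swap_to_mismatch=None):
    """Summary statistics matching a GenotypeMatrix, with optional allele games."""
    m = gm.n_variants
    beta = np.asarray(beta if beta is not None else np.linspace(0.1, 0.5, m))
    p = np.asarray(p if p is not None else np.full(m, 0.01))
    rows = []
    for j, v in enumerate(gm.variants):
        ea, oa = v.alt, v.ref
        if flip and j in flip:
            ea, oa = oa, ea
        if swap_to_mismatch and j in swap_to_mismatch:
            ea = "C" if ea != "C" else "T"
        rows.append(
            {
                "chrom": v.chrom,
                "pos": v.pos,
                "id": v.id,
                "effect_allele": ea,
                "other_allele": oa,
                "beta": -beta[j] if (flip and j in flip) else beta[j],
                "se": 0.05,
                "p": p[j],
            }
        )
    return SummaryStats(table=pd.DataFrame(rows))


class TestHarmonize:
    def test_ref_effect_allele_flips_sign(self, toy_genotypes):
        ss = sumstats_for(toy_genotypes, beta=[0.3, 0.1, 0.1, 0.1])
        ss.table.loc[0, ["effect_allele", "other_allele"]] = [
            toy_genotypes.variants[0].ref,
            toy_genotypes.variants[0].alt,
        ]
        aw = harmonize(ss, toy_genotypes)
        assert aw.beta[0] == pytest.approx(-0.3)
        assert aw.log["flipped"] == 1

    def test_ambiguous_pair_dropped_when_flagged(self, toy_genotypes):
        ss = sumstats_for(toy_genotypes)
        ss.table.loc[1, ["effect_allele", "other_allele"]] = ["A", "T"]
        aw = harmonize(ss, toy_genotypes, drop_ambiguous=True)
        assert aw.log["ambiguous"] == 1 and len(aw) == 3
        aw2 = harmonize(ss, toy_genotypes, drop_ambiguous=False)
        # unflagged: the A/T pair no longer matches this variant's alleles
        assert len(aw2) <= 4

    def test_six_variant_counts_by_hand(self):
        rng = np.random.default_rng(0)
        gm = make_genotypes(rng.binomial(2, 0.4, size=(10, 6)).astype(float))
        ss = sumstats_for(gm, flip={2}, swap_to_mismatch={5})
        aw = harmonize(ss, gm)
        assert aw.log["matched"] == 5
        assert aw.log["flipped"] == 1
        assert aw.log["mismatch"] == 1

    def test_zero_matches_fatal(self, toy_genotypes):
        ss = sumstats_for(toy_genotypes)
        ss.table["pos"] = ss.table["pos"] + 7  # no coordinate matches
        with pytest.raises(ValueError, match="zero matches"):
            harmonize(ss, toy_genotypes)


class TestLdR2:
    def test_identical_columns(self, toy_genotypes):
        gm = make_genotypes(np.column_stack([toy_genotypes.dosage[:, 0]] * 2))
        assert ld_r2(gm, 0, 1) == pytest.approx(1.0)

    def test_mirror_column(self):
        col = np.array([0.0, 1.0, 2.0, 1.0, 0.0])
        gm = make_genotypes(np.column_stack([col, 2 - col]))
        assert ld_r2(gm, 0, 1) == pytest.approx(1.0)

    def test_closed_form_pearson(self):
        a = np.array([0.0, 1.0, 2.0, 1.0, 0.0])
        b = np.array([1.0, 1.0, 0.0, 2.0, 0.0])
        gm = make_genotypes(np.column_stack([a, b]))
        assert ld_r2(gm, 0, 1) == pytest.approx(oracles.pearson_r2(a, b), abs=1e-12)

    def test_constant_column_rejected(self):
        gm = make_genotypes(np.column_stack([np.ones(5), np.arange(5) % 3]).astype(float))
        with pytest.raises(ValueError, match="variance"):
            ld_r2(gm, 0, 1)


def _correlated_matrix(rng, n, m, rho=0.6):
    """Dosage matrix with tunable neighbour correlation for clump tests."""
    z = rng.standard_normal((n, m))
    for j in range(1, m):
        z[:, j] = rho * z[:, j - 1] + np.sqrt(1 - rho**2) * z[:, j]
    return (z > 0).astype(float) + (z > 1).astype(float)


class TestClump:
    def test_single_variant_retained(self, toy_genotypes):
        aw = AlignedWeights(index=np.array([0]), beta=np.array([0.1]), p=np.array([0.01]), se=None)
        out = clump(aw, toy_genotypes, ClumpParams())
        assert list(out.index) == [0]

    def test_three_variant_derived_instance(self):
        # p = (1e-10, 1e-5, 1e-3); r2(1,2)=0.5 removes variant 2; variant 3 at
        # low LD with both survives -> retained {1, 3} (as original indices 0, 2)
        rng = np.random.default_rng(42)
        n = 4000
        a = rng.binomial(1, 0.5, n) + rng.binomial(1, 0.5, n)
        hap = (a / 2 > rng.random(n)).astype(float)
        b = np.clip(a * 0.0 + np.where(rng.random(n) < 0.85, a, rng.binomial(2, 0.5, n)), 0, 2)
        c = rng.binomial(2, 0.4, n).astype(float)
        gm = make_genotypes(np.column_stack([a, b, c]).astype(float))
        r12 = ld_r2(gm, 0, 1)
        r13 = ld_r2(gm, 0, 2)
        assert r12 > 0.1 and r13 < 0.1  # instance construction check
        aw = AlignedWeights(
            index=np.arange(3),
            beta=np.array([0.5, 0.4, 0.3]),
            p=np.array([1e-10, 1e-5, 1e-3]),
            se=None,
        )
        out = clump(aw, gm, ClumpParams(r2_max=0.1, window_kb=1000))
        assert list(out.index) == [0, 2]

    def test_no_ld_retains_everything(self):
        rng = np.random.default_rng(1)
        gm = make_genotypes(rng.binomial(2, 0.5, size=(2000, 6)).astype(float))
        aw = AlignedWeights(
            index=np.arange(6), beta=np.ones(6), p=rng.uniform(size=6), se=None
        )
        out = clump(aw, gm, ClumpParams(r2_max=0.1))
        assert len(out) == 6

    def test_r2max_one_retains_input(self):
        rng = np.random.default_rng(2)
        gm = make_genotypes(_correlated_matrix(rng, 500, 8, rho=0.9))
        aw = AlignedWeights(index=np.arange(8), beta=np.ones(8), p=rng.uniform(size=8), se=None)
        out = clump(aw, gm, ClumpParams(r2_max=1.0))
        assert len(out) == 8

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_bruteforce_oracle(self, seed):
        # <= 12-variant instances with real LD: greedy result must match the
        # explicit-loop reference implementation exactly
        rng = np.random.default_rng(seed)
        m = int(rng.integers(4, 13))
        gm = make_genotypes(
            _correlated_matrix(rng, 800, m, rho=0.7),
            positions=np.sort(rng.choice(np.arange(1000, 2_000_000, 1000), m, replace=False)),
        )
        p = rng.uniform(size=m)
        aw = AlignedWeights(index=np.arange(m), beta=np.ones(m), p=p, se=None)
        params = ClumpParams(r2_max=0.2, window_kb=500)
        got = sorted(clump(aw, gm, params).index.tolist())
        r2 = np.zeros((m, m))
        for i in range(m):
            for j in range(m):
                if i != j:
                    try:
                        r2[i, j] = ld_r2(gm, i, j)
                    except ValueError:
                        r2[i, j] = 0.0
        pos = [v.pos for v in gm.variants]
        expected = oracles.clump_greedy(p, pos, ["1"] * m, r2, 0.2, 500_000)
        assert got == expected

    def test_row_order_invariance(self):
        rng = np.random.default_rng(3)
        m = 10
        gm = make_genotypes(_correlated_matrix(rng, 600, m, rho=0.8))
        p = rng.uniform(size=m)
        aw = AlignedWeights(index=np.arange(m), beta=np.ones(m), p=p, se=np.full(m, 0.1))
        perm = rng.permutation(m)
        aw_perm = AlignedWeights(index=perm, beta=np.ones(m), p=p[perm], se=np.full(m, 0.1))
        a = set(clump(aw, gm, ClumpParams()).index.tolist())
        b = set(clump(aw_perm, gm, ClumpParams()).index.tolist())
        assert a == b


class TestThreshold:
    def test_inclusive_boundary(self):
        aw = AlignedWeights(
            index=np.arange(3),
            beta=np.ones(3),
            p=np.array([5e-8, 3e-8, 0.2]),
            se=None,
        )
        assert len(threshold(aw, 5e-8)) == 2

    def test_pt_one_is_identity_and_below_all_empty(self):
        aw = AlignedWeights(index=np.arange(4), beta=np.ones(4), p=np.array([0.2, 0.5, 0.9, 1.0]), se=None)
        assert len(threshold(aw, 1.0)) == 4
        assert len(threshold(aw, 1e-10)) == 0

    def test_nested_across_increasing_pt(self, small_cohort):
        gm = small_cohort.genotypes
        aw = harmonize(small_cohort.sumstats_a, gm)
        sets = [set(threshold(aw, pt).index.tolist()) for pt in DEFAULT_PT_GRID]
        for a, b in zip(sets, sets[1:]):
            assert a <= b


class TestRestrictRegion:
    def test_inclusive_bounds_apoe_region(self, toy_genotypes):
        from prsbench.apoe import apoe_region

        gm = make_genotypes(
            np.zeros((3, 3)),
            positions=[43_900_000, 46_000_000, 46_000_001],
            chroms=["19"] * 3,
        )
        aw = AlignedWeights(index=np.arange(3), beta=np.ones(3), p=np.full(3, 0.1), se=None)
        out = restrict_region(aw, gm, apoe_region(), mode="exclude")
        assert list(out.index) == [2]

    def test_include_exclude_partition(self, small_cohort):
        from prsbench.apoe import apoe_region

        gm = small_cohort.genotypes
        aw = harmonize(small_cohort.sumstats_a, gm)
        inc = set(restrict_region(aw, gm, apoe_region(), "include").index.tolist())
        exc = set(restrict_region(aw, gm, apoe_region(), "exclude").index.tolist())
        assert inc | exc == set(aw.index.tolist())
        assert inc & exc == set()


class TestScore:
    def test_arithmetic_cancellation(self):
        gm = make_genotypes(np.array([[2.0, 1.0]]))
        aw = AlignedWeights(index=np.arange(2), beta=np.array([0.1, -0.2]), p=None, se=None)
        assert score(gm, aw).values[0] == pytest.approx(0.0)

    def test_zero_weights_zero_scores(self, toy_genotypes):
        aw = AlignedWeights(index=np.arange(4), beta=np.zeros(4), p=None, se=None)
        assert np.all(score(toy_genotypes, aw).values == 0.0)

    def test_missing_dosage_mean_imputed_hand_computation(self):
        dosage = np.array(
            [
                [0.0, 2.0, 1.0],
                [1.0, np.nan, 0.0],
                [2.0, 1.0, 2.0],
            ]
        )
        gm = make_genotypes(dosage)
        beta = np.array([0.5, 1.0, -1.0])
        aw = AlignedWeights(index=np.arange(3), beta=beta, p=None, se=None)
        got = score(gm, aw).values
        imputed = (2.0 + 1.0) / 2  # mean of the non-missing dosages
        expected = np.array(
            [
                0.5 * 0 + 1.0 * 2 - 1.0 * 1,
                0.5 * 1 + 1.0 * imputed - 1.0 * 0,
                0.5 * 2 + 1.0 * 1 - 1.0 * 2,
            ]
        )
        np.testing.assert_allclose(got, expected, atol=1e-12)

    def test_empty_weight_set_scores_zero(self, toy_genotypes):
        aw = AlignedWeights(index=np.array([], dtype=int), beta=np.array([]), p=None, se=None)
        s = score(toy_genotypes, aw)
        assert s.n_snps == 0 and np.all(s.values == 0.0)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_linearity_in_weights(self, seed):
        rng = np.random.default_rng(seed)
        gm = make_genotypes(rng.binomial(2, 0.4, size=(6, 5)).astype(float))
        b1, b2 = rng.normal(size=5), rng.normal(size=5)
        aw = lambda b: AlignedWeights(index=np.arange(5), beta=b, p=None, se=None)
        np.testing.assert_allclose(
            score(gm, aw(b1 + b2)).values,
            score(gm, aw(b1)).values + score(gm, aw(b2)).values,
            atol=1e-10,
        )

    def test_allele_coding_flip_invariance(self):
        rng = np.random.default_rng(9)
        gm = make_genotypes(rng.binomial(2, 0.4, size=(8, 5)).astype(float))
        ss = sumstats_for(gm)
        ss_flipped = sumstats_for(gm, flip=set(range(5)))
        a = score(gm, harmonize(ss, gm)).values
        b = score(gm, harmonize(ss_flipped, gm)).values
        np.testing.assert_allclose(a, b, atol=1e-12)


class TestCtPipeline:
    def test_grid_of_eight_gives_eight_scoresets(self, small_cohort):
        sets = ct_pipeline(small_cohort.sumstats_a, small_cohort.genotypes)
        assert len(sets) == len(DEFAULT_PT_GRID) == 8
        assert all(s.pt == pt for s, pt in zip(sets, DEFAULT_PT_GRID))

    def test_clumped_sets_subset_of_harmonized(self, small_cohort):
        gm = small_cohort.genotypes
        aw = harmonize(small_cohort.sumstats_a, gm)
        cl = clump(aw, gm, ClumpParams())
        assert set(cl.index.tolist()) <= set(aw.index.tolist())

    def test_pt_one_equals_clumped_score(self, small_cohort):
        gm = small_cohort.genotypes
        params = ClumpParams(pt_grid=(0.5, 1.0))
        sets = ct_pipeline(small_cohort.sumstats_a, gm, params)
        aw = harmonize(small_cohort.sumstats_a, gm)
        cl = clump(aw, gm, params)
        np.testing.assert_allclose(sets[-1].values, score(gm, cl).values, atol=1e-12)


class TestExternalScores:
    def _weightfile(self, gm, weights, flip=False):
        rows = []
        for j, v in enumerate(gm.variants):
            ea = v.ref if flip else v.alt
            oa = v.alt if flip else v.ref
            rows.append(
                {
                    "chrom": v.chrom,
                    "pos": v.pos,
                    "id": v.id,
                    "effect_allele": ea,
                    "other_allele": oa,
                    "weight": -weights[j] if flip else weights[j],
                }
            )
        return WeightFile(table=pd.DataFrame(rows))

    def test_consistent_with_direct_scoring(self):
        rng = np.random.default_rng(10)
        gm = make_genotypes(rng.binomial(2, 0.3, size=(10, 4)).astype(float))
        w = rng.normal(size=4)
        aw = AlignedWeights(index=np.arange(4), beta=w, p=None, se=None)
        direct = score(gm, aw).values
        ext = external_scores(gm, self._weightfile(gm, w)).values
        np.testing.assert_allclose(ext, direct, atol=1e-12)

    def test_empty_weight_file_errors(self, toy_genotypes):
        wf = WeightFile(
            table=pd.DataFrame(
                columns=["chrom", "pos", "id", "effect_allele", "weight"]
            )
        )
        with pytest.raises(ValueError, match="empty"):
            external_scores(toy_genotypes, wf)

    def test_sign_flipped_coding_gives_identical_scores(self):
        rng = np.random.default_rng(11)
        gm = make_genotypes(rng.binomial(2, 0.3, size=(10, 5)).astype(float))
        w = rng.normal(size=5)
        a = external_scores(gm, self._weightfile(gm, w)).values
        b = external_scores(gm, self._weightfile(gm, w, flip=True)).values
        np.testing.assert_allclose(a, b, atol=1e-12)
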