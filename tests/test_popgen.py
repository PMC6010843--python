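"""Population-genetic estimators against enumeration and independent oracles."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from chemopop import popgen
from chemopop import synthetic_data as sd
from chemopop.popgen import GenotypeMatrix


# ---------------------------------------------------------------------------
# Oracles
# ---------------------------------------------------------------------------

def hwe_enumeration_oracle(n0, n1, n2):
    """Exact HWE p by brute-force enumeration of allele placements.

    The 2n allele slots (two per diploid) are equally likely to hold any
    subset of size n_minor of minor-allele copies, conditional on the
    allele counts.  Enumerating all C(2n, n_minor) subsets and counting
    heterozygotes per subset gives the exact conditional distribution of
    the heterozygote count, from which the two-sided p is the total mass
    of outcomes no more probable than the observed one.
    """
    n = n0 + n1 + n2
    n_minor = min(2 * n2 + n1, 2 * n0 + n1)
    if n_minor == 0:
        return 1.0
    weights = {}
    total = 0
    for slots in itertools.combinations(range(2 * n), n_minor):
        per_ind = [0] * n
        for s in slots:
            per_ind[s // 2] += 1
        het = sum(1 for c in per_ind if c == 1)
        weights[het] = weights.get(het, 0) + 1
        total += 1
    probs = {h: w / total for h, w in weights.items()}
    obs = probs[n1]
    return sum(p for p in probs.values() if p <= obs * (1 + 1e-12))


def wc_theta_oracle(genotypes_by_pop):
    """Independent multilocus Weir & Cockerham (1984) theta (ratio of sums).

    Written directly from the published variance-component formulas, with
    scalar loops and no shared code with the implementation under test.
    """
    n_loci = genotypes_by_pop[0].shape[1]
    sum_a = sum_abc = 0.0
    for locus in range(n_loci):
        samples = []
        for pop in genotypes_by_pop:
            col = pop[:, locus]
            col = col[~np.isnan(col)]
            if len(col) < 2:
                continue
            n_i = len(col)
            p_i = sum(col) / (2 * n_i)
            h_i = sum(1 for g in col if g == 1) / n_i
            samples.append((n_i, p_i, h_i))
        r = len(samples)
        if r < 2:
            continue
        nbar = sum(s[0] for s in samples) / r
        nc = (r * nbar - sum(s[0] ** 2 for s in samples) / (r * nbar)) / (r - 1)
        pbar = sum(s[0] * s[1] for s in samples) / (r * nbar)
        ssq = sum(s[0] * (s[1] - pbar) ** 2 for s in samples) / ((r - 1) * nbar)
        hbar = sum(s[0] * s[2] for s in samples) / (r * nbar)
        a = (nbar / nc) * (
            ssq - (pbar * (1 - pbar) - (r - 1) / r * ssq - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - (r - 1) / r * ssq - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2
        sum_a += a
        sum_abc += a + b + c
    return sum_a / sum_abc


def make_genotypes(dosage, tag_ids=None, classes=None, positions=None, fst=None):
    dosage = np.asarray(dosage, dtype=float)
    n, m = dosage.shape
    meta = pd.DataFrame({
        "snp_id": [f"s{j}" for j in range(m)],
        "tag_id": tag_ids or [f"t{j}" for j in range(m)],
        "pos_in_tag": positions or [0] * m,
        "selection_class": classes or ["neutral"] * m,
        "fst": fst if fst is not None else [np.nan] * m,
    }).set_index("snp_id")
    return GenotypeMatrix(dosage, meta, [f"i{k}" for k in range(n)])


# ---------------------------------------------------------------------------
# HWE exact test
# ---------------------------------------------------------------------------

class TestHweExact:
    def test_two_individual_hand_case(self):
        # 2 A + 2 a alleles in 2 diploids: P(het=0)=1/3, P(het=2)=2/3
        assert popgen.hwe_exact(1, 0, 1) == pytest.approx(1 / 3)

    def test_monomorphic_returns_one(self):
        assert popgen.hwe_exact(5, 0, 0) == 1.0

    @pytest.mark.parametrize("n", [1, 2, 3, 4])
    def test_all_heterozygote_tables_match_enumeration(self, n):
        assert popgen.hwe_exact(0, n, 0) == pytest.approx(
            hwe_enumeration_oracle(0, n, 0))

    def test_exhaustive_tables_up_to_six_individuals(self):
        # enumeration oracle is exhaustive itself, so keep n modest
        for n in range(1, 7):
            for n0 in range(n + 1):
                for n1 in range(n - n0 + 1):
                    n2 = n - n0 - n1
                    expected = hwe_enumeration_oracle(n0, n1, n2)
                    assert popgen.hwe_exact(n0, n1, n2) == pytest.approx(
                        expected, abs=1e-12), (n0, n1, n2)

    def test_rejects_negative_counts(self):
        with pytest.raises(ValueError):
            popgen.hwe_exact(-1, 2, 3)


# ---------------------------------------------------------------------------
# Filtering and panels
# ---------------------------------------------------------------------------

class TestFilterSnps:
    def grouping(self, g):
        half = g.n_samples // 2
        return pd.Series(["p1"] * half + ["p2"] * (g.n_samples - half),
                         index=g.sample_ids)

    def test_low_maf_removed(self, rng):
        n = 40
        good = rng.binomial(2, 0.5, size=(n, 1)).astype(float)
        rare = np.zeros((n, 1))
        rare[0, 0] = 1  # MAF 1/80 = 0.0125
        g = make_genotypes(np.hstack([good, rare]))
        out, report = popgen.filter_snps(g, self.grouping(g))
        assert out.snp_ids == ["s0"]
        assert report.loc["maf", "n_removed"] == 1

    def test_low_call_rate_removed(self, rng):
        n = 40
        good = rng.binomial(2, 0.5, size=(n, 1)).astype(float)
        gappy = rng.binomial(2, 0.5, size=(n, 1)).astype(float)
        gappy[: n // 4] = np.nan  # 75% call rate
        g = make_genotypes(np.hstack([good, gappy]))
        out, _ = popgen.filter_snps(g, self.grouping(g))
        assert "s1" not in out.snp_ids

    def test_hwe_rule_majority_of_subpops(self):
        # all-het genotypes violate HWE strongly in both subpops
        bad = np.ones((40, 1))
        g = make_genotypes(bad)
        out, report = popgen.filter_snps(g, self.grouping(g))
        assert out.n_snps == 0
        assert report.loc["hwe", "n_removed"] == 1

    def test_hwe_false_positive_rate_near_nominal(self):
        """Loci simulated under HWE should fail the rule at roughly the
        binomial rate implied by the per-test alpha."""
        rng = np.random.default_rng(11)
        n_reps, n_loci = 20, 60
        fail_frac = []
        for _ in range(n_reps):
            dosage = rng.binomial(2, 0.5, size=(60, n_loci)).astype(float)
            g = make_genotypes(dosage)
            out, _ = popgen.filter_snps(g, self.grouping(g), maf_min=0.0,
                                        call_rate_min=0.0)
            fail_frac.append(1 - out.n_snps / n_loci)
        # both-subpop failure needed; exact tests are conservative, so the
        # observed rate should be well below 2*alpha and usually below alpha
        assert np.mean(fail_frac) < 0.08


class TestSelectOneSnpPerTag:
    def test_neutral_keeps_cut_site_proximal(self):
        g = make_genotypes(np.zeros((4, 2)) + [[0, 1]] * 4,
                           tag_ids=["t", "t"], positions=[40, 10])
        neutral, assoc = popgen.select_one_snp_per_tag(g)
        assert assoc.snp_ids == ["s1"]  # position 10 < 40
        assert neutral.snp_ids == ["s1"]

    def test_outlier_keeps_highest_fst(self):
        g = make_genotypes(np.zeros((4, 2)) + [[0, 1]] * 4,
                           tag_ids=["t", "t"], classes=["outlier", "outlier"],
                           positions=[10, 40], fst=[0.1, 0.3])
        neutral, assoc = popgen.select_one_snp_per_tag(g)
        assert assoc.snp_ids == ["s1"]
        assert neutral.n_snps == 0

    def test_single_snp_tag_kept_and_mixed_tag_is_outlier(self):
        g = make_genotypes(
            np.tile([0.0, 1, 0], (4, 1)), tag_ids=["a", "b", "b"],
            classes=["neutral", "neutral", "outlier"], positions=[5, 3, 80],
            fst=[np.nan, 0.02, 0.4])
        neutral, assoc = popgen.select_one_snp_per_tag(g)
        assert set(assoc.snp_ids) == {"s0", "s2"}  # b treated as outlier
        assert neutral.snp_ids == ["s0"]


# ---------------------------------------------------------------------------
# Diversity statistics
# ---------------------------------------------------------------------------

class TestHeterozygosity:
    def test_all_het_locus(self):
        g = make_genotypes(np.ones((10, 1)))
        res = popgen.heterozygosity(g, pd.Series("p", index=g.sample_ids), n_boot=10)
        assert res.loc["p", "Ho"] == pytest.approx(1.0)

    def test_large_n_he_limit(self, rng):
        dosage = rng.binomial(2, 0.5, size=(2000, 1)).astype(float)
        g = make_genotypes(dosage)
        res = popgen.heterozygosity(g, pd.Series("p", index=g.sample_ids), n_boot=10)
        assert res.loc["p", "He"] == pytest.approx(0.5, abs=0.03)

    def test_balding_nichols_expectation(self):
        """Mean He across subpops matches 2p(1-p)(1-F) against the known
        subpopulation frequencies of the generator."""
        cfg = sd.CohortConfig(n_subpops=2, n_regions=1, individuals_per_subpop=60,
                              n_tags=150, snps_per_tag=1, fst_target=0.2,
                              region_differentiation=0.0, outlier_tag_fraction=0.0,
                              missing_rate=0.0, seed=5)
        g, truth = sd.simulate_genotypes(cfg)
        grouping = pd.Series([s.rsplit("_", 1)[0] for s in g.sample_ids],
                             index=g.sample_ids)
        res = popgen.heterozygosity(g, grouping, n_boot=10)
        # per-subpop expectation uses the realized subpop frequencies
        for sp in res.index:
            freqs = truth.subpop_freqs.loc[sp].to_numpy()
            expected = (2 * freqs * (1 - freqs)).mean()
            assert res.loc[sp, "He"] == pytest.approx(expected, abs=0.02)


class TestNucleotideDiversity:
    def test_single_tag_hand_value(self, rng):
        # choose p so sample-size-corrected He is ~0.45: solve on realized data
        dosage = rng.binomial(2, 0.35, size=(50, 1)).astype(float)
        g = make_genotypes(dosage)
        grouping = pd.Series("p", index=g.sample_ids)
        he = popgen.heterozygosity(g, grouping, n_boot=2).loc["p", "He"]
        pi = popgen.nucleotide_diversity(g, grouping).loc["p", "pi"]
        assert pi == pytest.approx(he / 90)

    def test_no_variable_sites_zero(self):
        g = make_genotypes(np.zeros((10, 2)))
        pi = popgen.nucleotide_diversity(g, pd.Series("p", index=g.sample_ids))
        assert pi.loc["p", "pi"] == 0.0

    def test_doubling_tags_halves_pi(self, rng):
        dosage = rng.binomial(2, 0.4, size=(30, 1)).astype(float)
        g1 = make_genotypes(dosage, tag_ids=["t0"])
        g2 = make_genotypes(np.hstack([dosage, np.zeros((30, 1))]),
                            tag_ids=["t0", "t1"])
        grouping = pd.Series("p", index=g1.sample_ids)
        pi1 = popgen.nucleotide_diversity(g1, grouping).loc["p", "pi"]
        pi2 = popgen.nucleotide_diversity(g2, grouping).loc["p", "pi"]
        assert pi2 == pytest.approx(pi1 / 2)


class TestRarefiedAllelicRichness:
    def test_three_one_counts_enumeration(self):
        """counts (3,1), g=2: all six 2-subsets average 9/6 distinct alleles."""
        assert popgen.allelic_richness_from_counts([3, 1], 2) == pytest.approx(1.5)

    def test_monomorphic_is_one(self):
        assert popgen.allelic_richness_from_counts([8, 0], 4) == pytest.approx(1.0)

    def test_full_sample_recovers_observed_count(self):
        assert popgen.allelic_richness_from_counts([5, 3], 8) == pytest.approx(2.0)

    def test_matches_monte_carlo_subsampling(self, rng):
        counts = np.array([11, 7])
        g = 6
        pool = np.repeat([0, 1], counts)
        draws = 10000
        distinct = np.empty(draws)
        for d in range(draws):
            distinct[d] = len(np.unique(rng.choice(pool, size=g, replace=False)))
        mc, se = distinct.mean(), distinct.std(ddof=1) / math.sqrt(draws)
        exact = popgen.allelic_richness_from_counts(counts, g)
        assert abs(exact - mc) < 3 * se + 1e-9

    def test_rejects_tiny_g(self):
        with pytest.raises(ValueError):
            popgen.allelic_richness_from_counts([4, 4], 1)

    def test_matrix_interface(self, small_cohort, small_grouping):
        res = popgen.rarefied_allelic_richness(small_cohort.genotypes, small_grouping)
        assert ((res["allelic_richness"] >= 1) & (res["allelic_richness"] <= 2)).all()


class TestInbreedingF:
    def test_fully_homozygous_individual(self, rng):
        dosage = rng.binomial(2, 0.5, size=(30, 50)).astype(float)
        dosage[0] = np.round(dosage[0] / 2) * 2  # strip hets from individual 0
        g = make_genotypes(dosage)
        res = popgen.inbreeding_f(g)
        assert res.iloc[0]["F"] == pytest.approx(1.0)

    def test_selfed_offspring_recover_half(self):
        """Selfing one generation from HWE parents gives expected F = 0.5."""
        rng = np.random.default_rng(21)
        est = []
        for _ in range(20):
            p = rng.uniform(0.2, 0.8, size=300)
            parents = rng.binomial(2, p, size=(150, 300)).astype(float)
            # selfing: the child draws each of its two alleles independently
            # from the same parent's genotype
            a1 = (rng.random(parents.shape) < parents / 2).astype(float)
            a2 = (rng.random(parents.shape) < parents / 2).astype(float)
            offspring = a1 + a2
            both = np.vstack([parents, offspring])
            g = make_genotypes(both)
            res = popgen.inbreeding_f(g)
            est.append(res.iloc[150:]["F"].mean())
        # offspring of selfing have F = 0.5 relative to the parental pool;
        # pooling parents+offspring shifts frequencies little at n=300 loci
        assert np.mean(est) == pytest.approx(0.5, abs=0.06)

    def test_short_profile_flagged_unreliable(self, rng):
        dosage = rng.binomial(2, 0.5, size=(5, 10)).astype(float)
        g = make_genotypes(dosage)
        assert not popgen.inbreeding_f(g)["reliable"].any()


class TestIbsMatrix:
    def test_identical_and_opposite(self):
        dosage = np.array([[0, 0, 0], [0, 0, 0], [2, 2, 2]], dtype=float)
        g = make_genotypes(dosage)
        k = popgen.ibs_matrix(g)
        assert k.iloc[0, 1] == 1.0
        assert k.iloc[0, 2] == 0.0

    def test_one_het_difference(self):
        a = np.zeros(10)
        b = np.zeros(10)
        b[0] = 1.0
        g = make_genotypes(np.vstack([a, b]))
        assert popgen.ibs_matrix(g).iloc[0, 1] == pytest.approx(0.95)

    def test_symmetry_and_permutation_consistency(self, rng):
        dosage = rng.binomial(2, 0.5, size=(8, 30)).astype(float)
        g = make_genotypes(dosage)
        k = popgen.ibs_matrix(g).to_numpy()
        assert np.allclose(k, k.T)
        assert np.allclose(np.diag(k), 1.0)
        perm = rng.permutation(8)
        g2 = make_genotypes(dosage[perm])
        k2 = popgen.ibs_matrix(g2).to_numpy()
        assert np.allclose(k2, k[np.ix_(perm, perm)])

    def test_no_shared_locus_errors(self):
        dosage = np.array([[0.0, np.nan], [np.nan, 1.0]])
        g = make_genotypes(dosage)
        with pytest.raises(ValueError, match="share no genotyped locus"):
            popgen.ibs_matrix(g)


# ---------------------------------------------------------------------------
# F_ST
# ---------------------------------------------------------------------------

class TestFst:
    def test_identical_subpopulations_near_zero(self, rng):
        block = rng.binomial(2, rng.uniform(0.2, 0.8, 40), size=(30, 40)).astype(float)
        g = make_genotypes(np.vstack([block, block]))
        grouping = pd.Series(["p1"] * 30 + ["p2"] * 30, index=g.sample_ids)
        lin = popgen.pairwise_fst(g, grouping)
        assert lin.loc["p1", "p2"] == pytest.approx(0.0, abs=1e-9)

    def test_fixed_differences_capped(self):
        g = make_genotypes(np.vstack([np.zeros((10, 5)), np.full((10, 5), 2.0)]))
        grouping = pd.Series(["p1"] * 10 + ["p2"] * 10, index=g.sample_ids)
        with pytest.warns(UserWarning, match="capped"):
            lin = popgen.pairwise_fst(g, grouping, cap=50.0)
        assert lin.loc["p1", "p2"] == 50.0

    def test_matches_independent_oracle_exactly(self, rng):
        """Ratio-of-sums multilocus theta vs the independently coded
        Weir-Cockerham oracle, to 1e-10."""
        for seed in range(5):
            r = np.random.default_rng(seed)
            pop1 = r.binomial(2, r.uniform(0.1, 0.9, 25), size=(20, 25)).astype(float)
            pop2 = r.binomial(2, r.uniform(0.1, 0.9, 25), size=(20, 25)).astype(float)
            pop1[r.random(pop1.shape) < 0.05] = np.nan
            g = make_genotypes(np.vstack([pop1, pop2]))
            grouping = pd.Series(["p1"] * 20 + ["p2"] * 20, index=g.sample_ids)
            ours = popgen.pairwise_fst(g, grouping, linearize=False).loc["p1", "p2"]
            oracle = wc_theta_oracle([pop1, pop2])
            assert ours == pytest.approx(oracle, abs=1e-10)

    def test_balding_nichols_recovery(self):
        """Two-subpop cohorts generated at F=0.05 yield a mean estimate
        within Monte-Carlo error of the target over 20 replicates."""
        target = 0.05
        ests = []
        for rep in range(20):
            cfg = sd.CohortConfig(
                n_subpops=2, n_regions=1, individuals_per_subpop=60,
                n_tags=200, snps_per_tag=1, fst_target=target,
                region_differentiation=0.0, outlier_tag_fraction=0.0,
                missing_rate=0.0, seed=100 + rep)
            g, _ = sd.simulate_genotypes(cfg)
            grouping = pd.Series([s.rsplit("_", 1)[0] for s in g.sample_ids],
                                 index=g.sample_ids)
            ests.append(popgen.pairwise_fst(g, grouping, linearize=False).iloc[0, 1])
        se = np.std(ests, ddof=1) / math.sqrt(len(ests))
        assert abs(np.mean(ests) - target) < 3 * se + 0.005

    def test_no_differentiation_limit(self):
        cfg = sd.CohortConfig(
            n_subpops=2, n_regions=1, individuals_per_subpop=50, n_tags=150,
            snps_per_tag=1, fst_target=1e-6, region_differentiation=0.0,
            outlier_tag_fraction=0.0, missing_rate=0.0, seed=9)
        g, _ = sd.simulate_genotypes(cfg)
        grouping = pd.Series([s.rsplit("_", 1)[0] for s in g.sample_ids],
                             index=g.sample_ids)
        theta = popgen.pairwise_fst(g, grouping, linearize=False).iloc[0, 1]
        assert abs(theta) < 0.01
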