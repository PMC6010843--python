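"""EMMA REML, EMMAX scans, Q-Q screening and overlap summaries."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar
from scipy.stats import linregress

from chemopop import mixed_model_gwa as gwa
from chemopop import synthetic_data as sd
from chemopop.popgen import ibs_matrix


def structured_kinship(rng, n, n_groups=4):
    """Block-structured PSD kinship resembling subpopulation relatedness."""
    groups = np.repeat(np.arange(n_groups), -(-n // n_groups))[:n]
    k = 0.5 * (groups[:, None] == groups[None, :]).astype(float)
    np.fill_diagonal(k, 1.0)
    jitter = rng.normal(0, 0.01, size=(n, n))
    k = k + jitter @ jitter.T / n  # keep PSD
    d = np.sqrt(np.diag(k))
    return k / np.outer(d, d)


def draw_trait(rng, k, h2, x=None, beta=None):
    n = k.shape[0]
    w, u = np.linalg.eigh(k)
    u_scaled = u * np.sqrt(np.clip(w, 0, None))
    g = u_scaled @ rng.standard_normal(n)
    g = g / g.std() * np.sqrt(h2)
    e = rng.standard_normal(n) * np.sqrt(1 - h2)
    y = g + e
    if x is not None and beta is not None:
        y = y + x @ beta
    return y


def reml_oracle(y, x, k):
    """Direct numerical REML maximization, independent of the EMMA path.

    Evaluates the restricted likelihood from its definition (log-dets of V
    and X'V^-1 X plus the GLS quadratic form) and maximizes over ln(delta)
    with a generic scalar optimizer.
    """
    n, q = x.shape

    def negll(log_delta):
        v = k + np.exp(log_delta) * np.eye(n)
        vi = np.linalg.inv(v)
        xvx = x.T @ vi @ x
        beta = np.linalg.solve(xvx, x.T @ vi @ y)
        r = y - x @ beta
        quad = r @ vi @ r
        sign1, logdet_v = np.linalg.slogdet(v)
        sign2, logdet_xvx = np.linalg.slogdet(xvx)
        sigma2 = quad / (n - q)
        ll = -0.5 * ((n - q) * np.log(2 * np.pi * sigma2) + logdet_v
                     + logdet_xvx + (n - q))
        # include the constant REML term so likelihoods are comparable
        sign3, logdet_xx = np.linalg.slogdet(x.T @ x)
        return -(ll + 0.5 * logdet_xx)

    res = minimize_scalar(negll, bounds=(-10, 10), method="bounded",
                          options={"xatol": 1e-10})
    delta = np.exp(res.x)
    return 1.0 / (1.0 + delta)


class TestEmmaReml:
    def test_matches_generic_reml_maximizer(self):
        """Pseudo-heritability agrees with a direct numerical REML
        optimization to 1e-4 on 10 random instances."""
        for seed in range(10):
            rng = np.random.default_rng(seed)
            n = 80
            k = structured_kinship(rng, n)
            x = np.c_[np.ones(n), rng.standard_normal(n)]
            y = draw_trait(rng, k, h2=rng.uniform(0.2, 0.8))
            ours = gwa.emma_reml(y, x, k)
            oracle_h2 = reml_oracle(y, x, k)
            assert ours.pseudo_heritability == pytest.approx(oracle_h2, abs=1e-4)

    def test_heritability_recovery(self):
        ests = []
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            k = structured_kinship(rng, 300)
            y = draw_trait(rng, k, h2=0.5)
            x = np.ones((300, 1))
            ests.append(gwa.emma_reml(y, x, k).pseudo_heritability)
        assert abs(np.mean(ests) - 0.5) < 0.1

    def test_null_noise_low_heritability(self):
        ests = []
        for seed in range(20):
            rng = np.random.default_rng(200 + seed)
            k = structured_kinship(rng, 200)
            y = rng.standard_normal(200)
            ests.append(gwa.emma_reml(y, np.ones((200, 1)), k).pseudo_heritability)
        assert np.median(ests) < 0.1

    def test_returned_optimum_dominates_grid(self, rng):
        n = 60
        k = structured_kinship(rng, n)
        y = draw_trait(rng, k, h2=0.4)
        x = np.ones((n, 1))
        vc = gwa.emma_reml(y, x, k)
        # recompute the profile likelihood on the same grid
        from scipy.special import expit  # noqa: F401  (doc anchor)
        grid = np.linspace(-10, 10, 100)
        lls = []
        for ld in grid:
            vc_g = gwa.emma_reml(y, x, k, n_grid=2, log_delta_range=(ld, ld + 1e-9))
            lls.append(vc_g.reml_loglik)
        assert vc.reml_loglik >= max(lls) - 1e-6

    def test_rank_deficient_covariates_rejected(self, rng):
        n = 30
        x = np.c_[np.ones(n), np.ones(n)]
        with pytest.raises(ValueError, match="rank"):
            gwa.emma_reml(rng.standard_normal(n), x, np.eye(n))


class TestGwaScan:
    def make_inputs(self, rng, n=60, m=30):
        dosage = rng.binomial(2, rng.uniform(0.2, 0.8, m), size=(n, m)).astype(float)
        samples = [f"i{t}" for t in range(n)]
        snps = [f"s{j}" for j in range(m)]
        geno = pd.DataFrame(dosage, index=samples, columns=snps)
        kin = pd.DataFrame(np.eye(n), index=samples, columns=samples)
        return geno, kin, samples

    def test_identity_kinship_reduces_to_ols(self, rng):
        """With K = I and no covariates every SNP p equals the ordinary
        regression t-test p to 1e-8."""
        geno, kin, samples = self.make_inputs(rng)
        y = rng.standard_normal(len(samples))
        traits = pd.DataFrame({"t": y}, index=samples)
        res = gwa.gwa_scan(traits, geno, kin, config="none")
        for _, row in res.table.iterrows():
            ols = linregress(geno[row["snp"]].to_numpy(), y)
            assert row["p"] == pytest.approx(ols.pvalue, abs=1e-8)
            assert row["beta"] == pytest.approx(ols.slope, abs=1e-8)

    def test_invariance_to_trait_affine_transform(self, rng):
        geno, kin, samples = self.make_inputs(rng)
        y = rng.standard_normal(len(samples))
        t1 = pd.DataFrame({"t": y}, index=samples)
        t2 = pd.DataFrame({"t": 3.0 * y + 11.0}, index=samples)
        p1 = gwa.gwa_scan(t1, geno, kin).table["p"].to_numpy()
        p2 = gwa.gwa_scan(t2, geno, kin).table["p"].to_numpy()
        np.testing.assert_allclose(p1, p2, atol=1e-9)

    def test_planted_effect_power_and_size(self):
        """Planted SNP effect sized for the Bonferroni level is recovered in
        >= 90% of replicates; null pairs stay within the Bonferroni budget."""
        hits = 0
        false_pos = 0
        reps = 20
        n_null_pairs = 0
        from chemopop.popgen import select_one_snp_per_tag

        for rep in range(reps):
            cfg = sd.CohortConfig(
                n_subpops=4, n_regions=2, individuals_per_subpop=30,
                n_tags=300, snps_per_tag=1, n_metabolites=12,
                n_latent_pathways=2, dropout_rate=0.0, seed=7000 + rep)
            cohort = sd.simulate_cohort(cfg)
            neutral, _ = select_one_snp_per_tag(cohort.genotypes)
            kin = ibs_matrix(neutral)  # kinship from the neutral panel
            truth_log = cohort.truth.metabolite_log_abundance
            traits = truth_log.T
            res = gwa.gwa_scan(traits, cohort.genotypes, kin,
                               covariates=cohort.metadata, config="none")
            planted = {(s, m) for s, m, _ in cohort.truth.snp_effects}
            planted_snps = {s for s, _, _ in cohort.truth.snp_effects}
            sig = set(map(tuple, res.table.loc[res.table["significant"],
                                               ["snp", "trait"]].to_numpy()))
            hits += sum((s, m) in sig for s, m in planted) / len(planted)
            null_sig = {pair for pair in sig
                        if pair not in planted and pair[0] not in planted_snps}
            false_pos += len(null_sig)
            n_null_pairs += len(res.table) - len(planted)
        assert hits >= 0.9 * reps
        # family-wise alpha 0.05 per trait: expected false hits per rep is
        # ~0.05 * n_traits; stay within 3x of that over all reps
        assert false_pos <= 3 * 0.05 * 12 * reps

    def test_confounded_environment_shrinks_with_covariate(self):
        """A metabolite driven only by Tcol (which tracks subpopulation)
        yields fewer significant SNPs once Tcol enters the model."""
        diff = 0
        for rep in range(5):
            cfg = sd.CohortConfig(
                n_subpops=4, n_regions=2, individuals_per_subpop=30,
                n_tags=80, snps_per_tag=1, fst_target=0.15,
                region_differentiation=0.15, n_metabolites=6,
                n_latent_pathways=1, planted_snp_effects=[],
                env_effect_sizes={"tcol": 2.0}, env_affected_fraction=1.0,
                noise_sd=0.3, dropout_rate=0.0, seed=7500 + rep)
            cohort = sd.simulate_cohort(cfg)
            kin = ibs_matrix(cohort.genotypes)
            traits = cohort.truth.metabolite_log_abundance.T
            raw_sig = gwa.gwa_scan(traits, cohort.genotypes, kin,
                                   covariates=cohort.metadata,
                                   config="none").table
            adj_sig = gwa.gwa_scan(traits, cohort.genotypes, kin,
                                   covariates=cohort.metadata,
                                   config="tcol").table
            # compare raw sub-threshold counts without the QQ gate so the
            # contrast reflects confound removal alone
            thr = 0.05 / 80
            diff += (raw_sig["p"] <= thr).sum() - (adj_sig["p"] <= thr).sum()
        assert diff > 0

    def test_monomorphic_snps_skipped(self, rng):
        geno, kin, samples = self.make_inputs(rng)
        geno["mono"] = 1.0
        traits = pd.DataFrame({"t": rng.standard_normal(len(samples))},
                              index=samples)
        res = gwa.gwa_scan(traits, geno, kin)
        assert "mono" not in set(res.table["snp"])


class TestQqScreen:
    def test_uniform_pvalues_pass(self):
        passes = 0
        reps = 20
        for rep in range(reps):
            rng = np.random.default_rng(300 + rep)
            lam, ok = gwa.qq_screen(rng.uniform(size=1000))
            passes += ok and abs(lam - 1) < 0.2
        assert passes >= 0.95 * reps

    def test_miscalibrated_pvalues_fail(self, rng):
        # sqrt-uniform p-values are right-shifted (too few small p): deflation
        lam_def, ok_def = gwa.qq_screen(rng.uniform(size=1000) ** 0.5)
        assert lam_def < 0.8 and not ok_def
        # squared uniforms are left-shifted (excess small p): inflation
        lam_inf, ok_inf = gwa.qq_screen(rng.uniform(size=1000) ** 2)
        assert lam_inf > 1.2 and not ok_inf

    def test_degenerate_constant_pvalues_fail(self):
        lam, ok = gwa.qq_screen(np.full(500, 0.5))
        assert not ok

    def test_too_few_pvalues_fail(self, rng):
        lam, ok = gwa.qq_screen(rng.uniform(size=50))
        assert not ok and np.isnan(lam)


class TestOverlapSummary:
    def fake_result(self, pairs):
        table = pd.DataFrame(
            [{"snp": s, "trait": t, "config": "x", "beta": 1.0, "se": 0.1,
              "p": 1e-9, "significant": True} for s, t in pairs],
            columns=["snp", "trait", "config", "beta", "se", "p", "significant"])
        return gwa.AssociationResult(table, 1e-3, pd.DataFrame(), {})

    def test_identical_sets_all_in_full_intersection(self):
        pairs = [("s1", "m1"), ("s2", "m2")]
        results = {c: self.fake_result(pairs) for c in ["none", "tcol", "bio14", "both"]}
        out = gwa.overlap_summary(results)
        assert out["features"]["venn_regions"]["none+tcol+bio14+both"] == 2
        assert out["features"]["venn_regions"]["none"] == 0

    def test_disjoint_sets_no_multi_intersections(self):
        results = {"none": self.fake_result([("s1", "m1")]),
                   "tcol": self.fake_result([("s2", "m2")])}
        out = gwa.overlap_summary(results)
        assert out["snps"]["venn_regions"]["none+tcol"] == 0
        assert out["snps"]["venn_regions"]["none"] == 1

    def test_partition_identity(self, rng):
        configs = ["none", "tcol", "bio14", "both"]
        results = {}
        pool = [(f"s{i}", f"m{i}") for i in range(12)]
        for c in configs:
            take = rng.random(12) < 0.5
            results[c] = self.fake_result([p for p, t in zip(pool, take) if t])
        out = gwa.overlap_summary(results)
        regions = out["features"]["venn_regions"]
        for c in configs:
            total = sum(v for key, v in regions.items() if c in key.split("+"))
            assert total == out["features"]["per_config"][c]
        assert sum(regions.values()) == out["features"]["union"]
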