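"""Stratified regression: exact algebra, null behaviour, derived quantities."""

import numpy as np
import pytest

from teherit import regression
from teherit.annotations import AnnotationMatrix
from teherit.ldscore import ld_scores
from teherit.pipeline import make_noiseless_fixture
from teherit.regression import (
    ModelFit,
    SizeGateError,
    expected_enrichment,
    observed_enrichment,
    tau_star,
)
from teherit.simulate import SimulationConfig, gwas_sumstats, simulate_genotypes, simulate_phenotype


def _fit_noiseless(fx, **kwargs):
    defaults = dict(n_blocks=50)
    defaults.update(kwargs)
    return regression.fit(fx["sumstats"], fx["ld"], fx["annot"], fx["herit_mask"], **defaults)


class TestExactAlgebra:
    @pytest.mark.parametrize("weighted", [True, False])
    @pytest.mark.parametrize("intercept", ["free", "fixed"])
    def test_noiseless_fixture_recovers_tau_exactly(self, noiseless, weighted, intercept):
        fit = _fit_noiseless(noiseless, weighted=weighted, intercept=intercept)
        np.testing.assert_allclose(fit.tau, noiseless["tau"], rtol=1e-8)
        assert fit.intercept == pytest.approx(1.0, abs=1e-8)

    def test_noiseless_derived_quantities_match_generating_values(self, noiseless):
        fit = _fit_noiseless(noiseless)
        tau = noiseless["tau"]
        A = noiseless["annot"].values
        var = A @ tau
        a = A[:, 1]
        true_pct = var[a > 0].sum() / var.sum()
        true_enr = true_pct / a.mean()
        obs = observed_enrichment(fit, "A")
        assert obs["pct_h2"] == pytest.approx(true_pct, rel=1e-8)
        assert obs["enrichment"] == pytest.approx(true_enr, rel=1e-8)
        sd = a.std()
        true_ts = tau[1] * sd / (var.sum() / len(a))
        assert tau_star(fit, "A")["tau_star"] == pytest.approx(true_ts, rel=1e-8)

    def test_h2_consistency_identity(self, noiseless):
        fit = _fit_noiseless(noiseless)
        assert fit.h2_g == pytest.approx(float(fit.annot_sums @ fit.tau))

    def test_all_ones_annotation_enrichment_is_one(self, noiseless):
        fit = _fit_noiseless(noiseless)
        obs = observed_enrichment(fit, "base")
        assert obs["enrichment"] == pytest.approx(1.0, abs=1e-12)
        assert obs["pct_h2"] == pytest.approx(1.0, abs=1e-12)

    def test_disjoint_partition_pct_h2_sums_to_one(self, noiseless):
        # A and its complement partition all SNPs: %h2 adds to 100%
        fx = noiseless
        am = AnnotationMatrix(snp_ids=fx["annot"].snp_ids)
        a = fx["annot"]["A"]
        am.add("A", a)
        am.add("notA", 1.0 - a)
        ld = fx["ld"]
        comp_scores = ld.column("base") - ld.column("A")
        from teherit.ldscore import LDScoreTable

        ld2 = LDScoreTable(
            snp_ids=ld.snp_ids, chrom=ld.chrom, pos=ld.pos, names=["A", "notA"],
            scores=np.column_stack([ld.column("A"), comp_scores]),
            w_ld=ld.w_ld, n_ref=ld.n_ref, window_bp=ld.window_bp,
            M=np.array([a.sum(), (1 - a).sum()]), M_common=np.array([a.sum(), (1 - a).sum()]),
        )
        fit = regression.fit(fx["sumstats"], ld2, am, fx["herit_mask"], n_blocks=50)
        p1 = observed_enrichment(fit, "A")["pct_h2"]
        p2 = observed_enrichment(fit, "notA")["pct_h2"]
        assert p1 + p2 == pytest.approx(1.0, abs=1e-10)

    def test_duplicate_annotation_rejected_naming_pair(self, noiseless):
        fx = noiseless
        am = AnnotationMatrix(snp_ids=fx["annot"].snp_ids)
        am.add("base", np.ones(len(fx["annot"].snp_ids)))
        am.add("A", fx["annot"]["A"])
        am.add("copy", fx["annot"]["A"])
        from teherit.ldscore import LDScoreTable

        ld = fx["ld"]
        ld2 = LDScoreTable(
            snp_ids=ld.snp_ids, chrom=ld.chrom, pos=ld.pos, names=["base", "A", "copy"],
            scores=np.column_stack([ld.scores, ld.column("A")]),
            w_ld=ld.w_ld, n_ref=ld.n_ref, window_bp=ld.window_bp,
            M=np.append(ld.M, ld.M[1]), M_common=np.append(ld.M_common, ld.M_common[1]),
        )
        with pytest.raises(ValueError, match="collinear"):
            regression.fit(fx["sumstats"], ld2, am, fx["herit_mask"], n_blocks=50)


class TestTauStar:
    def _hand_fit(self, tau, sd, h2, M):
        # minimal one-annotation fit with deterministic jackknife copies
        n_blocks = 5
        annot_sums = np.array([h2 / tau]) if tau else np.array([M * 1.0])
        return ModelFit(
            names=["A"],
            tau=np.array([tau]),
            intercept=1.0,
            tau_loo=np.tile([tau], (n_blocks, 1)),
            intercept_loo=np.ones(n_blocks),
            M=M,
            annot_sums=annot_sums,
            cross=np.array([[annot_sums[0]]]),
            sd=np.array([sd]),
            A_herit=np.zeros((1, 1)),
            n_blocks=n_blocks,
        )

    def test_hand_arithmetic(self):
        # tau = 2e-7, sd = 0.3, h2 = 0.5, M = 5e6 -> tau* = 2e-7 * 0.3 / 1e-7 = 0.6
        fit = self._hand_fit(tau=2e-7, sd=0.3, h2=0.5, M=5_000_000)
        res = tau_star(fit, "A")
        assert res["tau_star"] == pytest.approx(0.6)
        assert res["se"] == 0.0

    def test_zero_tau_gives_zero_tau_star(self, noiseless):
        fit = _fit_noiseless(noiseless)
        fit.tau = np.array([fit.tau[0], 0.0])
        fit.tau_loo = np.column_stack([fit.tau_loo[:, 0], np.zeros(fit.n_blocks)])
        assert tau_star(fit, "A")["tau_star"] == 0.0

    def test_scale_invariance_under_annotation_doubling(self, noiseless):
        # doubling every a_cj halves tau and doubles sd: tau* unchanged
        fx = noiseless
        fit1 = _fit_noiseless(fx)
        am2 = AnnotationMatrix(snp_ids=fx["annot"].snp_ids)
        am2.add("base", np.ones(len(fx["annot"].snp_ids)))
        am2.add("A", 2.0 * fx["annot"]["A"])
        from teherit.ldscore import LDScoreTable

        ld = fx["ld"]
        ld2 = LDScoreTable(
            snp_ids=ld.snp_ids, chrom=ld.chrom, pos=ld.pos, names=ld.names,
            scores=np.column_stack([ld.column("base"), 2.0 * ld.column("A")]),
            w_ld=ld.w_ld, n_ref=ld.n_ref, window_bp=ld.window_bp,
            M=ld.M * np.array([1.0, 2.0]), M_common=ld.M_common * np.array([1.0, 2.0]),
        )
        fit2 = regression.fit(fx["sumstats"], ld2, am2, fx["herit_mask"], n_blocks=50)
        assert fit2.tau[1] == pytest.approx(fit1.tau[1] / 2, rel=1e-8)
        assert tau_star(fit2, "A")["tau_star"] == pytest.approx(
            tau_star(fit1, "A")["tau_star"], rel=1e-8
        )

    def test_constant_annotation_warns_and_returns_zero(self):
        fit = self._hand_fit(tau=1e-7, sd=0.0, h2=0.5, M=1000)
        with pytest.warns(UserWarning, match="constant"):
            res = tau_star(fit, "A")
        assert res["tau_star"] == 0.0


class TestNullFit:
    def test_null_simulation_taus_and_intercept(self):
        # h2 = 0: every tau within 3 SE of 0, free intercept within 3 SE of 1
        m = 2000
        cfg = SimulationConfig(n_individuals=2000, n_snps=m, n_blocks_ld=40, h2_g=0.0, seed=13)
        cohort = simulate_genotypes(cfg)
        simulate_phenotype(cohort, np.zeros(m), 0.0, rng=cfg.rng("noise"))
        ss = gwas_sumstats(cohort)
        am = AnnotationMatrix.with_base(cohort.variants)
        rng = np.random.default_rng(5)
        am.add("A", (rng.random(m) < 0.2).astype(float))
        ld = ld_scores(cohort.genotypes[:1000], cohort.variants, am)
        herit = cohort.variants["maf"].to_numpy() >= 0.05
        fit = regression.fit(ss, ld, am, herit, n_blocks=40, intercept="free")
        for c in range(2):
            se = regression.jackknife_se(fit.tau[c], fit.tau_loo[:, c])
            assert abs(fit.tau[c]) <= 3 * se
        icpt_se = regression.jackknife_se(fit.intercept, fit.intercept_loo)
        assert abs(fit.intercept - 1.0) <= 3 * icpt_se


class TestSizeGateAndExpected:
    def test_small_annotation_gated(self, noiseless):
        fx = noiseless
        m = len(fx["annot"].snp_ids)
        am = AnnotationMatrix(snp_ids=fx["annot"].snp_ids)
        am.add("base", np.ones(m))
        tiny = np.zeros(m)
        tiny[0] = 1.0  # 0.25% of 400 SNPs, below the 0.4% gate
        am.add("tiny", tiny)
        from teherit.ldscore import LDScoreTable

        ld = fx["ld"]
        ld2 = LDScoreTable(
            snp_ids=ld.snp_ids, chrom=ld.chrom, pos=ld.pos, names=["base", "tiny"],
            scores=np.column_stack([ld.column("base"), ld.column("base") * tiny]),
            w_ld=ld.w_ld, n_ref=ld.n_ref, window_bp=ld.window_bp,
            M=np.array([m, 1.0]), M_common=np.array([m, 1.0]),
        )
        fit = regression.fit(fx["sumstats"], ld2, am, fx["herit_mask"], n_blocks=50)
        with pytest.raises(SizeGateError, match="expected_enrichment"):
            observed_enrichment(fit, "tiny")
        assert "enrichment" in observed_enrichment(fit, "tiny", force=True)

    def test_focal_in_conditioning_model_rejected(self, noiseless):
        fit = _fit_noiseless(noiseless)
        with pytest.raises(ValueError, match="conditioning"):
            expected_enrichment(fit, noiseless["annot"]["A"], name="A")

    def test_value_duplicate_reproduces_model_implied_enrichment(self, noiseless):
        # a copy of a conditioning annotation under a new name: expected
        # enrichment equals that annotation's model-implied (observed) enrichment
        fit = _fit_noiseless(noiseless)
        obs = observed_enrichment(fit, "A")
        exp = expected_enrichment(fit, noiseless["annot"]["A"], name="A_copy")
        assert exp["expected_enrichment"] == pytest.approx(obs["enrichment"], rel=1e-12)
        assert exp["expected_pct_h2"] == pytest.approx(obs["pct_h2"], rel=1e-12)

    def test_wrong_length_focal_rejected(self, noiseless):
        fit = _fit_noiseless(noiseless)
        with pytest.raises(ValueError, match="heritability SNPs"):
            expected_enrichment(fit, np.ones(7), name="x")


class TestJointPartition:
    def test_four_disjoint_classes_recovered(self):
        # distinct generating taus for 4 disjoint annotations, one replicate
        m, n, h2 = 2000, 20_000, 0.5
        rng = np.random.default_rng(21)
        assign = rng.integers(0, 8, m)  # 4 classes of ~12.5% each + background
        classes = [(assign == k).astype(float) for k in range(4)]
        A = np.column_stack([np.ones(m)] + classes)
        mult = np.array([2.0, 4.0, 6.0, 8.0])
        v = h2 / (m + sum((mult[k] - 1) * classes[k].sum() for k in range(4)))
        tau_true = np.concatenate([[v], (mult - 1) * v])
        cfg = SimulationConfig(
            n_individuals=n, n_snps=m, n_blocks_ld=40, ld_decay=0.9,
            h2_g=h2, tau_vector=tau_true, seed=17,
        )
        cohort = simulate_genotypes(cfg)
        from teherit.simulate import draw_effects

        beta = draw_effects(A, cfg)
        simulate_phenotype(cohort, beta, h2, rng=cfg.rng("noise"))
        ss = gwas_sumstats(cohort)
        am = AnnotationMatrix.with_base(cohort.variants)
        for k, c in enumerate(classes):
            am.add(f"class{k}", c)
        ld = ld_scores(cohort.genotypes[:1000], cohort.variants, am)
        herit = cohort.variants["maf"].to_numpy() >= 0.05
        results = regression.partition(
            ss, ld, am, herit, focal=[f"class{k}" for k in range(4)],
            n_blocks=40, intercept="fixed",
        )
        var = A @ tau_true
        for k in range(4):
            row = results[results["annotation"] == f"class{k}"].iloc[0]
            true_enr = (var[classes[k] > 0].sum() / var.sum()) / classes[k].mean()
            assert abs(row["enrichment"] - true_enr) <= 3 * row["enrichment_se"]

    def test_partition_with_flank_bookkeeping(self, noiseless):
        fx = noiseless
        m = len(fx["annot"].snp_ids)
        am = AnnotationMatrix(snp_ids=fx["annot"].snp_ids)
        am.add("base", np.ones(m))
        am.add("A", fx["annot"]["A"])
        flank = ((fx["annot"]["A"] == 0) & (np.arange(m) % 7 == 0)).astype(float)
        am.add("A.flank", flank, flank_of="A")
        from teherit.ldscore import LDScoreTable

        ld = fx["ld"]
        rng = np.random.default_rng(2)
        ld2 = LDScoreTable(
            snp_ids=ld.snp_ids, chrom=ld.chrom, pos=ld.pos, names=["base", "A", "A.flank"],
            scores=np.column_stack([ld.scores, flank + 0.1 * rng.random(m)]),
            w_ld=ld.w_ld, n_ref=ld.n_ref, window_bp=ld.window_bp,
            M=np.append(ld.M, flank.sum()), M_common=np.append(ld.M_common, flank.sum()),
        )
        results = regression.partition(fx["sumstats"], ld2, am, fx["herit_mask"], focal=["A"], n_blocks=50)
        assert list(results["annotation"]) == ["A"]
        # expected enrichment came from a conditioning fit without A or its flank
        assert np.isfinite(results.iloc[0]["expected_enrichment"])

    def test_unknown_focal_rejected(self, noiseless):
        with pytest.raises(ValueError, match="focal"):
            regression.partition(
                noiseless["sumstats"], noiseless["ld"], noiseless["annot"],
                noiseless["herit_mask"], focal=["nope"],
            )


def test_jackknife_se_matches_empirical_replicate_sd():
    """Across 50 seeded replicates the empirical SD of enrichment estimates
    agrees with the mean jackknife SE (well within a factor of 1.5)."""
    from teherit.studies import se_calibration_study

    res = se_calibration_study(n_replicates=50, seed=0)
    assert 1 / 1.5 <= res["ratio"] <= 1.5
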