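import numpy as np
import pandas as pd
import pytest

import vcqtl as v
from vcqtl.varcomp import (
    RankDeficientDesign,
    RemlWorkspace,
    build_model_data,
    fit_reml,
    litter_kernel,
)
from oracles import reml_loglik_direct


def _polygenic_sample(A, s2a, s2e, seed, mean=0.0):
    rng = np.random.default_rng(seed)
    n = A.shape[0]
    L = np.linalg.cholesky(A + 1e-10 * np.eye(n))
    return mean + L @ rng.normal(0, np.sqrt(s2a), n) + rng.normal(0, np.sqrt(s2e), n)


@pytest.fixture(scope="module")
def pedigree_60():
    design = v.SimulationDesign(
        n_f0_sires=3, n_f0_dams=4, n_f1_boars=3, n_f1_sows=6, sows_per_boar=(2, 2),
        litters_per_sow=(1, 2), n_f2=60, n_groups=1, markers_per_group=(3,),
    )
    return v.make_pedigree(design, seed=5)


class TestRemlAgainstOracles:
    def test_two_component_problem_matches_grid_search(self, pedigree_60):
        """60-record polygenic problem: REML solution within 1e-4 (logL) and
        1e-3 relative (components) of a dense grid + golden-section oracle."""
        ped = pedigree_60
        f2 = ped.ids_of_generation("F2")
        A = v.additive_matrix(ped, f2).values
        y = _polygenic_sample(A, 0.4, 0.6, seed=2, mean=3.0)
        X = np.ones((len(y), 1))
        fit = fit_reml(y, X, {"polygenic": A})

        def nll(sa, se):
            return -reml_loglik_direct(y, X, sa * A + se * np.eye(len(y)))

        # dense grid then golden-section refinement on each coordinate
        grid = np.linspace(0.01, 2.0, 60)
        best = min(((nll(a, e), a, e) for a in grid for e in grid))
        _, sa, se = best
        gr = (np.sqrt(5) - 1) / 2
        for _ in range(60):
            for coord in (0, 1):
                lo = max(1e-6, (sa if coord == 0 else se) - 0.05)
                hi = (sa if coord == 0 else se) + 0.05
                a_, b_ = lo, hi
                c_ = b_ - gr * (b_ - a_)
                d_ = a_ + gr * (b_ - a_)
                for _ in range(40):
                    fc = nll(c_, se) if coord == 0 else nll(sa, c_)
                    fd = nll(d_, se) if coord == 0 else nll(sa, d_)
                    if fc < fd:
                        b_, d_ = d_, c_
                        c_ = b_ - gr * (b_ - a_)
                    else:
                        a_, c_ = c_, d_
                        d_ = a_ + gr * (b_ - a_)
                if coord == 0:
                    sa = 0.5 * (a_ + b_)
                else:
                    se = 0.5 * (a_ + b_)
        assert fit.loglik == pytest.approx(-nll(sa, se), abs=1e-4)
        assert fit.components["polygenic"] == pytest.approx(sa, rel=1e-3, abs=1e-3)
        assert fit.components["residual"] == pytest.approx(se, rel=1e-3, abs=1e-3)

    def test_balanced_sire_design_matches_anova(self):
        """REML equals the Henderson-III/ANOVA estimators on a balanced
        s x n one-way design when those are interior."""
        rng = np.random.default_rng(8)
        s, n = 10, 8
        sire_eff = rng.normal(0, np.sqrt(0.5), s)
        y = np.repeat(sire_eff, n) + rng.normal(0, 1.0, s * n)
        groups = np.repeat(np.arange(s), n)
        K = (groups[:, None] == groups[None, :]).astype(float)
        fit = fit_reml(y, np.ones((s * n, 1)), {"sire": K})
        gm = y.reshape(s, n).mean(axis=1)
        msb = n * np.sum((gm - y.mean()) ** 2) / (s - 1)
        msw = np.sum((y.reshape(s, n) - gm[:, None]) ** 2) / (s * (n - 1))
        assert (msb - msw) / n > 0  # interior
        assert fit.components["sire"] == pytest.approx((msb - msw) / n, rel=1e-6)
        assert fit.components["residual"] == pytest.approx(msw, rel=1e-6)

    def test_boundary_under_null_majority(self, pedigree_60):
        """Data simulated without a QTL: fitted sigma2_q lands on the zero
        boundary in most replicates."""
        ped = pedigree_60
        f2 = ped.ids_of_generation("F2")
        A = v.additive_matrix(ped, f2).values
        rng = np.random.default_rng(0)
        G = np.eye(len(f2)) * 1.0  # an uninformative 'position' kernel
        X = np.ones((len(f2), 1))
        # make G distinct from residual by blending in A-structure
        G = 0.7 * np.eye(len(f2)) + 0.3 * A
        boundary = 0
        reps = 20
        ws = RemlWorkspace(X)
        for r in range(reps):
            y = _polygenic_sample(A, 0.3, 0.7, seed=100 + r)
            fit = fit_reml(y, X, {"polygenic": A, "qtl": G}, workspace=ws,
                           kernel_keys={"polygenic": "A", "qtl": "G"}, want_effects=False)
            if fit.at_boundary["qtl"]:
                boundary += 1
        assert boundary > reps / 2


class TestLrt:
    def test_nested_fits_nonnegative_and_boundary_zero(self, pedigree_60):
        ped = pedigree_60
        f2 = ped.ids_of_generation("F2")
        A = v.additive_matrix(ped, f2).values
        X = np.ones((len(f2), 1))
        y = _polygenic_sample(A, 0.3, 0.7, seed=42)
        h0 = fit_reml(y, X, {"polygenic": A})
        h1 = fit_reml(y, X, {"polygenic": A, "qtl": 0.5 * A + 0.5 * np.eye(len(f2))})
        stat = v.lrt(h0, h1)
        assert stat >= 0.0
        if h1.at_boundary["qtl"]:
            assert stat == pytest.approx(0.0, abs=1e-6)

    def test_record_mismatch_rejected(self, pedigree_60):
        ped = pedigree_60
        f2 = ped.ids_of_generation("F2")
        A = v.additive_matrix(ped, f2).values
        y = _polygenic_sample(A, 0.3, 0.7, seed=1)
        h0 = fit_reml(y, np.ones((len(y), 1)), {"polygenic": A}, ids=f2)
        h1 = fit_reml(y[:-1], np.ones((len(y) - 1, 1)), {"polygenic": A[:-1, :-1]}, ids=f2[:-1])
        with pytest.raises(ValueError, match="record sets"):
            v.lrt(h0, h1)

    def test_power_at_major_qtl(self):
        """A QTL explaining ~15% of variance at n=1000 gives LRT above the
        chi2_2DF 1% quantile at the true position in nearly all replicates."""
        design = v.SimulationDesign(
            n_f0_sires=8, n_f0_dams=12, n_f1_boars=8, n_f1_sows=24,
            sows_per_boar=(3, 3), litters_per_sow=(2, 2), n_f2=1000,
            n_groups=1, markers_per_group=(3,), marker_spacing_cm=20.0,
        )
        ped = v.make_pedigree(design, seed=3)
        gmap = v.make_map(design)
        geno, truth = v.drop_genomes(ped, gmap, design, seed=4)
        f2 = ped.ids_of_generation("F2")
        idx = ped.indices(f2)
        A = v.additive_matrix(ped, f2).values
        # realized IBD at the middle marker from the latent truth
        fp, fm = truth.slots(ped, "1", 1)
        C = np.zeros((len(f2), 2 * ped.n_founders))
        for j, i in enumerate(idx):
            C[j, fp[i]] += 1
            C[j, fm[i]] += 1
        G = 0.5 * C @ C.T
        # biallelic additive QTL riding on that locus
        rng = np.random.default_rng(9)
        slot_allele = (rng.random(2 * ped.n_founders) < 0.5).astype(float)
        dose = slot_allele[fp[idx]] + slot_allele[fm[idx]]
        var_q = 0.15
        a = np.sqrt(var_q / max(dose.var(), 1e-9))
        X = np.ones((len(f2), 1))
        ws = RemlWorkspace(X)
        hits = 0
        reps = 20
        for r in range(reps):
            y = a * dose + _polygenic_sample(A, 0.25, 0.60, seed=200 + r)
            h0 = fit_reml(y, X, {"polygenic": A}, workspace=ws,
                          kernel_keys={"polygenic": "A"}, want_effects=False)
            h1 = fit_reml(y, X, {"polygenic": A, "qtl": G}, workspace=ws,
                          kernel_keys={"polygenic": "A", "qtl": "G"}, want_effects=False)
            if v.lrt(h0, h1) > 9.21:
                hits += 1
        assert hits >= 0.9 * reps


class TestDecompositionAndErrors:
    def test_variance_explained_arithmetic(self):
        fit = v.VarianceComponentFit(
            components={"polygenic": 30.0, "qtl": 15.0, "residual": 55.0},
            loglik=0.0, converged=True, n_iter=1, n_records=10, ids=[],
        )
        fr = v.variance_explained(fit)
        assert fr["qtl"] == pytest.approx(0.15)
        assert sum(fr.values()) == pytest.approx(1.0)

    def test_sampling_error_matches_iid_closed_form(self):
        """One-component i.i.d. model: AI-based SE equals the analytic
        sqrt(2 sigma^4/(n-1)) REML information."""
        rng = np.random.default_rng(5)
        n = 400
        y = rng.normal(3.0, 2.0, n)
        fit = fit_reml(y, np.ones((n, 1)), {})
        s2 = fit.components["residual"]
        ratio = v.sampling_error_ratio(fit, "residual")
        expect = s2 / np.sqrt(2 * s2**2 / (n - 1))
        assert ratio == pytest.approx(expect, rel=1e-3)

    def test_duplicating_records_increases_precision(self, pedigree_60):
        ped = pedigree_60
        f2 = ped.ids_of_generation("F2")
        A = v.additive_matrix(ped, f2).values
        rng = np.random.default_rng(3)
        n = len(f2)
        g = np.linalg.cholesky(A + 1e-10 * np.eye(n)) @ rng.normal(0, np.sqrt(0.5), n)
        y = g + rng.normal(0, np.sqrt(0.5), n)
        fit1 = fit_reml(y, np.ones((n, 1)), {"polygenic": A})
        # each record measured twice with independent residuals
        y2 = np.concatenate([y, g + rng.normal(0, np.sqrt(0.5), n)])
        A2 = np.block([[A, A], [A, A]])
        fit2 = fit_reml(y2, np.ones((2 * n, 1)), {"polygenic": A2})
        r1 = v.sampling_error_ratio(fit1, "residual")
        r2 = v.sampling_error_ratio(fit2, "residual")
        assert r2 > r1

    def test_boundary_component_ratio_zero(self):
        fit = v.VarianceComponentFit(
            components={"qtl": 0.0, "residual": 1.0}, loglik=0.0, converged=True,
            n_iter=1, n_records=10, ids=[], at_boundary={"qtl": True, "residual": False},
        )
        assert v.sampling_error_ratio(fit, "qtl") == 0.0

    @pytest.mark.parametrize(
        "t0,t1,expect,flag", [(100.0, 100.0, 0.0, False), (100.0, 105.0, 5.0, True), (100.0, 101.0, 1.0, False)]
    )
    def test_total_variance_check(self, t0, t1, expect, flag):
        mk = lambda tot: v.VarianceComponentFit(
            components={"residual": tot}, loglik=0.0, converged=True, n_iter=1,
            n_records=10, ids=[],
        )
        dev, flagged = v.total_variance_check(mk(t0), mk(t1))
        assert dev == pytest.approx(expect)
        assert flagged is flag


class TestInvariances:
    def test_shift_and_covariate_rescale_leave_lrt_unchanged(self, pedigree_60):
        ped = pedigree_60
        f2 = ped.ids_of_generation("F2")
        n = len(f2)
        A = v.additive_matrix(ped, f2).values
        G = 0.6 * A + 0.4 * np.eye(n)
        rng = np.random.default_rng(11)
        cov = rng.normal(50, 5, n)
        y = _polygenic_sample(A, 0.4, 0.6, seed=12) + 0.1 * cov
        X = np.column_stack([np.ones(n), cov])

        def stat(yy, XX):
            h0 = fit_reml(yy, XX, {"polygenic": A})
            h1 = fit_reml(yy, XX, {"polygenic": A, "qtl": G})
            return v.lrt(h0, h1)

        base = stat(y, X)
        assert stat(y + 100.0, X) == pytest.approx(base, abs=1e-6)
        X2 = np.column_stack([np.ones(n), cov / 10.0])
        assert stat(y, X2) == pytest.approx(base, abs=1e-6)

    def test_parameter_recovery_within_mc_error(self, small_dataset):
        """Interior two-component truth is recovered on average over 25
        replicates within two Monte-Carlo standard errors."""
        _, _, ped, _, _ = small_dataset
        f2 = ped.ids_of_generation("F2")
        A = v.additive_matrix(ped, f2).values
        X = np.ones((len(f2), 1))
        ws = RemlWorkspace(X)
        est = []
        for r in range(25):
            y = _polygenic_sample(A, 0.4, 0.6, seed=700 + r)
            fit = fit_reml(y, X, {"polygenic": A}, workspace=ws,
                           kernel_keys={"polygenic": "A"}, want_effects=False)
            est.append(fit.components["polygenic"])
        est = np.array(est)
        se = est.std(ddof=1) / np.sqrt(len(est))
        assert abs(est.mean() - 0.4) < 2 * se + 1e-6


class TestModelBuilding:
    def test_design_and_missing_data_handling(self):
        phen = v.PhenotypeTable(
            pd.DataFrame(
                {
                    "id": [f"i{k}" for k in range(8)],
                    "t": [1.0, 2, np.nan, 4, 5, 6, 7, 8],
                    "batch": ["a", "a", "a", "b", "b", "b", "c", "b"],
                    "w": [1.0, 2, 3, 4, np.nan, 6, 7, 8],
                    "lit": ["x", "x", "y", "y", "z", "z", "x", "x"],
                }
            )
        )
        spec = v.TraitModelSpec(trait="t", factors=("batch",), covariates=("w",), litter="lit")
        data = build_model_data(phen, spec, min_level_count=2)
        # record 2 (missing t) and 4 (missing w) dropped
        assert data.ids == ["i0", "i1", "i3", "i5", "i6", "i7"]
        # level 'c' has one record -> merged into preceding level
        assert any("merged" in n for n in data.notes)
        K = litter_kernel(data.litter_codes)
        assert K[0, 1] == 1.0 and K[0, 2] == 0.0

    def test_rank_deficient_design_names_columns(self):
        X = np.column_stack([np.ones(40), np.arange(40.0), 2 * np.arange(40.0)])
        y = np.random.default_rng(0).normal(size=40)
        with pytest.raises(RankDeficientDesign, match="confounded"):
            fit_reml(y, X, {}, columns=["intercept", "w", "w2"])

    def test_too_few_records_rejected(self):
        with pytest.raises(ValueError, match="records"):
            fit_reml(np.ones(10), np.ones((10, 1)), {})
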