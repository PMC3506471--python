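import numpy as np
import pandas as pd
import pytest
from scipy import linalg

from mbgp.data import RelationshipMatrix
from mbgp.mixed_models import (Adjuster, Design, ModelSpec, RandomBlock,
                               VarianceComponents, adjust_phenotypes,
                               build_design, gblup_predict, reml_fit,
                               solve_mme)
from mbgp.relationships import build_grm, build_nrm


def random_psd(rng, n, strength=1.0):
    M = rng.normal(size=(n, n + 3))
    K = M @ M.T / (n + 3)
    return K + strength * np.eye(n)


def direct_gls_blup(y, X, kernels, variances, sigma_e2):
    """Oracle: BLUP via direct inversion of V (no MME)."""
    n = len(y)
    V = sigma_e2 * np.eye(n)
    for s2, K in zip(variances, kernels):
        V = V + s2 * K
    Vi = np.linalg.inv(V)
    beta = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
    resid = Vi @ (y - X @ beta)
    return beta, [s2 * K @ resid for s2, K in zip(variances, kernels)]


def reml_loglik_direct(y, X, V):
    """Oracle REML log-likelihood, written independently of the package."""
    n, p = X.shape
    Vi = np.linalg.inv(V)
    _, ld_v = np.linalg.slogdet(V)
    XtViX = X.T @ Vi @ X
    _, ld_x = np.linalg.slogdet(XtViX)
    P = Vi - Vi @ X @ np.linalg.solve(XtViX, X.T @ Vi)
    return -0.5 * (ld_v + ld_x + y @ P @ y)


def toy_design(rng, n, kernels_spec, p_fixed=2):
    X = np.column_stack([np.ones(n)]
                        + [rng.normal(size=n) for _ in range(p_fixed - 1)])
    y = rng.normal(size=n)
    blocks = []
    for i, (name, kind, K) in enumerate(kernels_spec):
        blocks.append(RandomBlock(name=name, kind=kind, Z=np.eye(n),
                                  level_ids=[f"l{i}_{j}" for j in range(n)],
                                  K=K))
    return Design(y=y, X=X, x_labels=[f"x{j}" for j in range(p_fixed)],
                  random=blocks, record_ids=[f"l0_{j}" for j in range(n)])


class TestBuildDesign:
    def _pheno(self):
        return pd.DataFrame({
            "animal_id": [f"a{i}" for i in range(8)],
            "trait": np.arange(8.0),
            "sex": ["M", "F"] * 4,
            "contemporary_group": ["g1"] * 4 + ["g2"] * 4,
            "age": np.linspace(250, 350, 8),
        })

    def test_reference_level_coding(self):
        spec = ModelSpec(fixed_factors=("sex", "contemporary_group"),
                         covariates=(), random_terms=())
        d = build_design(self._pheno(), spec)
        assert d.X.shape[1] == 3  # intercept + 1 per 2-level factor

    def test_genotyped_restriction(self):
        spec = ModelSpec(fixed_factors=("sex",), covariates=(),
                         random_terms=())
        d = build_design(self._pheno(), spec,
                         genotyped_ids={"a0", "a1", "a2"})
        assert d.record_ids == ["a0", "a1", "a2"]

    def test_covariate_passes_through_raw(self):
        spec = ModelSpec(fixed_factors=(), covariates=("age",),
                         random_terms=())
        d = build_design(self._pheno(), spec)
        np.testing.assert_array_equal(d.X[:, 1], self._pheno()["age"])

    def test_missing_response_dropped(self):
        df = self._pheno()
        df.loc[3, "trait"] = np.nan
        spec = ModelSpec(fixed_factors=(), covariates=(), random_terms=())
        d = build_design(df, spec)
        assert len(d.y) == 7


class TestREML:
    def test_matches_grid_search_oracle(self):
        rng = np.random.default_rng(21)
        for _ in range(3):
            n = 30
            K = random_psd(rng, n)
            L = np.linalg.cholesky(K)
            y = L @ rng.normal(size=n) * 0.8 + rng.normal(size=n) * 0.6
            d = toy_design(rng, n, [("g", "G", K)], p_fixed=1)
            d.y = y
            vc = reml_fit(d)
            # iteratively refined 2-D grid on the oracle likelihood
            lo = np.array([0.01, 0.01])
            hi = np.array([3.0, 3.0])
            for _ in range(8):
                grid = [np.linspace(lo[k], hi[k], 15) for k in range(2)]
                best, arg = -np.inf, None
                for sg in grid[0]:
                    for se in grid[1]:
                        ll = reml_loglik_direct(y, d.X,
                                                sg * K + se * np.eye(n))
                        if ll > best:
                            best, arg = ll, (sg, se)
                span = (hi - lo) / 14
                lo = np.maximum(np.array(arg) - span, 1e-4)
                hi = np.array(arg) + span
            assert vc.variances["g"] == pytest.approx(arg[0], abs=1e-3)
            assert vc.variances["residual"] == pytest.approx(arg[1], abs=1e-3)

    def test_null_variance_small_on_pure_noise(self):
        # low-rank marker kernel makes the genetic variance identifiable;
        # pure-noise phenotypes should give a near-zero genetic share
        rng = np.random.default_rng(5)
        n, m = 500, 300
        Z = rng.normal(size=(n, m))
        K = Z @ Z.T / m
        y = rng.normal(size=n)
        d = toy_design(rng, n, [("g", "G", K)], p_fixed=1)
        d.y = y
        vc = reml_fit(d)
        total = sum(vc.variances.values())
        assert vc.variances["g"] / total < 0.05

    def test_location_invariance(self):
        rng = np.random.default_rng(6)
        n = 80
        K = random_psd(rng, n)
        d = toy_design(rng, n, [("g", "G", K)])
        vc1 = reml_fit(d)
        d.y = d.y + 100.0
        vc2 = reml_fit(d)
        assert vc1.variances["g"] == pytest.approx(vc2.variances["g"],
                                                   abs=1e-8)
        assert vc1.variances["residual"] == pytest.approx(
            vc2.variances["residual"], abs=1e-8)

    def test_heritability_recovery_small(self):
        # GBLUP-exact generative model: u = Z beta with per-SNP variance
        # sigma_g2/m on standardised dosages, so cov(u) = sigma_g2 * G
        rng = np.random.default_rng(7)
        n, m = 600, 400
        p = rng.uniform(0.1, 0.9, m)
        X = rng.binomial(2, p, size=(n, m)).astype(float)
        pf = X.mean(axis=0) / 2
        Z = (X - 2 * pf) / np.sqrt(2 * pf * (1 - pf))
        G = Z @ Z.T / m
        h2 = 0.4
        hits = 0
        d = toy_design(rng, n, [("g", "G", G)], p_fixed=1)
        eig = np.linalg.eigh(G)
        for rep in range(6):
            rloc = np.random.default_rng(100 + rep)
            u = Z @ rloc.normal(0, np.sqrt(1.0 / m), m)
            y = u + rloc.normal(0, np.sqrt((1 - h2) / h2), n)
            d.y = y
            vc = reml_fit(d, eig=(eig.eigenvalues, eig.eigenvectors))
            hits += abs(vc.h2 - h2) < 0.1
        assert hits >= 5

    def test_g_equals_a_degenerate_total_matches(self):
        rng = np.random.default_rng(8)
        n = 150
        K = random_psd(rng, n)
        L = np.linalg.cholesky(K)
        y = L @ rng.normal(size=n) + rng.normal(size=n)
        d1 = toy_design(rng, n, [("polygenic", "A", K)], p_fixed=1)
        d1.y = y
        vc1 = reml_fit(d1)
        d2 = toy_design(rng, n, [("polygenic", "A", K), ("genomic", "G", K)],
                        p_fixed=1)
        d2.y = y
        vc2 = reml_fit(d2)
        total1 = vc1.variances["polygenic"]
        total2 = vc2.variances["polygenic"] + vc2.variances["genomic"]
        assert total2 == pytest.approx(total1, rel=0.1)

    def test_too_many_fixed_effects_rejected(self):
        rng = np.random.default_rng(9)
        d = toy_design(rng, 3, [("g", "G", np.eye(3))], p_fixed=4)
        with pytest.raises(ValueError):
            reml_fit(d)


class TestSolveMME:
    def test_matches_direct_gls(self):
        rng = np.random.default_rng(31)
        for _ in range(5):
            n = int(rng.integers(10, 20))
            K1 = random_psd(rng, n)
            d = toy_design(rng, n, [("polygenic", "A", K1)])
            vc = VarianceComponents(
                variances={"polygenic": 0.7, "residual": 0.5},
                loglik=0.0, converged=True, n_iter=0)
            sol = solve_mme(d, vc)
            beta, us = direct_gls_blup(d.y, d.X, [K1], [0.7], 0.5)
            np.testing.assert_allclose(sol.b_hat.to_numpy(), beta, atol=1e-8)
            np.testing.assert_allclose(
                sol.random_effects["polygenic"].to_numpy(), us[0], atol=1e-8)

    def test_zero_variance_shrinks_to_zero(self):
        rng = np.random.default_rng(32)
        n = 20
        d = toy_design(rng, n, [("polygenic", "A", random_psd(rng, n))])
        vc = VarianceComponents(
            variances={"polygenic": 1e-12, "residual": 1.0},
            loglik=0.0, converged=True, n_iter=0)
        sol = solve_mme(d, vc)
        assert np.abs(sol.random_effects["polygenic"].to_numpy()).max() < 1e-6

    def test_identical_twins_identical_predictions(self):
        # two animals with identical relationship rows and identical records
        n = 6
        K = np.eye(n)
        K[0, 1] = K[1, 0] = 1.0  # monozygotic pair
        K += 1e-8 * np.eye(n)
        y = np.array([2.0, 2.0, 1.0, 3.0, 0.5, 1.5])
        d = Design(y=y, X=np.ones((n, 1)), x_labels=["intercept"],
                   random=[RandomBlock("polygenic", "A", np.eye(n),
                                       [f"t{i}" for i in range(n)], K)],
                   record_ids=[f"t{i}" for i in range(n)])
        vc = VarianceComponents(variances={"polygenic": 1.0, "residual": 1.0},
                                loglik=0.0, converged=True, n_iter=0)
        sol = solve_mme(d, vc)
        u = sol.random_effects["polygenic"]
        assert u["t0"] == pytest.approx(u["t1"], abs=1e-8)

    def test_mme_residual_check_recorded(self):
        rng = np.random.default_rng(33)
        d = toy_design(rng, 12, [("polygenic", "A", random_psd(rng, 12))])
        vc = VarianceComponents(variances={"polygenic": 0.5, "residual": 1.0},
                                loglik=0.0, converged=True, n_iter=0)
        assert solve_mme(d, vc).residual_check < 1e-8


class TestGBLUPPredict:
    def _sim(self, rng, n=120, m=300):
        p = rng.uniform(0.1, 0.9, m)
        X = rng.binomial(2, p, size=(n, m)).astype(float)
        return X

    def test_clone_validation_animals_predicted_identically(self):
        # a0 and a1 are clones; with both held out their G rows to the
        # reference are identical, so their predictions must coincide
        rng = np.random.default_rng(41)
        X = self._sim(rng)
        X[0] = X[1]
        from test_relationships import geno
        G = build_grm(geno(X), variant="yang")
        y = rng.normal(size=120) + (X[:, 0] - X[:, 0].mean())
        pheno = pd.DataFrame({"animal_id": [f"a{i}" for i in range(120)],
                              "trait": y})
        spec = ModelSpec(fixed_factors=(), covariates=(),
                         random_terms=(("genomic", "G"),))
        vc = VarianceComponents(variances={"genomic": 0.5, "residual": 0.5},
                                loglik=0.0, converged=True, n_iter=0)
        preds, _ = gblup_predict(pheno, spec, {"G": G}, ["a0", "a1"], vc=vc)
        assert preds.loc["a0", "genomic"] == pytest.approx(
            preds.loc["a1", "genomic"], abs=1e-6)
        assert abs(preds.loc["a0", "genomic"]) > 1e-4  # informative, not 0

    def test_unrelated_validation_near_zero(self):
        rng = np.random.default_rng(42)
        n = 80
        G_vals = np.eye(n) * 1.0
        G = RelationshipMatrix(ids=[f"a{i}" for i in range(n)],
                               values=G_vals, kind="G")
        y = rng.normal(size=n)
        pheno = pd.DataFrame({"animal_id": [f"a{i}" for i in range(n)],
                              "trait": y})
        spec = ModelSpec(fixed_factors=(), covariates=(),
                         random_terms=(("genomic", "G"),))
        vc = VarianceComponents(variances={"genomic": 1.0, "residual": 1.0},
                                loglik=0.0, converged=True, n_iter=0)
        preds, _ = gblup_predict(pheno, spec, {"G": G}, ["a0"], vc=vc)
        assert abs(preds.loc["a0", "genomic"]) < 1e-8

    def test_validation_record_removed_from_fit(self):
        rng = np.random.default_rng(43)
        X = self._sim(rng, n=60, m=100)
        from test_relationships import geno
        G = build_grm(geno(X), variant="vanraden", freq_min=0.0)
        pheno = pd.DataFrame({"animal_id": [f"a{i}" for i in range(60)],
                              "trait": rng.normal(size=60)})
        spec = ModelSpec(fixed_factors=(), covariates=(),
                         random_terms=(("genomic", "G"),))
        vc = VarianceComponents(variances={"genomic": 0.5, "residual": 0.5},
                                loglik=0.0, converged=True, n_iter=0)
        _, sol = gblup_predict(pheno, spec, {"G": G}, ["a3", "a4"], vc=vc)
        assert len(sol.fitted_fixed) == 58

    def test_missing_validation_animal_rejected(self):
        G = RelationshipMatrix(ids=["a0", "a1", "a2"], values=np.eye(3),
                               kind="G")
        pheno = pd.DataFrame({"animal_id": ["a0", "a1", "a2"],
                              "trait": [1.0, 2.0, 3.0]})
        spec = ModelSpec(fixed_factors=(), covariates=(),
                         random_terms=(("genomic", "G"),))
        with pytest.raises(KeyError, match="missing from G"):
            gblup_predict(pheno, spec, {"G": G}, ["zz"])


class TestSnpBlupEquivalence:
    def test_small_instance(self):
        rng = np.random.default_rng(51)
        n, m = 80, 150
        p = rng.uniform(0.1, 0.9, m)
        X = rng.binomial(2, p, size=(n, m)).astype(float)
        from test_relationships import geno
        g = geno(X)
        G = build_grm(g, variant="vanraden", freq_min=0.0)
        y = rng.normal(size=n)
        sg2, se2 = 0.6, 0.4
        pheno = pd.DataFrame({"animal_id": g.animal_ids, "trait": y})
        spec = ModelSpec(fixed_factors=(), covariates=(),
                         random_terms=(("genomic", "G"),))
        vc = VarianceComponents(variances={"genomic": sg2, "residual": se2},
                                loglik=0.0, converged=True, n_iter=0)
        d = build_design(pheno, spec, relationships={"G": G})
        sol = solve_mme(d, vc)
        ghat = sol.random_effects["genomic"].to_numpy()
        # ridge-regression oracle with unpenalised intercept
        pf = X.mean(axis=0) / 2
        Z = (X - 2 * pf) / np.sqrt(2 * pf * (1 - pf))
        lam = m * se2 / sg2
        one = np.ones((n, 1))
        A = np.block([[np.array([[float(n)]]), one.T @ Z],
                      [Z.T @ one, Z.T @ Z + lam * np.eye(m)]])
        b = np.concatenate([(one.T @ y).ravel(), Z.T @ y])
        beta = np.linalg.solve(A, b)
        np.testing.assert_allclose(ghat, Z @ beta[1:], atol=1e-6)


class TestAdjustPhenotypes:
    def test_intercept_only_is_centring(self):
        rng = np.random.default_rng(61)
        y = rng.normal(5, 2, 40)
        pheno = pd.DataFrame({"animal_id": [f"a{i}" for i in range(40)],
                              "trait": y})
        spec = ModelSpec(fixed_factors=(), covariates=(), random_terms=())
        ystar = adjust_phenotypes(pheno, spec)
        np.testing.assert_allclose(ystar.to_numpy(), y - y.mean(), atol=1e-10)

    def test_fixed_effects_removed(self):
        rng = np.random.default_rng(62)
        n = 2000
        sex = rng.choice(["M", "F"], n)
        effect = np.where(sex == "M", 1.5, -1.5)
        y = 10 + effect + rng.normal(0, 0.5, n)
        pheno = pd.DataFrame({"animal_id": [f"a{i}" for i in range(n)],
                              "trait": y, "sex": sex})
        spec = ModelSpec(fixed_factors=("sex",), covariates=(),
                         random_terms=())
        ystar = adjust_phenotypes(pheno, spec)
        assert ystar.var() == pytest.approx(0.25, rel=0.1)
        assert abs(ystar.mean()) < 1e-10

    def test_idempotent(self):
        rng = np.random.default_rng(63)
        n = 50
        pheno = pd.DataFrame({
            "animal_id": [f"a{i}" for i in range(n)],
            "trait": rng.normal(size=n),
            "sex": rng.choice(["M", "F"], n),
        })
        spec = ModelSpec(fixed_factors=("sex",), covariates=(),
                         random_terms=())
        once = adjust_phenotypes(pheno, spec)
        again_input = pheno.copy()
        again_input["trait"] = once.to_numpy()
        twice = adjust_phenotypes(again_input, spec)
        np.testing.assert_allclose(once.to_numpy(), twice.to_numpy(),
                                   atol=1e-10)

    def test_adjuster_applies_to_held_out_records(self):
        rng = np.random.default_rng(64)
        n = 200
        sex = rng.choice(["M", "F"], n)
        y = np.where(sex == "M", 2.0, -2.0) + rng.normal(0, 0.1, n)
        pheno = pd.DataFrame({"animal_id": [f"a{i}" for i in range(n)],
                              "trait": y, "sex": sex})
        spec = ModelSpec(fixed_factors=("sex",), covariates=(),
                         random_terms=())
        adj = Adjuster(pheno.iloc[:150], spec)
        held = adj.apply(pheno.iloc[150:])
        assert held.abs().mean() < 0.5  # sex effect removed


class TestEndToEndModels(object):
    def test_model1_and_model2_on_simulation(self, small_dataset):
        ds = small_dataset
        A = build_nrm(ds.pedigree)
        G = build_grm(ds.genotypes)
        from mbgp.relationships import breed_composition_from_pedigree
        comp = breed_composition_from_pedigree(ds.pedigree)
        spec1 = ModelSpec(random_terms=(("polygenic", "A"), ("breed", "breed")))
        d1 = build_design(ds.phenotypes, spec1, relationships={"A": A},
                          breed_composition=comp)
        vc1 = reml_fit(d1, max_iter=150)
        assert all(v >= 0 for v in vc1.variances.values())
        sol1 = solve_mme(d1, vc1)
        assert sol1.residual_check < 1e-8
        spec2 = ModelSpec(random_terms=(("polygenic", "A"), ("genomic", "G"),
                                        ("breed", "breed")))
        d2 = build_design(ds.phenotypes, spec2,
                          relationships={"A": A, "G": G},
                          breed_composition=comp)
        vc2 = reml_fit(d2, max_iter=150)
        sol2 = solve_mme(d2, vc2)
        assert sol2.residual_check < 1e-8
        assert set(sol2.random_effects) == {"polygenic", "genomic", "breed"}
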