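"""Linear mixed models: design building, REML variance components,
Henderson mixed-model equations, GBLUP prediction and fixed-effect
phenotype adjustment.

Models supported are of the form

    y = 1 mu + X b + sum_k Z_k u_k + e,   u_k ~ N(0, sigma_k^2 K_k)

where K_k is a pedigree (A), genomic (G) or identity kernel; the random
breed term enters through Z = Q (per-record breed fractions) with an
identity kernel (random partial regressions on breed proportions).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize

from mbgp.data import BreedComposition, RelationshipMatrix

# Added to G at solve time: centred-dosage G is singular (the all-ones
# vector is in its null space), so the MME needs a small ridge. 1e-8
# keeps the SNP-BLUP equivalence error well below 1e-6.
RIDGE = 1e-8
VAR_FLOOR = 1e-10

#: random-term name -> conventional variance-component attribute
_VAR_ALIASES = {"polygenic": "sigma_a2", "genomic": "sigma_g2",
                "breed": "sigma_q2"}


@dataclass
class ModelSpec:
    """Trait, fixed effects, covariates and random terms for one model.

    ``random_terms`` is an ordered list of (name, kind) pairs with kind
    "A" (pedigree kernel), "G" (genomic kernel) or "breed" (random
    regressions on breed fractions, identity kernel).
    """

    response: str = "trait"
    fixed_factors: tuple = ("sex", "birth_type", "rearing_type",
                            "contemporary_group")
    covariates: tuple = ("age",)
    random_terms: tuple = (("polygenic", "A"),)

    def term_names(self) -> list[str]:
        return [name for name, _ in self.random_terms]


@dataclass
class RandomBlock:
    name: str
    kind: str  # "A", "G" or "breed"
    Z: np.ndarray  # records x levels
    level_ids: list
    K: np.ndarray | None = None  # None means identity
    Kinv: np.ndarray | None = None

    def kernel_on_records(self) -> np.ndarray:
        if self.K is None:
            return self.Z @ self.Z.T
        return self.Z @ self.K @ self.Z.T

    def kinverse(self) -> np.ndarray:
        if self.Kinv is not None:
            return self.Kinv
        if self.K is None:
            self.Kinv = np.eye(self.Z.shape[1])
        else:
            self.Kinv = _kinverse_cached(self.K)
        return self.Kinv


_KINV_CACHE: dict = {}


def _kinverse_cached(K: np.ndarray) -> np.ndarray:
    """Symmetric PSD-safe inverse of a relationship matrix.

    Eigenvalues are floored at RIDGE before inversion, which keeps the
    result symmetric positive definite even for rank-deficient G
    (centred-dosage G always is). Cached per matrix object: folds of a
    cross-validation share one inverse.
    """
    key = id(K)
    hit = _KINV_CACHE.get(key)
    if hit is not None and hit[0] is K:
        return hit[1]
    d, U = np.linalg.eigh(K)
    d = np.maximum(d, RIDGE)
    Kinv = (U / d) @ U.T
    Kinv = 0.5 * (Kinv + Kinv.T)
    _KINV_CACHE[key] = (K, Kinv)
    return Kinv


@dataclass
class Design:
    y: np.ndarray
    X: np.ndarray
    x_labels: list[str]
    random: list[RandomBlock]
    record_ids: list[str]

    @property
    def n(self) -> int:
        return len(self.y)


@dataclass
class VarianceComponents:
    variances: dict  # term name -> variance; includes "residual"
    loglik: float
    converged: bool
    n_iter: int
    h2: float = float("nan")

    def __getattr__(self, item):
        for name, alias in _VAR_ALIASES.items():
            if item == alias:
                return self.variances.get(name, 0.0)
        if item == "sigma_e2":
            return self.variances["residual"]
        raise AttributeError(item)

    def genetic_variance(self) -> float:
        return sum(v for k, v in self.variances.items()
                   if k not in ("residual", "breed"))

    def heritability(self) -> float:
        """(sigma_a2 + sigma_g2) / (genetic + breed + residual)."""
        total = sum(self.variances.values())
        return self.genetic_variance() / total if total > 0 else float("nan")


@dataclass
class Solutions:
    mu: float
    b_hat: pd.Series
    random_effects: dict  # term name -> pd.Series indexed by level id
    fitted_fixed: np.ndarray
    residual_check: float

    def predict(self, ids, terms) -> pd.Series:
        """Sum the requested random-effect solutions for the given ids."""
        total = pd.Series(0.0, index=list(ids))
        for term in terms:
            u = self.random_effects[term]
            total = total.add(u.reindex(total.index).fillna(0.0))
        return total


def build_design(phenotypes: pd.DataFrame, spec: ModelSpec,
                 relationships: dict[str, RelationshipMatrix] | None = None,
                 breed_composition: BreedComposition | None = None,
                 genotyped_ids=None) -> Design:
    """Construct y, X and random-effect incidence matrices.

    Records with a missing response are dropped; when ``genotyped_ids``
    is given the records are restricted to those animals. Fixed factors
    are dummy-coded with one reference level dropped per factor; rank
    deficiencies are resolved by QR column pivoting (dropped columns
    trigger a warning).
    """
    relationships = relationships or {}
    df = phenotypes[phenotypes[spec.response].notna()].copy()
    if genotyped_ids is not None:
        df = df[df["animal_id"].isin(set(genotyped_ids))]
    if df.empty:
        raise ValueError("no usable records after response/genotype filtering")
    df = df.reset_index(drop=True)
    n = len(df)

    cols = [np.ones((n, 1))]
    labels = ["intercept"]
    for factor in spec.fixed_factors:
        if factor not in df.columns:
            raise KeyError(f"fixed factor {factor!r} not in phenotype table")
        dummies = pd.get_dummies(df[factor].astype(str), prefix=factor,
                                 drop_first=True)
        cols.append(dummies.to_numpy(dtype=float))
        labels.extend(dummies.columns.tolist())
    for cov in spec.covariates:
        if cov not in df.columns:
            raise KeyError(f"covariate {cov!r} not in phenotype table")
        cols.append(df[[cov]].to_numpy(dtype=float))
        labels.append(cov)
    X = np.hstack(cols)

    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        _, _, piv = linalg.qr(X, mode="economic", pivoting=True)
        keep = np.sort(piv[:rank])
        if 0 not in keep:  # always keep the intercept
            keep = np.sort(np.concatenate([[0], piv[: rank - 1]]))
        dropped = [labels[j] for j in range(X.shape[1]) if j not in set(keep)]
        warnings.warn(f"dropping collinear fixed-effect columns: {dropped}")
        X = X[:, keep]
        labels = [labels[j] for j in keep]

    record_ids = df["animal_id"].tolist()
    random_blocks: list[RandomBlock] = []
    for name, kind in spec.random_terms:
        if kind in ("A", "G"):
            if kind not in relationships:
                raise KeyError(f"relationship matrix {kind!r} required for "
                               f"random term {name!r}")
            K = relationships[kind]
            idx = K.index()
            missing = [a for a in record_ids if a not in idx]
            if missing:
                raise KeyError(f"animals missing from {kind}: {missing[:5]}")
            Z = np.zeros((n, len(K.ids)))
            Z[np.arange(n), [idx[a] for a in record_ids]] = 1.0
            random_blocks.append(RandomBlock(name=name, kind=kind, Z=Z,
                                             level_ids=list(K.ids),
                                             K=K.values))
        elif kind == "breed":
            if breed_composition is None:
                raise ValueError("breed term requires a BreedComposition")
            frame = breed_composition.as_frame()
            Z = frame.reindex(record_ids).to_numpy(dtype=float)
            if np.isnan(Z).any():
                raise KeyError("records missing from breed composition")
            random_blocks.append(RandomBlock(
                name=name, kind=kind, Z=Z,
                level_ids=list(breed_composition.breed_names)))
        else:
            raise ValueError(f"unknown random term kind {kind!r}")

    return Design(y=df[spec.response].to_numpy(dtype=float), X=X,
                  x_labels=labels, random=random_blocks,
                  record_ids=record_ids)


# ---------------------------------------------------------------------------
# REML


def _reml_loglik_parts(y, X, V):
    """REML log-likelihood (up to a constant) via Cholesky of V."""
    n, p = X.shape
    c, low = linalg.cho_factor(V, lower=True)
    logdet_v = 2.0 * np.log(np.diag(c)).sum()
    Vi_y = linalg.cho_solve((c, low), y)
    Vi_X = linalg.cho_solve((c, low), X)
    XtViX = X.T @ Vi_X
    sign, logdet_x = np.linalg.slogdet(XtViX)
    if sign <= 0:
        return -np.inf
    XtViy = X.T @ Vi_y
    yPy = y @ Vi_y - XtViy @ np.linalg.solve(XtViX, XtViy)
    return -0.5 * (logdet_v + logdet_x + yPy)


def _reml_single_kernel(y, X, kernel, eig=None, max_iter=200):
    """Profiled REML for V = sigma2 * K + sigma_e2 * I via eigenrotation.

    Returns (sigma2, sigma_e2, loglik, n_iter, converged). ``eig`` may
    carry a precomputed ``np.linalg.eigh`` of the kernel for reuse.
    """
    n, p = X.shape
    if eig is None:
        d, U = np.linalg.eigh(kernel)
    else:
        d, U = eig
    d = np.clip(d, 0.0, None)
    yt = U.T @ y
    Xt = U.T @ X

    def neg_profiled(loglam):
        lam = np.exp(loglam)
        w = 1.0 / (lam * d + 1.0)
        XtW = Xt * w[:, None]
        XtWX = Xt.T @ XtW
        sign, logdet_x = np.linalg.slogdet(XtWX)
        if sign <= 0:
            return np.inf
        XtWy = XtW.T @ yt
        yPy = yt @ (w * yt) - XtWy @ np.linalg.solve(XtWX, XtWy)
        if yPy <= 0:
            return np.inf
        sigma_e2 = yPy / (n - p)
        ll = -0.5 * ((n - p) * np.log(sigma_e2) - np.log(w).sum()
                     + logdet_x + (n - p))
        return -ll

    res = optimize.minimize_scalar(neg_profiled, bounds=(-14.0, 14.0),
                                   method="bounded",
                                   options={"xatol": 1e-10, "maxiter": max_iter})
    lam = float(np.exp(res.x))
    w = 1.0 / (lam * d + 1.0)
    XtW = Xt * w[:, None]
    XtWX = Xt.T @ XtW
    XtWy = XtW.T @ yt
    yPy = yt @ (w * yt) - XtWy @ np.linalg.solve(XtWX, XtWy)
    sigma_e2 = float(yPy / (n - p))
    sigma2 = lam * sigma_e2
    ll = _reml_loglik_parts(y, X, sigma2 * kernel + sigma_e2 * np.eye(n))
    return max(sigma2, VAR_FLOOR), max(sigma_e2, VAR_FLOOR), float(ll), \
        int(res.nfev), bool(res.success)


def reml_fit(design: Design, start_values=None, max_iter: int = 400,
             eig=None) -> VarianceComponents:
    """Estimate variance components by REML.

    Single correlated random term: profiled likelihood on the
    eigenrotated model (exact, fast; ``eig`` can carry a reused
    eigendecomposition of the record-level kernel). Multiple terms:
    Nelder-Mead on log variances of the full REML log-likelihood.
    Variances are floored at 1e-10.
    """
    y, X = design.y, design.X
    n, p = X.shape
    if n <= p:
        raise ValueError("more fixed effects than records")
    # REML is invariant to y -> y - Xb; projecting out the fixed effects
    # up front makes that invariance hold numerically (location shifts in
    # y no longer perturb the likelihood through cancellation error)
    beta_ols, *_ = np.linalg.lstsq(X, y, rcond=None)
    y = y - X @ beta_ols
    names = [b.name for b in design.random]

    if len(design.random) == 1:
        kernel = design.random[0].kernel_on_records()
        s2, se2, ll, nit, ok = _reml_single_kernel(y, X, kernel, eig=eig,
                                                   max_iter=max_iter)
        vc = VarianceComponents(variances={names[0]: s2, "residual": se2},
                                loglik=ll, converged=ok, n_iter=nit)
        vc.h2 = vc.heritability()
        return vc

    kernels = [b.kernel_on_records() for b in design.random]
    vary = y.var()
    k = len(kernels) + 1
    if start_values is None:
        start_values = [vary / k] * k
    theta0 = np.log(np.maximum(start_values, 1e-8))
    eye = np.eye(n)

    def neg_loglik(log_theta):
        theta = np.exp(log_theta)
        V = theta[-1] * eye
        for t, Kr in zip(theta[:-1], kernels):
            V = V + t * Kr
        try:
            ll = _reml_loglik_parts(y, X, V)
        except linalg.LinAlgError:
            return np.inf
        return -ll if np.isfinite(ll) else np.inf

    res = optimize.minimize(neg_loglik, theta0, method="Nelder-Mead",
                            options={"maxiter": max_iter * k, "xatol": 1e-9,
                                     "fatol": 1e-9})
    theta = np.maximum(np.exp(res.x), VAR_FLOOR)
    variances = dict(zip(names, theta[:-1]))
    variances["residual"] = float(theta[-1])
    vc = VarianceComponents(variances={k: float(v) for k, v in variances.items()},
                            loglik=float(-res.fun), converged=bool(res.success),
                            n_iter=int(res.nit))
    vc.h2 = vc.heritability()
    if not res.success:
        warnings.warn("REML did not converge; returning best point found")
    return vc


# ---------------------------------------------------------------------------
# Mixed-model equations


class MMESolver:
    """Henderson mixed-model equations with a reusable factorisation.

    The coefficient matrix depends on the design and the variance
    components only, so one factorisation serves any number of
    right-hand sides (new phenotype vectors on the same design).
    """

    def __init__(self, design: Design, vc: VarianceComponents):
        self.design = design
        self.vc = vc
        se2 = max(vc.variances["residual"], VAR_FLOOR)
        blocks = [design.X] + [b.Z for b in design.random]
        self.W = np.hstack(blocks)
        p = design.X.shape[1]
        self.slices = [slice(0, p)]
        at = p
        for b in design.random:
            q = b.Z.shape[1]
            self.slices.append(slice(at, at + q))
            at += q
        C = self.W.T @ self.W / se2
        for b, sl in zip(design.random, self.slices[1:]):
            sk2 = max(vc.variances[b.name], VAR_FLOOR)
            C[sl, sl] += b.kinverse() / sk2
        self.C = C
        self.se2 = se2
        try:
            self._factor = linalg.cho_factor(C, lower=True)
            self._solve = lambda r: linalg.cho_solve(self._factor, r)
        except linalg.LinAlgError:
            # near-singular kernels can defeat Cholesky numerically even
            # though C is PD in exact arithmetic; fall back to LU
            try:
                self._factor = linalg.lu_factor(C)
                self._solve = lambda r: linalg.lu_solve(self._factor, r)
            except (linalg.LinAlgError, ValueError) as err:
                rank = np.linalg.matrix_rank(C)
                raise linalg.LinAlgError(
                    f"singular MME coefficient matrix: rank {rank} < "
                    f"{C.shape[0]}") from err

    def solve(self, y: np.ndarray | None = None) -> Solutions:
        design = self.design
        if y is None:
            y = design.y
        r = self.W.T @ y / self.se2
        sol = self._solve(r)
        check = np.linalg.norm(self.C @ sol - r) / max(np.linalg.norm(r), 1e-30)
        if check > 1e-8:
            warnings.warn(f"MME solution residual {check:.2e} exceeds 1e-8")
        beta = sol[self.slices[0]]
        b_hat = pd.Series(beta, index=design.x_labels)
        random_effects = {}
        for b, sl in zip(design.random, self.slices[1:]):
            random_effects[b.name] = pd.Series(sol[sl], index=b.level_ids)
        return Solutions(mu=float(beta[0]), b_hat=b_hat,
                         random_effects=random_effects,
                         fitted_fixed=design.X @ beta,
                         residual_check=float(check))


def solve_mme(design: Design, vc: VarianceComponents,
              y: np.ndarray | None = None) -> Solutions:
    """One-shot Henderson MME solve (see :class:`MMESolver`)."""
    return MMESolver(design, vc).solve(y)


def gblup_predict(phenotypes: pd.DataFrame, spec: ModelSpec,
                  relationships: dict[str, RelationshipMatrix],
                  validation_ids,
                  breed_composition: BreedComposition | None = None,
                  vc: VarianceComponents | None = None,
                  genotyped_ids=None) -> tuple[pd.DataFrame, Solutions]:
    """Predict breeding values for validation animals.

    Validation phenotype records are deleted before any fitting (not
    masked), so reference and validation stay independent; validation
    animals are still levels of every A/G random term and are predicted
    through their relationship-matrix links.
    """
    validation_ids = list(validation_ids)
    vset = set(validation_ids)
    for name, kind in spec.random_terms:
        if kind in ("A", "G"):
            idx = relationships[kind].index()
            missing = [a for a in validation_ids if a not in idx]
            if missing:
                raise KeyError(
                    f"validation animals missing from {kind}: {missing[:5]}")
    reference = phenotypes[~phenotypes["animal_id"].isin(vset)]
    design = build_design(reference, spec, relationships=relationships,
                          breed_composition=breed_composition,
                          genotyped_ids=genotyped_ids)
    if vset & set(design.record_ids):
        raise RuntimeError("leakage: validation records present in design")
    if vc is None:
        vc = reml_fit(design)
    solutions = solve_mme(design, vc)
    out = pd.DataFrame(index=validation_ids)
    for name, kind in spec.random_terms:
        if kind in ("A", "G"):
            u = solutions.random_effects[name]
            out[name] = u.reindex(validation_ids).to_numpy()
    return out, solutions


class Adjuster:
    """Fixed-effect (and random-breed) phenotype adjustment.

    Fits y = 1 mu + X b + Q q + e (no polygenic/genomic term) on the
    supplied records and can then apply the estimated effects to any
    record set, including animals excluded from the fit — which is what
    cross-validation needs to score validation animals on adjusted
    phenotypes without leakage.
    """

    def __init__(self, phenotypes: pd.DataFrame, spec: ModelSpec,
                 breed_composition: BreedComposition | None = None,
                 vc: VarianceComponents | None = None, genotyped_ids=None):
        terms = tuple((n, k) for n, k in spec.random_terms if k == "breed")
        self.spec = ModelSpec(response=spec.response,
                              fixed_factors=spec.fixed_factors,
                              covariates=spec.covariates, random_terms=terms)
        self.breed_composition = breed_composition
        design = build_design(phenotypes, self.spec,
                              breed_composition=breed_composition,
                              genotyped_ids=genotyped_ids)
        self.design = design
        if terms:
            if vc is None:
                vc = reml_fit(design)
            self.vc = vc
            solutions = solve_mme(design, vc)
            self.beta = solutions.b_hat
            self.q_hat = solutions.random_effects[terms[0][0]]
        else:
            self.vc = None
            beta, *_ = np.linalg.lstsq(design.X, design.y, rcond=None)
            self.beta = pd.Series(beta, index=design.x_labels)
            self.q_hat = None

    def _fixed_matrix(self, df: pd.DataFrame) -> np.ndarray:
        n = len(df)
        parts = {"intercept": np.ones(n)}
        for factor in self.spec.fixed_factors:
            dummies = pd.get_dummies(df[factor].astype(str), prefix=factor)
            for col in dummies.columns:
                parts[col] = dummies[col].to_numpy(dtype=float)
        for cov in self.spec.covariates:
            parts[cov] = df[cov].to_numpy(dtype=float)
        X = np.column_stack([
            parts.get(label, np.zeros(n)) for label in self.beta.index])
        return X

    def apply(self, phenotypes: pd.DataFrame) -> pd.Series:
        """y* = y - mu_hat - X b_hat - Q q_hat for the given records."""
        df = phenotypes[phenotypes[self.spec.response].notna()]
        fitted = self._fixed_matrix(df) @ self.beta.to_numpy()
        if self.q_hat is not None:
            Q = self.breed_composition.as_frame().reindex(df["animal_id"])
            fitted = fitted + Q.to_numpy() @ self.q_hat.to_numpy()
        return pd.Series(df[self.spec.response].to_numpy(dtype=float) - fitted,
                         index=df["animal_id"].tolist())


def adjust_phenotypes(phenotypes: pd.DataFrame, spec: ModelSpec,
                      breed_composition: BreedComposition | None = None,
                      vc: VarianceComponents | None = None,
                      genotyped_ids=None) -> pd.Series:
    """Fixed-effect (and random-breed) adjusted phenotypes y*.

    Fits the model without any polygenic/genomic term and returns
    y* = y - mu_hat - X b_hat - Q q_hat as a Series indexed by animal
    id. mean(y*) is ~0 by construction.
    """
    adj = Adjuster(phenotypes, spec, breed_composition=breed_composition,
                   vc=vc, genotyped_ids=genotyped_ids)
    return adj.apply(phenotypes if genotyped_ids is None else
                     phenotypes[phenotypes["animal_id"].isin(set(genotyped_ids))])
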