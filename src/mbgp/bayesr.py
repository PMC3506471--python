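"""Four-component normal-mixture marker model (BayesR) by Gibbs sampling.

Model: y* = 1 mu + W m + (Z a) + e, where W holds centred SNP dosages
and each marker effect m_j comes from one of four normal components
with variances (0, 1e-4, 1e-3, 1e-2) x sigma_g2. Mixture proportions
get a Dirichlet prior; sigma_g2 is, by default, redrawn each sweep from
its scaled inverse chi-square conditional given the current non-zero
effects (a fixed-sigma_g2 mode is available). The optional polygenic
term uses single-site updates against a dense A-inverse.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit

CLASS_MULTIPLIERS = (0.0, 1e-4, 1e-3, 1e-2)


@dataclass
class BayesRConfig:
    n_iter: int = 50_000
    burn_in: int = 20_000
    n_chains: int = 10
    class_variance_multipliers: tuple = CLASS_MULTIPLIERS
    dirichlet_prior: tuple = (1.0, 1.0, 1.0, 1.0)
    sigma_g2_init: float | None = None  # typically the GBLUP estimate
    update_sigma_g2: bool = True
    #: scale of the scaled-inv-chi-square prior on sigma_g2; None means
    #: 1% of var(y*). Deliberately decoupled from sigma_g2_init: with no
    #: marker signal the conditional update decays sigma_g2 to this
    #: anchor instead of random-walking around the starting value.
    prior_scale: float | None = None
    include_polygenic: bool = False
    nu0: float = 4.0
    seed: int = 0

    def validate(self) -> None:
        if self.burn_in >= self.n_iter:
            raise ValueError("burn_in must be smaller than n_iter")
        m = self.class_variance_multipliers
        if len(m) != 4 or m[0] != 0.0 or any(b <= a for a, b in zip(m, m[1:])):
            raise ValueError(
                "class multipliers must be 4 strictly increasing values, first 0")
        if self.n_chains < 1:
            raise ValueError("need at least one chain")


@dataclass
class MarkerPosterior:
    snp_ids: list
    chrom: np.ndarray
    pos: np.ndarray
    mean_effect: np.ndarray
    sd_effect: np.ndarray
    class_probs: np.ndarray  # SNPs x 4
    p_class4: np.ndarray
    standardised_effect: np.ndarray
    sd_ystar: float
    col_means: np.ndarray  # training dosage means used for centring
    chain_seeds: list = field(default_factory=list)


@dataclass
class ChainState:
    """Mutable Gibbs state; the residual identity e = y* - mu - Wm - Za
    holds after every sweep."""

    mu: float
    m: np.ndarray
    classes: np.ndarray  # 0-based class index per SNP
    pi: np.ndarray
    a: np.ndarray
    sigma_e2: float
    sigma_g2: float
    sigma_a2: float
    e: np.ndarray

    def recomputed_residual(self, y, W, Z=None) -> np.ndarray:
        r = y - self.mu - W @ self.m
        if Z is not None and len(self.a):
            r = r - Z @ self.a
        return r


@njit(cache=True)
def _set_seed(seed):
    np.random.seed(seed)


@njit(cache=True)
def _sweep(W, wtw, y, e, m, classes, pi, mults, alpha, scalars,
           update_sigma, a, Ainv, include_poly, nu0, s0_g, s0_a):
    # scalars: [mu, sigma_e2, sigma_g2, sigma_a2]
    n = y.shape[0]
    p = W.shape[1]
    mu = scalars[0]
    sigma_e2 = scalars[1]
    sigma_g2 = scalars[2]
    sigma_a2 = scalars[3]

    # intercept
    s = mu * n
    for i in range(n):
        s += e[i]
    mu_new = np.random.normal(s / n, math.sqrt(sigma_e2 / n))
    for i in range(n):
        e[i] += mu - mu_new
    mu = mu_new

    # marker effects and class indicators
    logl = np.empty(4)
    counts = np.zeros(4)
    ssq_scaled = 0.0  # sum m^2 / multiplier over non-zero classes
    n_nz = 0
    for j in range(p):
        old = m[j]
        rhs = old * wtw[j]
        for i in range(n):
            rhs += W[i, j] * e[i]
        for c in range(4):
            v = mults[c] * sigma_g2
            if v <= 0.0:
                logl[c] = math.log(pi[c]) if pi[c] > 0 else -1e30
            else:
                denom = wtw[j] * v + sigma_e2
                logl[c] = (math.log(pi[c]) if pi[c] > 0 else -1e30) \
                    - 0.5 * math.log(denom / sigma_e2) \
                    + 0.5 * rhs * rhs * v / (sigma_e2 * denom)
        mx = logl[0]
        for c in range(1, 4):
            if logl[c] > mx:
                mx = logl[c]
        tot = 0.0
        for c in range(4):
            logl[c] = math.exp(logl[c] - mx)
            tot += logl[c]
        u = np.random.random() * tot
        acc = 0.0
        cls = 3
        for c in range(4):
            acc += logl[c]
            if u <= acc:
                cls = c
                break
        classes[j] = cls
        counts[cls] += 1.0
        v = mults[cls] * sigma_g2
        if v <= 0.0:
            new = 0.0
        else:
            denom = wtw[j] * v + sigma_e2
            post_mean = rhs * v / denom
            post_var = v * sigma_e2 / denom
            new = np.random.normal(post_mean, math.sqrt(post_var))
            ssq_scaled += new * new / mults[cls]
            n_nz += 1
        if new != old:
            diff = old - new
            for i in range(n):
                e[i] += W[i, j] * diff
            m[j] = new

    # mixture proportions ~ Dirichlet(alpha + counts)
    tot = 0.0
    for c in range(4):
        pi[c] = np.random.gamma(alpha[c] + counts[c], 1.0)
        tot += pi[c]
    for c in range(4):
        pi[c] /= tot

    # polygenic effects: single-site updates with dense A-inverse
    if include_poly:
        for i in range(n):
            old_a = a[i]
            prior = 0.0
            for k in range(n):
                if k != i:
                    prior += Ainv[i, k] * a[k]
            prec = Ainv[i, i] / sigma_a2 + 1.0 / sigma_e2
            num = (e[i] + old_a) / sigma_e2 - prior / sigma_a2
            new_a = np.random.normal(num / prec, math.sqrt(1.0 / prec))
            e[i] += old_a - new_a
            a[i] = new_a
        quad = 0.0
        for i in range(n):
            for k in range(n):
                quad += a[i] * Ainv[i, k] * a[k]
        sigma_a2 = (quad + nu0 * s0_a) / np.random.chisquare(n + nu0)

    # residual variance, near-flat prior
    sse = 0.0
    for i in range(n):
        sse += e[i] * e[i]
    sigma_e2 = sse / np.random.chisquare(n - 2)

    # total marker-variance parameter given current effects
    if update_sigma:
        sigma_g2 = (ssq_scaled + nu0 * s0_g) / np.random.chisquare(n_nz + nu0)

    scalars[0] = mu
    scalars[1] = sigma_e2
    scalars[2] = sigma_g2
    scalars[3] = sigma_a2


@njit(cache=True)
def _run_chain(W, wtw, y, n_iter, burn_in, mults, alpha, sigma_g2_init,
               s0_g, update_sigma, Ainv, include_poly, nu0, s0_a, seed):
    np.random.seed(seed)
    n = y.shape[0]
    p = W.shape[1]
    e = y.copy()
    m = np.zeros(p)
    classes = np.zeros(p, dtype=np.int64)
    pi = np.array([0.97, 0.02, 0.0075, 0.0025])
    a = np.zeros(n if include_poly else 0)
    vary = y.var()
    scalars = np.array([0.0, vary if vary > 0 else 1.0, sigma_g2_init,
                        0.1 * sigma_g2_init])
    sum_m = np.zeros(p)
    sum_m2 = np.zeros(p)
    class_counts = np.zeros((p, 4))
    sum_pi = np.zeros(4)
    sum_a = np.zeros(a.shape[0])
    trace = np.empty(n_iter)
    n_saved = 0
    for it in range(n_iter):
        _sweep(W, wtw, y, e, m, classes, pi, mults, alpha, scalars,
               update_sigma, a, Ainv, include_poly, nu0, s0_g, s0_a)
        trace[it] = scalars[2]
        if it >= burn_in:
            n_saved += 1
            for j in range(p):
                sum_m[j] += m[j]
                sum_m2[j] += m[j] * m[j]
                class_counts[j, classes[j]] += 1.0
            for c in range(4):
                sum_pi[c] += pi[c]
            for i in range(a.shape[0]):
                sum_a[i] += a[i]
    return sum_m, sum_m2, class_counts, sum_pi, sum_a, n_saved, trace, \
        scalars, m, classes, pi, a, e


def _prepare(genotypes):
    X = genotypes.dosages
    if np.isnan(X).any():
        raise ValueError("genotypes must be imputed before BayesR")
    col_means = X.mean(axis=0)
    W = np.asfortranarray(X - col_means)
    wtw = (W ** 2).sum(axis=0)
    return W, wtw, col_means


def gibbs_step(state: ChainState, ystar: np.ndarray, genotypes,
               config: BayesRConfig, Ainv: np.ndarray | None = None,
               seed: int | None = None) -> ChainState:
    """Advance the chain by one full sweep (in place; state returned).

    Mainly for tests and diagnostics; :func:`run_chains` drives the same
    compiled kernel for full-length chains.
    """
    config.validate()
    if not np.all(np.isfinite(state.e)):
        raise FloatingPointError("non-finite residual; chain aborted")
    W, wtw, _ = _prepare(genotypes)
    if seed is not None:
        _set_seed(seed)
    scalars = np.array([state.mu, state.sigma_e2, state.sigma_g2,
                        state.sigma_a2])
    include_poly = config.include_polygenic
    if include_poly and Ainv is None:
        raise ValueError("polygenic updates need a dense A-inverse")
    if Ainv is None:
        Ainv = np.zeros((0, 0))
    y = np.asarray(ystar, dtype=float)
    s0_g = config.prior_scale
    if s0_g is None:
        s0_g = 0.01 * float(y.var()) or 0.01
    _sweep(W, wtw, y, state.e, state.m,
           state.classes, state.pi,
           np.asarray(config.class_variance_multipliers, dtype=float),
           np.asarray(config.dirichlet_prior, dtype=float), scalars,
           config.update_sigma_g2, state.a, Ainv, include_poly,
           config.nu0, s0_g, 10.0 * s0_g)
    state.mu, state.sigma_e2, state.sigma_g2, state.sigma_a2 = scalars
    if not np.all(np.isfinite(state.e)):
        raise FloatingPointError("non-finite residual; chain aborted")
    return state


def initial_state(ystar: np.ndarray, n_snp: int, config: BayesRConfig,
                  n_animals: int = 0) -> ChainState:
    y = np.asarray(ystar, dtype=float)
    sg = config.sigma_g2_init or 0.5 * float(y.var())
    return ChainState(mu=0.0, m=np.zeros(n_snp),
                      classes=np.zeros(n_snp, dtype=np.int64),
                      pi=np.array([0.97, 0.02, 0.0075, 0.0025]),
                      a=np.zeros(n_animals if config.include_polygenic else 0),
                      sigma_e2=float(y.var()) or 1.0, sigma_g2=sg,
                      sigma_a2=0.1 * sg, e=y.copy())


def split_rhat(traces: np.ndarray) -> float:
    """Gelman-Rubin split-R-hat across chains (rows = chains)."""
    half = traces.shape[1] // 2
    halves = np.vstack([traces[:, :half], traces[:, half:2 * half]])
    mchain = halves.mean(axis=1)
    within = halves.var(axis=1, ddof=1).mean()
    between = half * mchain.var(ddof=1)
    if within <= 0:
        return 1.0
    var_plus = (half - 1) / half * within + between / half
    return float(np.sqrt(var_plus / within))


def run_chains(ystar, genotypes, config: BayesRConfig,
               Ainv: np.ndarray | None = None):
    """Run the configured chains and summarise the posterior.

    Post-burn-in draws are averaged within each chain, then averaged
    (unweighted) across chains. Returns (MarkerPosterior, diagnostics);
    diagnostics carry the per-chain seeds and the split-R-hat of the
    marker-variance trace.
    """
    config.validate()
    y = np.asarray(ystar, dtype=float)
    W, wtw, col_means = _prepare(genotypes)
    if len(y) != genotypes.n_animals:
        raise ValueError("ystar length does not match genotyped animals")
    include_poly = config.include_polygenic
    if include_poly and Ainv is None:
        raise ValueError("polygenic updates need a dense A-inverse")
    if Ainv is None:
        Ainv = np.zeros((0, 0))
    sg_init = config.sigma_g2_init or 0.5 * float(y.var())
    s0_g = config.prior_scale
    if s0_g is None:
        s0_g = 0.01 * float(y.var()) or 0.01
    mults = np.asarray(config.class_variance_multipliers, dtype=float)
    alpha = np.asarray(config.dirichlet_prior, dtype=float)

    p = genotypes.n_snps
    chain_means = np.zeros((config.n_chains, p))
    chain_sq = np.zeros((config.n_chains, p))
    chain_class = np.zeros((config.n_chains, p, 4))
    traces = []
    seeds = [config.seed + 1000 * c for c in range(config.n_chains)]
    for c, seed in enumerate(seeds):
        (sum_m, sum_m2, class_counts, sum_pi, sum_a, n_saved, trace,
         *_rest) = _run_chain(W, wtw, y, config.n_iter, config.burn_in,
                              mults, alpha, sg_init, s0_g,
                              config.update_sigma_g2, Ainv, include_poly,
                              config.nu0, 10.0 * s0_g, seed)
        chain_means[c] = sum_m / n_saved
        chain_sq[c] = sum_m2 / n_saved
        chain_class[c] = class_counts / n_saved
        traces.append(trace[config.burn_in:])

    mean_effect = chain_means.mean(axis=0)
    second = chain_sq.mean(axis=0)
    sd_effect = np.sqrt(np.maximum(second - mean_effect ** 2, 0.0))
    class_probs = chain_class.mean(axis=0)
    sd_y = float(np.std(y))
    posterior = MarkerPosterior(
        snp_ids=list(genotypes.snp_ids), chrom=genotypes.chrom.copy(),
        pos=genotypes.pos.copy(), mean_effect=mean_effect,
        sd_effect=sd_effect, class_probs=class_probs,
        p_class4=class_probs[:, 3],
        standardised_effect=mean_effect / sd_y if sd_y > 0 else mean_effect,
        sd_ystar=sd_y, col_means=col_means, chain_seeds=seeds)
    diagnostics = {"seeds": seeds,
                   "rhat_sigma_g2": split_rhat(np.vstack(traces))}
    return posterior, diagnostics


def report_large_effects(posterior: MarkerPosterior,
                         threshold_sd: float = 0.005) -> pd.DataFrame:
    """SNPs whose |standardised effect| exceeds the threshold (default
    0.005 SD of the adjusted phenotype), largest first."""
    sel = np.abs(posterior.standardised_effect) > threshold_sd
    df = pd.DataFrame({
        "chrom": posterior.chrom[sel], "pos": posterior.pos[sel],
        "snp_id": np.asarray(posterior.snp_ids, dtype=object)[sel],
        "effect_sd": posterior.standardised_effect[sel],
        "p_class4": posterior.p_class4[sel],
    })
    return df.reindex(df["effect_sd"].abs().sort_values(ascending=False).index
                      ).reset_index(drop=True)


def genomic_value_from_markers(genotypes, posterior: MarkerPosterior,
                               polygenic: pd.Series | None = None) -> pd.Series:
    """GEBV = centred dosages x posterior mean effects (+ polygenic EBV
    when supplied). Requires the training SNP set, in order."""
    if list(genotypes.snp_ids) != list(posterior.snp_ids):
        missing = sorted(set(posterior.snp_ids) - set(genotypes.snp_ids))
        raise ValueError(f"SNP set mismatch; missing from genotypes: "
                         f"{missing[:5]} (and ordering must match)")
    X = genotypes.dosages
    if np.isnan(X).any():
        raise ValueError("genotypes must be imputed")
    g = (X - posterior.col_means) @ posterior.mean_effect
    out = pd.Series(g, index=genotypes.animal_ids)
    if polygenic is not None:
        out = out.add(polygenic.reindex(out.index).fillna(0.0))
    return out
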