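"""Eight-step compatible Gibbs sampler with exact full-conditional draws.

Every step draws from a closed-form conditional — normal, inverse gamma or
inverse Wishart — so there is no Metropolis accept/reject anywhere and the
sampler is compatible with the analytic HLM by construction.  One cycle:

1. random intercepts u_j          (normal)
2. level-2 variance tau           (inverse gamma)
3. fixed effects beta             (multivariate normal, GLS form)
4. level-1 variance sigma2        (inverse gamma)
5. missing outcomes Y_ij          (posterior predictive normal)
6. covariate-model effects alpha  (multivariate normal, GLS form)
7. covariate covariance T         (inverse Wishart)
8. missing covariates C_kj        (exact univariate normal, systematic
   scan k = 1..p with freshest values propagated within each cluster)

Observed Y and C entries are never overwritten.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, solve_triangular
from scipy.stats import invwishart

from .model import (
    DataSet,
    HLMSpec,
    ParameterState,
    PriorSpec,
    build_design_matrix,
)

__all__ = [
    "SamplerConfig",
    "ChainResult",
    "run_chain",
    "run_chains",
    "summarize",
    "step1_sample_u",
    "step2_sample_tau",
    "step3_sample_beta",
    "step4_sample_sigma2",
    "step5_impute_y",
    "step6_sample_alpha",
    "step7_sample_T",
    "step8_impute_c",
]


@dataclass(frozen=True)
class SamplerConfig:
    """Chain-management settings.

    Defaults mirror the headline analysis settings: 2,500 burn-in plus 2,500
    retained iterations and two chains with distinct initializations
    (regression-based imputation vs plain sample means), so that PSRF can be
    computed across the pair.
    """

    n_burn: int = 2500
    n_post: int = 2500
    n_chains: int = 2
    seed: int = 0
    init_strategies: tuple[str, ...] = ("regression", "mean")
    store_extras: bool = False  # also store u and imputed values

    def __post_init__(self):
        if self.n_burn < 0 or self.n_post < 1:
            raise ValueError("need n_burn >= 0 and n_post >= 1")
        if self.n_chains < 1:
            raise ValueError("need at least one chain")

    def chain_seed(self, chain_id: int) -> np.random.SeedSequence:
        return np.random.SeedSequence(self.seed, spawn_key=(chain_id,))

    def chain_init(self, chain_id: int) -> str:
        return self.init_strategies[chain_id % len(self.init_strategies)]


@dataclass
class ChainResult:
    """Post-burn-in draws of theta = (beta, tau, sigma2, alpha, vech T)."""

    param_names: tuple[str, ...]
    draws: np.ndarray  # (n_post, K)
    chain_id: int
    init_strategy: str
    extras: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.draws, columns=list(self.param_names))

    def summary(self) -> pd.DataFrame:
        return summarize([self])


def summarize(chains: list["ChainResult"]) -> pd.DataFrame:
    """Posterior table (mean, sd, equal-tailed 95% interval), pooling chains."""
    if not chains:
        raise ValueError("no chains to summarize")
    pooled = np.vstack([ch.draws for ch in chains])
    if pooled.size == 0:
        raise ValueError("empty draws")
    lo, hi = np.percentile(pooled, [2.5, 97.5], axis=0)
    return pd.DataFrame(
        {
            "mean": pooled.mean(axis=0),
            "sd": pooled.std(axis=0, ddof=1),
            "2.5%": lo,
            "97.5%": hi,
        },
        index=list(chains[0].param_names),
    )


# --------------------------------------------------------------------------
# individual steps (state in, draw out); all take an explicit Generator

def step1_sample_u(
    state: ParameterState, data: DataSet, spec: HLMSpec, rng: np.random.Generator
) -> np.ndarray:
    """u_j ~ N(Delta_j^-1 sigma^-2 sum_i(Y_ij - Xrow'beta), Delta_j^-1),
    Delta_j = nj/sigma2 + 1/tau."""
    if state.tau <= 0 or state.sigma2 <= 0:
        raise ValueError("tau and sigma2 must be positive")
    design = build_design_matrix(spec, state.C_imp, data.X1, data.X2, data.cluster_index)
    resid = state.Y_imp - design @ state.beta
    rsum = np.bincount(data.cluster_index, weights=resid, minlength=data.J)
    delta = data.nj / state.sigma2 + 1.0 / state.tau
    mean = rsum / state.sigma2 / delta
    return mean + rng.standard_normal(data.J) / np.sqrt(delta)


def step2_sample_tau(
    u: np.ndarray, prior: PriorSpec, rng: np.random.Generator
) -> float:
    """tau ~ IG(J/2 + a0, rate = sum_j u_j^2 / 2 + 1/b0)."""
    u = np.asarray(u, dtype=float)
    if u.size == 0:
        raise ValueError("u must be nonempty")
    shape = u.size / 2.0 + prior.ig_shape
    rate = float(u @ u) / 2.0 + prior.ig_rate
    return float(1.0 / rng.gamma(shape, 1.0 / rate))


def step3_sample_beta(
    state: ParameterState, data: DataSet, spec: HLMSpec, rng: np.random.Generator
) -> np.ndarray:
    """beta ~ N((X'X)^-1 X'(Y - u), sigma2 (X'X)^-1) under the flat prior."""
    design = build_design_matrix(spec, state.C_imp, data.X1, data.X2, data.cluster_index)
    XtX = design.T @ design
    yt = state.Y_imp - state.u[data.cluster_index]
    Xty = design.T @ yt
    try:
        cf = cho_factor(XtX)
    except np.linalg.LinAlgError as err:
        rank = np.linalg.matrix_rank(design)
        raise np.linalg.LinAlgError(
            f"design is rank deficient (rank {rank} < {design.shape[1]}); "
            f"columns: {spec.coef_names}"
        ) from err
    mean = cho_solve(cf, Xty)
    # draw = mean + sqrt(sigma2) * U^-1 z with XtX = U'U (upper Cholesky)
    z = rng.standard_normal(design.shape[1])
    upper = np.linalg.cholesky(XtX).T
    return mean + np.sqrt(state.sigma2) * solve_triangular(upper, z, lower=False)


def step4_sample_sigma2(
    state: ParameterState, data: DataSet, spec: HLMSpec, rng: np.random.Generator,
    prior: PriorSpec,
) -> float:
    """sigma2 ~ IG(N/2 + a0, rate = sum e_ij^2 / 2 + 1/b0)."""
    design = build_design_matrix(spec, state.C_imp, data.X1, data.X2, data.cluster_index)
    e = state.Y_imp - design @ state.beta - state.u[data.cluster_index]
    shape = data.N / 2.0 + prior.ig_shape
    rate = float(e @ e) / 2.0 + prior.ig_rate
    return float(1.0 / rng.gamma(shape, 1.0 / rate))


def step5_impute_y(
    state: ParameterState, data: DataSet, spec: HLMSpec, rng: np.random.Generator
) -> np.ndarray:
    """Replace missing Y by linear predictor + fresh N(0, sigma2) noise."""
    y = state.Y_imp.copy()
    miss = data.y_missing
    if miss.any():
        design = build_design_matrix(spec, state.C_imp, data.X1, data.X2, data.cluster_index)
        lp = design[miss] @ state.beta + state.u[data.cluster_index[miss]]
        y[miss] = lp + np.sqrt(state.sigma2) * rng.standard_normal(int(miss.sum()))
    return y


def _wmat(data: DataSet) -> np.ndarray:
    return np.column_stack([np.ones(data.J), data.X2])


def step6_sample_alpha(
    state: ParameterState, data: DataSet, spec: HLMSpec, rng: np.random.Generator
) -> np.ndarray:
    """alpha ~ N((sum W'T^-1 W)^-1 sum W'T^-1 C_j, (sum W'T^-1 W)^-1).

    With W_j = I_p (x) (1, x2_j') the precision is kron(T^-1, sum w_j w_j').
    """
    Wm = _wmat(data)
    Tinv = np.linalg.inv(state.T)
    G = Wm.T @ Wm
    prec = np.kron(Tinv, G)
    rhs = (Wm.T @ state.C_imp @ Tinv).T.ravel()
    try:
        cf = cho_factor(prec)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError("singular covariate-model precision") from err
    mean = cho_solve(cf, rhs)
    upper = np.linalg.cholesky(prec).T
    z = rng.standard_normal(prec.shape[0])
    return mean + solve_triangular(upper, z, lower=False)


def step7_sample_T(
    state: ParameterState, data: DataSet, spec: HLMSpec, rng: np.random.Generator,
    prior: PriorSpec,
) -> np.ndarray:
    """T ~ IW(V0 + J, S0 + sum (C_j - W alpha)(C_j - W alpha)')."""
    Wm = _wmat(data)
    mean = Wm @ state.alpha.reshape(spec.p, 1 + spec.q2).T
    resid = state.C_imp - mean
    scale = prior.iw_scale + resid.T @ resid
    return invwishart.rvs(df=prior.iw_dof + data.J, scale=scale, random_state=rng)


def step8_impute_c(
    state: ParameterState, data: DataSet, spec: HLMSpec, rng: np.random.Generator
) -> np.ndarray:
    """Impute each missing C_kj from its exact normal posterior.

    Systematic scan k = 1..p; within the scan, values imputed for earlier k
    are used immediately (C_(-k)j mixes cycle-t and cycle-(t-1) entries).
    Vectorized across clusters for each k — clusters are conditionally
    independent given theta.
    """
    C = state.C_imp.copy()
    Wm = _wmat(data)
    mean_all = Wm @ state.alpha.reshape(spec.p, 1 + spec.q2).T  # (J, p)
    for k in range(1, spec.p + 1):
        i = k - 1
        jmiss = np.flatnonzero(data.c_missing[:, i])
        if jmiss.size == 0:
            continue
        rest = [r for r in range(spec.p) if r != i]
        if rest:
            Trr = state.T[np.ix_(rest, rest)]
            Tri = state.T[rest, i]
            sol = np.linalg.solve(Trr, Tri)
            T_cond = float(state.T[i, i] - Tri @ sol)
            M_cond = mean_all[jmiss, i] + (C[np.ix_(jmiss, rest)] - mean_all[np.ix_(jmiss, rest)]) @ sol
        else:
            T_cond = float(state.T[i, i])
            M_cond = mean_all[jmiss, i]
        if T_cond <= 0:
            raise np.linalg.LinAlgError("conditional variance nonpositive in step 8")
        # mu1/mu2 per row via linearity of the design in C_k
        rows = np.isin(data.cluster_index, jmiss)
        cl = data.cluster_index[rows]
        C0 = C.copy()
        C0[jmiss, i] = 0.0
        C1 = C0.copy()
        C1[jmiss, i] = 1.0
        d0 = build_design_matrix(spec, C0, data.X1[rows], data.X2, cl)
        d1 = build_design_matrix(spec, C1, data.X1[rows], data.X2, cl)
        mu1 = d0 @ state.beta + state.u[cl]
        mu2 = (d1 - d0) @ state.beta
        r = state.Y_imp[rows] - mu1
        s_mu2sq = np.bincount(cl, weights=mu2 * mu2, minlength=data.J)[jmiss]
        s_mu2r = np.bincount(cl, weights=mu2 * r, minlength=data.J)[jmiss]
        Delta = 1.0 / T_cond + s_mu2sq / state.sigma2
        M_tilde = (M_cond / T_cond + s_mu2r / state.sigma2) / Delta
        C[jmiss, i] = M_tilde + rng.standard_normal(jmiss.size) / np.sqrt(Delta)
    return C


# --------------------------------------------------------------------------
# initialization

def _initial_state(
    data: DataSet, spec: HLMSpec, strategy: str, rng: np.random.Generator
) -> ParameterState:
    C = data.C.copy()
    col_means = np.array(
        [np.nanmean(np.where(data.c_missing[:, k], np.nan, data.C[:, k])) for k in range(spec.p)]
    )
    col_means = np.where(np.isnan(col_means), 0.0, col_means)
    for k in range(spec.p):
        C[data.c_missing[:, k], k] = col_means[k]
    if strategy == "regression":
        # refine per-variable means by an observed-case regression on (1, x2)
        Wm = _wmat(data)
        for k in range(spec.p):
            obs = ~data.c_missing[:, k]
            if obs.sum() > spec.q2 + 1 and (~obs).any():
                coef, *_ = np.linalg.lstsq(Wm[obs], data.C[obs, k], rcond=None)
                C[~obs, k] = Wm[~obs] @ coef
    elif strategy != "mean":
        raise ValueError(f"unknown init strategy {strategy!r}")

    y = data.y.copy()
    y_obs = ~data.y_missing
    y[~y_obs] = y[y_obs].mean() if y_obs.any() else 0.0
    design = build_design_matrix(spec, C, data.X1, data.X2, data.cluster_index)
    if strategy == "regression" and y_obs.sum() > design.shape[1] and (~y_obs).any():
        coef, *_ = np.linalg.lstsq(design[y_obs], y[y_obs], rcond=None)
        y[~y_obs] = design[~y_obs] @ coef

    # complete-data fit for starting theta: OLS + a one-way moment split
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    e = y - design @ beta
    cmean = np.bincount(data.cluster_index, weights=e, minlength=data.J) / data.nj
    sigma2 = max(float(np.mean((e - cmean[data.cluster_index]) ** 2)), 1e-3)
    tau = max(float(np.var(cmean) - sigma2 / data.nj.mean()), 0.1)
    Wm = _wmat(data)
    acoef, *_ = np.linalg.lstsq(Wm, C, rcond=None)  # (1+q2, p)
    alpha = acoef.T.ravel()
    cres = C - Wm @ acoef
    T = cres.T @ cres / max(data.J - Wm.shape[1], 1)
    T += np.eye(spec.p) * max(1e-6, 1e-6 * np.trace(T))
    return ParameterState(
        beta=beta, tau=tau, sigma2=sigma2, alpha=alpha, T=T,
        u=np.zeros(data.J), C_imp=C, Y_imp=y,
    )


def _vech(T: np.ndarray) -> np.ndarray:
    p = T.shape[0]
    return np.concatenate([T[s, s:] for s in range(p)])


def param_names(spec: HLMSpec) -> tuple[str, ...]:
    return spec.coef_names + ("tau", "sigma2") + spec.alpha_names + spec.t_names


def _run_kernel(data, spec, prior, config, state, chain_id):
    """Dispatch to the compiled kernel (gshlm._kernel)."""
    from ._kernel import gibbs_kernel

    ci = data.cluster_index.astype(np.int64)
    order = np.argsort(ci, kind="stable").astype(np.int64)
    row_off = np.concatenate([[0], np.cumsum(data.nj)]).astype(np.int64)
    cmiss_lists = [np.flatnonzero(data.c_missing[:, k]) for k in range(spec.p)]
    cmiss_j = (
        np.concatenate(cmiss_lists).astype(np.int64)
        if any(a.size for a in cmiss_lists)
        else np.zeros(0, dtype=np.int64)
    )
    cmiss_off = np.concatenate([[0], np.cumsum([a.size for a in cmiss_lists])]).astype(np.int64)
    Xrow = np.ascontiguousarray(
        np.column_stack([data.X1, data.X2[ci]]).reshape(data.N, -1), dtype=np.float64
    )
    seed = int(config.chain_seed(chain_id).generate_state(1, dtype=np.uint32)[0])
    return gibbs_kernel(
        state.Y_imp.astype(np.float64),
        np.flatnonzero(data.y_missing).astype(np.int64),
        state.C_imp.astype(np.float64),
        cmiss_j,
        cmiss_off,
        ci,
        data.nj.astype(np.float64),
        order,
        row_off,
        Xrow,
        _wmat(data),
        spec.p,
        spec.q,
        np.array([s - 1 for s in spec.xc_terms], dtype=np.int64),
        np.array([s - 1 for s, _ in spec.cc_terms], dtype=np.int64),
        np.array([t - 1 for _, t in spec.cc_terms], dtype=np.int64),
        state.beta.astype(np.float64),
        float(state.tau),
        float(state.sigma2),
        state.alpha.astype(np.float64),
        state.T.astype(np.float64),
        float(prior.ig_shape),
        float(prior.ig_rate),
        float(prior.iw_dof),
        prior.iw_scale.astype(np.float64),
        config.n_burn,
        config.n_post,
        seed,
    )


def run_chain(
    data: DataSet,
    spec: HLMSpec,
    prior: PriorSpec | None = None,
    config: SamplerConfig | None = None,
    chain_id: int = 0,
    engine: str = "auto",
) -> ChainResult:
    """Run one Gibbs chain: Steps 1-8 per cycle, store post-burn-in theta.

    ``engine="compiled"`` uses the numba kernel (the default when available
    and extras are not stored); ``engine="reference"`` composes the
    pure-Python step functions.  Both target the same posterior; each is
    reproducible given the seed.
    """
    config = config or SamplerConfig()
    prior = (prior or PriorSpec()).resolved(data, spec)
    rng = np.random.default_rng(config.chain_seed(chain_id))
    strategy = config.chain_init(chain_id)
    state = _initial_state(data, spec, strategy, rng)
    if engine not in ("auto", "compiled", "reference"):
        raise ValueError(f"unknown engine {engine!r}")
    use_kernel = engine == "compiled" or (engine == "auto" and not config.store_extras)
    if use_kernel:
        try:
            draws = _run_kernel(data, spec, prior, config, state, chain_id)
        except ImportError:
            if engine == "compiled":
                raise
            use_kernel = False
        else:
            return ChainResult(
                param_names=param_names(spec),
                draws=draws,
                chain_id=chain_id,
                init_strategy=strategy,
            )

    names = param_names(spec)
    K = len(names)
    draws = np.empty((config.n_post, K))
    extras = {"u": [], "C_imp": [], "Y_imp": []} if config.store_extras else None

    n_total = config.n_burn + config.n_post
    for t in range(n_total):
        try:
            state.u = step1_sample_u(state, data, spec, rng)
            state.tau = step2_sample_tau(state.u, prior, rng)
            state.beta = step3_sample_beta(state, data, spec, rng)
            state.sigma2 = step4_sample_sigma2(state, data, spec, rng, prior)
            state.Y_imp = step5_impute_y(state, data, spec, rng)
            state.alpha = step6_sample_alpha(state, data, spec, rng)
            state.T = step7_sample_T(state, data, spec, rng, prior)
            state.C_imp = step8_impute_c(state, data, spec, rng)
        except np.linalg.LinAlgError as err:
            raise RuntimeError(f"Gibbs cycle {t} failed: {err}") from err
        if t >= config.n_burn:
            s = t - config.n_burn
            draws[s, : spec.n_coef] = state.beta
            draws[s, spec.n_coef] = state.tau
            draws[s, spec.n_coef + 1] = state.sigma2
            draws[s, spec.n_coef + 2 : spec.n_coef + 2 + spec.n_alpha] = state.alpha
            draws[s, spec.n_coef + 2 + spec.n_alpha :] = _vech(state.T)
            if extras is not None:
                extras["u"].append(state.u.copy())
                extras["C_imp"].append(state.C_imp.copy())
                extras["Y_imp"].append(state.Y_imp.copy())
    result = ChainResult(
        param_names=names,
        draws=draws,
        chain_id=chain_id,
        init_strategy=strategy,
        extras={k: np.array(v) for k, v in extras.items()} if extras else {},
    )
    return result


def run_chains(
    data: DataSet,
    spec: HLMSpec,
    prior: PriorSpec | None = None,
    config: SamplerConfig | None = None,
) -> list[ChainResult]:
    config = config or SamplerConfig()
    return [
        run_chain(data, spec, prior, config, chain_id=c) for c in range(config.n_chains)
    ]
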