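"""Model specification, data containers and closed-form conditional moments.

The analytic model is a two-level random-intercept hierarchical linear model
(HLM) in which a vector of continuous cluster-level covariates ``C`` may be
partially observed and may enter through interaction terms::

    Y_ij = b0 + bC'C_j + bX'X_ij + sum_s bXC_s'(X_ij * C_sj)
           + sum_{s<t} bCC_st * C_sj C_tj + u_j + e_ij

with ``u_j ~ N(0, tau)`` and ``e_ij ~ N(0, sigma2)`` independent, level-1
units i nested in clusters j.  ``X_ij = (x1_ij, x2_j)`` is fully observed
(level-1 and level-2 parts), while the covariate model for C given the known
level-2 covariates is jointly normal,

    C_j | x2_j ~ N(W_j alpha, T),   W_j = I_p (x) (1, x2_j'),

which is what makes every full conditional of the Gibbs sampler available in
closed form.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "HLMSpec",
    "DataSet",
    "PriorSpec",
    "ParameterState",
    "ConditionalCMoments",
    "build_design_vector",
    "build_design_matrix",
    "conditional_c_moments",
    "split_linear_predictor",
    "c_posterior_moments",
    "icc",
]


def icc(tau: float, sigma2: float) -> float:
    """Intra-cluster correlation tau / (tau + sigma2)."""
    return tau / (tau + sigma2)


@dataclass(frozen=True)
class HLMSpec:
    """Declares which covariates and interaction terms enter the HLM.

    Parameters
    ----------
    p : number of (potentially partially observed) cluster-level covariates C.
    q1 : number of fully observed level-1 covariates x1.
    q2 : number of fully observed level-2 covariates x2.
    xc_terms : 1-based covariate indices s for which the full X x C_s
        interaction block (q = q1 + q2 coefficients) enters the model.
    cc_terms : ordered pairs (s, t), s < t, of C_s x C_t interactions.

    The stacked coefficient layout is
    ``[intercept, bC (p), bX (q), bXC_s (q per declared s), bCC_st (1 per pair)]``
    with xc_terms sorted ascending and cc_terms lexicographically.
    """

    p: int
    q1: int = 0
    q2: int = 0
    xc_terms: tuple[int, ...] = ()
    cc_terms: tuple[tuple[int, int], ...] = ()
    c_names: tuple[str, ...] | None = None
    x1_names: tuple[str, ...] | None = None
    x2_names: tuple[str, ...] | None = None

    def __post_init__(self):
        if self.p < 1:
            raise ValueError("need at least one cluster-level covariate C")
        object.__setattr__(self, "xc_terms", tuple(sorted(self.xc_terms)))
        object.__setattr__(self, "cc_terms", tuple(sorted(tuple(p_) for p_ in self.cc_terms)))
        for s in self.xc_terms:
            if not 1 <= s <= self.p:
                raise ValueError(f"xc_terms index {s} outside 1..{self.p}")
        for s, t in self.cc_terms:
            if not (1 <= s < t <= self.p):
                raise ValueError(f"cc_terms pair ({s},{t}) must satisfy 1 <= s < t <= p")
        if len(set(self.xc_terms)) != len(self.xc_terms) or len(set(self.cc_terms)) != len(self.cc_terms):
            raise ValueError("duplicate interaction terms")
        if self.c_names is None:
            object.__setattr__(self, "c_names", tuple(f"C{k}" for k in range(1, self.p + 1)))
        if self.x1_names is None:
            object.__setattr__(self, "x1_names", tuple(f"x1_{k}" for k in range(1, self.q1 + 1)))
        if self.x2_names is None:
            object.__setattr__(self, "x2_names", tuple(f"x2_{k}" for k in range(1, self.q2 + 1)))

    @property
    def q(self) -> int:
        return self.q1 + self.q2

    @property
    def n_coef(self) -> int:
        return 1 + self.p + self.q + len(self.xc_terms) * self.q + len(self.cc_terms)

    @property
    def n_alpha(self) -> int:
        """Length of the covariate-model fixed effect alpha: p blocks of (1, x2)."""
        return self.p * (1 + self.q2)

    @property
    def x_names(self) -> tuple[str, ...]:
        return self.x1_names + self.x2_names

    @property
    def coef_names(self) -> tuple[str, ...]:
        names = ["(Intercept)", *self.c_names, *self.x_names]
        for s in self.xc_terms:
            names += [f"{xn}:{self.c_names[s - 1]}" for xn in self.x_names]
        for s, t in self.cc_terms:
            names.append(f"{self.c_names[s - 1]}:{self.c_names[t - 1]}")
        return tuple(names)

    @property
    def alpha_names(self) -> tuple[str, ...]:
        names = []
        for k in range(self.p):
            names.append(f"alpha[{self.c_names[k]}~1]")
            names += [f"alpha[{self.c_names[k]}~{xn}]" for xn in self.x2_names]
        return tuple(names)

    @property
    def t_names(self) -> tuple[str, ...]:
        return tuple(
            f"T[{s},{t}]" for s in range(1, self.p + 1) for t in range(s, self.p + 1)
        )


def build_design_vector(
    spec: HLMSpec,
    c_row: np.ndarray,
    x1: np.ndarray | None = None,
    x2: np.ndarray | None = None,
) -> np.ndarray:
    """Stacked regressor vector for one level-1 unit.

    The inner product with the stacked coefficient vector reproduces the
    fixed part of the HLM mean, ``E(Y_ij | .) - u_j``.
    """
    c_row = np.asarray(c_row, dtype=float)
    if c_row.shape != (spec.p,):
        raise ValueError(f"c_row must have length p={spec.p}")
    if np.isnan(c_row).any():
        raise ValueError(
            "c_row contains missing entries: covariates must be imputed before "
            "the design vector is formed (imputation-order violation)"
        )
    x1 = np.zeros(0) if x1 is None else np.atleast_1d(np.asarray(x1, dtype=float))
    x2 = np.zeros(0) if x2 is None else np.atleast_1d(np.asarray(x2, dtype=float))
    if x1.shape != (spec.q1,) or x2.shape != (spec.q2,):
        raise ValueError("x1/x2 lengths do not match the model spec")
    x = np.concatenate([x1, x2])
    parts = [np.ones(1), c_row, x]
    for s in spec.xc_terms:
        parts.append(x * c_row[s - 1])
    for s, t in spec.cc_terms:
        parts.append(np.array([c_row[s - 1] * c_row[t - 1]]))
    return np.concatenate(parts)


def build_design_matrix(
    spec: HLMSpec,
    C: np.ndarray,
    X1: np.ndarray,
    X2: np.ndarray,
    cluster_index: np.ndarray,
) -> np.ndarray:
    """Row-stacked design for all N level-1 units (vectorized).

    C : (J, p) completed cluster covariates; X1 : (N, q1); X2 : (J, q2);
    cluster_index : (N,) 0-based cluster of each row.
    """
    C = np.asarray(C, dtype=float)
    if np.isnan(C).any():
        raise ValueError("completed C required: impute C before building the design")
    N = cluster_index.shape[0]
    Crows = C[cluster_index]  # (N, p)
    X = np.column_stack([X1.reshape(N, -1), X2[cluster_index].reshape(N, -1)])
    cols = [np.ones((N, 1)), Crows, X]
    for s in spec.xc_terms:
        cols.append(X * Crows[:, s - 1 : s])
    for s, t in spec.cc_terms:
        cols.append((Crows[:, s - 1] * Crows[:, t - 1])[:, None])
    return np.concatenate(cols, axis=1)


@dataclass
class DataSet:
    """Long-format two-level data with missingness masks.

    ``y`` holds one value per level-1 row; entries flagged in ``y_missing``
    are unobserved (they may still carry the pre-deletion truth in synthetic
    data, or NaN for real data — the sampler never reads them).  ``C`` is the
    (J, p) cluster-level covariate matrix with mask ``c_missing``; missing C
    means the value is absent for the whole cluster.  X1 and X2 must be fully
    observed.
    """

    y: np.ndarray
    y_missing: np.ndarray
    C: np.ndarray
    c_missing: np.ndarray
    X1: np.ndarray
    X2: np.ndarray
    cluster_index: np.ndarray
    cluster_ids: np.ndarray | None = None

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=float)
        self.y_missing = np.asarray(self.y_missing, dtype=bool)
        self.C = np.atleast_2d(np.asarray(self.C, dtype=float))
        self.c_missing = np.atleast_2d(np.asarray(self.c_missing, dtype=bool))
        self.cluster_index = np.asarray(self.cluster_index, dtype=np.intp)
        N = self.y.shape[0]
        J = self.C.shape[0]
        self.X1 = np.asarray(self.X1, dtype=float).reshape(N, -1)
        self.X2 = np.asarray(self.X2, dtype=float).reshape(J, -1)
        if self.cluster_ids is None:
            self.cluster_ids = np.arange(1, J + 1)
        if self.y_missing.shape != (N,):
            raise ValueError("y_missing must align with y")
        if self.c_missing.shape != self.C.shape:
            raise ValueError("c_missing must align with C")
        if self.cluster_index.shape != (N,):
            raise ValueError("cluster_index must align with y")
        if self.cluster_index.min() < 0 or self.cluster_index.max() >= J:
            raise ValueError("cluster_index out of range")
        if np.isnan(self.X1).any() or np.isnan(self.X2).any():
            raise ValueError("X1 and X2 must be fully observed")
        if np.bincount(self.cluster_index, minlength=J).min() < 1:
            raise ValueError("every cluster needs at least one level-1 row")
        if np.isnan(self.y[~self.y_missing]).any() or np.isnan(self.C[~self.c_missing]).any():
            raise ValueError("observed entries must not be NaN")

    @property
    def J(self) -> int:
        return self.C.shape[0]

    @property
    def N(self) -> int:
        return self.y.shape[0]

    @property
    def p(self) -> int:
        return self.C.shape[1]

    @property
    def nj(self) -> np.ndarray:
        return np.bincount(self.cluster_index, minlength=self.J)

    def missing_rates(self) -> dict[str, float]:
        out = {"Y": float(self.y_missing.mean())}
        for k in range(self.p):
            out[f"C{k + 1}"] = float(self.c_missing[:, k].mean())
        return out


@dataclass
class PriorSpec:
    """Hyperparameters of the conjugate priors.

    tau and sigma2 carry IG(a0, b0) priors written in the shape/scale-hyper
    convention where the posterior rate is ``(sum of squares)/2 + 1/b0``;
    the default a0 = 1, b0 = 0.5 therefore corresponds to prior rate 2.
    T carries an inverse-Wishart prior IW(iw_dof, iw_scale) with defaults
    iw_dof = p + 2 and iw_scale = complete-case residual covariance of C
    (identity fallback when complete cases are too few).  beta and alpha get
    flat priors.
    """

    ig_shape: float = 1.0
    ig_scale_hyper: float = 0.5
    iw_dof: float | None = None
    iw_scale: np.ndarray | None = None

    def __post_init__(self):
        if self.ig_shape <= 0 or self.ig_scale_hyper <= 0:
            raise ValueError("inverse-gamma hyperparameters must be positive")

    @property
    def ig_rate(self) -> float:
        return 1.0 / self.ig_scale_hyper

    def resolved(self, data: DataSet, spec: HLMSpec) -> "PriorSpec":
        """Fill iw_dof/iw_scale defaults from the data (complete-case T-hat)."""
        dof = self.iw_dof if self.iw_dof is not None else spec.p + 2
        if dof <= spec.p - 1:
            raise ValueError("iw_dof must exceed p - 1")
        scale = self.iw_scale
        if scale is None:
            scale = _complete_case_that(data, spec)
        scale = np.asarray(scale, dtype=float)
        if scale.shape != (spec.p, spec.p) or not np.all(np.linalg.eigvalsh(scale) > 0):
            raise ValueError("iw_scale must be a p x p positive definite matrix")
        return PriorSpec(self.ig_shape, self.ig_scale_hyper, float(dof), scale)


def _complete_case_that(data: DataSet, spec: HLMSpec) -> np.ndarray:
    """Residual covariance of C on (1, x2) over clusters with C fully observed."""
    cc = ~data.c_missing.any(axis=1)
    n_cc = int(cc.sum())
    if n_cc <= spec.p + spec.q2 + 1:
        return np.eye(spec.p)
    W = np.column_stack([np.ones(n_cc), data.X2[cc]])
    Cc = data.C[cc]
    coef, *_ = np.linalg.lstsq(W, Cc, rcond=None)
    resid = Cc - W @ coef
    that = resid.T @ resid / max(n_cc - W.shape[1], 1)
    if not np.all(np.linalg.eigvalsh(that) > 1e-10):
        return np.eye(spec.p)
    return that


@dataclass
class ParameterState:
    """One Gibbs-cycle snapshot of parameters and completed data."""

    beta: np.ndarray
    tau: float
    sigma2: float
    alpha: np.ndarray
    T: np.ndarray
    u: np.ndarray
    C_imp: np.ndarray
    Y_imp: np.ndarray

    def validate(self, data: DataSet) -> None:
        if not (self.tau > 0 and self.sigma2 > 0):
            raise ValueError("tau and sigma2 must be positive")
        if not np.allclose(self.T, self.T.T) or np.any(np.linalg.eigvalsh(self.T) <= 0):
            raise ValueError("T must be symmetric positive definite")
        if np.isnan(self.C_imp).any() or np.isnan(self.Y_imp).any():
            raise ValueError("completed arrays must have no missing entries")
        obs_y = ~data.y_missing
        obs_c = ~data.c_missing
        if not np.array_equal(self.Y_imp[obs_y], data.y[obs_y]) or not np.array_equal(
            self.C_imp[obs_c], data.C[obs_c]
        ):
            raise ValueError("observed entries were modified by the sampler")


@dataclass
class ConditionalCMoments:
    """Closed-form ingredients of the exact posterior of one missing C_kj.

    M_cond / T_cond are the mean and variance of C_kj given the other
    covariates under the joint normal covariate model; mu1/mu2 split the HLM
    linear predictor into the parts excluding and multiplying C_kj; M_tilde
    and Delta are the resulting posterior mean and precision,
    C_kj | . ~ N(M_tilde, 1/Delta).
    """

    M_cond: float
    T_cond: float
    mu1: np.ndarray
    mu2: np.ndarray
    M_tilde: float
    Delta: float


def conditional_c_moments(
    k: int,
    c_minus_k: np.ndarray,
    x2: np.ndarray | None,
    alpha: np.ndarray,
    T: np.ndarray,
) -> tuple[float, float]:
    """Mean and variance of C_kj | C_(-k)j, x2_j under C_j ~ N(W alpha, T).

    ``k`` is 1-based.  The conditional variance does not depend on the
    conditioning values.
    """
    T = np.asarray(T, dtype=float)
    p = T.shape[0]
    if not 1 <= k <= p:
        raise ValueError(f"k={k} outside 1..{p}")
    x2 = np.zeros(0) if x2 is None else np.atleast_1d(np.asarray(x2, dtype=float))
    w = np.concatenate([[1.0], x2])
    m = np.asarray(alpha, dtype=float).reshape(p, w.size) @ w  # marginal means, (p,)
    i = k - 1
    rest = [j for j in range(p) if j != i]
    if not rest:
        return float(m[i]), float(T[i, i])
    Trr = T[np.ix_(rest, rest)]
    Tri = T[rest, i]
    try:
        sol = np.linalg.solve(Trr, Tri)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            f"conditioning block T[-{k},-{k}] is singular"
        ) from err
    c_minus_k = np.asarray(c_minus_k, dtype=float)
    M_cond = m[i] + (c_minus_k - m[rest]) @ sol
    T_cond = T[i, i] - Tri @ sol
    if T_cond <= 0:
        raise np.linalg.LinAlgError("conditional variance is nonpositive; T is not PD")
    return float(M_cond), float(T_cond)


def split_linear_predictor(
    spec: HLMSpec,
    k: int,
    c_row: np.ndarray,
    x1: np.ndarray | None,
    x2: np.ndarray | None,
    beta: np.ndarray,
    u_j: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Split the HLM mean into mu1 (excluding C_kj) and mu2 (multiplying C_kj).

    For each level-1 unit i of cluster j, ``mu1_i + mu2_i * C_kj`` equals the
    full linear predictor including u_j, identically in C_kj: the design is
    exactly linear in C_kj, so the split is computed by evaluating the
    predictor at C_kj = 0 and C_kj = 1.

    x1 is (nj, q1) (or None when q1 = 0); returns (mu1, mu2) of length nj.
    """
    if not 1 <= k <= spec.p:
        raise ValueError(f"k={k} outside 1..{spec.p}")
    c_row = np.asarray(c_row, dtype=float)
    rest = [j for j in range(spec.p) if j != k - 1]
    if np.isnan(c_row[rest]).any():
        raise ValueError("c_minus_k must be complete")
    if spec.q1 > 0:
        x1 = np.asarray(x1, dtype=float).reshape(-1, spec.q1)
        nj = x1.shape[0]
    else:
        x1 = None
        nj = 1
    c0 = c_row.copy()
    c0[k - 1] = 0.0
    c1 = c_row.copy()
    c1[k - 1] = 1.0
    mu1 = np.empty(nj)
    mu2 = np.empty(nj)
    beta = np.asarray(beta, dtype=float)
    for i in range(nj):
        x1i = None if x1 is None else x1[i]
        v0 = build_design_vector(spec, c0, x1i, x2) @ beta
        v1 = build_design_vector(spec, c1, x1i, x2) @ beta
        mu1[i] = v0 + u_j
        mu2[i] = v1 - v0
    return mu1, mu2


def c_posterior_moments(
    spec: HLMSpec,
    k: int,
    c_row: np.ndarray,
    x1: np.ndarray | None,
    x2: np.ndarray | None,
    y_j: np.ndarray,
    beta: np.ndarray,
    u_j: float,
    sigma2: float,
    alpha: np.ndarray,
    T: np.ndarray,
) -> ConditionalCMoments:
    """Exact posterior N(M_tilde, 1/Delta) of a missing C_kj.

    Combines the covariate-model conditional N(M_cond, T_cond) with the nj
    outcome likelihood contributions of cluster j:

        Delta   = 1/T_cond + sum_i mu2_i^2 / sigma2
        M_tilde = (M_cond / T_cond + sum_i mu2_i (y_i - mu1_i) / sigma2) / Delta
    """
    c_row = np.asarray(c_row, dtype=float)
    rest = [j for j in range(spec.p) if j != k - 1]
    M_cond, T_cond = conditional_c_moments(k, c_row[rest], x2, alpha, T)
    mu1, mu2 = split_linear_predictor(spec, k, c_row, x1, x2, beta, u_j)
    y_j = np.atleast_1d(np.asarray(y_j, dtype=float))
    if spec.q1 == 0 and mu1.size == 1 and y_j.size > 1:
        mu1 = np.repeat(mu1, y_j.size)
        mu2 = np.repeat(mu2, y_j.size)
    Delta = 1.0 / T_cond + float(mu2 @ mu2) / sigma2
    M_tilde = (M_cond / T_cond + float(mu2 @ (y_j - mu1)) / sigma2) / Delta
    return ConditionalCMoments(M_cond, T_cond, mu1, mu2, float(M_tilde), float(Delta))
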