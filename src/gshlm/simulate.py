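"""Simulation-study data generators and missingness mechanisms.

Four scenarios, all with X_j ~ N(2, 1), tau = 4, sigma2 = 16 and every HLM
coefficient equal to 1:

``correct``
    C_j | X_j bivariate normal with C1 ~ N(0.75 + 0.7 X, 1.25),
    C2 ~ N(-0.5 + X, 1), conditional covariance -0.5;
    Y mean 1 + C1 + C2 + X + C1*C2.
``lognormal``
    C1 ~ logNormal(meanlog = 0.5 + 0.1 X, varlog = 0.2) — mean ~2, variance
    ~1, skewness ~1.6 — and C2 ~ N(1 + 0.1 C1 + 0.3 X, 1); the covariate
    normality assumed by the sampler is deliberately violated.
``mnar``
    Data as in ``correct`` but C1, C2 deleted by a mechanism that depends on
    the pre-deletion C1 (missing NOT at random); Y stays MAR.
``extra``
    Y mean adds two partially observed interactions C1*X + C2*X.

Missingness (all ~15-20% marginally):

MAR (depends only on the fully observed X):  logit(p_j) ~ N(c0 + c1 X_j, delta)
with delta a *variance*; one p_j per cluster.  For cluster-level C the whole
cluster's value is deleted with probability p_j; for Y each of the nj cells is
deleted independently with probability p_j.

MNAR: logit(p_j) = d0 + d1 * C1_j using pre-deletion C1 values.

Masked values are retained in the arrays so the truth is available for
scoring; only the masks mark them unobserved.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import expit

from .model import DataSet, HLMSpec

__all__ = [
    "ScenarioSpec",
    "MissingnessMechanism",
    "SCENARIOS",
    "make_scenario",
    "default_mechanisms",
    "generate_complete",
    "apply_missingness",
    "generate_scenario_data",
]

SCENARIOS = ("correct", "lognormal", "mnar", "extra")


@dataclass(frozen=True)
class ScenarioSpec:
    """Generator parameters for one simulation scenario."""

    scenario: str = "correct"
    J: int = 36
    nj: int = 4
    x_mean: float = 2.0
    x_var: float = 1.0
    # covariate model C | X (scenario correct/mnar/extra):
    alpha: tuple[float, ...] = (0.75, 0.7, -0.5, 1.0)  # (a10, a11, a20, a21)
    T: tuple[tuple[float, float], ...] = ((1.25, -0.5), (-0.5, 1.0))
    # lognormal scenario: C1 ~ logN(l0 + l1*X, varlog); C2 ~ N(g0 + g1*C1 + g2*X, g_var)
    lognormal_meanlog: tuple[float, float] = (0.5, 0.1)
    lognormal_varlog: float = 0.2
    c2_given_c1: tuple[float, float, float] = (1.0, 0.1, 0.3)
    c2_var: float = 1.0
    # HLM
    beta: tuple[float, ...] | None = None  # default: all ones
    tau: float = 4.0
    sigma2: float = 16.0

    def __post_init__(self):
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}; choose from {SCENARIOS}")
        if self.J < 2 or self.nj < 1:
            raise ValueError("need J >= 2 and nj >= 1")
        if self.x_var <= 0 or self.tau < 0 or self.sigma2 < 0:
            raise ValueError("variances must be nonnegative (x_var positive)")

    @property
    def hlm_spec(self) -> HLMSpec:
        xc = (1, 2) if self.scenario == "extra" else ()
        return HLMSpec(p=2, q1=0, q2=1, xc_terms=xc, cc_terms=((1, 2),),
                       c_names=("C1", "C2"), x2_names=("X",))


@dataclass(frozen=True)
class MissingnessMechanism:
    """One per-variable missingness rule.

    kind "MAR":  logit(p_j) ~ N(c0 + c1 X_j, delta), delta >= 0 a variance.
    kind "MNAR": logit(p_j) = d0 + d1 * C1_j (pre-deletion values).
    target: "Y", or "Ck" for the k-th cluster covariate.
    """

    kind: str
    target: str
    c0: float = 0.0
    c1: float = 0.0
    delta: float = 0.0
    d0: float = 0.0
    d1: float = 0.0

    def __post_init__(self):
        if self.kind not in ("MAR", "MNAR"):
            raise ValueError("kind must be MAR or MNAR")
        if self.delta < 0:
            raise ValueError("delta must be nonnegative")
        if self.target == "X" or self.target.startswith("x"):
            raise ValueError("X must stay fully observed; mechanisms cannot target it")

    def cluster_probs(self, X: np.ndarray, C_pre: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        if self.kind == "MAR":
            logit = self.c0 + self.c1 * X
            if self.delta > 0:
                logit = logit + np.sqrt(self.delta) * rng.standard_normal(X.shape[0])
        else:
            logit = self.d0 + self.d1 * C_pre[:, 0]
        return expit(logit)


def default_mechanisms(scenario: str = "correct") -> list[MissingnessMechanism]:
    """The study's per-variable mechanisms (~20% marginal missingness each)."""
    mar_y = MissingnessMechanism("MAR", "Y", c0=-1.9, c1=0.1, delta=1.0)
    if scenario == "mnar":
        return [
            mar_y,
            MissingnessMechanism("MNAR", "C1", d0=-5.0, d1=1.3),
            MissingnessMechanism("MNAR", "C2", d0=-10.5, d1=3.0),
        ]
    return [
        mar_y,
        MissingnessMechanism("MAR", "C1", c0=0.8, c1=-1.5, delta=0.0),
        MissingnessMechanism("MAR", "C2", c0=-2.8, c1=0.5, delta=0.0),
    ]


def make_scenario(scenario: str, J: int = 36, nj: int = 4, **kw) -> ScenarioSpec:
    return ScenarioSpec(scenario=scenario, J=J, nj=nj, **kw)


def generate_complete(
    scenario: ScenarioSpec, rng: np.random.Generator
) -> tuple[DataSet, dict[str, float]]:
    """Fully observed DataSet plus the record of true parameter values.

    Y is generated through explicit u_j ~ N(0, tau) and e_ij ~ N(0, sigma2)
    (distributionally identical to the collapsed N(mean, tau + sigma2) form)
    so that random-effect recovery can be checked.
    """
    J, nj = scenario.J, scenario.nj
    X = rng.normal(scenario.x_mean, np.sqrt(scenario.x_var), size=J)
    if scenario.scenario == "lognormal":
        l0, l1 = scenario.lognormal_meanlog
        C1 = np.exp(rng.normal(l0 + l1 * X, np.sqrt(scenario.lognormal_varlog)))
        g0, g1, g2 = scenario.c2_given_c1
        C2 = rng.normal(g0 + g1 * C1 + g2 * X, np.sqrt(scenario.c2_var))
        C = np.column_stack([C1, C2])
    else:
        a = np.asarray(scenario.alpha).reshape(2, 2)
        mean = np.column_stack([np.ones(J), X]) @ a.T  # (J, 2)
        L = np.linalg.cholesky(np.asarray(scenario.T))
        C = mean + rng.standard_normal((J, 2)) @ L.T

    spec = scenario.hlm_spec
    beta = (
        np.ones(spec.n_coef) if scenario.beta is None else np.asarray(scenario.beta, float)
    )
    if beta.shape != (spec.n_coef,):
        raise ValueError("beta length does not match the scenario's model")

    cluster_index = np.repeat(np.arange(J), nj)
    from .model import build_design_matrix

    X1 = np.zeros((J * nj, 0))
    design = build_design_matrix(spec, C, X1, X[:, None], cluster_index)
    u = np.sqrt(scenario.tau) * rng.standard_normal(J)
    e = np.sqrt(scenario.sigma2) * rng.standard_normal(J * nj)
    y = design @ beta + u[cluster_index] + e

    data = DataSet(
        y=y,
        y_missing=np.zeros(J * nj, dtype=bool),
        C=C,
        c_missing=np.zeros((J, 2), dtype=bool),
        X1=X1,
        X2=X[:, None],
        cluster_index=cluster_index,
    )
    truth: dict[str, float] = dict(zip(spec.coef_names, beta))
    truth["tau"] = scenario.tau
    truth["sigma2"] = scenario.sigma2
    if scenario.scenario != "lognormal":
        truth.update(zip(spec.alpha_names, np.asarray(scenario.alpha, float)))
        Tm = np.asarray(scenario.T, float)
        truth.update(zip(spec.t_names, [Tm[0, 0], Tm[0, 1], Tm[1, 1]]))
    return data, truth


def apply_missingness(
    data: DataSet,
    mechanisms: list[MissingnessMechanism],
    rng: np.random.Generator,
) -> DataSet:
    """Return a copy of ``data`` with missingness masks drawn per mechanism.

    Values are preserved under the masks (truth kept out-of-band).  MNAR
    mechanisms use the pre-deletion C matrix, which must be fully observed.
    """
    y_missing = data.y_missing.copy()
    c_missing = data.c_missing.copy()
    X = data.X2[:, 0] if data.X2.shape[1] else np.zeros(data.J)
    for mech in mechanisms:
        pj = mech.cluster_probs(X, data.C, rng)
        if mech.target == "Y":
            # one probability per cluster, applied to each level-1 cell
            draws = rng.random(data.N) < pj[data.cluster_index]
            y_missing |= draws
        else:
            k = int(mech.target[1:]) - 1
            if not 0 <= k < data.p:
                raise ValueError(f"unknown target {mech.target!r}")
            c_missing[:, k] |= rng.random(data.J) < pj
    return DataSet(
        y=data.y.copy(),
        y_missing=y_missing,
        C=data.C.copy(),
        c_missing=c_missing,
        X1=data.X1.copy(),
        X2=data.X2.copy(),
        cluster_index=data.cluster_index.copy(),
        cluster_ids=None if data.cluster_ids is None else data.cluster_ids.copy(),
    )


def generate_scenario_data(
    scenario: ScenarioSpec,
    rng: np.random.Generator,
    mechanisms: list[MissingnessMechanism] | None = None,
) -> tuple[DataSet, DataSet, dict[str, float]]:
    """Convenience: (complete data, masked data, truth) for one replicate."""
    complete, truth = generate_complete(scenario, rng)
    if mechanisms is None:
        mechanisms = default_mechanisms(scenario.scenario)
    masked = apply_missingness(complete, mechanisms, rng)
    return complete, masked, truth
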