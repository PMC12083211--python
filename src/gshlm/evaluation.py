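"""Replication harness: simulate -> fit -> score cycles and the CDML baseline.

The study design repeats, for R replicates: generate a complete dataset from
a scenario, fit the complete-data maximum-likelihood benchmark (CDML, a
random-intercept linear mixed model), delete values by the scenario's
missingness mechanisms, run the compatible Gibbs sampler on the masked data,
and score both estimators against the simulated truth with four metrics:

%bias    (mean point estimate - truth) * 100 / truth
ASE      mean of the per-replicate standard errors / posterior sds
ESE      standard deviation of the point estimates across replicates
coverage fraction of replicates whose 95% interval contains the truth

Point estimates are posterior means; intervals are equal-tailed 2.5/97.5
percentile credible intervals (Wald intervals for CDML).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .diagnostics import PSRF_THRESHOLD, GEWEKE_Z_CRIT, convergence_report
from .model import DataSet, HLMSpec, build_design_matrix
from .sampler import SamplerConfig, run_chains, summarize
from .simulate import (
    MissingnessMechanism,
    ScenarioSpec,
    default_mechanisms,
    generate_complete,
    apply_missingness,
)

__all__ = [
    "CDMLResult",
    "SimulationMetrics",
    "StudyResult",
    "cdml_fit",
    "metrics_from_estimates",
    "run_study",
]


@dataclass
class CDMLResult:
    """Complete-data ML fit of the random-intercept HLM."""

    params: pd.Series  # named: coefficients, then tau, sigma2
    se: pd.Series
    ci_lower: pd.Series
    ci_upper: pd.Series
    loglik: float
    converged: bool


def _ri_loglik(beta, tau, sigma2, y, design, cluster_index, J):
    """Marginal log-likelihood of the random-intercept model (Woodbury form)."""
    if tau < 0 or sigma2 <= 0:
        return -np.inf
    r = y - design @ beta
    nj = np.bincount(cluster_index, minlength=J)
    rsum = np.bincount(cluster_index, weights=r, minlength=J)
    denom = sigma2 + nj * tau
    quad = (r @ r - tau * np.sum(rsum**2 / denom)) / sigma2
    logdet = (y.size - J) * np.log(sigma2) + np.sum(np.log(denom))
    return -0.5 * (y.size * np.log(2 * np.pi) + logdet + quad)


def _ri_reml_crit(tau, sigma2, y, design, cluster_index, J):
    """Profile REML criterion of the random-intercept model at (tau, sigma2).

    Profiles the fixed effects at their GLS solution and adds the REML
    determinant correction log det(X'V^-1 X).
    """
    if tau < 0 or sigma2 <= 0:
        return -np.inf
    N, d = design.shape
    nj = np.bincount(cluster_index, minlength=J)
    denom = sigma2 + nj * tau
    w = tau / denom  # per-cluster Woodbury weight
    Xsum = np.zeros((J, d))
    for k in range(d):
        Xsum[:, k] = np.bincount(cluster_index, weights=design[:, k], minlength=J)
    ysum = np.bincount(cluster_index, weights=y, minlength=J)
    XtVX = (design.T @ design - (Xsum * w[:, None]).T @ Xsum) / sigma2
    XtVy = (design.T @ y - Xsum.T @ (w * ysum)) / sigma2
    beta = np.linalg.solve(XtVX, XtVy)
    r = y - design @ beta
    rsum = ysum - Xsum @ beta
    quad = (r @ r - tau * np.sum(rsum**2 / denom)) / sigma2
    logdet = (N - J) * np.log(sigma2) + np.sum(np.log(denom))
    sign, logdet_info = np.linalg.slogdet(XtVX)
    if sign <= 0:
        return -np.inf
    return -0.5 * ((N - d) * np.log(2 * np.pi) + logdet + quad + logdet_info)


def cdml_fit(data: DataSet, spec: HLMSpec, reml: bool = True) -> CDMLResult:
    """Benchmark mixed-model fit (statsmodels MixedLM) on fully observed data.

    The default is REML — the convention of the standard mixed-model
    software this benchmark emulates, and the choice under which the
    variance components are (near-)unbiased at small J; ``reml=False``
    gives straight ML.  Fixed-effect standard errors come from the
    mixed-model fit; standard errors for (tau, sigma2) are taken from the
    observed information of the closed-form (restricted) likelihood
    (central finite differences), because MixedLM reports
    variance-parameter uncertainty on a profiled scale.  95% intervals are
    Wald.
    """
    if data.y_missing.any() or data.c_missing.any():
        raise ValueError("CDML requires complete (pre-deletion) data")
    import warnings as _warnings

    from statsmodels.regression.mixed_linear_model import MixedLM
    from statsmodels.tools.sm_exceptions import ConvergenceWarning

    design = build_design_matrix(spec, data.C, data.X1, data.X2, data.cluster_index)
    model = MixedLM(data.y, design, groups=data.cluster_index)
    with np.errstate(all="ignore"), _warnings.catch_warnings():
        _warnings.simplefilter("ignore", UserWarning)
        _warnings.simplefilter("ignore", ConvergenceWarning)
        _warnings.simplefilter("ignore", RuntimeWarning)
        fit = model.fit(reml=reml)
        if not fit.converged:
            fit = model.fit(reml=reml, method="powell", maxiter=500)
    beta = np.asarray(fit.fe_params)
    tau = float(np.asarray(fit.cov_re)[0, 0])
    sigma2 = float(fit.scale)
    se_beta = np.asarray(fit.bse_fe)

    # observed information for (tau, sigma2), beta profiled out
    def ll(v):
        if reml:
            return _ri_reml_crit(v[0], v[1], data.y, design, data.cluster_index, data.J)
        return _ri_loglik(beta, v[0], v[1], data.y, design, data.cluster_index, data.J)

    v0 = np.array([max(tau, 1e-6), sigma2])
    h = np.maximum(1e-4 * np.abs(v0), 1e-6)
    H = np.empty((2, 2))
    for a in range(2):
        for b in range(2):
            va = np.zeros(2); va[a] = h[a]
            vb = np.zeros(2); vb[b] = h[b]
            H[a, b] = (
                ll(v0 + va + vb) - ll(v0 + va - vb) - ll(v0 - va + vb) + ll(v0 - va - vb)
            ) / (4 * h[a] * h[b])
    with np.errstate(all="ignore"):
        try:
            cov_v = np.linalg.inv(-H)
            se_v = np.sqrt(np.maximum(np.diag(cov_v), 0.0))
        except np.linalg.LinAlgError:
            se_v = np.array([np.nan, np.nan])

    names = list(spec.coef_names) + ["tau", "sigma2"]
    est = np.concatenate([beta, [tau, sigma2]])
    se = np.concatenate([se_beta, se_v])
    z = 1.959963984540054
    return CDMLResult(
        params=pd.Series(est, index=names),
        se=pd.Series(se, index=names),
        ci_lower=pd.Series(est - z * se, index=names),
        ci_upper=pd.Series(est + z * se, index=names),
        loglik=float(fit.llf),
        converged=bool(fit.converged),
    )


@dataclass
class SimulationMetrics:
    """Aggregated study metrics per parameter (one row each)."""

    table: pd.DataFrame  # columns: truth, pct_bias, abs_bias, ASE, ESE, coverage
    R: int
    mc_se: pd.Series  # Monte-Carlo SE of the %bias entries (points)

    def __repr__(self):
        return f"SimulationMetrics(R={self.R})\n{self.table.round(3)}"


def metrics_from_estimates(
    estimates: pd.DataFrame,
    ses: pd.DataFrame,
    lower: pd.DataFrame,
    upper: pd.DataFrame,
    truth: pd.Series,
) -> SimulationMetrics:
    """Compute %bias / ASE / ESE / coverage from aligned per-replicate tables.

    Rows are replicates, columns parameters.  Where truth is 0, %bias is
    undefined: pct_bias is NaN and abs_bias carries the absolute bias.
    """
    cols = list(estimates.columns)
    truth = truth.reindex(cols)
    R = len(estimates)
    if R < 2:
        raise ValueError("need at least two replicates")
    mean_est = estimates.mean(axis=0)
    bias = mean_est - truth
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = np.where(truth != 0, bias / truth * 100.0, np.nan)
    ese = estimates.std(axis=0, ddof=1)
    cover = ((lower.le(truth, axis=1)) & (upper.ge(truth, axis=1))).mean(axis=0)
    table = pd.DataFrame(
        {
            "truth": truth,
            "pct_bias": pct,
            "abs_bias": bias,
            "ASE": ses.mean(axis=0),
            "ESE": ese,
            "coverage": cover,
        },
        index=cols,
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        mc_se = np.where(truth != 0, (ese / np.sqrt(R)) / truth.abs() * 100.0, np.nan)
    return SimulationMetrics(table=table, R=R, mc_se=pd.Series(mc_se, index=cols))


@dataclass
class StudyResult:
    """Output of one scenario study: metrics per estimator plus convergence rates."""

    gibbs: SimulationMetrics
    cdml: SimulationMetrics | None
    convergence: dict
    scenario: ScenarioSpec
    n_failed: int = 0
    replicate_estimates: dict = field(default_factory=dict)


def run_study(
    scenario: ScenarioSpec,
    R: int,
    mechanisms: list[MissingnessMechanism] | None = None,
    sampler_config: SamplerConfig | None = None,
    base_seed: int = 0,
    include_cdml: bool = True,
    params: list[str] | None = None,
    progress: bool = False,
) -> StudyResult:
    """Repeat simulate -> fit -> score R times and aggregate the metrics.

    Replicate r uses seed ``base_seed + r`` for data generation and derives
    chain seeds from it, so the study is reproducible and parallelizable by
    replicate.  Replicate-level failures are logged and excluded, with the
    count reported.
    """
    if R < 2:
        raise ValueError("need R >= 2 replicates")
    spec = scenario.hlm_spec
    if mechanisms is None:
        mechanisms = default_mechanisms(scenario.scenario)
    cfg = sampler_config or SamplerConfig(n_burn=500, n_post=1000, n_chains=2)
    if params is None:
        params = list(spec.coef_names) + ["tau", "sigma2"]

    g_est, g_se, g_lo, g_hi = [], [], [], []
    c_est, c_se, c_lo, c_hi = [], [], [], []
    psrf_ok, geweke_ok = [], []
    truth_s = None
    n_failed = 0
    for r in range(R):
        rng = np.random.default_rng(base_seed + r)
        try:
            complete, truth = generate_complete(scenario, rng)
            if include_cdml:
                cd = cdml_fit(complete, spec)
                c_est.append(cd.params[params])
                c_se.append(cd.se[params])
                c_lo.append(cd.ci_lower[params])
                c_hi.append(cd.ci_upper[params])
            masked = apply_missingness(complete, mechanisms, rng)
            rep_cfg = SamplerConfig(
                n_burn=cfg.n_burn, n_post=cfg.n_post, n_chains=cfg.n_chains,
                seed=base_seed + r, init_strategies=cfg.init_strategies,
            )
            chains = run_chains(masked, spec, config=rep_cfg)
            summ = summarize(chains)
            g_est.append(summ["mean"][params])
            g_se.append(summ["sd"][params])
            g_lo.append(summ["2.5%"][params])
            g_hi.append(summ["97.5%"][params])
            if cfg.n_chains >= 2:
                rep = convergence_report(chains, params=params)
                psrf_ok.append(rep.psrf_converged)
                geweke_ok.append(rep.geweke_converged)
            truth_s = pd.Series(truth).reindex(params)
        except (RuntimeError, np.linalg.LinAlgError) as err:
            n_failed += 1
            import logging

            logging.getLogger(__name__).warning("replicate %d failed: %s", r, err)
        if progress and (r + 1) % 25 == 0:
            print(f"  replicate {r + 1}/{R}", flush=True)

    if len(g_est) < 2:
        raise RuntimeError("too few successful replicates")
    gibbs = metrics_from_estimates(
        pd.DataFrame(g_est).reset_index(drop=True),
        pd.DataFrame(g_se).reset_index(drop=True),
        pd.DataFrame(g_lo).reset_index(drop=True),
        pd.DataFrame(g_hi).reset_index(drop=True),
        truth_s,
    )
    cdml = None
    if include_cdml and c_est:
        cdml = metrics_from_estimates(
            pd.DataFrame(c_est).reset_index(drop=True),
            pd.DataFrame(c_se).reset_index(drop=True),
            pd.DataFrame(c_lo).reset_index(drop=True),
            pd.DataFrame(c_hi).reset_index(drop=True),
            truth_s,
        )
    convergence = {}
    if psrf_ok:
        convergence["psrf_rate"] = float(np.mean(psrf_ok))
        convergence["geweke_rate"] = float(np.mean(geweke_ok))
    return StudyResult(
        gibbs=gibbs,
        cdml=cdml,
        convergence=convergence,
        scenario=scenario,
        n_failed=n_failed,
        replicate_estimates={
            "gibbs_estimates": pd.DataFrame(g_est).reset_index(drop=True),
            "gibbs_lower": pd.DataFrame(g_lo).reset_index(drop=True),
            "gibbs_upper": pd.DataFrame(g_hi).reset_index(drop=True),
        },
    )
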