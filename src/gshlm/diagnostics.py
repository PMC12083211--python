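"""MCMC convergence assessment: Geweke Z, two-chain PSRF, trace plots.

Convergence of a fitted model is declared when all seven HLM parameters
(fixed effects plus tau and sigma2) individually satisfy the criterion:
|Geweke Z| < 1.96 within each chain, or PSRF < 1.1 across the chain pair.
Note that testing seven parameters at the 5% level inflates the familywise
rejection rate to about 1 - 0.95^7 = 0.30 even at stationarity, which is why
the PSRF criterion is the recommended one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "geweke_z",
    "psrf",
    "ConvergenceReport",
    "convergence_report",
    "familywise_rate",
    "export_traces",
]

PSRF_THRESHOLD = 1.1
GEWEKE_Z_CRIT = 1.96


def familywise_rate(alpha: float = 0.05, m: int = 7) -> float:
    """Probability of at least one rejection among m independent level-alpha tests."""
    return 1.0 - (1.0 - alpha) ** m


def _spectral_var(x: np.ndarray) -> float:
    """Spectral density at zero via a Bartlett lag window of width floor(sqrt(n)).

    Estimates the long-run variance s^2 = gamma_0 + 2 sum_l w_l gamma_l that
    accounts for autocorrelation in the segment mean.
    """
    n = x.size
    x = x - x.mean()
    L = int(np.sqrt(n))
    gamma0 = float(x @ x) / n
    s2 = gamma0
    for lag in range(1, L + 1):
        g = float(x[:-lag] @ x[lag:]) / n
        s2 += 2.0 * (1.0 - lag / (L + 1.0)) * g
    return max(s2, 0.0)


def geweke_z(draws: np.ndarray, frac_a: float = 0.2, frac_b: float = 0.5) -> float:
    """Two-sample Z comparing the first frac_a and last frac_b of one chain.

    Z = (mean_a - mean_b) / sqrt(s2_a/n_a + s2_b/n_b) with spectral
    (autocorrelation-consistent) variance estimates per segment.
    """
    x = np.asarray(draws, dtype=float).ravel()
    n = x.size
    if n < 50:
        raise ValueError("need at least 50 draws for the Geweke diagnostic")
    na = int(np.floor(frac_a * n))
    nb = int(np.floor(frac_b * n))
    a, b = x[:na], x[n - nb:]
    va, vb = _spectral_var(a), _spectral_var(b)
    denom = np.sqrt(va / na + vb / nb)
    if denom == 0:
        if a.mean() == b.mean():
            return 0.0
        raise ZeroDivisionError("zero-variance series with unequal segment means")
    return float((a.mean() - b.mean()) / denom)


def psrf(chains: np.ndarray) -> float:
    """Gelman-Rubin potential scale reduction factor across >= 2 full chains.

    chains : (m, n) array, one row per chain.  Classic (non-split,
    non-rank-normalized) estimator:
    PSRF = sqrt(((n-1)/n * W + B/n) / W).
    """
    chains = np.atleast_2d(np.asarray(chains, dtype=float))
    m, n = chains.shape
    if m < 2:
        raise ValueError("PSRF needs at least two chains")
    if n < 50:
        raise ValueError("chains too short for a meaningful PSRF")
    means = chains.mean(axis=1)
    B = n * np.var(means, ddof=1)
    W = np.mean(np.var(chains, axis=1, ddof=1))
    if W == 0:
        return 1.0 if B == 0 else np.inf
    vhat = (n - 1) / n * W + B / n
    return float(np.sqrt(vhat / W))


@dataclass
class ConvergenceReport:
    """Per-parameter diagnostics plus all-parameter convergence flags."""

    table: pd.DataFrame  # index: parameter; columns: geweke_z per chain, psrf
    frac_a: float
    frac_b: float
    params_checked: tuple[str, ...]

    @property
    def geweke_converged(self) -> bool:
        cols = [c for c in self.table.columns if c.startswith("geweke_z")]
        sub = self.table.loc[list(self.params_checked), cols]
        return bool((sub.abs() < GEWEKE_Z_CRIT).all().all())

    @property
    def psrf_converged(self) -> bool:
        if "psrf" not in self.table.columns or self.table["psrf"].isna().all():
            return False
        return bool((self.table.loc[list(self.params_checked), "psrf"] < PSRF_THRESHOLD).all())


def convergence_report(
    chains: list,
    params: list[str] | None = None,
    frac_a: float = 0.2,
    frac_b: float = 0.5,
) -> ConvergenceReport:
    """Geweke Z per chain and PSRF across chains for each parameter.

    ``chains`` is a list of ChainResult (or of DataFrames of draws).  The
    all-parameter flags are evaluated over ``params`` (default: all HLM
    parameters, i.e., the fixed effects plus tau and sigma2).
    """
    frames = [ch.to_frame() if hasattr(ch, "to_frame") else pd.DataFrame(ch) for ch in chains]
    names = list(frames[0].columns)
    rows = {}
    for name in names:
        row = {}
        for c, f in enumerate(frames):
            row[f"geweke_z_chain{c}"] = geweke_z(f[name].to_numpy(), frac_a, frac_b)
        if len(frames) >= 2:
            stacked = np.vstack([f[name].to_numpy() for f in frames])
            row["psrf"] = psrf(stacked)
        else:
            row["psrf"] = np.nan
        rows[name] = row
    table = pd.DataFrame.from_dict(rows, orient="index")
    if params is None:
        hlm = [n for n in names if not n.startswith(("alpha[", "T["))]
        params = hlm
    return ConvergenceReport(table=table, frac_a=frac_a, frac_b=frac_b,
                             params_checked=tuple(params))


def export_traces(chains: list, parameters: list[str], path, fmt: str = "png") -> list:
    """One trace plot per parameter with all chains overlaid; returns paths."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from pathlib import Path

    outdir = Path(path)
    outdir.mkdir(parents=True, exist_ok=True)
    frames = [ch.to_frame() if hasattr(ch, "to_frame") else pd.DataFrame(ch) for ch in chains]
    written = []
    for name in parameters:
        fig, ax = plt.subplots(figsize=(7, 3))
        for c, f in enumerate(frames):
            ax.plot(np.arange(1, len(f) + 1), f[name], lw=0.5, label=f"chain {c + 1}")
        ax.set_xlabel("iteration")
        ax.set_ylabel(name)
        ax.legend(loc="upper right", fontsize=8)
        fig.tight_layout()
        safe = name.replace("/", "_").replace(":", "x").replace("(", "").replace(")", "")
        out = outdir / f"trace_{safe}.{fmt}"
        fig.savefig(out, dpi=120)
        plt.close(fig)
        written.append(out)
    return written
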