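"""Concentration-response analysis for two-electrode voltage-clamp data.

The concentration-response curve is the four-parameter Hill model in its
log-concentration form,

    Y = R_basal + (R_max - R_basal) / (1 + 10^((logEC50 - logX) * nH))

fitted by nonlinear least squares with multi-start initialisation (the
surface has local minima in nH when data are noisy).  Modulator effects
are quantified as % modulation = (R_A - R_0) / R_0 * 100 relative to the
response R_0 to an EC20 agonist pulse, and groups (wild type vs mutant)
are compared per concentration by unpaired two-sided t tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .synthetic.dose import hill_response


@dataclass(frozen=True)
class DoseResponseFit:
    r_basal: float
    r_max: float
    log_ec50: float                 # log10 concentration
    n_h: float
    se: dict                        # per-parameter standard errors
    residual_ss: float
    converged: bool
    normalized: bool = False        # responses were I/I_max normalised

    @property
    def ec50(self) -> float:
        return float(10.0 ** self.log_ec50)


def _hill_logx(logx: np.ndarray, r_basal: float, r_max: float,
               log_ec50: float, n_h: float) -> np.ndarray:
    with np.errstate(over="ignore"):    # 10**big -> inf -> response -> r_basal
        return r_basal + (r_max - r_basal) / (1.0 + 10.0 ** ((log_ec50 - logx) * n_h))


def fit_hill(concentrations, responses, weights=None) -> DoseResponseFit:
    """Fit the Hill equation by multi-start nonlinear least squares.

    Starts span logEC50 over the observed concentration range and
    nH in {0.5, 1, 2, 4}; the best residual sum of squares wins.
    Raises RuntimeError if no start converges.
    """
    x = np.asarray(concentrations, float)
    y = np.asarray(responses, float)
    if len(np.unique(x)) < 4:
        raise ValueError("need at least 4 distinct concentrations")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y)) and np.all(x > 0)):
        raise ValueError("concentrations must be positive and responses finite")
    logx = np.log10(x)
    w = np.ones_like(y) if weights is None else np.asarray(weights, float)

    def resid(p):
        return (y - _hill_logx(logx, *p)) * np.sqrt(w)

    span = y.max() - y.min()
    best = None
    for le in np.linspace(logx.min(), logx.max(), 5):
        for nh in (0.5, 1.0, 2.0, 4.0):
            p0 = [y.min(), y.max(), le, nh]
            try:
                sol = optimize.least_squares(resid, p0, method="lm", max_nfev=10_000)
            except Exception:
                continue
            ss = float(np.sum(sol.fun**2))
            if sol.success and (best is None or ss < best[1]):
                best = (sol, ss)
    if best is None:
        raise RuntimeError("Hill fit failed to converge from any start")
    sol, ss = best
    p = sol.x
    # standard errors from the Jacobian (Gauss-Newton covariance)
    dof = max(1, len(y) - 4)
    try:
        cov = np.linalg.inv(sol.jac.T @ sol.jac) * ss / dof
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        se = np.full(4, np.nan)
    names = ("r_basal", "r_max", "log_ec50", "n_h")
    # canonicalise: R_max >= R_basal (swap + flip nH sign is the same curve)
    r_basal, r_max, log_ec50, n_h = p
    if r_max < r_basal:
        r_basal, r_max, n_h = r_max, r_basal, -n_h
    if span > 0 and ss / max(span, 1.0) ** 2 > 1e6:
        raise RuntimeError("Hill fit diverged (residuals exceed data scale)")
    return DoseResponseFit(
        r_basal=float(r_basal), r_max=float(r_max),
        log_ec50=float(log_ec50), n_h=float(n_h),
        se=dict(zip(names, se.tolist())), residual_ss=ss, converged=True,
    )


def ec_fraction(fit: DoseResponseFit, fraction: float) -> float:
    """Concentration producing the given fractional response.

    Inverts the Hill equation: X = EC50 * (f / (1 - f))^(1 / nH);
    fraction 0.5 returns EC50 exactly.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie strictly in (0, 1)")
    return float(fit.ec50 * (fraction / (1.0 - fraction)) ** (1.0 / fit.n_h))


def percent_modulation(r0: float, ra: float) -> float:
    """% modulation = (R_A - R_0) / R_0 * 100 of an EC20 agonist response."""
    if r0 <= 0:
        raise ValueError("reference response R_0 must be > 0")
    return float((ra - r0) / r0 * 100.0)


def normalize_per_experiment(df: pd.DataFrame, response: str = "response",
                             experiment: str = "replicate") -> pd.DataFrame:
    """I/I_max normalisation within each experiment before pooling."""
    out = df.copy()
    out[response] = out.groupby(experiment)[response].transform(
        lambda s: s / s.max()
    )
    return out


def compare_groups(wt: pd.DataFrame, mutant: pd.DataFrame,
                   value: str = "response",
                   concentration: str = "concentration") -> pd.DataFrame:
    """Per-concentration unpaired two-sided t tests, WT vs mutant.

    Returns mean +/- SEM per group with the t statistic and unadjusted
    p-value; degenerate (zero-variance) comparisons are flagged.
    """
    rows = []
    concs = sorted(set(wt[concentration]) & set(mutant[concentration]))
    for c in concs:
        a = wt.loc[wt[concentration] == c, value].to_numpy(float)
        b = mutant.loc[mutant[concentration] == c, value].to_numpy(float)
        if len(a) < 2 or len(b) < 2:
            raise ValueError(f"need >= 2 records per group at concentration {c}")
        degenerate = a.std(ddof=1) == 0 and b.std(ddof=1) == 0
        if degenerate and np.isclose(a.mean(), b.mean()):
            t, p = 0.0, 1.0
        else:
            t, p = stats.ttest_ind(a, b, equal_var=True)
        rows.append({
            "concentration": c,
            "wt_mean": a.mean(), "wt_sem": stats.sem(a) if len(a) > 1 else np.nan,
            "mut_mean": b.mean(), "mut_sem": stats.sem(b) if len(b) > 1 else np.nan,
            "t": float(t), "p": float(p), "degenerate": bool(degenerate),
            "significant": bool(p < 0.05),
        })
    return pd.DataFrame(rows)
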