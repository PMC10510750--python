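"""Post-fit statistics: goodness-of-fit, local CIs, sensitivity analysis.

All quantities derive from the weighted residual vector r and its Jacobian
J = dr/dtheta at convergence:

* chi-square test: Phi = rᵀr is compared with the [alpha/2, 1-alpha/2]
  quantiles of the chi-square distribution with dof = n_residuals -
  n_parameters degrees of freedom — a fit is rejected both when it is too
  poor and when it is suspiciously good (overfitting / overstated sds);
* normality of the weighted residuals (Shapiro-Wilk statistic plus the
  ordered quantile pairs of the normal probability plot);
* local confidence intervals from the Gauss-Newton covariance
  cov(theta) = (JᵀJ)⁻¹, propagated to the reported quantities (net fluxes,
  exchange fluxes, G-values, pool sizes) through the delta method;
* the sensitivity matrix d(estimate)/d(measurement) and the contribution
  matrix — the row-normalized share of each measurement's variance in each
  estimate's variance — which together identify the measurements that
  drive the uncertainty of each flux.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats as sps

from .estimate import FitResults

__all__ = ["FitStatistics", "chi2_test", "residual_normality",
           "local_confidence_intervals", "sensitivity_matrix",
           "contribution_matrix"]

RANK_RTOL = 1e-8  # singular values below RANK_RTOL * s_max are null directions


@dataclass
class FitStatistics:
    chi2: float
    dof: int
    alpha: float
    chi2_lo: float
    chi2_hi: float
    accepted: bool
    normality_stat: Optional[float] = None
    normality_p: Optional[float] = None

    def __str__(self):
        verdict = "accepted" if self.accepted else "rejected"
        s = (f"chi2 = {self.chi2:.3f}, dof = {self.dof}, "
             f"{(1 - self.alpha):.0%} band [{self.chi2_lo:.2f}, "
             f"{self.chi2_hi:.2f}]: {verdict}")
        if self.normality_p is not None:
            s += f"; residual normality p = {self.normality_p:.3f}"
        return s


def chi2_test(fit: FitResults, alpha: float = 0.05) -> FitStatistics:
    """Two-sided chi-square goodness-of-fit test of the weighted SSR."""
    dof = fit.dof
    if dof <= 0:
        raise ValueError(f"non-testable fit: dof = {dof} <= 0")
    lo = float(sps.chi2.ppf(alpha / 2, dof))
    hi = float(sps.chi2.ppf(1 - alpha / 2, dof))
    norm_stat = norm_p = None
    if fit.residuals.size >= 8 and np.ptp(fit.residuals) > 0:
        norm_stat, norm_p = sps.shapiro(fit.residuals)
    return FitStatistics(chi2=float(fit.phi), dof=dof, alpha=alpha,
                         chi2_lo=lo, chi2_hi=hi,
                         accepted=bool(lo <= fit.phi <= hi),
                         normality_stat=norm_stat, normality_p=norm_p)


def residual_normality(fit_or_residuals: Union[FitResults, np.ndarray]
                       ) -> Tuple[float, float, np.ndarray]:
    """Shapiro-Wilk statistic, p-value, and normal-probability-plot pairs.

    The returned array has shape (n, 2): theoretical normal quantiles in
    column 0 and the ordered weighted residuals in column 1.
    """
    r = (fit_or_residuals.residuals
         if isinstance(fit_or_residuals, FitResults)
         else np.asarray(fit_or_residuals, dtype=float))
    if r.size < 8:
        raise ValueError("need at least 8 residuals for a normality test")
    if np.ptp(r) == 0:
        raise ValueError("residuals are constant: normality test degenerate")
    stat, p = sps.shapiro(r)
    (osm, osr), _ = sps.probplot(r)
    return float(stat), float(p), np.column_stack([osm, osr])


def _covariance(fit: FitResults) -> Tuple[np.ndarray, np.ndarray]:
    """(pseudo-inverse of JᵀJ, boolean mask of null directions in theta).

    Singular directions of the Gauss-Newton normal matrix (unidentifiable
    parameter combinations, e.g. the two members of an unconstrained futile
    cycle) are excluded from the pseudo-inverse and reported.
    """
    J = fit.jacobian
    U, s, Vt = np.linalg.svd(J.T @ J)
    smax = s[0] if s.size else 0.0
    keep = s > RANK_RTOL * max(smax, 1e-300)
    inv = np.zeros_like(s)
    inv[keep] = 1.0 / s[keep]
    cov = (Vt.T * inv) @ Vt
    null_basis = Vt[~keep]  # rows span the unidentifiable subspace
    return cov, null_basis


def local_confidence_intervals(fit: FitResults, alpha: float = 0.05
                               ) -> pd.DataFrame:
    """Symmetric local CIs from the Hessian at convergence.

    cov(theta) = (JᵀJ)⁻¹ (pseudo-inverse on rank deficiency); reported
    quantities get CI = estimate ± z_{1-alpha/2} * sd via the delta method.
    Quantities with a component along an unidentifiable direction are
    flagged and reported with infinite half-width.
    """
    cov, null_basis = _covariance(fit)
    D = fit.problem.report_jacobian(fit.theta)
    est = fit.problem.report_values(fit.theta)
    var = np.einsum("ij,jk,ik->i", D, cov, D)
    sd = np.sqrt(np.clip(var, 0.0, None))
    z = sps.norm.ppf(1 - alpha / 2)
    identifiable = np.ones(len(est), dtype=bool)
    if null_basis.size:
        proj = np.abs(D @ null_basis.T)
        scale = np.maximum(np.linalg.norm(D, axis=1), 1e-300)
        identifiable = (proj.max(axis=1) / scale) < 1e-6
    lo = np.where(identifiable, est - z * sd, -np.inf)
    hi = np.where(identifiable, est + z * sd, np.inf)
    return pd.DataFrame({"estimate": est, "sd": np.where(identifiable, sd, np.inf),
                         "ci_lo": lo, "ci_hi": hi,
                         "identifiable": identifiable},
                        index=fit.problem.report_names)


def sensitivity_matrix(fit: FitResults) -> pd.DataFrame:
    """d(estimate_i)/d(measurement_j) at convergence.

    For weighted least squares the first-order influence of measurement j
    on the parameter estimate is (JᵀJ)⁻¹ Jᵀ e_j / sd_j; rows are the
    reported quantities (delta-method propagated), columns the stacked
    measurements.
    """
    cov, _ = _covariance(fit)
    D = fit.problem.report_jacobian(fit.theta)
    S = D @ cov @ fit.jacobian.T / fit.problem.stacked_sd[None, :]
    return pd.DataFrame(S, index=fit.problem.report_names,
                        columns=fit.problem.residual_labels)


def contribution_matrix(fit: FitResults) -> pd.DataFrame:
    """Fractional contribution of each measurement's variance to each
    estimate's variance: C_ij = S_ij² sd_j² / Σ_j S_ij² sd_j².

    Rows sum to 1; a row whose estimate is insensitive to every measurement
    (zero total variance) is left unnormalized as NaN.
    """
    S = sensitivity_matrix(fit)
    contrib = S.to_numpy() ** 2 * fit.problem.stacked_sd[None, :] ** 2
    total = contrib.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        C = np.where(total > 0, contrib / total, np.nan)
    return pd.DataFrame(C, index=S.index, columns=S.columns)
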