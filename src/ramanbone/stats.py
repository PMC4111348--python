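"""Correlation, influence diagnostics and dependent-correlation comparison.

This is the comparison stage between the Raman organic-phosphate ratio and
the wet-chemistry yields: product-moment correlations with Fisher-z
confidence intervals, leverage/studentized-residual diagnostics for the
ratio-vs-yield regressions, sensitivity re-analysis after removing
influential points, and two-sided tests for equality of two dependent
correlations that share a variable (Steiger's z by default, Williams' t as
an alternative — the published analysis does not name its test, so the
method used is always recorded in the result).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.stats.outliers_influence import OLSInfluence

__all__ = [
    "CorrelationResult",
    "InfluenceDiagnostics",
    "SensitivityResult",
    "DependentCorrelationComparison",
    "UndefinedCorrelationError",
    "pearson",
    "influence_diagnostics",
    "sensitivity_reanalysis",
    "compare_dependent_correlations",
]


class UndefinedCorrelationError(ValueError):
    """Correlation is undefined (zero variance or too few points)."""


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson correlation with t-based p-value and Fisher-z 95% CI."""

    r: float
    r_squared: float
    p_two_sided: float
    n: int
    ci95: tuple[float, float]

    @property
    def r_squared_pct(self) -> float:
        """Coefficient of determination on the percent scale."""
        return 100.0 * self.r_squared


@dataclass(frozen=True)
class InfluenceDiagnostics:
    """Per-point simple-regression influence measures (y regressed on x)."""

    leverage: np.ndarray
    studentized_residual: np.ndarray  # externally studentized


@dataclass(frozen=True)
class SensitivityResult:
    """Correlation recomputed after removing influential points."""

    removed_ids: tuple
    result_after: CorrelationResult


@dataclass(frozen=True)
class DependentCorrelationComparison:
    """Test of H0: rho_jk = rho_jh for two correlations sharing variable j.

    ``r_kh`` is the correlation between the two non-shared variables; it
    determines the dependence between the two correlation estimates.
    """

    r_jk: float
    r_jh: float
    r_kh: float
    n: int
    statistic: float
    p_two_sided: float
    method: str


def _validate_xy(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or y.ndim != 1 or x.size != y.size:
        raise ValueError("x and y must be 1-D of equal length")
    if x.size < 3:
        raise UndefinedCorrelationError("need n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("zero variance in x or y")
    return x, y


def pearson(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Product-moment correlation with exact t-based two-sided p-value.

    p comes from t = r sqrt((n-2)/(1-r^2)) on n-2 df; the 95% CI is the
    Fisher-z interval arctanh(r) +/- 1.96 / sqrt(n-3) back-transformed
    (degenerate to [r, r] at n = 3).
    """
    x, y = _validate_xy(x, y)
    n = x.size
    r, p = sps.pearsonr(x, y)
    r = float(r)
    if n > 3 and abs(r) < 1.0:
        z = np.arctanh(r)
        half = sps.norm.ppf(0.975) / np.sqrt(n - 3)
        ci = (float(np.tanh(z - half)), float(np.tanh(z + half)))
    else:
        ci = (r, r)
    return CorrelationResult(
        r=r, r_squared=r * r, p_two_sided=float(p), n=int(n), ci95=ci
    )


def influence_diagnostics(
    x: Sequence[float], y: Sequence[float]
) -> InfluenceDiagnostics:
    """Leverage h_i = 1/n + (x_i - xbar)^2 / S_xx and externally studentized
    residuals from the OLS fit of y on x."""
    x, y = _validate_xy(x, y)
    model = sm.OLS(y, sm.add_constant(x)).fit()
    infl = OLSInfluence(model)
    return InfluenceDiagnostics(
        leverage=np.asarray(infl.hat_matrix_diag, dtype=float),
        studentized_residual=np.asarray(infl.resid_studentized_external, dtype=float),
    )


def sensitivity_reanalysis(
    x: Sequence[float],
    y: Sequence[float],
    ids: Sequence | None = None,
    explicit: Sequence = (),
    top_k_leverage: int = 0,
    top_abs_residual: int = 0,
) -> SensitivityResult:
    """Remove influential points and recompute the correlation.

    Removal rules compose in a fixed order: ``explicit`` ids first, then the
    ``top_k_leverage`` highest-leverage points of the remaining data, then
    the ``top_abs_residual`` largest absolute externally studentized
    residuals recomputed on what is left after the leverage removals.  At
    least 3 points must remain.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ids = np.arange(x.size) if ids is None else np.asarray(ids)
    if ids.size != x.size:
        raise ValueError("ids must match data length")

    keep = np.ones(x.size, dtype=bool)
    removed: list = []
    if len(explicit):
        explicit_set = set(explicit)
        unknown = explicit_set - set(ids.tolist())
        if unknown:
            raise ValueError(f"explicit ids not in dataset: {sorted(unknown)}")
        for i, sid in enumerate(ids):
            if sid in explicit_set:
                keep[i] = False
                removed.append(sid)

    def _remove_top(score_fn, k):
        nonlocal keep
        for _ in range(k):
            if keep.sum() - 1 < 3:
                raise ValueError("over-removal: fewer than 3 points would remain")
            idx = np.flatnonzero(keep)
            scores = score_fn(x[idx], y[idx])
            drop = idx[int(np.argmax(scores))]
            keep[drop] = False
            removed.append(ids[drop])

    if top_k_leverage:
        _remove_top(lambda a, b: influence_diagnostics(a, b).leverage,
                    top_k_leverage)
    if top_abs_residual:
        _remove_top(
            lambda a, b: np.abs(influence_diagnostics(a, b).studentized_residual),
            top_abs_residual,
        )
    if keep.sum() < 3:
        raise ValueError("over-removal: fewer than 3 points remain")
    return SensitivityResult(
        removed_ids=tuple(removed),
        result_after=pearson(x[keep], y[keep]),
    )


def compare_dependent_correlations(
    r_jk: float,
    r_jh: float,
    r_kh: float,
    n: int,
    method: str = "steiger",
) -> DependentCorrelationComparison:
    """Two-sided test of rho_jk = rho_jh for overlapping dependent correlations.

    ``method="steiger"`` (default): Steiger's z comparing Fisher-transformed
    correlations, with the covariance term evaluated at the back-transformed
    average correlation.  ``method="williams"``: Williams' t on n-3 df.
    Degenerate inputs with |r| = 1 are rejected.
    """
    for name, r in (("r_jk", r_jk), ("r_jh", r_jh), ("r_kh", r_kh)):
        if not -1.0 <= r <= 1.0:
            raise ValueError(f"{name} must be in [-1, 1]")
    if abs(r_jk) == 1.0 or abs(r_jh) == 1.0:
        raise ValueError("degenerate input: |r| = 1")
    if n < 4:
        raise ValueError("need n >= 4")

    if method == "steiger":
        z_jk, z_jh = np.arctanh(r_jk), np.arctanh(r_jh)
        rbar = float(np.tanh((z_jk + z_jh) / 2.0))  # back-transformed average
        num = r_kh * (1.0 - 2.0 * rbar**2) - 0.5 * rbar**2 * (
            1.0 - 2.0 * rbar**2 - r_kh**2
        )
        psi = num / (1.0 - rbar**2) ** 2  # corr. between the two z estimates
        stat = float((z_jk - z_jh) * np.sqrt((n - 3) / (2.0 - 2.0 * psi)))
        p = float(2.0 * sps.norm.sf(abs(stat)))
    elif method == "williams":
        det = (
            1.0
            - r_jk**2
            - r_jh**2
            - r_kh**2
            + 2.0 * r_jk * r_jh * r_kh
        )
        rbar = (r_jk + r_jh) / 2.0
        denom = (
            2.0 * det * (n - 1) / (n - 3)
            + rbar**2 * (1.0 - r_kh) ** 3
        )
        stat = float(
            (r_jk - r_jh) * np.sqrt((n - 1) * (1.0 + r_kh) / denom)
        )
        p = float(2.0 * sps.t.sf(abs(stat), df=n - 3))
    else:
        raise ValueError(f"unknown method {method!r}")
    return DependentCorrelationComparison(
        r_jk=float(r_jk),
        r_jh=float(r_jh),
        r_kh=float(r_kh),
        n=int(n),
        statistic=stat,
        p_two_sided=p,
        method=method,
    )
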