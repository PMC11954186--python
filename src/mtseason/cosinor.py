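"""Seasonal sine--cosine (cosinor) regression with delta-method inference.

The annual rhythm of a standardized outcome is modelled by regressing it on
a single harmonic of the month of measurement,

    y = beta0 + beta_cos * cosw + beta_sin * sinw + sum_i beta_i * C_i + eps,

where ``cosw = cos(2*pi*(month - 1)/12)`` and ``sinw = sin(2*pi*(month - 1)/12)``.
The two harmonic coefficients are transformed into the amplitude
``A = sqrt(beta_cos**2 + beta_sin**2)`` and the acrophase
``phi = atan2(beta_sin, beta_cos)`` (peak angle of the fitted sinusoid);
standard errors for both are propagated from the coefficient covariance with
a first-order Taylor (delta-method) approximation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg as sla
from scipy import stats

__all__ = [
    "PERIOD",
    "COS_COL",
    "SIN_COL",
    "SeasonalBasis",
    "CosinorFit",
    "WaldSummary",
    "SeasonalCharacteristics",
    "AmplitudeDegenerateWarning",
    "seasonal_basis",
    "seasonal_design",
    "fit_cosinor",
    "amplitude_estimate",
    "acrophase_estimate",
    "wald_summary",
    "joint_seasonality_test",
    "acrophase_to_calendar",
    "seasonal_characteristics",
]

PERIOD = 12
COS_COL = "cosw"
SIN_COL = "sinw"
INTERCEPT = "const"

_Z975 = stats.norm.ppf(0.975)


class AmplitudeDegenerateWarning(UserWarning):
    """Delta-method SE for the amplitude is unreliable near zero amplitude."""


@dataclass(frozen=True)
class SeasonalBasis:
    """Harmonic basis values for one calendar month (1 = January)."""

    month: int
    sinw: float
    cosw: float


@dataclass(frozen=True)
class WaldSummary:
    """Normal-reference Wald summary of a single estimate."""

    estimate: float
    se: float
    t_score: float
    ci_low: float
    ci_high: float
    p_value: float

    def as_dict(self) -> dict:
        return {
            "estimate": self.estimate,
            "se": self.se,
            "t_score": self.t_score,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p_value": self.p_value,
        }


@dataclass
class CosinorFit:
    """OLS fit of the single-harmonic seasonal model.

    ``params`` and ``cov`` are indexed by coefficient name; the harmonic
    coefficients live under :data:`COS_COL` and :data:`SIN_COL` and the
    intercept under ``"const"``.
    """

    params: pd.Series
    cov: pd.DataFrame
    residual_df: int
    n_used: int

    def __post_init__(self) -> None:
        c = self.cov.to_numpy(float)
        if not np.allclose(c, c.T, atol=1e-10):
            raise ValueError("coefficient covariance must be symmetric")
        if np.any(np.diag(c) < -1e-12):
            raise ValueError("coefficient covariance has negative diagonal")

    @property
    def beta0(self) -> float:
        return float(self.params[INTERCEPT])

    @property
    def beta_cos(self) -> float:
        return float(self.params[COS_COL])

    @property
    def beta_sin(self) -> float:
        return float(self.params[SIN_COL])

    @property
    def covariate_betas(self) -> dict:
        drop = {INTERCEPT, COS_COL, SIN_COL}
        return {k: float(v) for k, v in self.params.items() if k not in drop}

    def harmonic_cov(self) -> np.ndarray:
        """2x2 covariance of (beta_cos, beta_sin)."""
        return self.cov.loc[[COS_COL, SIN_COL], [COS_COL, SIN_COL]].to_numpy(float)


@dataclass
class SeasonalCharacteristics:
    """Amplitude, acrophase and displacement of the fitted seasonal curve."""

    amplitude: WaldSummary
    acrophase: WaldSummary
    displacement: WaldSummary
    joint_p: float
    n_used: int
    peak_month: float = field(default=np.nan)
    trough_month: float = field(default=np.nan)

    def as_dict(self) -> dict:
        return {
            "amplitude": self.amplitude.as_dict(),
            "acrophase": self.acrophase.as_dict(),
            "displacement": self.displacement.as_dict(),
            "joint_p": self.joint_p,
            "n_used": self.n_used,
            "peak_month": self.peak_month,
            "trough_month": self.trough_month,
        }

    def to_frame(self) -> pd.DataFrame:
        rows = {
            "amplitude": self.amplitude.as_dict(),
            "acrophase": self.acrophase.as_dict(),
            "displacement": self.displacement.as_dict(),
        }
        frame = pd.DataFrame(rows).T
        frame.index.name = "quantity"
        return frame


def seasonal_basis(month: int) -> SeasonalBasis:
    """Return the sine/cosine basis for ``month`` (1--12, January = 1).

    ``sinw = sin(2*pi*(month - 1)/12)`` and ``cosw = cos(2*pi*(month - 1)/12)``,
    so January maps to (sinw, cosw) = (0, 1) and April to (1, 0).
    """
    m = np.asarray(month)
    if m.ndim != 0:
        raise TypeError("seasonal_basis expects a scalar month; use seasonal_design")
    if float(m) != int(m) or not 1 <= int(m) <= PERIOD:
        raise ValueError(f"month must be an integer in 1..{PERIOD}, got {month!r}")
    angle = 2.0 * np.pi * (int(m) - 1) / PERIOD
    return SeasonalBasis(int(m), float(np.sin(angle)), float(np.cos(angle)))


def seasonal_design(months) -> pd.DataFrame:
    """Vectorised seasonal basis: DataFrame with ``cosw`` and ``sinw`` columns."""
    m = np.asarray(months)
    if m.size == 0:
        raise ValueError("no months given")
    if np.any(~np.isfinite(m.astype(float))):
        raise ValueError("months contain missing values")
    mi = m.astype(float)
    if np.any(mi != np.round(mi)) or np.any((mi < 1) | (mi > PERIOD)):
        bad = int(np.flatnonzero((mi != np.round(mi)) | (mi < 1) | (mi > PERIOD))[0])
        raise ValueError(f"month out of range 1..{PERIOD} at row {bad}: {m.ravel()[bad]!r}")
    angle = 2.0 * np.pi * (mi - 1) / PERIOD
    return pd.DataFrame({COS_COL: np.cos(angle), SIN_COL: np.sin(angle)})


def _collinear_columns(X: pd.DataFrame) -> list:
    """Names of columns made redundant by earlier ones (rank-revealing QR)."""
    xv = X.to_numpy(float)
    r = sla.qr(xv, mode="r", pivoting=True)
    rdiag = np.abs(np.diag(r[0]))
    piv = r[1]
    tol = rdiag.max() * max(xv.shape) * np.finfo(float).eps if rdiag.size else 0.0
    bad = piv[rdiag <= tol] if rdiag.size else piv
    extra = piv[min(xv.shape[1], rdiag.size):]
    idx = sorted(set(bad.tolist()) | set(extra.tolist()))
    return [X.columns[i] for i in idx]


def _ols(X: pd.DataFrame, y: np.ndarray, robust: bool = False):
    """Classical OLS: coefficients, covariance (homoskedastic or HC1), df.

    Raises ``ValueError`` naming the collinear columns on a rank-deficient
    design.
    """
    xv = X.to_numpy(float)
    yv = np.asarray(y, float)
    n, k = xv.shape
    if n <= k:
        raise ValueError(f"need more rows ({n}) than coefficients ({k})")
    if np.linalg.matrix_rank(xv) < k:
        raise ValueError(
            "design matrix is rank deficient; collinear columns: "
            + ", ".join(map(str, _collinear_columns(X)))
        )
    xtx_inv = np.linalg.inv(xv.T @ xv)
    beta = xtx_inv @ (xv.T @ yv)
    resid = yv - xv @ beta
    df = n - k
    if robust:
        # HC1 sandwich
        meat = (xv * resid[:, None] ** 2).T @ xv
        cov = xtx_inv @ meat @ xtx_inv * (n / df)
    else:
        sigma2 = float(resid @ resid) / df
        cov = xtx_inv * sigma2
    params = pd.Series(beta, index=X.columns)
    covf = pd.DataFrame(cov, index=X.columns, columns=X.columns)
    return params, covf, df


def _as_covariate_frame(covariates, n: int) -> pd.DataFrame:
    if covariates is None:
        return pd.DataFrame(index=range(n))
    cov = pd.DataFrame(covariates).reset_index(drop=True)
    if len(cov) != n:
        raise ValueError(f"covariates have {len(cov)} rows, outcome has {n}")
    if cov.isna().to_numpy().any():
        bad = cov.columns[cov.isna().any()].tolist()
        raise ValueError(f"covariates contain missing values: {bad} (impute first)")
    return cov


def fit_cosinor(outcome, months, covariates=None, robust: bool = False) -> CosinorFit:
    """OLS fit of outcome ~ 1 + cosw + sinw (+ covariates).

    Parameters
    ----------
    outcome : array-like of float, no missing values
    months : array-like of int in 1..12
    covariates : optional DataFrame-like, complete after imputation
    robust : use the HC1 heteroskedasticity-robust covariance instead of the
        classical homoskedastic one.
    """
    y = np.asarray(outcome, float)
    if np.any(~np.isfinite(y)):
        raise ValueError("outcome contains missing/non-finite values")
    basis = seasonal_design(months)
    if len(basis) != len(y):
        raise ValueError("outcome and months differ in length")
    cov = _as_covariate_frame(covariates, len(y))
    X = pd.concat(
        [pd.Series(1.0, index=basis.index, name=INTERCEPT), basis, cov], axis=1
    )
    params, pcov, df = _ols(X, y, robust=robust)
    return CosinorFit(params=params, cov=pcov, residual_df=df, n_used=len(y))


def amplitude_estimate(fit: CosinorFit):
    """Amplitude ``sqrt(beta_cos**2 + beta_sin**2)`` and its delta-method SE.

    The gradient of the transform is ``(beta_cos/A, beta_sin/A)``; near
    A = 0 that gradient is ill-defined and the SE degenerates, in which case
    an :class:`AmplitudeDegenerateWarning` is emitted and the 2-df joint test
    (:func:`joint_seasonality_test`) should be preferred.
    """
    bc, bs = fit.beta_cos, fit.beta_sin
    sigma = fit.harmonic_cov()
    amp = float(np.hypot(bc, bs))
    if amp == 0.0:
        warnings.warn(
            "amplitude is exactly 0; delta-method SE undefined",
            AmplitudeDegenerateWarning,
            stacklevel=2,
        )
        return 0.0, float("nan")
    grad = np.array([bc / amp, bs / amp])
    se = float(np.sqrt(grad @ sigma @ grad))
    if amp < 3.0 * np.sqrt(np.max(np.diag(sigma))):
        warnings.warn(
            f"amplitude {amp:.3g} is within 3 coefficient-SEs of 0; "
            "delta-method SE unreliable, use joint_seasonality_test",
            AmplitudeDegenerateWarning,
            stacklevel=2,
        )
    return amp, se


def wrap_angle(phi: float) -> float:
    """Wrap an angle into (-pi, pi]."""
    out = np.remainder(np.asarray(phi, float) + np.pi, 2.0 * np.pi) - np.pi
    out = np.where(out == -np.pi, np.pi, out)
    return float(out) if np.ndim(phi) == 0 else out


def acrophase_estimate(fit: CosinorFit):
    """Acrophase ``atan2(beta_sin, beta_cos)`` in (-pi, pi] and delta-method SE.

    The four-quadrant arctangent is used (a single-argument arctan of the
    ratio is quadrant-ambiguous; both agree whenever ``beta_cos > 0``).
    """
    bc, bs = fit.beta_cos, fit.beta_sin
    a2 = bc * bc + bs * bs
    if a2 == 0.0:
        raise ValueError("acrophase undefined: both harmonic coefficients are 0")
    phi = wrap_angle(np.arctan2(bs, bc))
    grad = np.array([-bs / a2, bc / a2])  # d(phi)/d(beta_cos), d(phi)/d(beta_sin)
    se = float(np.sqrt(grad @ fit.harmonic_cov() @ grad))
    return phi, se


def wald_summary(estimate: float, se: float) -> WaldSummary:
    """T-score, 95% CI and two-sided p from a normal reference distribution."""
    if not np.isfinite(se) or se <= 0:
        raise ValueError(f"standard error must be positive, got {se!r}")
    t = float(estimate) / float(se)
    p = float(2.0 * stats.norm.sf(abs(t)))
    return WaldSummary(
        estimate=float(estimate),
        se=float(se),
        t_score=t,
        ci_low=float(estimate - _Z975 * se),
        ci_high=float(estimate + _Z975 * se),
        p_value=max(p, np.nextafter(0, 1)),
    )


def joint_seasonality_test(fit: CosinorFit) -> float:
    """2-df Wald test of (beta_cos, beta_sin) = (0, 0); robust at zero amplitude."""
    b = np.array([fit.beta_cos, fit.beta_sin])
    sigma = fit.harmonic_cov()
    try:
        w = float(b @ np.linalg.solve(sigma, b))
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular harmonic sub-covariance") from exc
    return float(stats.chi2.sf(w, df=2))


def acrophase_to_calendar(acrophase: float):
    """Calendar position (in months of the year, (0, 12]) of peak and trough.

    ``peak = 1 + 12 * acrophase / (2*pi)`` wrapped into (0, 12]; the trough
    sits half a period later. An acrophase of 0 peaks exactly at month 1
    (January), troughs at 7 (July).
    """
    phi = float(acrophase)
    if not np.isfinite(phi):
        raise ValueError("acrophase must be finite")
    peak = (1.0 + PERIOD * phi / (2.0 * np.pi)) % PERIOD
    if peak == 0.0:
        peak = float(PERIOD)
    trough = (peak + PERIOD / 2.0) % PERIOD
    if trough == 0.0:
        trough = float(PERIOD)
    return peak, trough


def seasonal_characteristics(fit: CosinorFit) -> SeasonalCharacteristics:
    """Full seasonal report: amplitude, acrophase, displacement with Wald stats."""
    amp, amp_se = amplitude_estimate(fit)
    phi, phi_se = acrophase_estimate(fit)
    beta0 = fit.beta0
    beta0_se = float(np.sqrt(fit.cov.loc[INTERCEPT, INTERCEPT]))
    peak, trough = acrophase_to_calendar(phi)
    return SeasonalCharacteristics(
        amplitude=wald_summary(amp, amp_se),
        acrophase=wald_summary(phi, phi_se),
        displacement=wald_summary(beta0, beta0_se),
        joint_p=joint_seasonality_test(fit),
        n_used=fit.n_used,
        peak_month=peak,
        trough_month=trough,
    )
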