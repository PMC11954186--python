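"""Marker x season interaction models and batch scans.

For a marker M the model is

    y = b0 + b1*M + b2*cosw + b3*sinw + b4*M*cosw + b5*M*sinw + sum_i bi*Ci

and the three seasonal characteristics a marker can modify are

- *amplitude change*: ``sqrt((b2+b4)**2 + (b3+b5)**2) - sqrt(b2**2 + b3**2)``
  per unit of M (exact difference; a linearised projection is available),
  reported as a signed percentage of a reference amplitude;
- *acrophase change*: difference of the two ``atan2`` phases, wrapped to
  (-pi, pi] and converted to months (and percent of a month);
- *displacement*: the marginal effect ``b1`` (vertical shift of the curve).

Standard errors for the first two are delta-method propagations over the
four-dimensional (b2, b3, b4, b5) sub-covariance. Batch scans apply a
Bonferroni (3 tests per marker) or fixed-threshold multiplicity policy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cosinor import (
    COS_COL,
    INTERCEPT,
    SIN_COL,
    WaldSummary,
    _as_covariate_frame,
    _ols,
    seasonal_design,
    wald_summary,
    wrap_angle,
)

__all__ = [
    "InteractionFit",
    "InteractionSummary",
    "ScanSettings",
    "ScanResult",
    "fit_interaction",
    "summarize_interaction",
    "run_scan",
    "incident_disease_exposure",
    "composite_disease_phenotypes",
    "mortality_interaction",
    "zscore_correlations",
    "lambda_gc",
]

MARKER_COL = "marker"
MCOS_COL = "marker:cosw"
MSIN_COL = "marker:sinw"
_INTERACTION_COLS = (MARKER_COL, COS_COL, SIN_COL, MCOS_COL, MSIN_COL)

CHI2_NULL_MEDIAN_1DF = float(stats.chi2.ppf(0.5, df=1))  # 0.4549...


@dataclass
class InteractionFit:
    """OLS fit of the marker-by-season interaction model."""

    marker_name: str
    params: pd.Series
    cov: pd.DataFrame
    residual_df: int
    n_used: int
    n_dropped: int = 0

    @property
    def beta_marker(self) -> float:
        return float(self.params[MARKER_COL])

    @property
    def beta_cos(self) -> float:
        return float(self.params[COS_COL])

    @property
    def beta_sin(self) -> float:
        return float(self.params[SIN_COL])

    @property
    def beta_mcos(self) -> float:
        return float(self.params[MCOS_COL])

    @property
    def beta_msin(self) -> float:
        return float(self.params[MSIN_COL])

    def sub_covariance(self) -> pd.DataFrame:
        """5x5 covariance over (marker, cosw, sinw, marker:cosw, marker:sinw)."""
        cols = list(_INTERACTION_COLS)
        return self.cov.loc[cols, cols]


@dataclass
class InteractionSummary:
    """Effect of one marker on the three seasonal characteristics.

    ``delta_amplitude_pct`` is in percent of ``reference_amplitude``,
    ``delta_acrophase_months`` in months within (-6, 6] (multiply by 100
    for "percent of a month"; also exposed as
    ``delta_acrophase_pct_month``), ``displacement`` in outcome SD units.
    """

    marker: str
    delta_amplitude_pct: WaldSummary
    delta_acrophase_months: WaldSummary
    displacement: WaldSummary
    baseline_amplitude: float
    reference_amplitude: float
    n_used: int
    definition: str = "exact"

    @property
    def delta_acrophase_pct_month(self) -> float:
        return 100.0 * self.delta_acrophase_months.estimate

    def as_row(self) -> dict:
        row: dict = {"marker": self.marker}
        for name, ws in (
            ("amplitude", self.delta_amplitude_pct),
            ("acrophase", self.delta_acrophase_months),
            ("displacement", self.displacement),
        ):
            row[f"{name}_est"] = ws.estimate
            row[f"{name}_se"] = ws.se
            row[f"{name}_z"] = ws.t_score
            row[f"{name}_p"] = ws.p_value
        row["n_used"] = self.n_used
        return row


@dataclass
class ScanSettings:
    """Batch-scan configuration.

    ``policy`` is ``"bonferroni"`` (adjusted p = min-p x 3m, significant
    below ``alpha``) or ``"fixed"`` (significant when min-p < ``threshold``,
    e.g. the 0.05/379 labWAS or 0.05/2923 PWAS cutoffs). ``mutual_adjust``
    enters all other scanned markers as main effects (blood-cell mode);
    ``marker_pcs`` appends the first k principal components of the
    standardized marker matrix to the adjustment set.
    """

    policy: str = "bonferroni"
    alpha: float = 0.05
    threshold: float | None = None
    reference_amplitude: float | None = None
    definition: str = "exact"
    mutual_adjust: bool = False
    marker_pcs: int = 0
    adjustment_name: str = "baseline"

    def __post_init__(self) -> None:
        if self.policy not in ("bonferroni", "fixed"):
            raise ValueError(f"unknown policy {self.policy!r}")
        if self.policy == "fixed" and self.threshold is None:
            raise ValueError("fixed policy requires a threshold")


@dataclass
class ScanResult:
    """Sorted per-marker summaries plus multiplicity bookkeeping."""

    table: pd.DataFrame
    n_tests: int
    policy: str
    threshold: float
    n_markers: int
    adjustment_name: str = "baseline"
    reference_amplitude: float | None = None
    skipped: list = field(default_factory=list)


def fit_interaction(
    outcome,
    months,
    marker,
    covariates=None,
    mutual_adjust=None,
    marker_name: str = MARKER_COL,
    robust: bool = False,
) -> InteractionFit:
    """Fit the interaction model for one marker.

    Rows with a missing marker value are dropped for this fit (the paper's
    incident-disease coding sets prevalent cases to missing). Markers in
    ``mutual_adjust`` enter as main effects only. A constant marker (after
    row filtering) raises.
    """
    y = np.asarray(outcome, float)
    m = np.asarray(marker, float)
    months_arr = np.asarray(months)
    if not len(y) == len(m) == len(months_arr):
        raise ValueError("outcome, months and marker differ in length")
    cov = _as_covariate_frame(covariates, len(y))
    if mutual_adjust is not None:
        mut = pd.DataFrame(mutual_adjust).reset_index(drop=True)
        cov = pd.concat([cov.reset_index(drop=True), mut], axis=1)
    keep = np.isfinite(m)
    n_dropped = int((~keep).sum())
    y, m, months_arr = y[keep], m[keep], months_arr[keep]
    cov = cov.loc[keep].reset_index(drop=True)
    if len(y) == 0 or np.all(m == m[0]):
        raise ValueError(f"marker {marker_name!r} is constant after row filtering")
    basis = seasonal_design(months_arr)
    X = pd.concat(
        [
            pd.Series(1.0, index=basis.index, name=INTERCEPT),
            pd.Series(m, index=basis.index, name=MARKER_COL),
            basis,
            pd.Series(m * basis[COS_COL], name=MCOS_COL),
            pd.Series(m * basis[SIN_COL], name=MSIN_COL),
            cov,
        ],
        axis=1,
    )
    params, pcov, df = _ols(X, y, robust=robust)
    return InteractionFit(
        marker_name=marker_name,
        params=params,
        cov=pcov,
        residual_df=df,
        n_used=len(y),
        n_dropped=n_dropped,
    )


def _delta_gradients(b2, b3, b4, b5, definition):
    """(delta_amp, grad) and (delta_phi, grad) over (b2, b3, b4, b5)."""
    a0 = np.hypot(b2, b3)
    a1 = np.hypot(b2 + b4, b3 + b5)
    if definition == "exact":
        d_amp = a1 - a0
        u_c, u_s = (b2 + b4) / a1, (b3 + b5) / a1
        v_c, v_s = b2 / a0, b3 / a0
        g_amp = np.array([u_c - v_c, u_s - v_s, u_c, u_s])
        d_phi = wrap_angle(np.arctan2(b3 + b5, b2 + b4) - np.arctan2(b3, b2))
        s1, c1 = (b3 + b5) / a1**2, (b2 + b4) / a1**2
        s0, c0 = b3 / a0**2, b2 / a0**2
        g_phi = np.array([-s1 + s0, c1 - c0, -s1, c1])
    elif definition == "linear":
        # first-order projections around the no-interaction point
        d_amp = (b2 * b4 + b3 * b5) / a0
        g_amp = np.array(
            [
                b4 / a0 - d_amp * b2 / a0**2,
                b5 / a0 - d_amp * b3 / a0**2,
                b2 / a0,
                b3 / a0,
            ]
        )
        d_phi = (b2 * b5 - b3 * b4) / a0**2
        g_phi = np.array(
            [
                b5 / a0**2 - 2.0 * d_phi * b2 / a0**2,
                -b4 / a0**2 - 2.0 * d_phi * b3 / a0**2,
                -b3 / a0**2,
                b2 / a0**2,
            ]
        )
    else:
        raise ValueError(f"unknown definition {definition!r}")
    return (float(d_amp), g_amp), (float(d_phi), g_phi)


def summarize_interaction(
    fit: InteractionFit,
    reference_amplitude: float | None = None,
    definition: str = "exact",
) -> InteractionSummary:
    """Transform an interaction fit into the three characteristic changes.

    The amplitude change is normalised to percent of ``reference_amplitude``
    (default: the same model's baseline amplitude ``sqrt(b2**2 + b3**2)``);
    the reference is treated as a fixed constant in the SE. The acrophase
    change is wrapped to (-pi, pi] and converted to months via 12/(2*pi).
    """
    b2, b3, b4, b5 = fit.beta_cos, fit.beta_sin, fit.beta_mcos, fit.beta_msin
    a0 = float(np.hypot(b2, b3))
    if a0 == 0.0:
        raise ValueError("baseline harmonic coefficients are both 0")
    a1 = float(np.hypot(b2 + b4, b3 + b5))
    if definition == "exact" and a1 < 1e-12:
        warnings.warn(
            f"marker {fit.marker_name!r}: marker-present amplitude ~ 0, "
            "acrophase change undefined",
            UserWarning,
            stacklevel=2,
        )
    ref = float(reference_amplitude) if reference_amplitude is not None else a0
    if not ref > 0:
        raise ValueError("reference_amplitude must be positive")
    cols = [COS_COL, SIN_COL, MCOS_COL, MSIN_COL]
    sigma = fit.cov.loc[cols, cols].to_numpy(float)
    (d_amp, g_amp), (d_phi, g_phi) = _delta_gradients(b2, b3, b4, b5, definition)
    amp_se = float(np.sqrt(g_amp @ sigma @ g_amp))
    phi_se = float(np.sqrt(g_phi @ sigma @ g_phi))
    month_scale = 12.0 / (2.0 * np.pi)
    disp_se = float(np.sqrt(fit.cov.loc[MARKER_COL, MARKER_COL]))
    return InteractionSummary(
        marker=fit.marker_name,
        delta_amplitude_pct=wald_summary(100.0 * d_amp / ref, 100.0 * amp_se / ref),
        delta_acrophase_months=wald_summary(d_phi * month_scale, phi_se * month_scale),
        displacement=wald_summary(fit.beta_marker, disp_se),
        baseline_amplitude=a0,
        reference_amplitude=ref,
        n_used=fit.n_used,
        definition=definition,
    )


_SCAN_COLUMNS = [
    "marker",
    "amplitude_est", "amplitude_se", "amplitude_z", "amplitude_p",
    "acrophase_est", "acrophase_se", "acrophase_z", "acrophase_p",
    "displacement_est", "displacement_se", "displacement_z", "displacement_p",
    "n_used", "p_adjusted", "significant",
]


def run_scan(
    outcome,
    months,
    markers: pd.DataFrame,
    covariates=None,
    settings: ScanSettings | None = None,
) -> ScanResult:
    """Scan every marker column for interaction with the seasonal pattern.

    Deterministic given its inputs; rows are sorted by the per-marker
    minimum p over the three characteristics. ``n_tests`` is always
    3 x (number of scanned markers); see :class:`ScanSettings` for the two
    significance policies. Degenerate markers are skipped and recorded.
    """
    settings = settings or ScanSettings()
    markers = pd.DataFrame(markers)
    if markers.shape[1] == 0:
        raise ValueError("empty marker table")
    cov = _as_covariate_frame(covariates, len(markers))
    if settings.marker_pcs > 0:
        cov = pd.concat([cov, _marker_pcs(markers, settings.marker_pcs)], axis=1)
    rows, skipped = [], []
    for name in markers.columns:
        mutual = None
        if settings.mutual_adjust and markers.shape[1] > 1:
            mutual = markers.drop(columns=[name]).apply(
                lambda c: c.fillna(c.mean())
            )
        try:
            fit = fit_interaction(
                outcome, months, markers[name].to_numpy(float),
                covariates=cov, mutual_adjust=mutual, marker_name=str(name),
            )
            summ = summarize_interaction(
                fit,
                reference_amplitude=settings.reference_amplitude,
                definition=settings.definition,
            )
        except (ValueError, np.linalg.LinAlgError) as exc:
            skipped.append((str(name), str(exc)))
            continue
        rows.append(summ.as_row())
    if not rows:
        raise ValueError(f"no scannable markers (skipped: {skipped})")
    table = pd.DataFrame(rows)
    n_markers = len(markers.columns)
    n_tests = 3 * n_markers
    min_p = table[["amplitude_p", "acrophase_p", "displacement_p"]].min(axis=1)
    if settings.policy == "bonferroni":
        threshold = settings.alpha / n_tests
        table["p_adjusted"] = np.minimum(min_p * n_tests, 1.0)
        table["significant"] = table["p_adjusted"] < settings.alpha
    else:
        threshold = float(settings.threshold)
        table["p_adjusted"] = min_p
        table["significant"] = min_p < threshold
    table = (
        table.assign(_min_p=min_p)
        .sort_values(["_min_p", "marker"], kind="mergesort")
        .drop(columns="_min_p")
        .reset_index(drop=True)
    )
    return ScanResult(
        table=table[_SCAN_COLUMNS],
        n_tests=n_tests,
        policy=settings.policy,
        threshold=threshold,
        n_markers=n_markers,
        adjustment_name=settings.adjustment_name,
        reference_amplitude=settings.reference_amplitude,
        skipped=skipped,
    )


def _marker_pcs(markers: pd.DataFrame, k: int) -> pd.DataFrame:
    """First k principal components of the standardized marker matrix."""
    x = markers.to_numpy(float)
    col_mean = np.nanmean(x, axis=0)
    miss = np.isnan(x)
    x[miss] = np.take(col_mean, np.where(miss)[1])
    sd = x.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    z = (x - x.mean(axis=0)) / sd
    u, s, _ = np.linalg.svd(z, full_matrices=False)
    k = min(k, len(s))
    return pd.DataFrame(u[:, :k] * s[:k], columns=[f"marker_pc{i+1}" for i in range(k)])


def incident_disease_exposure(event_time, recruit_time):
    """Incident-only disease coding: 0 none, 1 incident, NaN prevalent.

    No recorded event (NaN/NaT) -> 0; event strictly after recruitment -> 1;
    event on or before recruitment (prevalent) -> missing. Works on numbers
    or datetimes, scalars or arrays.
    """
    ev = pd.Series(np.atleast_1d(np.asarray(event_time, dtype=object)))
    rc = pd.Series(np.atleast_1d(np.asarray(recruit_time, dtype=object)))
    if len(rc) == 1 and len(ev) > 1:
        rc = pd.Series([rc.iloc[0]] * len(ev))
    has_event = ev.notna()
    out = np.zeros(len(ev), float)
    incident = has_event & (ev > rc)
    prevalent = has_event & ~incident
    out[incident.to_numpy()] = 1.0
    out[prevalent.to_numpy()] = np.nan
    if np.ndim(event_time) == 0:
        return float(out[0])
    return out


def composite_disease_phenotypes(groups: pd.DataFrame) -> pd.DataFrame:
    """Any-disease / multiple-disease composites over disease-group columns.

    Group columns are incident-coded (0/1 with NaN = prevalent). ``any``
    is 1 with >= 1 incident group; ``multiple`` is 1 with >= 2. A composite
    is missing only when its count criterion is not met outright and at
    least one group is missing (the prevalent exclusion propagates).
    """
    g = pd.DataFrame(groups)
    if g.shape[1] == 0:
        raise ValueError("need at least one disease-group column")
    vals = g.to_numpy(float)
    ones = np.nansum(vals == 1, axis=1)
    n_missing = np.isnan(vals).sum(axis=1)
    any_d = np.where(ones >= 1, 1.0, np.where(n_missing > 0, np.nan, 0.0))
    multi = np.where(ones >= 2, 1.0, np.where(n_missing > 0, np.nan, 0.0))
    return pd.DataFrame({"any_disease": any_d, "multiple_diseases": multi})


def mortality_interaction(
    outcome,
    months,
    death,
    followup_years,
    covariates=None,
    reference_amplitude: float | None = None,
    definition: str = "exact",
):
    """All-cause-mortality interaction: death indicator as the marker.

    Length of follow-up is appended to the adjustment set automatically;
    frailty index, hematocrit, lymphocyte and neutrophil counts should be
    supplied through ``covariates``. Returns ``(fit, summary)``.
    """
    cov = _as_covariate_frame(covariates, len(np.asarray(outcome)))
    cov = cov.assign(followup_years=np.asarray(followup_years, float))
    fit = fit_interaction(
        outcome, months, death, covariates=cov, marker_name="death"
    )
    return fit, summarize_interaction(
        fit, reference_amplitude=reference_amplitude, definition=definition
    )


def zscore_correlations(scan: ScanResult | pd.DataFrame) -> pd.DataFrame:
    """Pearson correlations between the three z-score columns of a scan."""
    table = scan.table if isinstance(scan, ScanResult) else scan
    cols = ["amplitude_z", "acrophase_z", "displacement_z"]
    z = table[cols].to_numpy(float)
    if z.shape[0] < 3:
        raise ValueError("need at least 3 markers for z-score correlations")
    sd = z.std(axis=0)
    if np.any(sd == 0):
        flagged = [c for c, s in zip(cols, sd) if s == 0]
        warnings.warn(f"zero-variance z-score columns: {flagged}", UserWarning,
                      stacklevel=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(z, rowvar=False)
    names = ["amplitude", "acrophase", "displacement"]
    return pd.DataFrame(corr, index=names, columns=names)


def lambda_gc(p_values) -> float:
    """Genomic inflation factor: median implied 1-df chi-square / 0.4549."""
    p = np.asarray(p_values, float)
    if p.size == 0:
        raise ValueError("empty p-value input")
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    chisq = stats.chi2.isf(p, df=1)
    return float(np.median(chisq) / CHI2_NULL_MEDIAN_1DF)
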