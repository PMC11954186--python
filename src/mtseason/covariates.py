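"""Derivation and imputation of adjustment covariates.

Lifestyle variables are coded as binaries with missing collapsed into the
reference category (ever smoked vs never/missing, more than three drinks a
week vs less/missing, below the physical-activity recommendation vs
meeting-it/missing, university degree vs none/missing). Pack-years are 0
for never-smokers and group-median imputed for past/current smokers; BMI
and eGFR are median-imputed. eGFR uses the 2009 CKD-EPI creatinine
equation. All derivations recompute from the raw columns, so applying
:func:`derive_lifestyle` twice is a no-op.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "derive_lifestyle",
    "egfr_ckd_epi",
    "frailty_index",
    "log2_standardize_omics",
]

UMOL_PER_MGDL = 88.42  # creatinine micromol/L per mg/dL

_SMOKER_GROUPS = ("past", "current")


def egfr_ckd_epi(creatinine_umol, age, sex):
    """Estimated GFR (mL/min/1.73m2), CKD-EPI 2009 creatinine equation.

    Creatinine in micromol/L is converted to mg/dL (divide by 88.42), then

        eGFR = scale * min(Scr/kappa, 1)**alpha * max(Scr/kappa, 1)**-1.209
               * 0.993**age

    with (kappa, alpha, scale) = (0.7, -0.329, 144) for females and
    (0.9, -0.411, 141) for males. The race coefficient is fixed at 1.
    ``sex`` accepts "female"/"male" (or "f"/"m", case-insensitive), scalars
    or arrays. Monotone decreasing in creatinine and in age.
    """
    scr = np.asarray(creatinine_umol, float) / UMOL_PER_MGDL
    if np.any(~np.isfinite(scr)) or np.any(scr <= 0):
        raise ValueError("creatinine must be positive")
    a = np.asarray(age, float)
    if np.any(a < 0):
        raise ValueError("age must be non-negative")
    female = _is_female(sex)
    kappa = np.where(female, 0.7, 0.9)
    alpha = np.where(female, -0.329, -0.411)
    scale = np.where(female, 144.0, 141.0)
    r = scr / kappa
    egfr = scale * np.minimum(r, 1.0) ** alpha * np.maximum(r, 1.0) ** -1.209 * 0.993 ** a
    if np.ndim(creatinine_umol) == 0 and np.ndim(age) == 0 and np.ndim(sex) == 0:
        return float(egfr)
    return egfr


def _is_female(sex) -> np.ndarray:
    s = np.asarray(sex)
    if s.dtype.kind in "bui":
        # numeric coding: 1 = female, 0 = male (matches the simulator's
        # `female` indicator)
        return s.astype(bool)
    flat = np.char.lower(s.astype(str))
    female = np.isin(flat, ["female", "f"])
    male = np.isin(flat, ["male", "m"])
    if not np.all(female | male):
        bad = np.asarray(s).ravel()[~(female | male).ravel()][0]
        raise ValueError(f"unrecognised sex value: {bad!r}")
    return female


def frailty_index(ailment_flags):
    """Percentage of self-reported ailments out of all queried items.

    1-D input (one individual, Q items) returns a scalar; 2-D input
    (n individuals x Q items) returns one percentage per row. Always in
    [0, 100].
    """
    flags = np.asarray(ailment_flags)
    if flags.size == 0 or flags.shape[-1] == 0:
        raise ValueError("need at least one questionnaire item")
    vals = flags.astype(float)
    if np.any(~np.isin(vals, (0.0, 1.0))):
        raise ValueError("ailment flags must be boolean/0-1")
    pct = 100.0 * vals.mean(axis=-1)
    return float(pct) if flags.ndim == 1 else pct


def derive_lifestyle(raw: pd.DataFrame) -> pd.DataFrame:
    """Derive the lifestyle/adjustment covariates from raw phenotype columns.

    Recognised raw columns (all optional; only those present are processed):

    - ``smoking_status`` ("never"/"past"/"current", NA allowed) ->
      ``ever_smoked`` (1 for past/current, 0 for never or missing) and
      pack-years handling.
    - ``packyears`` -> 0 for never-smokers/missing status; missing values in
      past/current smokers imputed to the median of that smoking group.
    - ``drinks_per_week`` -> ``risky_alcohol`` (1 if > 3, 0 if <= 3 or missing).
    - ``meets_activity_recommendation`` (bool) -> ``low_activity`` (1 only if
      explicitly below recommendation, 0 if meeting it or missing).
    - ``university_degree`` (bool/0-1, NA allowed) -> 0/1 with missing -> 0.
    - ``bmi`` -> median-imputed in place.
    - ``creatinine_umol`` + ``age`` + ``sex`` -> ``egfr``, median-imputed.

    Derived columns are recomputed from the raw ones on every call
    (idempotent); raw columns other than ``bmi`` are left untouched.
    """
    out = raw.copy()
    if "smoking_status" in out:
        status = out["smoking_status"].astype("object")
        ever = status.isin(_SMOKER_GROUPS)
        out["ever_smoked"] = ever.astype(int)
        if "packyears" in out:
            py = pd.to_numeric(out["packyears"], errors="coerce")
            filled = py.copy()
            filled[~ever] = 0.0  # never smoked or missing status
            for group in _SMOKER_GROUPS:
                in_group = status == group
                need = in_group & py.isna()
                if need.any():
                    observed = py[in_group].dropna()
                    filled[need] = observed.median() if len(observed) else 0.0
            out["packyears"] = filled
    if "drinks_per_week" in out:
        drinks = pd.to_numeric(out["drinks_per_week"], errors="coerce")
        out["risky_alcohol"] = (drinks > 3).fillna(False).astype(int)
    if "meets_activity_recommendation" in out:
        meets = out["meets_activity_recommendation"]
        out["low_activity"] = (meets == False).astype(int)  # noqa: E712 -- NA is not "below"
    if "university_degree" in out:
        deg = pd.to_numeric(out["university_degree"], errors="coerce")
        out["university_degree"] = (deg == 1).astype(int)
    if "bmi" in out:
        bmi = pd.to_numeric(out["bmi"], errors="coerce")
        out["bmi"] = bmi.fillna(bmi.median())
    if {"creatinine_umol", "age", "sex"}.issubset(out.columns):
        crea = pd.to_numeric(out["creatinine_umol"], errors="coerce")
        egfr = pd.Series(np.nan, index=out.index)
        ok = crea.notna() & (crea > 0)
        if ok.any():
            egfr[ok] = egfr_ckd_epi(
                crea[ok].to_numpy(), out.loc[ok, "age"].to_numpy(),
                out.loc[ok, "sex"].to_numpy(),
            )
        out["egfr"] = egfr.fillna(egfr.median())
    return out


def log2_standardize_omics(
    matrix: pd.DataFrame, method: str = "mean", rank: int = 2,
    max_iter: int = 100, tol: float = 1e-8,
) -> pd.DataFrame:
    """Impute, log2-transform and scale an omics marker matrix.

    Per marker (column): missing entries are imputed, values are log2
    transformed, then centered and scaled to mean 0 / sample SD 1.

    ``method="mean"`` (default) imputes the per-marker mean on the raw scale
    before the transform. ``method="lowrank"`` runs an iterative truncated-SVD
    reconstruction of the missing cells on the log2 scale (an approximation
    of PCA-based imputation). Non-positive observed values raise an error
    naming the marker, as do constant (zero-variance) markers.
    """
    mat = pd.DataFrame(matrix).astype(float)
    if mat.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    for col in mat.columns:
        observed = mat[col].dropna()
        if observed.empty:
            raise ValueError(f"marker {col!r} has no observed values")
        if (observed <= 0).any():
            raise ValueError(f"marker {col!r} contains non-positive values")
    if method == "mean":
        filled = mat.apply(lambda c: c.fillna(c.mean()))
        logged = np.log2(filled)
    elif method == "lowrank":
        logged = _lowrank_impute(np.log2(mat), rank=rank, max_iter=max_iter, tol=tol)
    else:
        raise ValueError(f"unknown imputation method {method!r}")
    sd = logged.std(ddof=1)
    constant = sd[sd == 0].index.tolist()
    if constant:
        raise ValueError(f"marker {constant[0]!r} has zero variance after transform")
    return (logged - logged.mean()) / sd


def _lowrank_impute(logged: pd.DataFrame, rank: int, max_iter: int, tol: float):
    x = logged.to_numpy(copy=True)
    miss = np.isnan(x)
    col_means = np.nanmean(x, axis=0)
    x[miss] = np.take(col_means, np.where(miss)[1])
    r = min(rank, min(x.shape) - 1)
    prev = x[miss].copy() if miss.any() else None
    for _ in range(max_iter):
        if prev is None:
            break
        u, s, vt = np.linalg.svd(x - x.mean(axis=0), full_matrices=False)
        recon = (u[:, :r] * s[:r]) @ vt[:r] + x.mean(axis=0)
        x[miss] = recon[miss]
        if np.max(np.abs(x[miss] - prev)) < tol:
            break
        prev = x[miss].copy()
    return pd.DataFrame(x, index=logged.index, columns=logged.columns)
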