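"""Coverage-based mitochondrial DNA abundance: normalisation, QC, scaling.

Per-sample mitochondrial mean coverage is divided by the sample's total
mapped reads, outliers beyond ``k`` interquartile ranges from the median are
excluded (default k = 4) in a single pass, and the surviving ratios are
standardized to mean 0, sample SD 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "QCConfig",
    "normalized_mtdna_ratio",
    "iqr_outlier_mask",
    "standardize",
    "abundance_table",
]


@dataclass(frozen=True)
class QCConfig:
    """Outlier rule: keep values within ``iqr_multiplier`` IQRs of the median."""

    iqr_multiplier: float = 4.0

    def __post_init__(self) -> None:
        if not self.iqr_multiplier > 0:
            raise ValueError("iqr_multiplier must be positive")


def normalized_mtdna_ratio(mt_mean_coverage, total_mapped_reads):
    """Mitochondrial mean coverage divided by total mapped reads.

    Scale-invariant in the sequencing effort: doubling both coverage and
    reads leaves the ratio unchanged. Accepts scalars or arrays.
    """
    cov = np.asarray(mt_mean_coverage, float)
    reads = np.asarray(total_mapped_reads, float)
    if np.any(~np.isfinite(reads)) or np.any(reads <= 0):
        raise ValueError("total_mapped_reads must be positive")
    if np.any(cov < 0):
        raise ValueError("mt_mean_coverage must be non-negative")
    ratio = cov / reads
    if np.ndim(mt_mean_coverage) == 0 and np.ndim(total_mapped_reads) == 0:
        return float(ratio)
    return ratio


def iqr_outlier_mask(values, qc: QCConfig | float = QCConfig()) -> np.ndarray:
    """Boolean keep-mask: True where ``|v - median| <= k * IQR``.

    Median and IQR (linear-interpolation quantiles) are computed once on the
    full input; the rule is deliberately *not* iterated. Non-finite entries
    are never kept. A zero IQR keeps only values equal to the median and
    emits a warning (literal application of the rule).
    """
    k = qc.iqr_multiplier if isinstance(qc, QCConfig) else float(qc)
    if not k > 0:
        raise ValueError("iqr multiplier must be positive")
    v = np.asarray(values, float)
    finite = np.isfinite(v)
    if finite.sum() < 4:
        raise ValueError("need at least 4 finite values for the IQR filter")
    vf = v[finite]
    med = float(np.median(vf))
    q1, q3 = np.quantile(vf, [0.25, 0.75])  # linear interpolation (default)
    iqr = float(q3 - q1)
    if iqr == 0.0:
        warnings.warn(
            "IQR is 0; keeping only values equal to the median", UserWarning,
            stacklevel=2,
        )
        keep = v == med
    else:
        keep = np.abs(v - med) <= k * iqr
    return keep & finite


def standardize(values) -> np.ndarray:
    """Center and scale to mean 0, sample SD 1 (ddof=1); order preserved."""
    v = np.asarray(values, float)
    if v.size < 2:
        raise ValueError("need at least 2 values to standardize")
    if np.any(~np.isfinite(v)):
        raise ValueError("values contain missing/non-finite entries")
    sd = v.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance: cannot standardize")
    return (v - v.mean()) / sd


def abundance_table(
    coverage: pd.DataFrame, qc: QCConfig = QCConfig()
) -> pd.DataFrame:
    """Full pipeline: ratio, single-pass IQR filter, then standardize survivors.

    ``coverage`` needs columns ``sample_id``, ``mt_mean_coverage`` and
    ``total_mapped_reads``. Returns one row per sample with ``ratio``,
    ``qc_pass`` and ``z`` (NaN for excluded samples). Standardization runs
    strictly after exclusion, so the z-values have mean 0 / SD 1 over the
    kept set only.
    """
    required = {"sample_id", "mt_mean_coverage", "total_mapped_reads"}
    missing = required - set(coverage.columns)
    if missing:
        raise ValueError(f"coverage table missing columns: {sorted(missing)}")
    ratio = normalized_mtdna_ratio(
        coverage["mt_mean_coverage"].to_numpy(),
        coverage["total_mapped_reads"].to_numpy(),
    )
    keep = iqr_outlier_mask(ratio, qc)
    z = np.full(len(ratio), np.nan)
    z[keep] = standardize(ratio[keep])
    return pd.DataFrame(
        {
            "sample_id": coverage["sample_id"].to_numpy(),
            "ratio": ratio,
            "qc_pass": keep,
            "z": z,
        }
    )
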