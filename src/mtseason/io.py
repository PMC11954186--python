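"""Readers/writers for cohort tables, coverage summaries and scan results.

Everything is tab-delimited UTF-8 with '.' decimals and NA for missing.
Result files start with '# key: value' metadata lines (package version,
seed, config hash, scan bookkeeping) so any output can be reproduced
exactly.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .scan import ScanResult

__all__ = [
    "read_cohort_table",
    "write_cohort_table",
    "read_mosdepth_summary",
    "write_coverage_files",
    "read_coverage_dir",
    "write_scan_results",
    "read_scan_results",
    "write_truth",
    "load_config",
    "config_hash",
]

MITO_CONTIGS = ("MT", "chrM")
_FLOAT_FMT = "%.17g"  # full float round trip
NA = "NA"


def _version() -> str:
    from . import __version__

    return __version__


def config_hash(obj) -> str:
    """Short sha256 of a canonical-JSON rendering of a config mapping."""
    blob = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _write_metadata(handle, metadata: dict | None) -> None:
    handle.write(f"# mtseason {_version()}\n")
    for key, value in (metadata or {}).items():
        handle.write(f"# {key}: {value}\n")


def _read_metadata(path) -> dict:
    meta = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if ":" in body:
                key, _, value = body.partition(":")
                meta[key.strip()] = value.strip()
    return meta


def write_cohort_table(cohort: pd.DataFrame, path, metadata: dict | None = None) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        _write_metadata(fh, metadata)
        cohort.to_csv(fh, sep="\t", index=False, na_rep=NA, float_format=_FLOAT_FMT)


def read_cohort_table(path, mapping: dict | None = None, month_col: str = "month") -> pd.DataFrame:
    """Read a tab-delimited cohort table; validate the month column.

    ``mapping`` renames input columns to canonical names
    ({input_name: canonical_name}); a mapped column that is absent raises an
    error naming it, and an out-of-range month raises with its row index.
    """
    table = pd.read_csv(path, sep="\t", comment="#", na_values=[NA])
    if mapping:
        missing = [c for c in mapping if c not in table.columns]
        if missing:
            raise ValueError(f"mapped column(s) not found in {path}: {missing}")
        table = table.rename(columns=mapping)
    if month_col not in table.columns:
        raise ValueError(f"month column {month_col!r} not found in {path}")
    months = pd.to_numeric(table[month_col], errors="coerce")
    bad = months.isna() | (months < 1) | (months > 12) | (months != months.round())
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValueError(
            f"month out of range 1..12 at row {row}: {table[month_col].iloc[row]!r}"
        )
    table[month_col] = months.astype(int)
    return table


def read_mosdepth_summary(path) -> float:
    """Mitochondrial mean coverage from a mosdepth summary file.

    The dialect is whitespace/tab-delimited with columns
    (chrom, length, bases, mean); the mitochondrial contig may be named
    "MT" or "chrM".
    """
    table = pd.read_csv(path, sep=r"\s+", comment="#")
    table.columns = [c.lower() for c in table.columns]
    if "chrom" not in table.columns or "mean" not in table.columns:
        raise ValueError(f"{path} is not a mosdepth summary (need chrom/mean columns)")
    hit = table[table["chrom"].isin(MITO_CONTIGS)]
    if hit.empty:
        raise ValueError(f"no mitochondrial contig ({'/'.join(MITO_CONTIGS)}) in {path}")
    return float(hit["mean"].iloc[0])


def write_coverage_files(coverage: pd.DataFrame, out_dir) -> None:
    """One mosdepth-dialect summary per sample plus a reads manifest."""
    out = Path(out_dir)
    (out / "coverage").mkdir(parents=True, exist_ok=True)
    for row in coverage.itertuples(index=False):
        p = out / "coverage" / f"{row.sample_id}.mosdepth.summary.txt"
        with open(p, "w", encoding="utf-8", newline="\n") as fh:
            fh.write("chrom\tlength\tbases\tmean\n")
            fh.write(
                f"{row.chrom}\t{row.length}\t{row.bases}\t{_FLOAT_FMT % row.mean}\n"
            )
    manifest = coverage[["sample_id", "total_mapped_reads"]]
    manifest.to_csv(out / "reads_manifest.tsv", sep="\t", index=False)


def read_coverage_dir(cov_dir, manifest_path) -> pd.DataFrame:
    """Join per-sample mosdepth summaries with the total-reads manifest."""
    manifest = pd.read_csv(manifest_path, sep="\t")
    if not {"sample_id", "total_mapped_reads"}.issubset(manifest.columns):
        raise ValueError("manifest needs sample_id and total_mapped_reads columns")
    cov_dir = Path(cov_dir)
    means = []
    for sample in manifest["sample_id"].astype(str):
        p = cov_dir / f"{sample}.mosdepth.summary.txt"
        if not p.exists():
            raise FileNotFoundError(f"no coverage summary for sample {sample}: {p}")
        means.append(read_mosdepth_summary(p))
    return pd.DataFrame(
        {
            "sample_id": manifest["sample_id"].to_numpy(),
            "mt_mean_coverage": means,
            "total_mapped_reads": manifest["total_mapped_reads"].to_numpy(),
        }
    )


def write_scan_results(scan: ScanResult, path, seed=None, confhash=None) -> None:
    """Deterministic scan output: metadata header then a fixed-order table."""
    meta = {
        "seed": seed if seed is not None else NA,
        "config_hash": confhash if confhash is not None else NA,
        "n_tests": scan.n_tests,
        "n_markers": scan.n_markers,
        "policy": scan.policy,
        "threshold": _FLOAT_FMT % scan.threshold,
        "adjustment": scan.adjustment_name,
        "reference_amplitude": (
            _FLOAT_FMT % scan.reference_amplitude
            if scan.reference_amplitude is not None
            else "baseline"
        ),
        "skipped": ";".join(name for name, _ in scan.skipped) or "none",
    }
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        _write_metadata(fh, meta)
        scan.table.to_csv(fh, sep="\t", index=False, na_rep=NA, float_format=_FLOAT_FMT)


def read_scan_results(path):
    """Inverse of :func:`write_scan_results`: (table, metadata dict)."""
    meta = _read_metadata(path)
    table = pd.read_csv(path, sep="\t", comment="#", na_values=[NA])
    return table, meta


def write_truth(truth, path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        json.dump(truth.as_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")


def load_config(path) -> dict:
    """YAML or JSON pipeline configuration."""
    text = Path(path).read_text(encoding="utf-8")
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text)
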