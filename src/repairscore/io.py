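"""Readers and writers for the interchange formats.

Cohorts travel as UTF-8 CSV with a fixed header-driven schema; counts as
TSV (genes x samples, first column gene ids) or MatrixMarket with gene and
sample sidecar files; gene sets as GMT; reports and manifests as JSON.
Every writer can emit a sidecar manifest recording parameters, seeds, and
input hashes so any result file traces back to its exact configuration.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from ._design import CASE_LEVELS, SEX_LEVELS, SMOKING_LEVELS

__all__ = [
    "CohortValidationError",
    "read_cohort",
    "write_cohort",
    "read_gene_sets",
    "write_gene_sets",
    "read_counts",
    "write_counts",
    "read_counts_mtx",
    "write_counts_mtx",
    "write_manifest",
    "file_sha256",
]

REQUIRED_COLS = ("id", "case_status", "ogg1", "mpg", "ape1", "age", "sex", "smoking")
OPTIONAL_COLS = ("stage", "t_cat", "n_cat", "m_cat", "pack_years", "copd", "batch")
_ENUMS = {"case_status": CASE_LEVELS, "sex": SEX_LEVELS, "smoking": SMOKING_LEVELS}


class CohortValidationError(ValueError):
    """Schema or value errors in a cohort table, with row-level detail."""

    def __init__(self, issues: list[str]):
        self.issues = issues
        super().__init__("cohort validation failed:\n  " + "\n  ".join(issues[:20]))


def validate_cohort(df: pd.DataFrame) -> list[str]:
    """Collect row-level validation issues (empty list = valid)."""
    issues = []
    missing = [c for c in REQUIRED_COLS if c not in df.columns]
    if missing:
        return [f"missing required columns: {missing}"]
    dup = df["id"][df["id"].duplicated()]
    if len(dup):
        issues.append(f"duplicate ids: {sorted(dup.unique().tolist())}")
    for col, levels in _ENUMS.items():
        vals = df[col].dropna()
        bad = ~vals.isin(levels)
        for idx in vals.index[bad]:
            issues.append(f"row {idx + 2}: {col}={df.at[idx, col]!r} not in {levels}")
    for col in ("ogg1", "mpg", "ape1", "age"):
        vals = pd.to_numeric(df[col], errors="coerce")
        neg = vals <= 0
        for idx in df.index[neg.fillna(False)]:
            issues.append(f"row {idx + 2}: {col}={df.at[idx, col]!r} must be positive")
    return issues


def read_cohort(path, *, strict: bool = True) -> pd.DataFrame:
    """Read and validate a cohort CSV.

    Row numbers in error messages are 1-based file lines (header = line 1).
    Missing enzyme activities are allowed on read (they are tallied into
    ``df.attrs['n_missing_activities']`` and excluded downstream by the
    scoring stage), but enumeration violations and duplicate ids raise.
    """
    df = pd.read_csv(path, dtype={"id": str})
    issues = validate_cohort(df)
    if issues and strict:
        raise CohortValidationError(issues)
    df.attrs["n_missing_activities"] = int(df[["ogg1", "mpg", "ape1"]].isna().any(axis=1).sum())
    df.attrs["validation_issues"] = issues
    return df


def write_cohort(df: pd.DataFrame, path) -> None:
    cols = [c for c in REQUIRED_COLS + OPTIONAL_COLS if c in df.columns]
    df.to_csv(path, index=False, columns=cols)


def read_gene_sets(path) -> dict[str, list[str]]:
    """Parse a GMT file: name <tab> description <tab> member genes."""
    sets: dict[str, list[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line needs >=3 tab-separated fields, got {len(fields)}"
                )
            name = fields[0]
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
            members, seen = [], set()
            dups = 0
            for g in fields[2:]:
                if not g:
                    continue
                if g in seen:
                    dups += 1
                    continue
                seen.add(g)
                members.append(g)
            if dups:
                import warnings

                warnings.warn(f"{path}:{lineno}: set {name!r} listed {dups} duplicate member(s)")
            sets[name] = members
    return sets


def write_gene_sets(sets: dict, path, description: str = "na") -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, description, *members]) + "\n")


def read_counts(path) -> pd.DataFrame:
    """Read a genes x samples TSV count matrix (first column gene ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = "gene"
    if (df.to_numpy() < 0).any():
        raise ValueError("count matrix contains negative values")
    return df


def write_counts(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index_label="gene")


def read_counts_mtx(mtx_path, genes_path, samples_path) -> pd.DataFrame:
    from scipy.io import mmread

    m = mmread(mtx_path)
    genes = [l.strip() for l in open(genes_path, encoding="utf-8") if l.strip()]
    samples = [l.strip() for l in open(samples_path, encoding="utf-8") if l.strip()]
    arr = np.asarray(m.todense() if hasattr(m, "todense") else m)
    if arr.shape != (len(genes), len(samples)):
        raise ValueError(f"matrix shape {arr.shape} != ({len(genes)}, {len(samples)})")
    return pd.DataFrame(arr, index=pd.Index(genes, name="gene"), columns=samples)


def write_counts_mtx(counts: pd.DataFrame, mtx_path, genes_path, samples_path) -> None:
    from scipy.io import mmwrite
    from scipy.sparse import csr_matrix

    mmwrite(str(mtx_path), csr_matrix(counts.to_numpy()))
    Path(genes_path).write_text("\n".join(counts.index) + "\n", encoding="utf-8")
    Path(samples_path).write_text("\n".join(map(str, counts.columns)) + "\n", encoding="utf-8")


def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(path, *, params: dict | None = None, seeds: dict | None = None,
                   inputs: dict | None = None) -> dict:
    """Write a JSON manifest: params, seeds, input-file hashes, version."""
    from . import __version__

    manifest = {
        "version": __version__,
        "params": params or {},
        "seeds": seeds or {},
        "inputs": {k: file_sha256(v) for k, v in (inputs or {}).items()},
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, default=_jsonable)
    return manifest


def _jsonable(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    return str(o)
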