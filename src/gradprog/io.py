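"""Readers and writers for the plain-text formats the pipeline exchanges.

All artifacts are diffable text: expression matrices and sample
annotation as TSV, gene-set collections as GMT, miRNA target edges as
two-column TSV, survival tables as TSV, ground truth as JSON.

An expression matrix is a :class:`pandas.DataFrame` with gene IDs as the
(unique) index and sample IDs as the (unique) columns, values in log2
units.  The loader is the single place where platform concerns live:
duplicate gene rows are collapsed to the row with the highest mean
(a common probe→gene rule) and missing entries are imputed with the
gene's row mean so every downstream stage can assume finite values.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

TISSUES = ("normal", "peri", "cancer")


class DataError(ValueError):
    """Malformed or inconsistent input data."""


# ---------------------------------------------------------------- expression


def validate_expression(expr: pd.DataFrame) -> pd.DataFrame:
    """Check the expression-matrix contract (unique IDs, finite values)."""
    if expr.index.has_duplicates:
        dups = expr.index[expr.index.duplicated()].unique().tolist()[:5]
        raise DataError(f"duplicate gene IDs: {dups}")
    if expr.columns.has_duplicates:
        raise DataError("duplicate sample IDs")
    if not np.isfinite(expr.to_numpy(dtype=float)).all():
        raise DataError("non-finite expression values after loading")
    return expr


def read_expression(path: str | Path) -> pd.DataFrame:
    """Load a genes × samples TSV (first column gene ID, header sample IDs).

    Duplicate gene rows are collapsed to the duplicate with the largest
    mean; remaining missing values are filled with the row mean.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df = df.astype(float)
    if df.index.has_duplicates:
        # collapse duplicate gene rows to the one with the largest mean
        means = df.mean(axis=1).to_numpy()
        best: dict[str, int] = {}
        for pos, (gid, m) in enumerate(zip(df.index, means)):
            if gid not in best or m > means[best[gid]]:
                best[gid] = pos
        df = df.iloc[sorted(best.values())]
    if df.isna().any().any():
        row_means = df.mean(axis=1)
        df = df.apply(lambda col: col.fillna(row_means))
        if df.isna().any().any():  # all-NaN rows
            raise DataError("rows with no finite value cannot be imputed")
    return validate_expression(df)


def write_expression(expr: pd.DataFrame, path: str | Path) -> None:
    expr.to_csv(path, sep="\t", index_label="gene_id", float_format="%.6g")


# ---------------------------------------------------------------- annotation


def validate_annotation(annot: pd.DataFrame) -> pd.DataFrame:
    required = {"sample_id", "patient_id", "tissue"}
    missing = required - set(annot.columns)
    if missing:
        raise DataError(f"annotation missing columns: {sorted(missing)}")
    bad = set(annot["tissue"]) - set(TISSUES)
    if bad:
        raise DataError(f"unknown tissue labels: {sorted(bad)}")
    if annot["sample_id"].duplicated().any():
        raise DataError("duplicate sample IDs in annotation")
    return annot


def read_annotation(path: str | Path) -> pd.DataFrame:
    return validate_annotation(pd.read_csv(path, sep="\t", dtype=str))


def write_annotation(annot: pd.DataFrame, path: str | Path) -> None:
    annot.to_csv(path, sep="\t", index=False)


def samples_of(annot: pd.DataFrame, tissue: str) -> list[str]:
    """Sample IDs of one tissue class, in annotation order."""
    if tissue not in TISSUES:
        raise DataError(f"unknown tissue {tissue!r}")
    return annot.loc[annot["tissue"] == tissue, "sample_id"].tolist()


def paired_samples(annot: pd.DataFrame) -> pd.DataFrame:
    """Patient-level table with one cancer and one peri sample per row."""
    wide = (
        annot[annot["tissue"].isin(["peri", "cancer"])]
        .pivot(index="patient_id", columns="tissue", values="sample_id")
        .dropna()
        .reset_index()
    )
    return wide


# ---------------------------------------------------------------- survival


def validate_survival(surv: pd.DataFrame) -> pd.DataFrame:
    required = {"patient_id", "time_months", "event"}
    missing = required - set(surv.columns)
    if missing:
        raise DataError(f"survival table missing columns: {sorted(missing)}")
    if (surv["time_months"] <= 0).any():
        raise DataError("survival times must be positive")
    if not surv["event"].isin([0, 1]).all():
        raise DataError("event indicator must be 0 or 1")
    return surv


def read_survival(path: str | Path) -> pd.DataFrame:
    surv = pd.read_csv(path, sep="\t")
    surv["patient_id"] = surv["patient_id"].astype(str)
    surv["time_months"] = surv["time_months"].astype(float)
    surv["event"] = surv["event"].astype(int)
    return validate_survival(surv)


def write_survival(surv: pd.DataFrame, path: str | Path) -> None:
    surv.to_csv(path, sep="\t", index=False, float_format="%.6g")


# ---------------------------------------------------------------- gene sets


def read_gmt(path: str | Path) -> dict[str, dict]:
    """Read a GMT file into ``{name: {"description": str, "genes": set}}``."""
    sets: dict[str, dict] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise DataError(f"GMT line with <3 fields: {line[:60]!r}")
        name, desc, *genes = fields
        if name in sets:
            raise DataError(f"duplicate gene-set name {name!r}")
        members = {g for g in genes if g}
        if not members:
            raise DataError(f"gene set {name!r} has no members")
        sets[name] = {"description": desc, "genes": members}
    return sets


def write_gmt(sets: dict[str, dict], path: str | Path) -> None:
    lines = []
    for name, rec in sets.items():
        genes = sorted(rec["genes"])
        lines.append("\t".join([name, rec.get("description", "")] + genes))
    Path(path).write_text("\n".join(lines) + "\n")


# ------------------------------------------------------------- target edges


def read_target_table(path: str | Path) -> set[tuple[str, str]]:
    """Read one miRNA→gene edge TSV (columns mirna_id, gene_id)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"mirna_id", "gene_id"} <= set(df.columns):
        raise DataError("target table needs columns mirna_id, gene_id")
    return set(zip(df["mirna_id"], df["gene_id"]))


def write_target_table(edges: set[tuple[str, str]], path: str | Path) -> None:
    df = pd.DataFrame(sorted(edges), columns=["mirna_id", "gene_id"])
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------- json blobs


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())
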