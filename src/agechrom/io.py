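"""Readers and writers for the on-disk formats the pipeline consumes and emits.

All genomic coordinates are 0-based half-open throughout the package; BED files
are read and written in that same convention, so round trips are exact. Summits
are stored as 1-bp intervals.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

logger = logging.getLogger("agechrom")

BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


class FormatError(ValueError):
    """A file violates its declared format."""


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read a BED file (>=3 columns) into a DataFrame of 0-based half-open intervals.

    Columns beyond the sixth are ignored. Input order is retained. Raises
    :class:`FormatError` naming the offending 1-based line for non-integer
    coordinates or start >= end.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}: line {lineno}: fewer than 3 columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(
                    f"{path}: line {lineno}: non-integer coordinate"
                ) from exc
            if start >= end:
                raise FormatError(f"{path}: line {lineno}: start >= end ({start} >= {end})")
            if start < 0:
                raise FormatError(f"{path}: line {lineno}: negative start")
            name = fields[3] if len(fields) > 3 else "."
            score = float(fields[4]) if len(fields) > 4 and fields[4] != "." else 0.0
            strand = fields[5] if len(fields) > 5 else "."
            rows.append((chrom, start, end, name, score, strand))
    return pd.DataFrame(rows, columns=BED_COLUMNS)


def write_bed(df: pd.DataFrame, path: str | Path) -> None:
    """Write intervals to BED; emits the six canonical columns."""
    out = df.copy()
    for col, default in [("name", "."), ("score", 0.0), ("strand", ".")]:
        if col not in out.columns:
            out[col] = default
    out["score"] = out["score"].map(lambda v: format(float(v), ".6g"))
    out[BED_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def read_counts_mtx(
    matrix_path: str | Path,
    rows_path: str | Path,
    cols_path: str | Path,
) -> tuple[sp.csr_matrix, list[str], list[str]]:
    """Read a MatrixMarket count matrix with row/column identifier files.

    Duplicate coordinate entries are summed (with a logged warning, the
    conventional sparse dialect). Negative entries and header/index length
    mismatches raise :class:`FormatError`.
    """
    mat = scipy.io.mmread(matrix_path)
    coo = sp.coo_matrix(mat)
    if coo.data.size and coo.data.min() < 0:
        raise FormatError(f"{matrix_path}: negative entry in count matrix")
    n_entries_raw = coo.data.size
    mat = coo.tocsr()
    if mat.data.size != n_entries_raw:
        # csr conversion merged duplicate coordinates by summation
        logger.warning(
            "%s: %d duplicate coordinate entries summed",
            matrix_path,
            n_entries_raw - mat.data.size,
        )
    row_ids = _read_index(rows_path)
    col_ids = _read_index(cols_path)
    if len(row_ids) != mat.shape[0]:
        raise FormatError(
            f"{rows_path}: {len(row_ids)} identifiers but matrix header says {mat.shape[0]} rows"
        )
    if len(col_ids) != mat.shape[1]:
        raise FormatError(
            f"{cols_path}: {len(col_ids)} identifiers but matrix header says {mat.shape[1]} columns"
        )
    return mat, row_ids, col_ids


def _read_index(path: str | Path) -> list[str]:
    with open(path) as fh:
        return [line.rstrip("\n").split("\t")[0] for line in fh if line.strip()]


def write_counts_mtx(
    matrix: sp.spmatrix,
    row_ids: list[str],
    col_ids: list[str],
    matrix_path: str | Path,
    rows_path: str | Path,
    cols_path: str | Path,
) -> None:
    coo = sp.coo_matrix(matrix)
    if coo.shape[0] != len(row_ids) or coo.shape[1] != len(col_ids):
        raise ValueError("identifier lists do not match matrix dimensions")
    scipy.io.mmwrite(str(matrix_path), coo, field="integer")
    Path(rows_path).write_text("".join(f"{r}\n" for r in row_ids))
    Path(cols_path).write_text("".join(f"{c}\n" for c in col_ids))


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read GMT gene sets: ``name<TAB>description<TAB>gene...`` per line.

    Duplicate genes within a set are deduplicated (first occurrence order);
    empty sets and duplicate set names raise :class:`FormatError`.
    """
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}: line {lineno}: empty gene set '{fields[0]}'")
            name = fields[0]
            if name in sets:
                raise FormatError(f"{path}: line {lineno}: duplicate set name '{name}'")
            genes = list(dict.fromkeys(g for g in fields[2:] if g))
            if not genes:
                raise FormatError(f"{path}: line {lineno}: empty gene set '{name}'")
            sets[name] = genes
    return sets


def write_gmt(sets: dict[str, list[str]], path: str | Path, description: str = ".") -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, description, *genes]) + "\n")


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


# ---------------------------------------------------------------------------
# pipeline configuration


@dataclasses.dataclass
class PipelineConfig:
    """Thresholds and options shared across pipeline stages.

    Defaults mirror the analysis gates of the study design this package
    implements: FDR 0.05 with R^2 > 0.4 for aging-associated composition
    changes, AUC > 0.9 for sex-dimorphic chromatin states, promoters within
    +/-1 kb of the TSS, universal peaks at summit +/-250 bp, >=10 concordant
    cell types for shared DA peaks and >=5 per direction for opposite ones.
    """

    fdr_q: float = 0.05
    r2_min: float = 0.4
    auc_min: float = 0.9
    shared_celltype_min: int = 10
    opposite_celltype_min: int = 5
    promoter_halfwidth_bp: int = 1000
    summit_halfwidth_bp: int = 250
    linkage_window_bp: int = 250_000
    linkage_r_min: float = 0.3
    specificity_s_min: float = 0.5
    specificity_min_cpm: float = 1.0
    sex_specific_logfc_floor: float = 0.02
    knn_k: int = 25
    knn_folds: int = 5
    min_fragments: int = 100
    min_promoter_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.fdr_q < 1:
            raise ValueError("fdr_q must be in (0, 1)")
        if not 0 <= self.r2_min <= 1:
            raise ValueError("r2_min must be in [0, 1]")
        if not 0 <= self.auc_min <= 1:
            raise ValueError("auc_min must be in [0, 1]")
        for field in ("promoter_halfwidth_bp", "summit_halfwidth_bp", "linkage_window_bp"):
            if getattr(self, field) <= 0:
                raise ValueError(f"{field} must be positive")
        if self.shared_celltype_min < 1 or self.opposite_celltype_min < 1:
            raise ValueError("cell-type count thresholds must be >= 1")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def log_stage(log_path: str | Path, stage: str, seed: int, inputs: list[str | Path],
              params: dict | None = None) -> None:
    """Append one structured line per stage with input hashes, for auditable reruns."""
    record = {
        "stage": stage,
        "seed": seed,
        # keyed by file name so logs from identical runs in different
        # directories compare equal
        "inputs": {Path(p).name: file_sha256(p) for p in inputs if Path(p).exists()},
        "params": params or {},
    }
    with open(log_path, "a") as fh:
        fh.write(json.dumps(record, sort_keys=True) + "\n")
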