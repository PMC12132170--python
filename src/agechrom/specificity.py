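"""Entropy-based scoring of cell-type-specific cis-regulatory elements.

Each universal peak's pseudobulk accessibility across K cell types is depth
normalised (counts per million within each cell type), rescaled to a
probability vector per peak, and scored by Shannon entropy H (bits). The
specificity statistic S = 1 - H/log2(K) is 1 when accessibility is
concentrated in a single cell type and 0 when uniform; peaks with high S and
adequate signal in their top cell type are called cell-type-specific CREs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def celltype_profiles(
    pseudobulk: np.ndarray,
    cell_types: list[str],
    peak_ids: list[str],
) -> tuple[pd.DataFrame, pd.Series]:
    """CPM-normalise a cell_type x peak count matrix, then rescale per peak to the simplex.

    Returns (profiles: peaks x cell_types summing to 1 per row, all_zero flag).
    Peaks with no counts in any cell type are flagged and given NaN profiles.
    """
    mat = np.asarray(pseudobulk, dtype=float)
    if mat.ndim != 2 or mat.shape[0] != len(cell_types):
        raise ValueError("pseudobulk must be cell_types x peaks")
    if len(cell_types) < 2:
        raise ValueError("specificity requires at least 2 cell types")
    libsizes = mat.sum(axis=1, keepdims=True)
    if (libsizes == 0).any():
        raise ValueError("cell type with zero library size")
    cpm = mat / libsizes * 1e6
    totals = cpm.sum(axis=0)
    all_zero = pd.Series(totals == 0, index=peak_ids, name="all_zero")
    with np.errstate(invalid="ignore", divide="ignore"):
        probs = np.where(totals > 0, cpm / np.where(totals > 0, totals, 1.0), np.nan)
    profiles = pd.DataFrame(probs.T, index=peak_ids, columns=cell_types)
    return profiles, all_zero


def entropy_specificity(profiles: pd.DataFrame) -> pd.DataFrame:
    """Shannon entropy (bits) and specificity S = 1 - H/log2 K per peak.

    The entropy formula is isolated in :func:`shannon_entropy_bits` so an
    alternative divergence-based specificity can be substituted in one place.
    """
    p = profiles.to_numpy(float)
    if np.nanmin(p) < -1e-12:
        raise ValueError("negative probability in profile")
    row_sums = np.nansum(p, axis=1)
    finite = ~np.isnan(p).any(axis=1)
    if finite.any() and not np.allclose(row_sums[finite], 1.0, atol=1e-9):
        raise ValueError("profiles must sum to 1")
    K = profiles.shape[1]
    H = shannon_entropy_bits(p)
    S = 1.0 - H / np.log2(K)
    argmax = profiles.columns.to_numpy()[np.nanargmax(np.nan_to_num(p, nan=-1.0), axis=1)]
    out = pd.DataFrame(
        {
            "peak": profiles.index,
            "entropy_bits": H,
            "specificity": S,
            "argmax_cell_type": argmax,
            "K": K,
        }
    )
    out.loc[~finite, ["entropy_bits", "specificity"]] = np.nan
    out.loc[~finite, "argmax_cell_type"] = pd.NA
    return out


def shannon_entropy_bits(p: np.ndarray) -> np.ndarray:
    """Row-wise Shannon entropy in bits, with 0*log(0) := 0."""
    with np.errstate(invalid="ignore", divide="ignore"):
        terms = np.where(p > 0, p * np.log2(np.where(p > 0, p, 1.0)), 0.0)
    return -np.sum(terms, axis=1)


def select_specific_cres(
    scores: pd.DataFrame,
    profiles: pd.DataFrame,
    cpm: pd.DataFrame | None = None,
    s_min: float = 0.5,
    min_cpm: float = 1.0,
) -> dict[str, list[str]]:
    """Assign peaks with specificity >= s_min (closed threshold) to their argmax cell type.

    ``cpm`` (peaks x cell_types, counts-per-million) gates on signal in the
    argmax cell type; if omitted, only the specificity threshold applies.
    Each peak lands in at most one cell type's set.
    """
    if not 0 < s_min <= 1:
        raise ValueError("s_min must be in (0, 1]")
    sets: dict[str, list[str]] = {ct: [] for ct in profiles.columns}
    for _, row in scores.iterrows():
        if pd.isna(row["specificity"]) or row["specificity"] < s_min:
            continue
        ct = row["argmax_cell_type"]
        if cpm is not None and cpm.loc[row["peak"], ct] < min_cpm:
            continue
        sets[ct].append(row["peak"])
    return sets
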