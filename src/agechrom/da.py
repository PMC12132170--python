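"""Sex-stratified pseudobulk differential chromatin accessibility along age.

For each tissue x cell type and each sex separately, per-peak counts across
pseudobulk samples are modelled with a negative-binomial log-linear GLM,

    log E[count] = log(library size) + b0 + b1 * age_months,

with per-peak dispersion shrunk toward a trended mean-dispersion fit. The age
effect is tested by a likelihood-ratio test on b1 and reported as a log2 fold
change per month (b1 / ln 2), with Benjamini-Hochberg correction within each
tissue x cell type x sex stratum. Cross-sex comparison then splits peaks into
sex-shared and sex-specific sets, and a cross-cell-type summary flags peaks
consistently altered across >= 10 cell types (shared) or altered in opposite
directions in >= 5 cell types each way (opposite).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from . import _glm
from .composition import adjust_fdr

LN2 = float(np.log(2.0))


@dataclass
class AccessibilityAgingModel:
    """NB GLM of pseudobulk accessibility on age for one stratum.

    Parameters
    ----------
    counts : samples x peaks integer table (pseudobulk within one
        tissue x cell type x sex stratum).
    sample_meta : per-sample metadata with an ``age_months`` column (indexed by
        or containing a ``sample`` column matching ``counts.index``).
    dispersion : None to estimate with shrinkage, or a float/array to force
        (0 forces exact Poisson regression).
    min_total : peaks with fewer total counts in the stratum are excluded
        before testing and reported on the results object.
    normalization : "median-ratio" (DESeq-style size factors from peaks
        detected in every sample; robust when a minority of peaks carry
        signal) or "libsize" (raw per-sample totals). Median-ratio falls back
        to libsize when too few peaks are positive everywhere.
    library_sizes : known per-sample depths overriding both normalizations
        (e.g. when the sequencing depth is controlled externally).
    """

    counts: pd.DataFrame
    sample_meta: pd.DataFrame
    tissue: str = ""
    cell_type: str = ""
    sex_stratum: str = ""
    dispersion: float | np.ndarray | None = None
    min_total: int = 5
    normalization: str = "median-ratio"
    library_sizes: np.ndarray | pd.Series | None = None

    def __post_init__(self) -> None:
        meta = self.sample_meta
        if "sample" in meta.columns:
            meta = meta.set_index("sample")
        self._meta = meta.loc[self.counts.index]
        ages = self._meta["age_months"]
        if ages.nunique() < 2:
            raise ValueError("stratum has a single age; DA along age is undefined")
        if len(self.counts) < 4:
            raise ValueError("need >= 4 pseudobulk samples in the stratum")

    def fit(self) -> "DAResults":
        Y_all = self.counts.to_numpy(float)
        libsize = Y_all.sum(axis=1)
        if (libsize <= 0).any():
            raise ValueError("pseudobulk sample with zero library size")
        totals = Y_all.sum(axis=0)
        tested = totals >= self.min_total
        excluded = [p for p, t in zip(self.counts.columns, tested) if not t]
        Y = Y_all[:, tested]
        peaks = np.asarray(self.counts.columns)[tested]
        age = self._meta["age_months"].to_numpy(float)
        if self.library_sizes is not None:
            offset = np.log(np.asarray(self.library_sizes, dtype=float))
        else:
            offset = np.log(_effective_libsize(Y_all, libsize, self.normalization))
        X_full = np.column_stack([np.ones_like(age), age])
        X_null = np.ones((len(age), 1))
        if Y.shape[1] == 0:
            table = pd.DataFrame(
                columns=["peak", "tissue", "cell_type", "sex_stratum",
                         "logfc_per_month", "p", "q", "direction", "mean_cpm"]
            )
            return DAResults(table=table, excluded_peaks=excluded, dispersion=np.array([]))
        if self.dispersion is None:
            alpha = _glm.estimate_dispersion(Y, X_full, offset)["alpha"]
        else:
            alpha = np.broadcast_to(np.asarray(self.dispersion, float), (Y.shape[1],)).copy()
        beta_full, ll_full = _glm.irls_nb(Y, X_full, offset, alpha)
        _, ll_null = _glm.irls_nb(Y, X_null, offset, alpha)
        lrt = np.maximum(2.0 * (ll_full - ll_null), 0.0)
        p = scipy.stats.chi2.sf(lrt, df=1)
        q = adjust_fdr(p)
        logfc = beta_full[:, 1] / LN2
        mean_cpm = (Y / libsize[:, None] * 1e6).mean(axis=0)
        table = pd.DataFrame(
            {
                "peak": peaks,
                "tissue": self.tissue,
                "cell_type": self.cell_type,
                "sex_stratum": self.sex_stratum,
                "logfc_per_month": logfc,
                "p": p,
                "q": q,
                "direction": np.where(logfc > 0, "up", "down"),
                "mean_cpm": mean_cpm,
            }
        )
        return DAResults(table=table, excluded_peaks=excluded, dispersion=alpha,
                         beta=beta_full)


def _effective_libsize(Y: np.ndarray, libsize: np.ndarray, normalization: str) -> np.ndarray:
    """Median-of-ratios size factors x mean depth, or raw library sizes."""
    if normalization == "libsize":
        return libsize
    if normalization != "median-ratio":
        raise ValueError("normalization must be 'median-ratio' or 'libsize'")
    positive = (Y > 0).all(axis=0)
    if positive.sum() < 50:
        return libsize
    logs = np.log(Y[:, positive])
    log_geomean = logs.mean(axis=0)
    size = np.exp(np.median(logs - log_geomean[None, :], axis=1))
    return size / size.mean() * libsize.mean()


@dataclass
class DAResults:
    """Per-peak DA table for one stratum, plus fitting diagnostics."""

    table: pd.DataFrame
    excluded_peaks: list
    dispersion: np.ndarray
    beta: np.ndarray | None = None

    def significant(self, q_max: float = 0.05) -> pd.DataFrame:
        return self.table[self.table["q"] < q_max]

    def summary(self) -> str:
        n_sig = int((self.table["q"] < 0.05).sum())
        lines = [
            f"Differential accessibility: {self.table['tissue'].iloc[0] if len(self.table) else ''}"
            f" / {self.table['cell_type'].iloc[0] if len(self.table) else ''}"
            f" / sex {self.table['sex_stratum'].iloc[0] if len(self.table) else ''}",
            f"  peaks tested: {len(self.table)}  excluded (low counts): {len(self.excluded_peaks)}",
            f"  significant at q<0.05: {n_sig}",
            f"  median dispersion: {np.median(self.dispersion):.4g}" if len(self.dispersion) else "",
        ]
        return "\n".join(line for line in lines if line)


def fit_da(
    counts: pd.DataFrame,
    sample_meta: pd.DataFrame,
    sex_stratum: str,
    tissue: str = "",
    cell_type: str = "",
    dispersion: float | None = None,
    min_total: int = 5,
) -> DAResults:
    """Functional wrapper: restrict to one sex stratum and fit the NB age GLM."""
    meta = sample_meta.set_index("sample") if "sample" in sample_meta.columns else sample_meta
    in_stratum = meta.loc[counts.index, "sex"] == sex_stratum
    sub = counts[in_stratum.to_numpy()]
    model = AccessibilityAgingModel(
        counts=sub,
        sample_meta=meta,
        tissue=tissue,
        cell_type=cell_type,
        sex_stratum=sex_stratum,
        dispersion=dispersion,
        min_total=min_total,
    )
    return model.fit()


def cross_sex(
    da_f: pd.DataFrame,
    da_m: pd.DataFrame,
    q_max: float = 0.05,
    logfc_floor: float = 0.02,
) -> dict:
    """Split DA peaks into sex-shared and sex-specific sets for one cell type.

    Shared = significant in both sexes. Sex-specific = significant in one sex
    while the other sex's |log2FC per month| stays below ``logfc_floor`` (so a
    mere power difference is not called biology). Also reports the Spearman
    correlation of shared log fold changes and the fraction with concordant
    sign.
    """
    f = da_f.set_index("peak")
    m = da_m.set_index("peak")
    common = f.index.intersection(m.index)
    f, m = f.loc[common], m.loc[common]
    sig_f = f["q"] < q_max
    sig_m = m["q"] < q_max
    shared = common[sig_f & sig_m]
    f_only = common[sig_f & ~sig_m & (m["logfc_per_month"].abs() < logfc_floor)]
    m_only = common[sig_m & ~sig_f & (f["logfc_per_month"].abs() < logfc_floor)]
    if len(shared) >= 2:
        rho = scipy.stats.spearmanr(
            f.loc[shared, "logfc_per_month"], m.loc[shared, "logfc_per_month"]
        ).statistic
        concordant = float(
            (np.sign(f.loc[shared, "logfc_per_month"]) == np.sign(m.loc[shared, "logfc_per_month"])).mean()
        )
    else:
        rho = np.nan
        concordant = np.nan
    return {
        "shared": list(shared),
        "F_specific": list(f_only),
        "M_specific": list(m_only),
        "spearman_shared_logfc": float(rho) if rho == rho else np.nan,
        "concordant_share": concordant,
    }


def summarize_across_celltypes(
    da_all: pd.DataFrame,
    q_max: float = 0.05,
    shared_min: int = 10,
    opposite_min: int = 5,
) -> pd.DataFrame:
    """Count, per peak, the cell types where it is significantly up or down.

    Class rules: shared-up / shared-down when one direction reaches
    ``shared_min`` cell types and the other direction has none; opposite when
    both directions reach ``opposite_min``; otherwise other.
    """
    if da_all["cell_type"].nunique() < 2:
        raise ValueError("cross-cell-type summary needs >= 2 cell types")
    sig = da_all[da_all["q"] < q_max]
    up = (
        sig[sig["direction"] == "up"].groupby("peak")["cell_type"].nunique()
    )
    down = (
        sig[sig["direction"] == "down"].groupby("peak")["cell_type"].nunique()
    )
    tissues = sig.groupby("peak")["tissue"].nunique()
    peaks = sorted(set(up.index) | set(down.index))
    rows = []
    for peak in peaks:
        n_up = int(up.get(peak, 0))
        n_down = int(down.get(peak, 0))
        if n_up >= shared_min and n_down == 0:
            cls = "shared-up"
        elif n_down >= shared_min and n_up == 0:
            cls = "shared-down"
        elif n_up >= opposite_min and n_down >= opposite_min:
            cls = "opposite"
        else:
            cls = "other"
        rows.append(
            {
                "peak": peak,
                "n_celltypes_up": n_up,
                "n_celltypes_down": n_down,
                "n_tissues": int(tissues.get(peak, 0)),
                "class": cls,
            }
        )
    return pd.DataFrame(rows, columns=["peak", "n_celltypes_up", "n_celltypes_down", "n_tissues", "class"])


def age_group_tracks(
    counts: pd.DataFrame,
    sample_meta: pd.DataFrame,
    peaks: pd.DataFrame,
    selected: list[str],
    path_prefix: str,
) -> list[str]:
    """Write one BEDGRAPH per age group of mean CPM over selected peaks."""
    meta = sample_meta.set_index("sample") if "sample" in sample_meta.columns else sample_meta
    libsize = counts.sum(axis=1)
    cpm = counts.div(libsize, axis=0) * 1e6
    coords = peaks.set_index("name")[["chrom", "start", "end"]]
    written = []
    for age, samples in meta.groupby("age_months").groups.items():
        samples = [s for s in samples if s in cpm.index]
        if not samples:
            continue
        mean_cpm = cpm.loc[samples, selected].mean(axis=0)
        out = coords.loc[selected].assign(value=mean_cpm.to_numpy())
        path = f"{path_prefix}.age{int(age)}.bedgraph"
        out.to_csv(path, sep="\t", header=False, index=False, float_format="%.6g")
        written.append(path)
    return written
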