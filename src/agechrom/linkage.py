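"""Promoter-CRE linkage by co-accessibility, filtered for expression concordance.

Non-promoter DA peaks (candidate distal CREs) are paired with gene promoter
peaks when the CRE summit lies within a distance window of the gene's TSS
(+/-250 kb by default). Each pair's co-accessibility is the Pearson
correlation of log1p-CPM pseudobulk accessibility across samples within one
cell type, with a t-distribution p-value and BH correction across pairs.
Significant, well-correlated pairs whose CRE is a DA peak become linkages;
a linkage is concordant when the CRE, the promoter's DA direction, and the
gene's expression change all agree in sign.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.stats

from .composition import adjust_fdr


def candidate_pairs(
    annotated_peaks: pd.DataFrame,
    genes: pd.DataFrame,
    window_bp: int = 250_000,
    promoter_halfwidth_bp: int = 1000,
) -> tuple[pd.DataFrame, dict]:
    """Enumerate (gene, promoter_peak, cre_peak) candidates.

    A gene's promoter peak is any peak overlapping [tss - h, tss + h + 1);
    a candidate CRE is any non-promoter-labelled peak whose summit is within
    ``window_bp`` of the TSS. Genes with no promoter peak are skipped and
    counted in the report.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    if "context" not in annotated_peaks.columns:
        raise ValueError("peaks must carry context labels (run annotate_context first)")
    rows = []
    skipped = 0
    nonpromoter = annotated_peaks[annotated_peaks["context"] != "TSS-promoter"]
    for _, gene in genes.iterrows():
        tss = int(gene["tss"])
        chrom = gene["chrom"]
        on_chrom = annotated_peaks[annotated_peaks["chrom"] == chrom]
        prom = on_chrom[
            (on_chrom["start"] < tss + promoter_halfwidth_bp + 1)
            & (on_chrom["end"] > tss - promoter_halfwidth_bp)
        ]
        if prom.empty:
            skipped += 1
            continue
        cres = nonpromoter[
            (nonpromoter["chrom"] == chrom)
            & ((nonpromoter["summit"] - tss).abs() <= window_bp)
        ]
        for pname in prom["name"]:
            for cname, cdist in zip(cres["name"], (cres["summit"] - tss).abs()):
                rows.append((gene["gene"], pname, cname, int(cdist)))
    pairs = pd.DataFrame(rows, columns=["gene", "promoter_peak", "cre_peak", "distance_bp"])
    return pairs, {"genes_without_promoter_peak": skipped, "n_pairs": len(pairs)}


def coaccessibility(
    cpm: pd.DataFrame,
    pairs: pd.DataFrame,
    method: str = "pearson",
) -> pd.DataFrame:
    """Correlate log1p-CPM of each CRE/promoter pair across samples.

    ``cpm`` is samples x peaks within one cell type (>= 5 samples). Pairs with
    a zero-variance column are dropped with a reason column. p-values use the
    t transform t = r sqrt(n-2)/sqrt(1-r^2); BH across retained pairs.
    """
    if len(cpm) < 5:
        raise ValueError("co-accessibility needs >= 5 samples")
    log_cpm = np.log1p(cpm)
    n = len(log_cpm)
    records = []
    for _, row in pairs.iterrows():
        x = log_cpm[row["cre_peak"]].to_numpy(float)
        y = log_cpm[row["promoter_peak"]].to_numpy(float)
        if np.std(x) == 0 or np.std(y) == 0:
            records.append({**row, "r": np.nan, "p": np.nan, "dropped": "zero-variance"})
            continue
        if method == "pearson":
            r = float(scipy.stats.pearsonr(x, y).statistic)
        elif method == "spearman":
            r = float(scipy.stats.spearmanr(x, y).statistic)
        else:
            raise ValueError("method must be 'pearson' or 'spearman'")
        r_clip = min(max(r, -1 + 1e-15), 1 - 1e-15)
        t = r_clip * np.sqrt(n - 2) / np.sqrt(1 - r_clip**2)
        p = 2 * scipy.stats.t.sf(abs(t), df=n - 2)
        records.append({**row, "r": r, "p": p, "dropped": ""})
    out = pd.DataFrame(records)
    if out.empty:
        out = pd.DataFrame(columns=[*pairs.columns, "r", "p", "q", "dropped"])
        return out
    out["q"] = adjust_fdr(out["p"].to_numpy())
    return out


def concordant_linkages(
    pairs: pd.DataFrame,
    da_results: pd.DataFrame,
    expression: pd.DataFrame,
    sex_stratum: str,
    q_max: float = 0.05,
    r_min: float = 0.3,
) -> pd.DataFrame:
    """Filter co-accessible pairs to DA-supported linkages and mark concordance.

    Keeps pairs with co-accessibility q < q_max and r >= r_min whose CRE is a
    significant DA peak in the stratum. Directions come from the DA table
    (CRE and promoter peaks) and from ``expression`` (columns gene, cell_type
    optional, sex, direction, q); genes absent from the expression table are
    retained with expression_direction "unknown" and concordant False.
    """
    da = da_results[da_results["sex_stratum"] == sex_stratum]
    # a peak may be tested in several tissues of one cell type: keep its most
    # significant record for direction lookup
    da = da.sort_values("q", kind="mergesort").drop_duplicates("peak").set_index("peak")
    sig_da = da[da["q"] < q_max]
    expr = expression[expression["sex"] == sex_stratum].set_index("gene")
    rows = []
    for _, row in pairs.iterrows():
        if row.get("dropped"):
            continue
        if not (pd.notna(row["q"]) and row["q"] < q_max and row["r"] >= r_min):
            continue
        if row["cre_peak"] not in sig_da.index:
            continue
        cre_dir = sig_da.loc[row["cre_peak"], "direction"]
        prom_dir = (
            da.loc[row["promoter_peak"], "direction"]
            if row["promoter_peak"] in da.index
            else "unknown"
        )
        if row["gene"] in expr.index:
            erow = expr.loc[row["gene"]]
            expr_dir = erow["direction"] if erow.get("q", 0) < q_max else "ns"
        else:
            expr_dir = "unknown"
        concordant = cre_dir == prom_dir == expr_dir and cre_dir in ("up", "down")
        rows.append(
            {
                "gene": row["gene"],
                "promoter_peak": row["promoter_peak"],
                "cre_peak": row["cre_peak"],
                "distance_bp": row["distance_bp"],
                "r": row["r"],
                "p": row["p"],
                "q": row["q"],
                "cre_direction": cre_dir,
                "promoter_direction": prom_dir,
                "expression_direction": expr_dir,
                "concordant": concordant,
                "sex_stratum": sex_stratum,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene", "promoter_peak", "cre_peak", "distance_bp", "r", "p", "q",
            "cre_direction", "promoter_direction", "expression_direction",
            "concordant", "sex_stratum",
        ],
    )


def linkage_summaries(linkages: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Per-gene CRE counts and per-stratum linkage counts."""
    per_gene = (
        linkages.groupby("gene")
        .agg(n_cres=("cre_peak", "nunique"), n_concordant=("concordant", "sum"))
        .reset_index()
    )
    per_stratum = (
        linkages.groupby("sex_stratum")
        .agg(n_linkages=("cre_peak", "size"), n_concordant=("concordant", "sum"))
        .reset_index()
    )
    return {"per_gene": per_gene, "per_stratum": per_stratum}
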