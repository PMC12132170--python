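"""Upstream-regulator inference: motif enrichment, motif deviation z-scores,
and cytokine-signature enrichment with secretion/receptor support.

Motif enrichment compares a DA peak set against a background matched on GC
content and mean accessibility (stratified decile sampling), with
hypergeometric upper-tail p-values. Motif deviation scores follow the
bias-corrected deviation statistic used for single-cell motif activity: the
observed motif-associated count per group minus its depth-scaled expectation,
normalised against the same statistic computed over B matched background peak
sets. Cytokine-signature enrichment is a hypergeometric overlap test of the
aging-associated gene set against each cytokine's response signature, and a
signature is "supported" when a secretion or receptor gene of that cytokine
also carries a significant aging-up promoter peak.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.stats

from .composition import adjust_fdr


def select_background(
    query_peaks: list[str],
    universe: pd.DataFrame,
    n_bins_gc: int = 10,
    n_bins_access: int = 10,
    multiplier: int = 2,
    seed: int = 0,
) -> tuple[list[str], dict]:
    """Sample non-query peaks matching the query's joint (GC, accessibility) histogram.

    ``universe`` must be indexed by peak name with columns ``gc`` and
    ``mean_access``. Bins are universe-wide quantile deciles; within each joint
    bin, multiplier x (query count) peaks are drawn without replacement from
    the non-query pool (shortfalls reported per bin).
    """
    query = set(query_peaks)
    unknown = query - set(universe.index)
    if unknown:
        raise ValueError(f"query peaks outside universe: {sorted(unknown)[:5]}")
    pool = universe.drop(index=list(query))
    if len(pool) == 0:
        raise ValueError("no non-query peaks available for background selection")
    if multiplier * len(query) > len(pool):
        raise ValueError("universe smaller than requested background")
    gc_bins = np.unique(np.quantile(universe["gc"], np.linspace(0, 1, n_bins_gc + 1)))
    ac_bins = np.unique(np.quantile(universe["mean_access"], np.linspace(0, 1, n_bins_access + 1)))

    def bin_of(df):
        g = np.clip(np.searchsorted(gc_bins, df["gc"], side="right") - 1, 0, len(gc_bins) - 2)
        a = np.clip(np.searchsorted(ac_bins, df["mean_access"], side="right") - 1, 0, len(ac_bins) - 2)
        return g * (len(ac_bins) - 1) + a

    q_bins = bin_of(universe.loc[list(query)])
    pool_bins = bin_of(pool)
    rng = np.random.default_rng(seed)
    chosen: list[str] = []
    shortfall: dict[int, int] = {}
    for b, want in pd.Series(q_bins).value_counts().sort_index().items():
        want *= multiplier
        avail = pool.index[pool_bins == b]
        take = min(want, len(avail))
        if take < want:
            shortfall[int(b)] = int(want - take)
        chosen.extend(sorted(rng.choice(avail, take, replace=False)))
    # top up shortfalls from the leftover pool so size = multiplier * |query|
    deficit = multiplier * len(query) - len(chosen)
    if deficit > 0:
        leftover = pool.index.difference(chosen)
        chosen.extend(sorted(rng.choice(leftover, min(deficit, len(leftover)), replace=False)))
    return chosen, {"shortfall_per_bin": shortfall, "n_background": len(chosen)}


def hypergeom_upper_tail(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeom(N population, K successes, n draws)."""
    return float(scipy.stats.hypergeom.sf(k - 1, N, K, n))


def motif_enrichment(
    query_peaks: list[str],
    background_peaks: list[str],
    motif_annotation: pd.DataFrame,
) -> pd.DataFrame:
    """Hypergeometric motif over-representation of query vs pooled query+background.

    ``motif_annotation`` is a binary peaks x motifs frame covering the pooled
    set. Reports fold = (k/n)/(K/N), the motif frequency difference in
    percentage points, the upper-tail p, and BH q across motifs. Motifs absent
    from the pool get p = 1 and NaN fold with a flag.
    """
    pool = list(query_peaks) + list(background_peaks)
    missing = set(pool) - set(motif_annotation.index)
    if missing:
        raise ValueError(f"peaks missing from motif annotation: {sorted(missing)[:5]}")
    ann = motif_annotation.loc[pool].to_numpy(bool)
    in_query = np.zeros(len(pool), dtype=bool)
    in_query[: len(query_peaks)] = True
    N = len(pool)
    n = len(query_peaks)
    rows = []
    for j, motif in enumerate(motif_annotation.columns):
        K = int(ann[:, j].sum())
        k = int(ann[in_query, j].sum())
        if K == 0:
            rows.append({"set_id": motif, "k": 0, "n": n, "K": 0, "N": N,
                         "fold": np.nan, "freq_diff_pct": 0.0, "p": 1.0,
                         "empty_annotation": True})
            continue
        fold = (k / n) / (K / N)
        freq_bg = (K - k) / max(N - n, 1)
        rows.append(
            {
                "set_id": motif,
                "k": k,
                "n": n,
                "K": K,
                "N": N,
                "fold": fold,
                "freq_diff_pct": 100.0 * (k / n - freq_bg),
                "p": hypergeom_upper_tail(k, N, K, n),
                "empty_annotation": False,
            }
        )
    out = pd.DataFrame(rows)
    out["q"] = adjust_fdr(out["p"].to_numpy())
    return out


def motif_deviations(
    pseudobulk: pd.DataFrame,
    motif_annotation: pd.DataFrame,
    universe: pd.DataFrame,
    B: int = 50,
    seed: int = 0,
) -> dict[str, pd.DataFrame]:
    """Bias-corrected motif deviation z-scores per pseudobulk group.

    For motif m and group g with depth d_g, the expected motif count is
    d_g * sum over motif peaks of the global mean fraction of reads in that
    peak; raw deviation = (observed - expected) / expected. The z-score
    standardises raw deviations against B background motifs whose peaks are
    GC/accessibility-matched draws (via :func:`select_background`). A motif
    annotating every peak has expected == observed identically, hence
    deviation 0 in every group.
    """
    if B < 10:
        raise ValueError("B must be >= 10")
    counts = pseudobulk.to_numpy(float)
    if (counts < 0).any():
        raise ValueError("counts must be nonnegative")
    depth = counts.sum(axis=1)
    peak_fraction = counts.sum(axis=0) / counts.sum()
    peak_index = {p: i for i, p in enumerate(pseudobulk.columns)}
    rng = np.random.default_rng(seed)

    def raw_dev(peak_names: list[str]) -> np.ndarray:
        idx = [peak_index[p] for p in peak_names]
        observed = counts[:, idx].sum(axis=1)
        expected = depth * peak_fraction[idx].sum()
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(expected > 0, (observed - expected) / expected, 0.0)

    raw = {}
    z = {}
    for motif in motif_annotation.columns:
        motif_peaks = list(motif_annotation.index[motif_annotation[motif].astype(bool)])
        if not motif_peaks:
            raw[motif] = np.zeros(len(pseudobulk))
            z[motif] = np.zeros(len(pseudobulk))
            continue
        dev = raw_dev(motif_peaks)
        raw[motif] = dev
        if len(motif_peaks) == len(pseudobulk.columns):
            z[motif] = np.zeros(len(pseudobulk))
            continue
        bg_devs = np.empty((B, len(pseudobulk)))
        for b in range(B):
            bg, _ = select_background(
                motif_peaks, universe, multiplier=1, seed=int(rng.integers(2**31 - 1))
            )
            bg_devs[b] = raw_dev(bg)
        sd = bg_devs.std(axis=0, ddof=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            z[motif] = np.where(sd > 0, (dev - bg_devs.mean(axis=0)) / sd, 0.0)
    idx = pseudobulk.index
    return {
        "raw": pd.DataFrame(raw, index=idx),
        "z": pd.DataFrame(z, index=idx),
    }


def cytokine_enrichment(
    aging_genes: set[str],
    signatures: dict[str, list[str]],
    gene_universe: set[str],
) -> pd.DataFrame:
    """Hypergeometric overlap of the aging gene set with each cytokine signature.

    Genes outside the universe are trimmed (with a warning) before testing;
    an empty aging set yields p = 1 everywhere. BH across cytokines.
    """
    import warnings

    universe = set(gene_universe)
    aging = set(aging_genes) & universe
    if aging != set(aging_genes):
        warnings.warn("aging genes outside the universe were trimmed")
    N = len(universe)
    n = len(aging)
    rows = []
    for name, genes in signatures.items():
        sig = set(genes) & universe
        if sig != set(genes):
            warnings.warn(f"signature {name}: genes outside the universe were trimmed")
        K = len(sig)
        k = len(sig & aging)
        p = 1.0 if n == 0 or K == 0 else hypergeom_upper_tail(k, N, K, n)
        fold = np.nan if n == 0 or K == 0 else (k / n) / (K / N)
        rows.append({"set_id": name, "k": k, "n": n, "K": K, "N": N, "fold": fold, "p": p})
    out = pd.DataFrame(rows)
    out["q"] = adjust_fdr(out["p"].to_numpy())
    return out


def signature_support(
    enrichment: pd.DataFrame,
    promoter_da_up_genes: set[str],
    cytokine_gene_map: pd.DataFrame,
    q_max: float = 0.05,
) -> pd.DataFrame:
    """Flag enriched cytokine signatures supported by secretion/receptor evidence.

    ``cytokine_gene_map`` has columns cytokine, gene, role in
    {secretion, receptor}. A cytokine is supported iff it is enriched
    (q < q_max) and at least one mapped secretion or receptor gene has a
    significant aging-up promoter DA peak (``promoter_da_up_genes``).
    """
    mapped = cytokine_gene_map.groupby("cytokine")
    rows = []
    for _, row in enrichment.iterrows():
        name = row["set_id"]
        enriched = pd.notna(row["q"]) and row["q"] < q_max
        if name not in mapped.groups:
            rows.append({"cytokine": name, "enriched": enriched, "supported": False,
                         "evidence": "no mapping"})
            continue
        genes = mapped.get_group(name)
        hits = genes[genes["gene"].isin(promoter_da_up_genes)]
        supported = enriched and not hits.empty
        evidence = ";".join(f"{r.role}:{r.gene}" for r in hits.itertuples()) if supported else (
            "" if enriched else "not enriched")
        rows.append({"cytokine": name, "enriched": enriched, "supported": supported,
                     "evidence": evidence})
    return pd.DataFrame(rows)


def aggregate_signature_score(
    values: pd.DataFrame,
    shared_genes: list[str],
) -> pd.Series:
    """Mean across a gene set of per-gene z-scores (standardised across conditions).

    ``values`` is conditions x genes (expression or CPM). Genes with zero
    variance across conditions contribute a z of 0.
    """
    genes = list(dict.fromkeys(shared_genes))
    if not genes:
        raise ValueError("empty gene set")
    missing = set(genes) - set(values.columns)
    if missing:
        raise ValueError(f"genes missing from table: {sorted(missing)[:5]}")
    sub = values[genes].to_numpy(float)
    mu = sub.mean(axis=0)
    sd = sub.std(axis=0, ddof=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        zs = np.where(sd > 0, (sub - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    return pd.Series(zs.mean(axis=1), index=values.index, name="aggregate_score")
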