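"""Universal peak set construction, genomic-context annotation, cell QC and pseudobulk.

Per-group peak summits (one set per cell type x tissue) are extended to
fixed-width peaks (summit +/-250 bp by default) and merged into a single
non-overlapping universal set by score-ranked greedy selection: pool every
group's peaks, sort by score descending, and accept a peak only if it overlaps
no previously accepted peak. This reproduces the iterative-overlap merging used
to build fixed-width universal peak sets from heterogeneous cell-type peak
calls. Context labels (TSS-promoter > exon > intron > intergenic, decided at
the summit) then stratify the universe, and counts are aggregated to
pseudobulk groups for replicate-level statistics.
"""

from __future__ import annotations

import bisect
import logging
import warnings

import numpy as np
import pandas as pd
import scipy.sparse as sp
from intervaltree import IntervalTree

logger = logging.getLogger("agechrom")

CONTEXT_LABELS = ["TSS-promoter", "exon", "intron", "intergenic"]


def extend_summits(
    summits: pd.DataFrame,
    halfwidth_bp: int,
    chrom_sizes: dict[str, int],
) -> pd.DataFrame:
    """Extend summit positions to fixed-width peaks [summit-h, summit+h+1).

    Peaks clipped at chromosome edges are flagged in a ``clipped`` column.
    Summits outside their chromosome raise ``ValueError``.
    """
    if halfwidth_bp <= 0:
        raise ValueError("halfwidth_bp must be positive")
    chroms = summits["chrom"].to_numpy()
    pos = summits["start"].to_numpy()
    unknown = set(chroms) - set(chrom_sizes)
    if unknown:
        raise ValueError(f"summits on unknown chromosomes: {sorted(unknown)}")
    sizes = np.array([chrom_sizes[c] for c in chroms])
    if (pos < 0).any() or (pos >= sizes).any():
        bad = summits.index[(pos < 0) | (pos >= sizes)][0]
        raise ValueError(f"summit at index {bad} lies outside its chromosome")
    start = pos - halfwidth_bp
    end = pos + halfwidth_bp + 1
    clipped = (start < 0) | (end > sizes)
    out = pd.DataFrame(
        {
            "chrom": chroms,
            "start": np.maximum(start, 0),
            "end": np.minimum(end, sizes),
            "summit": pos,
            "score": summits["score"].to_numpy(float)
            if "score" in summits
            else np.zeros(len(summits)),
            "clipped": clipped,
        }
    )
    if "source_group" in summits.columns:
        out["source_group"] = summits["source_group"].to_numpy()
    return out


def iterative_merge(peaksets: list[pd.DataFrame]) -> pd.DataFrame:
    """Merge per-group fixed-width peak sets into a non-overlapping universal set.

    Greedy by (score desc, chrom asc, start asc): a pooled peak is retained iff
    it overlaps no higher-ranked retained peak. The result is invariant to the
    order of the input peak sets and of rows within them.
    """
    pool = pd.concat(peaksets, ignore_index=True)
    if pool.empty:
        return pool
    pool = pool.sort_values(
        ["score", "chrom", "start"], ascending=[False, True, True], kind="mergesort"
    ).reset_index(drop=True)
    accepted_by_chrom: dict[str, tuple[list[int], list[int]]] = {}
    keep = np.zeros(len(pool), dtype=bool)
    chroms = pool["chrom"].to_numpy()
    starts = pool["start"].to_numpy()
    ends = pool["end"].to_numpy()
    for i in range(len(pool)):
        starts_acc, ends_acc = accepted_by_chrom.setdefault(chroms[i], ([], []))
        j = bisect.bisect_right(starts_acc, starts[i])
        # overlap possible only with the accepted neighbour on either side
        if j > 0 and ends_acc[j - 1] > starts[i]:
            continue
        if j < len(starts_acc) and starts_acc[j] < ends[i]:
            continue
        starts_acc.insert(j, starts[i])
        ends_acc.insert(j, ends[i])
        keep[i] = True
    out = pool[keep].sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
    out["name"] = out["chrom"] + ":" + out["start"].astype(str) + "-" + out["end"].astype(str)
    return out


class GeneAnnotation:
    """Minimal gene model: per-gene TSS with strand plus exon intervals.

    Expected columns: gene, chrom, strand (+/-), tss, exon_starts, exon_ends
    (comma-separated 0-based half-open coordinates).
    """

    def __init__(self, genes: pd.DataFrame):
        self.genes = genes.reset_index(drop=True)
        self._tss_by_chrom: dict[str, np.ndarray] = {}
        self._exons: dict[str, IntervalTree] = {}
        self._bodies: dict[str, IntervalTree] = {}
        for chrom, grp in self.genes.groupby("chrom"):
            self._tss_by_chrom[chrom] = np.sort(grp["tss"].to_numpy(int))
            exon_tree = IntervalTree()
            body_tree = IntervalTree()
            for _, row in grp.iterrows():
                ex_starts = _split_ints(row["exon_starts"])
                ex_ends = _split_ints(row["exon_ends"])
                for s, e in zip(ex_starts, ex_ends):
                    if e > s:
                        exon_tree.addi(s, e, row["gene"])
                if ex_starts:
                    body_tree.addi(min(ex_starts), max(ex_ends), row["gene"])
            self._exons[chrom] = exon_tree
            self._bodies[chrom] = body_tree

    def nearest_tss_distance(self, chrom: str, pos: int) -> int:
        tss = self._tss_by_chrom.get(chrom)
        if tss is None or len(tss) == 0:
            return np.iinfo(np.int64).max
        i = np.searchsorted(tss, pos)
        cands = []
        if i > 0:
            cands.append(abs(pos - tss[i - 1]))
        if i < len(tss):
            cands.append(abs(pos - tss[i]))
        return int(min(cands))

    def in_exon(self, chrom: str, pos: int) -> bool:
        tree = self._exons.get(chrom)
        return bool(tree is not None and tree.overlap(pos, pos + 1))

    def in_gene_body(self, chrom: str, pos: int) -> bool:
        tree = self._bodies.get(chrom)
        return bool(tree is not None and tree.overlap(pos, pos + 1))


def _split_ints(v) -> list[int]:
    if isinstance(v, (list, tuple)):
        return [int(x) for x in v]
    if pd.isna(v) or v == "":
        return []
    return [int(x) for x in str(v).rstrip(",").split(",")]


def annotate_context(
    peaks: pd.DataFrame,
    annotation: GeneAnnotation | pd.DataFrame,
    promoter_halfwidth_bp: int = 1000,
) -> pd.DataFrame:
    """Assign each peak one genomic-context label, decided by its summit.

    Precedence: TSS-promoter (summit within +/-promoter_halfwidth of a TSS)
    > exon > intron (inside a gene body but not an exon) > intergenic.
    Peaks on chromosomes absent from the annotation become intergenic with a
    warning.
    """
    if isinstance(annotation, pd.DataFrame):
        annotation = GeneAnnotation(annotation)
    labels = []
    missing_chroms = set()
    for chrom, summit in zip(peaks["chrom"], peaks["summit"]):
        if chrom not in annotation._tss_by_chrom:
            missing_chroms.add(chrom)
            labels.append("intergenic")
            continue
        if annotation.nearest_tss_distance(chrom, int(summit)) <= promoter_halfwidth_bp:
            labels.append("TSS-promoter")
        elif annotation.in_exon(chrom, int(summit)):
            labels.append("exon")
        elif annotation.in_gene_body(chrom, int(summit)):
            labels.append("intron")
        else:
            labels.append("intergenic")
    if missing_chroms:
        warnings.warn(
            f"peak chromosomes absent from annotation, labelled intergenic: {sorted(missing_chroms)}"
        )
    out = peaks.copy()
    out["context"] = pd.Categorical(labels, categories=CONTEXT_LABELS)
    return out


def context_summary(annotated: pd.DataFrame) -> pd.DataFrame:
    counts = annotated["context"].value_counts().reindex(CONTEXT_LABELS, fill_value=0)
    return pd.DataFrame(
        {"context": counts.index, "n": counts.to_numpy(), "fraction": counts.to_numpy() / max(len(annotated), 1)}
    )


def compute_cell_qc(
    counts: sp.spmatrix,
    cell_ids: list[str],
    peak_ids: list[str],
    promoter_peaks: set[str],
) -> pd.DataFrame:
    """Per-cell totals and promoter fraction (promoter counts / total counts).

    Zero-count cells get promoter_fraction 0 and ``zero_counts=True``.
    """
    unknown = promoter_peaks - set(peak_ids)
    if unknown:
        raise ValueError(f"promoter peaks not in matrix columns: {sorted(unknown)[:5]} ...")
    csr = sp.csr_matrix(counts)
    total = np.asarray(csr.sum(axis=1)).ravel()
    promoter_mask = np.array([p in promoter_peaks for p in peak_ids])
    promoter_counts = np.asarray(csr[:, promoter_mask].sum(axis=1)).ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(total > 0, promoter_counts / np.maximum(total, 1), 0.0)
    return pd.DataFrame(
        {
            "cell_id": cell_ids,
            "n_fragments": total.astype(int),
            "promoter_fraction": frac,
            "zero_counts": total == 0,
        }
    )


def filter_cells(
    qc: pd.DataFrame,
    min_fragments: int = 100,
    min_promoter_fraction: float = 0.0,
) -> tuple[list[str], dict[str, int]]:
    """Keep cells meeting both thresholds; report removals per criterion."""
    if min_fragments < 0 or min_promoter_fraction < 0:
        raise ValueError("thresholds must be >= 0")
    low_frag = qc["n_fragments"] < min_fragments
    low_prom = qc["promoter_fraction"] < min_promoter_fraction
    kept = qc.loc[~(low_frag | low_prom), "cell_id"].tolist()
    report = {
        "n_input": len(qc),
        "removed_low_fragments": int(low_frag.sum()),
        "removed_low_promoter_fraction": int(low_prom.sum()),
        "n_kept": len(kept),
    }
    if not kept:
        warnings.warn("cell filtering removed every cell")
    return kept, report


def aggregate_pseudobulk(
    counts: sp.spmatrix,
    cell_ids: list[str],
    cell_groups: pd.Series | dict[str, str],
) -> tuple[sp.csr_matrix, list[str], pd.Series]:
    """Sum cell x peak counts into group x peak pseudobulk counts.

    ``cell_groups`` maps cell_id -> group label (e.g. "sample|cell_type").
    Cells with missing labels raise ``ValueError`` listing them. Returns the
    pseudobulk matrix, its group order (sorted), and per-group library sizes.
    """
    groups = pd.Series(cell_groups) if isinstance(cell_groups, dict) else cell_groups
    missing = [c for c in cell_ids if c not in groups.index or pd.isna(groups.get(c))]
    if missing:
        raise ValueError(f"cells without group labels: {missing[:5]}" + (" ..." if len(missing) > 5 else ""))
    labels = groups.loc[cell_ids].to_numpy()
    group_order = sorted(set(labels))
    group_idx = {g: i for i, g in enumerate(group_order)}
    rows = np.array([group_idx[g] for g in labels])
    indicator = sp.csr_matrix(
        (np.ones(len(cell_ids)), (rows, np.arange(len(cell_ids)))),
        shape=(len(group_order), len(cell_ids)),
    )
    pseudo = sp.csr_matrix(indicator @ sp.csr_matrix(counts))
    libsizes = pd.Series(np.asarray(pseudo.sum(axis=1)).ravel(), index=group_order, name="library_size")
    return pseudo, group_order, libsizes
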