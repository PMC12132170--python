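"""Stage orchestration: each stage reads fixture/upstream artifacts from a run
directory and writes TSV/BED/JSON outputs under ``<dir>/outputs``, logging one
structured line per stage so reruns are auditable. Rerunning with the same
inputs and seed is byte-identical.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from . import composition as comp
from . import da as damod
from . import io as ageio
from . import linkage as linkmod
from . import peaks as peakmod
from . import regulators as regmod
from . import simulate as sim
from .io import PipelineConfig

STAGES = ["peaks", "specificity", "composition", "sexauc", "da", "linkage", "regulators"]


class MissingArtifactError(FileNotFoundError):
    pass


def _require(path: Path, produced_by: str) -> Path:
    if not path.exists():
        raise MissingArtifactError(
            f"missing artifact {path}; run the '{produced_by}' stage first"
        )
    return path


def _outdir(run_dir: Path) -> Path:
    out = run_dir / "outputs"
    out.mkdir(exist_ok=True)
    return out


def run_pipeline(run_dir: str | Path, config: PipelineConfig | None = None,
                 stages: list[str] | None = None) -> None:
    run_dir = Path(run_dir)
    config = config or PipelineConfig()
    stages = stages or STAGES
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}; choose from {STAGES}")
    log = _outdir(run_dir) / "run_log.jsonl"
    if stages == STAGES and log.exists():
        log.unlink()
    for stage in STAGES:
        if stage in stages:
            globals()[f"stage_{stage}"](run_dir, config)


# ---------------------------------------------------------------------------


def stage_peaks(run_dir: Path, config: PipelineConfig) -> None:
    run_dir = Path(run_dir)
    out = _outdir(run_dir)
    chrom_sizes = {}
    with open(_require(run_dir / "chrom.sizes", "simulate")) as fh:
        for line in fh:
            c, L = line.split()
            chrom_sizes[c] = int(L)
    genes = ageio.read_tsv(_require(run_dir / "genes.tsv", "simulate"))
    summit_files = sorted((run_dir / "summits").glob("*.bed"))
    if not summit_files:
        raise MissingArtifactError("no summit BED files; run the 'simulate' stage first")
    extended = []
    for f in summit_files:
        summits = ageio.read_bed(f)
        summits["source_group"] = f.stem
        extended.append(peakmod.extend_summits(summits, config.summit_halfwidth_bp, chrom_sizes))
    universal = peakmod.iterative_merge(extended)
    universal = peakmod.annotate_context(universal, genes, config.promoter_halfwidth_bp)
    bed = universal.rename(columns={})[["chrom", "start", "end", "name", "score"]].copy()
    bed["strand"] = "."
    ageio.write_bed(bed, out / "universal_peaks.bed")
    ageio.write_tsv(
        universal[["name", "chrom", "start", "end", "summit", "score", "context"]],
        out / "peak_context.tsv",
    )
    ageio.write_tsv(peakmod.context_summary(universal), out / "context_summary.tsv")

    counts, cell_ids, peak_ids = ageio.read_counts_mtx(
        _require(run_dir / "counts.mtx", "simulate"),
        run_dir / "counts.rows.tsv",
        run_dir / "counts.cols.tsv",
    )
    promoter_peaks = set(universal.loc[universal["context"] == "TSS-promoter", "name"]) & set(peak_ids)
    qc = peakmod.compute_cell_qc(counts, cell_ids, peak_ids, promoter_peaks)
    kept, report = peakmod.filter_cells(qc, config.min_fragments, config.min_promoter_fraction)
    ageio.write_tsv(qc, out / "cell_qc.tsv")
    Path(out / "cell_filter_report.json").write_text(json.dumps(report, sort_keys=True, indent=1))
    cell_meta = ageio.read_tsv(run_dir / "cell_metadata.tsv")
    kept_set = set(kept)
    cell_meta_kept = cell_meta[cell_meta["cell_id"].isin(kept_set)]
    ageio.write_tsv(cell_meta_kept, out / "cell_metadata.filtered.tsv")
    keep_idx = [i for i, c in enumerate(cell_ids) if c in kept_set]
    counts_kept = sp.csr_matrix(counts)[keep_idx]
    kept_ids = [cell_ids[i] for i in keep_idx]
    groups = (
        cell_meta_kept.set_index("cell_id")["sample"]
        + "|"
        + cell_meta_kept.set_index("cell_id")["cell_type"]
    )
    pseudo, group_order, libsizes = peakmod.aggregate_pseudobulk(counts_kept, kept_ids, groups)
    ageio.write_counts_mtx(
        pseudo, group_order, peak_ids,
        out / "pseudobulk.mtx", out / "pseudobulk.rows.tsv", out / "pseudobulk.cols.tsv",
    )
    ageio.log_stage(out / "run_log.jsonl", "peaks", config.seed,
                    [run_dir / "counts.mtx"], {"n_universal": len(universal), **report})


def _load_pseudobulk(out: Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    mat, rows, cols = ageio.read_counts_mtx(
        _require(out / "pseudobulk.mtx", "peaks"),
        out / "pseudobulk.rows.tsv",
        out / "pseudobulk.cols.tsv",
    )
    df = pd.DataFrame(mat.toarray(), index=rows, columns=cols)
    parts = pd.DataFrame(
        [r.split("|") for r in rows], columns=["sample", "cell_type"], index=rows
    )
    return df, parts


def stage_specificity(run_dir: Path, config: PipelineConfig) -> None:
    run_dir = Path(run_dir)
    out = _outdir(run_dir)
    from . import specificity as specmod

    pseudo, parts = _load_pseudobulk(out)
    by_ct = pseudo.groupby(parts["cell_type"]).sum()
    profiles, all_zero = specmod.celltype_profiles(
        by_ct.to_numpy(), list(by_ct.index), list(by_ct.columns)
    )
    scores = specmod.entropy_specificity(profiles)
    cpm = pd.DataFrame(
        (by_ct.to_numpy() / by_ct.sum(axis=1).to_numpy()[:, None] * 1e6).T,
        index=by_ct.columns, columns=by_ct.index,
    )
    sets = specmod.select_specific_cres(
        scores, profiles, cpm, config.specificity_s_min, config.specificity_min_cpm
    )
    ageio.write_tsv(scores, out / "specificity.tsv")
    context = ageio.read_tsv(_require(out / "peak_context.tsv", "peaks")).set_index("name")
    cre_dir = out / "specific_cres"
    cre_dir.mkdir(exist_ok=True)
    for ct, peaks_list in sets.items():
        if not peaks_list:
            continue
        bed = context.loc[peaks_list].reset_index()[["chrom", "start", "end", "name", "score"]]
        ageio.write_bed(bed, cre_dir / f"{ct}.bed")
    ageio.log_stage(out / "run_log.jsonl", "specificity", config.seed,
                    [out / "pseudobulk.mtx"], {"n_specific": sum(len(v) for v in sets.values())})


def stage_composition(run_dir: Path, config: PipelineConfig) -> None:
    run_dir = Path(run_dir)
    out = _outdir(run_dir)
    cell_meta = ageio.read_tsv(_require(out / "cell_metadata.filtered.tsv", "peaks"))
    sample_meta = ageio.read_tsv(_require(run_dir / "sample_metadata.tsv", "simulate"))
    tables = comp.compute_fractions(cell_meta, level="main")
    all_fits = []
    frac_rows = []
    for tissue, fractions in tables.items():
        model = comp.CompositionAgeModel(fractions=fractions, design=sample_meta, tissue=tissue)
        res = model.fit()
        res.classify(q_max=config.fdr_q, r2_min=config.r2_min)
        all_fits.append(res.table)
        long = fractions.reset_index().melt(id_vars="sample", var_name="cell_type", value_name="fraction")
        long.insert(0, "tissue", tissue)
        frac_rows.append(long)
    fits = pd.concat(all_fits, ignore_index=True)
    # one BH family across all tissue x cell-type tests of this analysis level
    fits["q_age"] = comp.adjust_fdr(fits["p_age"].to_numpy())
    fits["q_int"] = comp.adjust_fdr(fits["p_int"].to_numpy())
    fits = comp.classify_dynamics(fits, q_max=config.fdr_q, r2_min=config.r2_min)
    ageio.write_tsv(fits, out / "composition_fits.tsv")
    ageio.write_tsv(pd.concat(frac_rows, ignore_index=True), out / "fractions.tsv")
    ageio.log_stage(out / "run_log.jsonl", "composition", config.seed,
                    [out / "cell_metadata.filtered.tsv"],
                    {"n_significant": int((fits["category"] != "ns").sum())})


def stage_sexauc(run_dir: Path, config: PipelineConfig) -> None:
    run_dir = Path(run_dir)
    out = _outdir(run_dir)
    cell_meta = ageio.read_tsv(_require(run_dir / "cell_metadata.tsv", "simulate"))
    emb = np.loadtxt(_require(run_dir / "embeddings.tsv", "simulate"), delimiter="\t")
    rows = []
    for (tissue, ct, age), grp in cell_meta.groupby(["tissue", "cell_type", "age_months"]):
        n_f = int((grp["sex"] == "F").sum())
        n_m = int((grp["sex"] == "M").sum())
        if min(n_f, n_m) < 10:
            continue
        rec = comp.knn_sex_auc(
            emb[grp.index.to_numpy()], grp["sex"].to_numpy(),
            k=config.knn_k, n_folds=config.knn_folds, seed=config.seed,
            auc_min=config.auc_min,
        )
        rows.append({"tissue": tissue, "cell_type": ct, "age_group": age, **rec})
    ageio.write_tsv(pd.DataFrame(rows), out / "sex_auc.tsv")
    ageio.log_stage(out / "run_log.jsonl", "sexauc", config.seed,
                    [run_dir / "embeddings.tsv"], {"n_groups": len(rows)})


def stage_da(run_dir: Path, config: PipelineConfig) -> None:
    run_dir = Path(run_dir)
    out = _outdir(run_dir)
    pseudo, parts = _load_pseudobulk(out)
    sample_meta = ageio.read_tsv(run_dir / "sample_metadata.tsv").set_index("sample")
    results = []
    cross_rows = []
    for ct, grp in parts.groupby("cell_type"):
        sub = pseudo.loc[grp.index]
        sub.index = grp["sample"]
        meta = sample_meta.loc[sub.index].reset_index()
        for tissue, tgrp in meta.groupby("tissue"):
            sub_t = sub.loc[tgrp["sample"]]
            per_sex = {}
            for sex in ("F", "M"):
                try:
                    res = damod.fit_da(
                        sub_t, tgrp, sex_stratum=sex, tissue=tissue, cell_type=ct
                    )
                except ValueError:
                    continue
                results.append(res.table)
                per_sex[sex] = res.table
            if len(per_sex) == 2:
                cs = damod.cross_sex(per_sex["F"], per_sex["M"], q_max=config.fdr_q,
                                     logfc_floor=config.sex_specific_logfc_floor)
                cross_rows.append(
                    {
                        "tissue": tissue,
                        "cell_type": ct,
                        "n_shared": len(cs["shared"]),
                        "n_F_specific": len(cs["F_specific"]),
                        "n_M_specific": len(cs["M_specific"]),
                        "spearman_shared_logfc": cs["spearman_shared_logfc"],
                        "concordant_share": cs["concordant_share"],
                    }
                )
    da_all = pd.concat(results, ignore_index=True)
    ageio.write_tsv(da_all, out / "da_results.tsv")
    ageio.write_tsv(pd.DataFrame(cross_rows), out / "da_cross_sex.tsv")
    summary = damod.summarize_across_celltypes(
        da_all, q_max=config.fdr_q,
        shared_min=config.shared_celltype_min, opposite_min=config.opposite_celltype_min,
    )
    ageio.write_tsv(summary, out / "da_summary.tsv")
    ageio.log_stage(out / "run_log.jsonl", "da", config.seed, [out / "pseudobulk.mtx"],
                    {"n_strata": int(da_all.groupby(["tissue", "cell_type", "sex_stratum"]).ngroups)})


def stage_linkage(run_dir: Path, config: PipelineConfig) -> None:
    run_dir = Path(run_dir)
    out = _outdir(run_dir)
    context = ageio.read_tsv(_require(out / "peak_context.tsv", "peaks"))
    genes = ageio.read_tsv(run_dir / "genes.tsv")
    da_all = ageio.read_tsv(_require(out / "da_results.tsv", "da"))
    expression = ageio.read_tsv(run_dir / "expression.tsv")
    pseudo, parts = _load_pseudobulk(out)
    all_links = []
    for ct, grp in parts.groupby("cell_type"):
        da_ct = da_all[da_all["cell_type"] == ct]
        sig_cres = set(da_ct.loc[da_ct["q"] < config.fdr_q, "peak"])
        if not sig_cres:
            continue
        cand_peaks = context[context["name"].isin(sig_cres) | (context["context"] == "TSS-promoter")]
        pairs, _ = linkmod.candidate_pairs(
            cand_peaks, genes, config.linkage_window_bp, config.promoter_halfwidth_bp
        )
        pairs = pairs[pairs["cre_peak"].isin(sig_cres)]
        if pairs.empty:
            continue
        sub = pseudo.loc[grp.index]
        sub.index = grp["sample"]
        cpm = sub.div(sub.sum(axis=1), axis=0) * 1e6
        scored = linkmod.coaccessibility(cpm, pairs)
        for sex in ("F", "M"):
            links = linkmod.concordant_linkages(
                scored, da_ct, expression, sex_stratum=sex,
                q_max=config.fdr_q, r_min=config.linkage_r_min,
            )
            if not links.empty:
                links.insert(0, "cell_type", ct)
                all_links.append(links)
    linkages = (
        pd.concat(all_links, ignore_index=True)
        if all_links
        else pd.DataFrame(columns=["cell_type", "gene", "promoter_peak", "cre_peak"])
    )
    ageio.write_tsv(linkages, out / "linkages.tsv")
    if not linkages.empty:
        summaries = linkmod.linkage_summaries(linkages)
        ageio.write_tsv(summaries["per_gene"], out / "linkages_per_gene.tsv")
    ageio.log_stage(out / "run_log.jsonl", "linkage", config.seed, [out / "da_results.tsv"],
                    {"n_linkages": len(linkages)})


def stage_regulators(run_dir: Path, config: PipelineConfig) -> None:
    run_dir = Path(run_dir)
    out = _outdir(run_dir)
    da_all = ageio.read_tsv(_require(out / "da_results.tsv", "da"))
    context = ageio.read_tsv(_require(out / "peak_context.tsv", "peaks"))
    genes = ageio.read_tsv(run_dir / "genes.tsv")
    gc = ageio.read_tsv(run_dir / "peak_gc.tsv").set_index("peak")
    pseudo, parts = _load_pseudobulk(out)
    cpm = pseudo.div(pseudo.sum(axis=1), axis=0) * 1e6
    universe = pd.DataFrame(
        {"gc": gc.loc[cpm.columns, "gc"], "mean_access": cpm.mean(axis=0)},
        index=cpm.columns,
    )
    motif_long = ageio.read_tsv(run_dir / "motif_annotation.tsv")
    motif_ann = (
        motif_long.assign(value=1)
        .pivot_table(index="peak", columns="motif", values="value", fill_value=0)
        .reindex(cpm.columns, fill_value=0)
        .astype(bool)
    )
    sig = da_all[da_all["q"] < config.fdr_q]
    enr_tables = []
    for direction in ("up", "down"):
        query = sorted(set(sig.loc[sig["direction"] == direction, "peak"]))
        if not query:
            continue
        multiplier = min(2, (len(universe) - len(query)) // len(query))
        if multiplier < 1:
            continue
        bg, _ = regmod.select_background(query, universe, multiplier=multiplier, seed=config.seed)
        enr = regmod.motif_enrichment(query, bg, motif_ann)
        enr.insert(0, "direction", direction)
        enr_tables.append(enr)
    if enr_tables:
        ageio.write_tsv(pd.concat(enr_tables, ignore_index=True), out / "motif_enrichment.tsv")
    by_ct = pseudo.groupby(parts["cell_type"]).sum()
    dev = regmod.motif_deviations(by_ct, motif_ann, universe, B=25, seed=config.seed)
    ageio.write_tsv(dev["z"].reset_index(names="cell_type"), out / "motif_deviations_z.tsv")
    # aging gene set: genes with significant aging-up promoter peaks, plus
    # genes receiving concordant up linkages if the linkage stage ran
    up_peaks = set(sig.loc[sig["direction"] == "up", "peak"])
    promoter_peaks = set(context.loc[context["context"] == "TSS-promoter", "name"])
    prom_genes = set(
        sim.genes_with_promoter_peaks(
            context.rename(columns={}), genes, up_peaks & promoter_peaks,
            config.promoter_halfwidth_bp,
        )
    )
    link_genes = set()
    link_path = out / "linkages.tsv"
    if link_path.exists():
        links = ageio.read_tsv(link_path)
        if "concordant" in links.columns and len(links):
            link_genes = set(links.loc[(links["cre_direction"] == "up"), "gene"])
    aging_genes = prom_genes | link_genes
    signatures = ageio.read_gmt(run_dir / "signatures.gmt")
    enr = regmod.cytokine_enrichment(aging_genes, signatures, set(genes["gene"]))
    enr["source_promoter"] = enr["set_id"].map(lambda _: len(prom_genes))
    enr["source_linkage"] = enr["set_id"].map(lambda _: len(link_genes))
    cyto_map = ageio.read_tsv(run_dir / "cytokine_genes.tsv")
    support = regmod.signature_support(enr, prom_genes, cyto_map, q_max=config.fdr_q)
    ageio.write_tsv(enr, out / "cytokine_enrichment.tsv")
    ageio.write_tsv(support, out / "cytokine_support.tsv")
    ageio.log_stage(out / "run_log.jsonl", "regulators", config.seed,
                    [out / "da_results.tsv"], {"n_aging_genes": len(aging_genes)})
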