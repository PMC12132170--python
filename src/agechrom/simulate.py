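"""Synthetic-data generation with planted, recoverable ground truth.

Every input the pipeline consumes is emulated here for a 3-age-group
(1/5/21 months) x 2-sex x multi-mouse mouse study: per-group peak summits,
cell-by-peak sparse counts, cell/sample metadata, chromatin embeddings, gene
annotation, motif-by-peak annotations, cytokine-response gene sets and a
pseudobulk expression table. Effects are planted with known sizes
(composition slopes and age x sex interactions on the log-odds scale,
per-month log fold changes on peak accessibility, cell-type-specific peaks,
sex offsets in embedding space, latent promoter-CRE correlations, and
cytokine-signature overlaps) so every downstream stage has a recovery test
against ``truth.json`` without any download.

Noise models: Dirichlet-multinomial cell-type compositions across biological
replicates (overdispersion controlled by one concentration parameter) and
negative-binomial peak counts with a shared dispersion. Age enters in months
as a continuous covariate {1, 5, 21}.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from . import io as ageio
from . import peaks as peakmod

AGE_GROUPS = (1, 5, 21)


# ---------------------------------------------------------------------------
# domain types


@dataclass
class StudyDesign:
    """Mice (age x sex balanced), tissues, and the mouse x tissue samples."""

    mice: pd.DataFrame  # mouse_id, age_months, sex
    tissues: list[str]
    samples: pd.DataFrame  # sample_id, mouse_id, tissue

    def __post_init__(self) -> None:
        for age in AGE_GROUPS:
            for sex in ("F", "M"):
                cell = self.mice[(self.mice.age_months == age) & (self.mice.sex == sex)]
                if cell.empty:
                    raise ValueError(f"no mouse in age {age} x sex {sex}")
        if self.samples["sample_id"].duplicated().any():
            raise ValueError("duplicate sample_ids")
        orphan = set(self.samples["mouse_id"]) - set(self.mice["mouse_id"])
        if orphan:
            raise ValueError(f"samples reference unknown mice: {sorted(orphan)}")

    @property
    def sample_meta(self) -> pd.DataFrame:
        """samples joined with mouse age and sex; indexed by sample_id."""
        return (
            self.samples.merge(self.mice, on="mouse_id")
            .rename(columns={"sample_id": "sample"})
            .set_index("sample", drop=False)
        )


@dataclass
class PlantedEffects:
    """Ground truth planted by the generators, serialisable to truth.json."""

    composition_slopes: dict[str, tuple[float, float]] = field(default_factory=dict)
    da_effects: dict[str, dict] = field(default_factory=dict)
    specificity_plan: dict[str, str] = field(default_factory=dict)
    sex_separation: dict[str, float] = field(default_factory=dict)
    linkage_plan: list[dict] = field(default_factory=list)
    signature_overlap: dict[str, int] = field(default_factory=dict)

    def validate(self, peaks: set[str] | None = None, genes: set[str] | None = None,
                 cell_types: set[str] | None = None) -> None:
        for ct, (s, i) in self.composition_slopes.items():
            if not (np.isfinite(s) and np.isfinite(i)):
                raise ValueError(f"non-finite composition slope for {ct}")
            if cell_types is not None and ct not in cell_types:
                raise ValueError(f"composition slope references unknown cell type {ct}")
        for peak, eff in self.da_effects.items():
            if peaks is not None and peak not in peaks:
                raise ValueError(f"DA effect references unknown peak {peak}")
            if eff["sex_scope"] not in {"shared", "F-only", "M-only"}:
                raise ValueError(f"bad sex scope for {peak}")
        for peak in self.specificity_plan:
            if peaks is not None and peak not in peaks:
                raise ValueError(f"specificity plan references unknown peak {peak}")
        for link in self.linkage_plan:
            if not -1.0 <= link["latent_r"] <= 1.0:
                raise ValueError("latent correlation outside [-1, 1]")
            if genes is not None and link["gene"] not in genes:
                raise ValueError(f"linkage references unknown gene {link['gene']}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PlantedEffects":
        d = dict(d)
        d["composition_slopes"] = {k: tuple(v) for k, v in d.get("composition_slopes", {}).items()}
        return cls(**d)


# ---------------------------------------------------------------------------
# design and composition


def generate_design(n_mice_per_group: int, tissues: list[str], seed: int = 0) -> StudyDesign:
    """Sex-balanced design: n mice per age group, one sample per mouse x tissue."""
    if n_mice_per_group < 2:
        raise ValueError("need >= 2 mice per age group")
    if n_mice_per_group % 2 != 0:
        raise ValueError("n_mice_per_group must be even to sex-balance")
    rows = []
    for age in AGE_GROUPS:
        for j in range(n_mice_per_group):
            sex = "F" if j < n_mice_per_group // 2 else "M"
            rows.append((f"m{age:02d}{sex}{j % (n_mice_per_group // 2):02d}", age, sex))
    mice = pd.DataFrame(rows, columns=["mouse_id", "age_months", "sex"])
    samples = pd.DataFrame(
        [
            (f"{m}.{t}", m, t)
            for t in tissues
            for m in mice["mouse_id"]
        ],
        columns=["sample_id", "mouse_id", "tissue"],
    )
    return StudyDesign(mice=mice, tissues=list(tissues), samples=samples)


def generate_composition(
    design: StudyDesign,
    cell_types: list[str],
    baseline_fractions: np.ndarray,
    effects: PlantedEffects,
    total_cells_per_sample: int = 2000,
    concentration: float = 300.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Dirichlet-multinomial sample x cell-type cell counts with planted slopes.

    The mean fraction vector for a sample of age a and sex s is
    softmax(log baseline + slope * a + interaction * a * 1[s == F]); counts are
    Dirichlet(concentration * mean) then multinomial(total_cells_per_sample).
    """
    baseline = np.asarray(baseline_fractions, dtype=float)
    if (baseline <= 0).any():
        raise ValueError("baseline fractions must be positive")
    if not np.isclose(baseline.sum(), 1.0):
        raise ValueError("baseline fractions must sum to 1")
    if concentration <= 0:
        raise ValueError("concentration must be positive")
    slopes = np.array([effects.composition_slopes.get(ct, (0.0, 0.0))[0] for ct in cell_types])
    inters = np.array([effects.composition_slopes.get(ct, (0.0, 0.0))[1] for ct in cell_types])
    rng = np.random.default_rng(seed)
    meta = design.sample_meta
    rows = []
    for _, s in meta.iterrows():
        eta = np.log(baseline) + slopes * s.age_months
        if s.sex == "F":
            eta = eta + inters * s.age_months
        mean = np.exp(eta - eta.max())
        mean /= mean.sum()
        p = rng.dirichlet(concentration * mean)
        rows.append(rng.multinomial(total_cells_per_sample, p))
    return pd.DataFrame(rows, index=meta["sample"], columns=cell_types)


def expected_fractions(
    baseline: np.ndarray,
    cell_types: list[str],
    effects: PlantedEffects,
    age: float,
    sex: str,
) -> np.ndarray:
    """The planted mean fraction vector (softmax form), for oracle checks."""
    slopes = np.array([effects.composition_slopes.get(ct, (0.0, 0.0))[0] for ct in cell_types])
    inters = np.array([effects.composition_slopes.get(ct, (0.0, 0.0))[1] for ct in cell_types])
    eta = np.log(np.asarray(baseline, float)) + slopes * age
    if sex == "F":
        eta = eta + inters * age
    mean = np.exp(eta - eta.max())
    return mean / mean.sum()


# ---------------------------------------------------------------------------
# genome, peaks, genes


def generate_peak_universe(
    n_chroms: int,
    chrom_length: int,
    n_genes: int,
    n_peaks: int,
    seed: int = 0,
    promoter_fraction: float = 0.15,
    halfwidth_bp: int = 250,
    groups: list[str] | None = None,
    group_subset: float = 0.8,
    jitter_bp: int = 50,
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame, dict[str, int]]:
    """Place gene TSSs and peak summits; emit per-group jittered summit lists.

    A ``promoter_fraction`` of summits land within +/-1 kb of a TSS. Each
    group's list is a random subset of the universal summits, jittered within
    ``jitter_bp`` and given random scores, so iterative merging is exercised.
    Returns (summits per group, gene annotation, chrom sizes).
    """
    if n_peaks < n_genes:
        raise ValueError("need n_peaks >= n_genes")
    per_chrom = -(-n_peaks // n_chroms)
    margin = halfwidth_bp + jitter_bp + 1
    if per_chrom * (6 * halfwidth_bp) > chrom_length - 2 * margin:
        raise ValueError("chrom_length too small for the requested number of peaks")
    rng = np.random.default_rng(seed)
    chrom_sizes = {f"chr{i + 1}": int(chrom_length) for i in range(n_chroms)}
    chrom_names = list(chrom_sizes)
    # genes
    gene_rows = []
    for gi in range(n_genes):
        chrom = chrom_names[gi % n_chroms]
        tss = int(rng.integers(20_000, chrom_length - 60_000))
        strand = "+" if rng.random() < 0.5 else "-"
        body = int(rng.integers(5_000, 50_000))
        start, end = (tss, tss + body) if strand == "+" else (tss - body, tss)
        n_ex = int(rng.integers(2, 5))
        cuts = np.sort(rng.integers(start, end, 2 * n_ex))
        ex_starts, ex_ends = list(map(int, cuts[0::2])), list(map(int, cuts[1::2]))
        ex_starts[0], ex_ends[-1] = start, end
        ex_starts, ex_ends = zip(*[(s, e) for s, e in zip(ex_starts, ex_ends) if e > s])
        gene_rows.append(
            {
                "gene": f"gene{gi:04d}",
                "chrom": chrom,
                "strand": strand,
                "tss": tss,
                "exon_starts": ",".join(map(str, ex_starts)),
                "exon_ends": ",".join(map(str, ex_ends)),
            }
        )
    genes = pd.DataFrame(gene_rows)
    # universal summits, spaced so fixed-width peaks cannot collide after jitter
    summit_rows = []
    spacing = 6 * halfwidth_bp
    for ci, chrom in enumerate(chrom_names):
        n_here = min(per_chrom, n_peaks - ci * per_chrom)
        grid = margin + spacing * np.arange(n_here)
        grid = grid + rng.integers(0, spacing - 2 * (halfwidth_bp + jitter_bp), n_here)
        n_prom = int(round(promoter_fraction * n_here))
        tss_here = genes.loc[genes.chrom == chrom, "tss"].to_numpy()
        positions = grid.astype(int)
        if len(tss_here) and n_prom:
            # snap a subset of summits next to TSSs (within +/-900 bp)
            which = rng.choice(n_here, min(n_prom, len(tss_here)), replace=False)
            targets = rng.choice(tss_here, len(which), replace=False)
            offsets = rng.integers(-900, 901, len(which))
            positions[which] = np.clip(targets + offsets, margin, chrom_length - margin)
        for pos in positions:
            summit_rows.append((chrom, int(pos)))
    universal = pd.DataFrame(summit_rows, columns=["chrom", "pos"]).sort_values(
        ["chrom", "pos"], kind="mergesort"
    ).reset_index(drop=True)
    groups = groups or ["group1", "group2", "group3"]
    summits_by_group: dict[str, pd.DataFrame] = {}
    for g in groups:
        take = rng.random(len(universal)) < group_subset
        sub = universal[take].copy()
        sub["start"] = sub["pos"] + rng.integers(-jitter_bp, jitter_bp + 1, take.sum())
        sub["end"] = sub["start"] + 1
        sub["score"] = np.round(rng.uniform(1, 100, take.sum()), 3)
        sub["name"] = [f"{g}_p{i}" for i in range(take.sum())]
        sub["source_group"] = g
        summits_by_group[g] = sub[["chrom", "start", "end", "name", "score", "source_group"]].reset_index(drop=True)
    return summits_by_group, genes, chrom_sizes


def build_universal_peaks(
    summits_by_group: dict[str, pd.DataFrame],
    chrom_sizes: dict[str, int],
    halfwidth_bp: int = 250,
) -> pd.DataFrame:
    """Extend every group's summits and merge them into the universal set."""
    extended = [
        peakmod.extend_summits(df, halfwidth_bp, chrom_sizes) for df in summits_by_group.values()
    ]
    return peakmod.iterative_merge(extended)


# ---------------------------------------------------------------------------
# counts, embeddings


def generate_counts(
    design: StudyDesign,
    cell_table: pd.DataFrame,
    peaks: pd.DataFrame,
    effects: PlantedEffects,
    nb_dispersion: float = 0.2,
    baseline_mean: float = 0.3,
    da_peak_mean: float = 0.5,
    specific_fold: float = 20.0,
    linkage_sd: float = 1.0,
    seed: int = 0,
) -> tuple[sp.csr_matrix, pd.DataFrame]:
    """Sparse cell x peak NB counts with planted DA, specificity and linkage effects.

    Per-peak per-cell mean for a cell of age a, sex s, cell type c:
    mu = base_p * exp(lfc_p * a) when the planted DA effect covers (s, c),
    times ``specific_fold`` when peak p is planted specific to c (divided by
    it elsewhere), times exp(linkage latent) for planted promoter-CRE pairs
    (a per-sample bivariate normal latent shared by the pair at correlation
    latent_r). Counts are gamma-Poisson (NB) with shared dispersion.
    """
    if nb_dispersion < 0:
        raise ValueError("nb_dispersion must be >= 0")
    peak_names = list(peaks["name"])
    effects.validate(peaks=set(peak_names))
    rng = np.random.default_rng(seed)
    P = len(peak_names)
    peak_idx = {p: i for i, p in enumerate(peak_names)}
    base = baseline_mean * rng.lognormal(0.0, 0.5, P)
    for p in effects.da_effects:
        base[peak_idx[p]] = da_peak_mean
    for link in effects.linkage_plan:
        base[peak_idx[link["promoter_peak"]]] = da_peak_mean
        base[peak_idx[link["cre_peak"]]] = da_peak_mean
    lfc = np.zeros(P)
    scope = np.array(["all"] * P, dtype=object)
    affected: dict[int, set[str] | None] = {}
    for p, eff in effects.da_effects.items():
        i = peak_idx[p]
        lfc[i] = eff["lfc_per_month"]
        scope[i] = eff["sex_scope"]
        cts = eff.get("cell_types")
        affected[i] = set(cts) if cts else None
    meta = design.sample_meta
    # per-sample latent factors for planted promoter-CRE pairs
    link_latents: dict[str, dict[int, float]] = {}
    for link in effects.linkage_plan:
        r = link["latent_r"]
        cov = np.array([[1.0, r], [r, 1.0]])
        z = rng.multivariate_normal([0, 0], cov, size=len(meta))
        for k, (sample, zz) in enumerate(zip(meta["sample"], z)):
            link_latents.setdefault(sample, {})
            link_latents[sample][peak_idx[link["promoter_peak"]]] = linkage_sd * zz[0]
            link_latents[sample][peak_idx[link["cre_peak"]]] = linkage_sd * zz[1]
    blocks = []
    cell_rows = []
    cid = 0
    for sample in cell_table.index:
        s = meta.loc[sample]
        for ct in cell_table.columns:
            n_cells = int(cell_table.loc[sample, ct])
            if n_cells == 0:
                continue
            mu = base.copy()
            da_on = np.array(
                [
                    (scope[i] in ("all", "shared"))
                    or (scope[i] == "F-only" and s.sex == "F")
                    or (scope[i] == "M-only" and s.sex == "M")
                    for i in range(P)
                ]
            )
            ct_on = np.array(
                [affected.get(i) is None or ct in affected[i] for i in range(P)]
            )
            active = (lfc != 0) & da_on & ct_on
            mu[active] *= np.exp(lfc[active] * s.age_months)
            for p, spec_ct in effects.specificity_plan.items():
                i = peak_idx[p]
                mu[i] = base[i] * (specific_fold if ct == spec_ct else 1.0 / specific_fold)
            for i, latent in link_latents.get(sample, {}).items():
                mu[i] = mu[i] * np.exp(latent)
            lam = np.broadcast_to(mu, (n_cells, P))
            if nb_dispersion > 1e-12:
                shape = 1.0 / nb_dispersion
                lam = rng.gamma(shape, 1.0, size=(n_cells, P)) * nb_dispersion * lam
            block = rng.poisson(lam)
            blocks.append(sp.csr_matrix(block))
            for _ in range(n_cells):
                cell_rows.append(
                    {
                        "cell_id": f"c{cid:07d}",
                        "sample": sample,
                        "mouse_id": s.mouse_id,
                        "tissue": s.tissue,
                        "cell_type": ct,
                        "sex": s.sex,
                        "age_months": s.age_months,
                    }
                )
                cid += 1
    if not blocks:
        return sp.csr_matrix((0, P), dtype=np.int64), pd.DataFrame(
            columns=["cell_id", "sample", "mouse_id", "tissue", "cell_type", "sex", "age_months"]
        )
    counts = sp.vstack(blocks).tocsr().astype(np.int64)
    return counts, pd.DataFrame(cell_rows)


def generate_embeddings(
    cell_meta: pd.DataFrame,
    dim: int = 10,
    sex_separation: dict[str, float] | None = None,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> np.ndarray:
    """Gaussian embeddings per cell with a planted sex offset in chosen cell types.

    Cells of one cell type share a centre; in cell types named in
    ``sex_separation``, females and males are displaced by +/- half the stated
    magnitude along a random unit direction, so the F and M clouds are the
    stated distance apart.
    """
    if dim < 2:
        raise ValueError("dim must be >= 2")
    if noise_sd <= 0:
        raise ValueError("noise_sd must be positive")
    sex_separation = sex_separation or {}
    rng = np.random.default_rng(seed)
    cell_types = sorted(cell_meta["cell_type"].unique())
    centres = {ct: rng.normal(0, 5 * noise_sd, dim) for ct in cell_types}
    directions = {}
    for ct in cell_types:
        u = rng.normal(0, 1, dim)
        directions[ct] = u / np.linalg.norm(u)
    emb = rng.normal(0, noise_sd, (len(cell_meta), dim))
    for i, (_, row) in enumerate(cell_meta.iterrows()):
        ct = row["cell_type"]
        emb[i] += centres[ct]
        mag = sex_separation.get(ct, 0.0)
        if mag:
            sign = 0.5 if row["sex"] == "F" else -0.5
            emb[i] += sign * mag * directions[ct]
    return emb


# ---------------------------------------------------------------------------
# motifs, signatures, expression


def generate_motifs_and_signatures(
    peaks: pd.DataFrame,
    genes: pd.DataFrame,
    n_motifs: int,
    n_cytokines: int,
    effects: PlantedEffects,
    aging_genes: list[str],
    seed: int = 0,
    background_rate: float = 0.1,
    planted_fold: float = 3.0,
    signature_size: int = 50,
) -> tuple[pd.DataFrame, dict[str, list[str]], pd.DataFrame]:
    """Binary motif x peak annotation, cytokine GMT sets, secretion/receptor map.

    motif0000 is planted: its hit rate in planted DA peaks is
    ``planted_fold`` x the background rate. Each cytokine signature is a
    random gene set; cytokines named in ``effects.signature_overlap`` have
    exactly the stated overlap with ``aging_genes``. Every cytokine gets one
    secretion and one receptor gene; cytokines with planted overlap get a
    receptor gene drawn from the aging set so the support rule can fire.
    """
    if n_motifs < 1 or n_cytokines < 1:
        raise ValueError("need >= 1 motif and >= 1 cytokine")
    rng = np.random.default_rng(seed)
    peak_names = list(peaks["name"])
    gene_names = list(genes["gene"])
    motif_names = [f"motif{i:04d}" for i in range(n_motifs)]
    ann = rng.random((len(peak_names), n_motifs)) < background_rate
    da_peaks = [p for p in effects.da_effects if p in set(peak_names)]
    if da_peaks:
        da_idx = [peak_names.index(p) for p in da_peaks]
        ann[da_idx, 0] = rng.random(len(da_idx)) < min(planted_fold * background_rate, 1.0)
    annotation = pd.DataFrame(ann, index=peak_names, columns=motif_names)
    # cytokine signatures
    aging_set = [g for g in aging_genes if g in set(gene_names)]
    non_aging = [g for g in gene_names if g not in set(aging_set)]
    signatures: dict[str, list[str]] = {}
    for ci in range(n_cytokines):
        name = f"cytokine{ci:03d}"
        if name in effects.signature_overlap:
            overlap = effects.signature_overlap[name]
            if overlap > signature_size:
                raise ValueError(f"{name}: planted overlap exceeds signature size")
            if overlap > len(aging_set):
                raise ValueError(f"{name}: planted overlap exceeds aging gene set size")
            if signature_size - overlap > len(non_aging):
                raise ValueError(f"{name}: not enough non-aging genes for the signature")
            hit = list(rng.choice(aging_set, overlap, replace=False)) if overlap else []
            rest = list(rng.choice(non_aging, signature_size - overlap, replace=False))
            signatures[name] = sorted(hit + rest)
        else:
            # unplanted cytokines draw uniformly: their aging overlap follows
            # the hypergeometric null
            signatures[name] = sorted(rng.choice(gene_names, signature_size, replace=False))
    map_rows = []
    for name in signatures:
        overlap = effects.signature_overlap.get(name, 0)
        receptor_pool = aging_set if (overlap and aging_set) else gene_names
        map_rows.append({"cytokine": name, "gene": str(rng.choice(gene_names)), "role": "secretion"})
        map_rows.append({"cytokine": name, "gene": str(rng.choice(receptor_pool)), "role": "receptor"})
    return annotation, signatures, pd.DataFrame(map_rows)


def generate_expression(
    genes: pd.DataFrame,
    aging_up_genes: list[str],
    seed: int = 0,
) -> pd.DataFrame:
    """Per-gene, per-sex expression age-slope directions matching the planted DA."""
    rng = np.random.default_rng(seed)
    rows = []
    up = set(aging_up_genes)
    for sex in ("F", "M"):
        for g in genes["gene"]:
            if g in up:
                rows.append({"gene": g, "sex": sex, "slope": 0.05, "direction": "up", "q": 0.001})
            else:
                rows.append({"gene": g, "sex": sex, "slope": 0.0, "direction": "ns", "q": 1.0})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# focused pseudobulk generators for calibration / recovery studies


def generate_pseudobulk_da(
    n_samples: int = 30,
    n_peaks: int = 2000,
    planted_lfc: dict[int, float] | None = None,
    baseline_mean: float = 50.0,
    dispersion: float = 0.05,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pseudobulk sample x peak NB counts for DA calibration and recovery.

    Ages cycle through {1, 5, 21}; ``planted_lfc`` maps peak column index to a
    natural-log fold change per month. Returns (counts, sample metadata with a
    single-sex stratum).
    """
    rng = np.random.default_rng(seed)
    ages = np.array([AGE_GROUPS[i % 3] for i in range(n_samples)], dtype=float)
    base = baseline_mean * rng.lognormal(0.0, 0.3, n_peaks)
    lfc = np.zeros(n_peaks)
    for i, v in (planted_lfc or {}).items():
        lfc[i] = v
    mu = base[None, :] * np.exp(ages[:, None] * lfc[None, :])
    if dispersion > 1e-12:
        lam = rng.gamma(1.0 / dispersion, 1.0, mu.shape) * dispersion * mu
    else:
        lam = mu
    counts = rng.poisson(lam)
    samples = [f"s{i:03d}" for i in range(n_samples)]
    meta = pd.DataFrame({"sample": samples, "age_months": ages, "sex": "F"})
    return (
        pd.DataFrame(counts, index=samples, columns=[f"peak{j:05d}" for j in range(n_peaks)]),
        meta,
    )


def generate_linked_pseudobulk(
    n_samples: int = 30,
    n_true_pairs: int = 30,
    n_decoy_pairs: int = 300,
    latent_r: float = 0.8,
    baseline_mean: float = 500.0,
    dispersion: float = 0.01,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pseudobulk counts with planted promoter-CRE latent correlations plus decoys.

    True pairs share a bivariate-normal log-mean latent at correlation
    ``latent_r``; decoy pairs get independent latents. Counts are NB with low
    dispersion and high mean so the latent correlation survives measurement.
    Returns (counts, pair table with an is_true column).
    """
    if not -1.0 <= latent_r <= 1.0:
        raise ValueError("latent_r must be in [-1, 1]")
    rng = np.random.default_rng(seed)
    n_pairs = n_true_pairs + n_decoy_pairs
    names_prom = [f"prom{j:04d}" for j in range(n_pairs)]
    names_cre = [f"cre{j:04d}" for j in range(n_pairs)]
    sd = 0.5
    cols = {}
    for j in range(n_pairs):
        r = latent_r if j < n_true_pairs else 0.0
        z = rng.multivariate_normal([0, 0], [[1, r], [r, 1]], size=n_samples)
        for name, zz in [(names_prom[j], z[:, 0]), (names_cre[j], z[:, 1])]:
            mu = baseline_mean * np.exp(sd * zz)
            lam = rng.gamma(1.0 / dispersion, 1.0, n_samples) * dispersion * mu if dispersion > 1e-12 else mu
            cols[name] = rng.poisson(lam)
    counts = pd.DataFrame(cols, index=[f"s{i:03d}" for i in range(n_samples)])
    pairs = pd.DataFrame(
        {
            "gene": [f"gene{j:04d}" for j in range(n_pairs)],
            "promoter_peak": names_prom,
            "cre_peak": names_cre,
            "distance_bp": 50_000,
            "is_true": [j < n_true_pairs for j in range(n_pairs)],
        }
    )
    return counts, pairs


# ---------------------------------------------------------------------------
# default study and full fixture emission


@dataclass
class SimulationParams:
    """The default synthetic study: 3 tissues x 10 cell types x 2,000 peaks x 24 mice."""

    n_mice_per_group: int = 8
    tissues: tuple[str, ...] = ("kidney", "liver", "lung")
    n_cell_types: int = 10
    n_peaks: int = 2000
    n_genes: int = 200
    n_chroms: int = 3
    chrom_length: int = 8_000_000
    total_cells_per_sample: int = 150
    concentration: float = 300.0
    nb_dispersion: float = 0.2
    embedding_dim: int = 10
    noise_sd: float = 1.0
    n_motifs: int = 20
    n_cytokines: int = 12


def default_composition_plan(cell_types: list[str]) -> tuple[np.ndarray, dict[str, tuple[float, float]]]:
    """Closure-balanced composition planting: 5 slopes, 3 interactions.

    Fractions are relative, so planted expansions mechanically depress every
    other cell type; unless the planted log-odds slopes satisfy
    sum_k f_k * slope_k = 0, null cell types inherit a real (induced) trend.
    The plan therefore gives the two +0.03/month cell types baseline weight
    1.5 and the three -0.03/month cell types weight 1.0 (2 * 1.5 = 3 * 1.0),
    cancelling the closure term exactly. Interactions (+/-0.04/month,
    female - male) sit on cell types 2, 5 and 6; two of the three cancel,
    leaving a negligible residual on the female side.
    """
    K = len(cell_types)
    if K < 7:
        raise ValueError("the default composition plan needs >= 7 cell types")
    weights = np.ones(K)
    weights[:2] = 1.5
    baseline = weights / weights.sum()
    slopes: dict[str, tuple[float, float]] = {
        cell_types[0]: (0.03, 0.0),
        cell_types[1]: (0.03, 0.0),
        cell_types[2]: (-0.03, 0.04),
        cell_types[3]: (-0.03, 0.0),
        cell_types[4]: (-0.03, 0.0),
        cell_types[5]: (0.0, -0.04),
        cell_types[6]: (0.0, 0.04),
    }
    return baseline, slopes


def default_effects(
    cell_types: list[str],
    peaks: pd.DataFrame,
    genes: pd.DataFrame,
    noise_sd: float = 1.0,
    embedding_dim: int = 10,
    seed: int = 0,
) -> PlantedEffects:
    """The default planted truth for the study above.

    Composition: log-odds slopes +/-0.03 per month on five cell types, age x
    sex interactions 0.04 per month on three. DA: sex-shared up effects of
    +0.05 per month on the promoter peaks of ~30 genes (these genes define
    the planted aging gene set), 20 shared down peaks, 20 female-only and 20
    male-only up peaks, and 20 peaks restricted to three cell types across
    all cell types otherwise. Twenty peaks are planted cell-type-specific;
    two cell types carry an embedding sex offset of 2 * noise_sd per
    dimension; five promoter-CRE pairs (geometrically valid: the promoter
    peak overlaps the gene's +/-1 kb TSS window and the CRE summit lies
    within the linkage window but away from every TSS) share a latent at
    r = 0.8; the first two cytokine signatures overlap the aging gene set by
    20 and 12 genes.
    """
    rng = np.random.default_rng(seed)
    effects = PlantedEffects()
    _, effects.composition_slopes = default_composition_plan(cell_types)

    # geometry: promoter peaks per gene and distance of each peak to a TSS
    tss_by_chrom = {c: np.sort(g["tss"].to_numpy()) for c, g in genes.groupby("chrom")}

    def tss_distance(chrom, summit):
        tss = tss_by_chrom.get(chrom)
        if tss is None or not len(tss):
            return np.iinfo(np.int64).max
        i = np.searchsorted(tss, summit)
        d = []
        if i > 0:
            d.append(abs(summit - tss[i - 1]))
        if i < len(tss):
            d.append(abs(summit - tss[i]))
        return min(d)

    prom_of_gene: dict[str, str] = {}
    for _, gene in genes.iterrows():
        tss = int(gene["tss"])
        hit = peaks[
            (peaks["chrom"] == gene["chrom"])
            & (peaks["start"] < tss + 1001)
            & (peaks["end"] > tss - 1000)
        ]
        if not hit.empty:
            prom_of_gene[gene["gene"]] = hit["name"].iloc[0]
    aging_genes = list(prom_of_gene)[:30]
    used: set[str] = set()
    for g in aging_genes:
        p = prom_of_gene[g]
        effects.da_effects[p] = {"lfc_per_month": 0.05, "sex_scope": "shared", "cell_types": None}
        used.add(p)
    distal = peaks[
        [tss_distance(c, s) > 2000 for c, s in zip(peaks["chrom"], peaks["summit"])]
    ]
    free = [p for p in distal["name"] if p not in used]
    rng.shuffle(free)
    take = iter(free)
    for _ in range(20):
        effects.da_effects[next(take)] = {"lfc_per_month": -0.05, "sex_scope": "shared", "cell_types": None}
    for _ in range(20):
        effects.da_effects[next(take)] = {"lfc_per_month": 0.05, "sex_scope": "F-only", "cell_types": None}
    for _ in range(20):
        effects.da_effects[next(take)] = {"lfc_per_month": 0.05, "sex_scope": "M-only", "cell_types": None}
    for _ in range(20):
        # restricted to a few cell types: exercises "other" class in summaries
        effects.da_effects[next(take)] = {
            "lfc_per_month": 0.05, "sex_scope": "shared", "cell_types": cell_types[:3],
        }
    for j in range(20):
        effects.specificity_plan[next(take)] = cell_types[j % len(cell_types)]
    effects.sex_separation = {
        cell_types[0]: 2.0 * noise_sd * np.sqrt(embedding_dim),
        cell_types[1]: 2.0 * noise_sd * np.sqrt(embedding_dim),
    }
    # promoter-CRE linkages: distal CRE within the window of an aging gene's TSS
    distal_pos = distal.set_index("name")
    n_links = 0
    for g in aging_genes:
        if n_links >= 5:
            break
        grow = genes.set_index("gene").loc[g]
        cands = [
            p for p in free
            if p not in used
            and p not in effects.da_effects
            and distal_pos.loc[p, "chrom"] == grow["chrom"]
            and abs(int(distal_pos.loc[p, "summit"]) - int(grow["tss"])) <= 250_000
        ]
        if not cands:
            continue
        cre = cands[0]
        effects.da_effects[cre] = {"lfc_per_month": 0.05, "sex_scope": "shared", "cell_types": None}
        effects.linkage_plan.append(
            {"gene": g, "promoter_peak": prom_of_gene[g], "cre_peak": cre, "latent_r": 0.8}
        )
        used.add(cre)
        n_links += 1
    effects.signature_overlap = {"cytokine000": 20, "cytokine001": 12}
    return effects


def simulate_all(out_dir: str | Path, seed: int = 0, params: SimulationParams | None = None) -> dict:
    """Emit a complete fixture directory plus truth.json of planted effects."""
    params = params or SimulationParams()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    design = generate_design(params.n_mice_per_group, list(params.tissues), seed)
    cell_types = [f"ct{i:02d}" for i in range(params.n_cell_types)]
    summits, genes, chrom_sizes = generate_peak_universe(
        params.n_chroms,
        params.chrom_length,
        params.n_genes,
        params.n_peaks,
        seed=int(rng.integers(2**31 - 1)),
        groups=cell_types[:4],
    )
    universal = build_universal_peaks(summits, chrom_sizes)
    effects = default_effects(
        cell_types, universal, genes, params.noise_sd, params.embedding_dim,
        seed=int(rng.integers(2**31 - 1)),
    )
    baseline, _ = default_composition_plan(cell_types)
    cell_table = generate_composition(
        design, cell_types, baseline, effects,
        total_cells_per_sample=params.total_cells_per_sample,
        concentration=params.concentration,
        seed=int(rng.integers(2**31 - 1)),
    )
    counts, cell_meta = generate_counts(
        design, cell_table, universal, effects,
        nb_dispersion=params.nb_dispersion,
        seed=int(rng.integers(2**31 - 1)),
    )
    emb = generate_embeddings(
        cell_meta, params.embedding_dim, effects.sex_separation, params.noise_sd,
        seed=int(rng.integers(2**31 - 1)),
    )
    # aging gene set for planting signatures: genes whose TSS-promoter region
    # holds an up-planted DA peak (checked geometrically)
    up_peaks = {
        p for p, e in effects.da_effects.items()
        if e["lfc_per_month"] > 0 and e["sex_scope"] == "shared"
    }
    aging_up_genes = genes_with_promoter_peaks(universal, genes, up_peaks)
    signature_size = min(50, max(10, params.n_genes // 3))
    effects.signature_overlap = {
        k: min(v, signature_size, len(aging_up_genes))
        for k, v in effects.signature_overlap.items()
    }
    motif_ann, signatures, cyto_map = generate_motifs_and_signatures(
        universal, genes, params.n_motifs, params.n_cytokines, effects,
        aging_genes=aging_up_genes, seed=int(rng.integers(2**31 - 1)),
        signature_size=signature_size,
    )
    expression = generate_expression(genes, aging_up_genes, seed=int(rng.integers(2**31 - 1)))
    gc = pd.DataFrame({"peak": universal["name"], "gc": np.round(rng.uniform(0.3, 0.7, len(universal)), 4)})

    # --- write everything in the formats the pipeline reads
    with open(out / "chrom.sizes", "w") as fh:
        for c, L in chrom_sizes.items():
            fh.write(f"{c}\t{L}\n")
    ageio.write_tsv(genes, out / "genes.tsv")
    (out / "summits").mkdir(exist_ok=True)
    for g, df in summits.items():
        ageio.write_bed(df, out / "summits" / f"{g}.bed")
    ageio.write_tsv(design.mice, out / "mice.tsv")
    ageio.write_tsv(design.sample_meta.reset_index(drop=True), out / "sample_metadata.tsv")
    ageio.write_tsv(cell_meta, out / "cell_metadata.tsv")
    ageio.write_counts_mtx(
        counts, list(cell_meta["cell_id"]), list(universal["name"]),
        out / "counts.mtx", out / "counts.rows.tsv", out / "counts.cols.tsv",
    )
    np.savetxt(out / "embeddings.tsv", emb, delimiter="\t", fmt="%.6g")
    motif_long = motif_ann.astype(int).stack()
    motif_long = motif_long[motif_long > 0].reset_index()
    motif_long.columns = ["peak", "motif", "value"]
    ageio.write_tsv(motif_long, out / "motif_annotation.tsv")
    ageio.write_gmt(signatures, out / "signatures.gmt")
    ageio.write_tsv(cyto_map, out / "cytokine_genes.tsv")
    ageio.write_tsv(expression, out / "expression.tsv")
    ageio.write_tsv(gc, out / "peak_gc.tsv")
    truth = {
        "seed": seed,
        "params": dataclasses.asdict(params),
        "cell_types": cell_types,
        "effects": effects.to_dict(),
        "aging_up_genes": aging_up_genes,
        "n_universal_peaks": int(len(universal)),
    }
    with open(out / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
    return truth


def genes_with_promoter_peaks(
    universal: pd.DataFrame,
    genes: pd.DataFrame,
    peak_subset: set[str],
    promoter_halfwidth_bp: int = 1000,
) -> list[str]:
    """Genes whose +/-1 kb TSS region overlaps any peak in ``peak_subset``."""
    sub = universal[universal["name"].isin(peak_subset)]
    hits = []
    for _, gene in genes.iterrows():
        tss = int(gene["tss"])
        on = sub[
            (sub["chrom"] == gene["chrom"])
            & (sub["start"] < tss + promoter_halfwidth_bp + 1)
            & (sub["end"] > tss - promoter_halfwidth_bp)
        ]
        if not on.empty:
            hits.append(gene["gene"])
    return hits
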