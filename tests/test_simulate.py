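import numpy as np
import pandas as pd
import pytest

from agechrom.simulate import (
    PlantedEffects,
    StudyDesign,
    expected_fractions,
    generate_composition,
    generate_counts,
    generate_design,
    generate_embeddings,
    generate_motifs_and_signatures,
    generate_peak_universe,
)


def _toy_peaks(n=20):
    return pd.DataFrame(
        {
            "name": [f"p{i}" for i in range(n)],
            "chrom": "chr1",
            "start": np.arange(n) * 2000,
            "end": np.arange(n) * 2000 + 501,
            "summit": np.arange(n) * 2000 + 250,
        }
    )


class TestDesign:
    def test_counts_and_balance(self):
        d = generate_design(4, ["kidney"], seed=1)
        assert len(d.mice) == 12 and len(d.samples) == 12
        per = d.mice.groupby(["age_months", "sex"]).size()
        assert (per == 2).all()
        assert len(generate_design(8, ["kidney"], seed=1).mice) == 24

    def test_odd_group_size_rejected(self):
        with pytest.raises(ValueError, match="even"):
            generate_design(3, ["kidney"], seed=1)

    def test_determinism(self):
        a, b = (generate_design(6, ["lung", "liver"], seed=5) for _ in range(2))
        pd.testing.assert_frame_equal(a.mice, b.mice)
        pd.testing.assert_frame_equal(a.samples, b.samples)

    def test_invariants_enforced(self):
        d = generate_design(2, ["kidney"], seed=0)
        bad = d.samples.copy()
        bad.loc[0, "mouse_id"] = "ghost"
        with pytest.raises(ValueError, match="unknown mice"):
            StudyDesign(mice=d.mice, tissues=d.tissues, samples=bad)


class TestComposition:
    cell_types = [f"ct{i}" for i in range(4)]
    baseline = np.array([0.4, 0.3, 0.2, 0.1])

    def test_rows_sum_to_total(self):
        d = generate_design(4, ["kidney"], seed=0)
        tab = generate_composition(d, self.cell_types, self.baseline, PlantedEffects(),
                                   total_cells_per_sample=1000, seed=0)
        assert (tab.sum(axis=1) == 1000).all()

    def test_null_high_concentration_matches_baseline(self):
        d = generate_design(8, ["kidney"], seed=0)
        tab = generate_composition(d, self.cell_types, self.baseline, PlantedEffects(),
                                   total_cells_per_sample=5000, concentration=1e7, seed=2)
        frac = (tab / 5000).mean(axis=0)
        assert np.allclose(frac, self.baseline, atol=0.01)

    def test_planted_slope_shifts_mean_fraction(self):
        # Monte-Carlo check against the planted softmax mean function
        eff = PlantedEffects(composition_slopes={"ct0": (0.01, 0.0)})
        d = generate_design(4, ["kidney"], seed=0)
        meta = d.sample_meta
        fracs_young, fracs_old = [], []
        for rep in range(100):
            tab = generate_composition(d, self.cell_types, self.baseline, eff,
                                       total_cells_per_sample=2000, seed=rep)
            f = tab["ct0"] / 2000
            fracs_young.append(f[meta.age_months == 1].mean())
            fracs_old.append(f[meta.age_months == 21].mean())
        assert np.mean(fracs_old) > np.mean(fracs_young)
        exp_old = expected_fractions(self.baseline, self.cell_types, eff, 21, "M")[0]
        assert abs(np.mean(fracs_old) - exp_old) < 0.01

    def test_negative_baseline_rejected(self):
        d = generate_design(2, ["kidney"], seed=0)
        with pytest.raises(ValueError, match="positive"):
            generate_composition(d, self.cell_types, np.array([0.5, 0.6, -0.05, -0.05]),
                                 PlantedEffects(), seed=0)


class TestPeakUniverse:
    def test_sizes_and_bounds(self):
        summits, genes, sizes = generate_peak_universe(1, 1_000_000, 10, 100, seed=3,
                                                       groups=["g1"], group_subset=1.0)
        assert len(genes) == 10
        sub = summits["g1"]
        assert len(sub) == 100
        assert (sub["start"] >= 250).all()
        assert (sub["start"] < 1_000_000 - 250).all()
        assert genes["strand"].isin(["+", "-"]).all()

    def test_promoter_fraction_controllable(self):
        summits, genes, _ = generate_peak_universe(
            2, 4_000_000, 40, 400, seed=9, promoter_fraction=0.10,
            groups=["g1"], group_subset=1.0,
        )
        sub = summits["g1"]
        near = 0
        for chrom, grp in sub.groupby("chrom"):
            tss = np.sort(genes.loc[genes.chrom == chrom, "tss"].to_numpy())
            pos = grp["start"].to_numpy()
            i = np.searchsorted(tss, pos)
            for p, j in zip(pos, i):
                d = min(
                    [abs(p - tss[j - 1])] if j > 0 else [np.inf],
                    default=np.inf,
                )
                if j < len(tss):
                    d = min(d, abs(p - tss[j]))
                near += d <= 1000
        assert 0.05 <= near / len(sub) <= 0.2

    def test_determinism(self):
        a = generate_peak_universe(1, 1_000_000, 5, 50, seed=4)
        b = generate_peak_universe(1, 1_000_000, 5, 50, seed=4)
        for g in a[0]:
            pd.testing.assert_frame_equal(a[0][g], b[0][g])
        pd.testing.assert_frame_equal(a[1], b[1])

    def test_too_small_chromosome_rejected(self):
        with pytest.raises(ValueError, match="too small"):
            generate_peak_universe(1, 10_000, 2, 500, seed=0)


class TestCounts:
    def _design(self):
        return generate_design(4, ["kidney"], seed=0)

    def test_null_poisson_means_match_baseline(self):
        d = self._design()
        peaks = _toy_peaks()
        cell_table = pd.DataFrame(200, index=d.sample_meta["sample"], columns=["ct0"])
        counts, meta = generate_counts(d, cell_table, peaks, PlantedEffects(),
                                       nb_dispersion=0.0, baseline_mean=0.3,
                                       seed=1)
        # per-peak mean across all cells should sit near its lognormal base
        means = np.asarray(counts.mean(axis=0)).ravel()
        assert means.mean() == pytest.approx(0.3 * np.exp(0.5**2 / 2), rel=0.2)
        assert counts.min() >= 0

    def test_planted_lfc_fold_change(self):
        d = self._design()
        peaks = _toy_peaks()
        eff = PlantedEffects(da_effects={"p0": {"lfc_per_month": 0.1, "sex_scope": "shared",
                                                "cell_types": None}})
        cell_table = pd.DataFrame(400, index=d.sample_meta["sample"], columns=["ct0"])
        counts, meta = generate_counts(d, cell_table, peaks, eff, nb_dispersion=0.0,
                                       da_peak_mean=0.5, seed=2)
        col = np.asarray(counts[:, 0].todense()).ravel()
        young = col[(meta.age_months == 1).to_numpy()].mean()
        old = col[(meta.age_months == 21).to_numpy()].mean()
        assert old / young == pytest.approx(np.exp(0.1 * 20), rel=0.15)

    def test_empty_cell_table(self):
        d = self._design()
        cell_table = pd.DataFrame(0, index=d.sample_meta["sample"], columns=["ct0"])
        counts, meta = generate_counts(d, cell_table, _toy_peaks(), PlantedEffects(), seed=0)
        assert counts.shape == (0, 20) and len(meta) == 0

    def test_unknown_peak_in_effects_rejected(self):
        d = self._design()
        eff = PlantedEffects(da_effects={"ghost": {"lfc_per_month": 0.1,
                                                   "sex_scope": "shared", "cell_types": None}})
        cell_table = pd.DataFrame(10, index=d.sample_meta["sample"], columns=["ct0"])
        with pytest.raises(ValueError, match="unknown peak"):
            generate_counts(d, cell_table, _toy_peaks(), eff, seed=0)


class TestEmbeddings:
    def _meta(self, n=400):
        rng = np.random.default_rng(0)
        return pd.DataFrame(
            {
                "cell_id": [f"c{i}" for i in range(n)],
                "cell_type": "ct0",
                "sex": rng.choice(["F", "M"], n),
            }
        )

    def test_shape(self):
        meta = self._meta(10)
        emb = generate_embeddings(meta, dim=2, noise_sd=1.0, seed=0)
        assert emb.shape == (10, 2)

    def test_zero_separation_sexes_identical_in_law(self):
        meta = self._meta()
        emb = generate_embeddings(meta, dim=5, sex_separation={}, noise_sd=1.0, seed=1)
        f = emb[(meta.sex == "F").to_numpy()]
        m = emb[(meta.sex == "M").to_numpy()]
        assert np.linalg.norm(f.mean(axis=0) - m.mean(axis=0)) < 0.5

    def test_planted_separation_magnitude(self):
        meta = self._meta(2000)
        emb = generate_embeddings(meta, dim=5, sex_separation={"ct0": 4.0}, noise_sd=1.0, seed=2)
        f = emb[(meta.sex == "F").to_numpy()].mean(axis=0)
        m = emb[(meta.sex == "M").to_numpy()].mean(axis=0)
        assert np.linalg.norm(f - m) == pytest.approx(4.0, abs=0.3)

    def test_bad_noise_rejected(self):
        with pytest.raises(ValueError, match="noise_sd"):
            generate_embeddings(self._meta(5), dim=3, noise_sd=0.0, seed=0)


class TestMotifsSignatures:
    def test_planted_fold_binomial_mean(self):
        peaks = _toy_peaks(1100)
        eff = PlantedEffects(
            da_effects={
                f"p{i}": {"lfc_per_month": 0.1, "sex_scope": "shared", "cell_types": None}
                for i in range(100)
            }
        )
        genes = pd.DataFrame({"gene": [f"g{i}" for i in range(200)]})
        ann, sigs, cmap = generate_motifs_and_signatures(
            peaks, genes, n_motifs=5, n_cytokines=2, effects=eff,
            aging_genes=[f"g{i}" for i in range(50)], seed=0,
            background_rate=0.1, planted_fold=3.0,
        )
        hits_da = ann.loc[[f"p{i}" for i in range(100)], "motif0000"].sum()
        assert 18 <= hits_da <= 42  # binomial(100, 0.3)
        bg_rate = ann.loc[[f"p{i}" for i in range(100, 1100)], "motif0000"].mean()
        assert 0.07 <= bg_rate <= 0.13

    def test_planted_overlap_exact_and_support_genes(self):
        peaks = _toy_peaks(50)
        genes = pd.DataFrame({"gene": [f"g{i}" for i in range(200)]})
        eff = PlantedEffects(signature_overlap={"cytokine000": 7})
        ann, sigs, cmap = generate_motifs_and_signatures(
            peaks, genes, 2, 3, eff, aging_genes=[f"g{i}" for i in range(40)],
            seed=1, signature_size=20,
        )
        aging = {f"g{i}" for i in range(40)}
        assert len(set(sigs["cytokine000"]) & aging) == 7
        roles = cmap.groupby("cytokine")["role"].apply(set)
        assert all({"secretion", "receptor"} <= r for r in roles)

    def test_overlap_exceeding_signature_rejected(self):
        peaks = _toy_peaks(10)
        genes = pd.DataFrame({"gene": [f"g{i}" for i in range(100)]})
        eff = PlantedEffects(signature_overlap={"cytokine000": 30})
        with pytest.raises(ValueError, match="exceeds signature size"):
            generate_motifs_and_signatures(peaks, genes, 1, 1, eff,
                                           aging_genes=[f"g{i}" for i in range(50)],
                                           seed=0, signature_size=20)
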