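"""Cell-population dynamics: fractions, age x sex regression, and sex-dimorphism AUC.

The central model is, per tissue and cell type, an ordinary least squares fit
of the cell-type fraction on age with a sex main effect and an age x sex
interaction:

    fraction ~ b0 + b_age * age_months + b_sex * 1[female]
               + b_int * age_months * 1[female]

Aging association is the joint F-test of {b_age, b_int} against the sex-only
null, so cell types whose two sexes move in opposite directions (which can
leave the marginal age slope near zero) are still detected. A cell type is
called aging-associated when its Benjamini-Hochberg q-value is below 0.05 and
the model R^2 exceeds 0.4, and sex-interacting when additionally the
interaction q-value is below 0.05.

Sex dimorphism of chromatin state is quantified separately: a k-nearest
neighbour classifier distinguishes female from male cells of one cell type and
age group in embedding space, and cell types with cross-validated AUC > 0.9
are flagged dimorphic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
from sklearn.metrics import roc_auc_score
from sklearn.neighbors import KNeighborsClassifier
from statsmodels.stats.multitest import multipletests

CATEGORIES = [
    "up",
    "down",
    "interaction-female-biased",
    "interaction-male-biased",
    "interaction-opposite",
    "ns",
]


def compute_fractions(
    cell_meta: pd.DataFrame,
    level: str = "main",
) -> dict[str, pd.DataFrame]:
    """Per-tissue sample x cell-type fraction tables.

    ``cell_meta`` needs columns sample, tissue and cell_type (plus subtype when
    level="subtype"). Rows sum to 1; samples with zero cells in a tissue are
    simply absent (they contribute no rows).
    """
    if level not in {"main", "subtype"}:
        raise ValueError("level must be 'main' or 'subtype'")
    label_col = "cell_type" if level == "main" else "subtype"
    tables: dict[str, pd.DataFrame] = {}
    for tissue, grp in cell_meta.groupby("tissue"):
        counts = grp.groupby(["sample", label_col], observed=True).size().unstack(fill_value=0)
        totals = counts.sum(axis=1)
        empty = totals == 0
        if empty.any():
            warnings.warn(f"{tissue}: dropping samples with zero cells: {list(counts.index[empty])}")
            counts = counts[~empty]
            totals = totals[~empty]
        tables[tissue] = counts.div(totals, axis=0)
    return tables


# ---------------------------------------------------------------------------
# age x sex regression, statsmodels-style Model/Results pair


@dataclass
class CompositionAgeModel:
    """OLS age x sex interaction model for one tissue's fraction table.

    Parameters
    ----------
    fractions : sample x cell-type fraction table (rows sum to 1).
    design : per-sample metadata with columns sample, age_months, sex (F/M).
    logit : model logit-transformed fractions instead of raw fractions
        (off by default; raw fractions are what the gates were defined on).
    """

    fractions: pd.DataFrame
    design: pd.DataFrame
    tissue: str = ""
    logit: bool = False

    def __post_init__(self) -> None:
        design = self.design.set_index("sample") if "sample" in self.design.columns else self.design
        missing = [s for s in self.fractions.index if s not in design.index]
        if missing:
            raise ValueError(f"samples missing from design: {missing}")
        self._design = design.loc[self.fractions.index]
        if self._design["age_months"].nunique() < 2:
            raise ValueError("need >= 2 distinct ages")

    def fit(self) -> "CompositionAgeResults":
        age = self._design["age_months"].to_numpy(float)
        female = (self._design["sex"] == "F").to_numpy(float)
        both_sexes = 0 < female.sum() < len(female)
        rows = []
        for ct in self.fractions.columns:
            y = self.fractions[ct].to_numpy(float)
            if self.logit:
                eps = 1e-6
                y = scipy.stats.logit(np.clip(y, eps, 1 - eps))
            rows.append(self._fit_one(ct, y, age, female, both_sexes))
        table = pd.DataFrame(rows)
        table["q_age"] = adjust_fdr(table["p_age"].to_numpy())
        table["q_int"] = adjust_fdr(table["p_int"].to_numpy())
        return CompositionAgeResults(table=table, tissue=self.tissue)

    @staticmethod
    def _fit_one(ct, y, age, female, both_sexes):
        if both_sexes:
            X = np.column_stack([np.ones_like(age), age, female, age * female])
            X_null = np.column_stack([np.ones_like(age), female])
        else:
            X = np.column_stack([np.ones_like(age), age])
            X_null = np.ones((len(age), 1))
        full = sm.OLS(y, X).fit()
        null = sm.OLS(y, X_null).fit()
        f_stat, p_age, _ = full.compare_f_test(null)
        if np.var(y) == 0:
            p_age = 1.0
        beta_age = full.params[1]
        if both_sexes:
            beta_sex, beta_int = full.params[2], full.params[3]
            p_int = full.pvalues[3] if np.var(y) > 0 else 1.0
        else:
            beta_sex = beta_int = np.nan
            p_int = np.nan
        n = len(y)
        ages_c = age - age.mean()
        denom = np.sqrt((ages_c**2).sum() * ((y - y.mean()) ** 2).sum())
        pearson = float(ages_c @ (y - y.mean()) / denom) if denom > 0 else np.nan
        return {
            "tissue": "",
            "cell_type": ct,
            "beta_age": beta_age,
            "beta_sex": beta_sex,
            "beta_int": beta_int,
            "r2": 0.0 if np.var(y) == 0 else full.rsquared,
            "p_age": p_age,
            "p_int": p_int,
            "pearson_r_age": pearson,
            "n_samples": n,
            "single_sex": not both_sexes,
        }


@dataclass
class CompositionAgeResults:
    """Per-cell-type coefficient table with FDR, gates and categories."""

    table: pd.DataFrame
    tissue: str = ""

    def __post_init__(self) -> None:
        if self.tissue:
            self.table = self.table.assign(tissue=self.tissue)

    def classify(self, q_max: float = 0.05, r2_min: float = 0.4) -> pd.DataFrame:
        self.table = classify_dynamics(self.table, q_max=q_max, r2_min=r2_min)
        return self.table

    def summary(self) -> str:
        cols = ["tissue", "cell_type", "beta_age", "beta_int", "r2", "q_age", "q_int"]
        if "category" in self.table.columns:
            cols.append("category")
        with pd.option_context("display.float_format", "{:.4g}".format):
            header = f"Composition age x sex model ({self.tissue or 'all tissues'}), n cell types = {len(self.table)}"
            return header + "\n" + self.table[cols].to_string(index=False)


def adjust_fdr(pvalues: np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values; NaN p-values propagate as NaN."""
    p = np.asarray(pvalues, dtype=float)
    q = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    if (p[ok] < 0).any() or (p[ok] > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    if ok.any():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


def classify_dynamics(
    fits: pd.DataFrame,
    q_max: float = 0.05,
    r2_min: float = 0.4,
) -> pd.DataFrame:
    """Categorise fitted cell types by the stated gates.

    Aging-associated iff q_age < q_max and R^2 > r2_min; direction is the sign
    of the sex-averaged slope b_age + b_int/2. Among aging-associated cell
    types, q_int < q_max marks a sex interaction, subdivided into
    female-biased / male-biased (larger |slope| in that sex) or opposite when
    the sex-specific slopes disagree in sign.
    """
    out = fits.copy()
    cats = []
    for _, row in out.iterrows():
        significant = (
            pd.notna(row["q_age"]) and row["q_age"] < q_max and row["r2"] > r2_min
        )
        if not significant:
            cats.append("ns")
            continue
        slope_m = row["beta_age"]
        slope_f = row["beta_age"] + (0.0 if pd.isna(row["beta_int"]) else row["beta_int"])
        mean_slope = (slope_f + slope_m) / 2
        if pd.notna(row["q_int"]) and row["q_int"] < q_max:
            if slope_f * slope_m < 0:
                cats.append("interaction-opposite")
            elif abs(slope_f) >= abs(slope_m):
                cats.append("interaction-female-biased")
            else:
                cats.append("interaction-male-biased")
        else:
            cats.append("up" if mean_slope > 0 else "down")
    out["category"] = pd.Categorical(cats, categories=CATEGORIES)
    return out


def age_correlation(fractions: pd.DataFrame, ages: pd.Series) -> pd.Series:
    """Pearson r of fraction vs age_months per cell type; NaN on zero variance."""
    if len(fractions) < 3:
        raise ValueError("need >= 3 samples for a correlation")
    a = ages.loc[fractions.index].to_numpy(float)
    out = {}
    for ct in fractions.columns:
        y = fractions[ct].to_numpy(float)
        if np.std(y) == 0 or np.std(a) == 0:
            out[ct] = np.nan
        else:
            out[ct] = scipy.stats.pearsonr(y, a).statistic
    return pd.Series(out, name="pearson_r_age")


def knn_sex_auc(
    embedding: np.ndarray,
    sex: np.ndarray | pd.Series,
    k: int = 25,
    n_folds: int = 5,
    seed: int = 0,
    auc_min: float = 0.9,
) -> dict:
    """Cross-validated KNN female-vs-male AUC on chromatin embeddings.

    The majority sex is down-sampled to the minority count (seeded), then a
    stratified K-fold KNN produces, per held-out cell, the fraction of female
    neighbours among its k nearest training cells; the AUC of that score
    against true sex is returned. Swapping the sex labels mirrors the score
    around 0.5, leaving AUC unchanged.
    """
    sex = np.asarray(sex)
    embedding = np.asarray(embedding, dtype=float)
    labels = np.unique(sex)
    if not set(labels) <= {"F", "M"} or len(labels) < 2:
        raise ValueError("need both sexes F and M")
    # one global seeded permutation drives both the majority down-sampling and
    # the fold assignment; neither depends on which sex is called F, so
    # swapping labels mirrors the score around 0.5 and leaves AUC unchanged
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(sex))
    idx_f = [i for i in perm if sex[i] == "F"]
    idx_m = [i for i in perm if sex[i] == "M"]
    n_min = min(len(idx_f), len(idx_m))
    idx = np.array(idx_f[:n_min] + idx_m[:n_min])
    X, y = embedding[idx], (sex[idx] == "F").astype(int)
    n = len(y)
    if n < 2 * k:
        k_eff = max(1, n // 2)
        warnings.warn(f"too few cells for k={k}; reduced to {k_eff}")
        k = k_eff
    folds = np.empty(n, dtype=int)
    folds[:n_min] = np.arange(n_min) % n_folds  # round-robin within each sex
    folds[n_min:] = np.arange(n_min) % n_folds
    scores = np.zeros(n)
    for f in range(n_folds):
        train = np.flatnonzero(folds != f)
        test = np.flatnonzero(folds == f)
        k_fold = min(k, len(train))
        clf = KNeighborsClassifier(n_neighbors=k_fold)
        clf.fit(X[train], y[train])
        proba = clf.predict_proba(X[test])
        scores[test] = proba[:, list(clf.classes_).index(1)]
    auc = float(roc_auc_score(y, scores))
    return {
        "auc": auc,
        "n_cells": n,
        "k_neighbors": k,
        "dimorphic": auc > auc_min,
    }
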