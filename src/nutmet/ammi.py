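"""AMMI: additive main effects and multiplicative interaction.

The genotype × environment cell-mean table Ȳ_ij is decomposed as

    Ȳ_ij = μ + g_i + e_j + Σ_k λ_k α_ik γ_jk + ρ_ij,

where μ, g_i, e_j come from the two-way ANOVA (row/column means) and the
interaction term is the SVD of the double-centered residual matrix
Z_ij = Ȳ_ij − Ȳ_i· − Ȳ_·j + Ȳ··. Up to min(G, E) − 1 components carry all
of the interaction, so with full rank retained ρ ≡ 0 and the
reconstruction is exact.

Scores are stored in the symmetric scaling α_ik√λ_k and γ_jk√λ_k, so the
product of a genotype score and an environment score reconstructs that
component's contribution directly. A genotype whose PC1 score is near zero
interacts little with environments — it is *stable*; the stability ranking
combines this with above/below-average mean performance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data import METDataset, TraitMatrix

__all__ = ["AMMIDecomposition", "fit_ammi", "stability_ranking", "biplot_export"]

# Singular values whose square contributes less than this fraction of the
# trait's total squared scale are treated as numerically zero.
_REL_EPS = 1e-12


@dataclass
class AMMIDecomposition:
    """Fitted AMMI model for one trait."""

    trait_name: str
    grand_mean: float
    genotype_effects: pd.Series  # ĝ_i, sum 0
    environment_effects: pd.Series  # ê_j, sum 0
    singular_values: np.ndarray  # λ_k, descending
    genotype_scores: pd.DataFrame  # (genotype, PC k), symmetric scaling
    environment_scores: pd.DataFrame  # (environment, PC k)
    variance_explained: np.ndarray  # percent of interaction SS per PC
    anova: pd.DataFrame | None  # SS/df/MS/F/p when replicated data given

    @property
    def interaction_ss(self) -> float:
        """Frobenius identity: interaction sum of squares = Σ λ_k²."""
        return float(np.sum(self.singular_values**2))

    def reconstruct(self) -> pd.DataFrame:
        """μ̂ + ĝ_i + ê_j + Σ_k score_ik·score_jk (exact at full rank)."""
        add = (
            self.grand_mean
            + self.genotype_effects.to_numpy()[:, None]
            + self.environment_effects.to_numpy()[None, :]
        )
        mult = self.genotype_scores.to_numpy() @ self.environment_scores.to_numpy().T
        return pd.DataFrame(
            add + mult,
            index=self.genotype_effects.index,
            columns=self.environment_effects.index,
        )


def _orient_signs(u: np.ndarray, vt: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Fix the arbitrary SVD sign: largest-|score| environment positive per PC."""
    for k in range(vt.shape[0]):
        j = int(np.argmax(np.abs(vt[k])))
        if vt[k, j] < 0:
            vt[k] *= -1.0
            u[:, k] *= -1.0
    return u, vt


def fit_ammi(means: TraitMatrix, replicated_data: METDataset | None = None,
             config=None) -> AMMIDecomposition:
    """Fit the AMMI model to a complete genotype × environment mean table.

    If plot-level ``replicated_data`` is supplied (with ``config`` when the
    trait is a derived nutritional yield), the two-way ANOVA F-tests for
    genotype, environment and G×E against the pooled within-cell error are
    attached.
    """
    means.require_complete()
    Y = means.values.to_numpy(dtype=float)
    n_g, n_e = Y.shape
    if n_g < 2 or n_e < 2:
        raise ValueError(f"AMMI needs at least a 2×2 table, got {n_g}×{n_e}")

    grand = float(Y.mean())
    g_eff = Y.mean(axis=1) - grand
    e_eff = Y.mean(axis=0) - grand
    Z = Y - Y.mean(axis=1, keepdims=True) - Y.mean(axis=0, keepdims=True) + grand

    n_pc = min(n_g, n_e) - 1
    u, s, vt = np.linalg.svd(Z, full_matrices=False)
    u, s, vt = u[:, :n_pc], s[:n_pc], vt[:n_pc]
    # zero out numerically-null components (additive data)
    scale = max(float(np.abs(Y).max()), 1.0)
    s = np.where(s < np.sqrt(_REL_EPS) * scale, 0.0, s)
    u, vt = _orient_signs(u, vt)

    ss_int = float(np.sum(s**2))
    if ss_int > 0:
        var_exp = 100.0 * s**2 / ss_int
    else:
        var_exp = np.zeros_like(s)

    root = np.sqrt(s)
    pcs = [f"PC{k + 1}" for k in range(n_pc)]
    g_scores = pd.DataFrame(u * root, index=means.values.index, columns=pcs)
    e_scores = pd.DataFrame(vt.T * root, index=means.values.columns, columns=pcs)

    anova = None
    if replicated_data is not None:
        anova = _anova_table(means, replicated_data, g_eff, e_eff, ss_int, config)

    return AMMIDecomposition(
        trait_name=means.trait_name,
        grand_mean=grand,
        genotype_effects=pd.Series(g_eff, index=means.values.index, name="genotype_effect"),
        environment_effects=pd.Series(
            e_eff, index=means.values.columns, name="environment_effect"
        ),
        singular_values=s,
        genotype_scores=g_scores,
        environment_scores=e_scores,
        variance_explained=var_exp,
        anova=anova,
    )


def _anova_table(means: TraitMatrix, data: METDataset, g_eff, e_eff,
                 ss_int: float, config) -> pd.DataFrame:
    """Two-way ANOVA with G/E/G×E tested against pooled within-cell error."""
    from .nutrition import plot_nutritional_yields

    trait = means.trait_name
    if trait == "yield" or trait.startswith("ny_"):
        if config is None:
            raise ValueError("config required for ANOVA on yield/nutritional-yield traits")
        table = plot_nutritional_yields(data, config)
        col = "yield_adj" if trait == "yield" else trait
    else:
        table = data.to_frame().rename(columns={f"conc_{trait}_mg_kg": "value"})
        col = "value"
    reps = means.rep_counts.to_numpy()
    if not (reps == reps.flat[0]).all() or reps.flat[0] < 2:
        raise ValueError("ANOVA F-tests need balanced replication with r ≥ 2")
    r = int(reps.flat[0])
    n_g, n_e = means.values.shape

    cell = means.values.stack().rename("cell_mean")
    merged = table.merge(cell, left_on=["genotype", "environment"], right_index=True)
    ss_err = float(np.sum((merged[col] - merged["cell_mean"]) ** 2))
    df_err = n_g * n_e * (r - 1)

    rows = {
        "genotype": (r * n_e * float(np.sum(g_eff**2)), n_g - 1),
        "environment": (r * n_g * float(np.sum(e_eff**2)), n_e - 1),
        "gxe": (r * ss_int, (n_g - 1) * (n_e - 1)),
        "residual": (ss_err, df_err),
    }
    out = pd.DataFrame(
        {name: {"SS": ss, "df": df} for name, (ss, df) in rows.items()}
    ).T
    out["MS"] = out["SS"] / out["df"]
    ms_err = out.loc["residual", "MS"]
    out["F"] = np.nan
    out["p"] = np.nan
    if ms_err > 0:
        for name in ("genotype", "environment", "gxe"):
            f = out.loc[name, "MS"] / ms_err
            out.loc[name, "F"] = f
            out.loc[name, "p"] = stats.f.sf(f, out.loc[name, "df"], df_err)
    return out


def stability_ranking(decomp: AMMIDecomposition,
                      performance_means: pd.Series) -> pd.DataFrame:
    """Rank genotypes by stability (|PC1| ascending) within performance class.

    Genotypes are split at the grand mean of their performance means;
    above-average genotypes are listed first, each class ordered by |PC1|
    ascending. When every PC1 score is zero (purely additive data) the
    ordering falls back to performance descending. All ties break
    lexicographically by genotype name.
    """
    perf = performance_means.reindex(decomp.genotype_scores.index)
    pc1 = decomp.genotype_scores["PC1"]
    above = perf >= perf.mean()
    df = pd.DataFrame(
        {
            "performance": perf,
            "PC1": pc1,
            "abs_PC1": pc1.abs(),
            "above_average": above,
        }
    )
    # deterministic full ordering: class, |PC1| asc, performance desc, name
    df["_neg_perf"] = -df["performance"]
    df = (
        df.reset_index()
        .rename(columns={"index": "genotype"})
        .sort_values(
            by=["above_average", "abs_PC1", "_neg_perf", "genotype"],
            ascending=[False, True, True, True],
            kind="mergesort",
        )
        .drop(columns="_neg_perf")
        .set_index("genotype")
    )
    df["rank"] = np.arange(1, len(df) + 1)
    return df


def biplot_export(decomp: AMMIDecomposition,
                  performance_means: pd.Series) -> pd.DataFrame:
    """Biplot coordinates: one row per genotype and per environment.

    Columns: label, entity class, trait mean (vertical axis) and PC1/PC2
    scores (horizontal axes) — everything an external plotting tool needs
    to draw the mean-vs-PC1 stability biplot.
    """
    n_pc = decomp.genotype_scores.shape[1]
    pcs = ["PC1"] + (["PC2"] if n_pc >= 2 else [])
    env_means = (
        decomp.grand_mean + decomp.environment_effects
    )
    rows = []
    for g in decomp.genotype_scores.index:
        row = {
            "label": g,
            "entity": "genotype",
            "mean": float(performance_means.loc[g]),
        }
        for pc in pcs:
            row[pc] = float(decomp.genotype_scores.loc[g, pc])
        rows.append(row)
    for e in decomp.environment_scores.index:
        row = {"label": e, "entity": "environment", "mean": float(env_means.loc[e])}
        for pc in pcs:
            row[pc] = float(decomp.environment_scores.loc[e, pc])
        rows.append(row)
    return pd.DataFrame(rows)
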