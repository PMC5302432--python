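"""Nutritional yield and nutrient density.

Nutritional yield converts agronomic yield into a nutrition-centric unit:
the number of adults whose full yearly recommended intake of one mineral
is supplied by one hectare,

    NY = yield [kg·ha⁻¹] × concentration [mg·kg⁻¹] / (DRI [mg·day⁻¹] × 365),

in adults·ha⁻¹·year⁻¹. Nutrient density is expressed inversely as the
grams of wholemeal that must be eaten per day to reach 100% of the DRI,
1000 × DRI / concentration.

Hulled wheats (spelt, emmer, einkorn) are first put on a naked-grain basis
by multiplying yield by the dehulling factor (default 0.75).

Genotype-level summaries average *per-plot* nutritional yields, not the
formula applied to mean yield × mean concentration; the two differ whenever
yield and concentration co-vary across plots (they do, negatively).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .data import (
    AnalysisConfig,
    IncompleteDataError,
    METDataset,
    TraitMatrix,
)

__all__ = [
    "dehull_adjust",
    "nutritional_yield",
    "amount_for_dri",
    "plot_nutritional_yields",
    "genotype_summary",
    "population_summary",
    "trait_cell_means",
    "correlation_matrix",
    "variance_partition",
]


def dehull_adjust(yield_raw, is_hulled, factor: float = 0.75):
    """Naked-grain yield: ``factor × yield_raw`` when hulled, else unchanged.

    Vectorised over numpy arrays / pandas Series.
    """
    if not (0 < factor <= 1):
        raise ValueError(f"dehulling factor must be in (0, 1], got {factor}")
    y = np.asarray(yield_raw, dtype=float)
    if np.any(y < 0):
        raise ValueError("yield must be nonnegative")
    out = np.where(np.asarray(is_hulled, dtype=bool), factor * y, y)
    return out if out.ndim else float(out)


def nutritional_yield(yield_adj, conc, dri: float, year_days: float = 365.0):
    """Adults fed 100% of a mineral's DRI by one hectare for one year.

    Parameters are the dehulling-adjusted yield (kg·ha⁻¹), wholemeal
    concentration (mg·kg⁻¹), DRI (mg·day⁻¹) and days per year.
    """
    if dri <= 0:
        raise ValueError(f"DRI must be positive, got {dri}")
    if year_days <= 0:
        raise ValueError(f"year_days must be positive, got {year_days}")
    y = np.asarray(yield_adj, dtype=float)
    c = np.asarray(conc, dtype=float)
    if np.any(y < 0) or np.any(c < 0):
        raise ValueError("yield and concentration must be nonnegative")
    out = y * c / (dri * year_days)
    return out if out.ndim else float(out)


def amount_for_dri(conc, dri: float):
    """Grams of wholemeal per day supplying 100% of the DRI: 1000·DRI/conc."""
    if dri <= 0:
        raise ValueError(f"DRI must be positive, got {dri}")
    c = np.asarray(conc, dtype=float)
    if np.any(c <= 0):
        raise ValueError(
            "nutrient density undefined at zero concentration"
        )
    out = 1000.0 * dri / c
    return out if out.ndim else float(out)


def plot_nutritional_yields(data: METDataset, config: AnalysisConfig) -> pd.DataFrame:
    """Per-plot nutritional yields for every configured mineral.

    Returns a long table with one row per plot and columns ``genotype``,
    ``group``, ``environment``, ``replicate``, ``yield_adj`` and one
    ``ny_<mineral>`` column per mineral in the DRI map.
    """
    config.validate_against(data)
    df = data.to_frame()
    hulled = df["group"].isin(config.hulled_groups)
    df["yield_adj"] = dehull_adjust(df["yield_kg_ha"], hulled, config.dehulling_factor)
    out = df[["genotype", "group", "environment", "replicate", "yield_adj"]].copy()
    for m, dri in config.dri.items():
        out[f"ny_{m}"] = nutritional_yield(
            df["yield_adj"], df[f"conc_{m}_mg_kg"], dri, config.year_days
        )
    return out


def genotype_summary(ny_table: pd.DataFrame) -> pd.DataFrame:
    """Genotype means and sample SDs of adjusted yield and nutritional yields.

    Input is the long table from :func:`plot_nutritional_yields`; the mean
    for each genotype is taken over all its plots (N = environments ×
    replicates) and the SD uses N−1 in the denominator.
    """
    if ny_table.empty:
        raise ValueError("empty nutritional-yield table")
    value_cols = ["yield_adj"] + [c for c in ny_table.columns if c.startswith("ny_")]
    grouped = ny_table.groupby("genotype", sort=False)[value_cols]
    means = grouped.mean()
    sds = grouped.std(ddof=1)
    groups = ny_table.groupby("genotype", sort=False)["group"].first()
    out = means.join(sds, lsuffix="", rsuffix="_sd")
    out.insert(0, "group", groups)
    return out


def population_summary(summary: pd.DataFrame) -> pd.Series:
    """Unweighted mean over genotypes of each genotype-mean column."""
    cols = [c for c in summary.columns if c == "yield_adj" or
            (c.startswith("ny_") and not c.endswith("_sd"))]
    return summary[cols].mean()


def trait_cell_means(data: METDataset, trait: str, config: AnalysisConfig) -> TraitMatrix:
    """Genotype × environment cell means for yield, a concentration, or NY.

    ``trait`` may be ``"yield"`` (dehulling-adjusted), a mineral name (raw
    wholemeal concentration) or ``"ny_<mineral>"`` (nutritional yield).
    Cell means average over replicates; this is the matrix AMMI and the
    per-environment summaries operate on.
    """
    if trait in data.minerals:
        from .data import cell_means

        return cell_means(data, trait)
    ny = plot_nutritional_yields(data, config)
    if trait == "yield":
        col = "yield_adj"
    elif trait in ny.columns:
        col = trait
    else:
        raise KeyError(
            f"unknown trait {trait!r}; expected 'yield', 'ny_<mineral>' or a mineral name"
        )
    grouped = ny.groupby(["genotype", "environment"], sort=False)[col]
    means = grouped.mean().unstack()
    counts = grouped.size().unstack()
    means = means.reindex(index=data.genotypes, columns=data.environments)
    counts = counts.reindex(index=data.genotypes, columns=data.environments).fillna(0).astype(int)
    tm = TraitMatrix(values=means, trait_name=trait, rep_counts=counts)
    tm.require_complete()
    return tm


def correlation_matrix(data: METDataset, config: AnalysisConfig,
                       traits: list[str] | None = None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pearson correlations among traits over genotype × environment cells.

    Each observation is one genotype-in-environment cell mean (n =
    genotypes × environments). Returns ``(r, p)`` DataFrames; the r matrix
    is symmetric with unit diagonal and p-values come from the two-sided
    t-test. A zero-variance trait yields NaN off-diagonals (flagged by a
    warning) rather than an error.
    """
    if traits is None:
        traits = ["yield"] + [f"ny_{m}" for m in config.dri]
    stacked = {t: trait_cell_means(data, t, config).values.stack() for t in traits}
    frame = pd.DataFrame(stacked)
    n = len(frame)
    if n < 3:
        raise ValueError("need at least 3 paired observations for correlations")
    r = pd.DataFrame(np.eye(len(traits)), index=traits, columns=traits)
    p = pd.DataFrame(np.zeros((len(traits), len(traits))), index=traits, columns=traits)
    for i, a in enumerate(traits):
        for j, b in enumerate(traits):
            if j <= i:
                continue
            xa, xb = frame[a].to_numpy(), frame[b].to_numpy()
            if np.std(xa) == 0 or np.std(xb) == 0:
                warnings.warn(f"zero variance in {a if np.std(xa) == 0 else b}; "
                              f"correlation undefined", stacklevel=2)
                rij, pij = np.nan, np.nan
            else:
                rij, pij = stats.pearsonr(xa, xb)
            r.loc[a, b] = r.loc[b, a] = rij
            p.loc[a, b] = p.loc[b, a] = pij
    return r, p


def variance_partition(data: METDataset, trait: str, config: AnalysisConfig) -> pd.Series:
    """Share of the total sum of squares by genotype, environment, G×E, residual.

    Two-way fixed-effects ANOVA decomposition on plot-level values of the
    trait; requires a complete genotype × environment layout. With a single
    replicate everywhere, interaction and residual are confounded and are
    reported jointly under ``gxe_plus_residual`` with a warning. Proportions
    sum to 1; all-constant data has no variance to attribute and returns NaN.
    """
    tm = trait_cell_means(data, trait, config)
    if trait == "yield":
        col, table = "yield_adj", plot_nutritional_yields(data, config)
    elif trait.startswith("ny_"):
        col, table = trait, plot_nutritional_yields(data, config)
    else:
        col, table = "value", None
    if table is None:
        from .data import _trait_series

        table = _trait_series(data, trait)
        table = table.merge(data.to_frame()[["genotype", "environment", "replicate"]],
                            left_index=True, right_index=True, suffixes=("", "_r"))
    y = table[col].to_numpy(dtype=float)
    grand = y.mean()
    ss_total = float(np.sum((y - grand) ** 2))

    cell = tm.values
    reps = tm.rep_counts.to_numpy()
    g_means = table.groupby("genotype", sort=False)[col].mean()
    e_means = table.groupby("environment", sort=False)[col].mean()
    n_per_g = table.groupby("genotype", sort=False)[col].size()
    n_per_e = table.groupby("environment", sort=False)[col].size()
    ss_g = float(np.sum(n_per_g * (g_means - grand) ** 2))
    ss_e = float(np.sum(n_per_e * (e_means - grand) ** 2))
    # interaction SS from cell means, weighted by replicate counts
    dev = (cell.sub(g_means.reindex(cell.index), axis=0)
               .sub(e_means.reindex(cell.columns), axis=1) + grand)
    ss_ge = float(np.nansum(reps * dev.to_numpy() ** 2))
    # residual: within-cell variation
    cell_per_plot = table.merge(
        cell.stack().rename("cell_mean"),
        left_on=["genotype", "environment"], right_index=True,
    )
    ss_res = float(np.sum((cell_per_plot[col] - cell_per_plot["cell_mean"]) ** 2))

    if ss_total == 0:
        warnings.warn(f"trait {trait!r} is constant; variance proportions undefined",
                      stacklevel=2)
        return pd.Series(
            {"genotype": np.nan, "environment": np.nan, "gxe": np.nan, "residual": np.nan},
            name=trait,
        )
    if (reps <= 1).all():
        warnings.warn(
            "single replicate per cell: G×E and residual are confounded", stacklevel=2
        )
        return pd.Series(
            {
                "genotype": ss_g / ss_total,
                "environment": ss_e / ss_total,
                "gxe_plus_residual": (ss_ge + ss_res) / ss_total,
            },
            name=trait,
        )
    return pd.Series(
        {
            "genotype": ss_g / ss_total,
            "environment": ss_e / ss_total,
            "gxe": ss_ge / ss_total,
            "residual": ss_res / ss_total,
        },
        name=trait,
    )
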