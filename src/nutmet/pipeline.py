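"""End-to-end orchestration: from plot table to balanced-genotype ranking.

Every step lives in its own module; this one wires them together in the
order of the analysis — nutritional yields, AMMI stability per trait,
BLUP harmonic-mean statistics per trait, selection indexes, and the
aggregate ranking — and renders the result tables the CLI and the
analysis scripts write to disk.
"""

from __future__ import annotations

import json
import platform
from pathlib import Path

import numpy as np
import pandas as pd

from . import ammi as ammi_mod
from . import blup as blup_mod
from . import nutrition, reference, selection
from .data import AnalysisConfig, METDataset, round_half_away

__all__ = [
    "analysis_traits",
    "nutritional_yield_tables",
    "comparison_table",
    "ammi_tables",
    "blup_tables",
    "index_tables",
    "full_report",
    "write_tables",
    "run_manifest",
]


def analysis_traits(config: AnalysisConfig) -> list[str]:
    """Traits analysed for stability: adjusted yield plus each mineral NY."""
    return ["yield"] + [f"ny_{m}" for m in config.dri]


def nutritional_yield_tables(data: METDataset, config: AnalysisConfig):
    """Plot-level NY table, genotype summary, and rounded report table."""
    plots = nutrition.plot_nutritional_yields(data, config)
    summary = nutrition.genotype_summary(plots)
    report = summary.copy()
    value_cols = [c for c in report.columns if c != "group"]
    report[value_cols] = round_half_away(report[value_cols].to_numpy())
    population = nutrition.population_summary(summary)
    return plots, summary, report, population


def comparison_table(data: METDataset, config: AnalysisConfig) -> pd.DataFrame:
    """Cross-system comparison: concentration, NY and grams-per-DRI rows.

    Study genotypes are summarised from plot-level data (mean yield, mean
    concentration, mean per-plot NY); externally published wheats carry a
    single (yield, concentration) pair, so their NY comes straight from
    the formula. Grams-per-day to reach 100% DRI always uses the mean
    concentration. Values are reported rounded to integers.
    """
    minerals = list(config.dri)
    plots = nutrition.plot_nutritional_yields(data, config)
    summary = nutrition.genotype_summary(plots)

    rows = []
    study = [g for g in reference.study_concentrations().index if g in summary.index]
    conc_means = {
        m: data.to_frame().groupby("genotype", sort=False)[f"conc_{m}_mg_kg"].mean()
        for m in minerals
    }
    for g in study:
        row = {"genotype": g, "system": "this_trial",
               "yield_kg_ha": round_half_away(summary.loc[g, "yield_adj"])}
        for m in minerals:
            c = conc_means[m].loc[g]
            row[f"conc_{m}"] = float(np.round(c, 1))
            row[f"ny_{m}"] = round_half_away(summary.loc[g, f"ny_{m}"])
            row[f"grams_{m}"] = round_half_away(nutrition.amount_for_dri(c, config.dri[m]))
        rows.append(row)
    lit = reference.literature_rows()
    for g, lrow in lit.iterrows():
        row = {"genotype": g, "system": lrow["system"],
               "yield_kg_ha": round_half_away(lrow["yield_kg_ha"])}
        for m in minerals:
            c = lrow[m]
            if np.isnan(c):
                row[f"conc_{m}"] = row[f"ny_{m}"] = row[f"grams_{m}"] = np.nan
                continue
            row[f"conc_{m}"] = c
            row[f"ny_{m}"] = round_half_away(
                nutrition.nutritional_yield(lrow["yield_kg_ha"], c, config.dri[m],
                                            config.year_days)
            )
            row[f"grams_{m}"] = round_half_away(nutrition.amount_for_dri(c, config.dri[m]))
        rows.append(row)
    return pd.DataFrame(rows).set_index("genotype")


def ammi_tables(data: METDataset, config: AnalysisConfig, traits=None):
    """AMMI decomposition, stability ranking and biplot export per trait."""
    out = {}
    for trait in traits or analysis_traits(config):
        tm = nutrition.trait_cell_means(data, trait, config)
        decomp = ammi_mod.fit_ammi(tm, replicated_data=data, config=config)
        perf = tm.values.mean(axis=1)
        ranking = ammi_mod.stability_ranking(decomp, perf)
        biplot = ammi_mod.biplot_export(decomp, perf)
        out[trait] = {"decomposition": decomp, "ranking": ranking, "biplot": biplot}
    return out


def blup_tables(data: METDataset, config: AnalysisConfig, traits=None):
    """Variance components and HMGV/RPGV/HMRPGV statistics per trait."""
    out = {}
    for trait in traits or analysis_traits(config):
        vc = blup_mod.fit_random_genotype_model(data, trait, config)
        table = blup_mod.predict_genotypic_values(vc, data, trait, config)
        table = blup_mod.hmgv_rpgv_hmrpgv(table)
        out[trait] = table
    return out


def index_tables(data: METDataset, config: AnalysisConfig):
    """EMI and BDGI over the genotype-mean nutritional yields."""
    plots = nutrition.plot_nutritional_yields(data, config)
    summary = nutrition.genotype_summary(plots)
    minerals = list(config.dri)
    trait_means = summary[[f"ny_{m}" for m in minerals]].rename(
        columns={f"ny_{m}": m for m in minerals}
    )
    emi = selection.elston_index(trait_means, config.lal)
    G = selection.estimate_genotypic_covariance(
        data, [f"ny_{m}" for m in minerals], config
    )
    G = G.rename(index={f"ny_{m}": m for m in minerals},
                 columns={f"ny_{m}": m for m in minerals})
    bdgi = selection.baker_desired_gains_index(trait_means, G, config.desired_gains)
    return emi, bdgi, G


def full_report(data: METDataset, config: AnalysisConfig) -> dict[str, pd.DataFrame]:
    """Run the whole pipeline; return every result table keyed by name."""
    config.validate_against(data)
    plots, summary, report, population = nutritional_yield_tables(data, config)
    ammi_res = ammi_tables(data, config)
    blup_res = blup_tables(data, config)
    emi, bdgi, G = index_tables(data, config)

    components: dict[str, pd.Series] = {}
    for trait, res in ammi_res.items():
        components[f"ammi_{trait}"] = res["ranking"]["rank"]
    for trait, table in blup_res.items():
        components[f"blup_{trait}"] = table.stats["rank"]
    components["EMI"] = emi.ranks
    components["BDGI"] = bdgi.ranks
    balanced = selection.combined_balanced_ranking(components)

    tables: dict[str, pd.DataFrame] = {
        "nutritional_yield_plots": plots,
        "nutritional_yield_genotypes": report,
        "nutritional_yield_population": population.to_frame("mean"),
        "comparison": comparison_table(data, config),
        "index_scores": pd.DataFrame(
            {
                "EMI": emi.scores,
                "EMI_rank": emi.ranks,
                "EMI_flagged": emi.flagged,
                "BDGI": bdgi.scores,
                "BDGI_rank": bdgi.ranks,
            }
        ),
        "bdgi_coefficients": bdgi.coefficients.to_frame(),
        "balanced_ranking": balanced,
    }
    for trait, res in ammi_res.items():
        tables[f"ammi_ranking_{trait}"] = res["ranking"]
        tables[f"ammi_biplot_{trait}"] = res["biplot"]
        if res["decomposition"].anova is not None:
            tables[f"ammi_anova_{trait}"] = res["decomposition"].anova
    for trait, table in blup_res.items():
        vc = table.components
        tables[f"blup_stats_{trait}"] = table.stats
        tables[f"blup_components_{trait}"] = pd.DataFrame(
            {
                "estimate": [vc.sigma2_g, vc.sigma2_ge, vc.sigma2_eps],
            },
            index=["sigma2_g", "sigma2_ge", "sigma2_eps"],
        )
    return tables


def write_tables(tables: dict[str, pd.DataFrame], outdir: str | Path) -> list[Path]:
    """Write each result table as CSV (biplot exports as TSV)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, table in tables.items():
        if name.startswith("ammi_biplot"):
            path = outdir / f"{name}.tsv"
            table.to_csv(path, sep="\t", index=False)
        else:
            path = outdir / f"{name}.csv"
            table.to_csv(path)
        written.append(path)
    return written


def run_manifest(config: AnalysisConfig, seed: int | None = None,
                 extra: dict | None = None) -> dict:
    """JSON-serialisable record of the run: config echo, seed, versions."""
    from importlib.metadata import version as _dist_version

    import scipy
    import yaml as _yaml

    from . import __version__

    manifest = {
        "nutmet_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scipy": scipy.__version__,
        "click": _dist_version("click"),
        "pyyaml": _yaml.__version__,
        "seed": seed,
        "config": {
            "dri": config.dri,
            "year_days": config.year_days,
            "dehulling_factor": config.dehulling_factor,
            "hulled_groups": sorted(config.hulled_groups),
            "lal": config.lal,
            "desired_gains": config.desired_gains,
            "above_average_rule": config.above_average_rule,
            "rounding": config.rounding,
        },
    }
    if extra:
        manifest.update(extra)
    return manifest


def write_manifest(manifest: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n",
                          encoding="utf-8")
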