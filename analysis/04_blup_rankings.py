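"""BLUP genotypic values and HMGV/RPGV/HMRPGV rankings per trait.

Fits the environment-fixed mixed model to yield and each mineral
nutritional yield, predicts genotypic values per year, and ranks
genotypes by the harmonic mean of relative performance (HMRPGV), which
rewards level, stability and adaptability simultaneously.
"""

from pathlib import Path

from nutmet import AnalysisConfig, read_met_table
from nutmet.pipeline import blup_tables

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results"


def main() -> None:
    config = AnalysisConfig()
    path = OUT / "trial_plots.csv"
    if not path.exists():
        raise SystemExit("run 01_build_trial_dataset.py first")
    data = read_met_table(path, config)

    for trait, table in blup_tables(data, config).items():
        table.stats.to_csv(OUT / f"blup_stats_{trait}.csv")
        vc = table.components
        top = table.stats.sort_values("rank").index[:3]
        print(f"{trait}: sigma2_g={vc.sigma2_g:.4g} sigma2_ge={vc.sigma2_ge:.4g} "
              f"sigma2_eps={vc.sigma2_eps:.4g} ({vc.method}); "
              f"HMRPGV top 3: {', '.join(top)}")


if __name__ == "__main__":
    main()
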