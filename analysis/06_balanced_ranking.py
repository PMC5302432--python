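"""Combined "balanced genotype" ranking.

Aggregates the AMMI stability ranks and BLUP-HMRPGV ranks (yield + four
mineral nutritional yields) with the two selection-index ranks into a
mean-rank ordering: genotypes near the top of every list — high,
stable, adaptable and nutritious — surface first.
"""

from pathlib import Path

from nutmet import AnalysisConfig, read_met_table
from nutmet.pipeline import full_report

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results"


def main() -> None:
    config = AnalysisConfig()
    path = OUT / "trial_plots.csv"
    if not path.exists():
        raise SystemExit("run 01_build_trial_dataset.py first")
    data = read_met_table(path, config)

    tables = full_report(data, config)
    balanced = tables["balanced_ranking"]
    balanced.to_csv(OUT / "balanced_ranking.csv")
    print("combined balanced ranking (top 6):")
    for g, row in balanced.head(6).iterrows():
        print(f"  {int(row['rank']):2d}. {g:20s} mean rank {row['mean_rank']:.2f}")


if __name__ == "__main__":
    main()
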